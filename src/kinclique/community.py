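"""Daily affiliation communities and their turnover dynamics.

Daily weighted graphs are built from time-stamped dyadic events with an
exponential-decay memory (half-life in days); communities are detected by
the clique percolation method (CPM: two k-cliques are adjacent when they
share k-1 nodes; a community is a connected component of the k-clique
adjacency graph, so communities may overlap).  Day-to-day communities are
matched by maximal Jaccard overlap, giving per-individual turnover flags:

* EB  — existing member: in the matched community on both days;
* NFB — newly formed bond: joined the community that day;
* LND — leaving next day: absent from the next day's matched community.

The module also couples daily community size to the AMB-BB inter-band
distance (daily band centroids, haversine) and estimates the probability
of leaving as a function of outside-community contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import k_clique_communities
from scipy import stats

from .matrices import labelled_matrix

__all__ = [
    "edge_weights",
    "edge_weight_series",
    "cpm_communities",
    "track_communities",
    "band_distance",
    "haversine_m",
    "community_distance_model",
    "leave_probability",
    "CommunityTimeline",
    "DistanceModel",
]

EARTH_RADIUS_M = 6_371_000.0

#: Default distance-bin breakpoints (metres) for the cohesion model.
DEFAULT_DISTANCE_BINS = (200.0, 300.0, 900.0)


def _pair_events(events: pd.DataFrame) -> pd.DataFrame:
    cols = set(events.columns)
    if {"id_a", "id_b"} <= cols:
        out = events[["day", "id_a", "id_b"]].copy()
        if "together" in cols:
            out = out[events["together"].astype(bool).to_numpy()]
    elif {"initiator", "recipient"} <= cols:
        out = events.rename(columns={"initiator": "id_a",
                                     "recipient": "id_b"})[
            ["day", "id_a", "id_b"]].copy()
    else:
        raise ValueError("events need (id_a, id_b) or (initiator, recipient)")
    out["id_a"] = out["id_a"].astype(str)
    out["id_b"] = out["id_b"].astype(str)
    return out


def edge_weights(events: pd.DataFrame, day: int,
                 half_life_days: float = 14.0) -> pd.DataFrame:
    """Decayed dyadic affiliation weights on one day.

    w(a, b, t) = sum over event days s <= t of x(a, b, s) * 2^-((t-s)/hl)
    with x the day-s event count for the dyad.  ``half_life_days`` may be
    ``inf`` (cumulative counts).  Days before the first observation give
    an empty (all-zero) graph.
    """
    if not (half_life_days > 0):
        raise ValueError("half_life_days must be positive")
    series = edge_weight_series(events, days=[day],
                                half_life_days=half_life_days)
    return series[day]


def edge_weight_series(events: pd.DataFrame, days=None,
                       half_life_days: float = 14.0
                       ) -> dict[int, pd.DataFrame]:
    """Decayed weight matrices for a range of days (recursive update)."""
    if not (half_life_days > 0):
        raise ValueError("half_life_days must be positive")
    ev = _pair_events(events)
    ids = sorted(set(ev["id_a"]) | set(ev["id_b"]))
    idx = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    if days is None:
        if len(ev) == 0:
            raise ValueError("no events and no explicit day range")
        days = range(int(ev["day"].min()), int(ev["day"].max()) + 1)
    days = sorted(int(d) for d in days)
    decay = 0.5 ** (1.0 / half_life_days) if math.isfinite(half_life_days) else 1.0

    by_day: dict[int, np.ndarray] = {}
    for d, grp in ev.groupby("day"):
        x = np.zeros((n, n))
        a = grp["id_a"].map(idx).to_numpy()
        b = grp["id_b"].map(idx).to_numpy()
        np.add.at(x, (np.minimum(a, b), np.maximum(a, b)), 1.0)
        by_day[int(d)] = x + x.T

    out: dict[int, pd.DataFrame] = {}
    w = np.zeros((n, n))
    start = min(min(by_day, default=days[0]), days[0])
    d_prev = start - 1
    want = set(days)
    for d in range(start, max(days) + 1):
        w = w * decay ** (d - d_prev)
        if d in by_day:
            w = w + by_day[d]
        d_prev = d
        if d in want:
            out[d] = labelled_matrix(w.copy(), ids)
    for d in days:
        if d not in out:  # day precedes every observation
            out[d] = labelled_matrix(np.zeros((n, n)), ids)
    return out


def cpm_communities(weights: pd.DataFrame, k: int = 3,
                    w_star: float = 1.0) -> list[frozenset[str]]:
    """Clique-percolation communities on edges with weight >= w_star.

    Nodes may belong to several communities; every community contains at
    least one k-clique.  Returned sorted (size desc, then lexicographic)
    for determinism.
    """
    if k < 3:
        raise ValueError("k must be >= 3 for clique percolation")
    ids = list(weights.index)
    a = weights.to_numpy(dtype=float)
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if a[i, j] >= w_star:
                g.add_edge(ids[i], ids[j])
    comms = [frozenset(c) for c in k_clique_communities(g, k)]
    return sorted(comms, key=lambda c: (-len(c), tuple(sorted(c))))


@dataclass
class CommunityTimeline:
    """Per-day overlapping communities plus turnover flags.

    ``flags[d]`` is a dict with EB/NFB/LND membership sets for day ``d``;
    ``sizes`` is the daily size of the largest community (0 when no
    community forms).
    """

    days: list[int]
    communities: dict[int, list[frozenset[str]]]
    flags: dict[int, dict[str, set[str]]]
    sizes: pd.Series

    def members(self, day: int) -> set[str]:
        return set().union(*self.communities[day]) if self.communities[day] else set()


def _match(comm: frozenset, candidates: list[frozenset]) -> frozenset | None:
    """Best-Jaccard candidate; ties prefer the larger, then lexicographic."""
    best, best_key = None, None
    for cand in candidates:
        inter = len(comm & cand)
        union = len(comm | cand)
        jac = inter / union if union else 0.0
        key = (jac, len(cand), tuple(sorted(cand, reverse=True)))
        if jac > 0 and (best_key is None or key > best_key):
            best, best_key = cand, key
    return best


def track_communities(daily: dict[int, list[frozenset[str]]]
                      ) -> CommunityTimeline:
    """Build the turnover timeline from per-day community lists.

    Matching: each community on day t+1 is matched to the day-t community
    with maximal Jaccard overlap.  First-day members count as existing
    (EB); LND is undefined (left empty) on the final day.
    """
    days = sorted(daily)
    if len(days) < 2:
        raise ValueError("need at least 2 days to track turnover")
    flags: dict[int, dict[str, set[str]]] = {
        d: {"EB": set(), "NFB": set(), "LND": set()} for d in days}

    first = days[0]
    for comm in daily[first]:
        flags[first]["EB"] |= set(comm)

    for prev, cur in zip(days[:-1], days[1:]):
        matched_prev: dict[frozenset, frozenset | None] = {}
        for comm in daily[cur]:
            matched_prev[comm] = _match(comm, daily[prev])
        # forward flags for the current day
        for comm, m in matched_prev.items():
            stay = comm & m if m else set()
            flags[cur]["EB"] |= stay
            flags[cur]["NFB"] |= set(comm) - stay
        # leavers flagged on the previous day
        for pcomm in daily[prev]:
            successors = [c for c, m in matched_prev.items() if m == pcomm]
            kept = set().union(*successors) if successors else set()
            flags[prev]["LND"] |= set(pcomm) - kept
    # an individual can be NFB in one community and EB in another
    for d in days:
        flags[d]["NFB"] -= flags[d]["EB"]
    sizes = pd.Series(
        {d: (max(len(c) for c in daily[d]) if daily[d] else 0) for d in days})
    return CommunityTimeline(days=days, communities=daily, flags=flags,
                             sizes=sizes)


def haversine_m(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance in metres on a spherical Earth (R = 6371 km)."""
    lon1, lat1, lon2, lat2 = map(math.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = (math.sin(dlat / 2) ** 2
         + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2)
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(h))


def band_distance(gps_a: pd.DataFrame, gps_b: pd.DataFrame) -> pd.Series:
    """Daily inter-band distance: haversine between median daily centroids.

    Only days with fixes for both bands are reported.
    """
    for name, g in (("gps_a", gps_a), ("gps_b", gps_b)):
        if not {"day", "lon", "lat"} <= set(g.columns):
            raise ValueError(f"{name} needs day, lon, lat columns")
    ca = gps_a.groupby("day")[["lon", "lat"]].median()
    cb = gps_b.groupby("day")[["lon", "lat"]].median()
    days = sorted(set(ca.index) & set(cb.index))
    out = {}
    for d in days:
        out[d] = haversine_m(ca.at[d, "lon"], ca.at[d, "lat"],
                             cb.at[d, "lon"], cb.at[d, "lat"])
    return pd.Series(out, name="distance_m")


@dataclass(frozen=True)
class DistanceModel:
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    bin_means: pd.Series
    n_days: int


def community_distance_model(sizes: pd.Series, distances: pd.Series,
                             bins=DEFAULT_DISTANCE_BINS) -> DistanceModel:
    """Correlate daily community size with inter-band distance.

    Sizes and distances are matched on their day index (>= 10 paired days
    required).  Bin means use the breakpoints <b1, b1-b2, b2-b3, >b3
    (defaults 200 / 300 / 900 m).  Constant series give r = 0, p = 1.
    """
    days = sorted(set(sizes.index) & set(distances.index))
    if len(days) < 10:
        raise ValueError(f"need >= 10 paired days, got {len(days)}")
    s = sizes.loc[days].to_numpy(dtype=float)
    d = distances.loc[days].to_numpy(dtype=float)
    if np.ptp(s) == 0 or np.ptp(d) == 0:
        pearson = spearman = (0.0, 1.0)
    else:
        pearson = stats.pearsonr(s, d)
        spearman = stats.spearmanr(s, d)
    edges = [-np.inf, *bins, np.inf]
    labels = [f"<{bins[0]:g}"] + [
        f"{lo:g}-{hi:g}" for lo, hi in zip(bins[:-1], bins[1:])
    ] + [f">{bins[-1]:g}"]
    cats = pd.cut(d, bins=edges, labels=labels)
    bin_means = pd.Series(s).groupby(cats, observed=False).mean()
    return DistanceModel(pearson_r=float(pearson[0]), pearson_p=float(pearson[1]),
                         spearman_r=float(spearman[0]),
                         spearman_p=float(spearman[1]),
                         bin_means=bin_means, n_days=len(days))


def leave_probability(timeline: CommunityTimeline,
                      outside_contact: pd.DataFrame,
                      bins=(0.0, 1.0, 2.0, 4.0)) -> pd.DataFrame:
    """P(leave next day) as a function of outside-community contact.

    ``outside_contact`` holds per-individual-day contact rates (columns
    ``day``, ``id``, ``rate``).  Person-days are community members on days
    where LND status is defined (all but the final day); the probability
    per contact bin is (LND person-days) / (member person-days).  Empty
    bins report NaN.
    """
    if not {"day", "id", "rate"} <= set(outside_contact.columns):
        raise ValueError("outside_contact needs day, id, rate columns")
    rate = {(int(r.day), str(r.id)): float(r.rate)
            for r in outside_contact.itertuples()}
    rows = []
    for d in timeline.days[:-1]:
        members = timeline.members(d)
        for ind in members:
            key = (d, ind)
            if key not in rate:
                continue
            rows.append({"rate": rate[key],
                         "left": ind in timeline.flags[d]["LND"]})
    if not rows:
        raise ValueError("no leave events / person-days with contact rates")
    df = pd.DataFrame(rows)
    edges = [-np.inf, *bins, np.inf]
    labels = [f"<={bins[0]:g}"] + [
        f"{lo:g}-{hi:g}" for lo, hi in zip(bins[:-1], bins[1:])
    ] + [f">{bins[-1]:g}"]
    cats = pd.cut(df["rate"], bins=edges, labels=labels)
    grouped = df.groupby(cats, observed=False)["left"]
    out = pd.DataFrame({
        "person_days": grouped.size(),
        "leaves": grouped.sum(),
    })
    out["p_leave"] = out["leaves"] / out["person_days"]
    out.loc[out["person_days"] == 0, "p_leave"] = np.nan
    return out
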