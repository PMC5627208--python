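"""Association and interaction networks of the bachelor band.

Half-weight index (HWI) association matrices from scan samples, directional
affiliation index (DAI) interaction matrices from grooming bouts,
hierarchical clustering of the association network into all-male units
(AMUs), and sociogram filtering/export.

The HWI is the Cairns & Schwager half-weight form: for a dyad (a, b),

    HWI = x / (x + y_ab + (y_a + y_b) / 2)

where, over sampling periods (scans), x counts periods with the two seen
together, y_ab periods with both seen but apart, and y_a (y_b) periods with
only a (only b) seen.  The DAI defaults to the initiator-normalised
grooming share DAI_ij = G_ij / sum_k G_ik, with alternative denominators
behind a switch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from .matrices import check_square_labelled, labelled_matrix

__all__ = [
    "compute_hwi",
    "compute_dai",
    "cluster_subgroups",
    "filter_sociogram",
    "eigenvector_centrality",
    "group_mean_contrast",
    "SubgroupPartition",
]

logger = logging.getLogger(__name__)


def compute_hwi(scans: pd.DataFrame) -> pd.DataFrame:
    """Half-weight association index from a dyadic scan table.

    ``scans`` needs columns ``scan_id``, ``id_a``, ``id_b``, ``together``.
    An individual is "seen" in a scan if it appears in any dyadic row of
    that scan.  Dyads never co-observed score 0; an individual never
    observed at all gets NaN everywhere (excluded downstream).
    """
    required = {"scan_id", "id_a", "id_b", "together"}
    missing = required - set(scans.columns)
    if missing:
        raise ValueError(f"scan table lacks columns {sorted(missing)}")
    if len(scans) == 0:
        raise ValueError("need at least one scan record")

    ids = sorted(set(scans["id_a"].astype(str)) | set(scans["id_b"].astype(str)))
    id_idx = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    scan_codes, scan_uniques = pd.factorize(scans["scan_id"], sort=True)
    n_scans = len(scan_uniques)

    a = scans["id_a"].astype(str).map(id_idx).to_numpy()
    b = scans["id_b"].astype(str).map(id_idx).to_numpy()
    together = scans["together"].to_numpy().astype(bool)

    # presence[s, i]: individual i appears in some row of scan s
    presence = np.zeros((n_scans, n), dtype=bool)
    presence[scan_codes, a] = True
    presence[scan_codes, b] = True

    # x: scans in which the dyad has a together=1 record
    x = np.zeros((n, n))
    pairs = pd.DataFrame({"s": scan_codes[together],
                          "a": np.minimum(a, b)[together],
                          "b": np.maximum(a, b)[together]})
    pairs = pairs.drop_duplicates()
    np.add.at(x, (pairs["a"].to_numpy(), pairs["b"].to_numpy()), 1.0)
    x = x + x.T

    both = presence.astype(float).T @ presence.astype(float)  # co-seen scans
    seen = np.diag(both).copy()
    y_ab = both - x
    y_only = seen[:, None] - both  # seen a, not b (rows: a)
    denom = x + y_ab + 0.5 * (y_only + y_only.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        hwi = np.where(denom > 0, x / denom, 0.0)
    never_seen = seen == 0
    hwi[never_seen, :] = np.nan
    hwi[:, never_seen] = np.nan
    np.fill_diagonal(hwi, 0.0)
    return labelled_matrix(hwi, ids)


def compute_dai(grooming: pd.DataFrame, mode: str = "initiator_share",
                ids: list[str] | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directional affiliation index and raw counts from grooming bouts.

    ``grooming`` needs columns ``initiator`` and ``recipient``.  Modes:

    - ``initiator_share`` (default): DAI_ij = G_ij / sum_k G_ik; an
      individual with no initiated bouts has an all-zero row.
    - ``dyadic_sum``: DAI_ij = G_ij / (G_ij + G_ji).
    - ``total_share``: DAI_ij = G_ij / sum of all bouts.

    Returns ``(dai, counts)``.  Self-grooming records are a data error.
    """
    required = {"initiator", "recipient"}
    missing = required - set(grooming.columns)
    if missing:
        raise ValueError(f"grooming table lacks columns {sorted(missing)}")
    if len(grooming) == 0 and ids is None:
        raise ValueError("need at least one grooming bout (or explicit ids)")
    ini = grooming["initiator"].astype(str)
    rec = grooming["recipient"].astype(str)
    if (ini == rec).any():
        bad = grooming.index[(ini == rec)][0]
        raise ValueError(f"self-grooming record at row {bad}")
    if ids is None:
        ids = sorted(set(ini) | set(rec))
    idx = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    g = np.zeros((n, n))
    np.add.at(g, (ini.map(idx).to_numpy(), rec.map(idx).to_numpy()), 1.0)
    if mode == "initiator_share":
        rows = g.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            dai = np.where(rows > 0, g / rows, 0.0)
    elif mode == "dyadic_sum":
        tot = g + g.T
        with np.errstate(invalid="ignore", divide="ignore"):
            dai = np.where(tot > 0, g / tot, 0.0)
    elif mode == "total_share":
        total = g.sum()
        dai = g / total if total > 0 else g
    else:
        raise ValueError(f"unknown DAI mode {mode!r}")
    np.fill_diagonal(dai, 0.0)
    return labelled_matrix(dai, ids), labelled_matrix(g, ids)


@dataclass
class SubgroupPartition:
    """Hierarchical-clustering partition of the band into AMUs."""

    assignment: dict[str, str]
    linkage: np.ndarray          # scipy linkage matrix on 1 - HWI
    cliquishness: float          # Newman modularity Q of the chosen cut
    n_groups: int

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for ind, g in self.assignment.items():
            out.setdefault(g, []).append(ind)
        return {g: sorted(m) for g, m in sorted(out.items())}


def _modularity(hwi: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity Q of a partition on a weighted graph."""
    w = hwi.copy()
    np.fill_diagonal(w, 0.0)
    two_m = w.sum()
    if two_m == 0:
        return 0.0
    k = w.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((w - np.outer(k, k) / two_m) * same).sum() / two_m)


def cluster_subgroups(hwi: pd.DataFrame, linkage: str = "average",
                      n_groups: int | None = None) -> SubgroupPartition:
    """Agglomerative clustering of the association matrix into subgroups.

    Distance is 1 - HWI.  If ``n_groups`` is omitted, the dendrogram cut
    is chosen by maximum Newman modularity Q of the induced partition on
    the weighted HWI graph; Q of the chosen cut is reported as the
    cliquishness coefficient.
    """
    check_square_labelled(hwi)
    ids = sorted(hwi.index)
    hwi = hwi.reindex(index=ids, columns=ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    a = hwi.to_numpy(dtype=float).copy()
    if np.isnan(a).any():
        raise ValueError("HWI matrix has undefined entries; drop those "
                         "individuals before clustering")
    np.fill_diagonal(a, 0.0)
    if a.sum() == 0:
        logger.warning("all-zero association matrix: single cluster")
        return SubgroupPartition(
            assignment={i: "G1" for i in ids},
            linkage=np.empty((0, 4)), cliquishness=0.0, n_groups=1)
    dist = 1.0 - a
    np.fill_diagonal(dist, 0.0)
    z = sch.linkage(squareform(dist, checks=False), method=linkage)
    if n_groups is not None:
        if not (1 <= n_groups <= n):
            raise ValueError("n_groups out of range")
        flat = sch.fcluster(z, t=n_groups, criterion="maxclust")
        q = _modularity(a, flat)
        chosen = flat
    else:
        best_q, chosen = -np.inf, None
        for k in range(1, n + 1):
            flat = sch.fcluster(z, t=k, criterion="maxclust")
            q = _modularity(a, flat)
            if q > best_q + 1e-12:
                best_q, chosen = q, flat
        q = best_q
    # relabel clusters deterministically by first (sorted) member
    order: dict[int, str] = {}
    for ind, c in sorted(zip(ids, chosen)):
        if c not in order:
            order[c] = f"G{len(order) + 1}"
    assignment = {ind: order[c] for ind, c in zip(ids, chosen)}
    return SubgroupPartition(assignment=assignment, linkage=z,
                             cliquishness=float(q),
                             n_groups=len(set(chosen)))


def eigenvector_centrality(matrix: pd.DataFrame) -> pd.Series:
    """Principal-eigenvector centrality of a symmetric weight matrix.

    Non-negative and unit (L2) normalised.
    """
    check_square_labelled(matrix)
    a = matrix.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    vals, vecs = np.linalg.eigh(a)
    v = vecs[:, np.argmax(vals)]
    v = np.abs(v)
    norm = np.linalg.norm(v)
    if norm > 0:
        v = v / norm
    return pd.Series(v, index=matrix.index)


def filter_sociogram(matrix: pd.DataFrame, threshold: float,
                     node_attrs: pd.DataFrame | None = None,
                     directed: bool = False) -> nx.Graph:
    """Threshold a weight matrix into a sociogram graph.

    Edges with weight >= ``threshold`` are kept (the boundary is closed:
    a weight exactly at the threshold survives).  Node attributes (e.g.
    NDS, eigenvector centrality, subgroup, age class) are attached from
    ``node_attrs`` rows for export.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    check_square_labelled(matrix)
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    ids = list(matrix.index)
    g.add_nodes_from(ids)
    a = matrix.to_numpy(dtype=float)
    for i, u in enumerate(ids):
        js = range(len(ids)) if directed else range(i + 1, len(ids))
        for j in js:
            if j == i:
                continue
            w = a[i, j]
            if np.isfinite(w) and w >= threshold:
                g.add_edge(u, ids[j], weight=float(w))
    if node_attrs is not None:
        for col in node_attrs.columns:
            for ind in ids:
                if ind in node_attrs.index:
                    g.nodes[ind][col] = node_attrs.at[ind, col]
    return g


def group_mean_contrast(matrix: pd.DataFrame, groups: dict[str, str]
                        ) -> tuple[float, float]:
    """(mean within-group dyad value, mean between-group dyad value)."""
    check_square_labelled(matrix)
    ids = list(matrix.index)
    lab = np.array([groups[i] for i in ids])
    a = matrix.to_numpy(dtype=float)
    iu = np.triu_indices(len(ids), k=1)
    same = lab[iu[0]] == lab[iu[1]]
    tri = a[iu]
    ok = np.isfinite(tri)
    within = tri[same & ok]
    between = tri[~same & ok]
    return (float(within.mean()) if within.size else float("nan"),
            float(between.mean()) if between.size else float("nan"))
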