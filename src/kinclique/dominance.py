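"""Dominance hierarchies from agonistic bouts.

Win/loss matrices, David's scores (DS) and normalised David's scores
(NDS), hierarchy steepness, and Landau linearity with the correction for
unknown relationships.

David's score for individual i combines its dyadic win proportions with
an unweighted and a weighted sum of its dyadic loss proportions::

    DS_i = w_i + w2_i - l_i - l2_i
    w_i  = sum_j P_ij          w2_i = sum_j P_ij * w_j
    l_i  = sum_j P_ji          l2_i = sum_j P_ji * l_j

with P_ij the proportion of the dyad's bouts won by i (the Dij variant
applies the sample-size shrinkage D_ij = P_ij - (P_ij - 0.5)/(n_ij + 1)).
NDS_i = (DS_i + N(N-1)/2)/N maps the scores onto [0, N-1].  Steepness is
the absolute OLS slope of NDS against rank position 1..N (1 = despotic,
0 = egalitarian); significance comes from randomising bout outcomes
within dyads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import check_square_labelled, labelled_matrix

__all__ = [
    "build_conflict_matrix",
    "david_scores",
    "hierarchy_steepness",
    "hierarchy_linearity",
    "DominanceResult",
    "SteepnessResult",
    "LinearityResult",
    "AGONISTIC_BEHAVIOURS",
    "SUBMISSIVE_BEHAVIOURS",
]

logger = logging.getLogger(__name__)

#: Default ethogram mapping: which behaviour labels count as agonism and
#: which responses count as submission (a decided bout).
AGONISTIC_BEHAVIOURS = ("biting", "fighting", "chasing", "lunging",
                        "supplanting", "vocal_threat")
SUBMISSIVE_BEHAVIOURS = ("avoidance", "fleeing", "crouching")


def build_conflict_matrix(agonistic: pd.DataFrame,
                          agonistic_behaviours=AGONISTIC_BEHAVIOURS,
                          submissive_behaviours=SUBMISSIVE_BEHAVIOURS,
                          ids: list[str] | None = None,
                          ) -> tuple[pd.DataFrame, dict]:
    """Win-count matrix from decided agonistic bouts.

    A bout where the actor shows a listed agonistic behaviour and the
    recipient responds with a listed submissive behaviour (``outcome``
    column) increments wins[actor, recipient].  Undecided bouts are
    excluded and counted; records with unknown behaviour labels are
    rejected with a logged reason.

    Returns ``(wins, report)`` with report counts of used/undecided/
    rejected records.
    """
    required = {"actor", "recipient", "behaviour", "outcome"}
    missing = required - set(agonistic.columns)
    if missing:
        raise ValueError(f"agonistic table lacks columns {sorted(missing)}")
    actor = agonistic["actor"].astype(str)
    recip = agonistic["recipient"].astype(str)
    if ids is None:
        ids = sorted(set(actor) | set(recip))
    idx = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    wins = np.zeros((n, n))
    n_used = n_undecided = n_rejected = 0
    known_beh = set(agonistic_behaviours)
    known_sub = set(submissive_behaviours)
    for row in agonistic.itertuples(index=True):
        beh = str(row.behaviour)
        if beh not in known_beh:
            n_rejected += 1
            logger.warning("row %s: unknown behaviour %r rejected",
                           row.Index, beh)
            continue
        outcome = str(row.outcome)
        if outcome in known_sub:
            wins[idx[str(row.actor)], idx[str(row.recipient)]] += 1
            n_used += 1
        else:
            n_undecided += 1
    report = {"used": n_used, "undecided": n_undecided,
              "rejected": n_rejected}
    return labelled_matrix(wins, ids), report


def _win_proportions(wins: np.ndarray, dyadic: str) -> np.ndarray:
    n = wins.shape[0]
    total = wins + wins.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, wins / total, 0.0)
    if dyadic == "Dij":
        d = np.where(total > 0, p - (p - 0.5) / (total + 1), 0.5)
        np.fill_diagonal(d, 0.0)
        return d
    if dyadic != "Pij":
        raise ValueError(f"dyadic must be 'Pij' or 'Dij', got {dyadic!r}")
    np.fill_diagonal(p, 0.0)
    return p


@dataclass
class DominanceResult:
    ds: pd.Series
    nds: pd.Series
    rank_order: list[str]       # descending NDS, ties by label
    p_matrix: pd.DataFrame
    dyadic: str

    @property
    def n(self) -> int:
        return len(self.ds)


def david_scores(wins: pd.DataFrame, dyadic: str = "Pij") -> DominanceResult:
    """David's scores and normalised David's scores from a win matrix.

    Dyads with zero interactions contribute 0 to both directions under
    the ``Pij`` mode and the shrunk prior 0.5 under ``Dij``.
    """
    check_square_labelled(wins)
    ids = list(wins.index)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    w = wins.to_numpy(dtype=float)
    if (w < 0).any():
        raise ValueError("win counts must be non-negative")
    p = _win_proportions(w, dyadic)
    wsum = p.sum(axis=1)
    lsum = p.sum(axis=0)
    w2 = p @ wsum
    l2 = p.T @ lsum
    ds = wsum + w2 - lsum - l2
    nds = (ds + n * (n - 1) / 2.0) / n
    ds_s = pd.Series(ds, index=ids)
    nds_s = pd.Series(nds, index=ids)
    order = sorted(ids, key=lambda i: (-nds_s[i], i))
    return DominanceResult(ds=ds_s, nds=nds_s, rank_order=order,
                           p_matrix=labelled_matrix(p, ids), dyadic=dyadic)


def _steepness_stat(nds: np.ndarray) -> tuple[float, float]:
    """(|slope|, R^2) of sorted-descending NDS on rank positions 1..N."""
    y = np.sort(nds)[::-1]
    x = np.arange(1, y.size + 1, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    syy = float(yc @ yc)
    r2 = (slope**2 * sxx / syy) if syy > 0 else 1.0
    return abs(slope), r2


@dataclass(frozen=True)
class SteepnessResult:
    steepness: float
    r2: float
    p: float
    n_perm: int


def hierarchy_steepness(wins: pd.DataFrame, dyadic: str = "Pij",
                        n_perm: int = 1000, seed: int | None = None
                        ) -> SteepnessResult:
    """Hierarchy steepness K with a matrix-randomisation P value.

    K = |OLS slope| of NDS against rank position; the null redraws each
    dyad's wins as Binomial(n_ij, 1/2) keeping the interaction counts,
    and P is the fraction of randomisations with K at least as large
    (with the +1 correction).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    check_square_labelled(wins)
    n = wins.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals")
    res = david_scores(wins, dyadic=dyadic)
    k_obs, r2 = _steepness_stat(res.nds.to_numpy())
    rng = np.random.default_rng(seed)
    w = wins.to_numpy(dtype=float)
    iu = np.triu_indices(n, k=1)
    totals = (w + w.T)[iu].astype(int)
    n_exceed = 0
    for _ in range(n_perm):
        upper = rng.binomial(totals, 0.5)
        wp = np.zeros_like(w)
        wp[iu] = upper
        wp.T[iu] = totals - upper
        p = _win_proportions(wp, dyadic)
        wsum = p.sum(axis=1)
        lsum = p.sum(axis=0)
        ds = wsum + p @ wsum - lsum - p.T @ lsum
        nds = (ds + n * (n - 1) / 2.0) / n
        k_perm, _ = _steepness_stat(nds)
        if k_perm >= k_obs:
            n_exceed += 1
    return SteepnessResult(steepness=k_obs, r2=r2,
                           p=(n_exceed + 1) / (n_perm + 1), n_perm=n_perm)


def _landau_h(wins: np.ndarray) -> tuple[float, float, int]:
    """(h, h_corrected, n_unknown) for a win-count matrix.

    Dominance score S_ij = 1 if i won more bouts, 0 if fewer, 0.5 for
    tied or unknown (no-interaction) dyads.  h = 12/(N^3 - N) *
    sum_i (V_i - (N-1)/2)^2 with V_i = sum_j S_ij; the correction adds
    the expectation of randomly resolving the u unknown dyads:
    h' = h + 6u/(N^3 - N).
    """
    n = wins.shape[0]
    total = wins + wins.T
    s = np.where(wins > wins.T, 1.0, np.where(wins < wins.T, 0.0, 0.5))
    np.fill_diagonal(s, 0.0)
    v = s.sum(axis=1)
    h = 12.0 / (n**3 - n) * float(((v - (n - 1) / 2.0) ** 2).sum())
    iu = np.triu_indices(n, k=1)
    n_unknown = int((total[iu] == 0).sum())
    h_corr = h + 6.0 * n_unknown / (n**3 - n)
    return h, h_corr, n_unknown


@dataclass(frozen=True)
class LinearityResult:
    h: float
    h_corrected: float
    n_unknown_dyads: int
    p: float
    n_perm: int


def hierarchy_linearity(wins: pd.DataFrame, n_perm: int = 1000,
                        seed: int | None = None) -> LinearityResult:
    """Landau linearity h with the unknown-relationship correction.

    The randomisation null assigns each known dyad's direction at random
    (unknown dyads stay unknown) and P is the fraction of randomisations
    with corrected h at least the observed value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    check_square_labelled(wins)
    n = wins.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals")
    w = wins.to_numpy(dtype=float)
    h, h_corr, n_unknown = _landau_h(w)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    known = (w + w.T)[iu] > 0
    n_exceed = 0
    for _ in range(n_perm):
        direction = rng.random(known.size) < 0.5
        wp = np.zeros_like(w)
        up = (known & direction).astype(float)
        lo = (known & ~direction).astype(float)
        wp[iu] = up
        wp.T[iu] = lo
        _, hp, _ = _landau_h(wp)
        if hp >= h_corr:
            n_exceed += 1
    return LinearityResult(h=h, h_corrected=h_corr,
                           n_unknown_dyads=n_unknown,
                           p=(n_exceed + 1) / (n_perm + 1), n_perm=n_perm)
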