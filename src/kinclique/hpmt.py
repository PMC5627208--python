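"""Higher-order partial Mantel test (HPMT) with contribution rates.

The statistical core of the package.  A standard Mantel test measures the
correlation between two dyadic matrices (say, spatial association and
pairwise relatedness) with significance from joint row-and-column
permutations.  The first-order partial Mantel test (Smouse, Long & Sokal)
controls a single third matrix.  The HPMT extends this recursively: the
kth-order partial correlation between the tested matrix **X** and the
dependent matrix **Y**, controlling **Z**\\ :sub:`1` … **Z**\\ :sub:`k`, is
built from three (k−1)th-order partials::

    r_xy.z1..zk = (r_xy.z1..z(k-1) − r_xzk.z1..z(k-1) · r_yzk.z1..z(k-1))
                  / sqrt((1 − r_xzk.z1..z(k-1)²)(1 − r_yzk.z1..z(k-1)²))

Significance is Monte-Carlo: **X** alone is permuted (rows and columns
jointly) n₂ times; with n₁ permutations at least as extreme as the observed
statistic, the unbiased P is (n₁ + 1)/(n₂ + 1).

Two summary quantities follow.  The coefficient of multiple determination
of factors X₁..X_m on Y is

    R² = 1 − Π_i (1 − r²_{Y Xi · X1..X(i−1)}),

and the contribution rate (CR) of a factor is the drop in R² when that
factor is removed: CR_f = R²(all) − R²(all \\ f).  CR lies in [0, 1] and the
CRs of all factors sum to at most R²(all).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import align_matrices, upper_triangle

__all__ = [
    "matrix_pearson",
    "partial_r",
    "mantel",
    "hpmt_test",
    "multiple_determination",
    "contribution_rates",
    "hpmt_analysis",
    "label_permutation_test",
    "HpmtResult",
    "HpmtAnalysis",
    "LabelPermutationResult",
]

_CR_CLIP_TOL = 1e-9


class DegenerateControlError(ValueError):
    """A control matrix is perfectly correlated with X or Y at some
    recursion level, so the partial correlation is undefined."""


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance dyad vector: correlation undefined")
    return (v - v.mean()) / sd


def matrix_pearson(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Pearson correlation over the strict upper triangles of two
    identically labelled square matrices."""
    a, b = align_matrices(a, b)
    if a.shape[0] < 4:
        raise ValueError("need at least 4 individuals for a matrix correlation")
    va, vb = _standardize(upper_triangle(a)), _standardize(upper_triangle(b))
    return float(va @ vb / va.size)


def partial_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of (x, y) controlling z."""
    for r in (r_xy, r_xz, r_yz):
        if abs(r) > 1 + 1e-12:
            raise ValueError(f"correlation {r} outside [-1, 1]")
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 0:
        raise DegenerateControlError(
            "control matrix perfectly correlated with x or y"
        )
    return (r_xy - r_xz * r_yz) / np.sqrt(denom)


def _recursive_partial(corr: np.ndarray, i: int, j: int,
                       controls: tuple[int, ...]) -> np.ndarray:
    """kth-order partial correlation from a stack of correlation matrices.

    ``corr`` has shape ``(..., m, m)``; the leading axes (if any) index
    permutation replicates.  Controls are peeled from the end, one per
    recursion level, exactly as the defining recursion states.
    """
    if not controls:
        return corr[..., i, j]
    k = controls[-1]
    rest = controls[:-1]
    r_ij = _recursive_partial(corr, i, j, rest)
    r_ik = _recursive_partial(corr, i, k, rest)
    r_jk = _recursive_partial(corr, j, k, rest)
    denom = (1.0 - r_ik**2) * (1.0 - r_jk**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (r_ij - r_ik * r_jk) / np.sqrt(denom)
    return out


@dataclass(frozen=True)
class HpmtResult:
    """Result of a (higher-order partial) Mantel test."""

    r: float
    p: float
    order: int
    n_perm: int
    n_exceed: int
    alternative: str
    n_individuals: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"HpmtResult(r={self.r:.4f}, p={self.p:.4g}, "
                f"order={self.order}, n_perm={self.n_perm})")


def _observed_partial(y: pd.DataFrame, x: pd.DataFrame,
                      controls: list[pd.DataFrame]) -> float:
    mats = align_matrices(x, y, *controls)
    tris = [_standardize(upper_triangle(m)) for m in mats]
    m = len(tris)
    corr = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            corr[i, j] = corr[j, i] = tris[i] @ tris[j] / tris[i].size
    r = float(_recursive_partial(corr, 0, 1, tuple(range(2, m))))
    if not np.isfinite(r):
        raise DegenerateControlError(
            "partial correlation undefined: a control is collinear with "
            "the tested or dependent matrix"
        )
    return r


def hpmt_test(y: pd.DataFrame, x: pd.DataFrame,
              controls: list[pd.DataFrame] | None = None,
              n_perm: int = 999, seed: int | None = None,
              alternative: str = "greater") -> HpmtResult:
    """Higher-order partial Mantel test of X against Y controlling Z₁..Z_k.

    Parameters
    ----------
    y, x
        Dependent and tested matrices (identical id sets).
    controls
        Matrices controlled for; ``k = len(controls)``.  With no controls
        this is exactly a standard Mantel test.
    n_perm
        Number of joint row-and-column permutations of X (Y and the
        controls stay fixed).
    alternative
        ``"greater"`` (default): n1 counts permutations with r strictly
        greater than observed — the one-sided test of positive
        association defined by the unbiased-P formula, and the only
        variant calibrated at the nominal level under the null.
        ``"less"`` mirrors it; ``"two-sided"`` uses absolute values;
        ``"observed-direction"`` tests towards the sign of the observed
        statistic (anti-conservative by construction: its null
        rejection rate is about twice nominal).

    Notes
    -----
    Permutation replicates whose recursion hits a degenerate denominator
    (numerically collinear permuted X) yield NaN and are counted as not
    exceeding; the observed statistic itself raises instead.
    """
    controls = list(controls or [])
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less", "two-sided",
                           "observed-direction"):
        raise ValueError(f"unknown alternative {alternative!r}")
    mats = align_matrices(x, y, *controls)
    n = mats[0].shape[0]
    if n < 4:
        raise ValueError("need at least 4 individuals")
    tris = [_standardize(upper_triangle(m)) for m in mats]
    ndyad = tris[0].size
    m = len(tris)

    corr = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            corr[i, j] = corr[j, i] = tris[i] @ tris[j] / ndyad
    r_obs = float(_recursive_partial(corr, 0, 1, tuple(range(2, m))))
    if not np.isfinite(r_obs):
        raise DegenerateControlError(
            "observed partial correlation undefined (collinear control)"
        )

    # Permute X's rows and columns jointly, then rebuild only the
    # correlations that involve X; everything else is fixed.
    rng = np.random.default_rng(seed)
    xmat = mats[0].to_numpy(dtype=float)
    iu = np.triu_indices(n, k=1)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    x_perm = xmat[perms[:, iu[0]], perms[:, iu[1]]]           # (n_perm, ndyad)
    mu = x_perm.mean(axis=1, keepdims=True)
    sd = x_perm.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        x_std = (x_perm - mu) / sd
    others = np.stack(tris[1:], axis=0)                       # (m-1, ndyad)
    r_x_other = x_std @ others.T / ndyad                      # (n_perm, m-1)

    corr_perm = np.broadcast_to(corr, (n_perm, m, m)).copy()
    corr_perm[:, 0, 1:] = r_x_other
    corr_perm[:, 1:, 0] = r_x_other
    r_perm = _recursive_partial(corr_perm, 0, 1, tuple(range(2, m)))
    r_perm = np.asarray(r_perm, dtype=float)

    # n1 counts permutations STRICTLY more extreme than the observed
    # statistic, matching the unbiased-P formula p = (n1 + 1)/(n2 + 1).
    finite = np.isfinite(r_perm)
    if alternative == "two-sided":
        n_exceed = int(np.sum(np.abs(r_perm[finite]) > abs(r_obs)))
    elif alternative == "less":
        n_exceed = int(np.sum(r_perm[finite] < r_obs))
    elif alternative == "greater" or r_obs >= 0:
        n_exceed = int(np.sum(r_perm[finite] > r_obs))
    else:  # observed-direction with negative observed statistic
        n_exceed = int(np.sum(r_perm[finite] < r_obs))
    p = (n_exceed + 1) / (n_perm + 1)
    return HpmtResult(r=r_obs, p=p, order=len(controls), n_perm=n_perm,
                      n_exceed=n_exceed, alternative=alternative,
                      n_individuals=n)


def mantel(a: pd.DataFrame, b: pd.DataFrame, n_perm: int = 999,
           seed: int | None = None,
           alternative: str = "greater") -> HpmtResult:
    """Standard Mantel test: the order-0 special case of :func:`hpmt_test`."""
    return hpmt_test(b, a, controls=None, n_perm=n_perm, seed=seed,
                     alternative=alternative)


def multiple_determination(y: pd.DataFrame,
                           factors: list[pd.DataFrame]) -> float:
    """Coefficient of multiple determination of the factors on Y.

    Computed sequentially, R² = 1 − Π (1 − r²_{Y Xi · X1..X(i−1)}); the
    result is invariant to factor order up to floating tolerance.
    """
    if len(factors) < 1:
        raise ValueError("need at least one factor")
    prod = 1.0
    for i, f in enumerate(factors):
        prev = list(factors[:i])
        try:
            r = _observed_partial(y, f, prev)
        except DegenerateControlError:
            if prev and _in_span(f, prev):
                # factor carries no information beyond the previous ones
                continue
            raise
        prod *= 1.0 - r**2
    return 1.0 - prod


def _in_span(f: pd.DataFrame, others: list[pd.DataFrame],
             tol: float = 1e-9) -> bool:
    """Is f's dyad vector (numerically) in the affine span of the others?"""
    mats = align_matrices(f, *others)
    v = upper_triangle(mats[0])
    z = np.column_stack([np.ones(v.size)]
                        + [upper_triangle(m) for m in mats[1:]])
    resid = v - z @ np.linalg.lstsq(z, v, rcond=None)[0]
    scale = max(float(np.var(v)), 1.0)
    return float(np.var(resid)) < tol * scale


def contribution_rates(y: pd.DataFrame, factors: dict[str, pd.DataFrame]
                       ) -> tuple[dict[str, float], float]:
    """Per-factor contribution rates and the full-model R².

    CR_f = R²(all factors) − R²(all except f).  Tiny negative values from
    floating error are clipped to 0; a negative beyond tolerance warns.
    """
    if not factors:
        raise ValueError("need at least one factor")
    names = list(factors)
    all_mats = [factors[k] for k in names]
    r2_full = multiple_determination(y, all_mats)
    crs: dict[str, float] = {}
    for name in names:
        rest = [factors[k] for k in names if k != name]
        r2_red = multiple_determination(y, rest) if rest else 0.0
        cr = r2_full - r2_red
        if cr < -_CR_CLIP_TOL:
            warnings.warn(
                f"contribution rate for {name!r} negative ({cr:.3g}); "
                "clipped to 0", stacklevel=2)
        crs[name] = max(cr, 0.0)
    return crs, r2_full


@dataclass(frozen=True)
class HpmtAnalysis:
    """Full multi-factor attribution: per-factor partial tests + CRs."""

    tests: dict[str, HpmtResult]
    cr: dict[str, float]
    r2_full: float

    def to_dict(self) -> dict:
        return {
            "r2_full": self.r2_full,
            "factors": {
                name: {"r": t.r, "p": t.p, "order": t.order,
                       "n_perm": t.n_perm, "cr": self.cr[name]}
                for name, t in self.tests.items()
            },
        }


def hpmt_analysis(y: pd.DataFrame, factors: dict[str, pd.DataFrame],
                  n_perm: int = 999, seed: int | None = None,
                  alternative: str = "greater") -> HpmtAnalysis:
    """Test each factor against Y controlling all the others, and report
    contribution rates — the headline multi-factor attribution."""
    names = list(factors)
    rng = np.random.default_rng(seed)
    tests = {}
    for name in names:
        controls = [factors[k] for k in names if k != name]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        tests[name] = hpmt_test(y, factors[name], controls,
                                n_perm=n_perm, seed=sub_seed,
                                alternative=alternative)
    cr, r2_full = contribution_rates(y, factors)
    return HpmtAnalysis(tests=tests, cr=cr, r2_full=r2_full)


@dataclass(frozen=True)
class LabelPermutationResult:
    statistic: float
    p: float
    n_perm: int
    n_exceed: int
    mean_within: float
    mean_between: float


def label_permutation_test(values: pd.DataFrame, groups: dict[str, str],
                           n_perm: int = 999, seed: int | None = None
                           ) -> LabelPermutationResult:
    """Matrix permutation test for within- vs between-group dyad means.

    The statistic is mean(within-group dyads) − mean(between-group dyads);
    the null permutes individual group labels.  One-sided P (larger
    within-group mean) as (n₁ + 1)/(n₂ + 1).
    """
    values, = align_matrices(values)
    ids = list(values.index)
    try:
        labels = np.array([groups[i] for i in ids])
    except KeyError as e:
        raise ValueError(f"no group label for individual {e.args[0]!r}")
    if len(set(labels)) < 2:
        raise ValueError("need at least two groups for a between-group mean")
    a = values.to_numpy(dtype=float)
    iu = np.triu_indices(len(ids), k=1)
    tri = a[iu]

    def stat(lab: np.ndarray) -> float:
        same = lab[iu[0]] == lab[iu[1]]
        if not same.any():
            raise ValueError("no within-group dyads: test undefined")
        return float(tri[same].mean() - tri[~same].mean())

    same0 = labels[iu[0]] == labels[iu[1]]
    obs = stat(labels)
    rng = np.random.default_rng(seed)
    n_exceed = 0
    for _ in range(n_perm):
        if stat(rng.permutation(labels)) > obs:
            n_exceed += 1
    return LabelPermutationResult(
        statistic=obs, p=(n_exceed + 1) / (n_perm + 1), n_perm=n_perm,
        n_exceed=n_exceed, mean_within=float(tri[same0].mean()),
        mean_between=float(tri[~same0].mean()))
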