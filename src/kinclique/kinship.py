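"""Microsatellite kinship: allele frequencies, relatedness, clustering.

Four pieces:

* an expectation–maximisation estimator of per-locus allele frequencies
  that carries one latent *null* allele (an allele that fails to amplify,
  so visible/null heterozygotes are scored as visible homozygotes and
  null/null genotypes as missing);
* the Lynch & Ritland (1999) regression estimator of pairwise
  relatedness, locus-weighted by information content, with an optional
  null-allele correction that replaces allele-match indicators by their
  posterior expectations given the observed phenotypes;
* similarity UPGMA: repeatedly merge the two clusters with the highest
  mean cross-cluster relatedness;
* genetic diversity summaries (Na, Ho, He, F) and a chi-squared
  Hardy–Weinberg test per locus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeTable
from .matrices import labelled_matrix

__all__ = [
    "estimate_allele_freqs_em",
    "lr_relatedness",
    "upgma_relatedness",
    "diversity_stats",
    "hwe_chisq",
    "AlleleFrequencies",
    "EmResult",
    "UpgmaTree",
    "HweResult",
]

logger = logging.getLogger(__name__)

#: Visible allele frequencies per locus plus latent null frequency:
#: dict locus -> (pd.Series over visible alleles, null_freq).
AlleleFrequencies = dict


@dataclass
class EmResult:
    """Per-locus EM fit: visible + null frequencies and the likelihood path."""

    freqs: dict[str, tuple[pd.Series, float]]
    loglik: dict[str, list[float]]
    n_iter: dict[str, int]

    def null_freq(self, locus: str) -> float:
        return self.freqs[locus][1]

    def visible(self, locus: str) -> pd.Series:
        return self.freqs[locus][0]

    def full_simplex(self, locus: str) -> pd.Series:
        vis, p0 = self.freqs[locus]
        out = vis.copy()
        out.loc[0] = p0
        return out


def _locus_em(het_counts: dict[tuple[int, int], int],
              hom_counts: dict[int, int], n_missing: int,
              tol: float, max_iter: int
              ) -> tuple[pd.Series, float, list[float], int]:
    """EM for one locus.  Returns (visible freqs, null freq, loglik, iters).

    E-step splits each visible-homozygote count between true homozygote
    and visible/null heterozygote under the current frequencies; missing
    genotypes contribute to null/null.  M-step is allele counting.
    """
    alleles = sorted(set(a for pair in het_counts for a in pair)
                     | set(hom_counts))
    if not alleles:
        raise ValueError("locus has no typed individuals")
    k = len(alleles)
    a_idx = {a: i for i, a in enumerate(alleles)}
    n_obs = sum(het_counts.values()) + sum(hom_counts.values()) + n_missing

    # base allele counts from unambiguous heterozygotes
    het_base = np.zeros(k)
    for (a, b), c in het_counts.items():
        het_base[a_idx[a]] += c
        het_base[a_idx[b]] += c
    hom = np.zeros(k)
    for a, c in hom_counts.items():
        hom[a_idx[a]] += c

    # init: visible counting with a small null mass
    p = np.concatenate([het_base + 2 * hom, [0.0]])
    p[-1] = 0.1 * p[:-1].sum() if n_missing == 0 else 2.0 * n_missing
    if p.sum() == 0:
        raise ValueError("locus has no observable alleles")
    p = p / p.sum()

    if k == 1 and n_missing == 0 and sum(het_counts.values()) == 0:
        # monomorphic: the null frequency is unidentifiable; fix it at 0
        logger.warning("monomorphic locus: null frequency fixed at 0")
        vis = pd.Series([1.0], index=alleles)
        return vis, 0.0, [0.0], 0

    logliks: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        pv, p0 = p[:-1], p[-1]
        # observed-data log likelihood
        ll = 0.0
        for (a, b), c in het_counts.items():
            ll += c * np.log(2 * pv[a_idx[a]] * pv[a_idx[b]])
        for a, c in hom_counts.items():
            pa = pv[a_idx[a]]
            ll += c * np.log(pa * pa + 2 * pa * p0)
        if n_missing:
            ll += n_missing * np.log(max(p0 * p0, 1e-300))
        logliks.append(float(ll))

        counts = het_base.copy()
        null_count = 2.0 * n_missing
        for a, c in hom_counts.items():
            pa = pv[a_idx[a]]
            f_true = pa / (pa + 2 * p0) if (pa + 2 * p0) > 0 else 1.0
            counts[a_idx[a]] += c * (1 + f_true)
            null_count += c * (1 - f_true)
        new = np.concatenate([counts, [null_count]]) / (2.0 * n_obs)
        delta = np.max(np.abs(new - p))
        p = new
        if delta < tol:
            break
    vis = pd.Series(p[:-1], index=alleles)
    return vis, float(p[-1]), logliks, it


def estimate_allele_freqs_em(genotypes: GenotypeTable, tol: float = 1e-8,
                             max_iter: int = 1000,
                             missing_as_null: bool = True) -> EmResult:
    """Null-allele EM frequency estimates for every locus.

    With ``missing_as_null`` (default) untyped genotypes are attributed
    to null/null homozygotes, matching a panel where amplification
    failure is the dominant cause of missingness.
    """
    freqs, ll, iters = {}, {}, {}
    for locus in genotypes.loci:
        het: dict[tuple[int, int], int] = {}
        hom: dict[int, int] = {}
        n_missing = 0
        for v in genotypes.calls[locus]:
            if v is None:
                n_missing += 1
            elif v[0] == v[1]:
                hom[v[0]] = hom.get(v[0], 0) + 1
            else:
                het[v] = het.get(v, 0) + 1
        if not het and not hom:
            raise ValueError(f"locus {locus}: no typed individuals")
        vis, p0, lls, it = _locus_em(
            het, hom, n_missing if missing_as_null else 0, tol, max_iter)
        freqs[locus] = (vis, p0)
        ll[locus] = lls
        iters[locus] = it
    return EmResult(freqs=freqs, loglik=ll, n_iter=iters)


# ---------------------------------------------------------------------------
# Lynch & Ritland pairwise relatedness
# ---------------------------------------------------------------------------

def _lr_terms(a: int, b: int, c: int, d: int, p: dict[int, float]
              ) -> tuple[float, float, float]:
    """LR numerator, denominator and weight for reference (a,b), proband (c,d)."""
    pa, pb = p[a], p[b]
    dab = 1.0 if a == b else 0.0
    dbc = 1.0 if b == c else 0.0
    dbd = 1.0 if b == d else 0.0
    dac = 1.0 if a == c else 0.0
    dad = 1.0 if a == d else 0.0
    num = pa * (dbc + dbd) + pb * (dac + dad) - 4.0 * pa * pb
    den = (1.0 + dab) * (pa + pb) - 4.0 * pa * pb
    weight = den / (2.0 * pa * pb) if pa * pb > 0 else 0.0
    return num, den, weight


def _genotype_posterior(call, p_vis: dict[int, float], p0: float
                        ) -> list[tuple[tuple[int, int], float]]:
    """Posterior over true genotypes given an observed phenotype.

    The null allele is labelled 0.  Observed heterozygotes are certain;
    an observed homozygote (a,a) is true (a,a) or (a,0); missing is
    (0,0).
    """
    if call is None:
        return [((0, 0), 1.0)]
    a, b = call
    if a != b:
        return [((a, b), 1.0)]
    pa = p_vis.get(a, 0.0)
    w_true = pa * pa
    w_null = 2.0 * pa * p0
    z = w_true + w_null
    if z <= 0:
        return [((a, a), 1.0)]
    return [((a, a), w_true / z), ((a, 0), w_null / z)]


def lr_relatedness(genotypes: GenotypeTable,
                   freqs: EmResult | dict,
                   null_correction: bool = False,
                   pairs: list[tuple[str, str]] | None = None
                   ) -> pd.DataFrame:
    """Pairwise Lynch–Ritland relatedness matrix.

    Per locus, the regression estimator is evaluated with each member of
    the dyad as reference; loci are combined by their information-content
    weights and the two reciprocal multi-locus estimates are averaged.
    Dyads with no usable locus are NaN.

    With ``null_correction``, every allele-match indicator is replaced by
    its posterior expectation given the observed phenotype and the locus
    null frequency (missing genotypes are treated as null/null and carry
    no weight through the reference's uninformative-null guard).

    ``pairs`` restricts the computation to the listed dyads (all other
    entries stay NaN) — relevant when only a sparse set of dyads from a
    large panel is of interest.
    """
    ids = genotypes.individuals
    loci = genotypes.loci
    freq_map: dict[str, tuple[dict[int, float], float]] = {}
    for locus in loci:
        if isinstance(freqs, EmResult):
            vis, p0 = freqs.freqs[locus]
            freq_map[locus] = (dict(vis), p0)
        else:
            simplex = dict(freqs[locus])
            p0 = float(simplex.pop(0, 0.0))
            freq_map[locus] = ({int(k): float(v) for k, v in simplex.items()}, p0)

    n = len(ids)
    r = np.full((n, n), np.nan)
    np.fill_diagonal(r, 1.0)

    calls = {(i, l): genotypes.get(i, l) for i in ids for l in loci}

    def one_direction(ref: str, pro: str) -> tuple[float, float]:
        """(sum_w_times_r, sum_w) over loci with ref as reference."""
        swr = sw = 0.0
        for locus in loci:
            p_vis, p0 = freq_map[locus]
            g_ref = calls[(ref, locus)]
            g_pro = calls[(pro, locus)]
            if g_ref is None or g_pro is None:
                continue
            if not null_correction or p0 == 0.0:
                a, b = g_ref
                c, d = g_pro
                if p_vis.get(a, 0) <= 0 or p_vis.get(b, 0) <= 0:
                    continue
                num, den, w = _lr_terms(a, b, c, d, p_vis)
                if w <= 0 or den == 0:
                    continue
                swr += w * (num / den)
                sw += w
            else:
                p_all = dict(p_vis)
                p_all[0] = p0
                post_ref = _genotype_posterior(g_ref, p_vis, p0)
                post_pro = _genotype_posterior(g_pro, p_vis, p0)
                e_num = e_den = e_w = 0.0
                for (a, b), wr in post_ref:
                    if p_all.get(a, 0) <= 0 or p_all.get(b, 0) <= 0:
                        continue
                    for (c, d), wp in post_pro:
                        num, den, w = _lr_terms(a, b, c, d, p_all)
                        e_num += wr * wp * num
                        e_den += wr * wp * den
                        e_w += wr * wp * w
                if e_w <= 0 or e_den == 0:
                    continue
                swr += e_w * (e_num / e_den)
                sw += e_w
        return swr, sw

    pos = {ind: k for k, ind in enumerate(ids)}
    if pairs is None:
        wanted = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        wanted = [(pos[a], pos[b]) for a, b in pairs]
    for i, j in wanted:
        swr_ij, sw_ij = one_direction(ids[i], ids[j])
        swr_ji, sw_ji = one_direction(ids[j], ids[i])
        vals = []
        if sw_ij > 0:
            vals.append(swr_ij / sw_ij)
        if sw_ji > 0:
            vals.append(swr_ji / sw_ji)
        if vals:
            r[i, j] = r[j, i] = float(np.mean(vals))
    return labelled_matrix(r, ids)


# ---------------------------------------------------------------------------
# similarity UPGMA
# ---------------------------------------------------------------------------

@dataclass
class UpgmaTree:
    """Merge tree from similarity UPGMA on a relatedness matrix.

    ``merges`` lists (members_a, members_b, height) in merge order, with
    height the mean cross-cluster relatedness at the merge.
    """

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    ids: list[str]

    def to_newick(self) -> str:
        node: dict[tuple[str, ...], str] = {(i,): i for i in self.ids}
        for a, b, h in self.merges:
            merged = tuple(sorted(a + b))
            node[merged] = f"({node[a]},{node[b]}):{h:.6g}"
        if self.merges:
            root = tuple(sorted(self.ids))
            return node[root].rsplit(":", 1)[0] + ";"
        return f"({','.join(self.ids)});"


def upgma_relatedness(r: pd.DataFrame) -> UpgmaTree:
    """Similarity UPGMA: merge the two clusters with the highest mean
    cross-cluster relatedness, repeatedly, until one cluster remains.

    Mean cross-cluster relatedness of clusters a, b is
    (sum over i in a, j in b of r_ij) / (n_a n_b); undefined entries are
    handled pairwise-complete (mean of the defined dyads) with a log
    message.  Ties break lexicographically on the sorted member tuples.
    """
    ids = sorted(r.index)
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals")
    r = r.reindex(index=ids, columns=ids)
    a = r.to_numpy(dtype=float)
    if np.isnan(a[np.triu_indices(len(ids), 1)]).any():
        logger.info("undefined relatedness entries: pairwise-complete means")
    clusters: list[tuple[str, ...]] = [(i,) for i in ids]
    merges = []
    pos = {i: k for k, i in enumerate(ids)}

    def mean_cross(ca, cb) -> float:
        vals = [a[pos[x], pos[y]] for x in ca for y in cb
                if np.isfinite(a[pos[x], pos[y]])]
        return float(np.mean(vals)) if vals else -np.inf

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                m = mean_cross(clusters[i], clusters[j])
                key = (-m, clusters[i], clusters[j])
                if best is None or key < best[0]:
                    best = (key, i, j, m)
        _, i, j, m = best
        ca, cb = clusters[i], clusters[j]
        merges.append((ca, cb, m))
        merged = tuple(sorted(ca + cb))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        clusters.sort()
    return UpgmaTree(merges=merges, ids=ids)


# ---------------------------------------------------------------------------
# diversity statistics and HWE
# ---------------------------------------------------------------------------

def diversity_stats(genotypes: GenotypeTable) -> pd.DataFrame:
    """Per-locus Na, Ho, He (unbiased), F, plus a mean +/- sd row.

    He uses the small-sample correction 2n/(2n-1) * (1 - sum p^2) on the
    observed visible-allele frequencies; F = 1 - Ho/He, undefined (NaN)
    where He = 0 and excluded from the mean.
    """
    rows = {}
    for locus in genotypes.loci:
        typed = [v for v in genotypes.calls[locus] if v is not None]
        n = len(typed)
        if n == 0:
            raise ValueError(f"locus {locus}: no typed individuals")
        alleles: dict[int, int] = {}
        n_het = 0
        for a, b in typed:
            alleles[a] = alleles.get(a, 0) + 1
            alleles[b] = alleles.get(b, 0) + 1
            if a != b:
                n_het += 1
        p = np.array(list(alleles.values()), dtype=float) / (2 * n)
        ho = n_het / n
        he = (2 * n) / (2 * n - 1) * (1 - float((p**2).sum())) if n > 0 else 0.0
        f = 1 - ho / he if he > 0 else np.nan
        rows[locus] = {"n": n, "Na": len(alleles), "Ho": ho, "He": he, "F": f}
    out = pd.DataFrame.from_dict(rows, orient="index")
    means = out[["Na", "Ho", "He", "F"]].mean(skipna=True)
    sds = out[["Na", "Ho", "He", "F"]].std(skipna=True, ddof=1)
    out.loc["mean"] = {"n": np.nan, **means}
    out.loc["sd"] = {"n": np.nan, **sds}
    return out


@dataclass(frozen=True)
class HweResult:
    statistic: float
    df: int
    p: float
    small_expected: bool
    no_test: bool = False


def hwe_chisq(genotypes: GenotypeTable, locus: str) -> HweResult:
    """Pearson chi-squared test of Hardy–Weinberg genotype proportions.

    Expected counts come from the observed allele frequencies over all
    g = a(a+1)/2 genotype classes; df = g - a.  A locus with a single
    observed allele yields a no-test result; expected counts below 5
    raise the ``small_expected`` flag.
    """
    typed = [v for v in genotypes.calls[locus] if v is not None]
    n = len(typed)
    if n == 0:
        raise ValueError(f"locus {locus}: no typed individuals")
    allele_counts: dict[int, int] = {}
    geno_counts: dict[tuple[int, int], int] = {}
    for g in typed:
        geno_counts[g] = geno_counts.get(g, 0) + 1
        for a in g:
            allele_counts[a] = allele_counts.get(a, 0) + 1
    alleles = sorted(allele_counts)
    k = len(alleles)
    if k < 2:
        return HweResult(statistic=np.nan, df=0, p=np.nan,
                         small_expected=False, no_test=True)
    p = {a: allele_counts[a] / (2 * n) for a in alleles}
    obs, exp = [], []
    for a, b in combinations_with_replacement(alleles, 2):
        g = (a, b) if a <= b else (b, a)
        obs.append(geno_counts.get(g, 0))
        exp.append(n * (p[a]**2 if a == b else 2 * p[a] * p[b]))
    obs = np.asarray(obs, dtype=float)
    exp = np.asarray(exp, dtype=float)
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - k
    pval = float(stats.chi2.sf(stat, df)) if df > 0 else np.nan
    if min(exp) < 5:
        warnings.warn(f"locus {locus}: expected genotype count below 5",
                      stacklevel=2)
    return HweResult(statistic=stat, df=df, p=pval,
                     small_expected=bool(min(exp) < 5))
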