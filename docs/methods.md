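# Methods

This note documents the models, estimators and numerical choices behind
`kinclique`, and what the synthetic-herd experiments do and do not show.

## Association and interaction indices

**HWI.** The half-weight index uses the Cairns–Schwager form
`HWI = x / (x + y_ab + (y_a + y_b)/2)` with one scan timestamp as the
sampling period: `x` scans with the dyad together, `y_ab` with both seen
apart, `y_a`/`y_b` with only one seen.  An individual is "seen" in a scan
if it appears in any dyadic record of that scan; individuals never
observed get NaN rows and are excluded downstream.  Dyads never
co-observed score 0.

**DAI.** No single denominator convention is canonical for a directed
grooming index; the default is the initiator-normalised share
`DAI_ij = G_ij / Σ_k G_ik`, with `dyadic_sum` (`G_ij/(G_ij+G_ji)`) and
`total_share` variants behind a switch.  An individual that never
initiates has an all-zero row.

**Subgroups and cliquishness.** Agglomerative clustering (average
linkage, deterministic lexicographic tie order) on distance `1 − HWI`.
When the number of groups is not fixed, the dendrogram cut maximises
Newman modularity Q of the induced partition on the weighted HWI graph,
and Q of the chosen cut is reported as the cliquishness coefficient.  An
all-zero matrix yields a single cluster with Q = 0 and a logged warning.

## Dominance

Dyadic win proportions `P_ij = w_ij/(w_ij + w_ji)`; the `Dij` variant
applies the shrinkage `D_ij = P_ij − (P_ij − 0.5)/(n_ij + 1)`.
Zero-interaction dyads contribute 0 to both directions under `Pij`
(documented convention) and the prior 0.5 under `Dij`.  David's scores
`DS = w + w2 − l − l2` conserve `Σ DS = 0` for any matrix (asserted to
1e−9); `NDS = (DS + N(N−1)/2)/N`.

Steepness is the absolute OLS slope of NDS (sorted descending) on rank
positions 1..N; its P value randomises bout outcomes within dyads
(Binomial(n_ij, ½), interaction counts fixed).  Linearity is Landau's
`h = 12/(N³−N) Σ (V_i − (N−1)/2)²` with ties scored ½ and the
unknown-dyad correction `h' = h + 6u/(N³−N)` (the expectation of
resolving each of the `u` unknown dyads at random); its P value
randomises the direction of each known dyad.  These randomisation tests
use the conventional `≥` exceedance count.

## Kinship

**Null-allele EM.** Per locus, the E-step splits each observed visible
homozygote `aa` between true `aa` (weight `p_a/(p_a + 2p_0)`) and `a0`;
missing genotypes are attributed to `00` (configurable — appropriate when
amplification failure dominates missingness).  The M-step is allele
counting; iteration stops at an L∞ frequency change below 1e−8 or 1000
iterations.  The observed-data likelihood is non-decreasing (asserted per
run).  Convergence to the boundary `p_0 = 0` is sublinear, so estimates
at a truly-zero null settle near ~1e−3 rather than exactly 0.
Monomorphic loci with no missing data leave the null unidentifiable; it
is fixed at 0 with a warning.

**Lynch–Ritland relatedness.** The regression estimator with reference
`(a,b)` and proband `(c,d)`:

```
r = [p_a(δ_bc + δ_bd) + p_b(δ_ac + δ_ad) − 4 p_a p_b]
    / [(1 + δ_ab)(p_a + p_b) − 4 p_a p_b]
```

locus weights `W = [(1+δ_ab)(p_a+p_b) − 4p_a p_b]/(2 p_a p_b)`;
multi-locus values are the W-weighted average and the two reciprocal
references are averaged.  Loci where the reference is homozygous for a
fixed allele (denominator 0) are uninformative and skipped, as are
missing calls (pairwise deletion).  With null correction, the numerator,
denominator and weight are replaced by their expectations over the
posterior of each true genotype given the observed phenotype and the
locus null frequency (observed homozygotes may be visible/null
heterozygotes; missing is null/null).  This posterior-expectation
substitution is this package's own construction; it reduces exactly to
the uncorrected estimator when the null frequency is 0 (asserted to
1e−9).

**Similarity UPGMA.** Clusters merge by *maximum* mean cross-cluster
relatedness `R̄_ab = Σ r_ij/(n_a n_b)` (not minimum distance), heights
are the `R̄` at each merge, ties break lexicographically, and undefined
entries are handled pairwise-complete.

**Diversity.** `He` uses the unbiased correction `2n/(2n−1)(1 − Σp²)`;
`F = 1 − Ho/He` is undefined (and excluded from means) where `He = 0`.
The HWE test is a Pearson chi-squared over all `a(a+1)/2` genotype
classes with `df = g − a`, flagging expected counts below 5.

## Community dynamics

Daily edge weights decay exponentially,
`w(a,b,t) = Σ_{s≤t} x(a,b,s)·2^{−(t−s)/half-life}`, with a 14-day
half-life and percolation threshold `w* = 1.0` by default — both
stand-ins where no published constant exists, surfaced in the pipeline
config.  CPM communities (k-cliques adjacent when sharing k−1 nodes;
default k = 3, the smallest clique) come from networkx's percolation
implementation and are checked exactly against a brute-force k-clique
adjacency oracle on small graphs.  Day-to-day communities are matched by
maximal Jaccard overlap (ties: larger community, then lexicographic);
members present in the matched community on consecutive days are EB,
new members NFB, and members absent from the next day's matched
community LND (first-day members count as EB; LND is undefined on the
final day).  Inter-band distance is the haversine (R = 6 371 000 m)
between median daily centroids; community size is related to distance by
Pearson/Spearman correlation and by mean size within <200, 200–300,
300–900 and >900 m bins.

## HPMT

All matrix statistics operate on strict upper triangles (diagonals
excluded).  The kth-order partial correlation is computed by the
three-(k−1)th-order recursion, peeling controls in input order; exact
arithmetic is order-invariant and floating drift is tested ≤1e−9 against
an independent least-squares residualisation oracle.  Significance
permutes the rows and columns of the tested matrix **X** jointly (raw-X
permutation; a residualised variant is a candidate extension), recomputes
the full recursion per permutation, and uses the unbiased
`P = (n₁+1)/(n₂+1)` where `n₁` counts permutations with r *strictly*
greater than observed.  This fixed "greater" alternative is the default:
it is the test defined by the P formula and the only variant calibrated
at the nominal level under the null (measured 0.042 at α = 0.05 over 500
null replicates).  The data-dependent "observed-direction" variant is
exposed but documented as anti-conservative (~2× nominal).  Degenerate
denominators in the observed statistic raise an error naming the
collinear control; in permutation replicates they yield NaN, counted as
not exceeding.

`R² = 1 − Π(1 − r²)` over sequential partials; a factor numerically in
the affine span of its predecessors contributes nothing (guarded by a
least-squares span check rather than a 0/0).  `CR_f = R²(all) −
R²(all \ f)`, clipped at 0 with a warning when negative beyond 1e−9.
CR lies in [0, 1] and ΣCR ≤ 1; note that ΣCR ≤ R² is *not* guaranteed in
general (suppressor configurations violate it), so the tests assert the
[0, 1]/Σ≤1 bounds and report the R² ordering.

Matrices are correlated as given — relatedness and HWI are similarities,
age/NDS differences are distances — so signs are reported, never
auto-flipped.

## Synthetic herd generator

The generator defines the study conditions under which everything is
validated.  A scenario holds three families of seven males (21 total,
matching the emulated band): two adult founders (8–18 y) plus five
full-sib offspring (1–7 y) per family, giving a juvenile/sub-adult/adult
mix.  Age classes use cutoffs 3.5 y (juvenile/sub-adult) and 7 y
(sub-adult/adult) — conventions from the colobine literature, not
measured quantities.  Genotypes: 19 loci, four visible alleles per locus
(Dirichlet frequencies), null alleles at two loci (rate 0.1), Mendelian
transmission, visible/null heterozygotes recorded as visible homozygotes
and null/null as missing.

Dyadic behaviour follows a logistic stand-in (no distributional model is
canonical for such data): per scan, a dyad is together with probability
`sigmoid(b0 + 2.5·r_ij − 0.05·|Δage| − 0.02·|Δrank| + 0.5·same-subgroup)`
with `b0 = logit(0.05) ≈ −2.94`.  These defaults were chosen analytically
so realised within-subgroup HWI ≈ 0.2 and between ≈ 0.05 — the magnitudes
of the emulated system.  Grooming initiations are drawn over ordered
dyads with weight `exp(η)`; bout durations are truncated-normal
(186.6 ± 140.7 s).  Agonistic bouts pick dyads uniformly; the older male
wins with probability 0.9 (1.0 makes the hierarchy perfectly linear);
behaviour and response categories follow the published six-category
agonistic and three-category submissive profiles, with 2092/2194 of
bouts decided.  Default observation effort equals the emulated field
effort: 3 213 scans, 3 047 grooming bouts, 2 194 agonistic bouts over 90
days.  GPS tracks place the BB at a fixed Qinling-like base point and
displace the AMB eastward by a smooth 100–1500 m approach/retreat profile
plus N(0, 50 m) daily jitter, with 8 fixes/day scattered 20 m around
each centroid.  A single scenario seed fans out to per-stream sub-seeds
through `numpy.random.SeedSequence([seed, hash(stream name)])`, so every
bundle is byte-reproducible.

What the generator does **not** emulate: unequal observability (every
male is seen in every scan, so HWI reduces to co-presence frequency),
female/OMU behaviour, takeover events, habitat structure, genotyping
error beyond null alleles, and temporal autocorrelation in behaviour
beyond the community-weight decay.  Passing recovery tests therefore
demonstrates estimator correctness under the stated model, not
robustness to field-data pathologies such as sighting bias or scoring
error.

## Problem sizes in the validation suite

The suite validates at the emulated study's scale where that is cheap
(full 3 213-scan scenarios for the 50-herd recovery experiment; 500
replicates × 999 permutations for the null calibration; 200 dyads per
relatedness class) and at small n where an exact oracle exists
(brute-force CPM on ≤8 nodes, exhaustive Mann–Whitney enumeration,
all-partition modularity on 6 nodes).  The whole suite runs in a few
minutes on one CPU.

## Known limitations

* The DAI denominator, the CPM weight formula and threshold, and the
  cliquishness statistic are operationalisations chosen here; published
  sources name the indices without printing the formulas, so numeric
  values of those quantities are comparable only within this package.
* The null-allele correction of the relatedness estimator uses
  independent genotype posteriors per individual; for dyads sharing rare
  alleles the joint posterior would differ slightly.
* EM boundary convergence is sublinear (see above); null-frequency
  estimates below ~1e−3 should be read as "no evidence of a null allele".
* The leave-probability curve conditions only on an externally supplied
  outside-contact rate; it does not model censoring on the final day
  beyond dropping it.
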