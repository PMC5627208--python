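# kinclique

Kin-structured social network analysis for bachelor-male bands.

Golden snub-nosed monkeys (*Rhinopithecus roxellana*) live in multilevel
societies: one-male breeding units aggregate into a breeding band (BB),
shadowed by an all-male band (AMB) of bachelor males.  Within the AMB,
males form distinct subgroups ("all-male units", AMUs).  This package
implements the full analytical chain needed to ask *why* particular males
affiliate — kinship, age, or dominance rank — and how those alliances
dissolve and re-form as breeding opportunities come and go:

* **Affiliation networks** — half-weight association index (HWI) from
  scan samples, `HWI = x / (x + y_ab + (y_a + y_b)/2)`; directional
  affiliation index (DAI) from grooming bouts; hierarchical clustering of
  the association network into AMUs with a modularity-based cliquishness
  coefficient; threshold-filtered sociograms with eigenvector centrality.
* **Dominance** — win/loss matrices from agonistic bouts, David's scores
  `DS_i = w_i + w2_i − l_i − l2_i`, normalised David's scores
  `NDS_i = (DS_i + N(N−1)/2)/N`, hierarchy steepness (|OLS slope| of NDS
  on rank) and Landau linearity *h* with the unknown-relationship
  correction, both with randomisation P values.
* **Kinship** — GenePop I/O; per-locus allele frequencies by an EM
  algorithm with a latent null allele; pairwise Lynch & Ritland (1999)
  relatedness with optional null-allele correction; similarity UPGMA
  clustering; diversity statistics (Na, Ho, He, F) and Hardy–Weinberg
  chi-squared tests with Holm's sequential Bonferroni correction.
* **Community dynamics** — exponentially decayed daily affiliation
  graphs, clique-percolation (CPM) communities, day-to-day matching with
  EB/NFB/LND turnover flags, inter-band GPS distance (haversine on daily
  centroids) and its coupling to community size.
* **HPMT** — the higher-order partial Mantel test: the kth-order partial
  correlation between a tested matrix **X** and the dependent matrix
  **Y** controlling **Z**₁..**Z**ₖ via the recursion

  ```
  r_xy·z1..zk = (r_xy·z1..z(k−1) − r_xzk·… · r_yzk·…)
                / sqrt((1 − r²_xzk·…)(1 − r²_yzk·…))
  ```

  with Monte-Carlo P = (n₁+1)/(n₂+1) from joint row/column permutations
  of **X** only; the coefficient of multiple determination
  `R² = 1 − Π(1 − r²_{Y Xi·X1..X(i−1)})`; and per-factor contribution
  rates `CR_f = R²(all) − R²(all \ f)`.
* **Synthetic herd generator** — pedigreed families with Mendelian
  microsatellite genotypes (including null-allele masking), logistic
  kin/age/rank-driven proximity and grooming, an age-linear dominance
  hierarchy, and paired GPS tracks; every stage seeded and
  byte-reproducible, so the whole pipeline is testable against known
  ground truth without any field data.

## Worked example

```bash
kinclique demo --seed 1 --out demo_out
```

simulates a 21-male, three-family herd (3 213 scans, 3 047 grooming
bouts, 2 194 agonistic bouts, 19 loci) and runs the full pipeline.  It
prints:

```json
{
 "n_subgroups": 3,
 "cliquishness": 0.329,
 "mean_hwi_within": 0.169,
 "mean_hwi_between": 0.037,
 "steepness": 0.776,
 "hpmt_proximity": {
  "relatedness": {"r": 0.863, "p": 0.002, "cr": 0.731},
  "age_diff":    {"r": -0.199, "p": 0.992, "cr": 0.01},
  "rank_diff":   {"r": -0.032, "p": 0.682, "cr": 0.0}
 },
 "r2_full": 0.75
}
```

Reading: hierarchical clustering recovers the three planted families as
subgroups (modularity 0.33); spatial association is an order of magnitude
stronger within subgroups than between; the dominance hierarchy is steep
(0.78); and the HPMT attributes proximity overwhelmingly to relatedness
(CR 0.73) rather than to age or rank differences — the generator's
ground truth.  `demo_out/` holds the full JSON report plus HWI/DAI/
relatedness CSV matrices, a GraphML sociogram, and a Newick relatedness
tree.

The same stages are available as `kinclique simulate | affiliation |
dominance | kinship | community | hpmt | run`, e.g.

```bash
kinclique hpmt --dependent hwi.csv --test relatedness.csv \
          --control age_diff.csv,nds_diff.csv --n-perm 9999 --seed 7
```

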