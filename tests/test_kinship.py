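"""Null-allele EM, Lynch-Ritland relatedness, similarity UPGMA, diversity."""

import numpy as np
import pandas as pd
import pytest

from kinclique.genotypes import GenotypeTable, read_genepop, write_genepop
from kinclique.kinship import (diversity_stats, estimate_allele_freqs_em,
                               hwe_chisq, lr_relatedness, upgma_relatedness)
from kinclique.matrices import labelled_matrix
from kinclique.synthetic import (random_allele_freqs, simulate_genotypes,
                                 simulate_pedigree)


def table_from_calls(calls: dict[str, list], loci=None) -> GenotypeTable:
    loci = loci or [f"L{k+1:02d}" for k in range(len(next(iter(calls.values()))))]
    return GenotypeTable(pd.DataFrame.from_dict(calls, orient="index",
                                                columns=loci))


class TestEm:
    def test_hwe_counts_give_zero_null(self):
        # exact Hardy-Weinberg proportions at p = q = 0.5, n = 100
        calls = {}
        k = 0
        for geno, count in (((1, 1), 25), ((1, 2), 50), ((2, 2), 25)):
            for _ in range(count):
                calls[f"x{k}"] = [geno]
                k += 1
        em = estimate_allele_freqs_em(table_from_calls(calls))
        # boundary (p0 = 0) convergence of EM is sublinear: a loose
        # absolute band is the honest check
        assert em.null_freq("L01") == pytest.approx(0.0, abs=1e-3)
        assert em.visible("L01")[1] == pytest.approx(0.5, abs=1e-3)

    def test_recovers_simulated_null_frequency(self):
        ids = [f"x{i}" for i in range(500)]
        freqs = random_allele_freqs(1, n_alleles=4, null_rates=[0.2], seed=3)
        obs, _ = simulate_genotypes({}, ids, freqs, seed=3)
        em = estimate_allele_freqs_em(obs)
        assert em.null_freq("L01") == pytest.approx(0.2, abs=0.05)

    def test_likelihood_monotone_and_simplex(self):
        ids = [f"x{i}" for i in range(120)]
        freqs = random_allele_freqs(3, n_alleles=3,
                                    null_rates=[0.15, 0.0, 0.3], seed=5)
        obs, _ = simulate_genotypes({}, ids, freqs, seed=5)
        em = estimate_allele_freqs_em(obs)
        for locus in obs.loci:
            lls = np.array(em.loglik[locus])
            assert np.all(np.diff(lls) >= -1e-9), locus
            simplex = em.full_simplex(locus)
            assert simplex.sum() == pytest.approx(1.0, abs=1e-9)
            assert (simplex >= 0).all()


def simulate_dyads(kind: str, n_dyads: int, n_loci: int = 19, seed: int = 0):
    """Independent replicate dyads of a given true relatedness."""
    freqs = random_allele_freqs(n_loci, n_alleles=4, seed=seed)
    rng = np.random.default_rng(seed)
    pedigree = {}
    ids = []
    pairs = []
    for d in range(n_dyads):
        if kind == "unrelated":
            a, b = f"u{d}a", f"u{d}b"
            ids += [a, b]
        elif kind == "parent_offspring":
            a, b, mate = f"p{d}", f"o{d}", f"m{d}"
            ids += [a, mate, b]
            pedigree[b] = (a, mate)
        elif kind == "half_sib":
            sire, da, db, a, b = (f"s{d}", f"da{d}", f"db{d}",
                                  f"h{d}a", f"h{d}b")
            ids += [sire, da, db, a, b]
            pedigree[a] = (sire, da)
            pedigree[b] = (sire, db)
        pairs.append((a, b))
    obs, _ = simulate_genotypes(pedigree, ids, freqs,
                                seed=int(rng.integers(2**31 - 1)))
    rel = lr_relatedness(obs, {f"L{k+1:02d}": freqs[k] for k in range(n_loci)})
    return np.array([rel.at[a, b] for a, b in pairs])


class TestLynchRitland:
    def test_unrelated_dyads_centred_on_zero(self):
        r = simulate_dyads("unrelated", 200, seed=11)
        assert abs(r.mean()) < 0.05

    def test_parent_offspring_centred_on_half(self):
        r = simulate_dyads("parent_offspring", 200, seed=12)
        assert r.mean() == pytest.approx(0.5, abs=0.05)

    def test_untyped_locus_carries_no_weight(self):
        freqs = {"L01": {1: 0.6, 2: 0.4}, "L02": {1: 0.6, 2: 0.4}}
        calls = {"a": [(1, 2), None], "b": [(1, 2), None],
                 "c": [(1, 1), (1, 2)], "d": [(2, 2), (1, 2)]}
        t = table_from_calls(calls, loci=["L01", "L02"])
        rel_full = lr_relatedness(t, freqs)
        # a-b value must equal the single-locus estimate: drop L02 entirely
        t1 = GenotypeTable(t.calls[["L01"]].copy())
        rel_one = lr_relatedness(t1, {"L01": freqs["L01"]})
        assert rel_full.at["a", "b"] == pytest.approx(rel_one.at["a", "b"])

    def test_null_correction_identity_when_no_nulls(self):
        ids = [f"x{i}" for i in range(40)]
        freqs = random_allele_freqs(6, n_alleles=4, seed=2)
        obs, _ = simulate_genotypes({}, ids, freqs, seed=2)
        fmap = {f"L{k+1:02d}": freqs[k] for k in range(6)}
        r0 = lr_relatedness(obs, fmap, null_correction=False)
        r1 = lr_relatedness(obs, fmap, null_correction=True)
        assert np.allclose(r0.to_numpy(), r1.to_numpy(), atol=1e-9,
                           equal_nan=True)

    def test_within_family_exceeds_between(self, scenario, bundle):
        from kinclique.affiliation import group_mean_contrast
        em = estimate_allele_freqs_em(bundle["genotypes"])
        rel = lr_relatedness(bundle["genotypes"], em, null_correction=True)
        w, b = group_mean_contrast(rel, scenario.subgroups)
        assert w > b


class TestUpgma:
    def test_hand_example_merge_order_and_heights(self):
        r = labelled_matrix(np.array([
            [1.0, 0.5, 0.1],
            [0.5, 1.0, 0.0],
            [0.1, 0.0, 1.0]]), ["1", "2", "3"])
        tree = upgma_relatedness(r)
        (a1, b1, h1), (a2, b2, h2) = tree.merges
        assert set(a1 + b1) == {"1", "2"}
        assert h1 == pytest.approx(0.5)
        assert h2 == pytest.approx(0.05)  # mean of r(1,3) and r(2,3)

    def test_two_individuals(self):
        r = labelled_matrix(np.array([[1.0, 0.3], [0.3, 1.0]]), ["a", "b"])
        tree = upgma_relatedness(r)
        assert len(tree.merges) == 1
        assert tree.merges[0][2] == pytest.approx(0.3)
        assert tree.to_newick().endswith(";")

    def test_input_order_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(5, 5))
        a = (a + a.T) / 2
        ids = list("abcde")
        m1 = labelled_matrix(a, ids)
        perm = [3, 1, 4, 0, 2]
        m2 = m1.iloc[perm, perm]
        assert upgma_relatedness(m1).merges == upgma_relatedness(m2).merges


class TestDiversity:
    def test_all_heterozygous_locus(self):
        calls = {f"x{i}": [(1, 2)] for i in range(200)}
        stats = diversity_stats(table_from_calls(calls))
        row = stats.loc["L01"]
        assert row["Ho"] == 1.0
        assert row["He"] == pytest.approx(0.5, abs=0.01)
        assert row["F"] == pytest.approx(-1.0, abs=0.03)

    def test_monomorphic_locus_f_undefined(self):
        calls = {f"x{i}": [(1, 1)] for i in range(10)}
        stats = diversity_stats(table_from_calls(calls))
        assert stats.at["L01", "Ho"] == 0.0
        assert stats.at["L01", "He"] == 0.0
        assert np.isnan(stats.at["L01", "F"])

    def test_two_homozygotes(self):
        calls = {"a": [(1, 1)], "b": [(2, 2)]}
        stats = diversity_stats(table_from_calls(calls))
        assert stats.at["L01", "Na"] == 2
        assert stats.at["L01", "Ho"] == 0.0


class TestHwe:
    def test_exact_hwe_proportions_give_zero(self):
        calls = {}
        k = 0
        for geno, count in (((1, 1), 25), ((1, 2), 50), ((2, 2), 25)):
            for _ in range(count):
                calls[f"x{k}"] = [geno]
                k += 1
        res = hwe_chisq(table_from_calls(calls), "L01")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_toy_counts_hand_arithmetic(self):
        calls = {}
        k = 0
        for geno, count in (((1, 1), 30), ((1, 2), 40), ((2, 2), 30)):
            for _ in range(count):
                calls[f"x{k}"] = [geno]
                k += 1
        res = hwe_chisq(table_from_calls(calls), "L01")
        assert res.statistic == pytest.approx(4.0)

    def test_all_homozygotes_closed_form(self):
        # AA = BB = 50, n = 100, p = q = 0.5: expected (25, 50, 25)
        calls = {}
        k = 0
        for geno, count in (((1, 1), 50), ((2, 2), 50)):
            for _ in range(count):
                calls[f"x{k}"] = [geno]
                k += 1
        res = hwe_chisq(table_from_calls(calls), "L01")
        expected = (50 - 25) ** 2 / 25 + (0 - 50) ** 2 / 50 + (50 - 25) ** 2 / 25
        assert res.statistic == pytest.approx(expected)

    def test_single_allele_no_test(self):
        calls = {f"x{i}": [(1, 1)] for i in range(5)}
        res = hwe_chisq(table_from_calls(calls), "L01")
        assert res.no_test


class TestGenepopRoundTrip:
    def test_write_read_round_trip(self, tmp_path, bundle):
        path = tmp_path / "geno.gen"
        write_genepop(bundle["genotypes"], path)
        back = read_genepop(path)
        assert back.individuals == bundle["genotypes"].individuals
        assert back.loci == bundle["genotypes"].loci
        pd.testing.assert_frame_equal(back.calls, bundle["genotypes"].calls)
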