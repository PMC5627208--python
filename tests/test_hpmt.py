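"""Higher-order partial Mantel test: recursion, permutation P, CRs."""

import numpy as np
import pandas as pd
import pytest

from kinclique.hpmt import (DegenerateControlError, contribution_rates,
                            hpmt_test, label_permutation_test, mantel,
                            matrix_pearson, multiple_determination, partial_r)
from kinclique.matrices import from_upper_triangle, upper_triangle

from conftest import random_symmetric


def matrices_from_triangles(vectors, ids):
    return [from_upper_triangle(v, ids) for v in vectors]


class TestMatrixPearson:
    def test_identity_and_negation(self):
        rng = np.random.default_rng(0)
        a = random_symmetric(5, rng)
        assert matrix_pearson(a, a) == pytest.approx(1.0)
        assert matrix_pearson(a, -a) == pytest.approx(-1.0)

    def test_hand_evaluated_four_by_four(self):
        ids = list("abcd")
        va = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        vb = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        a, b = matrices_from_triangles([va, vb], ids)
        expected = np.corrcoef(va, vb)[0, 1]
        assert matrix_pearson(a, b) == pytest.approx(expected, abs=1e-12)
        # hand value: r = 1 - 2*6/(2*17.5) ... cross-check numerically only

    def test_constant_matrix_rejected(self):
        ids = list("abcd")
        const, other = matrices_from_triangles(
            [np.ones(6), np.arange(6.0)], ids)
        with pytest.raises(ValueError, match="zero-variance"):
            matrix_pearson(const, other)


class TestPartialR:
    def test_orthogonal_controls_no_change(self):
        assert partial_r(0.6, 0.0, 0.0) == pytest.approx(0.6)

    def test_hand_arithmetic(self):
        assert partial_r(0.6, 0.5, 0.5) == pytest.approx(0.35 / 0.75)

    def test_fully_explained_is_zero(self):
        assert partial_r(0.5 * 0.4, 0.5, 0.4) == pytest.approx(0.0)

    def test_degenerate_control(self):
        with pytest.raises(DegenerateControlError):
            partial_r(0.3, 1.0, 0.2)


def residual_partial_oracle(y, x, controls):
    """Independent oracle: partial correlation via least-squares
    residualisation of the dyad vectors on the control dyad vectors."""
    vy = upper_triangle(y)
    vx = upper_triangle(x)
    if not controls:
        return np.corrcoef(vx, vy)[0, 1]
    z = np.column_stack([np.ones(vy.size)]
                        + [upper_triangle(c) for c in controls])
    ry = vy - z @ np.linalg.lstsq(z, vy, rcond=None)[0]
    rx = vx - z @ np.linalg.lstsq(z, vx, rcond=None)[0]
    return np.corrcoef(rx, ry)[0, 1]


class TestHpmt:
    def test_order_zero_reduces_to_mantel(self):
        rng = np.random.default_rng(1)
        a, b = random_symmetric(10, rng), random_symmetric(10, rng)
        r1 = hpmt_test(b, a, controls=None, n_perm=99, seed=5)
        r2 = mantel(a, b, n_perm=99, seed=5)
        assert r1.r == pytest.approx(r2.r, abs=1e-12)
        assert r1.p == r2.p

    def test_mantel_r_agrees_with_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(2)
        a, b = random_symmetric(12, rng), random_symmetric(12, rng)
        b = b + 0.5 * a  # some signal
        # skbio requires distance semantics: shift to non-negative
        def as_dm(m):
            v = m.to_numpy() - m.to_numpy().min()
            np.fill_diagonal(v, 0)
            return skbio_distance.DistanceMatrix(v, ids=list(m.index))
        r_sk, p_sk, _ = skbio_distance.mantel(
            as_dm(a), as_dm(b), method="pearson", permutations=999,
            alternative="greater")
        ours = mantel(a, b, n_perm=999, seed=0)
        assert ours.r == pytest.approx(r_sk, abs=1e-9)
        assert ours.p == pytest.approx(p_sk, abs=0.03)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_recursion_matches_residual_regression_oracle(self, k):
        rng = np.random.default_rng(10 + k)
        for rep in range(5):
            n = int(rng.integers(6, 11))
            y = random_symmetric(n, rng)
            x = random_symmetric(n, rng) + 0.3 * y
            controls = [random_symmetric(n, rng) + 0.2 * y
                        for _ in range(k)]
            res = hpmt_test(y, x, controls, n_perm=5, seed=0)
            oracle = residual_partial_oracle(y, x, controls)
            assert res.r == pytest.approx(oracle, abs=1e-9), (k, rep)

    def test_unbiased_p_formula(self):
        # X perfectly predicts Y: no permutation can reach the observed r
        ids = [f"i{k}" for k in range(8)]
        v = np.arange(28.0)
        x, y = matrices_from_triangles([v, 2 * v + 1], ids)
        res = hpmt_test(y, x, n_perm=999, seed=3)
        assert res.n_exceed == 0
        assert res.p == pytest.approx(1 / 1000)

    def test_consistent_relabelling_invariance(self):
        rng = np.random.default_rng(6)
        n = 9
        y, x, z = (random_symmetric(n, rng) for _ in range(3))
        x = x + 0.4 * y
        perm = rng.permutation(n)
        def relabel(m):
            out = m.iloc[perm, perm].copy()
            return out
        r1 = hpmt_test(y, x, [z], n_perm=49, seed=8)
        r2 = hpmt_test(relabel(y), relabel(x), [relabel(z)],
                       n_perm=49, seed=8)
        assert r1.r == pytest.approx(r2.r, abs=1e-12)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        a = random_symmetric(5, rng)
        b = random_symmetric(5, rng)
        b.index = b.columns = [f"Z{k}" for k in range(5)]
        with pytest.raises(ValueError):
            hpmt_test(a, b, n_perm=9)


def orthogonal_design(n_ids=8, r=0.5):
    """Y with two mutually orthogonal predictors each correlated r with Y.

    Built from an explicit orthonormal basis of the centred dyad space,
    so the correlations are exact by construction.
    """
    ndyad = n_ids * (n_ids - 1) // 2
    rng = np.random.default_rng(0)
    basis = []
    for _ in range(3):
        v = rng.normal(size=ndyad)
        v -= v.mean()
        for u in basis:
            v -= (v @ u) * u
        v /= np.linalg.norm(v)
        basis.append(v)
    e1, e2, e3 = basis
    x1, x2 = e1, e2
    # y = x1 + x2 + noise with |noise| chosen so corr(y, xi) = r
    lam = np.sqrt(1.0 / r**2 - 2.0)
    y = e1 + e2 + lam * e3
    ids = [f"i{k}" for k in range(n_ids)]
    return matrices_from_triangles([y, x1, x2], ids)


class TestMultipleDetermination:
    def test_single_factor_is_r_squared(self):
        rng = np.random.default_rng(3)
        y = random_symmetric(7, rng)
        x = random_symmetric(7, rng) + 0.5 * y
        r = matrix_pearson(y, x)
        assert multiple_determination(y, [x]) == pytest.approx(r**2)

    def test_two_orthogonal_predictors(self):
        y, x1, x2 = orthogonal_design(r=0.5)
        r2 = multiple_determination(y, [x1, x2])
        assert r2 == pytest.approx(0.5, abs=1e-9)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        y = random_symmetric(8, rng)
        xs = [random_symmetric(8, rng) + 0.3 * y for _ in range(3)]
        r2a = multiple_determination(y, xs)
        r2b = multiple_determination(y, xs[::-1])
        assert r2a == pytest.approx(r2b, abs=1e-9)

    def test_duplicated_factor_adds_nothing(self):
        rng = np.random.default_rng(5)
        y = random_symmetric(7, rng)
        x = random_symmetric(7, rng) + 0.4 * y
        single = multiple_determination(y, [x])
        doubled = multiple_determination(y, [x, x.copy()])
        assert doubled == pytest.approx(single, abs=1e-9)


class TestContributionRates:
    def test_single_factor_cr_is_r2(self):
        rng = np.random.default_rng(7)
        y = random_symmetric(7, rng)
        x = random_symmetric(7, rng) + 0.5 * y
        cr, r2 = contribution_rates(y, {"x": x})
        assert cr["x"] == pytest.approx(r2)
        assert r2 == pytest.approx(matrix_pearson(y, x) ** 2)

    def test_symmetric_orthogonal_case(self):
        y, x1, x2 = orthogonal_design(r=0.5)
        cr, r2 = contribution_rates(y, {"x1": x1, "x2": x2})
        assert cr["x1"] == pytest.approx(0.25, abs=1e-9)
        assert cr["x2"] == pytest.approx(0.25, abs=1e-9)
        assert r2 == pytest.approx(0.5, abs=1e-9)

    def test_irrelevant_factor_near_zero(self):
        rng = np.random.default_rng(8)
        y = random_symmetric(10, rng)
        x = random_symmetric(10, rng) + 0.6 * y
        noise = random_symmetric(10, rng)
        cr, _ = contribution_rates(y, {"x": x, "noise": noise})
        assert cr["noise"] < cr["x"]
        assert cr["noise"] < 0.15

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_cr_bounds_hold(self, seed):
        rng = np.random.default_rng(100 + seed)
        y = random_symmetric(9, rng)
        factors = {f"f{k}": random_symmetric(9, rng) + 0.2 * y
                   for k in range(3)}
        cr, r2 = contribution_rates(y, factors)
        assert all(0 <= v <= 1 for v in cr.values())
        assert sum(cr.values()) <= 1.0
        assert r2 <= 1.0


class TestLabelPermutation:
    def test_maximal_separation(self):
        ids = list("abcdef")
        groups = {"a": "g1", "b": "g1", "c": "g1",
                  "d": "g2", "e": "g2", "f": "g2"}
        a = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                if i != j and groups[ids[i]] == groups[ids[j]]:
                    a[i, j] = 1.0
        m = pd.DataFrame(a, index=ids, columns=ids)
        res = label_permutation_test(m, groups, n_perm=199, seed=0)
        assert res.mean_within == 1.0 and res.mean_between == 0.0
        assert res.p == pytest.approx(1 / 200)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(1)
        m = random_symmetric(4, rng)
        with pytest.raises(ValueError, match="two groups"):
            label_permutation_test(m, {i: "g" for i in m.index}, n_perm=9)

    def test_type_one_calibration(self):
        """Random labels on i.i.d. values: P is roughly uniform."""
        rng = np.random.default_rng(2)
        ps = []
        for rep in range(100):
            m = random_symmetric(8, rng)
            groups = {ind: f"g{k % 2}" for k, ind in enumerate(m.index)}
            res = label_permutation_test(m, groups, n_perm=49,
                                         seed=int(rng.integers(2**31)))
            ps.append(res.p)
        assert 0.4 < np.mean(ps) < 0.62
        assert np.mean(np.array(ps) <= 0.1) < 0.2
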