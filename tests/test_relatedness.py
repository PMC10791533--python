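"""Jacquard-state probabilities, EM relatedness and site filters."""

import itertools

import numpy as np
import pytest
from scipy import stats

from dyadkin.relatedness import (
    GenotypeLikelihoodMatrix,
    RelatednessError,
    STATE_CLASSES,
    em_estimate,
    genotype_pair_table,
    hard_call,
    hedrick_lacy_r,
    hwe_test,
    pair_genotype_prob,
    pair_loglik,
    site_filters,
    theta_from_delta,
    validate_against_pedigree,
)
from dyadkin.simulate import simulate_gls


def certain_gl(genotypes):
    """One-hot genotype likelihoods for an array of true genotypes."""
    g = np.asarray(genotypes)
    vals = np.zeros((g.shape[0], 3))
    vals[np.arange(g.shape[0]), g] = 1.0
    return vals


class TestPairGenotypeProb:
    def test_state9_is_product_of_hwe(self):
        p = 0.3
        hwe = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        for g1, g2 in itertools.product(range(3), repeat=2):
            assert pair_genotype_prob(g1, g2, 9, p) == pytest.approx(hwe[g1] * hwe[g2])

    def test_state1_single_founder_allele(self):
        p = 0.3
        assert pair_genotype_prob(2, 2, 1, p) == pytest.approx(p)
        assert pair_genotype_prob(0, 0, 1, p) == pytest.approx(1 - p)
        for g1, g2 in itertools.product(range(3), repeat=2):
            if g1 != g2 or g1 == 1:
                assert pair_genotype_prob(g1, g2, 1, p) == 0.0

    def test_each_state_sums_to_one(self):
        for state in STATE_CLASSES:
            total = sum(
                pair_genotype_prob(g1, g2, state, 0.17)
                for g1, g2 in itertools.product(range(3), repeat=2)
            )
            assert total == pytest.approx(1.0)

    def test_full_table_matches_monte_carlo_allele_drawing(self):
        """10^6 random allele draws per state reproduce every cell to 3 s.e."""
        p = 0.3
        n = 1_000_000
        rng = np.random.default_rng(42)
        for state, classes in STATE_CLASSES.items():
            draws = rng.random((n, len(classes))) < p
            g1 = np.zeros(n, dtype=int)
            g2 = np.zeros(n, dtype=int)
            for ci, cls in enumerate(classes):
                for idx in cls:
                    if idx in (0, 1):
                        g1 += draws[:, ci]
                    else:
                        g2 += draws[:, ci]
            for a, b in itertools.product(range(3), repeat=2):
                freq = np.mean((g1 == a) & (g2 == b))
                exact = pair_genotype_prob(a, b, state, p)
                se = np.sqrt(max(exact * (1 - exact), 1e-12) / n)
                assert abs(freq - exact) < max(3 * se, 1e-5)

    def test_invalid_inputs_raise(self):
        with pytest.raises(RelatednessError):
            pair_genotype_prob(0, 0, 10, 0.3)
        with pytest.raises(RelatednessError):
            pair_genotype_prob(3, 0, 9, 0.3)
        with pytest.raises(RelatednessError):
            pair_genotype_prob(0, 0, 9, 1.0)


class TestHedrickLacy:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (np.eye(9)[7], 0.5),  # outbred parent-offspring (D8 = 1)
            (0.25 * np.eye(9)[6] + 0.5 * np.eye(9)[7] + 0.25 * np.eye(9)[8], 0.5),
            (np.eye(9)[8], 0.0),  # unrelated
            (np.eye(9)[0], 1.0),  # fully inbred identical lineage
        ],
    )
    def test_closed_forms(self, delta, expected):
        assert hedrick_lacy_r(delta) == pytest.approx(expected)

    def test_invalid_simplex_raises(self):
        with pytest.raises(RelatednessError):
            hedrick_lacy_r(np.full(9, 0.5))


class TestPairLoglik:
    def test_certain_genotypes_unrelated_reduces_to_hwe(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.5, 60)
        g1 = rng.binomial(2, p)
        g2 = rng.binomial(2, p)
        delta9 = np.eye(9)[8]
        ll = pair_loglik(certain_gl(g1), certain_gl(g2), p, delta9)
        hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        expected = np.log(hwe[g1, np.arange(60)]).sum() + np.log(
            hwe[g2, np.arange(60)]
        ).sum()
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_uniform_likelihoods_carry_no_ibd_information(self):
        gl = np.full((1, 3), 1.0 / 3.0)
        p = np.array([0.3])
        vals = {
            k: pair_loglik(gl, gl, p, np.eye(9)[k]) for k in range(9)
        }
        assert max(vals.values()) - min(vals.values()) < 1e-12

    def test_matches_nested_loop_oracle(self):
        """Direct site x genotype x state summation, 100 sites, to 1e-10."""
        rng = np.random.default_rng(3)
        p = rng.uniform(0.05, 0.5, 100)
        gl_a = rng.dirichlet(np.ones(3), size=100)
        gl_b = rng.dirichlet(np.ones(3), size=100)
        delta = rng.dirichlet(np.ones(9))
        expected = 0.0
        for s in range(100):
            site = 0.0
            for g1 in range(3):
                for g2 in range(3):
                    mix = sum(
                        delta[k - 1] * pair_genotype_prob(g1, g2, k, p[s])
                        for k in STATE_CLASSES
                    )
                    site += gl_a[s, g1] * gl_b[s, g2] * mix
            expected += np.log(site)
        assert pair_loglik(gl_a, gl_b, p, delta) == pytest.approx(expected, abs=1e-10)

    def test_no_shared_sites_raises(self):
        gl = np.full((5, 3), np.nan)
        with pytest.raises(RelatednessError):
            pair_loglik(gl, gl, np.full(5, 0.3), np.eye(9)[8])


def _hard_call_em_oracle(g1, g2, p, n_iter=2000, tol=0.0):
    """Independent EM on hard genotypes, written with explicit loops."""
    deltas = np.full(9, 1.0 / 9.0)
    n = len(g1)
    pk = np.array(
        [
            [pair_genotype_prob(int(g1[s]), int(g2[s]), k, p[s]) for k in range(1, 10)]
            for s in range(n)
        ]
    )
    for _ in range(n_iter):
        site = pk @ deltas
        w = pk * deltas / site[:, None]
        new = w.mean(axis=0)
        if tol and np.abs(new - deltas).max() < tol:
            deltas = new
            break
        deltas = new
    return deltas


class TestEMEstimate:
    def test_certain_genotypes_match_hard_call_oracle(self):
        """With one-hot likelihoods the GL-EM equals a genotype-based EM."""
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.5, 400)
        # simulate a parent-offspring pair
        g_parent = rng.binomial(2, p)
        transmitted = rng.binomial(1, g_parent / 2.0)
        g_child = transmitted + rng.binomial(1, p)
        # same iteration budget for both, so the comparison isolates the
        # E/M update itself (mixture EM approaches boundary optima slowly)
        est = em_estimate(
            certain_gl(g_parent), certain_gl(g_child), p,
            tol=0.0, max_iter=1500, n_restarts=0,
        )
        oracle = _hard_call_em_oracle(g_parent, g_child, p, n_iter=1500)
        assert np.max(np.abs(est.delta - oracle)) < 1e-6
        assert est.r == pytest.approx(hedrick_lacy_r(oracle), abs=1e-6)

    def test_parent_offspring_pairs_recover_half(self, rng):
        """Simulated PO pairs at 5000 sites, depth 10, error 1%: r ~ 0.5."""
        n_sites, n_pairs = 5000, 12
        rs = []
        for _ in range(n_pairs):
            p = rng.uniform(0.05, 0.5, n_sites)
            g_parent = rng.binomial(2, p)
            g_child = rng.binomial(1, g_parent / 2.0) + rng.binomial(1, p)
            gl = simulate_gls(np.stack([g_parent, g_child]), 10.0, 0.01, rng)
            est = em_estimate(gl.values[0], gl.values[1], p, seed=0, n_restarts=1)
            rs.append(est.r)
            assert est.delta[7] > 0.8  # D8 dominates for outbred PO
        assert abs(np.mean(rs) - 0.5) < 0.05

    def test_unrelated_pairs_near_zero(self, rng):
        n_sites = 5000
        rs = []
        for _ in range(8):
            p = rng.uniform(0.05, 0.5, n_sites)
            g = rng.binomial(2, np.stack([p, p]))
            gl = simulate_gls(g, 10.0, 0.01, rng)
            est = em_estimate(gl.values[0], gl.values[1], p, seed=0, n_restarts=1)
            rs.append(est.r)
            assert est.delta[8] > 0.8
        assert np.mean(rs) < 0.05

    def test_loglik_monotone_nondecreasing(self, rng):
        p = rng.uniform(0.05, 0.5, 800)
        g = rng.binomial(2, np.stack([p, p]))
        gl = simulate_gls(g, 6.0, 0.02, rng)
        est = em_estimate(gl.values[0], gl.values[1], p, seed=1)
        diffs = np.diff(est.loglik_trace)
        assert np.all(diffs >= -1e-9)

    def test_pair_symmetry(self, rng):
        p = rng.uniform(0.05, 0.5, 1500)
        g_parent = rng.binomial(2, p)
        g_child = rng.binomial(1, g_parent / 2.0) + rng.binomial(1, p)
        gl = simulate_gls(np.stack([g_parent, g_child]), 8.0, 0.01, rng)
        ab = em_estimate(gl.values[0], gl.values[1], p, n_restarts=0, tol=1e-10)
        ba = em_estimate(gl.values[1], gl.values[0], p, n_restarts=0, tol=1e-10)
        assert ab.r == pytest.approx(ba.r, abs=1e-6)
        swap = ba.delta[[0, 1, 4, 5, 2, 3, 6, 7, 8]]  # D3<->D5, D4<->D6
        assert np.max(np.abs(ab.delta - swap)) < 1e-4
        assert ab.f_a == pytest.approx(ba.f_b, abs=1e-4)

    def test_minor_allele_relabelling_invariance(self, rng):
        """Flipping which allele is minor at any site leaves r unchanged."""
        p = rng.uniform(0.05, 0.5, 1000)
        g_parent = rng.binomial(2, p)
        g_child = rng.binomial(1, g_parent / 2.0) + rng.binomial(1, p)
        gl = simulate_gls(np.stack([g_parent, g_child]), 10.0, 0.01, rng)
        flip = rng.random(1000) < 0.5
        p2 = np.where(flip, 1 - p, p)
        vals2 = gl.values.copy()
        vals2[:, flip, :] = vals2[:, flip, ::-1]
        a1 = em_estimate(gl.values[0], gl.values[1], p, n_restarts=0, tol=1e-10)
        a2 = em_estimate(vals2[0], vals2[1], p2, n_restarts=0, tol=1e-10)
        assert a1.r == pytest.approx(a2.r, abs=1e-8)

    def test_few_shared_sites_warns(self):
        p = np.full(10, 0.3)
        gl = certain_gl(np.zeros(10, dtype=int))
        with pytest.warns(UserWarning, match="shared sites"):
            em_estimate(gl, gl, p)


class TestGenotypeLikelihoodMatrix:
    def test_normalization_enforced(self):
        vals = np.full((1, 2, 3), 0.4)
        with pytest.raises(RelatednessError, match="not normalized"):
            GenotypeLikelihoodMatrix(["a"], ["s1", "s2"], vals)

    def test_missing_mask_and_row_lookup(self):
        vals = np.full((2, 2, 3), 1 / 3)
        vals[0, 1] = np.nan
        gl = GenotypeLikelihoodMatrix(["a", "b"], ["s1", "s2"], vals)
        assert gl.missing.tolist() == [[False, True], [False, False]]
        with pytest.raises(RelatednessError):
            gl.row("zz")


class TestSiteFilters:
    def test_monomorphic_and_hwe_and_missingness(self, rng):
        """200-site toy panel with planted violations vs per-site recount."""
        n_ind, n_sites = 80, 200
        p = rng.uniform(0.1, 0.4, n_sites)
        g = rng.binomial(2, p, size=(n_ind, n_sites))
        g[:, 0] = 0  # monomorphic
        g[:, 1] = np.where(rng.random(n_ind) < 0.5, 0, 2)  # extreme HWE violation
        gl = simulate_gls(g, 30.0, 0.001, rng)
        gl.values[: int(0.2 * n_ind), 2] = np.nan  # 20% missing at site 2
        keep = set(site_filters(gl, min_ind_frac=0.9, hwe_alpha=0.001, maf_min=0.05))
        assert 0 not in keep and 1 not in keep and 2 not in keep
        # oracle: recompute the three rules per site from hard calls
        calls = hard_call(gl)
        expected = set()
        for s in range(n_sites):
            obs = calls[:, s][calls[:, s] >= 0]
            if len(obs) < 0.9 * n_ind:
                continue
            maf = (2 * (obs == 2).sum() + (obs == 1).sum()) / (2 * len(obs))
            maf = min(maf, 1 - maf)
            if maf < 0.05:
                continue
            if hwe_test((obs == 0).sum(), (obs == 1).sum(), (obs == 2).sum()).p_value < 0.001:
                continue
            expected.add(s)
        assert keep == expected

    def test_exact_hwe_counts_retained(self):
        res = hwe_test(36, 48, 16)  # p=0.4 exactly at HWE proportions
        assert res.lrt == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)


class TestValidation:
    def _estimates(self, pairs_r):
        from dyadkin.relatedness import RelatednessEstimate

        out = []
        for (a, b), r in pairs_r.items():
            # delta with the requested Hedrick-Lacy r (outbred mixture of D8/D9)
            d = np.zeros(9)
            d[7] = 2 * r
            d[8] = 1 - 2 * r
            out.append(
                RelatednessEstimate(pair=(a, b), delta=d, n_sites=100, loglik=0.0,
                                    n_iter=1, converged=True)
            )
        return out

    def test_perfect_agreement(self):
        from dyadkin.pedigree import Pedigree

        ped = Pedigree.from_trios([("c", "f", "m"), ("d", "f", "m"), ("e", "f", "x")])
        ests = self._estimates({("c", "f"): 0.5, ("c", "d"): 0.5, ("c", "e"): 0.25, ("f", "m"): 0.0})
        res = validate_against_pedigree(ests, ped)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_estimates_give_zero_r2(self):
        from dyadkin.pedigree import Pedigree

        ped = Pedigree.from_trios([("c", "f", "m"), ("d", "f", "m"), ("e", "f", "x")])
        ests = self._estimates({("c", "f"): 0.1, ("c", "d"): 0.1, ("c", "e"): 0.1})
        assert validate_against_pedigree(ests, ped).r_squared == pytest.approx(0.0, abs=1e-12)

    def test_too_few_pairs_raises(self):
        from dyadkin.pedigree import Pedigree

        ped = Pedigree.from_trios([("c", "f", "m")])
        with pytest.raises(RelatednessError):
            validate_against_pedigree(self._estimates({("c", "f"): 0.5}), ped)
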