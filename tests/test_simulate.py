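"""Community simulator: mate choice, gene dropping, likelihood noise."""

import datetime as dt

import numpy as np
import pytest
from scipy import stats

from dyadkin.demography import philopatry_rate
from dyadkin.pedigree import Pedigree
from dyadkin.simulate import (
    ExtinctionError,
    SimulationConfig,
    allele_frequencies,
    gene_drop,
    mate_choice,
    sample_unrelated,
    simulate_community,
    simulate_dataset,
    simulate_gls,
)


class TestMateChoice:
    class FlatKin:
        def __init__(self, rel):
            self.rel = rel

        def relatedness(self, a, b):
            return self.rel.get(b, 0.0)

    def test_gamma_zero_is_uniform(self, rng):
        kin = self.FlatKin({"m1": 0.5, "m2": 0.0, "m3": 0.25, "m4": 0.1})
        males = ["m1", "m2", "m3", "m4"]
        counts = {m: 0 for m in males}
        for _ in range(10_000):
            counts[mate_choice("mom", males, 0.0, kin, rng)] += 1
        chi2 = sum((c - 2500) ** 2 / 2500 for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.999, df=3)

    def test_gamma_infinite_limit_picks_unrelated(self, rng):
        kin = self.FlatKin({"kin": 0.5, "stranger": 0.0})
        for _ in range(200):
            assert mate_choice("mom", ["kin", "stranger"], 1e6, kin, rng) == "stranger"

    def test_selection_ratio_matches_exponential_weights(self, rng):
        """gamma=20 with candidates at r in {0, 0.25}: closed-form odds."""
        gamma = 20.0
        kin = self.FlatKin({"rel": 0.25, "unrel": 0.0})
        n = 10_000
        hits = sum(
            mate_choice("mom", ["rel", "unrel"], gamma, kin, rng) == "rel"
            for _ in range(n)
        )
        expected = np.exp(-gamma * 0.25) / (1 + np.exp(-gamma * 0.25))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < max(4 * se, 5e-3)

    def test_empty_candidates_no_conception(self, rng):
        assert mate_choice("mom", [], 0.0, self.FlatKin({}), rng) is None


class TestGeneDrop:
    def test_homozygote_parents_are_mendelian(self, rng):
        ped = Pedigree.from_trios([("kid", "pa", "ma")])
        freqs = np.full(50, 0.5)
        geno = gene_drop(ped, freqs, rng)
        geno["pa"][:] = 0
        geno["ma"][:] = 0
        # redrop with parents forced homozygous: child of two 0-dosage parents
        child = rng.binomial(1, geno["pa"] / 2.0) + rng.binomial(1, geno["ma"] / 2.0)
        assert np.all(child == 0)

    def test_full_sib_realized_relatedness(self, rng):
        """Genotype-correlation r of full sibs averages 0.5 over 10k sites."""
        ped = Pedigree.from_trios([("s1", "f", "m"), ("s2", "f", "m")])
        freqs = rng.uniform(0.05, 0.5, 10_000)
        geno = gene_drop(ped, freqs, rng)
        a = geno["s1"] - 2 * freqs
        b = geno["s2"] - 2 * freqs
        denom = 2 * freqs * (1 - freqs)
        r = np.mean(a * b / denom)
        assert r == pytest.approx(0.5, abs=0.02)

    def test_founder_genotypes_at_hwe(self, rng):
        freqs = np.full(3000, 0.3)
        ped = Pedigree.from_trios([("f1", None, None)])
        g = gene_drop(ped, freqs, rng)["f1"]
        counts = [np.sum(g == k) for k in range(3)]
        expected = np.array([0.49, 0.42, 0.09]) * 3000
        chi2 = sum((c - e) ** 2 / e for c, e in zip(counts, expected))
        assert chi2 < stats.chi2.ppf(0.999, df=2)

    def test_pedigree_expectation_equals_gene_drop_mean(self, rng):
        """Realized correlation-based r matches path-counting expectation."""
        ped = Pedigree.from_trios(
            [("c1", "f", "m"), ("c2", "f", "m"), ("g", "c1", "other")]
        )
        freqs = rng.uniform(0.1, 0.5, 20_000)
        geno = gene_drop(ped, freqs, rng)
        for a, b in [("c1", "c2"), ("g", "c2"), ("g", "f")]:
            za = geno[a] - 2 * freqs
            zb = geno[b] - 2 * freqs
            realized = np.mean(za * zb / (2 * freqs * (1 - freqs)))
            assert realized == pytest.approx(ped.expected_relatedness(a, b), abs=0.03)


class TestSimulateGLs:
    def test_noiseless_high_depth_concentrates_on_truth(self, rng):
        g = np.array([[2, 0, 1]])
        gl = simulate_gls(g, 60.0, 0.0, rng)
        for s in range(3):
            assert np.nanargmax(gl.values[0, s]) == g[0, s]
            assert gl.values[0, s].max() > 0.999

    def test_depth_zero_is_missing(self, rng):
        g = np.zeros((1, 4000), dtype=int)
        gl = simulate_gls(g, 0.05, 0.01, rng)  # nearly all sites depth 0
        assert gl.missing.mean() > 0.9

    def test_hard_call_accuracy_matches_analytic_error(self, rng):
        """Misclassification at depth ~ Poisson(10), error 1%, vs closed form."""
        lam, eps = 10.0, 0.01
        n = 60_000
        g = np.ones(n, dtype=int)  # heterozygotes: the hardest genotype
        gl = simulate_gls(g[None, :], lam, eps, rng)
        calls = np.nanargmax(np.where(np.isnan(gl.values[0]), -1.0, gl.values[0]), axis=1)
        observed_ok = np.mean(calls[~gl.missing[0]] == 1)
        # analytic: P(het call correct | depth d) summed over Poisson depths
        p_ok = 0.0
        norm = 0.0
        for d in range(1, 60):
            pd = stats.poisson.pmf(d, lam)
            norm += pd
            ks = np.arange(d + 1)
            lik1 = stats.binom.pmf(ks, d, 0.5)
            lik0 = stats.binom.pmf(ks, d, eps)
            lik2 = stats.binom.pmf(ks, d, 1 - eps)
            correct = (lik1 > lik0) & (lik1 > lik2)
            p_ok += pd * np.sum(stats.binom.pmf(ks, d, 0.5) * correct)
        p_ok /= norm
        assert observed_ok == pytest.approx(p_ok, abs=0.01)

    def test_triples_normalized(self, rng):
        g = rng.integers(0, 3, size=(3, 100))
        gl = simulate_gls(g, 5.0, 0.02, rng)
        sums = gl.values.sum(axis=2)
        assert np.allclose(sums[~np.isnan(sums)], 1.0, atol=1e-12)


class TestSimulateCommunity:
    def test_philopatry_matches_config(self):
        """Emigration prob 0.5 over a long horizon: measured rate ~ 50%."""
        cfg = SimulationConfig(seed=3, years=45, n_founders=40)
        comm = simulate_community(cfg)
        res = philopatry_rate(
            comm.records, dt.date(cfg.start_year, 1, 1),
            dt.date(cfg.start_year + cfg.years, 1, 1),
        )
        # binomial tolerance around 50%
        se = np.sqrt(0.25 / res.denominator)
        assert abs(res.rate / 100 - 0.5) < 4 * se

    def test_zero_emigration_gives_full_philopatry(self):
        cfg = SimulationConfig(seed=4, years=35, female_emigration_prob=0.0)
        comm = simulate_community(cfg)
        res = philopatry_rate(
            comm.records, dt.date(cfg.start_year, 1, 1),
            dt.date(cfg.start_year + cfg.years, 1, 1),
        )
        assert res.rate == 100.0

    def test_random_mating_null_balances_actual_and_potential(self):
        """gamma=0: mean hidden-pedigree r of actual vs potential pairs agree."""
        from dyadkin.demography import enumerate_parent_pairs

        diffs = []
        for seed in range(6):
            cfg = SimulationConfig(seed=100 + seed, years=35, n_founders=30)
            comm = simulate_community(cfg)
            hidden = comm.truth.hidden_pedigree
            pairs = enumerate_parent_pairs(comm.parentage, comm.records)
            r = np.array(
                [
                    hidden.expected_relatedness(a, b)
                    for a, b in zip(pairs["mother_id"], pairs["male_id"])
                ]
            )
            act = pairs["pair_kind"].to_numpy() == "actual"
            diffs.append(r[act].mean() - r[~act].mean())
        # two-sample difference within Monte-Carlo error of zero
        assert abs(np.mean(diffs)) < 2.5 * np.std(diffs) / np.sqrt(len(diffs)) + 0.01

    def test_strong_avoidance_lowers_actual_relatedness(self):
        from dyadkin.demography import enumerate_parent_pairs

        cfg = SimulationConfig(seed=21, years=35, n_founders=30, avoidance_gamma=30.0)
        comm = simulate_community(cfg)
        hidden = comm.truth.hidden_pedigree
        pairs = enumerate_parent_pairs(comm.parentage, comm.records)
        r = np.array(
            [
                hidden.expected_relatedness(a, b)
                for a, b in zip(pairs["mother_id"], pairs["male_id"])
            ]
        )
        act = pairs["pair_kind"].to_numpy() == "actual"
        assert r[act].mean() < r[~act].mean()

    def test_extinction_raises(self):
        cfg = SimulationConfig(
            seed=5, years=30, n_founders=4, birth_prob=0.0, annual_immigration=0.0,
            adult_mortality=0.4, senescent_mortality=0.9, infant_mortality=0.4,
        )
        with pytest.raises(ExtinctionError):
            simulate_community(cfg)

    def test_same_seed_reproduces_everything(self):
        cfg = SimulationConfig(seed=9, years=25)
        a = simulate_community(cfg)
        b = simulate_community(cfg)
        assert [r.id for r in a.records] == [r.id for r in b.records]
        assert [r.birth_date for r in a.records] == [r.birth_date for r in b.records]
        assert a.truth.sires == b.truth.sires

    def test_observable_pedigree_masks_immigrant_ancestry(self, small_dataset):
        comm = small_dataset.community
        for rec in comm.records:
            if rec.natality == "immigrant":
                assert comm.pedigree.parents(rec.id) == (None, None)
                sire, dam = comm.truth.hidden_pedigree.parents(rec.id)
                assert sire is not None and dam is not None

    def test_invariants_of_records(self, small_dataset):
        comm = small_dataset.community
        for rec in comm.records:
            if rec.natality == "immigrant":
                assert rec.immigration_date is not None
            if rec.death_date is not None:
                assert rec.death_date >= rec.birth_date


class TestDataset:
    def test_panel_frequencies_close_to_truth(self, small_dataset):
        err = np.abs(small_dataset.freqs_panel - small_dataset.freqs_true)
        assert np.mean(err) < 0.06

    def test_allele_frequency_shrinkage_stays_interior(self, rng):
        g = np.zeros((10, 5), dtype=int)
        f = allele_frequencies(g)
        assert np.all((f > 0) & (f < 1))

    def test_gl_matrix_covers_genotyped_individuals(self, small_dataset):
        comm = small_dataset.community
        genotyped = {r.id for r in comm.records if r.in_genetic_dataset}
        assert set(small_dataset.gl.individuals) == genotyped

    def test_panel_is_unrelated_sample(self, rng):
        freqs = rng.uniform(0.1, 0.5, 2000)
        panel = sample_unrelated(40, freqs, rng)
        assert panel.shape == (40, 2000)
        # mean genotype matches 2p
        assert np.allclose(panel.mean(axis=0), 2 * freqs, atol=0.5)
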