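"""Region recurrence/clustering machinery: promoters, background model,
Poisson-binomial tails, clustering permutation, Fisher combination,
expression validation and the orchestrated pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import COVARIATES, enumerate_poisson_binomial
from leukdriver import synthetic_cohort as sc
from leukdriver.noncoding_drivers import (
    build_promoter_regions,
    clustering_permutation_test,
    expression_association,
    fisher_combine,
    fit_background,
    poisson_binomial_pmf,
    poisson_binomial_tail,
    poisson_binomial_tail_batch,
    run_region_pipeline,
)


class TestPromoters:
    def test_single_tss_plus_strand(self):
        tx = pd.DataFrame(
            [{"gene": "G", "contig": "chr1", "tss": 10_000, "strand": "+"}]
        )
        out = build_promoter_regions(tx)
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (8000, 10_000)

    def test_minus_strand_window_upstream(self):
        tx = pd.DataFrame(
            [{"gene": "G", "contig": "chr1", "tss": 10_000, "strand": "-"}]
        )
        out = build_promoter_regions(tx)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (10_001, 12_001)

    def test_two_tss_500bp_apart_merge_to_2500bp(self):
        tx = pd.DataFrame(
            [
                {"gene": "G", "contig": "chr1", "tss": 10_000, "strand": "+"},
                {"gene": "G", "contig": "chr1", "tss": 10_500, "strand": "+"},
            ]
        )
        out = build_promoter_regions(tx)
        assert len(out) == 1
        assert out.loc[0, "end"] - out.loc[0, "start"] == 2500

    def test_coding_overlap_subtracted(self):
        tx = pd.DataFrame(
            [{"gene": "G", "contig": "chr1", "tss": 10_000, "strand": "+"}]
        )
        cds = pd.DataFrame(
            [{"contig": "chr1", "start": 9000, "end": 9500}]
        )
        out = build_promoter_regions(tx, cds)
        spans = sorted((s, e) for s, e in zip(out["start"], out["end"]))
        assert spans == [(8000, 9000), (9500, 10_000)]

    def test_fully_masked_promoter_excluded(self):
        tx = pd.DataFrame(
            [{"gene": "G", "contig": "chr1", "tss": 10_000, "strand": "+"}]
        )
        cds = pd.DataFrame([{"contig": "chr1", "start": 7000, "end": 11_000}])
        out = build_promoter_regions(tx, cds)
        assert len(out) == 0


class TestPoissonBinomial:
    def test_degenerate_all_zero(self):
        assert poisson_binomial_tail([0, 0, 0], 0)[0] == 1.0
        assert poisson_binomial_tail([0, 0, 0], 1)[0] == 0.0

    def test_three_probability_enumeration_oracle(self):
        # P(K >= 2) for p = (0.1, 0.2, 0.3): enumeration over 2^3 outcomes
        pmf = enumerate_poisson_binomial([0.1, 0.2, 0.3])
        expected = pmf[2:].sum()
        assert expected == pytest.approx(0.098)
        assert poisson_binomial_tail([0.1, 0.2, 0.3], 2)[0] == pytest.approx(expected)

    def test_equal_p_reduces_to_binomial(self):
        p, method = poisson_binomial_tail([0.5] * 10, 5)
        assert method == "exact"
        assert p == pytest.approx(0.623046875)

    def test_dp_matches_enumeration_small_n(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 13))
            probs = rng.random(n)
            pmf = poisson_binomial_pmf(probs)
            oracle = enumerate_poisson_binomial(probs)
            np.testing.assert_allclose(pmf, oracle, atol=1e-12)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_tail_nonincreasing_in_k(self, rng):
        probs = rng.random(30)
        tails = [poisson_binomial_tail(probs, k)[0] for k in range(31)]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))

    def test_k_above_n_returns_zero(self):
        assert poisson_binomial_tail([0.5], 2)[0] == 0.0

    def test_refined_normal_close_to_exact_at_crossover(self, rng):
        probs = rng.uniform(0.01, 0.3, 2000)
        k = int(probs.sum() + 2 * np.sqrt((probs * (1 - probs)).sum()))
        exact, m1 = poisson_binomial_tail(probs, k)
        approx, m2 = poisson_binomial_tail(probs, k, exact_limit=100)
        assert (m1, m2) == ("exact", "refined-normal")
        assert approx == pytest.approx(exact, abs=1e-3)

    def test_batch_matches_single(self, rng):
        pmat = rng.random((40, 25))
        ks = rng.integers(0, 41, 25)
        batch = poisson_binomial_tail_batch(pmat, ks)
        single = [poisson_binomial_tail(pmat[:, j], int(ks[j]))[0]
                  for j in range(25)]
        np.testing.assert_allclose(batch, single, atol=1e-12)


class TestBackgroundModel:
    def test_zero_effect_truth_recovered_within_3se(self):
        cfg = sc.CohortConfig(
            n_samples=20, n_regions=500, covariate_effects=(0, 0, 0, 0), seed=8
        )
        c = sc.generate_cohort(cfg)
        bg = fit_background(c.truth["mutated_matrix"], c.regions[COVARIATES])
        # pooled slope means should be within ~3 pooled SE of zero
        mean_beta = bg.coefficients[:, 1:].mean(axis=0)
        assert np.all(np.abs(mean_beta) < 0.3)

    def test_gc_effect_recovered(self):
        cfg = sc.CohortConfig(n_samples=30, n_regions=2000, seed=9)
        c = sc.generate_cohort(cfg)
        bg = fit_background(c.truth["mutated_matrix"], c.regions[COVARIATES])
        assert bg.coefficients[:, 1].mean() == pytest.approx(1.0, abs=0.2)

    def test_zero_mutation_tumour_gets_floor_probability(self):
        mutated = np.zeros((3, 100), dtype=bool)
        mutated[0, :10] = True
        cov = pd.DataFrame({"gc": np.linspace(0.3, 0.7, 100)})
        bg = fit_background(mutated, cov)
        assert not bg.converged[1]
        np.testing.assert_allclose(bg.probabilities[1], 1 / 200)

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            fit_background(np.zeros((2, 10)), pd.DataFrame({"gc": np.zeros(10)}))


class TestClusteringPermutation:
    def test_five_mutations_not_tested(self, rng):
        assert clustering_permutation_test([1, 2, 3, 4, 5], 1000, rng=rng) is None

    def test_six_mutations_tested(self, rng):
        p = clustering_permutation_test([1, 2, 3, 500, 700, 900], 1000, rng=rng)
        assert p is not None and 0 < p <= 1

    def test_coincident_positions_extreme(self, rng):
        p = clustering_permutation_test([100] * 6, 1000, n_perm=10_000, rng=rng)
        assert p <= 1e-3

    def test_null_p_uniform(self, rng):
        """Positions drawn uniformly: empirical P approximately uniform."""
        ps = []
        for _ in range(200):
            pos = rng.integers(0, 1000, size=8)
            ps.append(
                clustering_permutation_test(pos, 1000, n_perm=500, rng=rng)
            )
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.001


class TestFisherCombine:
    def test_both_one(self):
        assert fisher_combine(1.0, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("p1,p2", [(0.05, 0.05), (0.5, 0.5), (0.01, 0.9)])
    def test_matches_chi2_closed_form(self, p1, p2):
        x = -2 * (np.log(p1) + np.log(p2))
        assert fisher_combine(p1, p2) == pytest.approx(stats.chi2.sf(x, 4))

    def test_worked_values(self):
        assert fisher_combine(0.05, 0.05) == pytest.approx(0.0175, abs=5e-4)
        assert fisher_combine(0.5, 0.5) == pytest.approx(0.5966, abs=5e-4)

    def test_zero_clamped(self):
        assert fisher_combine(0.0, 0.5) > 0.0


class TestExpressionAssociation:
    def _setup(self, shift=1.0, n_mut=10, n_tot=60, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"S{i}" for i in range(n_tot)]
        tpm = rng.lognormal(2, 0.5, n_tot)
        tpm[:n_mut] *= shift
        expr = pd.DataFrame([tpm], index=["G"], columns=samples)
        tested = pd.DataFrame([{"region_id": "r", "gene": "G"}])
        mut = {"r": set(samples[:n_mut])}
        return expr, tested, mut, samples

    def test_planted_shift_detected(self):
        hits = 0
        for seed in range(10):
            expr, tested, mut, _ = self._setup(shift=5.0, seed=seed)
            out = expression_association(expr, tested, mut)
            hits += out.loc[0, "p_expr"] < 0.05
        assert hits >= 8

    def test_null_p_not_extreme(self):
        ps = []
        for seed in range(20):
            expr, tested, mut, _ = self._setup(shift=1.0, seed=seed)
            ps.append(expression_association(expr, tested, mut).loc[0, "p_expr"])
        assert (np.array(ps) < 0.05).mean() <= 0.25

    def test_all_mutated_cnv_excluded_gives_missing(self):
        expr, tested, mut, samples = self._setup()
        out = expression_association(
            expr, tested, mut, cnv_excluded_samples={"r": set(samples[:10])}
        )
        assert np.isnan(out.loc[0, "p_expr"])
        assert out.loc[0, "reason"] == "too_few_samples"


class TestPipeline:
    def test_empty_variant_set_all_burden_p_one(self):
        cfg = sc.CohortConfig(n_samples=10, n_regions=100, background_rate=0.0,
                              seed=4)
        c = sc.generate_cohort(cfg)
        res = run_region_pipeline(
            c.variants, c.regions, COVARIATES, list(c.samples["sample_id"]),
            seed=4,
        )
        np.testing.assert_allclose(res.table["p_burden"], 1.0)

    def test_deterministic_given_seed(self):
        cfg = sc.CohortConfig(n_samples=20, n_regions=150, seed=5)
        c = sc.generate_cohort(cfg)
        args = (c.variants, c.regions, COVARIATES, list(c.samples["sample_id"]))
        r1 = run_region_pipeline(*args, n_perm=500, seed=11)
        r2 = run_region_pipeline(*args, n_perm=500, seed=11)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_planted_driver_ranked_first(self):
        cfg = sc.CohortConfig(
            n_samples=100, n_regions=300, seed=6,
            planted_drivers=[sc.PlantedDriver("R00010", recurrence_multiplier=8,
                                              cluster_width=30)],
        )
        c = sc.generate_cohort(cfg)
        res = run_region_pipeline(
            c.variants, c.regions, COVARIATES, list(c.samples["sample_id"]),
            n_perm=2000, seed=6,
        )
        assert res.table.iloc[0]["region_id"] == "R00010"
        assert res.table.iloc[0]["q"] < 0.1
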