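"""Null model fit, score statistic, mixture weights, p-values, and scans."""

import numpy as np
import pytest

from smckat import (
    CNVDataError,
    CNVProfile,
    CNVRecord,
    DELETION,
    AMPLIFICATION,
    PhenotypeTable,
    davies_pvalue,
    fit_null_logistic,
    kernel_matrix,
    mixture_weights,
    scan_regions,
    score_statistic,
    smckat_test,
)
from smckat.association import (
    bonferroni_threshold,
    conditional_moment_pvalue,
    results_to_frame,
    threshold_2sf,
)

from conftest import CHR8_BANDS


def pheno_of(y, ids=None, covariates=None):
    y = np.asarray(y, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(y))]
    return PhenotypeTable(sample_ids=list(ids), y=y, covariates=covariates)


class TestFitNullLogistic:
    def test_intercept_only_fits_sample_mean(self):
        null = fit_null_logistic(pheno_of([1, 1, 1, 1, 1, 1, 0, 0, 0, 0]))
        assert np.allclose(null.fitted_probabilities, 0.6, atol=1e-8)

    def test_constant_y_rejected(self):
        with pytest.raises(CNVDataError, match="single phenotype class"):
            fit_null_logistic(pheno_of([1, 1, 1, 1]))

    def test_saturated_binary_covariate_fits_group_means(self):
        # balanced 2x2: fitted probabilities are the per-group proportions
        z = np.array([[0.0], [0.0], [0.0], [0.0], [1.0], [1.0], [1.0], [1.0]])
        y = [0, 0, 0, 1, 0, 1, 1, 1]
        null = fit_null_logistic(pheno_of(y, covariates=z))
        assert np.allclose(null.fitted_probabilities[:4], 0.25, atol=1e-6)
        assert np.allclose(null.fitted_probabilities[4:], 0.75, atol=1e-6)

    def test_perfect_separation_rejected(self):
        z = np.array([[-2.0], [-1.5], [-1.0], [1.0], [1.5], [2.0]])
        y = [0, 0, 0, 1, 1, 1]
        with pytest.raises(CNVDataError, match="separation"):
            fit_null_logistic(pheno_of(y, covariates=z))

    def test_rank_deficient_covariates_rejected(self):
        z = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        with pytest.raises(CNVDataError, match="rank"):
            fit_null_logistic(pheno_of([0, 1, 0, 1], covariates=z))


class TestScoreStatistic:
    def test_zero_residuals_give_zero(self):
        K = np.eye(3)
        y = np.array([0.0, 1.0, 0.0])
        assert score_statistic(y, y, K) == 0.0

    def test_identity_kernel_gives_residual_sum_of_squares(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        fitted = np.full(4, 0.5)
        assert score_statistic(y, fitted, np.eye(4)) == pytest.approx(1.0)

    def test_hand_quadratic_form(self):
        K = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        y = np.array([1.0, 0.0, 0.5])
        fitted = np.array([0.5, 0.5, 0.5])
        # r = (0.5, -0.5, 0): 0.25 + 0.25 - 2*0.5*0.25 = 0.25
        assert score_statistic(y, fitted, K) == pytest.approx(0.25)

    def test_sample_order_mismatch_rejected(self, rng, cohort_factory):
        profiles = cohort_factory(rng, 4, min_len=2, max_len=4)
        K = kernel_matrix(profiles, 2)
        y = np.array([0.0, 1.0, 0.0, 1.0])
        with pytest.raises(CNVDataError, match="align"):
            score_statistic(y, y * 0.5, K, sample_ids=["s1", "s0", "s2", "s3"])

    def test_permutation_invariance(self, rng, cohort_factory):
        profiles = cohort_factory(rng, 6, min_len=2, max_len=5)
        K = kernel_matrix(profiles, 2).values
        y = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        fitted = np.full(6, y.mean())
        q0 = score_statistic(y, fitted, K)
        perm = rng.permutation(6)
        q1 = score_statistic(y[perm], fitted[perm], K[np.ix_(perm, perm)])
        assert q1 == pytest.approx(q0)


class TestMixtureWeights:
    def test_zero_kernel_gives_empty_weights(self):
        null = fit_null_logistic(pheno_of([0, 1, 0, 1]))
        assert mixture_weights(np.zeros((4, 4)), null).size == 0

    def test_centering_projection_closed_form(self):
        # intercept-only with fitted 0.5: P = 0.25 (I - J/4); with K = I the
        # weights are 0.25 with multiplicity 3
        null = fit_null_logistic(pheno_of([1, 1, 0, 0]))
        w = mixture_weights(np.eye(4), null)
        assert np.allclose(w, 0.25, atol=1e-10)
        assert len(w) == 3

    def test_weight_sum_equals_trace_identity(self, rng, cohort_factory):
        profiles = cohort_factory(rng, 8, min_len=1, max_len=6)
        K = kernel_matrix(profiles, 2).values
        y = (rng.random(8) < 0.5).astype(float)
        if y.sum() in (0, 8):
            y[0] = 1 - y[0]
        null = fit_null_logistic(pheno_of(y))
        v = null.fitted_probabilities * (1 - null.fitted_probabilities)
        X = null.design
        VX = X * v[:, None]
        P = np.diag(v) - VX @ np.linalg.solve(X.T @ VX, VX.T)
        w = mixture_weights(K, null)
        assert w.sum() == pytest.approx(np.trace(P @ K), abs=1e-8)


class TestDaviesPvalue:
    def test_single_weight_95th_percentile(self):
        res = davies_pvalue(3.841459, [1.0])
        assert res.p == pytest.approx(0.05, abs=1e-5)
        assert res.method == "davies"

    def test_two_weights_closed_form(self):
        res = davies_pvalue(5.991465, [1.0, 1.0])
        assert res.p == pytest.approx(0.05, abs=1e-5)

    def test_empty_weights_degenerate(self):
        res = davies_pvalue(1.0, [])
        assert res.p == 1.0 and res.method == "degenerate"

    def test_deep_tail_stays_positive_and_monotone(self):
        lam = [2.0, 1.0, 0.5]
        ps = [davies_pvalue(q, lam).p for q in (50.0, 80.0, 120.0)]
        assert all(p > 0 for p in ps)
        assert ps[0] > ps[1] > ps[2]


class TestConditionalMomentPvalue:
    def test_deterministic(self, rng, cohort_factory):
        profiles = cohort_factory(rng, 10, min_len=1, max_len=5)
        K = kernel_matrix(profiles, 2)
        y = np.array([1.0] * 3 + [0.0] * 7)
        q = 5.0
        assert conditional_moment_pvalue(q, K, y) == conditional_moment_pvalue(
            q, K, y
        )

    def test_monotone_in_q(self, rng, cohort_factory):
        profiles = cohort_factory(rng, 10, min_len=1, max_len=5)
        K = kernel_matrix(profiles, 2)
        y = np.array([1.0] * 4 + [0.0] * 6)
        ps = [conditional_moment_pvalue(q, K, y) for q in (1.0, 5.0, 20.0)]
        assert ps[0] >= ps[1] >= ps[2]


class TestSmckatTest:
    def test_all_zero_kernel_is_degenerate(self, rng, profile_factory):
        # every profile shorter than the window
        profiles = [profile_factory(rng, f"s{i}", 1) for i in range(6)]
        pheno = pheno_of([0, 1, 0, 1, 0, 1])
        with pytest.warns(UserWarning):
            result = smckat_test(profiles, pheno, 3)
        assert result.degenerate and result.p_value == 1.0

    def test_separated_cohort_detected(self, rng):
        # cases share a long amplified region that controls lack
        profiles = []
        y = []
        for i in range(30):
            case = i < 15
            records = [
                CNVRecord(
                    "1",
                    1_000 + int(rng.integers(0, 200)),
                    60_000 + int(rng.integers(0, 200)),
                    AMPLIFICATION if case else DELETION,
                    5 if case else 1,
                ),
                CNVRecord(
                    "1",
                    100_000 + int(rng.integers(0, 500)),
                    150_000 + int(rng.integers(0, 500)),
                    AMPLIFICATION if case else DELETION,
                    6 if case else 0,
                ),
            ]
            profiles.append(CNVProfile(f"s{i}", tuple(records)))
            y.append(1.0 if case else 0.0)
        result = smckat_test(profiles, pheno_of(y), 1)
        assert result.p_value < 0.05

    def test_alignment_is_by_sample_id(self, rng, cohort_factory):
        profiles = cohort_factory(rng, 6, min_len=2, max_len=5)
        y = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        ids = [p.sample_id for p in profiles]
        direct = smckat_test(profiles, pheno_of(y, ids), 2)
        shuffled = PhenotypeTable(
            sample_ids=ids[::-1], y=y[::-1].copy()
        )
        assert smckat_test(profiles, shuffled, 2).Q == pytest.approx(direct.Q)

    def test_missing_sample_rejected(self, rng, cohort_factory):
        profiles = cohort_factory(rng, 4, min_len=2, max_len=4)
        pheno = pheno_of([0, 1, 0, 1], ids=["s0", "s1", "s2", "other"])
        with pytest.raises(CNVDataError, match="missing sample"):
            smckat_test(profiles, pheno, 2)

    def test_mixture_p_recorded_alongside_adjusted_p(self, rng, cohort_factory):
        profiles = cohort_factory(rng, 10, min_len=1, max_len=5)
        y = (np.arange(10) < 4).astype(float)
        result = smckat_test(profiles, pheno_of(y), 2)
        assert result.method == "conditional_moment"
        assert result.p_value_mixture is not None
        never = smckat_test(
            profiles, pheno_of(y), 2, small_sample="never"
        )
        assert never.method in ("davies", "moment_matching")
        assert never.p_value == pytest.approx(result.p_value_mixture)


class TestScanRegions:
    def test_chromosome_scan_thresholds(self, rng, profile_factory):
        chroms = [str(c) for c in range(1, 23)] + ["X"]
        profiles = [
            profile_factory(rng, f"s{i}", 8, chroms=chroms) for i in range(12)
        ]
        y = (np.arange(12) % 2).astype(float)
        pheno = pheno_of(y)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results, threshold = scan_regions(profiles, pheno, 1, chroms)
        assert len(results) == 23
        assert threshold == pytest.approx(0.05 / 23)
        assert threshold_2sf(threshold) == pytest.approx(2.2e-3)

    def test_single_region_threshold_is_fwer(self, rng, profile_factory):
        profiles = [profile_factory(rng, f"s{i}", 4) for i in range(8)]
        pheno = pheno_of((np.arange(8) % 2).astype(float))
        _, threshold = scan_regions(profiles, pheno, 1, ["1"], fwer=0.05)
        assert threshold == 0.05

    def test_empty_region_still_counts_in_denominator(self, rng, profile_factory):
        profiles = [profile_factory(rng, f"s{i}", 4, chroms=("1",)) for i in range(8)]
        pheno = pheno_of((np.arange(8) % 2).astype(float))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results, threshold = scan_regions(profiles, pheno, 1, ["1", "2"])
        assert threshold == pytest.approx(0.025)
        empty = [r for r in results if r.region == "2"]
        assert empty[0].degenerate and empty[0].p_value == 1.0

    def test_results_frame_layout(self, rng, profile_factory):
        profiles = [profile_factory(rng, f"s{i}", 4) for i in range(8)]
        pheno = pheno_of((np.arange(8) % 2).astype(float))
        results, _ = scan_regions(profiles, pheno, 1, ["1"])
        frame = results_to_frame(results)
        assert list(frame.columns) == [
            "region",
            "n_cnvs",
            "group_size",
            "Q",
            "p_value",
            "method",
            "significant_after_bonferroni",
        ]

    def test_bonferroni_threshold_validation(self):
        with pytest.raises(CNVDataError):
            bonferroni_threshold(1.5, 10)
        assert bonferroni_threshold(0.05, 40) == pytest.approx(1.25e-3)
        assert threshold_2sf(bonferroni_threshold(0.05, 40)) == pytest.approx(
            1.2e-3
        )
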