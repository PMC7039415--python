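import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from anisosim.growth_analysis import (
    DEFAULT_AGE_INTERVALS,
    FitFailedError,
    akaike_weights,
    compare_groups,
    confidence_bands,
    effect_size_d,
    extract_scaling_factors,
    fit_growth_model,
    gender_balance_weights,
    goodness_stats,
    normalize_to_baseline,
    reference_influence,
    select_model,
)
from anisosim.pointset_estimation import FitReport, PairedPointSet, fit_anisotropic_similarity, fit_rigid
from anisosim.synthetic_fixtures import CohortSpec, make_cohort
from anisosim.transform_core import ScalingFrame

from .conftest import random_frame


def brute_force_bh(pvals, alpha=0.05):
    """Step-up definition: reject the k smallest p-values where k is the
    largest index with p_(k) <= k*alpha/m."""
    p = np.asarray(pvals)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * alpha / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestExtraction:
    def test_passthrough_of_decomposition_scalings(self):
        rng = np.random.default_rng(0)
        U = random_frame(1)
        x = rng.normal(size=(12, 3))
        S0 = np.array([1.3, 0.9, 1.1])
        y = x @ (U.U @ np.diag(S0) @ U.U.T).T
        rep = fit_anisotropic_similarity(PairedPointSet(x, y), U)
        assert np.allclose(extract_scaling_factors(rep), S0, atol=1e-8)

    def test_wrong_kind_rejected(self):
        x = np.random.default_rng(2).normal(size=(8, 3))
        rep = fit_rigid(PairedPointSet(x, x))
        with pytest.raises(ValueError):
            extract_scaling_factors(rep)


def records_from(rows):
    return pd.DataFrame(
        rows, columns=["subject", "age", "sex", "roi", "direction", "reference",
                       "scaling"]
    )


class TestNormalization:
    def test_direct_substitution(self):
        df = records_from(
            [
                ("b1", 0.05, "male", "r", 1, "ref1", 0.5),
                ("b2", 0.05, "female", "r", 1, "ref1", 0.5),
                ("s1", 5.0, "male", "r", 1, "ref1", 1.0),
            ]
        )
        out = normalize_to_baseline(df, ["b1", "b2"])
        assert out.loc[out.subject == "s1", "scaling"].item() == pytest.approx(2.0)

    def test_baseline_mean_exactly_one_and_idempotent(self):
        df = make_cohort(CohortSpec(n_subjects=50, seed=4))
        neo = df.loc[df.age <= 0.1, "subject"].unique()
        out = normalize_to_baseline(df, neo)
        means = out[out.subject.isin(neo)].groupby(["roi", "direction"])[
            "scaling"].mean()
        assert np.allclose(means, 1.0, atol=1e-12)
        again = normalize_to_baseline(out, neo)
        assert np.allclose(again.scaling, out.scaling, atol=1e-12)

    def test_empty_baseline_cell_reported(self):
        df = records_from([("s1", 5.0, "male", "r", 1, "ref1", 1.0)])
        with pytest.raises(ValueError, match="baseline"):
            normalize_to_baseline(df, ["nobody"])

    def test_recovers_expansion_from_birth(self):
        spec = CohortSpec(n_subjects=150, seed=6, noise_sigma=0.01)
        df = make_cohort(spec)
        neo = df.loc[df.age <= 0.1, "subject"].unique()
        out = normalize_to_baseline(df, neo)
        from anisosim.synthetic_fixtures import GROWTH_FAMILIES

        fam = GROWTH_FAMILIES[spec.growth_family]
        old = out[(out.age > 15) & (out.direction == 1)]
        true_exp = fam(old.age.to_numpy(), *spec.growth_coefficients[0]) / fam(
            0.05, *spec.growth_coefficients[0]
        )
        assert np.abs(old.scaling.to_numpy() / true_exp - 1).max() < 0.08


class TestGenderBalanceWeights:
    def test_three_males_one_female(self):
        w = gender_balance_weights(
            np.array([5.0, 5.1, 5.2, 5.3]), ["male", "male", "male", "female"]
        )
        assert np.allclose(w, [0.25, 0.25, 0.25, 0.75])

    def test_balanced_window(self):
        w = gender_balance_weights(np.array([2.0, 2.5]), ["male", "female"])
        assert np.allclose(w, 0.5)

    def test_single_sex_window_gets_zero_weight(self, caplog):
        w = gender_balance_weights(np.array([1.0, 1.5]), ["male", "male"])
        assert np.allclose(w, 0.0)

    def test_window_width_respected(self):
        # at width 2 the two subjects do not see each other
        w = gender_balance_weights(np.array([0.0, 3.0]), ["male", "female"])
        assert np.allclose(w, 0.0)


class TestGrowthModels:
    def test_rational_noiseless_recovery(self):
        ages = np.linspace(0, 19, 40)
        y = (1.3 * ages + 1.0) / (ages + 1.2)
        r = fit_growth_model("rational", ages, y)
        assert np.allclose(r.coefficients, [1.3, 1.0, 1.2], atol=1e-6)
        assert r.mse < 1e-12

    def test_exponential_noiseless_recovery(self):
        ages = np.linspace(0, 19, 40)
        y = 1.5 - 0.5 * np.exp(-0.8 * ages)
        r = fit_growth_model("exponential", ages, y)
        assert np.allclose(r.coefficients, [1.5, -0.5, 0.8], atol=1e-6)

    def test_weibull_and_gompertz_recovery(self):
        ages = np.linspace(0.01, 19, 60)
        yw = 1.4 - 0.6 * np.exp(-0.5 * ages**0.9)
        rw = fit_growth_model("weibull", ages, yw)
        assert rw.mse < 1e-10
        yg = 1.4 * np.exp(-0.4 * np.exp(-0.6 * ages))
        rg = fit_growth_model("gompertz", ages, yg)
        assert np.allclose(rg.coefficients, [1.4, 0.4, 0.6], atol=1e-4)

    def test_constant_data_rational_ridge_flagged(self):
        ages = np.linspace(0, 19, 30)
        y = np.full(30, 2.0)
        r = fit_growth_model("rational", ages, y)
        assert np.allclose(r.fitted, 2.0, atol=1e-8)
        assert r.identifiability_warning is not None

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_growth_model("cubic", np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError):
            fit_growth_model("rational", np.arange(3.0), np.arange(3.0))
        with pytest.raises(ValueError):
            fit_growth_model("rational", -np.arange(10.0), np.ones(10))


class TestGoodnessStats:
    def test_perfect_fit_mse_zero(self):
        y = np.arange(10.0)
        mse, aic, aicc, ll = goodness_stats(y, y, p=3)
        assert mse == 0.0

    def test_penalty_monotonic_in_p(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=30)
        yh = y + rng.normal(0, 0.1, 30)
        _, aic1, aicc1, ll1 = goodness_stats(y, yh, p=3)
        _, aic2, aicc2, ll2 = goodness_stats(y, yh, p=4)
        assert ll1 == ll2
        assert aic1 < aic2 and aicc1 < aicc2

    def test_hand_computed_five_points(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        yh = np.array([1.1, 1.9, 3.2, 3.8, 5.1])
        p = 2
        r = y - yh
        mse_expect = np.mean(r**2)
        sigma2 = mse_expect  # unweighted: MLE variance = MSE
        ll_expect = -0.5 * 5 * (np.log(2 * np.pi * sigma2) + 1)
        aic_expect = 2 * p - 2 * ll_expect
        aicc_expect = aic_expect + 2 * p * (p + 1) / (5 - p - 1)
        mse, aic, aicc, ll = goodness_stats(y, yh, p=p)
        assert mse == pytest.approx(mse_expect)
        assert ll == pytest.approx(ll_expect)
        assert aic == pytest.approx(aic_expect)
        assert aicc == pytest.approx(aicc_expect)

    def test_aicc_needs_enough_points(self):
        with pytest.raises(ValueError):
            goodness_stats(np.ones(4), np.ones(4), p=3)


class TestAkaikeWeights:
    def test_single_model(self):
        assert akaike_weights([12.3]) == pytest.approx([1.0])

    def test_two_equal(self):
        assert np.allclose(akaike_weights([5.0, 5.0]), [0.5, 0.5])

    def test_delta_two(self):
        w = akaike_weights([10.0, 12.0])
        e = np.exp(-1.0)
        assert np.allclose(w, [1 / (1 + e), e / (1 + e)])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8),
           st.floats(-100, 100))
    def test_sum_one_and_shift_invariance(self, vals, shift):
        w = akaike_weights(vals)
        assert np.isclose(w.sum(), 1.0, atol=1e-9)
        assert np.allclose(w, akaike_weights(np.asarray(vals) + shift), atol=1e-9)


class TestSelectModel:
    def test_rational_truth_usually_selected(self):
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(rep)
            ages = np.concatenate(
                [rng.uniform(0, 0.1, 30), rng.uniform(0.1, 6, 120),
                 rng.uniform(6, 12, 100), rng.uniform(12, 19, 50)]
            )
            y = (1.35 * ages + 1.0) / (ages + 1.0) + rng.normal(0, 0.02, len(ages))
            best, table = select_model(ages, y, seed=rep)
            assert np.isclose(
                sum(t.akaike_weight for t in table.values()), 1.0, atol=1e-9
            )
            wins += best == "rational"
        assert wins >= 8

    def test_small_n_prefers_parsimony(self):
        rng = np.random.default_rng(3)
        ages = np.array([0.1, 2.0, 5.0, 9.0, 14.0, 18.0])
        y = 1.4 - 0.4 * np.exp(-0.5 * ages) + rng.normal(0, 0.01, 6)
        best, table = select_model(
            ages, y, families=("rational", "gompertz", "exponential")
        )
        assert best in table  # all 3-parameter candidates; AICc finite
        assert all(t.p == 3 for t in table.values())


class TestCompareGroups:
    def test_identical_groups_null(self):
        rows = []
        vals = [1.0, 1.1, 1.2, 1.3, 1.4]
        for i, v in enumerate(vals):
            rows.append((f"m{i}", 3.0, "male", "r", 1, "ref1", v))
            rows.append((f"f{i}", 3.0, "female", "r", 1, "ref1", v))
        res = compare_groups(records_from(rows))
        assert res.p_value.item() == pytest.approx(1.0)
        assert res.effect_size.item() == 0.0

    def test_effect_size_formula(self):
        male = np.array([1.0, 2.0, 3.0])
        female = np.array([0.0, 1.0, 2.0])
        assert effect_size_d(male, female) == pytest.approx(0.5)

    def test_detects_injected_sex_effect(self):
        df = make_cohort(CohortSpec(n_subjects=250, seed=11, sex_effect={1: 1.06}))
        neo = df.loc[df.age <= 0.1, "subject"].unique()
        res = compare_groups(normalize_to_baseline(df, neo))
        by_dir = res.groupby("direction").rejected.sum()
        assert by_dir.loc[1] >= 1
        assert by_dir.loc[2] == 0 and by_dir.loc[3] == 0

    def test_empty_group_skipped(self):
        rows = [(f"m{i}", 3.0, "male", "r", 1, "ref1", 1.0 + i) for i in range(5)]
        res = compare_groups(records_from(rows))
        assert len(res) == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_bh_matches_brute_force_step_up(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        reject, _, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.array_equal(reject, brute_force_bh(p))

    def test_bh_example_vector(self):
        reject = brute_force_bh([0.01, 0.02, 0.04, 0.2], alpha=0.05)
        assert list(reject) == [True, True, False, False]
        from statsmodels.stats.multitest import multipletests

        sm, _, _, _ = multipletests([0.01, 0.02, 0.04, 0.2], alpha=0.05,
                                    method="fdr_bh")
        assert np.array_equal(sm, reject)


class TestReferenceInfluence:
    def test_identical_references_zero(self):
        rows = []
        for k in ("ref1", "ref2"):
            for i in range(4):
                rows.append((f"s{i}", 3.0, "male", "r", 1, k, 1.0 + i / 10))
        pw, rs = reference_influence(records_from(rows))
        assert np.allclose(pw.D, 0.0)
        assert np.allclose(rs.D, 0.0)

    def test_direct_substitution(self):
        rows = [
            ("s", 3.0, "male", "r", 1, "ref1", 1.1),
            ("s", 3.0, "male", "r", 1, "ref2", 0.9),
        ]
        pw, _ = reference_influence(records_from(rows))
        assert pw.D.item() == pytest.approx(0.2)

    def test_jitter_scale_recovered(self):
        df = make_cohort(
            CohortSpec(n_subjects=120, seed=12, n_references=3,
                       reference_jitter_sigma=0.05, noise_sigma=0.0)
        )
        pw, rs = reference_influence(df)
        # pairwise |s_k − s_l|/mean for lognormal jitter ~ HalfNormal(σ√2)
        expected_median = 0.05 * np.sqrt(2) * 0.6745
        assert abs(pw.D.median() / expected_median - 1) < 0.2

    def test_needs_two_references(self):
        df = make_cohort(CohortSpec(n_subjects=10, seed=0))
        with pytest.raises(ValueError):
            reference_influence(df)


@pytest.fixture(scope="module")
def noisy_fit():
    rng = np.random.default_rng(0)
    ages = rng.uniform(0, 19, 120)
    y = (1.35 * ages + 1.0) / (ages + 1.0) + rng.normal(0, 0.03, 120)
    return fit_growth_model("rational", ages, y)


class TestConfidenceBands:
    def test_seeded_determinism(self, noisy_fit):
        a = confidence_bands(noisy_fit, n_boot=100, seed=3)
        b = confidence_bands(noisy_fit, n_boot=100, seed=3)
        assert np.array_equal(a["lower"], b["lower"])
        assert a["kind"] == "pointwise bootstrap"

    def test_band_width_shrinks_with_noise(self):
        widths = []
        for sigma in (0.05, 0.005):
            rng = np.random.default_rng(1)
            ages = rng.uniform(0, 19, 150)
            y = (1.35 * ages + 1.0) / (ages + 1.0) + rng.normal(0, sigma, 150)
            fit = fit_growth_model("rational", ages, y)
            band = confidence_bands(fit, n_boot=150, seed=2)
            widths.append(np.median(band["upper"] - band["lower"]))
        assert widths[1] < 0.3 * widths[0]

    def test_band_covers_truth(self, noisy_fit):
        band = confidence_bands(noisy_fit, level=0.99, n_boot=300, seed=4)
        truth = (1.35 * band["ages"] + 1.0) / (band["ages"] + 1.0)
        inside = (truth >= band["lower"]) & (truth <= band["upper"])
        assert inside.mean() >= 0.95
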