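"""Psychometric discrimination functions: evaluation, thresholds, fitting,
model comparison, and the bootstrap equality-of-means test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimicolor.discrimination import (
    ChoiceDataset,
    DiscriminationFunction,
    bootstrap_mean_equality,
    eval_discrimination,
    fit_discrimination,
    lrt_compare,
    threshold_distance,
)
from mimicolor.synthetic import ChoiceRecipe, make_choice_data


def _inv_logistic3(fn, target):
    """Closed-form inverse, independent of the root finder."""
    K, r, Mo = (fn.coefficients[k] for k in ("K", "r", "Mo"))
    return -np.log((Mo * K / target - Mo) / (K - Mo)) / r


def _inv_logistic4(fn, target):
    K, Mo, xmid, scal = (fn.coefficients[k] for k in ("K", "Mo", "xmid", "scal"))
    return xmid - scal * np.log((K - Mo) / (target - Mo) - 1.0)


class TestEvaluation:
    def test_logistic3_at_zero_reduces_to_Mo(self, disc_fns):
        fn = disc_fns["successive_blue"]
        assert eval_discrimination(fn, 0.0) == pytest.approx(0.528, abs=1e-9)

    @pytest.mark.parametrize(
        "key, dc, expected",
        [
            ("successive_blue", 0.056, 0.949),   # petal-pair accuracy, experienced bee
            ("successive_blue", 0.053, 0.94),    # at the MC petal median distance
            ("successive_blue", 0.138, 0.99),    # labellum/pollen distance
            ("absolute", 0.138, 0.841),          # same distance, inexperienced bee
        ],
    )
    def test_published_accuracies(self, disc_fns, key, dc, expected):
        assert eval_discrimination(disc_fns[key], dc) == pytest.approx(expected, abs=0.005)

    def test_clamp_floors_subchance_values(self, disc_fns):
        fn = disc_fns["absolute"]
        raw = eval_discrimination(fn, 0.01, clamp=False)
        assert raw < 0.5
        assert eval_discrimination(fn, 0.01, clamp=True) == 0.5

    def test_negative_distance_rejected(self, disc_fns):
        with pytest.raises(ValueError):
            eval_discrimination(disc_fns["absolute"], -0.1)

    def test_monotone_and_asymptotes(self, disc_fns):
        grid = np.linspace(0.0, 1.0, 1001)
        for fn in disc_fns.values():
            pi = eval_discrimination(fn, grid, clamp=False)
            assert np.all(np.diff(pi) >= -1e-12)
            assert eval_discrimination(fn, 10.0, clamp=False) == pytest.approx(fn.K, abs=1e-6)
            at0 = eval_discrimination(fn, 0.0, clamp=False)
            # logistic3 passes exactly through Mo at zero; logistic4 only
            # approaches its lower asymptote (xmid/scal = 9 leaves ~5e-5)
            tol = 1e-9 if fn.form == "logistic3" else 1e-3
            assert at0 == pytest.approx(fn.coefficients["Mo"], abs=tol)

    @settings(max_examples=60, derandomize=True)
    @given(
        K=st.floats(0.76, 1.0),
        Mo=st.floats(0.4, 0.7),
        rate=st.floats(5.0, 200.0),
        dc1=st.floats(0.0, 0.5),
        dc2=st.floats(0.0, 0.5),
    )
    def test_monotonicity_property_logistic3(self, K, Mo, rate, dc1, dc2):
        if Mo >= K:
            return
        fn = DiscriminationFunction("logistic3", {"K": K, "r": rate, "Mo": Mo})
        lo, hi = sorted((dc1, dc2))
        assert eval_discrimination(fn, lo, clamp=False) <= eval_discrimination(fn, hi, clamp=False) + 1e-12


class TestThreshold:
    def test_pi75_absolute_rounds_to_009(self, disc_fns):
        thr = threshold_distance(disc_fns["absolute"], 0.75)
        assert thr == pytest.approx(0.092, abs=0.0015)
        assert round(thr, 2) == 0.09

    def test_pi75_successive_blue_against_closed_form(self, disc_fns):
        fn = disc_fns["successive_blue"]
        thr = threshold_distance(fn, 0.75)
        assert thr == pytest.approx(_inv_logistic3(fn, 0.75), abs=1e-8)
        assert thr == pytest.approx(0.0187, abs=1e-4)

    def test_closed_form_inverse_logistic4(self, disc_fns):
        fn = disc_fns["absolute"]
        for tgt in (0.6, 0.75, 0.8):
            assert threshold_distance(fn, tgt) == pytest.approx(_inv_logistic4(fn, tgt), abs=1e-8)

    def test_round_trip_eval_of_threshold(self, disc_fns):
        for fn in disc_fns.values():
            for tgt in (0.6, 0.75, 0.9):
                if tgt >= fn.K:
                    continue
                dc = threshold_distance(fn, tgt)
                assert eval_discrimination(fn, dc, clamp=False) == pytest.approx(tgt, abs=1e-6)

    def test_target_above_asymptote_errors(self, disc_fns):
        with pytest.raises(ValueError, match="range"):
            threshold_distance(disc_fns["successive_blue"], 0.999)  # K = 0.990


class TestFitting:
    def test_single_level_is_underdetermined(self, disc_fns):
        df = pd.DataFrame({
            "subject_id": ["b1"] * 4,
            "delta_c_hu": [0.05] * 4,
            "proportion_correct": [0.7, 0.75, 0.8, 0.72],
        })
        with pytest.raises(ValueError, match="levels"):
            fit_discrimination(ChoiceDataset(df), "logistic3")

    def test_logistic4_recovery_within_ci(self, disc_fns):
        """Fixed-effect NLS recovery: simulated binomial data from the
        published 4-parameter coefficients, 50 replicates."""
        truth = disc_fns["absolute"].coefficients
        # levels concentrated over the steep transition so xmid/scal are
        # identifiable, plus anchors for the two asymptotes
        levels = tuple(np.concatenate(
            [[0.01, 0.03, 0.05], np.linspace(0.065, 0.11, 6), [0.15, 0.2, 0.25]]))
        n_rep = 50
        covered = {k: 0 for k in ("K", "Mo", "xmid")}
        for rep in range(n_rep):
            data = make_choice_data(ChoiceRecipe(
                fn=disc_fns["absolute"], delta_c_levels=levels,
                n_subjects=5, trials_per_level=100, seed=rep,
            ))
            fit = fit_discrimination(data, "logistic4", n_restarts=1, seed=rep)
            for k in covered:
                covered[k] += fit.ci95[k][0] - 1e-9 <= truth[k] <= fit.ci95[k][1] + 1e-9
        for k, hits in covered.items():
            assert hits >= int(0.9 * n_rep), (k, hits)

    def test_logistic3_mixed_effect_recovery(self, disc_fns):
        """Mixed model with a per-subject deviation on the rate r: fixed
        effects should land near the generating coefficients."""
        truth = disc_fns["successive_blue"].coefficients
        data = make_choice_data(ChoiceRecipe(
            fn=disc_fns["successive_blue"],
            delta_c_levels=tuple(np.linspace(0.005, 0.12, 10)),
            n_subjects=5, random_param="r", subject_sd=4.0,
            trials_per_level=200, seed=11,
        ))
        fit = fit_discrimination(data, "logistic3", random_param="r",
                                 n_restarts=2, seed=11)
        assert fit.coefficients["K"] == pytest.approx(truth["K"], abs=0.05)
        assert fit.coefficients["Mo"] == pytest.approx(truth["Mo"], abs=0.05)
        assert fit.coefficients["r"] == pytest.approx(truth["r"], rel=0.25)
        assert fit.random_param == "r"

    def test_random_effect_needs_multiple_subjects(self, disc_fns):
        data = make_choice_data(ChoiceRecipe(
            fn=disc_fns["successive_blue"],
            delta_c_levels=(0.01, 0.03, 0.06, 0.1),
            n_subjects=1, trials_per_level=50, seed=0,
        ))
        with pytest.raises(ValueError, match="two subjects"):
            fit_discrimination(data, "logistic3", random_param="r")


@pytest.fixture(scope="module")
def fits(disc_fns):
    data = make_choice_data(ChoiceRecipe(
        fn=disc_fns["successive_blue"],
        delta_c_levels=tuple(np.linspace(0.005, 0.15, 10)),
        n_subjects=4, trials_per_level=80, seed=3,
    ))
    f3 = fit_discrimination(data, "logistic3", n_restarts=3, seed=3)
    f4 = fit_discrimination(data, "logistic4", n_restarts=3, seed=3)
    return f3, f4


class TestModelComparison:

    def test_chi_sq_nonnegative_and_df(self, fits):
        f3, f4 = fits
        cmp_ = lrt_compare(f3, f4)
        assert cmp_.chi_sq >= -1e-6
        assert cmp_.df == 1
        assert 0.0 <= cmp_.p_value <= 1.0

    def test_identical_refits_prefer_simpler(self, fits):
        f3, _ = fits
        cmp_ = lrt_compare(f3, f3_plus(f3))
        assert cmp_.chi_sq == pytest.approx(0.0, abs=1e-9)
        assert cmp_.preferred == "logistic3"

    def test_genuine_lower_asymptote_prefers_logistic4(self, disc_fns):
        """Data with a non-chance lower asymptote (Mo = 0.6) that logistic3
        (pinned near its own Mo at zero) fits worse; the LRT should pick the
        4-parameter form in a majority of replicates."""
        gen = DiscriminationFunction(
            "logistic4", {"K": 0.95, "Mo": 0.60, "xmid": 0.08, "scal": 0.02})
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            data = make_choice_data(ChoiceRecipe(
                fn=gen, delta_c_levels=tuple(np.linspace(0.0, 0.25, 12)),
                n_subjects=5, trials_per_level=200, seed=100 + rep,
            ))
            f3 = fit_discrimination(data, "logistic3", n_restarts=2, seed=rep)
            f4 = fit_discrimination(data, "logistic4", n_restarts=2, seed=rep)
            wins += lrt_compare(f3, f4).preferred == "logistic4"
        assert wins > n_rep // 2

    def test_non_nested_usage_error(self, fits, disc_fns):
        f3, f4 = fits
        with pytest.raises(ValueError):
            lrt_compare(f4, f3)  # larger model passed as the small one
        with pytest.raises(ValueError):
            lrt_compare(disc_fns["successive_blue"], f4)  # fixture has no loglik


def f3_plus(f3):
    """A 'larger' copy of the same fit used for the identity LRT check."""
    return DiscriminationFunction(
        form="logistic4",
        coefficients={"K": f3.K, "Mo": f3.coefficients["Mo"], "xmid": 0.01, "scal": 0.01},
        loglik=f3.loglik, n_obs=f3.n_obs, n_params=f3.n_params + 1,
    )


class TestBootstrapEquality:
    def test_identical_samples(self, rng):
        a = rng.normal(0.7, 0.05, 40)
        res = bootstrap_mean_equality(a, a.copy(), n_resamples=2000, seed=0)
        assert res.t_Ho == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9

    def test_gross_separation(self, rng):
        a = rng.normal(0.5, 0.01, 200)
        b = rng.normal(0.9, 0.01, 200)
        res = bootstrap_mean_equality(a, b, n_resamples=5000, seed=1)
        assert res.p_value < 0.001
        assert res.t_Ho < -100

    def test_reproducible_under_seed(self, rng):
        a, b = rng.normal(0.6, 0.1, 30), rng.normal(0.62, 0.1, 30)
        r1 = bootstrap_mean_equality(a, b, n_resamples=3000, seed=7)
        r2 = bootstrap_mean_equality(a, b, n_resamples=3000, seed=7)
        assert r1.p_value == r2.p_value and r1.t_Ho == r2.t_Ho

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            bootstrap_mean_equality([0.5] * 10, [0.6] * 10, n_resamples=100)

    def test_type_i_error_calibration(self):
        """Under H0 both samples share a distribution; the rejection rate at
        alpha = 0.05 over 500 simulated datasets should be near nominal."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_sets = 500
        for _ in range(n_sets):
            a = rng.normal(0.7, 0.08, 25)
            b = rng.normal(0.7, 0.08, 25)
            res = bootstrap_mean_equality(a, b, n_resamples=500,
                                          seed=int(rng.integers(2**31)))
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / n_sets <= 0.07

    def test_experience_effect_on_common_grid(self, disc_fns):
        """Accuracies predicted by the successive (3-par) and absolute
        (4-par) functions differ significantly on a common distance grid —
        the experience effect that rejects colour-as-a-trait."""
        grid = np.linspace(0.005, 0.25, 50)
        succ = eval_discrimination(disc_fns["successive_blue"], grid)
        absf = eval_discrimination(disc_fns["absolute"], grid)
        res = bootstrap_mean_equality(absf, succ, n_resamples=20_000, seed=5)
        assert res.p_value < 0.001
        assert res.t_Ho < 0  # absolute conditioning is the poorer discriminator
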