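"""Decay-curve fitting: recovery, hierarchy, intervals, model selection."""

import numpy as np
import pytest

from mirdecay import (
    DecayDataset,
    REFERENCE_RATES,
    add_measurement_noise,
    aic,
    aic_compare,
    analytic_decay_curve,
    condition_network,
    confidence_intervals,
    fit_decay,
    hierarchical_fit,
)
from mirdecay.fitting import FREE_RATES, UnderdeterminedFitError
from mirdecay.rates import RateSet
from mirdecay.simulate import DEFAULT_TIME_GRID

GRID = DEFAULT_TIME_GRID


def _noiseless(condition):
    net = condition_network(condition, REFERENCE_RATES)
    ds = analytic_decay_curve(net, GRID)
    return DecayDataset(condition, ds.observations, normalized=True), net


class TestFitDecay:
    def test_noiseless_round_trip_recovers_baseline_rates(self):
        ds, net = _noiseless("control_negative")
        fit = fit_decay(ds, net, ("lambda", "mu", "nu"))
        assert fit.converged
        for sym, truth in (("lambda", 0.0008), ("mu", 0.0276), ("nu", 0.0028)):
            assert fit.estimates[sym] == pytest.approx(truth, rel=1e-3)

    @pytest.mark.parametrize("condition", ["mirisc_only", "pan3_kd", "control_positive"])
    def test_noiseless_round_trip_all_networks(self, condition):
        """Generate -> fit recovers every free rate to better than 0.1% relative."""
        ds, net = _noiseless(condition)
        free = FREE_RATES[condition]
        fit = fit_decay(ds, net, free)
        for sym in free:
            assert fit.estimates[sym] == pytest.approx(REFERENCE_RATES[sym], rel=1e-3)

    def test_pure_exponential_truth_flags_degenerate_branch(self):
        """Two-state model on single-exponential data: branch entry pinned at 0,
        its exit rate carries no information."""
        t = GRID
        ds = DecayDataset.from_arrays(
            "control_negative", t, np.exp(-0.0276 * t), normalized=True
        )
        net = condition_network("control_negative", REFERENCE_RATES)
        fit = fit_decay(ds, net, ("lambda", "mu", "nu"))
        assert fit.estimates["mu"] == pytest.approx(0.0276, rel=1e-3)
        assert fit.estimates["lambda"] < 1e-6
        assert "nu" in fit.unidentifiable or "lambda" in fit.at_boundary

    def test_observation_order_does_not_change_estimates(self, noisy_control):
        net = condition_network("control_negative", REFERENCE_RATES)
        fit_a = fit_decay(noisy_control, net, ("lambda", "mu", "nu"))
        shuffled = DecayDataset(
            noisy_control.condition,
            noisy_control.observations.sample(frac=1, random_state=3),
            normalized=True,
        )
        fit_b = fit_decay(shuffled, net, ("lambda", "mu", "nu"))
        for s in fit_a.free:
            assert abs(fit_a.estimates[s] - fit_b.estimates[s]) < 1e-12

    def test_underdetermined_raises(self):
        ds = DecayDataset.from_arrays("x", [0.0, 30.0], [1.0, 0.5], normalized=True)
        net = condition_network("control_negative", REFERENCE_RATES)
        with pytest.raises(UnderdeterminedFitError):
            fit_decay(ds, net, ("lambda", "mu", "nu"))

    def test_unlisted_rates_fixed_from_network(self):
        """Rates neither freed nor explicitly fixed inherit the network's bound values."""
        ds, net = _noiseless("control_negative")
        fit = fit_decay(ds, net, ("lambda",), fixed_rates={"mu": 0.03})
        assert fit.fixed["mu"] == 0.03
        assert fit.fixed["nu"] == REFERENCE_RATES["nu"]


class TestHierarchicalFit:
    def test_full_bundle_structure(self, noiseless_bundle):
        fits = hierarchical_fit(noiseless_bundle.datasets)
        assert set(fits) == set(noiseless_bundle.datasets)
        stage1 = fits["control_negative"]
        assert stage1.k == 3 and not stage1.fixed
        for cond, fit in fits.items():
            if cond == "control_negative":
                continue
            assert fit.k == 2
            # stage 2 inherits the frozen baseline rates from stage 1
            for s in ("lambda", "mu", "nu"):
                assert fit.fixed[s] == pytest.approx(stage1.estimates[s], abs=0)

    def test_noiseless_bundle_recovers_all_generating_rates(self, noiseless_bundle):
        fits = hierarchical_fit(noiseless_bundle.datasets)
        for cond, fit in fits.items():
            truth = noiseless_bundle.metadata["true_rates"][cond]
            for s in fit.free:
                assert fit.estimates[s] == pytest.approx(truth[s], rel=1e-3), (cond, s)

    def test_stage2_positive_control_recovers_branch_rates(self):
        ds, _ = _noiseless("control_positive")
        ds = DecayDataset("control_positive", ds.observations, normalized=True)
        fits = hierarchical_fit(
            {"control_negative": _noiseless("control_negative")[0], "control_positive": ds}
        )
        assert fits["control_positive"].estimates["lambda_RNP"] == pytest.approx(0.1501, rel=1e-3)
        assert fits["control_positive"].estimates["mu_RNP"] == pytest.approx(0.0493, rel=1e-3)

    def test_control_only_bundle_gives_single_fit(self):
        ds, _ = _noiseless("control_negative")
        fits = hierarchical_fit({"control_negative": ds})
        assert list(fits) == ["control_negative"]

    def test_missing_control_raises(self):
        ds, _ = _noiseless("control_positive")
        with pytest.raises(ValueError, match="control_negative"):
            hierarchical_fit({"control_positive": ds})

    def test_unknown_condition_raises(self):
        ds, _ = _noiseless("control_negative")
        bad = DecayDataset("mystery_kd", ds.observations, normalized=True)
        with pytest.raises(ValueError, match="mystery_kd"):
            hierarchical_fit({"control_negative": ds, "mystery_kd": bad})


class TestConfidenceIntervals:
    def test_noiseless_asymptotic_interval_degenerates_to_point(self):
        ds, net = _noiseless("control_negative")
        fit = fit_decay(ds, net, ("lambda", "mu", "nu"))
        ci = confidence_intervals(fit, ds, method="asymptotic")
        for s in fit.free:
            assert ci[s][1] - ci[s][0] < 1e-6
            assert ci[s][0] <= fit.estimates[s] <= ci[s][1]

    def test_boundary_estimate_gets_zero_lower_bound(self):
        t = GRID
        ds = DecayDataset.from_arrays(
            "control_negative", t, np.exp(-0.0276 * t), normalized=True
        )
        net = condition_network("control_negative", REFERENCE_RATES)
        fit = fit_decay(ds, net, ("lambda", "mu"), fixed_rates={"nu": 0.0028})
        ci = confidence_intervals(fit, ds, method="bootstrap", n_boot=50, seed=0)
        assert ci["lambda"][0] == 0.0

    def test_bootstrap_is_deterministic_under_seed(self, noisy_control):
        net = condition_network("control_negative", REFERENCE_RATES)
        fit = fit_decay(noisy_control, net, ("lambda", "mu", "nu"))
        ci1 = confidence_intervals(fit, noisy_control, method="bootstrap", n_boot=60, seed=11)
        ci2 = confidence_intervals(fit, noisy_control, method="bootstrap", n_boot=60, seed=11)
        assert ci1 == ci2

    def test_intervals_contain_estimates(self, noisy_control):
        net = condition_network("control_negative", REFERENCE_RATES)
        fit = fit_decay(noisy_control, net, ("lambda", "mu", "nu"))
        for method in ("asymptotic", "bootstrap"):
            ci = confidence_intervals(fit, noisy_control, method=method, n_boot=60, seed=2)
            for s in fit.free:
                assert ci[s][0] <= fit.estimates[s] <= ci[s][1]


class TestModelSelection:
    def test_two_state_preferred_on_biphasic_control_data(self, noisy_control):
        """The biphasic negative-control pattern rejects the single-exponential null."""
        two_state = fit_decay(
            noisy_control,
            condition_network("control_negative", REFERENCE_RATES),
            ("lambda", "mu", "nu"),
        )
        single = fit_decay(
            noisy_control,
            condition_network("single_exponential", RateSet({"mu": 0.01})),
            ("mu",),
        )
        tab = aic_compare([single, two_state])
        assert tab.loc[0, "model"] == "control_negative"
        assert tab.loc[1, "delta_aic"] > 10

    def test_identical_fits_have_zero_delta(self, noisy_control):
        net = condition_network("control_negative", REFERENCE_RATES)
        f1 = fit_decay(noisy_control, net, ("lambda", "mu", "nu"))
        f2 = fit_decay(noisy_control, net, ("lambda", "mu", "nu"))
        tab = aic_compare([f1, f2])
        assert tab["delta_aic"].abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_datasets_rejected(self, noisy_control):
        ds2, net = _noiseless("control_negative")
        f1 = fit_decay(noisy_control, net, ("lambda", "mu", "nu"))
        f2 = fit_decay(ds2, net, ("lambda", "mu", "nu"))
        with pytest.raises(ValueError, match="different datasets"):
            aic_compare([f1, f2])

    def test_aic_formula_and_small_sample_correction(self, noisy_control):
        net = condition_network("control_negative", REFERENCE_RATES)
        fit = fit_decay(noisy_control, net, ("lambda", "mu", "nu"))
        expected = fit.n * np.log(fit.rss / fit.n) + 2 * fit.k
        assert aic(fit) == pytest.approx(expected, rel=1e-12)
        assert aic(fit, corrected=True) > aic(fit)

    def test_spurious_branch_never_beats_true_two_state(self):
        """Adding an inactive miRISC branch to two-state truth cannot win on AIC."""
        net2 = condition_network("control_negative", REFERENCE_RATES)
        net3 = condition_network("mirisc_only", REFERENCE_RATES)
        base = analytic_decay_curve(net2, GRID)
        wins = 0
        for rep in range(20):
            noisy = add_measurement_noise(base, 0.05, 3, seed=500 + rep)
            ds = DecayDataset("control_negative", noisy.observations, normalized=True)
            f2 = fit_decay(ds, net2, ("lambda", "mu", "nu"))
            f3 = fit_decay(
                ds, net3, ("lambda", "mu", "nu", "lambda_R", "mu_R")
            )
            if aic(f3) < aic(f2):
                wins += 1
        assert wins <= 4  # the spurious branch may win only rarely, by chance
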