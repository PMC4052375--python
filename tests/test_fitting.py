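import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kvinact import (
    DEFAULT_ACTIVATION,
    CurrentTrace,
    FitConstraints,
    GatingProtocol,
    RateSet,
    default_rates,
    estimate_activation_rates,
    extent_of_inactivation,
    fit_cohort,
    fit_inactivation,
    sensitivity_analysis,
    simulate_current,
)
from kvinact.synth import NoiseModel, PatchCohortSpec, generate_cohort, generate_trace

from conftest import REPORTED_RATES


def zero_trace(protocol):
    t = protocol.times()
    return CurrentTrace(times=t, current=np.zeros_like(t), protocol=protocol)


class TestFitInactivation:
    @pytest.mark.parametrize("k_on,k_off", list(REPORTED_RATES.values()))
    def test_noiseless_roundtrip_at_reported_rates(self, protocol, constraints, k_on, k_off):
        tr = simulate_current(default_rates(k_on, k_off), 100.0, protocol)
        res = fit_inactivation(tr, constraints)
        assert res.converged
        assert res.k_on == pytest.approx(k_on, rel=1e-3)
        assert res.k_off == pytest.approx(k_off, rel=1e-3)
        assert res.iN == pytest.approx(100.0, rel=1e-3)

    def test_noiseless_roundtrip_over_random_rate_draws(self, constraints):
        rng = np.random.default_rng(7)
        for _ in range(20):
            k_on, k_off = np.exp(rng.uniform(np.log(10), np.log(1000), size=2))
            duration = float(np.clip(5 * 1000.0 / (k_on + k_off), 40.0, 250.0))
            protocol = GatingProtocol(duration=duration, pre_step_baseline=2.0)
            tr = simulate_current(default_rates(k_on, k_off), 80.0, protocol)
            res = fit_inactivation(tr, constraints)
            assert res.converged
            assert res.k_on == pytest.approx(k_on, rel=1e-3)
            assert res.k_off == pytest.approx(k_off, rel=1e-3)
            assert res.iN == pytest.approx(80.0, rel=1e-3)

    def test_zero_trace_rejected(self, short_protocol, constraints):
        with pytest.raises(ValueError, match="no current"):
            fit_inactivation(zero_trace(short_protocol), constraints)

    def test_k_on_bound_activates_when_truth_outside(self, protocol):
        # wild-type concatemer mean +- SD box (108 +- 21) applied to a
        # trace whose true k_on is 200: the unconstrained estimate
        # exceeds the box, so the bounded fit must pin at the upper edge
        tr = simulate_current(default_rates(200.0, 40.0), 100.0, protocol)
        free = fit_inactivation(tr, FitConstraints(fixed_activation=DEFAULT_ACTIVATION))
        assert free.k_on > 129.0  # oracle: bound really is binding
        res = fit_inactivation(
            tr, FitConstraints(fixed_activation=DEFAULT_ACTIVATION, k_on_bounds=(87.0, 129.0))
        )
        assert res.k_on == pytest.approx(129.0, rel=1e-3)
        assert "k_on_upper" in res.active_constraints

    def test_initial_guess_outside_bounds_is_projected_with_warning(self, protocol):
        tr = simulate_current(default_rates(108.0, 40.0), 100.0, protocol)
        c = FitConstraints(fixed_activation=DEFAULT_ACTIVATION, k_on_bounds=(87.0, 129.0))
        with pytest.warns(UserWarning, match="outside bounds"):
            res = fit_inactivation(tr, c, initial_guess=(500.0, 40.0, 100.0))
        assert 87.0 <= res.k_on <= 129.0

    def test_empty_k_on_interval_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            FitConstraints(fixed_activation=DEFAULT_ACTIVATION, k_on_bounds=(129.0, 87.0))

    def test_fit_window_outside_trace_rejected(self, short_protocol, constraints):
        tr = simulate_current(default_rates(108, 40), 100.0, short_protocol)
        c = FitConstraints(fixed_activation=DEFAULT_ACTIVATION, fit_window=(0.0, 1e4))
        with pytest.raises(ValueError, match="fit_window"):
            fit_inactivation(tr, c)

    def test_noise_bias_below_sem_with_antithetic_pairs(self, constraints):
        # 50 antithetic noise pairs (+eps, -eps): the linear noise term in
        # the mean estimation error cancels, so the mean error measures
        # genuine estimator bias, which must sit below the Monte-Carlo SEM
        from scipy.signal import sosfilt

        from kvinact.synth import _filter_sos, _filtered_noise

        protocol = GatingProtocol(duration=40.0, pre_step_baseline=2.0)
        k_on, k_off, iN = 430.0, 21.0, 100.0
        clean = simulate_current(default_rates(k_on, k_off), iN, protocol)
        sos = _filter_sos(2.0, protocol.sample_rate)
        filtered = sosfilt(sos, clean.current)
        sd = 0.02 * clean.current.max()
        rng = np.random.default_rng(11)
        ests = []
        for _ in range(50):
            eps = _filtered_noise(rng, filtered.size, sd, sos)
            for sign in (1.0, -1.0):
                tr = CurrentTrace(
                    times=clean.times, current=filtered + sign * eps,
                    protocol=protocol, filter_cutoff=2.0,
                )
                res = fit_inactivation(tr, constraints)
                ests.append(res.k_on)
        ests = np.array(ests)
        sem = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean() - k_on) < sem


@given(
    k_on_true=st.floats(50.0, 600.0),
    lo=st.floats(20.0, 150.0),
    width=st.floats(10.0, 300.0),
    seed=st.integers(0, 2**31 - 1),
)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_constrained_estimates_respect_bounds(k_on_true, lo, width, seed):
    protocol = GatingProtocol(duration=25.0, pre_step_baseline=2.0)
    tr = generate_trace(
        default_rates(k_on_true, 40.0), 100.0, protocol, NoiseModel(), seed=seed
    )
    c = FitConstraints(fixed_activation=DEFAULT_ACTIVATION, k_on_bounds=(lo, lo + width))
    res = fit_inactivation(tr, c)
    assert lo <= res.k_on <= lo + width
    assert res.k_off > 0
    assert res.iN <= 3.0 * np.max(np.abs(tr.current)) * (1 + 1e-9)


def test_reported_residual_not_worse_than_initial_guess(protocol, constraints):
    tr = generate_trace(default_rates(108, 40), 200.0, protocol, NoiseModel(), seed=5)
    res = fit_inactivation(tr, constraints, initial_guess=(300.0, 10.0, 150.0))
    rates0 = RateSet(*DEFAULT_ACTIVATION, 300.0, 10.0)
    from kvinact.fitting import _baseline_subtracted, _model_current, _trace_filter_sos

    data = _baseline_subtracted(tr)
    rss0 = np.sum((_model_current(tr, rates0, 150.0, _trace_filter_sos(tr)) - data) ** 2)
    assert res.residual_sum_of_squares <= rss0


class TestFitCohort:
    def test_identical_noiseless_traces_have_zero_spread(self, short_protocol, constraints):
        tr = simulate_current(default_rates(108, 40), 100.0, short_protocol)
        res = fit_cohort([tr, tr, tr], constraints)
        assert res.k_on_sd == pytest.approx(0.0, abs=1e-8)
        assert res.n_traces == 3

    def test_empty_cohort_rejected(self, constraints):
        with pytest.raises(ValueError, match="at least one"):
            fit_cohort([], constraints)

    def test_failed_trace_flagged_and_excluded(self, short_protocol, constraints):
        good = simulate_current(default_rates(108, 40), 100.0, short_protocol)
        with pytest.warns(UserWarning, match="failed to fit"):
            res = fit_cohort([good, zero_trace(short_protocol)], constraints)
        assert res.n_traces == 1
        assert not res.converged
        assert len(res.per_trace_results) == 2
        assert not res.per_trace_results[1].converged

    def test_recovers_cohort_mean_under_patch_scatter(self, constraints):
        # lognormal patch scatter (CV 15%, 20 patches) around the
        # wild-type concatemer rates: the cohort mean estimate must land
        # within 1 SEM of the mean of the realized patch-level rates
        spec = PatchCohortSpec(
            rates=default_rates(108.0, 40.0),
            n_patches=20, traces_per_patch=1,
            protocol=GatingProtocol(duration=50.0, pre_step_baseline=2.0),
            noise=NoiseModel(gaussian_sd=0.02),
            rate_scatter=0.15, seed=42,
        )
        traces = generate_cohort(spec)
        truth = np.array([tr.meta["k_on_true"] for tr in traces])
        res = fit_cohort(traces, constraints)
        sem = res.k_on_sd / np.sqrt(res.n_traces)
        assert abs(res.k_on - truth.mean()) < sem


class TestExtent:
    def test_closed_form_from_fit_rates(self):
        from kvinact.fitting import FitResult

        mk = lambda k_on, k_off: FitResult(k_on, k_off, 100.0, 0.0, 1, True)
        assert extent_of_inactivation(mk(430, 21)) == pytest.approx(430 / 451, rel=1e-12)
        assert extent_of_inactivation(mk(0, 21)) == 0.0
        assert extent_of_inactivation(mk(33, 33)) == 0.5

    def test_trace_extent_matches_kinetic_prediction(self, protocol):
        # the operational (1 - steady/peak) and kinetic k_on/(k_on+k_off)
        # definitions coincide when activation is much faster than gating
        tr = simulate_current(RateSet(30000, 0, 30000, 0, 430, 21), 100.0, protocol)
        assert extent_of_inactivation(tr) == pytest.approx(430 / 451, rel=0.02)

    def test_flat_zero_trace_rejected(self, short_protocol):
        with pytest.raises(ValueError, match="peak"):
            extent_of_inactivation(zero_trace(short_protocol))


class TestSensitivity:
    def test_zero_perturbation_changes_nothing(self, short_protocol, constraints):
        tr = simulate_current(default_rates(108, 40), 100.0, short_protocol)
        table = sensitivity_analysis(tr, constraints, perturbation=0.0)
        assert np.allclose(table["rel_dk_on"], 0.0, atol=1e-9)
        assert np.allclose(table["rel_dk_off"], 0.0, atol=1e-9)

    def test_fast_activation_rates_are_insensitive(self, protocol):
        # timescale separation makes the frozen activation rates
        # irrelevant to the inactivation estimates: the impact of a 20%
        # activation perturbation falls off with the separation ratio
        # and drops below 2% once activation is ~50x faster than k_on
        worst = []
        for mult in (10.0, 50.0):
            a = 430.0 * mult
            fast = (a, 0.0, a, 0.0)
            tr = simulate_current(RateSet(*fast, 430.0, 21.0), 100.0, protocol)
            table = sensitivity_analysis(
                tr, FitConstraints(fixed_activation=fast), perturbation=0.2
            )
            moved = table[table["parameter"].isin(["a1", "a2"])]
            worst.append(float(np.max(np.abs(moved["rel_dk_on"]))))
        assert worst[1] < worst[0]
        assert worst[1] < 0.02

    def test_comparable_activation_rates_show_larger_sensitivity(self):
        # activation comparable to k_on: sensitivity must be visible,
        # not hidden
        slow = (600.0, 0.0, 600.0, 0.0)
        protocol = GatingProtocol(duration=60.0)
        tr = simulate_current(RateSet(*slow, 430.0, 21.0), 100.0, protocol)
        table = sensitivity_analysis(
            tr, FitConstraints(fixed_activation=slow), perturbation=0.2
        )
        moved = table[table["parameter"].isin(["a1", "a2"])]
        assert np.max(np.abs(moved["rel_dk_on"])) > 0.02


class TestActivationEstimation:
    def test_noiseless_roundtrip_recovers_activation_pair(self, protocol):
        gen = RateSet(800.0, 0.0, 1500.0, 0.0, 108.0, 40.0)
        tr = simulate_current(gen, 100.0, protocol)
        guess = RateSet(1000.0, 0.0, 1200.0, 0.0, 150.0, 30.0)
        est = estimate_activation_rates([tr], guess, fix_deactivation=True)
        assert est.converged
        # a1 and a2 are exchangeable in a forward cascade: compare sorted
        assert sorted([est.a1, est.a2]) == pytest.approx([800.0, 1500.0], rel=1e-3)

    def test_duplicated_trace_gives_same_estimate(self, protocol):
        gen = RateSet(800.0, 0.0, 1500.0, 0.0, 108.0, 40.0)
        tr = simulate_current(gen, 100.0, protocol)
        guess = RateSet(1000.0, 0.0, 1200.0, 0.0, 150.0, 30.0)
        one = estimate_activation_rates([tr], guess, fix_deactivation=True)
        two = estimate_activation_rates([tr, tr], guess, fix_deactivation=True)
        assert sorted([two.a1, two.a2]) == pytest.approx(sorted([one.a1, one.a2]), rel=1e-6)

    def test_all_zero_traces_rejected(self, short_protocol):
        guess = RateSet(1000.0, 0.0, 1200.0, 0.0, 150.0, 30.0)
        with pytest.raises(ValueError, match="no current"):
            estimate_activation_rates([zero_trace(short_protocol)], guess)
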