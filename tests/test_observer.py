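"""Kalman observer: measurement law, gain, updates, trial simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from serialtoe import (
    DesignSpec,
    ObserverParams,
    ObserverState,
    Trial,
    TruncatedNormal,
    build_design,
    kalman_gain,
    measure,
    resolve_noise,
    run_trial,
    simulate_cohort,
    simulate_subject,
    steady_state_variance,
    update_state,
)

LN120 = math.log(120.0)


class TestMeasure:
    def test_noiseless_is_log(self, rng):
        assert measure(120, 0.0, rng).x_m == pytest.approx(LN120)
        assert measure(220, 0.0, rng).x_m == pytest.approx(math.log(220), abs=1e-12)

    def test_monte_carlo_mean(self, rng):
        n = 100_000
        xs = np.array([measure(120, 0.1, rng).x_m for _ in range(n)])
        assert abs(xs.mean() - LN120) < 3 * 0.1 / math.sqrt(n)
        assert xs.std() == pytest.approx(0.1, rel=0.02)

    def test_domain_errors(self, rng):
        with pytest.raises(ValueError):
            measure(0, 0.1, rng)
        with pytest.raises(ValueError):
            measure(120, -0.1, rng)


class TestKalmanGain:
    def test_equal_variances(self):
        assert kalman_gain(1.5, 1.5, 1.5) == pytest.approx(2 / 3)

    def test_limits(self):
        assert kalman_gain(0.0, 1e-4, 1e6) == pytest.approx(0.0, abs=1e-9)
        assert kalman_gain(1e6, 0.0, 1.0) == pytest.approx(1.0, abs=1e-5)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            kalman_gain(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            kalman_gain(0.0, 0.0, 1.0)

    @given(
        p=hst.floats(0.0, 100.0),
        q=hst.floats(1e-6, 100.0),
        r=hst.floats(1e-6, 100.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_and_monotonicity(self, p, q, r):
        k = kalman_gain(p, q, r)
        assert 0.0 < k < 1.0
        assert kalman_gain(p + 1.0, q, r) > k  # more prior uncertainty
        assert kalman_gain(p, q, r + 1.0) < k  # noisier measurement


class TestUpdateState:
    def test_midpoint(self):
        # p + q = r forces k = 1/2: the posterior mean is the midpoint
        state = ObserverState(mu_p=4.0, p=0.5)
        new, percept = update_state(state, x_m=5.0, r=1.0, q=0.5)
        assert percept == pytest.approx(4.5)
        assert new.mu_p == pytest.approx(4.5)

    def test_measurement_dominates(self):
        state = ObserverState(mu_p=4.0, p=1e9)
        _, percept = update_state(state, x_m=5.0, r=1.0, q=0.0)
        assert percept == pytest.approx(5.0, abs=1e-6)

    @given(
        mu=hst.floats(-10, 10),
        p=hst.floats(0, 10),
        q=hst.floats(1e-6, 10),
        r=hst.floats(1e-6, 10),
        x=hst.floats(-10, 10),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_variance_contraction_and_convexity(self, mu, p, q, r, x):
        state = ObserverState(mu_p=mu, p=p)
        new, percept = update_state(state, x, r, q)
        assert new.p <= r + 1e-12
        assert new.p <= p + q + 1e-12
        assert min(mu, x) - 1e-9 <= percept <= max(mu, x) + 1e-9

    def test_variance_fixed_point(self):
        q, r = 0.25, 1.0
        state = ObserverState(mu_p=0.0, p=5.0)
        for _ in range(100):
            state, _ = update_state(state, 0.0, r, q)
        p_star = steady_state_variance(q, r)
        assert state.p == pytest.approx(p_star, abs=1e-10)
        # closed form satisfies the recursion exactly
        assert p_star == pytest.approx(r * (p_star + q) / (p_star + q + r), abs=1e-12)


class TestResolveNoise:
    @staticmethod
    def _trial(group="SC", c=140.0, isi=400.0):
        return Trial(group, 120.0, c, abs(c - 120), 1 if c > 120 else -1, isi, 1500, 0, 0)

    def test_isi_ordering(self):
        params = ObserverParams(isi_noise={400.0: 2.0, 2000.0: 1.0})
        hi = resolve_noise(self._trial(isi=400), "second", params, 0.1)
        lo = resolve_noise(self._trial(isi=2000), "second", params, 0.1)
        assert hi.sigma > lo.sigma
        assert lo.sigma == pytest.approx(0.1)

    def test_weak_level_targets_shorter_first_interval(self):
        weak = TruncatedNormal(0.5, 0.5, 0.0)
        params = ObserverParams(weak_level_noise=weak)
        # SC: the standard (first) is the shorter one on +delta20 trials
        assert resolve_noise(self._trial("SC", 140), "first", params, 0.1).shape is weak
        assert resolve_noise(self._trial("SC", 100), "first", params, 0.1).shape is not weak
        # CS: the comparison (first) is the shorter one on -delta20 trials
        assert resolve_noise(self._trial("CS", 100), "first", params, 0.1).shape is weak
        assert resolve_noise(self._trial("CS", 140), "first", params, 0.1).shape is not weak
        # the bias is specific to the weak (20 ms) step
        assert resolve_noise(self._trial("SC", 180), "first", params, 0.1).shape is not weak

    def test_position_pair_selects_second_interval_shape(self):
        lf = TruncatedNormal(-0.2, 1.0)
        ls = TruncatedNormal(-0.8, 1.0)
        params = ObserverParams(longer_first_noise=lf, longer_second_noise=ls)
        # SC with short C: longer (S) first
        assert resolve_noise(self._trial("SC", 100), "second", params, 0.1).shape is lf
        # SC with long C: longer (C) second
        assert resolve_noise(self._trial("SC", 140), "second", params, 0.1).shape is ls

    def test_identity_configuration(self):
        params = ObserverParams()
        noise = resolve_noise(self._trial(), "second", params, 0.17)
        assert noise.sigma == pytest.approx(0.17)
        assert noise.shape.loc == 0.0 and noise.shape.scale == 1.0

    def test_floor_inflates_short_first_intervals(self):
        params = ObserverParams(noise_floor_ms=120.0)
        short = resolve_noise(self._trial("CS", c=20.0), "first", params, 0.1)
        long = resolve_noise(self._trial("CS", c=220.0), "first", params, 0.1)
        assert short.sigma == pytest.approx(0.1 * (1 + 120 / 20))
        assert short.sigma > long.sigma

    def test_unknown_isi_rejected(self):
        with pytest.raises(KeyError):
            resolve_noise(self._trial(isi=999.0), "second", ObserverParams(), 0.1)


class TestRunTrial:
    def test_noiseless_always_correct(self, noiseless_params, tiny_spec, rng):
        recs = simulate_subject(0, tiny_spec, "SC", noiseless_params, rng,
                                sigma_subject=0.0)
        assert all(r.correct for r in recs)

    def test_decision_rule_orientation(self, noiseless_params, rng):
        t = Trial("SC", 120.0, 140.0, 20.0, 1, 400.0, 1500, 0, 0)
        state = noiseless_params.initial_state()
        rec, _ = run_trial(t, state, noiseless_params, rng, sigma_subject=0.0)
        assert rec.response == 1 and rec.correct

    def test_exact_tie_uses_fair_coin(self, rng):
        # zero noise with the prior already at ln(120) makes both
        # percepts exactly equal on a catch trial
        params = ObserverParams(prior_mean0=LN120, prior_var0=1.0)
        t = Trial("SC", 120.0, 120.0, 0.0, 1, 400.0, 1500, 0, 0)
        responses = set()
        for _ in range(64):
            rec, _ = run_trial(t, params.initial_state(), params, rng,
                               sigma_subject=0.0)
            responses.add(rec.response)
        assert responses == {0, 1}

    def test_state_carries_forward(self, rng):
        params = ObserverParams(sigma_subject=TruncatedNormal(0.1, 0.0))
        t = Trial("SC", 120.0, 180.0, 60.0, 1, 400.0, 1500, 0, 0)
        state = params.initial_state()
        _, new = run_trial(t, state, params, rng, sigma_subject=0.1)
        assert new.n_updates == state.n_updates + 2
        assert new.p < state.p


class TestSimulateCohort:
    def test_row_count_and_determinism(self, tiny_spec, study):
        params, _ = study
        a = simulate_cohort(2, tiny_spec, "CS", params, np.random.default_rng(5))
        b = simulate_cohort(2, tiny_spec, "CS", params, np.random.default_rng(5))
        assert len(a) == 2 * 4 * 6
        assert a.equals(b)

    def test_full_size_arithmetic(self):
        # 100 subjects x 4 ISI blocks x 120 trials = 48,000 rows; check
        # the arithmetic on a scaled-down cohort with the same structure
        spec = DesignSpec(trials_per_block=12)
        params = ObserverParams(sigma_subject=TruncatedNormal(0.1, 0.0))
        rec = simulate_cohort(5, spec, "SC", params, np.random.default_rng(0))
        assert len(rec) == 5 * 4 * 12

    def test_accuracy_monotone_in_noise(self, tiny_spec):
        accs = []
        for sigma in (0.02, 0.1, 0.4, 1.2):
            params = ObserverParams(sigma_subject=TruncatedNormal(sigma, 0.0))
            rec = simulate_cohort(6, tiny_spec, "SC", params,
                                  np.random.default_rng(99))
            accs.append(rec["correct"].mean())
        assert accs == sorted(accs, reverse=True)

    def test_requires_subjects(self, tiny_spec, study):
        params, _ = study
        with pytest.raises(ValueError):
            simulate_cohort(0, tiny_spec, "SC", params, np.random.default_rng(0))


class TestNullObserverSymmetry:
    def test_pse_is_order_invariant_without_asymmetries(self):
        # with symmetric noise the two presentation orders face the
        # same discrimination problem, so the fitted PSE must agree
        # between groups (no time-order error); note the common PSE may
        # sit slightly above the standard because a linear-duration
        # probit is fitted to log-scale behavior
        from serialtoe import fit_subjects, null_params

        params, spec = null_params()
        pse = {}
        for group, seed in (("SC", 5), ("CS", 6)):
            rec = simulate_cohort(50, spec, group, params,
                                  np.random.default_rng(seed))
            fits = fit_subjects(rec, per_isi=False)
            pse[group] = (fits["pse_ms"].mean(),
                          fits["pse_ms"].std(ddof=1) / np.sqrt(len(fits)))
        diff = abs(pse["SC"][0] - pse["CS"][0])
        se = math.hypot(pse["SC"][1], pse["CS"][1])
        assert diff < 3 * se


class TestTruncatedNormal:
    def test_draw_respects_bounds(self, rng):
        tn = TruncatedNormal(0.0, 1.0, lower=0.0)
        draws = tn.draw(rng, size=2000)
        assert (draws >= 0).all()
        assert draws.mean() == pytest.approx(tn.mean, abs=0.06)

    def test_degenerate_scale(self, rng):
        tn = TruncatedNormal(0.7, 0.0)
        assert tn.draw(rng) == 0.7
        assert tn.mean == 0.7

    def test_invalid(self):
        with pytest.raises(ValueError):
            TruncatedNormal(0, -1)
        with pytest.raises(ValueError):
            TruncatedNormal(0, 1, lower=2.0, upper=1.0)
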