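"""Protocol statistics: exclusion windows, responses, summation, fits, t test."""

import numpy as np
import pytest

from ototrap import trialstats
from ototrap.tracking import BoutEvent
from ototrap.trialstats import (
    ProtocolConfig,
    TrialRecord,
    apply_exclusion,
    linear_summation_test,
    onset_offset_response,
    paired_t_test,
    power_response_fit,
    swim_probability,
)

PROTO = ProtocolConfig()  # onset 2 s, 1 s exposure


def _trial(bouts, condition="lateral", power=600.0, n=1001, excluded=False,
           reason="none"):
    t = np.arange(n) / 200.0
    return TrialRecord(
        larva_id="L0", condition=condition, power_mw=power,
        time_s=t, tail_deg=np.zeros(n), bouts=bouts,
        excluded=excluded, exclusion_reason=reason,
    )


def _bout(onset, offset, cls="swim"):
    return BoutEvent(onset, offset, 20.0, cls)


class TestExclusion:
    @pytest.mark.parametrize(
        "bouts,expected",
        [
            ([_bout(1.2, 1.5)], "pre_swim"),       # ends 0.5 s before onset
            ([_bout(-0.5, 0.0)], "none"),          # ends 2.0 s before onset
            ([_bout(3.2, 3.5)], "post_swim"),      # starts 0.2 s after offset
            ([_bout(4.5, 4.8)], "none"),           # starts 1.5 s after offset
            ([_bout(2.3, 2.5, "escape")], "escape"),   # escape during trap
            ([_bout(2.2, 2.6)], "none"),           # evoked swim during trap
            ([_bout(1.2, 1.5), _bout(2.3, 2.5, "escape")], "escape"),  # precedence
        ],
    )
    def test_window_rules(self, bouts, expected):
        out = apply_exclusion([_trial(bouts)], PROTO)
        assert out[0].exclusion_reason == expected
        assert out[0].excluded == (expected != "none")

    def test_idempotent_and_order_independent(self):
        trials = [
            _trial([_bout(1.2, 1.5)]),
            _trial([]),
            _trial([_bout(2.1, 2.4, "escape")]),
        ]
        once = apply_exclusion(trials, PROTO)
        twice = apply_exclusion(once, PROTO)
        assert [t.exclusion_reason for t in once] == [
            t.exclusion_reason for t in twice
        ]
        rev = apply_exclusion(trials[::-1], PROTO)
        assert [t.exclusion_reason for t in rev] == [
            t.exclusion_reason for t in once
        ][::-1]


class TestOnsetOffset:
    def test_lateral_plateau_and_rebound_toward_zero(self):
        from ototrap.synthetic import _postural_trace

        t = np.arange(0, 5, 1 / 200.0)
        x = _postural_trace(t, 2.0, 3.0, 15.0, 0.15, 0.3)
        onset, offset = onset_offset_response(t, x, PROTO)
        assert onset == pytest.approx(15.0, abs=0.2)
        # decays toward 0 with tau = 0.3 s; ~0.5 deg remains after the 1 s window
        assert offset == pytest.approx(-14.5, abs=1.0)

    def test_medial_flat_then_rebound(self):
        from ototrap.synthetic import _postural_trace

        t = np.arange(0, 5, 1 / 200.0)
        x = _postural_trace(t, 2.0, 3.0, 0.0, 0.15, 0.3, rebound=-8.0)
        onset, offset = onset_offset_response(t, x, PROTO)
        assert onset == pytest.approx(0.0, abs=0.1)
        assert offset == pytest.approx(-8.0, abs=0.3)

    def test_flat_trace_gives_zero_zero(self):
        t = np.arange(0, 5, 1 / 200.0)
        onset, offset = onset_offset_response(t, np.zeros_like(t), PROTO)
        assert onset == 0.0 and offset == 0.0

    def test_bouts_masked_before_extremum(self):
        from ototrap.synthetic import _postural_trace, _sine_bout

        t = np.arange(0, 5, 1 / 200.0)
        x = _postural_trace(t, 2.0, 3.0, 10.0, 0.15, 0.3)
        x = x + _sine_bout(t, 2.3, 0.35, 12.0, 20.0)
        bouts = [_bout(2.3, 2.65)]
        onset, _ = onset_offset_response(t, x, PROTO, bouts)
        assert onset == pytest.approx(10.0, abs=0.5)


class TestSummation:
    def _traces(self, additivity=1.0, noise=0.0, seed=0):
        from ototrap.synthetic import _postural_trace

        rng = np.random.default_rng(seed)
        t = np.arange(0, 5, 1 / 200.0)
        lat = _postural_trace(t, 2.0, 3.0, 20.0, 0.15, 0.3)
        med = _postural_trace(t, 2.0, 3.0, 0.0, 0.15, 0.3, rebound=-8.0)
        dual = additivity * (lat + med)
        if noise:
            lat = lat + rng.normal(0, noise, t.size)
            med = med + rng.normal(0, noise, t.size)
            dual = dual + rng.normal(0, noise, t.size)
        return lat, med, dual

    def test_exact_additivity_gives_zero_residual(self):
        lat, med, dual = self._traces()
        res = linear_summation_test(lat, med, dual)
        assert res["max_abs_residual"] < 1e-12

    def test_thirty_percent_sublinear_gives_fraction_point_three(self):
        lat, med, dual = self._traces(additivity=0.7)
        res = linear_summation_test(lat, med, dual)
        assert res["residual_fraction"] == pytest.approx(0.3, abs=0.01)

    def test_zero_medial_reduces_to_dual_minus_lateral(self):
        lat, _, dual = self._traces()
        res = linear_summation_test(lat, np.zeros_like(lat), dual)
        np.testing.assert_allclose(res["residual"], dual - lat, rtol=1e-12)

    def test_misaligned_traces_rejected(self):
        lat, med, dual = self._traces()
        with pytest.raises(ValueError):
            linear_summation_test(lat[:-1], med, dual)


class TestSwimProbability:
    def test_all_and_none(self):
        swim = [_trial([_bout(2.2, 2.6)], power=600.0) for _ in range(3)]
        still = [_trial([], power=50.0) for _ in range(3)]
        probs = swim_probability(swim + still, PROTO)
        assert probs[600.0] == 1.0
        assert probs[50.0] == 0.0

    def test_excluded_trials_are_dropped(self):
        tr = [
            _trial([_bout(2.2, 2.6)], power=400.0),
            _trial([_bout(1.2, 1.5)], power=400.0, excluded=True,
                   reason="pre_swim"),
        ]
        assert swim_probability(tr, PROTO)[400.0] == 1.0

    def test_zero_usable_trials_flagged_nan(self):
        tr = [_trial([], power=100.0, excluded=True, reason="escape")]
        assert np.isnan(swim_probability(tr, PROTO)[100.0])


class TestPowerFit:
    def test_exact_quadratic_recovered_to_1e9(self):
        p = np.array([50.0, 100.0, 200.0, 400.0, 600.0])
        y = 1.0 + 0.02 * p + 1e-5 * p**2
        fit = power_response_fit(p, y[None, :])
        np.testing.assert_allclose(
            fit["coefficients"], [1e-5, 0.02, 1.0], atol=1e-9
        )

    def test_constant_input_gives_zero_curvature_and_slope(self):
        p = np.array([50.0, 100.0, 200.0])
        fit = power_response_fit(p, np.full((4, 3), 7.0))
        assert abs(fit["coefficients"][0]) < 1e-12
        assert abs(fit["coefficients"][1]) < 1e-9
        np.testing.assert_allclose(fit["sem_deg"], 0.0, atol=1e-12)

    def test_too_few_powers_rejected(self):
        with pytest.raises(ValueError):
            power_response_fit(np.array([50.0, 100.0]), np.zeros((2, 2)))


class TestPairedT:
    def test_worked_example(self):
        t, p = paired_t_test([1.0, 2.0, 3.0, 4.0, 5.0], [0.0] * 5)
        assert t == pytest.approx(4.2426, abs=1e-4)
        assert p == pytest.approx(0.0132, abs=5e-4)

    def test_identical_pairs_give_null_result(self):
        t, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_sign_flip_flips_t_preserves_p(self):
        x = [1.0, 2.5, 3.0, 4.0, 5.5]
        y = [0.5, 1.0, 2.0, 2.5, 3.0]
        t1, p1 = paired_t_test(x, y)
        t2, p2 = paired_t_test(y, x)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [0.0])
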