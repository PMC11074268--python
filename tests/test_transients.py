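"""Per-cell transient analysis: dF/F0, responder call, decay, class."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fibromech as fm
from fibromech.errors import (
    DegenerateBaselineError,
    SchemaError,
    UndefinedDecayError,
)
from fibromech.transients import DecayResult, DffTrace, decay_time


def trace(F, B=None, **kw):
    F = np.asarray(F, float)
    B = np.zeros_like(F) if B is None else np.asarray(B, float)
    return fm.FluorescenceTrace(np.arange(F.size) / 2.0, F, B, **kw)


class TestComputeDff:
    @pytest.mark.parametrize(
        "F,B,expected",
        [
            # constant signal: identically zero
            ([100, 100, 100, 100, 100], None, [0, 0, 0, 0, 0]),
            # hand evaluation of ((F-B)-(F0-B0))/(F0-B0) with B = 0
            ([100, 100, 100, 100, 150], None, [0, 0, 0, 0, 0.5]),
            # hand evaluation with nonzero constant background
            ([110, 110, 110, 110, 210], [10] * 5, [0, 0, 0, 0, 1.0]),
        ],
    )
    def test_hand_computed_examples(self, F, B, expected):
        dff = fm.compute_dff(trace(F, B))
        np.testing.assert_allclose(dff.dff, expected, atol=1e-14)

    def test_baseline_mean_is_zero(self):
        rng = np.random.default_rng(3)
        F = 100 + rng.normal(0, 5, 40)
        B = 10 + rng.normal(0, 1, 40)
        dff = fm.compute_dff(trace(F, B), n_baseline=4)
        assert abs(np.mean(dff.dff[:4])) < 1e-12

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        """dF/F0 is unchanged by rescaling F and B by a common factor."""
        rng = np.random.default_rng(11)
        F = 100 + rng.normal(0, 5, 30) + np.linspace(0, 50, 30)
        B = 8 + rng.normal(0, 0.5, 30)
        d1 = fm.compute_dff(trace(F, B)).dff
        d2 = fm.compute_dff(trace(scale * F, scale * B)).dff
        np.testing.assert_allclose(d1, d2, rtol=1e-9, atol=1e-12)

    def test_neglect_background_substitutes_zero(self):
        F = np.array([110, 110, 110, 110, 210.0])
        B = np.full(5, 10.0)
        dff = fm.compute_dff(trace(F, B), neglect_background=True)
        # with B forced to 0 the denominator is F0 alone
        np.testing.assert_allclose(dff.dff[-1], 100 / 110)

    def test_degenerate_baseline_raises(self):
        with pytest.raises(DegenerateBaselineError):
            fm.compute_dff(trace([5, 5, 5, 5, 6], [9] * 5))

    def test_too_short_raises(self):
        with pytest.raises(SchemaError):
            fm.compute_dff(trace([1, 1, 1, 1, 2.0]), n_baseline=5)


class TestDetectResponse:
    def make_dff(self, peak):
        d = np.zeros(20)
        d[10] = peak
        return DffTrace(np.arange(20) / 2.0, d, 100.0, 0.0)

    @pytest.mark.parametrize(
        "peak,modality,expected",
        [
            (0.009, "AFM", False),        # sub-threshold
            (0.05, "AFM", True),          # mechanical threshold 0.01
            (0.05, "OT", True),
            (0.05, "chemical", False),    # chemical threshold 0.1
            (0.15, "chemical", True),
            (0.01, "AFM", False),         # strict inequality at boundary
            (0.1, "chemical", False),
        ],
    )
    def test_thresholds(self, peak, modality, expected):
        assert fm.detect_response(self.make_dff(peak), modality) is expected

    def test_threshold_monotonicity(self):
        """Raising the threshold never turns a non-responder into one."""
        dff = self.make_dff(0.05)
        calls = [
            fm.detect_response(dff, "AFM", threshold=thr)
            for thr in np.linspace(0.001, 0.2, 50)
        ]
        # once False, stays False
        assert calls == sorted(calls, reverse=True)

    def test_peak_search_starts_after_baseline(self):
        d = np.zeros(20)
        d[1] = 5.0   # inside the baseline window: must be ignored
        dff = DffTrace(np.arange(20) / 2.0, d, 100.0, 0.0, n_baseline=4)
        assert fm.detect_response(dff, "AFM") is False


class TestDecayTime:
    def test_exponential_closed_form(self, noise_free_trace_cfg):
        """First crossing of peak/3 on a pure exponential is tau*ln(3)."""
        tr = fm.simulate_trace(noise_free_trace_cfg)
        dff = fm.compute_dff(tr)
        res = decay_time(dff)
        assert not res.censored
        assert res.tau_s == pytest.approx(5.0 * np.log(3), abs=0.5)

    def test_immediate_decay_is_one_frame(self):
        d = np.zeros(30)
        d[10] = 1.0  # next frame already at 0 <= peak/3
        dff = DffTrace(np.arange(30) / 2.0, d, 100.0, 0.0)
        res = decay_time(dff)
        assert res == DecayResult(0.5, False)

    def test_never_decaying_is_censored(self):
        t = np.arange(120) / 2.0
        d = np.where(t >= 10, 1.0, 0.0)
        dff = DffTrace(t, d, 100.0, 0.0)
        res = decay_time(dff)
        assert res.censored and res.tau_s == pytest.approx(59.5 - 10.0)

    def test_nonpositive_peak_raises(self):
        dff = DffTrace(np.arange(10) / 2.0, np.full(10, -0.1), 100.0, 0.0)
        with pytest.raises(UndefinedDecayError):
            decay_time(dff)


class TestClassify:
    @pytest.mark.parametrize(
        "responder,tau,censored,expected",
        [
            (True, 25.0, False, "generalized"),
            (True, 3.0, False, "transitory"),
            (True, 10.0, False, "generalized"),   # boundary -> generalized
            (True, 9.999, False, "transitory"),
            (True, 5.0, True, "generalized"),     # censored counts as slow
            (False, float("nan"), False, "none"),
        ],
    )
    def test_rules(self, responder, tau, censored, expected):
        assert fm.classify_response(responder, tau, censored) == expected

    def test_noise_free_class_recovery_is_exact(self):
        """On clean traces every simulated class is recovered."""
        rng = np.random.default_rng(5)
        for i in range(60):
            gen = i % 2 == 0
            tau = rng.uniform(*(18.0, 40.0) if gen else (1.5, 6.0))
            tr = fm.simulate_trace(fm.TraceSimConfig(
                amplitude=0.5, tau_decay=float(tau), noise_sd=0.0, seed=i))
            m = fm.analyze_trace(tr)
            assert m.response_class == ("generalized" if gen else "transitory")


class TestAnalyzeTrace:
    def test_flat_trace_is_non_responder(self):
        tr = fm.simulate_trace(fm.TraceSimConfig(amplitude=0.0, noise_sd=0.0))
        m = fm.analyze_trace(tr)
        assert not m.responder and m.response_class == "none"
        assert m.dff_max == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_passthrough_noise_free(self):
        """Peak dF/F0 equals the configured amplitude up to one-frame
        discretization of the fast-rise transient."""
        cfg = fm.TraceSimConfig(amplitude=0.5, tau_rise=1e-6, tau_decay=200.0,
                                noise_sd=0.0)
        m = fm.analyze_trace(fm.simulate_trace(cfg))
        assert m.dff_max == pytest.approx(0.5, rel=3e-3)


class TestExtractRoi:
    def test_uniform_frames(self):
        stack = np.full((10, 8, 8), 7.0)
        cell = np.zeros((8, 8), bool)
        cell[:4] = True
        bg = ~cell
        tr = fm.extract_roi_trace(stack, cell, bg)
        np.testing.assert_allclose(tr.cell_signal, 7.0)
        np.testing.assert_allclose(tr.background_signal, 7.0)

    def test_movie_round_trip_matches_trace(self):
        """ROI-mean of a noise-free synthetic movie equals simulate_trace."""
        cfg = fm.TraceSimConfig(amplitude=0.4, noise_sd=0.0, seed=2)
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        stack = fm.simulate_movie(mask, cfg)
        tr = fm.extract_roi_trace(stack, mask, ~mask, frame_rate=cfg.frame_rate)
        ref = fm.simulate_trace(cfg)
        np.testing.assert_allclose(tr.cell_signal, ref.cell_signal, rtol=1e-12)
        np.testing.assert_allclose(tr.background_signal, ref.background_signal)

    def test_overlapping_masks_raise(self):
        stack = np.zeros((6, 4, 4))
        m = np.ones((4, 4), bool)
        with pytest.raises(SchemaError):
            fm.extract_roi_trace(stack, m, m)

    def test_empty_mask_raises(self):
        stack = np.zeros((6, 4, 4))
        with pytest.raises(SchemaError):
            fm.extract_roi_trace(stack, np.zeros((4, 4), bool), np.ones((4, 4), bool))
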