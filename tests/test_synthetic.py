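"""Synthetic-data generator: ground-truth contracts and statistical laws."""

import numpy as np
import pytest

import fibromech as fm
from fibromech.transients import analyze_trace


class TestTraceConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("baseline_intensity", 0.0),
            ("tau_rise", -1.0),
            ("tau_decay", 0.0),
            ("noise_sd", -0.1),
            ("stim_onset", 70.0),     # beyond the 60 s recording
            ("background_level", 200.0),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ValueError, match=field):
            fm.TraceSimConfig(**{field: value})


class TestSimulateTrace:
    def test_no_transient_identity(self):
        """amplitude=0, noise=0: flat channels, dF/F0 identically zero."""
        tr = fm.simulate_trace(fm.TraceSimConfig(amplitude=0.0, noise_sd=0.0))
        dff = fm.compute_dff(tr)
        np.testing.assert_allclose(dff.dff, 0.0, atol=1e-14)

    def test_shape_and_spacing(self):
        cfg = fm.TraceSimConfig(n_frames=120, frame_rate=2.0)
        tr = fm.simulate_trace(cfg)
        assert len(tr) == 120
        np.testing.assert_allclose(np.diff(tr.time), 0.5)

    def test_closed_form_decay_and_class(self):
        """tau_decay = 5 s: decay time 5*ln3 ~ 5.49 s, class transitory."""
        cfg = fm.TraceSimConfig(amplitude=0.5, tau_rise=1e-6, tau_decay=5.0,
                                noise_sd=0.0)
        m = analyze_trace(fm.simulate_trace(cfg))
        assert m.tau_s == pytest.approx(5.0 * np.log(3), abs=0.5)
        assert m.response_class == "transitory"

    def test_seed_determinism(self):
        cfg = fm.TraceSimConfig(noise_sd=2.0, seed=9)
        a = fm.simulate_trace(cfg)
        b = fm.simulate_trace(cfg)
        np.testing.assert_array_equal(a.cell_signal, b.cell_signal)
        c = fm.simulate_trace(fm.TraceSimConfig(noise_sd=2.0, seed=10))
        assert not np.array_equal(a.cell_signal, c.cell_signal)

    def test_truth_always_attached(self):
        tr = fm.simulate_trace(fm.TraceSimConfig())
        assert tr.truth is not None and "amplitude" in tr.truth

    def test_drift_is_linear_in_baseline(self):
        cfg = fm.TraceSimConfig(amplitude=0.0, noise_sd=0.0, drift_rate=0.01)
        tr = fm.simulate_trace(cfg)
        expected = 100.0 * (1 + 0.01 * tr.time)
        np.testing.assert_allclose(tr.cell_signal, expected)


class TestSimulatePopulation:
    def test_step_function_limit(self):
        """Tiny slope with all forces above f_half: everyone responds."""
        cfg = fm.PopulationSimConfig(
            forces=(310.0, 350.0), n_per_force=50, slope_true=1e-9, seed=1)
        pairs = fm.simulate_population(cfg)
        assert all(r.responder_true for r, _ in pairs)

    def test_binomial_law_at_half_activation(self):
        """At F = f_half the responder fraction converges to 0.5."""
        n = 100_000
        cfg = fm.PopulationSimConfig(forces=(300.0,), n_per_force=n, seed=4)
        # draw responder flags only (traces not needed): use the same
        # Bernoulli stream the generator uses
        pa = fm.boltzmann_pa(300.0, cfg.f_half_true, cfg.slope_true)
        assert pa == 0.5
        from fibromech._rng import substream
        rng = substream(cfg.seed, "population", 0)
        frac = np.mean(rng.random(n) < pa)
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * se

    def test_responder_fraction_tracks_boltzmann(self):
        """Full generator at moderate n stays within 3 SE of PA(F)."""
        cfg = fm.PopulationSimConfig(n_per_force=400, seed=8)
        pairs = fm.simulate_population(cfg)
        for force in cfg.forces:
            flags = [r.responder_true for r, _ in pairs if r.force_nN == force]
            pa = fm.boltzmann_pa(force, cfg.f_half_true, cfg.slope_true)
            se = np.sqrt(pa * (1 - pa) / len(flags))
            assert abs(np.mean(flags) - pa) < 3.5 * se

    def test_degenerate_share_all_generalized(self):
        cfg = fm.PopulationSimConfig(
            gen_share_low=1.0, gen_share_high=1.0, n_per_force=40, seed=2)
        pairs = fm.simulate_population(cfg)
        responders = [r for r, _ in pairs if r.responder_true]
        assert responders and all(r.class_true == "generalized" for r in responders)

    def test_class_decay_times_respect_boundary(self):
        cfg = fm.PopulationSimConfig(n_per_force=60, seed=3)
        for r, _ in fm.simulate_population(cfg):
            if r.class_true == "generalized":
                assert r.tau_decay_true * np.log(3) > 10.0
            elif r.class_true == "transitory":
                assert r.tau_decay_true * np.log(3) < 10.0

    def test_substreams_stable_under_resizing(self):
        """Adding cells at one force leaves other forces' draws unchanged."""
        a = fm.simulate_population(fm.PopulationSimConfig(
            forces=(150.0, 350.0), n_per_force=10, seed=5))
        b = fm.simulate_population(fm.PopulationSimConfig(
            forces=(150.0, 350.0), n_per_force=20, seed=5))
        a350 = [(r, t) for r, t in a if r.force_nN == 350.0]
        b350 = [(r, t) for r, t in b if r.force_nN == 350.0]
        for (ra, ta), (rb, tb) in zip(a350, b350):
            assert ra.responder_true == rb.responder_true
            np.testing.assert_array_equal(ta.cell_signal, tb.cell_signal)

    def test_empty_force_list_raises(self):
        with pytest.raises(ValueError, match="forces"):
            fm.PopulationSimConfig(forces=())


class TestSimulateForceCurve:
    def test_round_trip_recovers_modulus(self):
        """Noise-free generator/fitter loop recovers E within 0.5%."""
        cfg = fm.ForceCurveSimConfig(young_modulus_true=10e3,
                                     deflection_noise_sd=0.0)
        fit = fm.fit_force_curve(fm.simulate_force_curve(cfg))
        assert fit.young_modulus == pytest.approx(10e3, rel=5e-3)

    def test_soft_limit_deflection_vanishes(self):
        cfg = fm.ForceCurveSimConfig(young_modulus_true=1e-6,
                                     deflection_noise_sd=0.0)
        curve = fm.simulate_force_curve(cfg)
        assert np.max(np.abs(curve.deflection)) < 1e-12

    def test_seed_contract(self):
        cfg1 = fm.ForceCurveSimConfig(seed=1)
        cfg2 = fm.ForceCurveSimConfig(seed=2)
        c1, c1b, c2 = (fm.simulate_force_curve(c) for c in (cfg1, cfg1, cfg2))
        np.testing.assert_array_equal(c1.deflection, c1b.deflection)
        assert not np.array_equal(c1.deflection, c2.deflection)
        assert c1.truth["young_modulus"] == c2.truth["young_modulus"]

    def test_invalid_indentation_raises(self):
        with pytest.raises(ValueError, match="max_indentation"):
            fm.ForceCurveSimConfig(max_indentation=0.0)

    def test_force_balance_holds_past_contact(self):
        """k d = C ((z - z_c) - d)^2 at every generated sample."""
        cfg = fm.ForceCurveSimConfig(deflection_noise_sd=0.0)
        curve = fm.simulate_force_curve(cfg)
        from fibromech.mechanics import pyramid_prefactor
        C = pyramid_prefactor(cfg.young_modulus_true, cfg.poisson_ratio,
                              cfg.half_angle)
        s = curve.piezo_position - cfg.contact_offset
        past = s > 0
        lhs = cfg.spring_constant * curve.deflection[past]
        rhs = C * (s[past] - curve.deflection[past]) ** 2
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9)


class TestSimulateMovie:
    def test_filament_decay_ordering(self):
        """Filament ROI decays slower than the cytosol ROI."""
        cfg = fm.TraceSimConfig(amplitude=0.6, tau_decay=5.0, noise_sd=0.0)
        mask = np.zeros((20, 20), bool)
        mask[2:18, 2:18] = True
        filament = np.zeros((20, 20), bool)
        filament[5:7, 5:15] = True
        stack = fm.simulate_movie(mask, cfg, [filament], filament_tau_decay=50.0)
        cytosol = mask & ~filament
        tr_fil = fm.extract_roi_trace(stack, filament, ~mask)
        tr_cyt = fm.extract_roi_trace(stack, cytosol, ~mask)
        tau_fil = analyze_trace(tr_fil).tau_s
        tau_cyt = analyze_trace(tr_cyt).tau_s
        assert tau_fil > tau_cyt

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            fm.simulate_movie(np.zeros((8, 8), bool), fm.TraceSimConfig())

    def test_filament_outside_cell_raises(self):
        mask = np.zeros((8, 8), bool)
        mask[:4] = True
        fil = np.zeros((8, 8), bool)
        fil[6, 6] = True
        with pytest.raises(ValueError, match="inside"):
            fm.simulate_movie(mask, fm.TraceSimConfig(), [fil])

    def test_shape_mismatch_raises(self):
        mask = np.ones((8, 8), bool)
        fil = np.zeros((4, 4), bool)
        with pytest.raises(ValueError, match="shape"):
            fm.simulate_movie(mask, fm.TraceSimConfig(), [fil])
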