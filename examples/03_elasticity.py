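"""Estimate cell stiffness from simulated AFM approach curves.

Simulates force-distance curves on cells of known Young's modulus, detects
the contact point, converts to force-indentation, and fits the
Hertz-Sneddon quadrilateral-pyramid model over the first 200 nm of
indentation.  The thin-sample validity conditions are checked against the
typical geometry (cell height ~2 um, tip radius ~20 nm).
"""

import fibromech as fm

for e_true_kpa in (5.0, 20.0):
    curve = fm.simulate_force_curve(fm.ForceCurveSimConfig(
        young_modulus_true=e_true_kpa * 1e3, seed=3))
    fit = fm.fit_force_curve(curve, cell_height=2e-6, probe_radius=20e-9)
    ok_depth, ok_height = fit.valid_thin_sample
    print(f"true E = {e_true_kpa:5.1f} kPa -> fitted E = "
          f"{fit.young_modulus / 1e3:5.2f} kPa "
          f"(contact at {fit.contact_point * 1e6:.3f} um, "
          f"{fit.n_points_fit} pts <= 200 nm)")
    print(f"  semi-infinite-sample checks: depth<=0.1h: {ok_depth}, "
          f"h>=12.8R: {ok_height}")
# The fit uses only shallow indentation (<= 200 nm, under 10% of cell
# height), where the semi-infinite Hertz-Sneddon assumption holds.
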