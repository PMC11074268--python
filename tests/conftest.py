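import numpy as np
import pytest

import fibromech as fm

STUDY_FORCES = np.array([150.0, 200.0, 250.0, 300.0, 350.0])
F_HALF = 300.0
SLOPE = 85.77


@pytest.fixture(scope="session")
def study_forces():
    return STUDY_FORCES.copy()


@pytest.fixture(scope="session")
def exact_fractions():
    """Responder fractions generated exactly from the Boltzmann model."""
    return fm.boltzmann_pa(STUDY_FORCES, F_HALF, SLOPE)


@pytest.fixture()
def noise_free_trace_cfg():
    return fm.TraceSimConfig(
        amplitude=0.5, tau_rise=1e-6, tau_decay=5.0,
        noise_sd=0.0, drift_rate=0.0, seed=0,
    )


def slope_grid_oracle(forces, fractions, f_half, lo=1.0, hi=1e4):
    """Brute-force slope search: dense log grid plus parabolic refinement.

    Independent of the package's optimizer; used to cross-check the
    1-D least-squares slope fit.
    """
    from scipy.special import expit

    def sse(b):
        r = fractions - expit((forces - f_half) / b)
        return float(r @ r)

    grid = np.geomspace(lo, hi, 20001)
    vals = np.array([sse(b) for b in grid])
    i = int(np.argmin(vals))
    # golden-section refinement on the bracketing interval
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    phi = (np.sqrt(5) - 1) / 2
    for _ in range(200):
        c = b - phi * (b - a)
        d = a + phi * (b - a)
        if sse(c) < sse(d):
            b = d
        else:
            a = c
    return 0.5 * (a + b)


def modulus_grid_oracle(delta, force, prefactor_unit, e_true, step=1.0, span=500.0):
    """Brute-force Young's-modulus grid at ``step`` Pa resolution around truth."""
    grid = np.arange(max(e_true - span, step), e_true + span, step)
    d2 = delta**2
    sse = [float(np.sum((force - e * prefactor_unit * d2) ** 2)) for e in grid]
    return float(grid[int(np.argmin(sse))])
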