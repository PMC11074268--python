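"""AFM contact mechanics: Hertz-Sneddon elasticity and bead contact pressure.

An AFM approach curve records cantilever deflection d against piezo
position z.  Past the contact point z_c the indentation is
delta = (z - z_c) - d and the force F = k d (k: spring constant).  For a
quadrilateral-pyramid indenter the Hertz-Sneddon model gives

    F = E / (1 - nu^2) * tan(theta) / sqrt(2) * delta^2

with Young's modulus E, Poisson ratio nu, and face half-opening angle
theta.  Fitting is restricted to shallow indentation (default 200 nm) so
that the semi-infinite-sample assumption holds; the thin-sample validity
conditions delta <= 0.1 h and h >= 12.8 R (cell height h, tip radius R) are
checked explicitly.

The bead contact pressure for stimulation with a spherical bead takes the
contact area as half of the bead's surface, P = F / (2 pi r^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ContactPointError, SchemaError

__all__ = [
    "ForceCurve",
    "ForceIndentation",
    "HertzFit",
    "pyramid_prefactor",
    "detect_contact_point",
    "to_force_indentation",
    "fit_hertz_pyramid",
    "fit_force_curve",
    "check_thin_sample",
    "bead_contact_pressure",
]

DEFAULT_DEPTH_LIMIT = 200e-9
DEFAULT_POISSON_RATIO = 0.5
DEFAULT_HALF_ANGLE_DEG = 17.5


@dataclass
class ForceCurve:
    """Approach segment of an AFM force-distance curve.

    ``piezo_position`` increases toward the sample (m); ``deflection`` is
    the cantilever deflection (m); ``spring_constant`` in N/m.
    """

    piezo_position: np.ndarray
    deflection: np.ndarray
    spring_constant: float
    truth: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.piezo_position = np.asarray(self.piezo_position, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.piezo_position.size != self.deflection.size:
            raise SchemaError("piezo_position and deflection must have equal length")
        if self.piezo_position.size < 50:
            raise SchemaError("force curve needs at least 50 samples")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")

    @property
    def force(self) -> np.ndarray:
        """Force F = k * deflection, in N."""
        return self.spring_constant * self.deflection


@dataclass
class ForceIndentation:
    """Force-indentation pairs past the contact point."""

    indentation: np.ndarray
    force: np.ndarray
    contact_point: float

    def __post_init__(self) -> None:
        self.indentation = np.asarray(self.indentation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.indentation.size != self.force.size:
            raise SchemaError("indentation and force must have equal length")


@dataclass
class HertzFit:
    """Young's-modulus estimate with its fit context and validity flags."""

    young_modulus: float          # Pa
    poisson_ratio: float
    half_angle_deg: float
    depth_limit: float            # m
    contact_point: float          # m (piezo coordinate)
    rms_residual: float           # N
    n_points_fit: int
    valid_thin_sample: Optional[tuple] = None
    cell_height: Optional[float] = None
    probe_radius: Optional[float] = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("young_modulus must be positive")
        if self.depth_limit <= 0:
            raise ValueError("depth_limit must be positive")


def pyramid_prefactor(young_modulus: float, poisson_ratio: float, half_angle_deg: float) -> float:
    """C in F = C * delta^2 for a four-sided pyramid indenter."""
    theta = math.radians(half_angle_deg)
    return young_modulus / (1.0 - poisson_ratio**2) * math.tan(theta) / math.sqrt(2.0)


def detect_contact_point(
    curve: ForceCurve,
    baseline_fraction: float = 0.3,
    threshold_sd: float = 5.0,
    sustain: int = 5,
) -> float:
    """Locate the piezo coordinate where deflection departs from baseline.

    The first ``baseline_fraction`` of samples defines the baseline; a
    linear drift fitted there is removed from the whole curve.  Contact is
    the first sample from which the drift-corrected deflection stays above
    ``threshold_sd`` baseline standard deviations for ``sustain``
    consecutive samples.

    Raises
    ------
    ContactPointError
        If no such departure exists (e.g. a pure-noise curve).
    """
    z = curve.piezo_position
    d = curve.deflection
    n_base = max(int(baseline_fraction * z.size), 5)
    coeff = np.polyfit(z[:n_base], d[:n_base], 1)
    corrected = d - np.polyval(coeff, z)
    sd = float(np.std(corrected[:n_base]))
    scale = max(np.max(np.abs(corrected)), 1e-30)
    thr = max(threshold_sd * sd, 1e-4 * scale)
    above = corrected > thr
    # first run of `sustain` consecutive above-threshold samples
    run = 0
    start = None
    for i in range(n_base, z.size):
        run = run + 1 if above[i] else 0
        if run >= sustain:
            start = i - sustain + 1
            break
    if start is None:
        raise ContactPointError("no sustained departure from baseline found")
    # walk back to the last sample at/below the baseline level
    j = start
    while j > 0 and corrected[j - 1] > 0:
        j -= 1
    return float(z[j])


def to_force_indentation(curve: ForceCurve, contact_point: float) -> ForceIndentation:
    """Convert the post-contact part of a curve to (indentation, force).

    delta = (z - z_c) - d and F = k d; pre-contact samples are dropped.
    """
    z = curve.piezo_position
    if contact_point >= z[-1]:
        raise ValueError("contact point at or beyond the last sample")
    sel = z > contact_point
    delta = (z[sel] - contact_point) - curve.deflection[sel]
    force = curve.spring_constant * curve.deflection[sel]
    return ForceIndentation(delta, force, float(contact_point))


def fit_hertz_pyramid(
    fi: ForceIndentation,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
    half_angle_deg: float = DEFAULT_HALF_ANGLE_DEG,
    depth_limit: float = DEFAULT_DEPTH_LIMIT,
    min_points: int = 10,
) -> HertzFit:
    """Least-squares Hertz-Sneddon pyramid fit over 0 < delta <= depth_limit.

    F = C delta^2 is linear in C, so the fit is the closed-form projection
    C = sum(F delta^2) / sum(delta^4); E follows from the pyramid
    prefactor.  A non-positive projection (possible only on pathological
    data) is clamped to a tiny positive modulus and flagged unconverged.
    """
    sel = (fi.indentation > 0) & (fi.indentation <= depth_limit)
    if int(sel.sum()) < min_points:
        raise ValueError(
            f"only {int(sel.sum())} points with 0 < delta <= {depth_limit:.3g} m; "
            f"need at least {min_points}"
        )
    delta = fi.indentation[sel]
    force = fi.force[sel]
    d2 = delta**2
    denom = float(d2 @ d2)
    c_hat = float(force @ d2) / denom
    converged = c_hat > 0
    geom = pyramid_prefactor(1.0, poisson_ratio, half_angle_deg)
    e_hat = c_hat / geom if converged else 1e-9
    resid = force - (e_hat * geom) * d2
    return HertzFit(
        young_modulus=e_hat,
        poisson_ratio=poisson_ratio,
        half_angle_deg=half_angle_deg,
        depth_limit=depth_limit,
        contact_point=fi.contact_point,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        n_points_fit=int(sel.sum()),
        converged=converged,
    )


def fit_force_curve(
    curve: ForceCurve,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
    half_angle_deg: float = DEFAULT_HALF_ANGLE_DEG,
    depth_limit: float = DEFAULT_DEPTH_LIMIT,
    cell_height: Optional[float] = None,
    probe_radius: Optional[float] = None,
    refine_contact: bool = True,
) -> HertzFit:
    """Full per-curve analysis: contact detection, joint refinement, fit.

    The baseline-statistics contact estimate cp0 is biased late on noisy
    shallow-indentation data (the crossing happens only once the force
    clears the noise floor), so it is refined by profiled least squares
    with the contact point free: for each candidate cp the piecewise model
    F = C * max((z - cp) - d, 0)^2 is fitted (closed form in C) over a
    fixed evaluation set — all samples up to one depth-limit past cp0 —
    and the SSE-minimizing cp is kept.  Candidates scan from the end of
    the baseline window up to cp0, then the best sample is refined by
    bounded 1-D minimization.  Thin-sample validity flags are attached
    when ``cell_height`` and ``probe_radius`` are given.
    """
    z = curve.piezo_position
    d = curve.deflection
    force = curve.force
    cp0 = detect_contact_point(curve)

    def fit_at(cp: float) -> HertzFit:
        fi = to_force_indentation(curve, cp)
        return fit_hertz_pyramid(
            fi, poisson_ratio=poisson_ratio, half_angle_deg=half_angle_deg,
            depth_limit=depth_limit,
        )

    if refine_contact:
        n_base = max(int(0.3 * z.size), 5)
        eval_mask = z <= cp0 + depth_limit
        z_ev, d_ev, f_ev = z[eval_mask], d[eval_mask], force[eval_mask]

        def sse(cp: float) -> float:
            delta = np.clip((z_ev - cp) - d_ev, 0.0, None)
            d2 = delta**2
            denom = float(d2 @ d2)
            if denom <= 0:
                return float(f_ev @ f_ev)
            c_hat = max(float(f_ev @ d2) / denom, 0.0)
            r = f_ev - c_hat * d2
            return float(r @ r)

        lo_idx = min(n_base, int(np.searchsorted(z, cp0)) - 1)
        candidates = z[lo_idx: int(np.searchsorted(z, cp0)) + 2]
        if candidates.size == 0:
            cp = cp0
        else:
            vals = [sse(c) for c in candidates]
            i = int(np.argmin(vals))
            lo = candidates[max(i - 1, 0)]
            hi = candidates[min(i + 1, candidates.size - 1)]
            if hi > lo:
                res = minimize_scalar(sse, bounds=(float(lo), float(hi)),
                                      method="bounded",
                                      options={"xatol": (hi - lo) * 1e-4})
                cp = float(res.x)
            else:
                cp = float(candidates[i])
    else:
        cp = cp0

    fit = fit_at(cp)
    if cell_height is not None and probe_radius is not None:
        fit.valid_thin_sample = check_thin_sample(depth_limit, cell_height, probe_radius)
        fit.cell_height = cell_height
        fit.probe_radius = probe_radius
    return fit


def check_thin_sample(depth_limit: float, cell_height: float, probe_radius: float) -> tuple:
    """Semi-infinite-sample validity: (delta <= 0.1 h, h >= 12.8 R)."""
    if depth_limit <= 0 or cell_height <= 0 or probe_radius <= 0:
        raise ValueError("all inputs must be positive")
    return (depth_limit <= 0.1 * cell_height, cell_height >= 12.8 * probe_radius)


def bead_contact_pressure(force_nn: float, bead_radius_um: float) -> float:
    """Contact pressure of a bead pressed with ``force_nn`` (nN), in kPa.

    The contact area is taken as half of the bead's surface area,
    A = 2 pi r^2, so P = F / (2 pi r^2).
    """
    if force_nn < 0:
        raise ValueError("force must be non-negative")
    if bead_radius_um <= 0:
        raise ValueError("bead radius must be positive")
    force_n = force_nn * 1e-9
    radius_m = bead_radius_um * 1e-6
    pressure_pa = force_n / (2.0 * math.pi * radius_m**2)
    return pressure_pa / 1e3
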