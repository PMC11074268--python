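"""Synthetic data generation with known ground truth.

Stands in for the microscope and the AFM: generates (i) single-cell
stimulus-evoked calcium fluorescence traces, (ii) whole populations of
cells whose response probability follows a Boltzmann function of force, and
(iii) AFM approach curves obeying the Hertz-Sneddon pyramid contact law.
Every generated object carries its ground-truth record, so all downstream
analysis stages can be validated without any experimental recording.

Trace model
-----------
The noise-free cell-ROI signal is a linearly drifting baseline plus, after
stimulus onset t0, a transient shaped as the product of an exponential rise
and an exponential decay:

    F(t) = F_b (1 + drift t) + (F_b - B_b) A (1 - e^{-(t-t0)/tau_r}) e^{-(t-t0)/tau_d}

where F_b is the baseline intensity, B_b the background level and A the
transient amplitude.  Scaling the transient by the background-corrected
baseline (F_b - B_b) makes A the peak dF/F0 the analysis stage recovers in
the noise-free, fast-rise limit.  The background channel is constant at B_b.
Additive Gaussian noise of one standard deviation applies to both channels.
Acquisition defaults mirror the imaging protocol: 120 frames at 2 frames/s,
stimulus about 10 s after recording start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._rng import substream
from .activation import boltzmann_pa
from .mechanics import ForceCurve, pyramid_prefactor
from .transients import FluorescenceTrace

__all__ = [
    "TraceSimConfig",
    "PopulationSimConfig",
    "ForceCurveSimConfig",
    "StimulationRecord",
    "simulate_trace",
    "simulate_population",
    "simulate_force_curve",
    "simulate_movie",
]


def _require(cond: bool, name: str, message: str) -> None:
    if not cond:
        raise ValueError(f"invalid {name}: {message}")


@dataclass(frozen=True)
class TraceSimConfig:
    """Parameters of one simulated fluorescence trace.

    Attributes
    ----------
    baseline_intensity : float
        Pre-stimulus cell-ROI intensity F_b (arbitrary units, > 0).
    stim_onset : float
        Stimulus time t0 in seconds (within the recording).
    amplitude : float
        Peak dF/F0 of the transient (dimensionless; 0 = no response).
    tau_rise, tau_decay : float
        Rise and decay time constants in seconds.
    drift_rate : float
        Fractional baseline change per second (photobleaching-like drift).
    noise_sd : float
        Gaussian noise standard deviation (intensity units, both
        channels).  The default keeps noise-only dF/F0 excursions below
        the 0.01 mechanical responder threshold, matching the negligible
        background fluctuation of the imaging protocol.
    frame_rate : float
        Frames per second (default 2).
    n_frames : int
        Number of frames (default 120, i.e. 60 s at 2 FPS).
    background_level : float
        Background-ROI intensity B_b.
    seed : int
        Substream seed for the noise.
    """

    baseline_intensity: float = 100.0
    stim_onset: float = 10.0
    amplitude: float = 0.5
    tau_rise: float = 0.25
    tau_decay: float = 8.0
    drift_rate: float = 0.0
    noise_sd: float = 0.15
    frame_rate: float = 2.0
    n_frames: int = 120
    background_level: float = 10.0
    modality: str = "AFM"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.baseline_intensity > 0, "baseline_intensity", "must be > 0")
        _require(self.tau_rise > 0, "tau_rise", "must be > 0")
        _require(self.tau_decay > 0, "tau_decay", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.frame_rate > 0, "frame_rate", "must be > 0")
        _require(self.n_frames >= 5, "n_frames", "must be >= 5")
        _require(self.amplitude >= 0, "amplitude", "must be >= 0")
        _require(
            0 <= self.stim_onset < self.n_frames / self.frame_rate,
            "stim_onset", "must lie within the recording",
        )
        _require(
            0 <= self.background_level < self.baseline_intensity,
            "background_level", "must be >= 0 and below baseline_intensity",
        )


def _clean_cell_signal(cfg: TraceSimConfig, t: np.ndarray) -> np.ndarray:
    base = cfg.baseline_intensity * (1.0 + cfg.drift_rate * t)
    s = t - cfg.stim_onset
    with np.errstate(over="ignore"):
        shape = np.where(
            s >= 0,
            (1.0 - np.exp(-np.maximum(s, 0) / cfg.tau_rise))
            * np.exp(-np.maximum(s, 0) / cfg.tau_decay),
            0.0,
        )
    transient = (cfg.baseline_intensity - cfg.background_level) * cfg.amplitude * shape
    return base + transient


def _simulate_trace_arrays(
    cfg: TraceSimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.arange(cfg.n_frames) / cfg.frame_rate
    cell = _clean_cell_signal(cfg, t)
    background = np.full(cfg.n_frames, cfg.background_level)
    if cfg.noise_sd > 0:
        cell = cell + rng.normal(0.0, cfg.noise_sd, cfg.n_frames)
        background = background + rng.normal(0.0, cfg.noise_sd, cfg.n_frames)
    return t, np.clip(cell, 0.0, None), background


def simulate_trace(cfg: TraceSimConfig) -> FluorescenceTrace:
    """Generate one stimulated-cell trace with its ground truth attached."""
    rng = substream(cfg.seed, "trace")
    t, cell, background = _simulate_trace_arrays(cfg, rng)
    truth = {
        "amplitude": cfg.amplitude,
        "tau_rise": cfg.tau_rise,
        "tau_decay": cfg.tau_decay,
        "stim_onset": cfg.stim_onset,
        "drift_rate": cfg.drift_rate,
        "noise_sd": cfg.noise_sd,
    }
    return FluorescenceTrace(
        time=t,
        cell_signal=cell,
        background_signal=background,
        modality=cfg.modality,
        stim_time=cfg.stim_onset,
        truth=truth,
    )


@dataclass(frozen=True)
class PopulationSimConfig:
    """Population design: cells stimulated over a range of forces.

    Each of ``n_per_force`` cells at force F responds with Boltzmann
    probability PA(F; f_half_true, slope_true).  Responders draw their
    class ("generalized" with a share interpolated linearly between
    ``gen_share_low`` at the lowest force and ``gen_share_high`` at the
    highest), a decay constant consistent with the class (decay time above
    or below 10 s), and a peak amplitude whose mean grows linearly with
    force with lognormal scatter.  Non-responders have zero transient
    amplitude, so only noise crosses the detection threshold.
    """

    forces: Sequence[float] = (150.0, 200.0, 250.0, 300.0, 350.0)
    n_per_force: int = 105
    f_half_true: float = 300.0
    slope_true: float = 85.77
    gen_share_low: float = 0.66
    gen_share_high: float = 0.82
    amplitude_intercept: float = 0.15
    amplitude_slope: float = 0.002     # mean peak dF/F0 increase per nN
    amplitude_noise: float = 0.3       # lognormal sigma
    tau_decay_generalized: tuple = (18.0, 40.0)
    tau_decay_transitory: tuple = (1.5, 6.0)
    trace: TraceSimConfig = field(default_factory=TraceSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(len(self.forces) > 0, "forces", "must be non-empty")
        _require(all(f > 0 for f in self.forces), "forces", "must be positive")
        _require(self.n_per_force >= 1, "n_per_force", "must be >= 1")
        _require(self.slope_true > 0, "slope_true", "must be > 0")
        _require(
            0 <= self.gen_share_low <= self.gen_share_high <= 1,
            "gen_share", "need 0 <= low <= high <= 1",
        )
        _require(self.amplitude_noise >= 0, "amplitude_noise", "must be >= 0")

    def generalized_share_at(self, force: float) -> float:
        """Linear interpolation of the generalized share across the force range."""
        lo, hi = min(self.forces), max(self.forces)
        if hi == lo:
            return 0.5 * (self.gen_share_low + self.gen_share_high)
        frac = (force - lo) / (hi - lo)
        return self.gen_share_low + frac * (self.gen_share_high - self.gen_share_low)

    def mean_amplitude_at(self, force: float) -> float:
        return self.amplitude_intercept + self.amplitude_slope * force


@dataclass(frozen=True)
class StimulationRecord:
    """Ground truth for one simulated stimulated cell."""

    cell_id: str
    force_nN: float
    modality: str
    responder_true: bool
    class_true: str
    amplitude_true: float
    tau_decay_true: float


def simulate_population(
    cfg: PopulationSimConfig,
) -> list[tuple[StimulationRecord, FluorescenceTrace]]:
    """Simulate the full stimulation campaign across forces.

    Each force level uses its own named random substream, so changing the
    number of cells at one force leaves all other forces' draws unchanged.
    """
    out: list[tuple[StimulationRecord, FluorescenceTrace]] = []
    for i_force, force in enumerate(cfg.forces):
        pa = boltzmann_pa(force, cfg.f_half_true, cfg.slope_true)
        gen_share = cfg.generalized_share_at(force)
        rng = substream(cfg.seed, "population", i_force)
        for i_cell in range(cfg.n_per_force):
            responds = bool(rng.random() < pa)
            if responds:
                is_gen = bool(rng.random() < gen_share)
                tau_rng = (
                    cfg.tau_decay_generalized if is_gen else cfg.tau_decay_transitory
                )
                tau_decay = float(rng.uniform(*tau_rng))
                amp = cfg.mean_amplitude_at(force)
                if cfg.amplitude_noise > 0:
                    sigma = cfg.amplitude_noise
                    amp *= float(
                        rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
                    )
                cls = "generalized" if is_gen else "transitory"
            else:
                amp = 0.0
                tau_decay = cfg.trace.tau_decay
                cls = "none"
            trace_cfg = replace(
                cfg.trace, amplitude=amp, tau_decay=tau_decay,
                seed=cfg.trace.seed,
            )
            t, cell, background = _simulate_trace_arrays(trace_cfg, rng)
            record = StimulationRecord(
                cell_id=f"F{int(round(force))}_c{i_cell:04d}",
                force_nN=float(force),
                modality=cfg.trace.modality,
                responder_true=responds,
                class_true=cls,
                amplitude_true=amp,
                tau_decay_true=tau_decay,
            )
            trace = FluorescenceTrace(
                time=t, cell_signal=cell, background_signal=background,
                modality=cfg.trace.modality, stim_time=cfg.trace.stim_onset,
                truth={
                    "responder": responds, "class": cls, "amplitude": amp,
                    "tau_decay": tau_decay, "force_nN": float(force),
                },
            )
            out.append((record, trace))
    return out


@dataclass(frozen=True)
class ForceCurveSimConfig:
    """Parameters of a simulated AFM approach curve on a soft sample.

    The cantilever base advances linearly (piezo position z, increasing
    toward the cell).  Before ``contact_offset`` the deflection is zero
    plus noise; past contact the deflection solves the force balance
    k d = C ((z - z_c) - d)^2 with the pyramid prefactor
    C = E/(1-nu^2) tan(theta)/sqrt(2).
    """

    young_modulus_true: float = 20e3     # Pa; stiff-substrate cells are ~20 kPa
    poisson_ratio: float = 0.5
    half_angle: float = 17.5             # degrees
    spring_constant: float = 0.1         # N/m
    contact_offset: float = 2e-6         # m
    max_indentation: float = 0.5e-6      # m
    deflection_noise_sd: float = 0.3e-9  # m
    n_points: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.young_modulus_true > 0, "young_modulus_true", "must be > 0")
        _require(
            0 <= self.poisson_ratio <= 0.5,
            "poisson_ratio", "must be in [0, 0.5]",
        )
        _require(self.spring_constant > 0, "spring_constant", "must be > 0")
        _require(self.max_indentation > 0, "max_indentation", "must be > 0")
        _require(self.deflection_noise_sd >= 0, "deflection_noise_sd", "must be >= 0")
        _require(self.n_points >= 50, "n_points", "must be >= 50")
        _require(self.contact_offset > 0, "contact_offset", "must be > 0")
        _require(0 < self.half_angle < 90, "half_angle", "must be in (0, 90) degrees")


def simulate_force_curve(cfg: ForceCurveSimConfig) -> ForceCurve:
    """Generate one approach curve with ground-truth modulus attached."""
    rng = substream(cfg.seed, "force_curve")
    C = pyramid_prefactor(cfg.young_modulus_true, cfg.poisson_ratio, cfg.half_angle)
    k = cfg.spring_constant
    d_max = C * cfg.max_indentation**2 / k
    z_end = cfg.contact_offset + cfg.max_indentation + d_max
    z = np.linspace(0.0, z_end, cfg.n_points)
    s = z - cfg.contact_offset
    deflection = np.zeros_like(z)
    past = s > 0
    sp = s[past]
    # solve C (s - d)^2 = k d for d; cancellation-free form of the smaller root
    deflection[past] = (2 * C * sp**2) / (
        (2 * C * sp + k) + np.sqrt(k**2 + 4 * C * sp * k)
    )
    if cfg.deflection_noise_sd > 0:
        deflection = deflection + rng.normal(0.0, cfg.deflection_noise_sd, z.size)
    truth = {
        "young_modulus": cfg.young_modulus_true,
        "poisson_ratio": cfg.poisson_ratio,
        "half_angle": cfg.half_angle,
        "contact_offset": cfg.contact_offset,
        "max_indentation": cfg.max_indentation,
        "deflection_noise_sd": cfg.deflection_noise_sd,
    }
    return ForceCurve(
        piezo_position=z, deflection=deflection,
        spring_constant=k, truth=truth,
    )


def simulate_movie(
    mask: np.ndarray,
    cfg: TraceSimConfig,
    filament_masks: Optional[Sequence[np.ndarray]] = None,
    filament_tau_decay: float = 50.0,
) -> np.ndarray:
    """Render the trace model as a per-pixel image stack.

    Pixels inside ``mask`` follow the cell-signal model; pixels outside
    follow the background level; optional ``filament_masks`` (inside the
    cell mask, mutually non-overlapping) use a slower decay constant,
    emulating slow-releasing filamentous compartments.  Per-pixel Gaussian
    noise is added everywhere.  With zero noise, the mean over ``mask``
    equals the output of :func:`simulate_trace` for the same config.

    Returns a float array of shape (n_frames, rows, cols), writable as a
    multi-page TIFF with ``tifffile.imwrite``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D image")
    if not mask.any():
        raise ValueError("mask is empty")
    combined_filament = np.zeros_like(mask)
    if filament_masks:
        for fm in filament_masks:
            fm = np.asarray(fm, dtype=bool)
            if fm.shape != mask.shape:
                raise ValueError("filament mask shape must match cell mask shape")
            if np.any(fm & ~mask):
                raise ValueError("filament masks must lie inside the cell mask")
            if np.any(fm & combined_filament):
                raise ValueError("filament masks must not overlap")
            combined_filament |= fm
    rng = substream(cfg.seed, "movie")
    t = np.arange(cfg.n_frames) / cfg.frame_rate
    cell_trace = _clean_cell_signal(cfg, t)
    filament_trace = _clean_cell_signal(
        replace(cfg, tau_decay=filament_tau_decay), t
    )
    stack = np.full((cfg.n_frames, *mask.shape), cfg.background_level)
    cytosol = mask & ~combined_filament
    stack[:, cytosol] = cell_trace[:, None]
    if combined_filament.any():
        stack[:, combined_filament] = filament_trace[:, None]
    if cfg.noise_sd > 0:
        stack = stack + rng.normal(0.0, cfg.noise_sd, stack.shape)
    return np.clip(stack, 0.0, None)
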