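"""Per-cell calcium-transient analysis.

Turns a raw paired-ROI fluorescence recording (cell ROI mean intensity F and
background ROI mean intensity B over time) into the derived quantities used
throughout the study of fibroblast mechanosensitivity:

* the background-corrected fractional fluorescence change
  ``dF/(F0 - B0) = ((F - B) - (F0 - B0)) / (F0 - B0)``, where F0 and B0 are
  the mean signals over the first ``n_baseline`` (default 4) frames;
* a responder call (peak dF/F0 strictly above a modality-dependent
  threshold: 0.01 for mechanical stimulation, 0.1 for chemical agonist,
  where background fluctuations are larger);
* the decay time tau — the time after the peak at which dF/F0 first falls
  to one third of its maximum;
* the response class: "generalized" (tau >= 10 s, or never decaying within
  the recording) versus "transitory" (tau < 10 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .errors import DegenerateBaselineError, SchemaError, UndefinedDecayError

__all__ = [
    "FluorescenceTrace",
    "DffTrace",
    "DecayResult",
    "TransientMetrics",
    "MECHANICAL_THRESHOLD",
    "CHEMICAL_THRESHOLD",
    "default_threshold",
    "compute_dff",
    "detect_response",
    "decay_time",
    "classify_response",
    "analyze_trace",
    "extract_roi_trace",
]

#: Peak dF/F0 a mechanically stimulated cell must strictly exceed to count
#: as a responder.
MECHANICAL_THRESHOLD = 0.01
#: Threshold for chemical (agonist) stimulation, where background
#: fluorescence fluctuations are no longer negligible.
CHEMICAL_THRESHOLD = 0.1

_MECHANICAL_MODALITIES = frozenset({"OT", "AFM"})
_MODALITIES = _MECHANICAL_MODALITIES | {"chemical"}


def default_threshold(modality: str) -> float:
    """Responder threshold on peak dF/F0 for a stimulation modality."""
    if modality in _MECHANICAL_MODALITIES:
        return MECHANICAL_THRESHOLD
    if modality == "chemical":
        return CHEMICAL_THRESHOLD
    raise ValueError(f"unknown modality {modality!r}; expected one of {sorted(_MODALITIES)}")


@dataclass
class FluorescenceTrace:
    """Paired cell/background ROI intensity series for one stimulated cell.

    Attributes
    ----------
    time : array of float
        Acquisition times in seconds, strictly increasing.
    cell_signal : array of float
        Mean fluorescence intensity F over the cell ROI (arbitrary units,
        non-negative).
    background_signal : array of float
        Mean intensity B over the background ROI.
    modality : str
        Stimulation modality: "OT", "AFM" or "chemical".
    stim_time : float, optional
        Stimulus onset in seconds, if known.
    truth : dict, optional
        Ground-truth record attached by the synthetic generator.
    """

    time: np.ndarray
    cell_signal: np.ndarray
    background_signal: np.ndarray
    modality: str = "AFM"
    stim_time: Optional[float] = None
    truth: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.cell_signal = np.asarray(self.cell_signal, dtype=float)
        self.background_signal = np.asarray(self.background_signal, dtype=float)
        n = self.time.size
        if self.cell_signal.size != n or self.background_signal.size != n:
            raise SchemaError("time, cell_signal and background_signal must have equal length")
        if n < 5:
            raise SchemaError(f"trace has {n} frames; at least 5 required (4 baseline + data)")
        if np.any(np.diff(self.time) <= 0):
            raise SchemaError("time must be strictly increasing")
        if np.any(self.cell_signal < 0):
            raise SchemaError("cell_signal must be non-negative")
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class DffTrace:
    """Background-corrected dF/F0 series with its baseline statistics."""

    time: np.ndarray
    dff: np.ndarray
    baseline_f0: float
    baseline_b0: float
    n_baseline: int = 4
    stim_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if not np.all(np.isfinite(self.dff)):
            raise SchemaError("dff contains non-finite values")
        if self.baseline_f0 - self.baseline_b0 <= 0:
            raise DegenerateBaselineError("baseline F0 - B0 must be positive")


class DecayResult(NamedTuple):
    """Decay time in seconds; ``censored`` marks traces that never reach
    peak/decay_factor within the recording (tau is then a lower bound)."""

    tau_s: float
    censored: bool


@dataclass
class TransientMetrics:
    """Per-cell summary of one stimulated recording."""

    dff_max: float
    t_peak: float
    responder: bool
    tau_s: float
    censored: bool
    response_class: str

    def __post_init__(self) -> None:
        if self.response_class not in ("generalized", "transitory", "none"):
            raise ValueError(f"invalid response_class {self.response_class!r}")
        if not self.responder and self.response_class != "none":
            raise ValueError("non-responder must have response_class 'none'")


def compute_dff(
    trace: FluorescenceTrace,
    n_baseline: int = 4,
    neglect_background: bool = False,
) -> DffTrace:
    """Background-corrected fractional fluorescence change.

    ``dff[t] = ((F[t] - B[t]) - (F0 - B0)) / (F0 - B0)`` with F0, B0 the
    means of the first ``n_baseline`` frames.  With ``neglect_background``
    the background channel is treated as identically zero before applying
    the formula (appropriate for mechanical stimulation, where background
    fluctuation is negligible).
    """
    if len(trace) <= n_baseline:
        raise SchemaError(
            f"trace has {len(trace)} frames; need more than n_baseline={n_baseline}"
        )
    F = trace.cell_signal
    B = np.zeros_like(F) if neglect_background else trace.background_signal
    f0 = float(np.mean(F[:n_baseline]))
    b0 = float(np.mean(B[:n_baseline]))
    denom = f0 - b0
    if denom <= 0:
        raise DegenerateBaselineError(
            f"baseline F0 - B0 = {denom:.6g} <= 0; dF/F0 undefined"
        )
    dff = ((F - B) - denom) / denom
    return DffTrace(
        time=trace.time,
        dff=dff,
        baseline_f0=f0,
        baseline_b0=b0,
        n_baseline=n_baseline,
        stim_time=trace.stim_time,
    )


def _post_stimulus_slice(dff: DffTrace) -> slice:
    # Peak search window: from the stimulus time when known, otherwise from
    # the first frame after the baseline window.
    if dff.stim_time is not None:
        start = int(np.searchsorted(dff.time, dff.stim_time, side="left"))
    else:
        start = dff.n_baseline
    start = min(start, dff.time.size - 1)
    return slice(start, None)


def _peak(dff: DffTrace) -> tuple[float, int]:
    window = _post_stimulus_slice(dff)
    seg = dff.dff[window]
    i_rel = int(np.argmax(seg))
    i_abs = (window.start or 0) + i_rel
    return float(dff.dff[i_abs]), i_abs


def peak_dff(dff: DffTrace) -> tuple[float, float]:
    """Maximum post-stimulus dF/F0 and the time at which it occurs."""
    value, idx = _peak(dff)
    return value, float(dff.time[idx])


def detect_response(
    dff: DffTrace,
    modality: str = "AFM",
    threshold: Optional[float] = None,
) -> bool:
    """True iff the post-stimulus peak dF/F0 strictly exceeds the threshold.

    The default threshold is 0.01 for mechanical modalities (OT, AFM) and
    0.1 for chemical stimulation; pass ``threshold`` to override.
    """
    if threshold is None:
        threshold = default_threshold(modality)
    value, _ = _peak(dff)
    return bool(value > threshold)


def decay_time(dff: DffTrace, decay_factor: float = 3.0) -> DecayResult:
    """Time after the peak at which dF/F0 first falls to peak/decay_factor.

    Returns a censored result (tau equal to the remaining recording length)
    when the signal never decays that far before the recording ends.
    """
    if decay_factor <= 1:
        raise ValueError("decay_factor must exceed 1")
    peak, i_peak = _peak(dff)
    if peak <= 0:
        raise UndefinedDecayError("decay time undefined for a non-positive peak")
    target = peak / decay_factor
    after = dff.dff[i_peak + 1 :]
    below = np.nonzero(after <= target)[0]
    t_peak = dff.time[i_peak]
    if below.size == 0:
        return DecayResult(float(dff.time[-1] - t_peak), True)
    return DecayResult(float(dff.time[i_peak + 1 + below[0]] - t_peak), False)


def classify_response(
    responder: bool,
    tau_s: float,
    censored: bool = False,
    tau_boundary: float = 10.0,
) -> str:
    """Assign the response class from the responder call and decay time.

    Non-responders are "none".  A responder whose decay time is at least
    ``tau_boundary`` (default 10 s) — or whose decay is censored by the end
    of the recording — is "generalized"; a faster decay is "transitory".
    The boundary itself is assigned to "generalized", grouping slow and
    censored decays together.
    """
    if not responder:
        return "none"
    if censored or tau_s >= tau_boundary:
        return "generalized"
    return "transitory"


def _median3(x: np.ndarray) -> np.ndarray:
    """3-point running median with edge replication."""
    padded = np.concatenate([x[:1], x, x[-1:]])
    stacked = np.stack([padded[:-2], padded[1:-1], padded[2:]])
    return np.median(stacked, axis=0)


def analyze_trace(
    trace: FluorescenceTrace,
    n_baseline: int = 4,
    threshold: Optional[float] = None,
    decay_factor: float = 3.0,
    tau_boundary: float = 10.0,
    neglect_background: bool = False,
    median_filter: bool = False,
) -> TransientMetrics:
    """Full per-cell analysis: dF/F0 -> responder -> decay time -> class.

    ``median_filter`` applies an optional 3-frame running median to the
    dF/F0 series before the peak/decay measurements.  It is off by default
    (metrics are reported on the raw dF/F0); enabling it makes the
    first-crossing decay time robust to single-frame noise excursions.
    """
    dff = compute_dff(trace, n_baseline=n_baseline, neglect_background=neglect_background)
    if median_filter:
        dff = DffTrace(
            time=dff.time,
            dff=_median3(dff.dff),
            baseline_f0=dff.baseline_f0,
            baseline_b0=dff.baseline_b0,
            n_baseline=dff.n_baseline,
            stim_time=dff.stim_time,
        )
    peak, t_peak = peak_dff(dff)
    responder = detect_response(dff, modality=trace.modality, threshold=threshold)
    if responder:
        tau = decay_time(dff, decay_factor=decay_factor)
        cls = classify_response(True, tau.tau_s, tau.censored, tau_boundary)
        return TransientMetrics(peak, t_peak, True, tau.tau_s, tau.censored, cls)
    return TransientMetrics(peak, t_peak, False, float("nan"), False, "none")


def extract_roi_trace(
    stack: np.ndarray,
    cell_mask: np.ndarray,
    background_mask: np.ndarray,
    frame_rate: float = 2.0,
    modality: str = "AFM",
    stim_time: Optional[float] = None,
) -> FluorescenceTrace:
    """Mean-intensity trace of a (frames, rows, cols) stack over two ROIs.

    The two masks must be non-empty and disjoint.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise SchemaError("stack must be a 3-D (frames, rows, cols) array")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if cell_mask.shape != stack.shape[1:] or background_mask.shape != stack.shape[1:]:
        raise SchemaError("mask shape must match the frame shape")
    if not cell_mask.any():
        raise SchemaError("cell_mask is empty")
    if not background_mask.any():
        raise SchemaError("background_mask is empty")
    if np.any(cell_mask & background_mask):
        raise SchemaError("cell and background ROIs overlap")
    time = np.arange(stack.shape[0]) / frame_rate
    cell = stack[:, cell_mask].mean(axis=1)
    background = stack[:, background_mask].mean(axis=1)
    return FluorescenceTrace(
        time=time,
        cell_signal=cell,
        background_signal=background,
        modality=modality,
        stim_time=stim_time,
    )
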