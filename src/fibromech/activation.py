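"""Population-level channel-activation analysis.

Aggregates per-cell responder calls into per-force response fractions and
fits the two-state Boltzmann gating model

    PA(F) = 1 / (1 + exp[-(F - F0) / B])

where F0 is the half-activation force (PA(F0) = 50%) and B > 0 the slope
factor, both in nN.  The fit minimizes the sum of squared deviations of the
observed responder *fractions* (not percentages) from PA(F); a binomial
maximum-likelihood alternative is provided.  F0 may be fixed from the data
(the study fixes F0 = 300 nN, where the observed activation is ~50%) or fit
freely.

Also houses the small auxiliary statistics used alongside the activation
analysis: the generalized-response share among responders, relative qPCR
expression 2^-(dCq), the percentage of marker-positive cells, and the
ellipse approximation of spread cell area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import expit, xlog1py, xlogy

from .errors import NonIdentifiableWarning
from ._rng import substream

__all__ = [
    "PopulationResponse",
    "BoltzmannFit",
    "boltzmann_pa",
    "fit_activation",
    "predict_activation",
    "bootstrap_activation",
    "generalized_share",
    "qpcr_expression",
    "positive_fraction",
    "ellipse_area",
]

_SLOPE_BOUNDS = (1e-2, 1e6)


def boltzmann_pa(
    force: Union[float, np.ndarray],
    f_half: float,
    slope: float,
) -> Union[float, np.ndarray]:
    """Two-state Boltzmann activation probability PA(F).

    Strictly increasing in force, with PA(f_half) = 0.5 and point symmetry
    PA(f_half + x) + PA(f_half - x) = 1.

    Parameters
    ----------
    force : float or array
        Applied force in nN.
    f_half : float
        Half-activation force F0 in nN.
    slope : float
        Slope factor B in nN; must be positive.
    """
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    out = expit((np.asarray(force, dtype=float) - f_half) / slope)
    return float(out) if np.isscalar(force) or np.ndim(force) == 0 else out


@dataclass
class PopulationResponse:
    """Responder/class counts per force level, pooled over cultures."""

    forces: np.ndarray
    n_total: np.ndarray
    n_responding: np.ndarray
    n_generalized: np.ndarray
    n_transitory: np.ndarray

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        self.n_total = np.asarray(self.n_total, dtype=int)
        self.n_responding = np.asarray(self.n_responding, dtype=int)
        self.n_generalized = np.asarray(self.n_generalized, dtype=int)
        self.n_transitory = np.asarray(self.n_transitory, dtype=int)
        n = self.forces.size
        if n == 0:
            raise ValueError("at least one force level required")
        for name in ("n_total", "n_responding", "n_generalized", "n_transitory"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length must match forces")
        if np.unique(self.forces).size != n:
            raise ValueError("forces must be distinct")
        if np.any(self.n_generalized + self.n_transitory != self.n_responding):
            raise ValueError("n_generalized + n_transitory must equal n_responding")
        if np.any(self.n_responding > self.n_total):
            raise ValueError("n_responding cannot exceed n_total")
        order = np.argsort(self.forces)
        for name in ("forces", "n_total", "n_responding", "n_generalized", "n_transitory"):
            setattr(self, name, getattr(self, name)[order])

    @property
    def fractions(self) -> np.ndarray:
        """Observed responder fraction per force."""
        return self.n_responding / self.n_total

    @classmethod
    def from_metrics(cls, table) -> "PopulationResponse":
        """Build counts from a per-cell metrics table.

        ``table`` is a pandas DataFrame with columns ``force_nN``,
        ``responder`` and ``response_class``.
        """
        grouped = table.groupby("force_nN", sort=True)
        forces, tot, resp, gen, tra = [], [], [], [], []
        for force, grp in grouped:
            forces.append(force)
            tot.append(len(grp))
            resp.append(int(grp["responder"].sum()))
            gen.append(int((grp["response_class"] == "generalized").sum()))
            tra.append(int((grp["response_class"] == "transitory").sum()))
        return cls(np.array(forces), np.array(tot), np.array(resp),
                   np.array(gen), np.array(tra))


@dataclass
class BoltzmannFit:
    """Fitted Boltzmann activation model with diagnostics.

    ``sse`` and ``r_squared`` are computed on the fraction scale.  R^2 can
    be negative for fits worse than the flat mean; it is reported as-is.
    ``non_identifiable`` flags degenerate data (flat fractions push the
    slope to its bound; all-0/all-1 data leave F0 unconstrained).
    """

    f_half: float
    slope: float
    f_half_fixed: bool
    sse: float
    r_squared: float
    method: str = "ls"
    log_likelihood: Optional[float] = None
    non_identifiable: bool = False
    force_range: tuple = (float("nan"), float("nan"))
    n_points: int = 0
    slope_ci: Optional[tuple] = field(default=None)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("fitted slope must be positive")


def _sse(pa_obs: np.ndarray, forces: np.ndarray, f_half: float, slope: float) -> float:
    r = pa_obs - expit((forces - f_half) / slope)
    return float(r @ r)


def _fit_slope_fixed_fhalf(
    forces: np.ndarray, pa_obs: np.ndarray, f_half: float,
    objective,
) -> tuple[float, bool]:
    """1-D slope optimization: coarse log-grid presearch, then bounded
    refinement on the bracketing interval."""
    lo, hi = _SLOPE_BOUNDS
    grid = np.geomspace(lo, hi, 64)
    vals = [objective(b) for b in grid]
    i = int(np.argmin(vals))
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        objective, bounds=(b_lo, b_hi), method="bounded",
        options={"xatol": 1e-10 * max(1.0, grid[i])},
    )
    slope = float(res.x)
    non_ident = slope >= 0.95 * hi
    return slope, non_ident


def fit_activation(
    data,
    f_half: Optional[float] = 300.0,
    method: str = "ls",
) -> BoltzmannFit:
    """Fit PA(F) = 1/(1+exp[-(F-F0)/B]) to per-force responder fractions.

    Parameters
    ----------
    data : PopulationResponse or (forces, fractions) pair
        Per-force counts, or raw arrays of forces (nN) and observed
        responder fractions in [0, 1].  The "mle" method needs counts and
        therefore a PopulationResponse.
    f_half : float or None
        Fix F0 at this value (nN); ``None`` fits F0 freely (requires >= 3
        distinct forces).
    method : {"ls", "mle"}
        "ls" minimizes the sum of squared fraction residuals (equal weight
        per force level); "mle" maximizes the binomial likelihood and
        additionally reports the log-likelihood.

    Returns
    -------
    BoltzmannFit
    """
    if isinstance(data, PopulationResponse):
        forces = data.forces
        pa_obs = data.fractions
        n_total = data.n_total
        n_resp = data.n_responding
    else:
        forces, pa_obs = data
        forces = np.asarray(forces, dtype=float)
        pa_obs = np.asarray(pa_obs, dtype=float)
        if forces.size != pa_obs.size:
            raise ValueError("forces and fractions must have equal length")
        if np.any((pa_obs < 0) | (pa_obs > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if method == "mle":
            raise ValueError("method='mle' requires a PopulationResponse with counts")
        n_total = np.ones_like(pa_obs)
        n_resp = pa_obs
    if method not in ("ls", "mle"):
        raise ValueError(f"unknown method {method!r}")
    n_free = 1 if f_half is not None else 2
    if forces.size < n_free + 1:
        raise ValueError(
            f"need at least {n_free + 1} distinct forces for {n_free} free parameter(s)"
        )

    def nll(f0: float, b: float) -> float:
        p = expit((forces - f0) / b)
        ll = xlogy(n_resp, p) + xlog1py(n_total - n_resp, -p)
        return -float(np.sum(ll))

    non_ident = False
    if f_half is not None:
        if method == "ls":
            obj = lambda b: _sse(pa_obs, forces, f_half, b)
        else:
            obj = lambda b: nll(f_half, b)
        slope, non_ident = _fit_slope_fixed_fhalf(forces, pa_obs, f_half, obj)
        f0_hat = float(f_half)
    else:
        if np.all(n_resp == 0) or np.all(n_resp == n_total):
            warnings.warn(
                "all-or-none response data: F0 is not identifiable; "
                "returning a boundary result",
                NonIdentifiableWarning,
            )
            f0_hat = float(forces.max() if np.all(n_resp == 0) else forces.min())
            slope = _SLOPE_BOUNDS[0]
            non_ident = True
        else:
            span = forces.max() - forces.min()
            f0_init = float(np.interp(0.5, pa_obs, forces)) if np.any(
                np.diff(pa_obs) > 0
            ) else float(np.median(forces))
            lb = [forces.min() - 10 * span, math.log(_SLOPE_BOUNDS[0])]
            ub = [forces.max() + 10 * span, math.log(_SLOPE_BOUNDS[1])]
            best = None
            for b0 in (10.0, 100.0, 1000.0):
                if method == "ls":
                    def resid(x):
                        return pa_obs - expit((forces - x[0]) / math.exp(x[1]))
                else:
                    def resid(x):
                        # least_squares on sqrt of per-point NLL shares the optimum
                        p = expit((forces - x[0]) / math.exp(x[1]))
                        ll = xlogy(n_resp, p) + xlog1py(n_total - n_resp, -p)
                        return np.sqrt(np.maximum(-ll, 0.0) + 1e-12)
                sol = least_squares(
                    resid, x0=[f0_init, math.log(b0)], bounds=(lb, ub),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
                if best is None or sol.cost < best.cost:
                    best = sol
            f0_hat = float(best.x[0])
            slope = float(math.exp(best.x[1]))
            non_ident = slope >= 0.95 * _SLOPE_BOUNDS[1]
        if non_ident and slope < _SLOPE_BOUNDS[0]:
            slope = _SLOPE_BOUNDS[0]

    sse = _sse(pa_obs, forces, f0_hat, slope)
    tss = float(np.sum((pa_obs - pa_obs.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else float("nan")
    ll = -nll(f0_hat, slope) if method == "mle" else None
    if non_ident and f_half is not None:
        warnings.warn(
            "slope hit its bound: data carry no force dependence; "
            "fit flagged non-identifiable",
            NonIdentifiableWarning,
        )
    return BoltzmannFit(
        f_half=f0_hat,
        slope=slope,
        f_half_fixed=f_half is not None,
        sse=sse,
        r_squared=r2,
        method=method,
        log_likelihood=ll,
        non_identifiable=non_ident,
        force_range=(float(forces.min()), float(forces.max())),
        n_points=int(forces.size),
    )


def predict_activation(
    fit: BoltzmannFit, forces: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the fitted PA at the requested forces.

    Returns (probabilities, extrapolated) where ``extrapolated`` flags
    forces outside the range the model was fitted on.
    """
    forces = np.asarray(forces, dtype=float)
    pa = expit((forces - fit.f_half) / fit.slope)
    lo, hi = fit.force_range
    extrapolated = (forces < lo) | (forces > hi)
    return pa, extrapolated


def bootstrap_activation(
    data: PopulationResponse,
    n_boot: int = 1000,
    seed: int = 0,
    f_half: Optional[float] = 300.0,
    method: str = "ls",
    ci_level: float = 0.95,
) -> dict:
    """Nonparametric bootstrap of the slope over cells within each force.

    Cells are resampled with replacement within each force level (binomial
    resampling of the responder counts), the model is refit on each
    resample, and a percentile confidence interval for the slope is
    returned.
    """
    rng = substream(seed, "bootstrap")
    slopes = np.empty(n_boot)
    for i in range(n_boot):
        n_resp = rng.binomial(data.n_total, data.fractions)
        n_gen = np.minimum(data.n_generalized, n_resp)
        resampled = PopulationResponse(
            data.forces, data.n_total, n_resp, n_gen, n_resp - n_gen
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonIdentifiableWarning)
            slopes[i] = fit_activation(resampled, f_half=f_half, method=method).slope
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(slopes, [alpha, 1 - alpha])
    return {
        "slopes": slopes,
        "ci": (float(lo), float(hi)),
        "ci_level": ci_level,
        "n_boot": n_boot,
    }


def generalized_share(n_generalized: int, n_transitory: int) -> float:
    """Fraction of responders whose response is generalized.

    Equal to %Generalized / (%Generalized + %Transitory): the common
    denominator of the two percentages cancels, so counts and percentages
    give the same value.  Returns NaN when there are no responders.
    """
    if n_generalized < 0 or n_transitory < 0:
        raise ValueError("counts must be non-negative")
    total = n_generalized + n_transitory
    if total == 0:
        return float("nan")
    return n_generalized / total


def qpcr_expression(cq_target: float, cq_reference: float) -> float:
    """Relative expression 2^-(dCq) with dCq = Cq_target - Cq_reference."""
    if not (math.isfinite(cq_target) and math.isfinite(cq_reference)):
        raise ValueError("Cq values must be finite")
    return 2.0 ** -(cq_target - cq_reference)


def positive_fraction(n_positive: int, n_negative: int) -> float:
    """Percentage of marker-positive cells: 100 * pos / (pos + neg)."""
    if n_positive < 0 or n_negative < 0:
        raise ValueError("counts must be non-negative")
    total = n_positive + n_negative
    if total == 0:
        raise ValueError("empty sample: no cells counted")
    return 100.0 * n_positive / total


def ellipse_area(major_axis: float, minor_axis: float) -> float:
    """Area of the ellipse approximating a spread cell, from its two axes.

    Axes are full lengths (e.g. in um); the area is pi * a/2 * b/2.
    """
    if major_axis <= 0 or minor_axis <= 0:
        raise ValueError("axes must be positive")
    return math.pi * (major_axis / 2.0) * (minor_axis / 2.0)
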