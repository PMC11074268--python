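# Methods

This note documents the models, the synthetic-data assumptions, the
numerical choices and the known limitations of `fibromech`.

## Transient model and per-cell statistics

A paired-ROI fluorescence recording is reduced to
ΔF/(F₀−B₀) = ((F−B)−(F₀−B₀))/(F₀−B₀), with F₀ and B₀ the means of the
first `n_baseline = 4` frames.  The baseline window therefore has mean
ΔF/F₀ exactly zero, and the statistic is invariant under rescaling both
channels by a common gain.  For mechanical stimulation the background can
be declared negligible (`neglect_background=True` substitutes B ≡ 0
before the formula); for chemical stimulation the background term is kept
and the responder threshold is raised from 0.01 to 0.1 because the poorly
soluble agonist itself perturbs the background.  Both thresholds are
strict inequalities on the post-stimulus peak.

The decay time τ is the first time after the peak at which ΔF/F₀ ≤
peak/3.  If the signal never decays that far before the recording ends,
τ is censored at the remaining recording length and — because a calcium
elevation still present at the end of a 60 s recording is the signature
of the sustained, cell-wide response — the cell is classified
*generalized*, exactly as for τ ≥ 10 s.  The tie at τ = 10 s is assigned
to generalized; the published class definitions (τ > 10 s vs τ < 10 s)
leave equality open, and slow/censored cases group naturally together.
The peak search starts at the stimulus time when known, otherwise at the
first frame after the baseline window.

**Smoothing.**  Metrics are computed on the raw ΔF/F₀ by default — no
filtering — because the reported per-cell quantities are raw-trace
statistics.  A 3-frame running median (`median_filter=True`) is provided
for noisy data: the first-crossing definition of τ is fragile when
per-frame noise is a non-trivial fraction of peak/3, since any single
downward noise excursion triggers an early crossing.  At peak
signal-to-noise ratio 10 (peak ΔF divided by per-frame intensity noise),
raw first-crossing classification recovers the true class on ~88% of
simulated traces, while the median-filtered estimator recovers ≥ 95%
(the robustness tests use the filter; the noise-free tests use the raw
path, where recovery is exact).  At the noise level typical of the
mean-over-ROI recordings the package emulates (SNR of order 10²) the raw
path is accurate and the filter changes nothing.

## Boltzmann activation model

Responder counts per force are modeled as binomial with
PA(F) = 1/(1+exp[−(F−F₀)/B]); F₀ is the half-activation force
(PA(F₀) = 0.5) and B > 0 the slope factor, both in nN.  The default fit
minimizes Σ(p̂ᵢ − PA(Fᵢ))² over the *fraction* scale with equal weight
per force level; a binomial maximum-likelihood mode is available when
per-force weighting is preferred.  R² = 1 − SSE/TSS about the mean
observed fraction (it may be negative for fits worse than a constant and
is reported as-is).

With F₀ fixed the problem is one-dimensional: a 64-point logarithmic
grid over B ∈ [10⁻², 10⁶] nN locates the basin and bounded minimization
on the bracketing interval refines it (relative accuracy better than
10⁻⁶ on clean data, ~0.5 ms per fit — cheap enough for dense
bootstraps).  With F₀ free, trust-region least squares on (F₀, log B)
runs from three slope initializations (10, 100, 1000 nN) and keeps the
best optimum.  Degeneracies are flagged rather than hidden: flat
fractions push B to its upper bound (`non_identifiable=True`, warning);
all-0/all-1 data leave F₀ unconstrained and return a boundary result
with a warning.

Uncertainty comes from a seeded nonparametric bootstrap: cells are
resampled with replacement within each force level (binomial resampling
of the counts), the model refit per resample (default 1000), and a
percentile interval reported.  In simulation at the study design
(5 forces × 105 cells, truth F₀ = 300 nN, B = 85.77 nN) the median
relative slope error over 200 replicates is ~8% and the 95% interval
covers the truth ~92% of the time (the test suite re-measures both with
200 bootstrap resamples per replicate to stay fast).

## Contact mechanics

Approach curves are (piezo position z, deflection d); force is F = k·d.
Past the contact point z_c the indentation is δ = (z − z_c) − d.  The
quadrilateral-pyramid Hertz–Sneddon law is used in the common
instrument-software form F = E/(1−ν²)·(tan θ/√2)·δ², with defaults
ν = 0.5 (incompressible cell) and face half-angle θ = 17.5° (typical of
the soft silicon-nitride lever family); both are configurable and
recorded in the output.  The model is linear in E, so for a given
contact point the least-squares modulus is the closed-form projection
E ∝ Σ F δ²/Σ δ⁴ over 0 < δ ≤ 200 nm (at least 10 points required).  The
200 nm depth limit keeps the fit inside the semi-infinite-sample regime;
the explicit validity pair (δ ≤ 0.1 h, h ≥ 12.8 R) is evaluated when the
cell height and tip radius are supplied.

**Contact point.**  The initial estimate removes a linear drift fitted
to the first 30% of samples and takes the first sustained departure
(5 consecutive samples above 5 baseline SDs).  On noisy
shallow-indentation data this crossing is systematically late — the
force must clear the noise floor — so the estimate is refined by
profiled least squares with the contact point free: for each candidate
z_c the piecewise model F = C·max((z − z_c) − d, 0)² is fitted (closed
form in C) over a fixed evaluation set (all samples up to one depth
limit past the initial estimate), candidates scan every sample from the
end of the baseline window to the initial estimate, and the best
candidate is polished by bounded 1-D minimization.  On simulated curves
this recovers the contact point to sub-sample accuracy and, at
signal-to-noise 20 referenced to the deflection at the 200 nm fit depth,
yields ~3% median modulus error over 100 seeds.

**Bead pressure.**  For bead stimulation the contact area is taken as
half the bead surface (2πr²), so P = F/(2πr²); inputs in nN and μm,
output in kPa.  For the 5 μm bead this gives 3.82 kPa at 150 nN and
8.91 kPa at 350 nN.  The corresponding convention for the
optical-tweezers picture is not asserted (the half-surface rule gives
~3.5 Pa for 50 pN on a 3 μm bead, which need not match other published
roundings), so no optical-tweezers pressure is reported.

## Synthetic data: what it emulates and what it does not

The generator encodes the study conditions: 120 frames at 2 frames/s
with stimulus onset at 10 s; populations of 105 cells per force at
150–350 nN in 50 nN steps; response probability Boltzmann in force with
F₀ = 300 nN, B = 85.77 nN; among responders a generalized share
interpolated linearly from 0.66 at the lowest force to 0.82 at the
highest; AFM curves with a 0.1 N/m lever.  Where the underlying
distributions are not published, the defaults are plausible choices
made once:

* transient shape — product of exponential rise (τ_r = 0.25 s) and decay,
  the simplest form matching the recorded morphologies; amplitude is
  scaled by the background-corrected baseline so the configured value
  *is* the peak ΔF/F₀;
* class-conditional decay constants — uniform on [18, 40] s
  (generalized) and [1.5, 6] s (transitory), keeping the factor-3 decay
  times clearly on either side of the 10 s boundary;
* peak amplitude — mean linear in force (0.15 + 0.002/nN) with lognormal
  scatter (σ = 0.3), mean-preserving;
* noise — additive Gaussian on both channels, default 0.15 intensity
  units on a 100-unit baseline: per-frame ΔF/F₀ noise ≈ 0.0024, so
  noise-only traces stay below the 0.01 responder threshold, matching
  the negligible background fluctuation of the recordings;
* non-responders — zero transient amplitude plus noise, so the threshold
  logic is genuinely exercised;
* AFM — default E = 20 kPa (stiff-substrate cells), contact at 2 μm,
  500 nm maximum indentation, 600 samples, 0.3 nm deflection noise.

Seeding is hierarchical: one integer seed, split into named substreams
per stage and per force level, so enlarging one force's sample leaves
every other draw unchanged and identical configs are bit-reproducible.

Not emulated: optics (PSF, camera statistics), photobleaching beyond a
linear drift, calcium-wave spatial propagation, viscoelastic or
substrate-compliance corrections to the contact model, and any
correlation between a cell's elasticity and its channel response.
Passing tests on this generator therefore validate the *analysis
chain* — formulas, estimators, thresholds, determinism — not the
biological effect sizes, which require real recordings.

## Problem sizes in the shipped checks

The test suite uses the study-scale population (5 × 105 cells) for the
end-to-end runs, 200 binomial replicates with 200 bootstrap resamples
for recovery/coverage, 500 traces for the noisy classification check,
and 100 seeded curves for the noisy elasticity check; the whole suite
runs in well under a minute of compute per heavy test.

## Known limitations

* The decay time is a first-crossing statistic, not an exponential fit;
  it is exactly τ_d·ln 3 only for mono-exponential decay and is
  discretized to the 0.5 s frame grid.
* The free-(F₀, B) fit is only as identifiable as the data: fractions
  spanning neither side of 0.5 constrain F₀ weakly; the package flags
  but does not repair this.
* The Hertz fit assumes the pyramid law down to contact; real curves
  with adhesion or a blunt tip apex need a different contact model.
* `simulate_movie` renders spatially uniform compartments (cytosol /
  filamentous structures); it is a consistency oracle for ROI
  extraction, not an image-realism benchmark.
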