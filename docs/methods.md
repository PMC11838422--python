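# Methods

This note documents the models, conventions and design choices behind
`geciquant`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Equilibrium biophysics

A calcium indicator is modelled as a two-state (apo/saturated) sensor with
Hill-type binding:

    F([Ca]) = F_apo + (F_sat − F_apo) · [Ca]^n / ([Ca]^n + Kd^n)

Parameters: dissociation constant `Kd` (nM, half-saturation), Hill
coefficient `n` (cooperativity), apo and saturated brightness (a.u.). The
dynamic range is `F_sat/F_apo`. The packaged `FRCAMPI` constants are
Kd = 81 nM, n = 3.1, dynamic range 16.3, pKa (saturated state) 6.48.

Titration fitting uses bounded nonlinear least squares
(`scipy.optimize.curve_fit`) with data-driven initialisation: `kd0` at the
half-range crossing of the curve (linear interpolation), `n0 = 2`,
`f_apo0 = min(y)`, `f_sat0 = max(y)`; bounds `kd ∈ (0, 1e6]` nM,
`n ∈ (0, 10]`, brightness > 0. The bounds prevent the sign-flip degeneracy of
the Hill form. A curve whose max/min ratio is below 1.05 is rejected as
non-identifiable rather than fitted.

Calibration buffers follow the reciprocal EGTA/Ca-EGTA dilution rule

    Ca_free = correction · Kd_chelator_eff · f / (1 − f),   f = Ca_total / chelator_total

with `correction = 1.084` by default. The effective chelator Kd depends on
ionic strength, pH and temperature and must be supplied by the user; the
example configuration ships 287 nM, the value implied by back-solving the
formula against the standard 16-point free-calcium series (the series itself
is therefore a consistency example, not a reproduction target).

pH titrations are fitted with the Hill form in proton concentration,
`F(pH) = f_lo + (f_hi − f_lo)/(1 + 10^(n·(pKa − pH)))`; `pKa` is the pH of
half-maximal fluorescence between the fitted asymptotes. Photobleaching is
fitted mono- (`A·exp(−t/τ) + C`) or bi-exponentially; a non-decaying trace
returns `converged = False` instead of a spurious τ.

## Synthetic transients

The calcium surrogate is a linear exponential-kernel model:

    ca(t) = ca_rest + Σ_i a_per_ap · exp(−(t − t_i)/τ_ca) · 1[t ≥ t_i]

Defaults: `ca_rest = 50 nM` (neuronal resting calcium is of order 30–100 nM,
which places rest on the steep foot of the FRCaMPi binding curve),
`a_per_ap = 150 nM`, `τ_ca = 1 s`. There is no extrusion saturation or
endogenous buffer pool; indicator buffering can be emulated only by scaling
`a_per_ap`. This is deliberately the simplest model that supports all the
transient metrics.

Spike sources are (a) homogeneous Poisson trains thinned to a refractory
minimum gap, and (b) field-stimulation schedules — the standard culture
protocol is eight trains of 1, 2, 3, 5, 10, 20, 40, 80, 160 pulses at 83 Hz.
Frame-rate defaults mirror the imaging regimes the package emulates: 20 Hz
(culture), ~3 Hz (larval confocal), 33 and 7 Hz (two-photon), 10 Hz
(wide-field).

Fluorescence transduction is equilibrium by default (pointwise Hill map),
valid when binding equilibrates faster than the frame interval. The kinetic
mode integrates the bound fraction `b` through

    db/dt = k_off · (ca/Kd)^n · (1 − b) − k_off · b

i.e. a two-state scheme whose on-drive inherits the Hill cooperativity, so
its fast-binding limit recovers the equilibrium map exactly (a literal 1:1
single-site scheme could not converge to an n = 3.1 equilibrium curve). Each
substep (default ≥ 20 per frame, calcium linearly interpolated within the
frame) applies the exact exponential update of the linear ODE, which is
unconditionally stable and keeps `b ∈ [0, 1]` by construction.

Photon noise: `Poisson(photons_per_unit · F)/photons_per_unit` plus optional
Gaussian read noise; unbiased, reproducible for a fixed seed.

## Scenes and rendering

Somas are disks sampled uniformly without overlap (minimum centre distance =
sum of radii, plus an optional `min_gap`); neurites are random-walk polylines
(2 µm steps, 0.35 rad angular diffusion) leaving the soma edge. Per-pixel
neurite expression weight is `exp(−d/λ)` with `d` the arclength from the soma
edge, rasterised at half-pixel substeps with a max-reduction per pixel, so
the weight one length constant out is e⁻¹ ≈ 36.8 % of the soma-edge weight.

Length constants default to λ = 100 µm (non-targeted, cytosolic) and
λ = 16 µm (soma-targeted). The soma-targeted constant is set slightly below
one fifth of the non-targeted one so that the *integrated* neurite
fluorescence — `λ(1 − e^(−L/λ))` at the default neurite length L = 300 µm,
which penalises the long-λ condition more — stays at or below one fifth of
the matched non-targeted scene, the regime of a strongly soma-restricted
sensor.

Coordinate conventions: 0-based pixel indices, pixel (0, 0) at top-left,
positions in µm converted through `pixel_size` (default 1.0 µm/px), masks
are half-open pixel sets.

Rendering composes, per frame: each neuron's soma mask and neurite weight
map times its trace; an out-of-focus/scatter term `oof_weight ·
gaussian_blur(footprints, σ)` — a two-parameter caricature of optical
sectioning, not a 3-D PSF; an optional shared neuropil trace on non-soma
pixels; a constant background; then per-pixel photon noise. Presets:
wide-field σ = 15 px, oof = 1.5 (out-of-focus light in one-photon
epifluorescence exceeds the in-focus signal); two-photon σ = 2 px,
oof = 0.05. The presets are chosen to reproduce the *ordering*
wide-field ≫ two-photon contamination; absolute correlation magnitudes are
configuration-dependent and are not treated as quantitative predictions.

## Trace metrics

Conventions pinned for reproducibility (the sources that motivated the
metrics leave them unstated): sample SD (ddof = 1) everywhere; sliding
windows centred and truncated (not padded) at edges; percentiles by linear
interpolation; strict inequalities at decision thresholds (z > 2.5,
excluded when r² < 0.8).

Baselines: `pre_window_mean` (e.g. 1 s before stimulus), `sliding_percentile`
(e.g. 20th percentile of a 200-frame window, or 10th of a 60-s window),
`spline_fit` (smoothing spline over the full trace, for drift and
photobleaching), `pre_spike_spline` (B-spline through the 3 frames before an
event onset, evaluated at the onset).

Half-rise/half-decay times fit the rise and decay segments to single
exponentials and locate the half-maximum crossings by linear interpolation of
the fitted curve at the frame times; the half levels are referenced on the
fitted curve rather than the raw single-frame peak, which would be biased
upward by noise. Epochs whose combined fit r² falls below 0.8 are flagged
`excluded`. The full decay time is read as the time from the peak to the
first post-peak zero crossing of ΔF/F₀ (the underlying definition — "the
first time point that reached the negative ΔF/F₀ of the spike" — is
ambiguous; the zero-crossing reading is flagged to the user and a trace that
never returns is reported right-censored, not clipped).

Peak SNR divides the maximal fluorescence change by a baseline noise SD with
two bases: `raw_f_sd` (SD of a pre-stimulus window) and `low_quantile_sd`
(SD of the frames at or below the 20th percentile of the whole recording —
the reading adopted for the ambiguous "SD of fluorescence in the 20th
percentile of the session"). A zero-variance baseline returns an infinite
sentinel with a warning rather than raising.

The trial-based responsiveness classifier requires both a Wilcoxon rank-sum
p < 0.05 of per-trial post- vs pre-onset means (exact null below 8 trials,
tie-corrected normal approximation above) and a trial-averaged peak above 4
baseline SDs. No multiple-testing correction is applied across conditions
("at least one condition at p < 0.05"); a Bonferroni flag can be layered on
by the caller. The z-score classifier needs ≥ 10 baseline frames and is
strict at 2.5. OSI = (R_pref − R_orth)/(R_pref + R_orth); values above 1
(negative R_orth) are returned unclipped so the standard OSI > 1 exclusion
can be applied downstream.

## Spatial metrics

The neuropil annulus is the set of pixels whose Euclidean distance to the
nearest ROI pixel lies in (inner, outer] px (defaults 5 and 15), with pixels
of any other ROI excluded; its per-frame median is the neuropil estimate and
`F_corrected = F_soma − 0.7·F_neuropil` is the standard subtraction. ROI
matching computes IOU for all cross-channel pairs and matches greedily on
descending IOU with a ≥ 0.5 threshold; ties are broken by (lower id_A, lower
id_B) for determinism, and an optimal-assignment variant
(`strategy="optimal"`) is exposed because greedy and optimal can differ on
adversarial overlap patterns. Labeling density is the fraction of reference
ROIs with a co-detected GECI ROI (default rule: IOU ≥ 0.25 or centroid
containment — a package decision, since co-detection criteria are rarely
stated); edge ROIs can be trimmed via `edge_margin`. The minimal segmenter
(Gaussian smooth → threshold → connected components → area filter) is a
deterministic stand-in for real segmentation tools and is only intended for
synthetic scenes.

## Population analysis and the contamination experiment

Pairwise Pearson correlations are computed for all unordered ROI pairs on
z-scored traces (PCC is scale-invariant; z-scoring is kept for parity between
raw and corrected variants), with centroid-to-centroid distances in µm and
half-open distance bins [0, 200), [200, 400), [400, 800) µm.

`run_contamination_experiment` builds two scenes that share soma placement,
activity and noise seeds and differ only in targeting. Population activity
mixes independent Poisson spiking (0.3 Hz) with population events (0.04 Hz,
75 ms jitter) that recruit each neuron with probability 0.5 — the
synchronous component that neuropil contamination broadcasts across the
field. The shared neuropil field (the aggregate neurite fluorescence of the
mostly out-of-view population, taken as the population-mean trace) is mixed
into non-soma pixels with a weight that scales with the integrated neurite
expression `λ(1 − e^(−L/λ))`, so soma-targeting suppresses it by the same
factor as in-view neurite fluorescence. Because somas occlude the neuropil
beneath them, the annulus sees more of this shared field than the soma pixel
does — which is exactly the situation the conventional 0.7 subtraction
coefficient compensates for.

The shipped default (128 × 128 px at 1 µm/px, 30 neurons, 600 frames at
10 Hz, wide-field preset, `neuropil_weight_base = 0.5`) was designed once to
sit in the regime the method is meant to exhibit — non-targeted raw
correlations dominated by contamination, a ≥ 3-fold drop after 0.7
subtraction, and soma-targeted raw correlations comparable to corrected
non-targeted ones — and then frozen. A zero-neuropil configuration
(`oof_weight = 0`, `neurite_gain = 0`, `neuropil_weight_base = 0`) renders
bit-identical movies for both targeting conditions and serves as the
negative control.

Problem sizes used by the test suite and acceptance script: titrations use
the 16-point series; kinetics Monte-Carlo uses 100 seeds at 33 Hz sampling
(the two-photon kinetics regime) with SNR 20; matcher validation uses 200
random mask sets of ≤ 6 ROIs; the contamination experiment uses 10 seeds at
the full default size; the z-score false-positive study uses 1000 pure-noise
neurons at 1 Hz (the effective per-plane rate of volumetric multi-plane
acquisitions, where the 3-s/2.5-z criterion originates — at high frame rates
a max-over-window z test necessarily has a larger false-positive rate).

## Known limitations

- The calcium model is linear (no buffering, extrusion saturation or
  stores); the optics model is 2-D with a single blur/mixing caricature (no
  3-D PSF, motion, vasculature or hemodynamics).
- Passing contamination orderings on synthetic scenes shows the analysis
  chain behaves correctly under the modelled physics; it does not by itself
  validate absolute correlation magnitudes in tissue.
- Spike inference/deconvolution is out of scope: analyses consume
  ground-truth or user-supplied event times.
- The greedy IOU matcher replicates the "highest IOU among all potential
  pairs" rule; on rare overlap patterns an optimal assignment differs, and
  both are exposed.
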