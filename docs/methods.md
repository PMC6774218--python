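# Methods

`retinad` reproduces, end to end, the measurement and analysis chain of a
longitudinal retinal-phenotyping study in the APP/PS1 mouse model of
Alzheimer's disease and wild-type (WT) littermates: dark-adapted
electroretinography (ERG), optical coherence tomography (OCT) of the
retina around the optic nerve head, the novel-object-recognition (NOR)
behavioural test, and the statistical battery comparing the two
genotypes across 3, 6, 9 and 12 months of age.  Because no raw data
from such studies are publicly deposited, the package ships a
synthetic-cohort generator whose ground truth is the published group
means and standard deviations; every analysis stage is validated by
recovering those configured values from raw simulated signals.

## ERG measurement conventions

All ERG quantities are amplitudes in microvolts read off voltage-vs-time
traces with a known flash time:

* **baseline** — mean of the pre-flash samples (50 ms at the default
  1 kHz sampling).
* **pSTR** — baseline to the maximum post-flash peak of the trace
  obtained by averaging 30 dim-flash scotopic-threshold-response
  sweeps.
* **a-wave** — baseline to the minimum within a 50 ms post-flash window
  (configurable); reported signed-negative.
* **b-wave** — a-wave trough to the maximum occurring anywhere after
  it (trough-to-peak, non-negative by construction).
* **Oscillatory potentials (OPs)** — the bright-flash trace is
  band-pass filtered at 60–235 Hz with a 4th-order Butterworth applied
  forward–backward (zero phase, so OP peak times are not shifted).
  Peaks are searched in a 120 ms post-flash window above a prominence
  floor of 5 % of the filtered-trace maximum, with a minimum
  separation of 4 ms (half a cycle at the band's geometric centre,
  ~119 Hz).  The three most prominent peaks, taken in temporal order,
  are OP1–OP3 — prominence ranking rather than first-three-found,
  because the zero-phase filter produces a small precursor ripple
  ahead of the burst and noise can raise spurious wiggles above the
  floor; an examiner labelling wavelets by eye performs the same
  selection.  Each OP amplitude is its peak minus the nearest
  preceding qualified trough, and the total OP response is the exact
  sum OP1 + OP2 + OP3.

Two numerical choices emulate how such cursor measurements are made on
instrument displays, and materially reduce the extreme-value bias of
reading extrema off noisy samples:

* slow-component extrema (a-trough, b-peak, pSTR peak) are located on
  a Gaussian-smoothed copy of the trace (σ = 4 ms — far below the slow
  components' time scales, so their amplitudes change by < 0.1 %, and
  with a monotone step response so step-like inputs are not overshot);
  the baseline always comes from the raw samples;
* peak and trough values in the OP band are read from a 3-point
  parabolic vertex rather than the single most extreme sample.

With the default recording noise (white Gaussian, 10 μV per sweep)
these choices keep the residual bias of every cohort-mean amplitude
within a fraction of its between-animal SEM; without them the b-wave
alone is overestimated by tens of microvolts.

## Synthetic ERG waveform and its closed-loop contract

The bright-flash waveform is composed of three parts, all zero before
the flash (default record: 500 ms at 1 kHz, flash at 50 ms):

* an **a-component**: a C2-smooth transient dip peaking near 15 ms
  post-flash that partially recovers to a sustained plateau at 85 % of
  the trough depth.  The transient makes the a-trough a localized
  extremum (bounding noise bias); the sustained tail keeps the trace
  below baseline for the rest of the record, which is required to
  represent aged cells where the printed trough-to-peak b-wave is
  smaller than the a-wave magnitude;
* a **b-component**: a gamma-shaped positive lobe peaking 100 ms
  post-flash;
* an **OP burst**: three Gaussian-windowed sinusoid wavelets at
  120 Hz, crests two carrier periods apart (≈23, 40, 57 ms
  post-flash), envelope σ of a third of a period.  Separate wavelets
  — rather than one continuous windowed sinusoid — keep the three
  peak-to-trough amplitudes nearly independent, which a shared
  envelope cannot do.

Because the components overlap (the a-trough rides the rising
b-wave, the OPs ride both), the generator calibrates itself in closed
loop: it measures the composed noise-free waveform with the package's
own extractor and rescales each component multiplicatively (damped,
with a diminishing step to suppress limit cycles from discrete peak
selection) until every measured amplitude is within 1.5 % of its
target, well inside the documented 2 % contract.  Waveforms whose OP
amplitudes cannot be rendered as three resolvable wavelets — adjacent
amplitude ratios beyond ≈2.5, or wavelets rivalling the b-wave
trough-to-peak — raise a calibration error; the cohort sampler treats
such truth draws as unmeasurable and redraws them (see below).

The dim-flash STR sweep is a single gamma lobe peaking 110 ms
post-flash whose height is exactly the configured pSTR amplitude;
30 independent noisy sweeps are generated per session and averaged
before measurement, as in the recording protocol.

## OCT phantom and graph segmentation

Phantom B-scans (default 96 × 120 px at 3.9 μm/px axial — the device's
axial resolution) stack five reflectance bands: vitreous (0.03), inner
retina (0.60), outer retina (0.35), RPE (0.85, 12 μm thick) and
below-RPE (0.06).  The values are chosen so the vitreous/ILM step is
the strongest dark→light edge and the RPE base the strongest
light→dark edge, matching the sequential search order below.  All
three interfaces (ILM, INL/OPL, RPE base) share a low-order lateral
undulation (first three Fourier modes, amplitude 2 px, integer periods
so the column mean is exactly zero and thickness is unbiased), each
adds a small independent wiggle, and all dip together by 8 px under a
Gaussian optic-nerve-head profile (the common dip leaves thickness
unchanged; ONH columns are excluded from averaging regardless).
Pixels crossing a boundary are area-weighted, and multiplicative
Gaussian speckle (relative SD 0.15) is applied.  Ground-truth
positions are stored in pixel-centre coordinates (band coordinate
− 0.5), the location at which a central-difference gradient estimator
responds; with this convention the noise-free phantom is recovered to
≤ 0.5 px and the default-speckle ensemble to ≤ 0.5 px mean absolute
error per boundary.

Segmentation follows the graph formulation for layered tissue: the
column-normalized vertical gradient of the requested polarity gives
per-pixel affinities in [0, 1]; a boundary is the monotone (one row
per column, |Δrow| ≤ 1) left-to-right path minimizing the summed edge
weights `2 − (g_a + g_b) + 1e-5`, with free start and end rows
(phantom zero-cost margins) and ties resolved toward smaller row
indices.  The dynamic program is verified against exhaustive
enumeration of all monotone paths on small matrices.  The three
interfaces are found sequentially — ILM (dark→light, whole image), RPE
base (light→dark, restricted below the ILM with a 2 px guard band),
INL/OPL (light→dark, strictly between them) — and any ordering
violation raises rather than returning crossed boundaries.  Inner
retinal thickness is the column mean of (INL/OPL − ILM) × axial pitch
with the central 10 % of columns (or an explicit ONH interval)
excluded; outer thickness likewise from (RPE base − INL/OPL).  An eye
is summarized as the arithmetic mean over its five B-scans (125 μm
apart), with layer reflectances normalized to a 3 px strip above the
RPE base to cancel per-scan gain.  Manual corrections can overwrite
per-column positions; touching more than 5 % of columns triggers an
error-budget warning.  Sub-pixel parabolic refinement of boundary
positions is available but off by default.

## Cohort generator

The default design is two genotypes × four ages × 15 animals per cell
(NOR at 6, 9 and 12 months only), with cell means and between-animal
SDs set to the published functional and structural tables; recording
noise (10 μV) and speckle sit on top of the between-animal variation.
Each animal/modality draws from an independent seeded stream, so the
dataset is reproducible bit-for-bit given the design seed and
unchanged when other modalities are toggled.  Animals at different
ages are sampled independently (the analysis battery, like the
original one-way ANOVA/ANCOVA design, does not model within-animal
correlation).

Truth draws are normals floored at 20 % of the cell mean, and the
(b-wave, total-OP) pair is redrawn while the largest implied OP
wavelet exceeds 0.7 × the b-wave: a recording in which a single OP
rivals the trough-to-peak b-wave is self-contradictory under the
measurement conventions (the OP crest would *be* the b-peak), so such
tail draws cannot occur in a measured cohort either.  The rejection
probability is zero at the young cells that serve as recovery targets
and ≲10 % in the oldest cells.  The printed total OP is split
(0.3, 0.4, 0.3) over OP1–OP3.

What the generator does *not* emulate: intensity–response functions
(flash strengths are metadata labels), latency changes with age or
genotype, within-animal longitudinal correlation, eye-to-eye
differences, retinal curvature beyond low-order undulation, vessel
shadows, or histology.  Passing the recovery suite therefore shows
that the extraction and statistics are faithful to their definitions
and calibrated on signals of realistic shape and noise — not that they
are robust to every artefact of real recordings.

## Statistics

Within each genotype, a one-way ANOVA across ages (age categorical)
with Tukey HSD post-hoc for all age pairs; the studentized-range
p-values come from statsmodels and are cross-checked against a
first-principles implementation in the tests.  Significance letters in
the summary tables follow the tier scheme a/b/c/d for p < .05, .01,
.001, .0001: each significant pair contributes its tier letter to both
its cells, so a shared letter marks a significant pairwise difference.
Between genotypes, the slope-equality ANCOVA fits
`value ~ age × genotype` with age numeric (months) and reports the
interaction F-test — its p-value is the chance of drawing data with
slopes this different if the true slopes coincide; the test's type-I
error is verified by simulation to sit at the nominal α.  At each age,
an independent two-sample t-test (classic equal-variance by default,
Welch behind a flag).  No correction is applied across parameters,
mirroring the original analysis; this is a known limitation.  All
p-values, F and t statistics agree with closed-form textbook
computations to 1e-8 on random datasets.

## Problem sizes and defaults used for validation

Parameter-recovery checks run the 3-month cells with 30 animals per
genotype (ERG) and 20 phantom eyes × 5 B-scans (OCT); the boundary
oracle covers 200 random matrices up to 7 × 7; the ANCOVA calibration
uses 500 null and 200 alternative simulations at n = 15 per cell.
These sizes give sub-SEM Monte-Carlo error for every asserted
tolerance while the whole suite completes in about a minute.

## Known limitations

* Total-OP extraction from the single bright-flash sweep retains a
  small positive bias (≈ +3 μV at the default 10 μV noise) from
  extreme-value reading of six extrema; it is well inside the
  between-animal SEM at the validated cohort sizes but visible in
  unlucky seeds.
* OP amplitude patterns with adjacent ratios beyond ≈2.5 are not
  representable as three resolvable 120 Hz wavelets.
* The a-wave/OP timing parameters (a-window, OP window, onset) are
  conventions exposed as configuration, not facts about any particular
  instrument.
* Whether the inner compound layer should include the nerve-fibre
  layer above the ganglion-cell layer is anatomically ambiguous; the
  segmentation treats the ILM as the upper bound.
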