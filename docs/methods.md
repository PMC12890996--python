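# Methods

This note records the models behind each pipeline, the conventions the
implementation pins down, the defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical decisions a
maintainer would otherwise have to reverse-engineer.

## Beating-frequency analysis

### Signal model

The measured quantity is the mean gray value of an ROI over a beating area,
sampled at Δt = 0.5 s for 30 s–3 min. The working model is

x(t) = baseline + Σ_k p(t − t_k) + d(t) + n(t)

where p is a contraction transient, t_k are beat times, d is slow drift from
sample/stage movement, and n is measurement noise. The pipeline assumes
beats are the only content in the ~0.15–1 Hz band; it does not model
contraction amplitude or propagation (out of scope).

### Detrending and normalization

The baseline estimate is a centered weighted moving average, truncated and
re-normalized at the trace edges (reflection would fabricate symmetric
drift). Defaults: **window 8 s, triangular weights**. The window trades off
drift removal against beat preservation through its sinc² frequency
response: at 8 s it attenuates a 12-BPM (0.2 Hz) fundamental by < 6% while
removing > 97% of 0.02-Hz stage wander. A 5-s window — a natural first
choice — removes ~40% of a 12-BPM fundamental, enough to push the largest
spectral peak onto the second harmonic and double the FFT estimate at slow
rates; that failure mode drove the 8-s default. The residual is z-scored so
that downstream thresholds are in SD units and transfer across recordings;
a numerically-zero residual (constant trace) returns all zeros rather than
amplified rounding noise (tolerance 1e-12 × signal scale).

### Peak detection

Candidates are local maxima with topographic prominence ≥ 0.75·SD;
conflicts under the 1.0-s minimum spacing are resolved by keeping the
higher-prominence candidate (greedy, descending prominence, earliest index
on ties). Two conventions matter:

- **Open boundaries.** The series is padded with its minimum before peak
  search. A beat whose sampled maximum lands on, or one sample from, the
  recording boundary otherwise loses its peak entirely or has its
  prominence clipped by the truncated relaxation; with the padding the
  pipeline counts noiseless pulse trains exactly at every rate up to the
  Nyquist-consistent 60 BPM.
- **Quantization.** Before the search the series is quantized to 1e-9 of
  its SD. Beats that land exactly midway between samples produce two-sample
  plateaus of analytically equal values; floating-point rescaling of the
  input perturbs such ties at the last ulp and would move the reported peak
  index by one sample. Quantization makes peak positions exactly invariant
  under amplitude scaling without affecting any genuine structure (the
  signal is z-scored, so 1e-9 is far below noise).

The prominence default (0.75 SD) was calibrated on the synthetic design
conditions (noise SD at 20% of the pulse amplitude, drift up to 10×): under
those conditions noise-bump prominences sit near 0.5 SD and transient
prominences at ≥ 2 SD, so 0.75 rejects noise at slow rates (long exposed
gaps) without losing the low-contrast overlapping transients near 50 BPM.
At 0.5-s sampling the 1.0-s spacing cap means detection tops out at 60 BPM;
`analyze_trace` flags rates above 80% of Nyquist (`nyquist_warning`), where
counting becomes unreliable regardless of thresholds.

### FFT cross-validation

The detrended series is Hann-windowed, zero-padded to 4× its length, and
the largest magnitude at f ≥ 0.1 Hz is converted to BPM. Padding reduces
bin quantization: a 30-s recording has 2-BPM native resolution but 0.5-BPM
padded resolution. A bin must exceed 4× the median in-band magnitude (a
noise-floor test) or 0 is returned — a flat trace yields 0 BPM from both
estimators and counts as agreement. Peak/FFT agreement uses
max(15%, one padded bin): the 15% tolerates one missed beat on short
recordings, the bin term keeps the comparison meaningful when the relative
tolerance collapses near 0 BPM.

### Known limitations

A subtractive moving-average detrend has finite stopband attenuation near
its band edge: drift at ~1/W Hz with 10× the pulse amplitude leaves a
residual whose slopes exceed pulse prominence, and no prominence threshold
can recover the count. The drift-robustness guarantee therefore applies to
the stage-wander band (≲ 0.03 Hz for the 8-s window), not to arbitrary
sub-band-edge sinusoids. Above ~50 BPM at 0.5-s sampling there are only
~2.2 samples per beat; with 20% noise, occasional argmax shifts collide
with the spacing cap and a few percent of beats are missed — an intrinsic
sampling limit, not a threshold choice.

## Synthetic beat traces

The generator is the test bed's ground truth, so its realism assumptions
are stated explicitly:

- **Transient**: raised cosine (smooth, unimodal — a delta train would make
  peak detection trivially easy at low rates and impossible at high ones).
  Width defaults to min(1.2 s, 0.8 × beat period): a contraction-relaxation
  cycle spans roughly a second at slow rates, compresses with rate, and
  cannot outlast its cycle (explicit widths longer than the period are
  rejected). A width fixed below the period independently of rate would
  also degenerate at 0.5-s sampling into a single-sample spike whose comb
  spectrum has no dominant fundamental.
- **Beat times**: renewal process with gamma-distributed intervals,
  CV = `irregularity_cv` (default 0.05; 0 gives a strictly periodic train
  with exactly round(bpm·T/60) beats, first beat half a period in).
- **Drift**: one sinusoid, default 0.02 Hz at 2× the pulse amplitude, with
  a seeded random phase — slow mechanical/thermal wander.
- **Noise**: two-component Gaussian with total SD = `noise_sd` (default 20%
  of the pulse amplitude): 30% of the SD is white (photon/readout noise —
  small in a mean over thousands of ROI pixels) and 70% carries a 2-s
  correlation time (texture and sample-motion fluctuation, which dominates
  at this magnitude and has little power at the frame rate). A pure-white
  reading of "20% noise" is not a property of real ROI-mean traces and
  makes peak counting information-theoretically unreliable at slow rates.

What the generator does **not** emulate: amplitude variation between beats,
ectopic/double-peaked transients, photobleaching trends, ROI-boundary
motion artifacts correlated with contraction. Passing tests therefore show
correct recovery under drift, stationary noise, and timing irregularity —
not robustness to arrhythmic morphology changes.

Stacks (`gen_beat_stack`) render the trace into a constant-background
16-bit frame sequence; frame count is round(T/Δt) with timestamps
0, Δt, …, (n−1)Δt.

## Mitochondrial morphometry

Conventions are pinned because packages genuinely disagree:

- **Connectivity** is 8-connected everywhere; orthogonal steps weigh 1,
  diagonal steps √2.
- **Perimeter** is the closed outer Moore-contour length through pixel
  centers (single-pixel particle: 0; a 10×10 square: 36; inner boundaries
  of rare donut-shaped particles are not added).
- **Solidity** = pixel count / number of pixel centers inside or on the
  convex hull of the particle's pixel centers. The hull count is computed
  as shoelace area + B/2 + 1 (Pick's identity, B = boundary lattice
  points); collinear particles use segment lattice counting. This makes any
  convex particle score exactly 1 and keeps the ratio a pure pixel-count
  comparison.
- **Skeleton graph**: pixels classify by 8-neighbor count (1 endpoint,
  2 path, ≥3 junction); chains of mutually adjacent junction pixels merge
  into one node (thinning emits junction clusters; without merging,
  node-degree statistics are artifacts). Node degree counts branch
  incidences: endpoints have degree 1, a loop attached to a node adds 2, an
  isolated cycle is one self-branch on a single degree-2 node. Direct
  pixel adjacencies between two distinct nodes collapse to one branch of
  minimal step weight. `avg_node_degree` averages over nodes, including
  isolated single-pixel nodes at degree 0.

Every one of these quantities is recomputed by an independent route in
`skeleton_reference` (BFS flood fill; clockwise — rather than
counterclockwise — contour following with periodic-state termination;
Delaunay-membership lattice enumeration instead of Pick's identity; a full
networkx pixel graph contracted by connected components instead of path
walking), and the test suite requires agreement on a battery of line,
cross, T/H/Y, comb, loop, and seeded random shapes.

Segmentation is deliberately plain (Gaussian smooth, Otsu or fixed
threshold, minimum object size 4 px to drop shot-noise specks): the
morphometry, not the segmentation, is the point, and thresholds are
configurable. A uniform image under Otsu warns and returns zero particles
rather than failing. Features are reported in pixels; an optional
µm-per-pixel scale multiplies lengths and areas on output only.

The synthetic mitochondrial images are binary renderings of line/rectangle
primitives — deliberately not photorealistic (no PSF, no fluorophore noise,
single channel). They exercise the measurement conventions exactly; they do
not validate segmentation against realistic confocal noise.

## Respirometry

The record is modeled as piecewise-linear O2 decline: one slope per
coupling-control state (basal → oligomycin/leak → FCCP titration/ET →
rotenone → antimycin A/ROX), with events marking injections. Analysis
choices:

- **State segments** come from the event times; a 10-sample guard band
  after each injection absorbs mixing artifacts (the synthetic generator
  blends slopes over 5 samples at each transition, so the guard is
  load-bearing in tests). The rotenone → antimycin A span is measured by
  neither state. The basal segment starts at the record start with no
  guard.
- **OCR per state** is −slope/density from an ordinary least-squares line
  over the contiguous **45-sample** window minimizing the fit residual SD —
  the protocol's averaging length, treated as a pinned constant (overriding
  it warns). A slope over the window is the numerically robust reading of
  averaging a rate; pointwise finite differences would amplify noise.
  Ties (e.g. an exactly linear segment) break to the earliest window, with
  residuals within rounding tolerance (1e-6 relative + 1e-10 × O2 scale)
  counted as tied.
- **Units**: with O2 in nmol/mL and density in 10⁶ cells/mL, OCR is in
  nmol·s⁻¹ per 10⁶ cells (= pmol·s⁻¹ per 10³ cells). No solubility or
  temperature corrections are applied (out of scope).
- **Derived parameters**: maximal = max over FCCP steps; residual = ROX
  OCR; corrected values subtract residual and are reported alongside the
  raw ones (negative corrected values are flagged, not clipped), since
  whether published bar plots are ROX-corrected is often unstated.
- The per-window slope standard error is reported; the noisy-recovery tests
  check parameters against generator truth within 3 fitted SEs. Selecting
  the minimum-residual window deflates the SE slightly and the max over
  FCCP steps is upward-biased under noise, so the 3-SE containment rate
  across seeds is ≈ 0.85–1.0 rather than the nominal 0.99 — visible in the
  acceptance report as `resp_noisy_within_3se_rate`.

Generator defaults emulate an O2k-style record: 2-s sampling, 200 nmol/mL
starting O2 (air-saturated medium), basal slope −0.08 nmol/mL/s (≈ 80
pmol·s⁻¹ per 10⁶ cells at 10⁶ cells/mL), three FCCP steps peaking at the
second, 5-sample injection ramps, optional Gaussian noise.

## Onset kinetics and statistics

- Daily onset percentage uses the seeded-well denominator (30 per
  replicate), so wells that never beat lower the percentage but never the
  denominator; SEM is across biological replicates (n = 3), not wells.
- Cumulative counts sum onset_day ≤ d over wells, per replicate, stacked to
  group totals; never-beating wells are excluded. Conservation (Σ daily
  onsets = final cumulative) and monotonicity are tested over 200 generated
  tables.
- The t-test is Student's pooled-variance form (the named test), two-tailed.
  Zero pooled variance with equal means returns t = 0, p = 1; with unequal
  means the statistic is undefined and raises.
- The F-test is two-tailed by doubling the smaller tail of F = s²x/s²y
  (n−1 variances), capped at 1 — the symmetric standard convention, making
  p invariant under exchanging the samples. Its type-I error at α = 0.05 is
  verified empirically on 10 000 null simulations (n = 8 per group,
  matching a plate-column layout).

The onset-table generator draws each well independently from a per-group
day distribution plus a never-beats mass. Defaults mirror the reported
differentiation kinetics: the light-treated group begins around day 8 with
a day-15 peak at 42% of wells; the control group starts later with a lower,
flatter profile. Real plates violate independence (edge effects, shared
media); the generators do not emulate that, so the tests validate the
summaries' arithmetic, not plate-level correlation structure.

## Problem sizes

The test suite and acceptance script run at the sizes the analyses are
designed for: 60-s traces at 0.5-s sampling (120 samples), 100-fixture BPM
ensembles, ≤ 64×64 shape canvases (≈ 22 shapes), ~1800-sample O2 records,
200 onset tables of 180 wells, and 10 000 F-test null simulations — the
full suite completes in well under a minute on one core.
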