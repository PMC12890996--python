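# cmquant

Quantification pipelines for studies of iPSC-derived cardiomyocyte cultures:
video-based beat detection, mitochondrial network morphometry,
high-resolution respirometry state analysis, and differentiation-onset
kinetics with the associated two-group statistics.

The package is aimed at labs that record phase-contrast videos of beating
monolayers, confocal images of stained mitochondria, closed-chamber oxygen
traces, and per-well beating-onset logs — and want the downstream numbers
(BPM, network features, OCR per bioenergetic state, onset percentages) from
auditable, configurable, tested code rather than one-off scripts.

## What it computes

**Contractility** (`cmquant.contractility`). A contracting cluster modulates
the mean pixel intensity of a region of interest (ROI). For a trace
x(t) sampled every Δt (typically 0.5 s) the pipeline subtracts a centered
weighted-moving-average baseline b(t) (window W = 8 s, triangular weights,
truncated and renormalized at the edges), z-scores the residual
z(t) = (x − b − mean)/SD, counts peaks with topographic prominence ≥ 0.75·SD
and spacing ≥ 1 s, and reports BPM = 60·n_peaks/T. The rate is
cross-validated against the dominant frequency of the Hann-windowed, 4×
zero-padded FFT of z; the two estimates must agree within
max(15%, one padded bin).

**Mitochondrial morphometry** (`cmquant.mito`). Per manually cropped cell:
Gaussian smoothing, Otsu or fixed thresholding, 8-connected labeling with a
minimum object size, then particle features (count, area = pixel count,
perimeter = outer Moore-contour length with orthogonal steps 1 and diagonal
steps √2, solidity = area / lattice-point count of the pixel-center convex
hull, so convex particles score exactly 1) and skeleton features from a
topology-preserving thinning: branches, branch lengths, and node degree
(number of branches meeting at an endpoint or merged junction). An
independent exhaustive pixel-graph implementation
(`cmquant.skeleton_reference`) recomputes every quantity by a different
route and backs both the synthetic ground truth and the test oracles.

**Respirometry** (`cmquant.respirometry`). A closed-chamber O2 record with
oligomycin → FCCP (titration) → rotenone → antimycin A injections is split
into basal / leak / ET / ROX states (10-sample post-injection guard bands),
each state's OCR is −slope/density from the 45-sample window with the
smallest linear-fit residual, maximal respiration is the best FCCP step, and
basal/leak/maximal are also reported ROX-corrected.

**Kinetics and statistics** (`cmquant.kinetics`). Daily new-onset percentage
of seeded wells (mean ± SEM across biological replicates), cumulative
beating-well counts stacked by replicate, the unpaired two-tailed Student's
t-test (pooled variance), and a two-tailed F-test for equality of variances
(F = s²x/s²y, p = 2·min(tails) capped at 1).

**Synthetic data** (`cmquant.synthetic`). Seeded generators produce
ground-truth-labeled inputs for every stage: pulsatile intensity traces
(raised-cosine transients on gamma-renewal beat times, slow sinusoidal
drift, two-component noise), image stacks, mitochondrial shape images,
piecewise-linear O2 records with injection mixing ramps, and per-well onset
tables for the 3-replicate × 30-well design.

## Worked example

```python
from cmquant.synthetic import BeatTraceSpec, RespTraceSpec, gen_beat_trace, gen_resp_trace
from cmquant import contractility as ct, respirometry as rp

# a 60-s recording at 27 BPM with 5x drift and 20% noise
spec = BeatTraceSpec(bpm_true=27.0, drift_amplitude=50.0, noise_sd=2.0, seed=42)
trace, beat_times = gen_beat_trace(spec)
res = ct.analyze_trace(trace)
print(f"bpm_peaks = {res.bpm_peaks:.1f}, bpm_fft = {res.bpm_fft:.2f}, "
      f"agreement_ok = {res.agreement_ok}")

o2, truth = gen_resp_trace(RespTraceSpec(noise_sd=0.2, seed=42))
states, summary = rp.analyze_resp_trace(o2)
print(f"basal = {summary.basal:.4f}, leak = {summary.leak:.4f}, "
      f"maximal = {summary.maximal:.4f}, residual = {summary.residual:.4f}")
```

prints

```
bpm_peaks = 27.0, bpm_fft = 27.25, agreement_ok = True
basal = 0.0796, leak = 0.0202, maximal = 0.1391, residual = 0.0081
```

The detector recovers all 27 true beats (27.0 BPM) despite drift five times
the pulse amplitude; the FFT estimate lands on the nearest padded bin
(27.25 BPM), inside the agreement tolerance. The respirometry summary
recovers the generator's per-state oxygen consumption rates (true values
0.08, 0.02, 0.14, 0.01 nmol·s⁻¹ per 10⁶ cells) to within the fit noise.

The same pipelines are available from a shell:

```bash
cmquant simulate --kind beat_stack --spec spec.json --out sim/day15
cmquant beats --stack sim/day15_stack.tif --rois rois.csv --dt 0.5 --out beats.csv
cmquant resp --trace o2.csv --events events.csv --density 1.0
cmquant mito --images cells/ --group control --out features.csv
cmquant kinetics --table onsets.csv --wells-per-replicate 30
```

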