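"""Ground-truth-labeled synthetic fixtures for every analysis stage.

Real recordings of beating cultures, mitochondrial networks, and chamber
respirometry carry no ground truth; the generators here produce inputs with
the same statistical structure *and* the exact labels each analysis is meant
to recover:

- ``gen_beat_trace`` / ``gen_beat_stack``: pulsatile ROI intensity series
  (raised-cosine contraction transients at renewal-process beat times, slow
  sinusoidal drift, Gaussian noise) with the true beat times;
- ``gen_mito_image``: binary-foreground mitochondrial shapes rendered from
  line/rectangle primitives, with particle and skeleton ground truth computed
  by the independent pixel-graph routes in
  :mod:`cmquant.skeleton_reference` (never by the analysis code);
- ``gen_resp_trace``: piecewise-linear O2 decline across the coupling-control
  states with short injection mixing ramps, plus the true per-state OCR;
- ``gen_onset_table``: per-well first-beating days sampled from per-group
  day distributions over a 3-replicate x 30-well design.

Every generator is a pure function of its spec: identical specs (including
the seed) give bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from skimage import draw as _draw

from .contractility import IntensityTrace
from .mito import MitoFeatureSet, MitoParticleFeatures, SkeletonFeatures, skeletonize_mask
from .respirometry import RespTrace
from . import skeleton_reference as _ref

__all__ = [
    "BeatTraceSpec",
    "MitoImageSpec",
    "RespTraceSpec",
    "OnsetTableSpec",
    "gen_beat_trace",
    "gen_beat_stack",
    "gen_mito_image",
    "gen_resp_trace",
    "gen_onset_table",
]


@dataclass(frozen=True)
class BeatTraceSpec:
    """Parameters of a synthetic contraction intensity trace.

    Defaults emulate a typical day-15 recording: 60 s at the 0.5-s video
    sampling interval, 10 a.u. contraction transients, slow stage drift
    (0.02 Hz, twice the pulse amplitude), sensor noise at 20% of the pulse
    amplitude, and mildly irregular beating (inter-beat CV 5%).

    ``pulse_width_s`` defaults to 80% of the beat period capped at 1.2 s
    (a contraction-relaxation transient occupies much of the cycle at fast
    rates but cannot outlast it); an explicit width longer than the period
    is rejected as unphysical.

    Noise is two-component Gaussian with total SD ``noise_sd``: a white
    per-frame part carrying ``noise_white_fraction`` of the SD (photon and
    readout noise, small for a mean over thousands of ROI pixels) plus a
    slow part with ``noise_correlation_s`` correlation time (texture and
    sample-motion wobble, which dominates at this magnitude and has little
    power at the frame rate). Set ``noise_white_fraction = 1`` for pure
    white noise.
    """

    bpm_true: float
    duration_s: float = 60.0
    dt_s: float = 0.5
    pulse_width_s: Optional[float] = None
    pulse_amplitude: float = 10.0
    drift_amplitude: float = 20.0
    drift_freq_hz: float = 0.02
    noise_sd: float = 2.0
    noise_correlation_s: float = 2.0
    noise_white_fraction: float = 0.3
    irregularity_cv: float = 0.05
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bpm_true <= 0:
            raise ValueError("bpm_true must be positive")
        if self.dt_s <= 0 or self.duration_s <= 0:
            raise ValueError("dt_s and duration_s must be positive")
        if self.bpm_true / 60.0 >= 0.5 / self.dt_s:
            raise ValueError(
                f"bpm_true={self.bpm_true} at dt={self.dt_s}s violates the Nyquist "
                f"limit ({30.0 / self.dt_s:.1f} BPM): beats cannot be resolved"
            )
        if self.duration_s < 2 * 60.0 / self.bpm_true:
            raise ValueError("duration_s must cover at least two beat periods")
        if self.pulse_width_s is not None:
            if self.pulse_width_s < 0:
                raise ValueError("pulse_width_s must be >= 0")
            if self.pulse_width_s > 60.0 / self.bpm_true:
                raise ValueError(
                    "pulse_width_s exceeds the beat period: a contraction "
                    "transient cannot outlast its cycle"
                )
        for name in ("pulse_amplitude", "drift_amplitude", "noise_sd",
                     "noise_correlation_s", "irregularity_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.noise_white_fraction <= 1.0):
            raise ValueError("noise_white_fraction must be in [0, 1]")

    @property
    def effective_pulse_width_s(self) -> float:
        """Explicit width, or 80% of the beat period capped at 1.2 s."""
        if self.pulse_width_s is not None:
            return self.pulse_width_s
        return min(1.2, 0.8 * 60.0 / self.bpm_true)


def _beat_times(spec: BeatTraceSpec, rng: np.random.Generator) -> np.ndarray:
    """Renewal-process beat times: gamma intervals with CV = irregularity_cv."""
    mu = 60.0 / spec.bpm_true
    t = mu / 2.0  # first beat half a period in, so a clean trace holds
    times = []    # exactly round(bpm * duration / 60) beats
    if spec.irregularity_cv == 0:
        while t < spec.duration_s:
            times.append(t)
            t += mu
    else:
        shape = 1.0 / spec.irregularity_cv**2
        scale = mu * spec.irregularity_cv**2
        while t < spec.duration_s:
            times.append(t)
            t += rng.gamma(shape, scale)
    return np.array(times)


def gen_beat_trace(spec: BeatTraceSpec) -> tuple[IntensityTrace, np.ndarray]:
    """Synthetic ROI intensity trace plus the exact beat times.

    The trace is ``baseline + raised-cosine pulse train + sinusoidal drift +
    Gaussian noise`` sampled on the grid ``0, dt, ..., (n-1) dt`` with
    ``n = round(duration / dt)``.
    """
    rng = np.random.default_rng(spec.seed)
    drift_phase = rng.uniform(0.0, 2.0 * math.pi)  # always drawn: stable stream
    beats = _beat_times(spec, rng)
    n = int(round(spec.duration_s / spec.dt_s))
    times = np.arange(n) * spec.dt_s
    values = np.full(n, spec.baseline, dtype=float)
    if spec.drift_amplitude > 0:
        values += spec.drift_amplitude * np.sin(
            2.0 * math.pi * spec.drift_freq_hz * times + drift_phase
        )
    w = spec.effective_pulse_width_s
    if spec.pulse_amplitude > 0 and w > 0:
        for tb in beats:
            lo = max(0, int(math.ceil((tb - w / 2) / spec.dt_s)))
            hi = min(n - 1, int(math.floor((tb + w / 2) / spec.dt_s)))
            if hi < lo:
                continue
            tt = times[lo : hi + 1]
            values[lo : hi + 1] += (
                spec.pulse_amplitude / 2.0 * (1.0 + np.cos(2.0 * math.pi * (tt - tb) / w))
            )
    if spec.noise_sd > 0:
        f = spec.noise_white_fraction
        white = rng.normal(0.0, 1.0, n)
        noise = f * white
        if f < 1.0:
            slow = rng.normal(0.0, 1.0, n)
            k = int(round(spec.noise_correlation_s / spec.dt_s))
            if k >= 2:
                kernel = np.hanning(k + 2)[1:-1]
                slow = np.convolve(slow, kernel / kernel.sum(), mode="same")
                slow = slow / slow.std()  # unit SD after smoothing
            noise = noise + math.sqrt(1.0 - f * f) * slow
        values += spec.noise_sd * noise
    trace = IntensityTrace(times=times, values=values)
    return trace, beats


def gen_beat_stack(
    spec: BeatTraceSpec,
    frame_shape: tuple[int, int] = (256, 256),
    roi_bounds: tuple[int, int, int, int] = (96, 96, 64, 64),
    background: int = 50,
) -> tuple[np.ndarray, IntensityTrace, np.ndarray]:
    """16-bit grayscale image stack whose ROI pixels follow a beat trace.

    ``roi_bounds`` is ``(x, y, width, height)`` (half-open). Pixels inside the
    ROI carry the trace value rounded to the stored bit depth; all other
    pixels are a constant background. Returns (stack, trace, beat_times).
    """
    x, y, w, h = (int(v) for v in roi_bounds)
    height, width = frame_shape
    if w <= 0 or h <= 0:
        raise ValueError("ROI is empty (width and height must be >= 1)")
    if x < 0 or y < 0 or x + w > width or y + h > height:
        raise ValueError("ROI lies outside the frame bounds")
    trace, beats = gen_beat_trace(spec)
    stack = np.full((trace.n, height, width), background, dtype=np.uint16)
    vals = np.clip(np.rint(trace.values), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    stack[:, y : y + h, x : x + w] = vals[:, None, None]
    return stack, trace, beats


@dataclass(frozen=True)
class MitoImageSpec:
    """Canvas plus line / filled-rectangle primitives (all integer coords).

    Primitives are tuples ``("line", r0, c0, r1, c1)`` (1-px 8-connected
    segment, endpoints inclusive) or ``("rect", r0, c0, r1, c1)`` (filled,
    bounds inclusive). Overlaps are allowed; anything outside the canvas is
    rejected.
    """

    canvas_size: tuple[int, int] = (64, 64)
    primitives: tuple[tuple, ...] = ()
    foreground: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.canvas_size
        if rows < 1 or cols < 1:
            raise ValueError("canvas must be at least 1x1")
        object.__setattr__(self, "primitives", tuple(tuple(p) for p in self.primitives))
        for prim in self.primitives:
            kind, r0, c0, r1, c1 = prim
            if kind not in ("line", "rect"):
                raise ValueError(f"unknown primitive kind {kind!r}")
            for r, c in ((r0, c0), (r1, c1)):
                if not (0 <= r < rows and 0 <= c < cols):
                    raise ValueError(f"primitive {prim!r} lies outside the canvas")


def render_mito_mask(spec: MitoImageSpec) -> np.ndarray:
    """Boolean foreground mask rendered from the spec's primitives."""
    mask = np.zeros(spec.canvas_size, dtype=bool)
    for kind, r0, c0, r1, c1 in spec.primitives:
        if kind == "line":
            rr, cc = _draw.line(r0, c0, r1, c1)
        else:
            rr, cc = _draw.rectangle((min(r0, r1), min(c0, c1)),
                                     end=(max(r0, r1), max(c0, c1)))
            rr, cc = rr.astype(int).ravel(), cc.astype(int).ravel()
        mask[rr, cc] = True
    return mask


def gen_mito_image(spec: MitoImageSpec) -> tuple[np.ndarray, MitoFeatureSet]:
    """Render a binary-foreground image and its independent ground truth.

    Particle features (areas, perimeters, solidity) come from BFS flood fill,
    Moore tracing, and brute-force hull lattice counting; skeleton features
    come from the exhaustive networkx pixel-graph summary — all in
    :mod:`cmquant.skeleton_reference`, none shared with the analysis code.
    """
    mask = render_mito_mask(spec)
    image = np.where(mask, spec.foreground, 0).astype(np.uint16)
    regions = _ref.label_regions_bfs(mask)
    areas = np.array([float(len(r)) for r in regions])
    perims = np.array([_ref.perimeter_reference(r) for r in regions])
    solidity = np.array([_ref.solidity_reference(r) for r in regions])
    particles = MitoParticleFeatures(
        count=len(regions), areas=areas, perimeters=perims, solidity=solidity
    )
    summary = _ref.summarize_skeleton_reference(skeletonize_mask(mask))
    skeleton = SkeletonFeatures(
        n_branches=summary.n_branches,
        branch_lengths=np.array(summary.branch_lengths),
        node_degrees=np.array(summary.node_degrees, dtype=int),
        avg_node_degree=summary.avg_node_degree,
    )
    return image, MitoFeatureSet(particles=particles, skeleton=skeleton)


# state sequence accepted by the generator: the coupling-control protocol
_RESP_STATE_ORDER = ("basal", "leak", "et", "post_rotenone", "rox")


@dataclass(frozen=True)
class RespTraceSpec:
    """Piecewise-linear chamber O2 record specification.

    ``state_slopes`` is an ordered list of ``(state, slope, duration_s)`` with
    states ``basal, leak, et (one or more), post_rotenone, rox`` and slopes in
    nmol/mL/s (<= 0: oxygen is only consumed). Between states the slope blends
    linearly over ``ramp_samples`` samples (injection mixing artifact), which
    is why stable-window search is required downstream. Defaults emulate an
    O2k record: 2-s sampling, air-saturated medium (200 nmol/mL), basal flux
    ~80 pmol s^-1 per 10^6 cells.
    """

    state_slopes: tuple[tuple[str, float, float], ...] = (
        ("basal", -0.080, 300.0),
        ("leak", -0.020, 300.0),
        ("et", -0.100, 300.0),
        ("et", -0.140, 300.0),
        ("et", -0.120, 300.0),
        ("post_rotenone", -0.015, 240.0),
        ("rox", -0.010, 300.0),
    )
    dt_s: float = 2.0
    noise_sd: float = 0.0
    o2_start: float = 200.0
    cell_density: float = 1.0
    ramp_samples: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.noise_sd < 0 or self.ramp_samples < 0:
            raise ValueError("noise_sd and ramp_samples must be >= 0")
        if self.cell_density <= 0:
            raise ValueError("cell_density must be positive")
        states = tuple(tuple(s) for s in self.state_slopes)
        object.__setattr__(self, "state_slopes", states)
        labels = [s[0] for s in states]
        for label, slope, dur in states:
            if slope > 0:
                raise ValueError(f"state {label!r} has positive slope (O2 produced)")
            if dur <= 0:
                raise ValueError(f"state {label!r} has non-positive duration")
        n_et = labels.count("et")
        expected = ["basal", "leak"] + ["et"] * n_et + ["post_rotenone", "rox"]
        if labels != expected or n_et < 1:
            raise ValueError(
                "state order must follow the protocol: basal, leak, et (>=1), "
                f"post_rotenone, rox; got {labels}"
            )


# chemical injected at the start of each post-basal state
_STATE_EVENT = {
    "leak": "oligomycin",
    "et": "fccp",
    "post_rotenone": "rotenone",
    "rox": "antimycin_a",
}


def gen_resp_trace(spec: RespTraceSpec) -> tuple[RespTrace, dict]:
    """Piecewise-linear O2 record with events, plus the true per-state OCR.

    Truth is ``{-slope / cell_density}`` per state:
    ``{"basal": x, "leak": x, "et": [per FCCP step], "rox": x}``.
    """
    rng = np.random.default_rng(spec.seed)
    slopes: list[float] = []
    events: list[tuple[float, str]] = []
    prev_slope: Optional[float] = None
    for label, slope, dur in spec.state_slopes:
        n_state = int(round(dur / spec.dt_s))
        t_start = len(slopes) * spec.dt_s
        if label != "basal":
            events.append((t_start, _STATE_EVENT[label]))
        seg = np.full(n_state, slope)
        if prev_slope is not None and spec.ramp_samples > 0:
            k = min(spec.ramp_samples, n_state)
            seg[:k] = prev_slope + (np.arange(1, k + 1) / (spec.ramp_samples + 1)) * (
                slope - prev_slope
            )
        slopes.extend(seg.tolist())
        prev_slope = slope
    slopes_arr = np.array(slopes)
    n = slopes_arr.size
    times = np.arange(n) * spec.dt_s
    o2 = spec.o2_start + np.concatenate([[0.0], np.cumsum(slopes_arr[:-1] * spec.dt_s)])
    if spec.noise_sd > 0:
        o2 = o2 + rng.normal(0.0, spec.noise_sd, n)
    trace = RespTrace(
        times=times, o2=o2, events=tuple(events), cell_density=spec.cell_density
    )
    truth: dict = {"et": []}
    for label, slope, _ in spec.state_slopes:
        ocr = -slope / spec.cell_density
        if label == "et":
            truth["et"].append(ocr)
        elif label in ("basal", "leak", "rox"):
            truth[label] = ocr
    return trace, truth


@dataclass(frozen=True)
class OnsetTableSpec:
    """Per-well beating-onset sampling design.

    ``onset_pmf`` maps each group to ``{day: probability of first beating on
    that day}``; the remaining probability mass is "never beats". Defaults
    follow the reported differentiation kinetics: the light-treated group
    shows first onsets around day 8 and a day-15 peak at 42% of wells, the
    control group starts later with a lower, flatter profile.
    """

    n_wells_per_replicate: int = 30
    n_replicates: int = 3
    onset_pmf: tuple[tuple[str, tuple[tuple[int, float], ...]], ...] = (
        (
            "control",
            ((10, 0.02), (11, 0.03), (12, 0.05), (13, 0.07), (14, 0.10),
             (15, 0.15), (16, 0.10), (17, 0.06)),
        ),
        (
            "light",
            ((8, 0.02), (9, 0.03), (10, 0.05), (11, 0.05), (12, 0.06),
             (13, 0.08), (14, 0.10), (15, 0.42), (16, 0.05), (17, 0.03)),
        ),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells_per_replicate < 1 or self.n_replicates < 1:
            raise ValueError("well and replicate counts must be >= 1")
        pmf = tuple((g, tuple((int(d), float(p)) for d, p in dist))
                    for g, dist in self.onset_pmf)
        object.__setattr__(self, "onset_pmf", pmf)
        for group, dist in pmf:
            probs = [p for _, p in dist]
            if any(p < 0 for p in probs):
                raise ValueError(f"group {group!r} has negative probabilities")
            if sum(probs) > 1.0 + 1e-12:
                raise ValueError(f"group {group!r} probabilities sum above 1")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.onset_pmf)


def gen_onset_table(spec: OnsetTableSpec) -> pd.DataFrame:
    """Sample one row per (replicate, group, well): onset day or missing.

    Well labels are unique within a replicate across groups (group-initial
    prefix), so (replicate, well) identifies a row.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, dist in spec.onset_pmf:
        days = [d for d, _ in dist]
        probs = [p for _, p in dist]
        p_never = max(0.0, 1.0 - sum(probs))
        outcomes = days + [-1]  # -1 encodes "never beats"
        pvec = np.array(probs + [p_never])
        pvec = pvec / pvec.sum()
        for rep in range(spec.n_replicates):
            draws = rng.choice(outcomes, size=spec.n_wells_per_replicate, p=pvec)
            for i, day in enumerate(draws):
                rows.append(
                    {
                        "replicate": f"R{rep + 1}",
                        "group": group,
                        "well": f"{group[:1].upper()}{i + 1:02d}",
                        "onset_day": pd.NA if day < 0 else int(day),
                    }
                )
    table = pd.DataFrame(rows)
    table["onset_day"] = pd.array(table["onset_day"], dtype="Int64")
    return table
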