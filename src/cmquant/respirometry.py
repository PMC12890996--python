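"""High-resolution respirometry state analysis (closed-chamber O2 records).

A coupling-control protocol on suspended cells records chamber oxygen
concentration while inhibitors are injected in sequence: basal (routine)
respiration first, oligomycin to expose proton leak, stepwise FCCP titration
to reach the maximal capacity of the electron transport system, then rotenone
and antimycin A to measure residual (non-mitochondrial, ROX) oxygen
consumption. Oxygen declines piecewise-linearly; the oxygen consumption rate
(OCR) in each state is the negative slope of the O2 record over a stable
window, normalized per 10^6 cells.

Pipeline: ``locate_states`` splits the record at injection events (with a
post-injection guard band for mixing artifacts), ``find_stable_window``
selects the 45-sample window with the smallest linear-fit residual inside
each state segment, ``ocr_from_slope`` converts slopes to OCR, and
``summarize_respiration`` derives basal / leak / maximal / residual
respiration with ROX-corrected values reported alongside the raw ones.

Units: O2 in nmol/mL, time in seconds, cell density in 10^6 cells/mL, so
OCR = -slope / density is in nmol O2 s^-1 per 10^6 cells (equivalently
pmol s^-1 per 10^3 cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RespTrace",
    "RespConfig",
    "StateOCR",
    "RespirationSummary",
    "PROTOCOL_EVENT_ORDER",
    "WINDOW_POINTS",
    "locate_states",
    "find_stable_window",
    "ocr_from_slope",
    "summarize_respiration",
    "analyze_resp_trace",
]

#: protocol-pinned averaging window: OCR is computed over exactly 45 samples
WINDOW_POINTS = 45

#: required injection order for the coupling-control protocol
PROTOCOL_EVENT_ORDER = ("oligomycin", "fccp", "rotenone", "antimycin_a")


@dataclass(frozen=True)
class RespTrace:
    """Chamber O2 record with injection events.

    ``events`` is a list of ``(time_s, label)`` with labels from
    ``{oligomycin, fccp, rotenone, antimycin_a}``; fccp may repeat (titration
    steps). ``cell_density`` is in 10^6 cells/mL.
    """

    times: np.ndarray
    o2: np.ndarray
    events: tuple[tuple[float, str], ...]
    cell_density: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        o2 = np.asarray(self.o2, dtype=float)
        if t.ndim != 1 or t.size != o2.size or t.size < 2:
            raise ValueError("times and o2 must be equal-length 1-D arrays (>= 2)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.cell_density <= 0:
            raise ValueError("cell_density must be positive")
        ev = tuple((float(et), str(lab)) for et, lab in self.events)
        for et, lab in ev:
            if lab not in PROTOCOL_EVENT_ORDER:
                raise ValueError(f"unknown event label {lab!r}")
            if not (t[0] <= et <= t[-1]):
                raise ValueError(f"event {lab!r} at t={et} outside the record")
        if any(ev[i][0] > ev[i + 1][0] for i in range(len(ev) - 1)):
            raise ValueError("events must be time-ordered")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "o2", o2)
        object.__setattr__(self, "events", ev)

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class RespConfig:
    """Analysis settings: window length (protocol constant 45), guard band."""

    window_points: int = WINDOW_POINTS
    guard_samples: int = 10

    def __post_init__(self) -> None:
        if self.window_points < 3:
            raise ValueError("window_points must be >= 3")
        if self.guard_samples < 0:
            raise ValueError("guard_samples must be >= 0")
        if self.window_points != WINDOW_POINTS:
            warnings.warn(
                f"window_points={self.window_points} deviates from the protocol "
                f"constant {WINDOW_POINTS}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class StateOCR:
    """OCR in one bioenergetic state, from a fixed-width stable window."""

    state: str  # basal | leak | et_max | rox (et sub-steps report as et_max candidates)
    window: tuple[int, int]  # absolute sample-index range [start, stop)
    ocr: float  # nmol O2 s^-1 (10^6 cells)^-1
    fit_residual_sd: float
    ocr_se: float  # standard error of the OCR from the window fit


@dataclass(frozen=True)
class RespirationSummary:
    """Derived respiration parameters (raw and ROX-corrected)."""

    basal: float
    leak: float
    maximal: float
    residual: float
    basal_corrected: float
    leak_corrected: float
    maximal_corrected: float
    negative_corrected_flags: tuple[str, ...] = ()


def _event_indices(trace: RespTrace) -> dict[str, list[int]]:
    by_label: dict[str, list[int]] = {}
    for et, lab in trace.events:
        idx = int(np.searchsorted(trace.times, et, side="left"))
        by_label.setdefault(lab, []).append(idx)
    return by_label


def locate_states(
    trace: RespTrace, guard_samples: int = 10
) -> dict[str, list[tuple[int, int]]]:
    """Split the record into per-state sample-index segments.

    Returns ``{"basal": [seg], "leak": [seg], "et": [seg per FCCP step],
    "rox": [seg]}`` with half-open index ranges. A guard band of
    ``guard_samples`` after each injection is excluded (mixing artifacts).
    The rotenone -> antimycin_a span is not assigned to any state.
    """
    ev = _event_indices(trace)
    for lab in ("oligomycin", "fccp", "rotenone", "antimycin_a"):
        if lab not in ev:
            raise ValueError(f"missing protocol event: {lab!r}")
    for lab in ("oligomycin", "rotenone", "antimycin_a"):
        if len(ev[lab]) != 1:
            raise ValueError(f"event {lab!r} must occur exactly once")
    i_oligo = ev["oligomycin"][0]
    i_fccp = sorted(ev["fccp"])
    i_rot = ev["rotenone"][0]
    i_anti = ev["antimycin_a"][0]
    if not (i_oligo < i_fccp[0]):
        raise ValueError("protocol order violated: 'fccp' must follow 'oligomycin'")
    if not (i_fccp[-1] < i_rot):
        raise ValueError("protocol order violated: 'rotenone' must follow 'fccp'")
    if not (i_rot < i_anti):
        raise ValueError("protocol order violated: 'antimycin_a' must follow 'rotenone'")
    n = trace.times.size
    segments: dict[str, list[tuple[int, int]]] = {
        "basal": [(0, i_oligo)],
        "leak": [(min(i_oligo + guard_samples, n), i_fccp[0])],
        "et": [],
        "rox": [(min(i_anti + guard_samples, n), n)],
    }
    fccp_bounds = i_fccp + [i_rot]
    for k in range(len(i_fccp)):
        start = min(i_fccp[k] + guard_samples, n)
        segments["et"].append((start, fccp_bounds[k + 1]))
    for state, segs in segments.items():
        for a, b in segs:
            if b <= a:
                raise ValueError(f"state {state!r} segment is empty after guard band")
    return segments


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares line fit: slope, intercept, residual SD, slope SE."""
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    n = t.size
    resid_sd = float(np.sqrt(np.sum(resid**2) / max(n - 2, 1)))
    sxx = float(np.sum((t - t.mean()) ** 2))
    slope_se = resid_sd / np.sqrt(sxx) if sxx > 0 else np.inf
    return float(slope), float(intercept), resid_sd, float(slope_se)


def find_stable_window(
    times: np.ndarray, o2: np.ndarray, width: int = WINDOW_POINTS
) -> tuple[int, float, float, float]:
    """Most-linear contiguous window of exactly ``width`` samples.

    Scans every window of ``width`` samples, fits an ordinary least-squares
    line, and returns ``(start_index, slope, residual_sd, slope_se)`` for the
    window with the smallest residual SD. Ties break to the earliest window;
    residuals within a rounding-level tolerance of the minimum count as tied,
    so an exactly linear segment returns its first window.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(o2, dtype=float)
    n = t.size
    if n < width:
        raise ValueError(
            f"segment has {n} samples but the averaging window needs {width}; "
            "reduce the guard band or the window width"
        )
    fits = [
        _ols_line(t[start : start + width], y[start : start + width])
        for start in range(n - width + 1)
    ]
    rsds = np.array([f[2] for f in fits])
    tol = rsds.min() * 1e-6 + 1e-10 * max(1.0, float(np.max(np.abs(y))))
    start = int(np.argmax(rsds <= rsds.min() + tol))  # earliest within tolerance
    slope, _, rsd, se = fits[start]
    return start, slope, rsd, se


def ocr_from_slope(slope: float, cell_density: float) -> float:
    """OCR = -slope / cell_density (nmol O2 s^-1 per 10^6 cells)."""
    if cell_density <= 0:
        raise ValueError("cell_density must be positive")
    return -slope / cell_density


def _state_ocr(
    trace: RespTrace, seg: tuple[int, int], state: str, width: int
) -> StateOCR:
    a, b = seg
    start, slope, rsd, se = find_stable_window(
        trace.times[a:b], trace.o2[a:b], width=width
    )
    return StateOCR(
        state=state,
        window=(a + start, a + start + width),
        ocr=ocr_from_slope(slope, trace.cell_density),
        fit_residual_sd=rsd,
        ocr_se=se / trace.cell_density,
    )


def summarize_respiration(state_ocrs: dict[str, list[StateOCR]]) -> RespirationSummary:
    """Derive basal / leak / maximal / residual respiration.

    ``maximal`` is the largest OCR across FCCP titration steps (the uncoupler
    optimum). Corrected values subtract residual (ROX) respiration and are
    reported even when negative, with a flag.
    """
    for state in ("basal", "leak", "et", "rox"):
        if not state_ocrs.get(state):
            raise ValueError(f"missing state group: {state!r}")
    basal = state_ocrs["basal"][0].ocr
    leak = state_ocrs["leak"][0].ocr
    maximal = max(s.ocr for s in state_ocrs["et"])
    residual = state_ocrs["rox"][0].ocr
    corrected = {
        "basal": basal - residual,
        "leak": leak - residual,
        "maximal": maximal - residual,
    }
    flags = tuple(name for name, v in corrected.items() if v < 0)
    return RespirationSummary(
        basal=basal,
        leak=leak,
        maximal=maximal,
        residual=residual,
        basal_corrected=corrected["basal"],
        leak_corrected=corrected["leak"],
        maximal_corrected=corrected["maximal"],
        negative_corrected_flags=flags,
    )


def analyze_resp_trace(
    trace: RespTrace, cfg: Optional[RespConfig] = None
) -> tuple[dict[str, list[StateOCR]], RespirationSummary]:
    """Full pipeline: locate states, fit stable windows, summarize."""
    cfg = cfg or RespConfig()
    segments = locate_states(trace, guard_samples=cfg.guard_samples)
    state_ocrs: dict[str, list[StateOCR]] = {}
    for state, segs in segments.items():
        state_ocrs[state] = [
            _state_ocr(trace, seg, state, cfg.window_points) for seg in segs
        ]
    return state_ocrs, summarize_respiration(state_ocrs)
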