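"""Calcium transient detection and per-culture activity statistics.

Traces are first normalised to ΔF/F against a running-percentile baseline,
then events are extracted with a two-threshold (hysteresis) detector: an
oscillation opens when ΔF/F rises to ``theta_on`` and closes when it falls
below ``theta_off``.  A cell with at least one detected oscillation counts
as "working"; oscillation frequency is events per minute over working cells
and duration is the onset-to-offset interval in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import percentile_filter

from .errors import NonPositiveFluorescenceError

__all__ = [
    "NormalizedTrace",
    "CalciumEvent",
    "ActivitySummary",
    "compute_dff",
    "detect_events",
    "detect_recording",
    "summarize_activity",
    "match_events",
]

#: default detector settings (ΔF/F thresholds, minimum event length)
THETA_ON = 0.2
THETA_OFF = 0.1
MIN_DURATION_S = 1.0
BASELINE_WINDOW_S = 60.0
BASELINE_PERCENTILE = 20.0


@dataclass
class NormalizedTrace:
    cell_id: int
    dff: np.ndarray       # ΔF/F per frame
    baseline: np.ndarray  # running F0, a.u.
    frame_rate: float


@dataclass(frozen=True)
class CalciumEvent:
    cell_id: int
    onset_frame: int
    offset_frame: int
    duration: float   # s, (offset - onset) / frame_rate
    peak_dff: float


@dataclass
class ActivitySummary:
    percent_working: float
    durations: np.ndarray       # s, all events pooled over the culture
    frequencies: np.ndarray     # osc/min, one per working cell
    median_duration: float
    duration_iqr: tuple[float, float]
    median_frequency: float
    frequency_iqr: tuple[float, float]


def compute_dff(trace: np.ndarray, frame_rate: float,
                window_s: float = BASELINE_WINDOW_S,
                cell_id: int = -1) -> NormalizedTrace:
    """ΔF/F against a running 20th-percentile baseline.

    F0 is the 20th percentile of the raw trace in a centred window
    (default 60 s, clipped at the trace edges); dff = (F − F0) / F0.
    The percentile baseline tracks slow drift while sitting below the
    transients, so isolated events survive normalisation unattenuated.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)) or np.any(trace <= 0):
        raise NonPositiveFluorescenceError(
            f"cell {cell_id}: fluorescence must be finite and > 0")
    w = int(round(window_s * frame_rate))
    w = max(w | 1, 3)  # odd, at least 3 frames
    if len(trace) < 3:
        raise ValueError("trace shorter than the minimal baseline window")
    w = min(w, len(trace) if len(trace) % 2 else len(trace) - 1)
    f0 = percentile_filter(trace, BASELINE_PERCENTILE, size=w, mode="nearest")
    return NormalizedTrace(cell_id=cell_id, dff=(trace - f0) / f0,
                           baseline=f0, frame_rate=frame_rate)


def detect_events(normalized: NormalizedTrace,
                  theta_on: float = THETA_ON,
                  theta_off: float = THETA_OFF,
                  min_duration_s: float = MIN_DURATION_S,
                  ) -> list[CalciumEvent]:
    """Hysteresis event detection on a ΔF/F trace.

    An event opens at the first frame with dff ≥ ``theta_on`` and closes at
    the first subsequent frame with dff < ``theta_off`` (or at the end of
    the trace).  Events shorter than ``min_duration_s`` are discarded; the
    returned list is disjoint and time-ordered.
    """
    if not theta_on > theta_off > 0:
        raise ValueError("need theta_on > theta_off > 0")
    dff = normalized.dff
    fr = normalized.frame_rate
    events: list[CalciumEvent] = []
    n = len(dff)
    i = 0
    while i < n:
        if dff[i] >= theta_on:
            onset = i
            j = i + 1
            while j < n and dff[j] >= theta_off:
                j += 1
            offset = j  # first frame below theta_off, or n
            duration = (offset - onset) / fr
            if duration >= min_duration_s:
                events.append(CalciumEvent(
                    cell_id=normalized.cell_id, onset_frame=onset,
                    offset_frame=offset, duration=duration,
                    peak_dff=float(np.max(dff[onset:offset]))))
            i = offset + 1
        else:
            i += 1
    return events


def detect_recording(recording, theta_on: float = THETA_ON,
                     theta_off: float = THETA_OFF,
                     min_duration_s: float = MIN_DURATION_S,
                     window_s: float = BASELINE_WINDOW_S,
                     ) -> dict[int, list[CalciumEvent]]:
    """Run ΔF/F normalisation and event detection on every cell of a recording."""
    out: dict[int, list[CalciumEvent]] = {}
    for i, cell in enumerate(recording.cells):
        norm = compute_dff(recording.traces[:, i], recording.frame_rate,
                           window_s=window_s, cell_id=cell.cell_id)
        out[cell.cell_id] = detect_events(norm, theta_on, theta_off,
                                          min_duration_s)
    return out


def summarize_activity(events_by_cell: dict[int, list[CalciumEvent]],
                       n_cells: int, duration_s: float) -> ActivitySummary:
    """Culture-level activity statistics.

    percent_working = 100 × (cells with ≥1 event) / n_cells.  Frequency
    (osc/min) is computed over working cells only; duration pools every
    event in the culture.  Centres are medians with (Q1, Q3).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    working = [cid for cid, evs in events_by_cell.items() if len(evs) > 0]
    percent = 100.0 * len(working) / n_cells
    durations = np.array([e.duration for evs in events_by_cell.values()
                          for e in evs])
    freqs = np.array([len(events_by_cell[cid]) / (duration_s / 60.0)
                      for cid in working])

    def _med_iqr(v: np.ndarray) -> tuple[float, tuple[float, float]]:
        if v.size == 0:
            return float("nan"), (float("nan"), float("nan"))
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return float(med), (float(q1), float(q3))

    med_d, iqr_d = _med_iqr(durations)
    med_f, iqr_f = _med_iqr(freqs)
    return ActivitySummary(percent_working=percent, durations=durations,
                           frequencies=freqs, median_duration=med_d,
                           duration_iqr=iqr_d, median_frequency=med_f,
                           frequency_iqr=iqr_f)


def match_events(true_onsets: np.ndarray, detected: list[CalciumEvent],
                 frame_rate: float, tol_s: float = 2.0,
                 ) -> tuple[float, float]:
    """Recall and precision of detected events against planted onsets.

    A planted onset is matched if some detected event starts within
    ``tol_s`` of it, or if the onset falls inside the detected interval
    (overlapping transients merge under hysteresis detection); a detected
    event is a true positive if it matches at least one planted onset.
    Returns ``(recall, precision)``; vacuous denominators give 1.0.
    """
    true_onsets = np.asarray(true_onsets, dtype=float)
    matched_true = 0
    for t0 in true_onsets:
        for e in detected:
            on_s = e.onset_frame / frame_rate
            off_s = e.offset_frame / frame_rate
            if abs(on_s - t0) <= tol_s or on_s <= t0 <= off_s:
                matched_true += 1
                break
    matched_det = 0
    for e in detected:
        on_s = e.onset_frame / frame_rate
        off_s = e.offset_frame / frame_rate
        if np.any((np.abs(on_s - true_onsets) <= tol_s)
                  | ((true_onsets >= on_s) & (true_onsets <= off_s))):
            matched_det += 1
    recall = matched_true / len(true_onsets) if len(true_onsets) else 1.0
    precision = matched_det / len(detected) if detected else 1.0
    return recall, precision
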