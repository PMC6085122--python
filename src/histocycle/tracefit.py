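"""Cell-cycle segmentation of nuclear-reporter traces.

A cycling cell shows a fluorescence plateau while unbudded, a linear ramp as
the reporter pool doubles during replication, a second plateau, and a sudden
drop when the nucleus divides.  This module detects the drops, fits the
continuous plateau-ramp-plateau model between consecutive drops by exhaustive
breakpoint search, converts breakpoints into the four phase durations
(cytokinesis is placed a fixed offset after the end of the drop), and applies
explicit quality control.

Frames are 0-based; intervals are half-open ``[start, end)`` in minutes;
breakpoints live on the acquisition frame grid (no sub-frame interpolation).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .simkit import Trace

__all__ = [
    "DropEvent",
    "PhaseSegmentation",
    "QCPolicy",
    "detect_anaphase_drops",
    "fit_piecewise",
    "assign_phases",
    "segment_trace",
    "qc_filter",
]

DEFAULT_CYTO_OFFSET_MIN = 5.6  # cytokinesis follows the end of the drop by this


@dataclass(frozen=True)
class DropEvent:
    """A detected anaphase fluorescence drop (frame indices, inclusive)."""

    onset: int
    end: int


@dataclass
class PhaseSegmentation:
    """Fitted plateau-ramp-plateau model of one cell-cycle window."""

    cell_id: str
    cycle_index: int
    t_cyto_prev: float  # minutes; NaN if the previous cytokinesis is unknown
    t1: float  # ramp onset (S start)
    t2: float  # ramp end (S end)
    t_ana: float  # anaphase onset (drop onset)
    t_ana_end: float  # end of the drop
    F1: float  # pre-ramp plateau level
    F2: float  # post-ramp plateau level
    ramp_slope: float
    rss: float
    r2: float
    T_G1: float = math.nan
    T_S: float = math.nan
    T_G2M: float = math.nan
    T_Ana: float = math.nan
    qc_pass: bool = False
    qc_reason: str = ""

    @property
    def plateau_ratio(self) -> float:
        return self.F2 / self.F1 if self.F1 else math.inf


@dataclass
class QCPolicy:
    """Explicit pass/fail rules (the published pass rate came with no stated
    criteria, so the policy is spelled out here and fully configurable)."""

    r2_min: float = 0.85
    ratio_min: float = 1.5
    ratio_max: float = 2.7
    min_cycle_min: float = 30.0
    max_cycle_min: float = 400.0
    min_phase_frames: int = 1
    frame_interval_min: float = 3.0
    require_positive_slope: bool = True
    require_prev_cytokinesis: bool = True


# ---------------------------------------------------------------------------
# drop detection
# ---------------------------------------------------------------------------

def detect_anaphase_drops(
    trace: Trace,
    drop_frac: float = 0.25,
    min_cycle_frames: int = 10,
    max_drop_frames: int = 6,
) -> list[DropEvent]:
    """Locate sudden fluorescence drops (nuclear divisions).

    A frame is a drop candidate when F falls by more than ``drop_frac`` of
    its local 3-frame median within at most 2 frames.  Candidate runs are
    merged into events; the event ends at the signal minimum within
    ``max_drop_frames`` of the onset.  Events closer than
    ``min_cycle_frames`` are merged, keeping the larger drop.
    """
    F = np.asarray(trace.F, dtype=float)
    n = len(F)
    if n == 0:
        raise ValueError("empty trace")
    if n < 10:
        raise ValueError(f"trace too short for drop detection ({n} frames)")
    med3 = np.array([np.median(F[max(0, i - 1):i + 2]) for i in range(n)])
    cand = np.zeros(n, dtype=bool)
    for i in range(n - 1):
        thr = drop_frac * med3[i]
        if thr <= 0:
            continue
        if F[i] - F[i + 1] > thr or (i + 2 < n and F[i] - F[i + 2] > thr):
            cand[i] = True

    events: list[DropEvent] = []
    i = 0
    while i < n:
        if not cand[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and (cand[j + 1] or (j + 2 < n and cand[j + 2])):
            j += 1
            if j - i >= max_drop_frames:
                break
        hi = min(i + max_drop_frames, n - 1)
        end = i + int(np.argmin(F[i:hi + 1]))
        events.append(DropEvent(onset=i, end=max(end, i + 1)))
        i = max(j, end) + 1

    # merge events that are implausibly close, keeping the larger drop
    merged: list[DropEvent] = []
    for ev in events:
        if merged and ev.onset - merged[-1].onset < min_cycle_frames:
            prev = merged[-1]
            size_prev = F[prev.onset] - F[prev.end]
            size_new = F[ev.onset] - F[ev.end]
            if size_new > size_prev:
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


# ---------------------------------------------------------------------------
# piecewise fit
# ---------------------------------------------------------------------------

def fit_piecewise(t: np.ndarray, F: np.ndarray, min_ramp_frames: int = 2):
    """Best continuous plateau-ramp-plateau fit on ``(t, F)``.

    Exhaustive search over breakpoint pairs ``(t1, t2)`` on the frame grid
    with ``t2 - t1 >= min_ramp_frames`` frames; for each pair the plateau
    level and ramp slope follow from closed-form least squares.  Ties in RSS
    are broken by the lexicographically earliest ``(t1, t2)``.

    Returns ``(i1, i2, F1, slope, rss, r2)`` with ``i1, i2`` frame indices.
    """
    t = np.asarray(t, dtype=float)
    F = np.asarray(F, dtype=float)
    n = len(t)
    if n < 6:
        raise ValueError(f"window too short to fit ({n} frames)")
    pairs_i, pairs_j = [], []
    for i in range(0, n - min_ramp_frames):
        for j in range(i + min_ramp_frames, n):
            pairs_i.append(i)
            pairs_j.append(j)
    pi = np.asarray(pairs_i)
    pj = np.asarray(pairs_j)
    t1 = t[pi]
    L = t[pj] - t1
    # ramp regressor g(t) = clip(t - t1, 0, t2 - t1), one row per pair
    G = np.clip(t[None, :] - t1[:, None], 0.0, L[:, None])
    Sg = G.sum(axis=1)
    Sgg = np.einsum("ij,ij->i", G, G)
    SgF = G @ F
    SF = F.sum()
    SFF = float(F @ F)
    denom = n * Sgg - Sg**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * SgF - Sg * SF) / denom
        F1 = (SF - slope * Sg) / n
    bad = ~np.isfinite(slope)
    rss = (
        SFF
        - 2.0 * (F1 * SF + slope * SgF)
        + n * F1**2
        + 2.0 * F1 * slope * Sg
        + slope**2 * Sgg
    )
    rss = np.where(bad, np.inf, np.maximum(rss, 0.0))
    if not np.any(np.isfinite(rss)):
        raise ValueError("all candidate fits are singular")
    rmin = rss.min()
    best = int(np.flatnonzero(rss <= rmin + 1e-12 * (abs(rmin) + 1.0))[0])
    tss = float(np.sum((F - F.mean()) ** 2))
    if tss > 0:
        r2 = 1.0 - rss[best] / tss
    else:
        r2 = 1.0 if rss[best] < 1e-12 else 0.0
    return int(pi[best]), int(pj[best]), float(F1[best]), float(slope[best]), float(rss[best]), float(r2)


def assign_phases(seg: PhaseSegmentation, cyto_offset_min: float = DEFAULT_CYTO_OFFSET_MIN) -> PhaseSegmentation:
    """Fill phase durations from fitted breakpoints.

    Cytokinesis is placed ``cyto_offset_min`` after the end of the drop, so
    ``T_Ana`` covers drop onset through cytokinesis and ``T_G1`` runs from the
    previous cytokinesis to the ramp onset.  An unknown previous cytokinesis
    leaves ``T_G1`` missing.
    """
    seg.T_S = seg.t2 - seg.t1
    seg.T_G2M = seg.t_ana - seg.t2
    seg.T_Ana = (seg.t_ana_end + cyto_offset_min) - seg.t_ana
    seg.T_G1 = seg.t1 - seg.t_cyto_prev if math.isfinite(seg.t_cyto_prev) else math.nan
    return seg


def segment_trace(
    trace: Trace,
    cell_id: str = "",
    birth_is_cytokinesis: bool = False,
    cyto_offset_min: float = DEFAULT_CYTO_OFFSET_MIN,
    drop_frac: float = 0.25,
    min_cycle_frames: int = 10,
) -> list[PhaseSegmentation]:
    """Segment every complete cycle (drop-to-drop window) of one trace.

    ``birth_is_cytokinesis=True`` declares the first frame a known
    cytokinesis (a cell born under observation), making the first cycle's G1
    measurable.  The stretch after the final drop is an incomplete cycle and
    is not fitted.
    """
    drops = detect_anaphase_drops(trace, drop_frac=drop_frac, min_cycle_frames=min_cycle_frames)
    t = trace.t
    segs: list[PhaseSegmentation] = []
    start = 0
    t_cyto_prev = float(t[0]) if birth_is_cytokinesis else math.nan
    for k, ev in enumerate(drops):
        win = slice(start, ev.onset + 1)  # fit on [window start, drop onset]
        tw, Fw = t[win], trace.F[win]
        if len(tw) < 6:
            seg = PhaseSegmentation(
                cell_id, k, t_cyto_prev,
                math.nan, math.nan, float(t[ev.onset]), float(t[ev.end]),
                math.nan, math.nan, math.nan, math.nan, math.nan,
                qc_reason="short",
            )
        else:
            try:
                i1, i2, F1, slope, rss, r2 = fit_piecewise(tw, Fw)
            except ValueError:
                seg = PhaseSegmentation(
                    cell_id, k, t_cyto_prev,
                    math.nan, math.nan, float(t[ev.onset]), float(t[ev.end]),
                    math.nan, math.nan, math.nan, math.nan, math.nan,
                    qc_reason="degenerate",
                )
            else:
                t1, t2 = float(tw[i1]), float(tw[i2])
                seg = PhaseSegmentation(
                    cell_id, k, t_cyto_prev, t1, t2,
                    float(t[ev.onset]), float(t[ev.end]),
                    F1, F1 + slope * (t2 - t1), slope, rss, r2,
                )
                assign_phases(seg, cyto_offset_min)
        segs.append(seg)
        start = ev.end
        t_cyto_prev = float(t[ev.end]) + cyto_offset_min
    return segs


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def _qc_reason(seg: PhaseSegmentation, policy: QCPolicy) -> str | None:
    if seg.qc_reason in ("short", "degenerate"):
        return seg.qc_reason
    if policy.require_prev_cytokinesis and not math.isfinite(seg.t_cyto_prev):
        return "missing_prev_cytokinesis"
    if not math.isfinite(seg.r2) or seg.r2 < policy.r2_min:
        return "low_r2"
    if policy.require_positive_slope and not seg.ramp_slope > 0:
        return "nonpositive_slope"
    ratio = seg.plateau_ratio
    if not (policy.ratio_min <= ratio <= policy.ratio_max):
        return "ratio_out_of_range"
    min_phase = policy.min_phase_frames * policy.frame_interval_min
    durations = [seg.T_S, seg.T_G2M, seg.T_Ana]
    if math.isfinite(seg.t_cyto_prev):
        durations.append(seg.T_G1)
    if any((not math.isfinite(d)) or d < min_phase for d in durations):
        return "short_phase"
    cycle_len = seg.T_G1 + seg.T_S + seg.T_G2M + seg.T_Ana
    if math.isfinite(cycle_len) and not (policy.min_cycle_min <= cycle_len <= policy.max_cycle_min):
        return "cycle_length_out_of_range"
    return None


def qc_filter(
    segs: Iterable[PhaseSegmentation], policy: QCPolicy | None = None
) -> tuple[list[PhaseSegmentation], list[PhaseSegmentation], Counter]:
    """Split segmentations into passed / rejected and tally rejection reasons."""
    policy = policy or QCPolicy()
    passed, rejected = [], []
    tally: Counter = Counter()
    for seg in segs:
        reason = _qc_reason(seg, policy)
        if reason is None:
            seg.qc_pass = True
            seg.qc_reason = ""
            passed.append(seg)
        else:
            seg.qc_pass = False
            seg.qc_reason = reason
            tally[reason] += 1
            rejected.append(seg)
    return passed, rejected, tally
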