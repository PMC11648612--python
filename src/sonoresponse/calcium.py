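"""Quantification of stimulus-evoked calcium transients from ROI traces.

Fluorescence time series (one trace per region of interest, nominally
sampled at 1 Hz from a GCaMP-type indicator) are normalized per stimulus as

    dF/F0 = (F(t) - F0) / F0

where F0 is the mean fluorescence over a pre-stimulus baseline window
(default 30 s).  The response magnitude is the sum of dF/F0 samples over a
post-stimulus window (default 10 s), reported in arbitrary units (AU), plus
the peak dF/F0 in the same window.  Group summaries average over session
means, the experimental unit being one imaging session.

All windows are half-open [start, stop) so every frame belongs to exactly
one window.  F0 is recomputed before each stimulus, so repeated stimuli
within one recording are each referenced to their own local baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateBaselineError,
    InsufficientBaselineError,
    InsufficientResponseWindowError,
    MissingDataError,
    OverlappingWindowsError,
)

__all__ = [
    "RoiTraceSet",
    "NormalizedTraces",
    "compute_f0",
    "normalize_dff",
    "response_auc",
    "response_peak",
    "response_table",
    "heatmap_matrix",
    "session_summary",
]


@dataclass
class RoiTraceSet:
    """Per-ROI raw fluorescence traces for one imaging session.

    Attributes
    ----------
    times : array of float
        Frame times in seconds, strictly increasing.
    raw : 2-D array
        Raw fluorescence, shape (n_rois, n_frames), strictly positive.
    stim_times : array of float
        Stimulus onset times in seconds.
    labels : list of str
        Per-ROI identifiers (defaults to roi0, roi1, ...).
    condition : str
        Free-text condition tag (e.g. "control", "BI-749327").
    """

    times: np.ndarray
    raw: np.ndarray
    stim_times: np.ndarray
    labels: Sequence[str] = field(default_factory=list)
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw = np.atleast_2d(np.asarray(self.raw, dtype=float))
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.raw.shape[1] != self.times.size:
            raise ValueError(
                f"raw has {self.raw.shape[1]} frames but times has {self.times.size}"
            )
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.raw <= 0):
            raise ValueError("raw fluorescence values must be strictly positive")
        if not self.labels:
            self.labels = [f"roi{i}" for i in range(self.raw.shape[0])]

    @property
    def n_rois(self) -> int:
        return self.raw.shape[0]

    def frame_interval(self) -> float:
        """Median inter-frame interval in seconds (nominal sampling period)."""
        if self.times.size < 2:
            raise ValueError("need at least two frames to estimate frame interval")
        return float(np.median(np.diff(self.times)))


@dataclass
class NormalizedTraces:
    """dF/F0-normalized traces with their per-ROI baseline."""

    times: np.ndarray
    dff: np.ndarray
    f0: np.ndarray
    stim_times: np.ndarray
    condition: str = ""

    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.times)))


def compute_f0(
    traces: RoiTraceSet, stim_time: float, baseline_window: float = 30.0
) -> np.ndarray:
    """Per-ROI baseline: mean raw fluorescence over the pre-stimulus window.

    The window is half-open, [stim_time - baseline_window, stim_time), and
    must lie entirely inside the recording (to within half a frame): a
    truncated baseline is refused rather than silently shortened.
    """
    start = stim_time - baseline_window
    mask = (traces.times >= start) & (traces.times < stim_time)
    if not mask.any():
        raise InsufficientBaselineError(
            f"no frames in baseline window [{start}, {stim_time}) s"
        )
    half_frame = 0.5 * traces.frame_interval() if traces.times.size >= 2 else 0.0
    if start < traces.times[0] - half_frame:
        raise InsufficientBaselineError(
            f"baseline window [{start}, {stim_time}) s starts before the "
            f"recording ({traces.times[0]} s)"
        )
    return traces.raw[:, mask].mean(axis=1)


def normalize_dff(
    traces: RoiTraceSet, stim_time: float, baseline_window: float = 30.0
) -> NormalizedTraces:
    """Normalize every trace to dF/F0 = (F - F0) / F0 for one stimulus."""
    f0 = compute_f0(traces, stim_time, baseline_window)
    if np.any(f0 <= 0):
        raise DegenerateBaselineError("per-ROI baseline F0 must be strictly positive")
    dff = (traces.raw - f0[:, None]) / f0[:, None]
    return NormalizedTraces(
        times=traces.times,
        dff=dff,
        f0=f0,
        stim_times=traces.stim_times,
        condition=traces.condition,
    )


def _response_mask(
    norm: NormalizedTraces, stim_time: float, response_window: float
) -> np.ndarray:
    mask = (norm.times >= stim_time) & (norm.times < stim_time + response_window)
    dt = norm.frame_interval()
    expected = int(round(response_window / dt))
    if mask.sum() < expected:
        raise InsufficientResponseWindowError(
            f"response window [{stim_time}, {stim_time + response_window}) s "
            f"contains {int(mask.sum())} frames, expected {expected} at the "
            "nominal frame rate"
        )
    return mask


def response_auc(
    norm: NormalizedTraces,
    stim_time: float,
    response_window: float = 10.0,
    method: Literal["sum", "trapezoid"] = "sum",
) -> np.ndarray:
    """Per-ROI response magnitude over the post-stimulus window, in AU.

    The default is a plain sum of the dF/F0 samples in
    [stim_time, stim_time + response_window); ``method="trapezoid"``
    integrates with the trapezoid rule (units AU x s) instead.
    """
    mask = _response_mask(norm, stim_time, response_window)
    if method == "sum":
        return norm.dff[:, mask].sum(axis=1)
    if method == "trapezoid":
        return np.trapezoid(norm.dff[:, mask], norm.times[mask], axis=1)
    raise ValueError(f"unknown AUC method {method!r}")


def response_peak(
    norm: NormalizedTraces, stim_time: float, response_window: float = 10.0
) -> np.ndarray:
    """Per-ROI peak dF/F0 in the post-stimulus window."""
    mask = _response_mask(norm, stim_time, response_window)
    return norm.dff[:, mask].max(axis=1)


def response_table(
    traces: RoiTraceSet,
    baseline_window: float = 30.0,
    response_window: float = 10.0,
    auc_method: Literal["sum", "trapezoid"] = "sum",
) -> pd.DataFrame:
    """One row per (ROI, stimulus): AUC and peak dF/F0.

    Each stimulus is re-baselined over its own pre-stimulus window.
    Stimuli whose response windows would overlap are refused rather than
    split heuristically.
    """
    stims = np.sort(traces.stim_times)
    if stims.size == 0:
        raise MissingDataError("trace set has no stimulus times")
    if stims.size >= 2 and np.any(np.diff(stims) < response_window):
        raise OverlappingWindowsError(
            "stimuli are closer than the response window; overlapping "
            "response windows are not supported"
        )
    rows = []
    for k, st in enumerate(stims):
        norm = normalize_dff(traces, st, baseline_window)
        auc = response_auc(norm, st, response_window, method=auc_method)
        peak = response_peak(norm, st, response_window)
        for i, label in enumerate(traces.labels):
            rows.append(
                {
                    "roi_id": label,
                    "stim_index": k,
                    "auc": auc[i],
                    "peak_dff": peak[i],
                    "condition": traces.condition,
                }
            )
    return pd.DataFrame(rows)


def heatmap_matrix(
    norm: NormalizedTraces, sort: Literal["none", "by_peak"] = "none"
) -> tuple[np.ndarray, np.ndarray]:
    """ROI x frame dF/F0 matrix plus its row ordering.

    ``sort="by_peak"`` orders rows by descending whole-trace peak (strongest
    responders first); values themselves are never altered.
    """
    if sort == "none":
        order = np.arange(norm.dff.shape[0])
    elif sort == "by_peak":
        order = np.argsort(-norm.dff.max(axis=1), kind="stable")
    else:
        raise ValueError(f"unknown sort {sort!r}")
    return norm.dff[order], order


def session_summary(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-condition mean and SEM of AUC over session means.

    Each table is one session's response table; the session mean (AUC
    averaged over all its ROI x stimulus rows) is the experimental unit.
    SEM is reported as NaN for a single-session condition.
    """
    if not tables:
        raise MissingDataError("no response tables supplied")
    session_means = []
    for i, tab in enumerate(tables):
        if tab.empty:
            raise MissingDataError(f"response table {i} is empty")
        conds = tab["condition"].unique()
        if len(conds) != 1:
            raise ValueError(f"response table {i} mixes conditions {list(conds)}")
        session_means.append({"condition": conds[0], "session_mean": tab["auc"].mean()})
    df = pd.DataFrame(session_means)
    out = (
        df.groupby("condition", sort=False)["session_mean"]
        .agg(
            mean_auc="mean",
            sem_auc=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
            n_sessions="count",
        )
        .reset_index()
    )
    return out
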