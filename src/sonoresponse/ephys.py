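"""Extracellular multiunit activity: filtering, detection, and PSTHs.

Raw voltage (nominally sampled at 20 kHz) is high-pass filtered to isolate
spike-band activity, multiunit events are extracted by robust negative
threshold crossing, and spike timestamps are aligned to stimulus onsets in
a peristimulus time histogram (PSTH) with 100-ms bins over a +/-3 s window,
counts summed over the ~20 stimuli of a session.

The spike detector uses the standard robust noise estimate
sigma = median(|v|) / 0.6745 (the MAD of a zero-mean Gaussian), a threshold
of -k * sigma (default k = 4), and a dead time (default 1 ms) that
suppresses re-triggering within one spike waveform.  Each reported
timestamp is the trough of the crossing.

Binning convention: bins are half-open, and an offset exactly on a bin edge
belongs to the bin on its right.  Stimuli whose aligned window is truncated
by the recording edges are dropped with a logged warning, never zero-padded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError, GeometryMismatchError

__all__ = [
    "SessionRecording",
    "PsthParams",
    "Psth",
    "highpass_filter",
    "detect_multiunit",
    "build_psth",
    "included_stimuli",
]

logger = logging.getLogger("sonoresponse.ephys")


@dataclass
class SessionRecording:
    """One in vivo recording session: spikes, stimuli, and metadata.

    ``t_start``/``t_stop`` are the recording bounds used to decide whether a
    stimulus window is fully contained in the recording; if ``t_stop`` is
    omitted it is inferred as the latest event time (so give it explicitly
    when the true recording length is known).
    """

    spike_times: np.ndarray
    stim_times: np.ndarray
    intensity: float | None = None  # mW/cm^2
    condition: str = ""
    animal: str = ""
    site: str = ""
    t_start: float = 0.0
    t_stop: float | None = None
    raw_voltage: np.ndarray | None = None
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike_times must be sorted ascending")
        if np.any(np.diff(self.stim_times) < 0):
            raise ValueError("stim_times must be sorted ascending")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")
        if self.t_stop is None:
            events = np.concatenate([self.spike_times, self.stim_times])
            self.t_stop = float(events.max()) if events.size else self.t_start


@dataclass(frozen=True)
class PsthParams:
    """Bin geometry of a stimulus-aligned histogram.

    ``(pre + post) / bin_width`` must be integral.
    """

    bin_width: float = 0.1  # s
    pre: float = 3.0  # s before stimulus onset
    post: float = 3.0  # s after stimulus onset

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.pre < 0 or self.post <= 0:
            raise ValueError("bin_width and post must be > 0, pre >= 0")
        n = (self.pre + self.post) / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"(pre + post) / bin_width = {n} must be an integer number of bins"
            )

    @property
    def n_bins(self) -> int:
        return int(round((self.pre + self.post) / self.bin_width))

    def bin_left_edges(self) -> np.ndarray:
        """Left edge of each bin as an offset from stimulus onset (s)."""
        return -self.pre + np.arange(self.n_bins) * self.bin_width

    def matches(self, other: "PsthParams") -> bool:
        return (
            abs(self.bin_width - other.bin_width) < 1e-12
            and abs(self.pre - other.pre) < 1e-12
            and abs(self.post - other.post) < 1e-12
        )


@dataclass
class Psth:
    """Stimulus-aligned spike counts, summed over stimuli."""

    counts: np.ndarray  # int, one per bin
    params: PsthParams
    n_stimuli: int
    included_stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def bin_left_edges(self) -> np.ndarray:
        return self.params.bin_left_edges()


def highpass_filter(
    raw_voltage: np.ndarray,
    sample_rate: float,
    cutoff: float = 300.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth high-pass filter (forward-backward).

    Isolates the spike band from slow field potentials.  The cutoff must be
    below Nyquist.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    if sample_rate <= 2 * cutoff:
        raise ValueError(
            f"sample_rate {sample_rate} Hz must exceed twice the cutoff {cutoff} Hz"
        )
    sos = sps.butter(order, cutoff, btype="highpass", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(raw_voltage, dtype=float))


def detect_multiunit(
    filtered: np.ndarray,
    sample_rate: float,
    threshold_k: float = 4.0,
    dead_time: float = 1e-3,
    sigma: float | None = None,
) -> np.ndarray:
    """Multiunit timestamps from negative threshold crossings.

    The noise scale is estimated robustly as median(|v|)/0.6745 unless
    ``sigma`` is given explicitly (useful when the noise level is known, or
    on synthetic traces without additive noise).  An event is registered
    when the trace crosses below ``-threshold_k * sigma``; the reported time
    is the trough within the following dead-time window, and further
    crossings within the dead time are suppressed.
    """
    v = np.asarray(filtered, dtype=float)
    if sigma is None:
        sigma = float(np.median(np.abs(v)) / 0.6745)
    if sigma <= 0:
        raise DegenerateSignalError(
            "estimated noise scale is zero; supply sigma explicitly"
        )
    thr = -threshold_k * sigma
    below = v < thr
    onsets = np.flatnonzero(below & ~np.concatenate([[False], below[:-1]]))
    dead = max(1, int(round(dead_time * sample_rate)))
    times = []
    last = -np.inf
    for i in onsets:
        if i < last + dead:
            continue
        trough = i + int(np.argmin(v[i : i + dead]))
        times.append(trough / sample_rate)
        last = i
    return np.asarray(times, dtype=float)


def included_stimuli(rec: SessionRecording, params: PsthParams) -> np.ndarray:
    """Stimuli whose aligned window fits inside the recording bounds.

    Stimuli truncated by the recording edges are excluded (with a warning);
    their windows are never zero-padded.
    """
    ok = (rec.stim_times - params.pre >= rec.t_start) & (
        rec.stim_times + params.post <= rec.t_stop
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "excluding %d of %d stimuli whose +/-(%g, %g) s window is "
            "truncated by the recording edges",
            n_dropped,
            rec.stim_times.size,
            params.pre,
            params.post,
        )
    return rec.stim_times[ok]


def _bin_offsets(offsets: np.ndarray, params: PsthParams) -> np.ndarray:
    """Map offsets (already inside [-pre, post)) to bin indices."""
    idx = np.floor((offsets + params.pre) / params.bin_width).astype(np.int64)
    # guard against float round-up exactly at the right-most edge
    return np.clip(idx, 0, params.n_bins - 1)


def build_psth(rec: SessionRecording, params: PsthParams | None = None) -> Psth:
    """Peristimulus time histogram of a session.

    counts[b] is the number of (spike, stimulus) pairs whose offset
    ``spike - stimulus`` falls in half-open bin b; the total equals the
    number of such pairs exactly.
    """
    if params is None:
        params = PsthParams()
    stims = included_stimuli(rec, params)
    counts = np.zeros(params.n_bins, dtype=np.int64)
    spikes = rec.spike_times
    for st in stims:
        lo = np.searchsorted(spikes, st - params.pre, side="left")
        hi = np.searchsorted(spikes, st + params.post, side="left")
        if hi > lo:
            idx = _bin_offsets(spikes[lo:hi] - st, params)
            counts += np.bincount(idx, minlength=params.n_bins)
    return Psth(
        counts=counts,
        params=params,
        n_stimuli=int(stims.size),
        included_stim_times=stims,
    )


def check_same_geometry(a: PsthParams, b: PsthParams) -> None:
    if not a.matches(b):
        raise GeometryMismatchError(f"bin geometries differ: {a} vs {b}")
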