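"""Jitter-surrogate null test for stimulus-evoked multiunit activity.

The question: does a multiunit spike train show stimulus-locked rate
modulation, over and above its slow background rate structure?  The null
model is built by resampling: every spike time is displaced by an
independent uniform draw on [-h, +h] (default h = 3 s), which destroys any
locking to the stimulus on time scales below h while preserving the
coarse rate envelope.  From 1,000 such surrogate spike trains, PSTHs are
recomputed with the real stimulus times and bin geometry, yielding

* pointwise acceptance bands -- per-bin empirical quantiles (default 95%,
  i.e. the 2.5th and 97.5th percentiles of surrogate counts in that bin);
* global significance bands -- the 95th percentile of each surrogate's
  *maximum* count over all bins (upper), and the 5th percentile of the
  per-surrogate *minimum* (lower).  Because a single draw from the null
  exceeds the upper global band anywhere with probability <= 5%, comparing
  the observed PSTH against the global bands corrects the multiple
  comparisons across bins that inflate pointwise tests;
* the per-bin surrogate mean, the null expectation.

A session is called significant when any observed bin with left edge in
the first second after stimulus onset (default) goes strictly above the
upper global band (activated) or strictly below the lower one
(suppressed); activation is checked first.

Quantiles use the nearest-rank (type-1) convention throughout.  Surrogate
randomness is keyed by (rng_seed, surrogate_index), so surrogate i is
reproducible in isolation and independent of execution order.  Spikes
jittered outside the recording bounds are kept; they simply fall outside
all aligned windows.

The condition-level comparison (e.g. control vs. TRPC6 blocker at one
intensity) is a Pearson chi-square test on the 2x2 table of significant /
not-significant session counts per condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as spstats

from .ephys import Psth, PsthParams, SessionRecording, check_same_geometry, included_stimuli
from .errors import ConfigError, DegenerateTableError, MissingDataError

__all__ = [
    "JitterConfig",
    "JitterBands",
    "SignificanceCall",
    "jitter_surrogate",
    "surrogate_count_matrix",
    "compute_bands",
    "call_significance",
    "pointwise_significant",
    "activated_fraction",
    "chi2_2x2",
]

#: chunk of surrogates processed at once when vectorizing the null PSTHs
_CHUNK = 128


@dataclass(frozen=True)
class JitterConfig:
    """Parameters of the jitter-surrogate test.

    Attributes
    ----------
    n_surrogates : int
        Number of jittered null datasets (default 1000; at least 100).
    jitter_halfwidth : float
        Half-range h of the uniform jitter in seconds (default 3).
    pointwise_level : float
        Coverage of the per-bin acceptance band (default 0.95).
    global_level : float
        Coverage of the global band over all bins (default 0.95).
    post_window : float
        Length of the post-stimulus decision window in seconds (default 1):
        only bins with left edge in [0, post_window) can trigger a call.
    rng_seed : int
        Seed keying the surrogate random streams.
    """

    n_surrogates: int = 1000
    jitter_halfwidth: float = 3.0
    pointwise_level: float = 0.95
    global_level: float = 0.95
    post_window: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surrogates < 100:
            raise ConfigError(
                f"n_surrogates must be >= 100, got {self.n_surrogates}"
            )
        for name in ("pointwise_level", "global_level"):
            lv = getattr(self, name)
            if not (0.0 < lv < 1.0):
                raise ConfigError(f"{name} must be in (0, 1), got {lv}")
        if self.jitter_halfwidth < 0:
            raise ConfigError("jitter_halfwidth must be >= 0")
        if self.post_window <= 0:
            raise ConfigError("post_window must be > 0")
        # the lower pointwise quantile must be resolvable from the surrogates
        if self.n_surrogates * (1.0 - self.pointwise_level) / 2.0 < 1.0:
            raise ConfigError(
                f"{self.n_surrogates} surrogates cannot resolve the "
                f"{(1 - self.pointwise_level) / 2:.4f} pointwise quantile"
            )


@dataclass
class JitterBands:
    """Null acceptance bands derived from jitter surrogates."""

    pointwise_low: np.ndarray
    pointwise_high: np.ndarray
    global_low: float
    global_high: float
    surrogate_mean: np.ndarray
    params: PsthParams
    n_surrogates: int


@dataclass(frozen=True)
class SignificanceCall:
    """Outcome of the global-band test for one session."""

    significant: bool
    direction: Literal["activated", "suppressed", "none"]
    first_crossing_bin: int | None

    def __post_init__(self) -> None:
        if self.significant != (self.direction != "none"):
            raise ValueError("significant must agree with direction")


def _surrogate_rng(seed: int, surrogate_index: int) -> np.random.Generator:
    """Counter-based stream: surrogate i depends only on (seed, i)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(surrogate_index),))
    return np.random.default_rng(ss)


def jitter_surrogate(
    spike_times: np.ndarray, cfg: JitterConfig, surrogate_index: int
) -> np.ndarray:
    """One jittered null spike train, re-sorted.

    Every spike is displaced by an independent uniform draw on [-h, +h].
    Deterministic given (cfg.rng_seed, surrogate_index).
    """
    spikes = np.asarray(spike_times, dtype=float)
    rng = _surrogate_rng(cfg.rng_seed, surrogate_index)
    shifts = rng.uniform(-cfg.jitter_halfwidth, cfg.jitter_halfwidth, spikes.size)
    return np.sort(spikes + shifts)


def surrogate_count_matrix(
    rec: SessionRecording, params: PsthParams, cfg: JitterConfig
) -> np.ndarray:
    """PSTH counts of every surrogate: shape (n_surrogates, n_bins).

    Row i equals the PSTH of ``jitter_surrogate(spike_times, cfg, i)``
    built with the observed session's included stimuli and bin geometry.

    Implementation note: only (spike, stimulus) pairs with base offset in
    [-pre - h, post + h) can land in a bin after jittering, so those pairs
    are enumerated once; each surrogate then only draws one shift per spike
    and re-bins the shifted pair offsets (a spike near two stimuli keeps a
    single shared shift, exactly as if the whole train were jittered).
    """
    stims = included_stimuli(rec, params)
    spikes = rec.spike_times
    h = cfg.jitter_halfwidth
    n_bins = params.n_bins
    counts = np.zeros((cfg.n_surrogates, n_bins), dtype=np.int64)
    if spikes.size == 0 or stims.size == 0:
        return counts

    pair_spike: list[np.ndarray] = []
    pair_offset: list[np.ndarray] = []
    for st in stims:
        lo = np.searchsorted(spikes, st - params.pre - h, side="left")
        hi = np.searchsorted(spikes, st + params.post + h, side="left")
        if hi > lo:
            pair_spike.append(np.arange(lo, hi))
            pair_offset.append(spikes[lo:hi] - st)
    if not pair_spike:
        return counts
    spike_idx = np.concatenate(pair_spike)
    base = np.concatenate(pair_offset)

    for start in range(0, cfg.n_surrogates, _CHUNK):
        stop = min(start + _CHUNK, cfg.n_surrogates)
        shifts = np.empty((stop - start, spikes.size))
        for i in range(start, stop):
            rng = _surrogate_rng(cfg.rng_seed, i)
            shifts[i - start] = rng.uniform(-h, h, spikes.size)
        off = base[None, :] + shifts[:, spike_idx]
        inside = (off >= -params.pre) & (off < params.post)
        row, col = np.nonzero(inside)
        idx = np.floor((off[row, col] + params.pre) / params.bin_width).astype(np.int64)
        np.clip(idx, 0, n_bins - 1, out=idx)
        flat = np.bincount(
            (row + start) * n_bins + idx, minlength=cfg.n_surrogates * n_bins
        )
        counts += flat.reshape(cfg.n_surrogates, n_bins)
    return counts


def _nearest_rank_quantile(x: np.ndarray, q: float, axis: int = 0) -> np.ndarray:
    """Type-1 (nearest-rank, inverted CDF) empirical quantile."""
    return np.quantile(x, q, axis=axis, method="inverted_cdf")


def compute_bands(
    rec: SessionRecording, params: PsthParams, cfg: JitterConfig
) -> JitterBands:
    """Pointwise and global acceptance bands from the jitter null.

    Pointwise bands are per-bin (1 +/- level)/2 quantiles of surrogate
    counts.  The upper global band is the global_level quantile of
    per-surrogate maxima over all bins of the window, the lower global band
    the (1 - global_level) quantile of per-surrogate minima; both are
    computed over the full +/-(pre, post) window, which keeps the band
    construction independent of the decision window.
    """
    counts = surrogate_count_matrix(rec, params, cfg)
    alpha = (1.0 - cfg.pointwise_level) / 2.0
    pointwise_low = _nearest_rank_quantile(counts, alpha).astype(float)
    pointwise_high = _nearest_rank_quantile(counts, 1.0 - alpha).astype(float)
    maxima = counts.max(axis=1)
    minima = counts.min(axis=1)
    global_high = float(_nearest_rank_quantile(maxima, cfg.global_level))
    global_low = float(_nearest_rank_quantile(minima, 1.0 - cfg.global_level))
    return JitterBands(
        pointwise_low=pointwise_low,
        pointwise_high=pointwise_high,
        global_low=global_low,
        global_high=global_high,
        surrogate_mean=counts.mean(axis=0),
        params=params,
        n_surrogates=cfg.n_surrogates,
    )


def _decision_bins(params: PsthParams, post_window: float) -> np.ndarray:
    edges = params.bin_left_edges()
    return np.flatnonzero((edges >= -1e-12) & (edges < post_window - 1e-12))


def call_significance(
    observed: Psth, bands: JitterBands, cfg: JitterConfig
) -> SignificanceCall:
    """Global-band decision for one session.

    Only bins whose left edge lies in [0, post_window) are examined.  The
    session is *activated* if any such count is strictly above the upper
    global band, else *suppressed* if any is strictly below the lower one;
    the first offending bin (by time) is reported.
    """
    check_same_geometry(observed.params, bands.params)
    sel = _decision_bins(observed.params, cfg.post_window)
    obs = observed.counts[sel]
    above = np.flatnonzero(obs > bands.global_high)
    if above.size:
        return SignificanceCall(True, "activated", int(sel[above[0]]))
    below = np.flatnonzero(obs < bands.global_low)
    if below.size:
        return SignificanceCall(True, "suppressed", int(sel[below[0]]))
    return SignificanceCall(False, "none", None)


def pointwise_significant(observed: Psth, bands: JitterBands, cfg: JitterConfig) -> bool:
    """Uncorrected per-bin test: does any decision-window bin leave its
    pointwise band?  Used to demonstrate the multiple-comparison inflation
    that the global bands remove."""
    check_same_geometry(observed.params, bands.params)
    sel = _decision_bins(observed.params, cfg.post_window)
    obs = observed.counts[sel]
    return bool(
        np.any(obs > bands.pointwise_high[sel]) or np.any(obs < bands.pointwise_low[sel])
    )


def activated_fraction(calls: Sequence[SignificanceCall]) -> float:
    """Fraction of sessions called activated."""
    if len(calls) == 0:
        raise MissingDataError("no significance calls in group")
    return sum(c.direction == "activated" for c in calls) / len(calls)


def chi2_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 count table.

    No continuity correction by default (``correction=True`` enables
    Yates).  Returns (statistic, p-value) with 1 degree of freedom.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("table counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateTableError("every row and column marginal must be > 0")
    res = spstats.chi2_contingency(t, correction=correction)
    return float(res.statistic), float(res.pvalue)


def plot_session(observed: Psth, bands: JitterBands, ax=None):
    """PSTH bars with surrogate mean, pointwise, and global band lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    edges = observed.bin_left_edges()
    w = observed.params.bin_width
    ax.bar(edges, observed.counts, width=w, align="edge", color="0.3", label="PSTH")
    ax.step(edges, bands.pointwise_high, where="post", color="red", ls="--", lw=1,
            label="pointwise band")
    ax.step(edges, bands.pointwise_low, where="post", color="red", ls="--", lw=1)
    ax.axhline(bands.global_high, color="magenta", ls="--", lw=1, label="global band")
    ax.axhline(bands.global_low, color="magenta", ls="--", lw=1)
    ax.step(edges, bands.surrogate_mean, where="post", color="blue", ls="--", lw=1,
            label="surrogate mean")
    ax.axvline(0.0, color="orange", lw=1)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel(f"counts / {observed.params.bin_width * 1e3:.0f} ms bin")
    ax.legend(fontsize=7, loc="upper right")
    return ax
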