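"""Synthetic data generators with ground truth for every analysis stage.

Two families of generators emulate the statistical structure the analyses
assume, so the whole pipeline is exercisable without recorded data:

* ``simulate_calcium`` -- per-ROI fluorescence at 1 Hz with GCaMP6s-like
  double-exponential evoked transients in responder ROIs, population-wide
  spontaneous network events, per-ROI baseline spread, and multiplicative
  Gaussian noise.
* ``simulate_spikes`` -- multiunit spike trains as inhomogeneous Poisson
  processes (baseline 20 Hz) with a transient multiplicative rate elevation
  after each of 20 stimuli delivered at random 10-20 s intervals;
  ``simulate_voltage`` turns timestamps into a noisy extracellular trace
  with stereotyped biphasic spike waveforms.

Drug effects are modelled as a multiplicative scale on the evoked
modulation (``condition_scale`` / ``condition_gain_scale``): a scale of 0
is full blockade, 1 leaves the response untouched.  Every generator is
bit-reproducible given its seed and returns its ground truth next to the
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calcium import RoiTraceSet
from .ephys import SessionRecording

__all__ = [
    "CalciumSimParams",
    "EphysSimParams",
    "calcium_kernel",
    "simulate_calcium",
    "simulate_spikes",
    "simulate_voltage",
]


@dataclass(frozen=True)
class CalciumSimParams:
    """Conditions of a simulated calcium-imaging session.

    Defaults describe a typical widefield GCaMP6s recording of cultured
    cortical neurons: ~40 ROIs imaged at 1 Hz, evoked peak dF/F0 around
    1.5 with 25% lognormal cell-to-cell spread, rise/decay time constants
    of 1 s / 4 s, 80% of cells responding, rare (0.01 Hz) spontaneous
    network events shared across the population, and 5% multiplicative
    shot noise.
    """

    n_rois: int = 40
    frame_rate: float = 1.0  # Hz
    duration: float = 100.0  # s
    baseline_f: float = 100.0  # mean raw fluorescence (counts)
    baseline_spread: float = 0.2  # lognormal sigma of per-ROI baseline
    noise_sd: float = 0.05  # multiplicative Gaussian noise, fraction of F
    stim_times: tuple[float, ...] = (40.0,)
    evoked_amplitude: float = 1.5  # peak dF/F0 of the evoked transient
    amplitude_spread: float = 0.25  # lognormal sigma of per-ROI amplitude
    rise_tau: float = 1.0  # s
    decay_tau: float = 4.0  # s
    responder_fraction: float = 0.8
    spont_event_rate: float = 0.01  # Hz, population events
    spont_participation: float = 0.5  # per-ROI probability per event
    spont_amplitude: float = 1.0  # peak dF/F0 of spontaneous events
    condition_scale: float = 1.0  # drug effect on evoked amplitude
    condition: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be > 0")
        if self.rise_tau >= self.decay_tau:
            raise ValueError("rise_tau must be < decay_tau")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise ValueError("responder_fraction must be in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")


@dataclass(frozen=True)
class EphysSimParams:
    """Conditions of a simulated in vivo multiunit session.

    Defaults match the recording protocol the analyses target: 20 Hz
    baseline multiunit rate, 20 stimuli at random 10-20 s intervals.  The
    evoked response multiplies the rate by ``evoked_gain`` for
    ``evoked_duration`` seconds starting ``evoked_latency`` after stimulus
    onset; gain 1 (the default) is a null session with no stimulus locking.
    """

    baseline_rate: float = 20.0  # Hz
    n_stimuli: int = 20
    isi_range: tuple[float, float] = (10.0, 20.0)  # s
    evoked_gain: float = 1.0
    evoked_latency: float = 0.1  # s
    evoked_duration: float = 0.5  # s
    condition_gain_scale: float = 1.0  # drug effect on the evoked modulation
    pre_margin: float = 5.0  # s of recording before the first stimulus
    post_margin: float = 5.0  # s after the last stimulus
    intensity: float | None = None  # mW/cm^2 label, carried through
    condition: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.evoked_gain < 0:
            raise ValueError("rates and gains must be >= 0")
        lo, hi = self.isi_range
        if not (0 < lo <= hi):
            raise ValueError("isi_range must be positive and ordered")
        if self.evoked_duration <= 0 or self.evoked_latency < 0:
            raise ValueError("evoked window must have positive duration")

    @property
    def effective_gain(self) -> float:
        """Evoked gain after the condition (drug) scale is applied."""
        return 1.0 + (self.evoked_gain - 1.0) * self.condition_gain_scale


def calcium_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak double-exponential transient, zero for t < 0.

    k(t) = (exp(-t/decay) - exp(-t/rise)) / k_peak, so an "amplitude" that
    multiplies this kernel is directly the peak dF/F0 of the transient.
    """
    t = np.asarray(t, dtype=float)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    out = np.where(t >= 0, np.exp(-t / decay_tau) - np.exp(-t / rise_tau), 0.0)
    return out / peak


def simulate_calcium(params: CalciumSimParams) -> tuple[RoiTraceSet, dict]:
    """Generate one imaging session plus its ground truth.

    F_i(t) = B_i * (1 + s_i(t)) * (1 + eps), where s_i sums the evoked
    kernels (responders only, per-ROI lognormal amplitude scaled by the
    condition factor) and the spontaneous-event kernels this ROI
    participates in, and eps is iid Gaussian noise of sd ``noise_sd``.

    Returns
    -------
    (RoiTraceSet, dict)
        The trace set and a ground-truth record with per-ROI baselines,
        responder flags, evoked amplitudes (0 for non-responders), and the
        spontaneous event times.
    """
    rng = np.random.default_rng(params.seed)
    n_frames = int(round(params.duration * params.frame_rate))
    times = np.arange(n_frames) / params.frame_rate

    baselines = params.baseline_f * np.exp(
        rng.normal(0.0, params.baseline_spread, params.n_rois)
    )
    responders = rng.random(params.n_rois) < params.responder_fraction
    amplitudes = (
        params.evoked_amplitude
        * params.condition_scale
        * np.exp(rng.normal(0.0, params.amplitude_spread, params.n_rois))
    )
    amplitudes = np.where(responders, amplitudes, 0.0)

    signal = np.zeros((params.n_rois, n_frames))
    for st in params.stim_times:
        k = calcium_kernel(times - st, params.rise_tau, params.decay_tau)
        signal += amplitudes[:, None] * k[None, :]

    n_events = rng.poisson(params.spont_event_rate * params.duration)
    event_times = np.sort(rng.uniform(0.0, params.duration, n_events))
    for et in event_times:
        k = calcium_kernel(times - et, params.rise_tau, params.decay_tau)
        participates = rng.random(params.n_rois) < params.spont_participation
        amps = params.spont_amplitude * np.exp(
            rng.normal(0.0, params.amplitude_spread, params.n_rois)
        )
        signal += np.where(participates, amps, 0.0)[:, None] * k[None, :]

    noise = rng.normal(0.0, params.noise_sd, (params.n_rois, n_frames))
    raw = baselines[:, None] * (1.0 + signal) * (1.0 + noise)
    raw = np.maximum(raw, 1e-9)  # fluorescence counts are positive

    traces = RoiTraceSet(
        times=times,
        raw=raw,
        stim_times=np.asarray(params.stim_times, dtype=float),
        condition=params.condition,
    )
    truth = {
        "baselines": baselines,
        "responders": responders,
        "amplitudes": amplitudes,
        "spont_event_times": event_times,
    }
    return traces, truth


def _rate_profile(t: np.ndarray, stims: np.ndarray, params: EphysSimParams) -> np.ndarray:
    """Instantaneous rate at times t under the multiplicative evoked model."""
    g = params.effective_gain
    rate = np.full(t.shape, params.baseline_rate)
    if g == 1.0 or stims.size == 0:
        return rate
    idx = np.searchsorted(stims, t, side="right") - 1
    has_prev = idx >= 0
    dt = np.where(has_prev, t - stims[np.clip(idx, 0, None)], np.inf)
    in_window = (dt > params.evoked_latency) & (
        dt <= params.evoked_latency + params.evoked_duration
    )
    return np.where(in_window, params.baseline_rate * g, rate)


def simulate_spikes(params: EphysSimParams) -> tuple[SessionRecording, dict]:
    """Generate one multiunit session plus its ground truth.

    Stimulus times have uniform inter-stimulus intervals in ``isi_range``.
    Spikes are drawn from an inhomogeneous Poisson process by thinning: a
    homogeneous candidate process at the peak rate is thinned with
    probability rate(t) / rate_max, where rate(t) is the baseline rate
    multiplied by the effective gain inside each post-stimulus window.
    """
    rng = np.random.default_rng(params.seed)
    isis = rng.uniform(params.isi_range[0], params.isi_range[1], params.n_stimuli)
    stims = params.pre_margin + np.concatenate([[0.0], np.cumsum(isis[:-1])])
    t_stop = float(stims[-1] + params.post_margin)

    g = params.effective_gain
    rate_max = params.baseline_rate * max(1.0, g)
    if rate_max > 0:
        n_cand = rng.poisson(rate_max * t_stop)
        cand = np.sort(rng.uniform(0.0, t_stop, n_cand))
        accept = rng.random(n_cand) * rate_max < _rate_profile(cand, stims, params)
        spikes = cand[accept]
    else:
        spikes = np.empty(0)

    rec = SessionRecording(
        spike_times=spikes,
        stim_times=stims,
        intensity=params.intensity,
        condition=params.condition,
        t_start=0.0,
        t_stop=t_stop,
    )
    truth = {
        "effective_gain": g,
        "baseline_rate": params.baseline_rate,
        "evoked_window": (
            params.evoked_latency,
            params.evoked_latency + params.evoked_duration,
        ),
        "stim_times": stims,
    }
    return rec, truth


def _biphasic_waveform(sample_rate: float) -> np.ndarray:
    """Stereotyped extracellular spike: sharp negative trough then a
    slower positive overshoot, ~1.5 ms long, trough normalized to -1."""
    t = np.arange(int(round(1.5e-3 * sample_rate))) / sample_rate
    w = -np.exp(-0.5 * ((t - 0.3e-3) / 0.1e-3) ** 2) + 0.45 * np.exp(
        -0.5 * ((t - 0.75e-3) / 0.25e-3) ** 2
    )
    return w / (-w.min())


def simulate_voltage(
    spike_times: np.ndarray,
    sample_rate: float = 20000.0,
    duration: float | None = None,
    noise_sd: float = 1.0,
    spike_amplitude: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Extracellular voltage: Gaussian noise plus biphasic spike waveforms.

    ``spike_amplitude`` is the trough depth in units of ``noise_sd`` (in
    sigma units when noise_sd > 0; absolute units for a noiseless trace).
    """
    if sample_rate < 10000:
        raise ValueError("sample_rate must be >= 10 kHz to resolve spike waveforms")
    spikes = np.asarray(spike_times, dtype=float)
    if duration is None:
        duration = (spikes.max() if spikes.size else 0.0) + 0.01
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    v = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    scale = spike_amplitude * (noise_sd if noise_sd > 0 else 1.0)
    w = scale * _biphasic_waveform(sample_rate)
    trough = int(np.argmin(w))
    for st in spikes:
        i0 = int(round(st * sample_rate)) - trough
        a, b = max(i0, 0), min(i0 + w.size, n)
        if b > a:
            v[a:b] += w[a - i0 : b - i0]
    return v
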