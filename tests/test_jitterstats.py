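"""Jitter-surrogate null: surrogates, bands, calls, and the 2x2 test."""

import numpy as np
import pytest

from sonoresponse import (
    EphysSimParams,
    JitterConfig,
    Psth,
    PsthParams,
    SessionRecording,
    activated_fraction,
    build_psth,
    call_significance,
    chi2_2x2,
    compute_bands,
    jitter_surrogate,
    pointwise_significant,
    simulate_spikes,
    surrogate_count_matrix,
)
from sonoresponse.jitterstats import JitterBands, SignificanceCall
from sonoresponse.errors import (
    ConfigError,
    DegenerateTableError,
    GeometryMismatchError,
    MissingDataError,
)


def small_cfg(**kw):
    kw.setdefault("n_surrogates", 250)
    return JitterConfig(**kw)


class TestSurrogates:
    def test_zero_halfwidth_is_identity(self):
        spikes = np.array([1.0, 2.5, 7.0])
        out = jitter_surrogate(spikes, small_cfg(jitter_halfwidth=0.0), 3)
        assert np.array_equal(out, spikes)

    def test_spike_count_conserved_and_sorted(self, rng):
        spikes = np.sort(rng.uniform(0, 100, 500))
        out = jitter_surrogate(spikes, small_cfg(), 0)
        assert out.size == spikes.size
        assert np.all(np.diff(out) >= 0)

    def test_displacement_moments_match_uniform_law(self):
        # over many surrogates the shifts are U[-h, h]: mean 0, var h^2/3
        spikes = np.zeros(200)
        cfg = small_cfg(jitter_halfwidth=3.0, rng_seed=9)
        shifts = np.concatenate(
            [jitter_surrogate(spikes, cfg, i) for i in range(100)]
        )
        assert abs(shifts.mean()) < 0.05
        assert shifts.var() == pytest.approx(3.0**2 / 3.0, rel=0.05)

    def test_counter_based_reproducibility(self):
        spikes = np.arange(50, dtype=float)
        cfg = small_cfg(rng_seed=42)
        a = jitter_surrogate(spikes, cfg, 17)
        b = jitter_surrogate(spikes, cfg, 17)
        c = jitter_surrogate(spikes, cfg, 18)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_count_matrix_row_matches_explicit_surrogate(self, null_session):
        # the vectorized null PSTHs equal PSTHs of the jittered trains
        rec, _ = null_session
        params = PsthParams()
        cfg = small_cfg(rng_seed=13, n_surrogates=100)
        counts = surrogate_count_matrix(rec, params, cfg)
        for i in (0, 57, 99):
            jittered = jitter_surrogate(rec.spike_times, cfg, i)
            ref = SessionRecording(
                spike_times=jittered, stim_times=rec.stim_times,
                t_start=rec.t_start, t_stop=rec.t_stop,
            )
            # surrogates keep the observed session's stimulus inclusion,
            # and jittered spikes outside the recording are retained
            assert np.array_equal(counts[i], build_psth(ref, params).counts)


class TestBands:
    def test_empty_spike_train_gives_zero_bands(self):
        rec = SessionRecording(spike_times=[], stim_times=[10.0],
                               t_start=0.0, t_stop=20.0)
        bands = compute_bands(rec, PsthParams(), small_cfg())
        assert bands.global_high == 0 and bands.global_low == 0
        assert not bands.surrogate_mean.any()

    def test_surrogate_mean_matches_poisson_rate(self, null_session, null_bands):
        _, truth = null_session
        _, bands, _ = null_bands
        expected = 20 * truth["baseline_rate"] * 0.1
        se = bands.surrogate_mean.std(ddof=1) / np.sqrt(bands.surrogate_mean.size)
        assert abs(bands.surrogate_mean.mean() - expected) < 3 * se + 1.0

    def test_pointwise_band_brackets_surrogate_mean(self, null_bands):
        _, bands, _ = null_bands
        assert np.all(bands.pointwise_low <= bands.surrogate_mean)
        assert np.all(bands.surrogate_mean <= bands.pointwise_high)

    def test_bands_deterministic_given_seed(self, null_session):
        rec, _ = null_session
        params = PsthParams()
        a = compute_bands(rec, params, small_cfg(rng_seed=3))
        b = compute_bands(rec, params, small_cfg(rng_seed=3))
        assert np.array_equal(a.pointwise_low, b.pointwise_low)
        assert np.array_equal(a.pointwise_high, b.pointwise_high)
        assert a.global_low == b.global_low and a.global_high == b.global_high
        assert np.array_equal(a.surrogate_mean, b.surrogate_mean)

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ConfigError):
            JitterConfig(n_surrogates=50)
        with pytest.raises(ConfigError):
            JitterConfig(n_surrogates=100, pointwise_level=0.999)


def make_bands(params, low=10.0, high=50.0):
    n = params.n_bins
    return JitterBands(
        pointwise_low=np.full(n, low + 5.0),
        pointwise_high=np.full(n, high - 5.0),
        global_low=low,
        global_high=high,
        surrogate_mean=np.full(n, (low + high) / 2),
        params=params,
        n_surrogates=1000,
    )


class TestCalls:
    params = PsthParams()

    def observed(self, counts):
        return Psth(counts=np.asarray(counts), params=self.params, n_stimuli=20)

    def test_counts_inside_bands_not_significant(self):
        call = call_significance(
            self.observed(np.full(60, 30)), make_bands(self.params), small_cfg()
        )
        assert not call.significant
        assert call.direction == "none" and call.first_crossing_bin is None

    def test_post_stimulus_excursion_is_activated(self):
        counts = np.full(60, 30)
        counts[33] = 55  # left edge +0.3 s
        call = call_significance(
            self.observed(counts), make_bands(self.params), small_cfg()
        )
        assert call.direction == "activated"
        assert call.first_crossing_bin == 33

    def test_pre_stimulus_excursion_ignored(self):
        counts = np.full(60, 30)
        counts[25] = 99  # left edge -0.5 s: outside the decision window
        call = call_significance(
            self.observed(counts), make_bands(self.params), small_cfg()
        )
        assert not call.significant

    def test_suppression_detected_and_activation_takes_precedence(self):
        counts = np.full(60, 30)
        counts[31] = 5
        call = call_significance(
            self.observed(counts), make_bands(self.params), small_cfg()
        )
        assert call.direction == "suppressed" and call.first_crossing_bin == 31
        counts[34] = 70  # both excursions: activation wins
        call = call_significance(
            self.observed(counts), make_bands(self.params), small_cfg()
        )
        assert call.direction == "activated" and call.first_crossing_bin == 34

    def test_decision_window_follows_config(self):
        counts = np.full(60, 30)
        counts[45] = 70  # left edge +1.5 s
        cfg = small_cfg(post_window=1.0)
        assert not call_significance(
            self.observed(counts), make_bands(self.params), cfg
        ).significant
        cfg2 = small_cfg(post_window=2.0)
        assert call_significance(
            self.observed(counts), make_bands(self.params), cfg2
        ).direction == "activated"

    def test_geometry_mismatch_rejected(self):
        other = PsthParams(bin_width=0.2)
        observed = Psth(counts=np.zeros(30, dtype=int), params=other, n_stimuli=20)
        with pytest.raises(GeometryMismatchError):
            call_significance(observed, make_bands(self.params), small_cfg())

    def test_call_invariant_enforced(self):
        with pytest.raises(ValueError):
            SignificanceCall(significant=True, direction="none", first_crossing_bin=None)


class TestGroupStats:
    def test_activated_fraction_examples(self):
        act = SignificanceCall(True, "activated", 30)
        sup = SignificanceCall(True, "suppressed", 30)
        none = SignificanceCall(False, "none", None)
        assert activated_fraction([none] * 10) == 0.0
        assert activated_fraction([act] * 10) == 1.0
        assert activated_fraction([act] * 3 + [none] * 8 + [sup]) == 0.25

    def test_empty_group_rejected(self):
        with pytest.raises(MissingDataError):
            activated_fraction([])

    def test_chi2_independence_and_diagonal(self):
        stat, p = chi2_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0
        stat, _ = chi2_2x2([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)

    def test_chi2_homogeneity(self, rng):
        # closed-form oracle: chi2 = N (ad - bc)^2 / (r1 r2 c1 c2) doubles
        # when every cell doubles
        for _ in range(20):
            t = rng.integers(1, 50, (2, 2))
            stat, _ = chi2_2x2(t)
            a, b, c, d = t.ravel().astype(float)
            n = t.sum()
            oracle = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert stat == pytest.approx(oracle)
            assert chi2_2x2(2 * t)[0] == pytest.approx(2 * stat)

    def test_yates_correction_reduces_statistic(self):
        t = [[12, 5], [6, 14]]
        assert chi2_2x2(t, correction=True)[0] < chi2_2x2(t)[0]

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi2_2x2([[0, 0], [5, 5]])


class TestDetectionProperties:
    def test_evoked_session_called_activated_in_decision_window(self):
        rec, _ = simulate_spikes(EphysSimParams(seed=21, evoked_gain=3.0))
        params = PsthParams()
        psth = build_psth(rec, params)
        cfg = small_cfg(rng_seed=22)
        call = call_significance(psth, compute_bands(rec, params, cfg), cfg)
        assert call.direction == "activated"
        # first crossing inside [0, 1 s)
        left = psth.bin_left_edges()[call.first_crossing_bin]
        assert 0.0 <= left < 1.0

    def test_pointwise_calls_exceed_global_calls_on_null(self):
        # multiple-comparison inflation: uncorrected per-bin tests fire far
        # more often than the global-band test on null sessions
        n, glob, pw = 40, 0, 0
        params = PsthParams()
        for i in range(n):
            rec, _ = simulate_spikes(EphysSimParams(seed=700 + i))
            cfg = small_cfg(rng_seed=800 + i)
            psth = build_psth(rec, params)
            bands = compute_bands(rec, params, cfg)
            glob += call_significance(psth, bands, cfg).significant
            pw += pointwise_significant(psth, bands, cfg)
        assert pw > glob
        assert glob <= 0.2 * n

    def test_activated_fraction_monotone_in_evoked_gain(self):
        params = PsthParams()
        fractions = []
        for gain in (1.0, 2.0, 3.0):
            calls = []
            for i in range(20):
                rec, _ = simulate_spikes(
                    EphysSimParams(seed=900 + i, evoked_gain=gain)
                )
                cfg = small_cfg(rng_seed=950 + i)
                calls.append(
                    call_significance(
                        build_psth(rec, params), compute_bands(rec, params, cfg), cfg
                    )
                )
            fractions.append(activated_fraction(calls))
        assert fractions == sorted(fractions)
        assert fractions[-1] >= 0.95
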