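import numpy as np
import pytest

from ephyskit import (ContinuousRecord, EventList, ParameterError,
                      SimComponent, SimSpec, simulate)
from ephyskit.preprocess import (apply_fir, butterworth_filter,
                                 interpolate_bad_channels,
                                 reject_fixed_threshold, reject_range)
from ephyskit.synthetic import fibonacci_montage, harmonic_topography


def rec_with_epoch(values, fs=1000.0, ev_sample=500):
    """One-channel record whose event epoch [0, len(values)) holds values."""
    data = np.zeros((1, 2 * ev_sample + len(values)))
    data[0, ev_sample:ev_sample + len(values)] = values
    return ContinuousRecord(data, fs, ["c1"], ["uV"],
                            EventList([ev_sample], [1]))


class TestFixedThreshold:
    @pytest.mark.parametrize("peak,expect_rejected", [
        (75.1, True),   # exceeds the +-75 uV limit
        (74.9, False),  # stays below
        (75.0, False),  # a tie does not *exceed* the limit
    ])
    def test_decision_boundary(self, peak, expect_rejected):
        rec = rec_with_epoch(np.full(100, peak))
        ev = reject_fixed_threshold(rec, [1], (0.0, 0.1), 75.0)
        assert bool(ev.rejects[0]) is expect_rejected

    def test_negative_excursions_count(self):
        rec = rec_with_epoch(np.full(100, -80.0))
        ev = reject_fixed_threshold(rec, [1], (0.0, 0.1), 75.0)
        assert ev.rejects[0]

    def test_signal_untouched_and_input_flags_untouched(self):
        rec = rec_with_epoch(np.full(100, 80.0))
        before = rec.data.copy()
        ev = reject_fixed_threshold(rec, [1], (0.0, 0.1), 75.0)
        assert np.array_equal(rec.data, before)
        assert not rec.events.rejects[0]
        assert ev.rejects[0]

    def test_simulated_artifacts_detected_exactly(self):
        spec = SimSpec(fs=256.0, n_channels=2, noise_sd=1.0,
                       events=[(1, 100, 0.8, 0.0)],
                       components=[SimComponent(
                           "artifact_step", [1], 0.1, 0.2, 200.0,
                           event_code=None)],
                       seed=4)
        rec = simulate(spec)
        # keep the step on only 7 chosen trials by erasing the others
        rng = np.random.default_rng(0)
        chosen = np.sort(rng.choice(100, size=7, replace=False))
        for i, s in enumerate(rec.events.samples):
            if i not in chosen:
                n0 = int(s + 0.1 * 256) - 3
                n1 = int(s + 0.3 * 256) + 3
                rec.data[1, n0:n1] = 0.0
        ev = reject_fixed_threshold(rec, [1], (0.0, 0.5), 75.0)
        assert np.flatnonzero(ev.rejects).tolist() == chosen.tolist()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        data = 50 * rng.standard_normal((2, 5000))
        rec = ContinuousRecord(data, 500.0, ["a", "b"], ["uV", "uV"],
                               EventList(np.arange(300, 4500, 300), np.ones(14)))
        n_prev = None
        for thr in (40.0, 60.0, 80.0, 120.0):
            n = int(reject_fixed_threshold(rec, [1], (0.0, 0.3), thr)
                    .rejects.sum())
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_edge_epoch_rejected(self):
        rec = ContinuousRecord(np.zeros((1, 100)), 100.0, ["c"], ["uV"],
                               EventList([95], [1]))
        ev = reject_fixed_threshold(rec, [1], (0.0, 0.2), 75.0)
        assert ev.rejects[0]

    def test_unknown_channel_in_threshold_map(self):
        rec = rec_with_epoch(np.zeros(10))
        with pytest.raises(ParameterError):
            reject_fixed_threshold(rec, [1], (0.0, 0.01), {"nope": 75.0})


class TestRangeRejection:
    def test_ramp_exceeding_range(self):
        # 2500 fT linear ramp over 500 ms against a 2000 fT / 500 ms limit
        fs = 1000.0
        ramp = np.linspace(0.0, 2500.0, 500)
        rec = rec_with_epoch(ramp, fs=fs)
        ev = reject_range(rec, [1], (0.0, 0.5), 0.5, 2000.0)
        assert ev.rejects[0]

    def test_constant_signal_kept(self):
        rec = rec_with_epoch(np.full(500, 123.0))
        ev = reject_range(rec, [1], (0.0, 0.5), 0.5, 1.0)
        assert not ev.rejects[0]

    def test_slow_ramp_kept(self):
        ramp = np.linspace(0.0, 1900.0, 500)
        rec = rec_with_epoch(ramp)
        ev = reject_range(rec, [1], (0.0, 0.5), 0.5, 2000.0)
        assert not ev.rejects[0]

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        fs = 200.0
        w = 20  # 0.1 s window
        for trial in range(10):
            sig = np.cumsum(rng.standard_normal(160))
            rec = rec_with_epoch(sig, fs=fs, ev_sample=200)
            limit = float(rng.uniform(2, 10))
            ev = reject_range(rec, [1], (0.0, 0.8), w / fs, limit)
            flag = False
            for start in range(len(sig) - w + 1):
                seg = sig[start:start + w]
                if seg.max() - seg.min() > limit:
                    flag = True
                    break
            assert bool(ev.rejects[0]) is flag

    def test_window_too_short(self):
        rec = rec_with_epoch(np.zeros(100))
        with pytest.raises(ParameterError):
            reject_range(rec, [1], (0.0, 0.1), 0.001, 10.0)


class TestButterworth:
    @staticmethod
    def steady_gain(mode, freq=30.0, fs=1000.0):
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * freq * t)
        rec = ContinuousRecord(x[None, :], fs, ["c"], ["uV"])
        y = butterworth_filter(rec, "low", 30.0, order=4, mode=mode).data[0]
        mid = slice(int(2 * fs), int(8 * fs))
        return np.sqrt(np.mean(y[mid] ** 2)) / np.sqrt(np.mean(x[mid] ** 2))

    def test_causal_cutoff_gain(self):
        db = 20 * np.log10(self.steady_gain("causal"))
        assert abs(db - (-3.01)) < 0.1

    def test_zero_phase_cutoff_gain(self):
        db = 20 * np.log10(self.steady_gain("zero_phase"))
        assert abs(db - (-6.02)) < 0.2

    def test_zero_phase_no_phase_shift(self):
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        rec = ContinuousRecord(x[None, :], fs, ["c"], ["uV"])
        y = butterworth_filter(rec, "low", 30.0, mode="zero_phase").data[0]
        mid = slice(int(fs), int(3 * fs))
        # projection-based phase estimate at 10 Hz
        ref = np.exp(-2j * np.pi * 10.0 * t[mid])
        shift = np.angle(np.sum(y[mid] * ref) / np.sum(x[mid] * ref))
        assert abs(shift) < 0.01

    def test_linearity(self):
        rng = np.random.default_rng(2)
        fs = 500.0
        x = rng.standard_normal((1, 2000))
        y = rng.standard_normal((1, 2000))
        a, b = 2.5, -1.3

        def filt(sig):
            rec = ContinuousRecord(sig, fs, ["c"], ["uV"])
            return butterworth_filter(rec, "band", [8.0, 12.0],
                                      mode="causal").data

        lhs = filt(a * x + b * y)
        rhs = a * filt(x) + b * filt(y)
        assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_cutoff_beyond_nyquist_refused(self):
        rec = ContinuousRecord(np.zeros((1, 100)), 100.0, ["c"], ["uV"])
        with pytest.raises(ParameterError):
            butterworth_filter(rec, "low", 60.0)


class TestFir:
    def test_identity_tap(self):
        rec = ContinuousRecord(np.random.default_rng(0).normal(size=(2, 50)),
                               100.0, ["a", "b"], ["uV", "uV"])
        out = apply_fir(rec, [1.0])
        assert np.array_equal(out.data, rec.data)

    def test_two_point_average_on_impulse(self):
        x = np.zeros((1, 10))
        x[0, 1] = 1.0
        rec = ContinuousRecord(x, 100.0, ["c"], ["uV"])
        y = apply_fir(rec, [0.5, 0.5]).data[0]
        assert np.allclose(y[1:3], [0.5, 0.5])
        assert np.allclose(y[3:], 0.0)

    def test_matches_direct_convolution(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(200)
        taps = rng.standard_normal(7)
        rec = ContinuousRecord(x[None, :], 100.0, ["c"], ["uV"])
        got = apply_fir(rec, taps).data[0]
        padded = np.concatenate([x[1:len(taps)][::-1], x])  # reflect left
        expected = np.convolve(padded, taps, mode="full")[
            len(taps) - 1:len(taps) - 1 + len(x)]
        assert np.max(np.abs(got - expected)) < 1e-12


class TestBadChannelInterpolation:
    def test_constant_topography_recovered(self, cap64):
        data = np.full((64, 10), 3.7)
        rec = ContinuousRecord(data, 100.0, cap64.labels, ["uV"] * 64)
        out = interpolate_bad_channels(rec, cap64, [cap64.labels[5]])
        assert np.allclose(out.data[5], 3.7, atol=1e-6)

    def test_harmonic_reconstruction(self, cap64):
        v = harmonic_topography(cap64, 1, 0)
        data = np.tile(v[:, None], (1, 4))
        rec = ContinuousRecord(data, 100.0, cap64.labels, ["uV"] * 64)
        bad = cap64.labels[10]
        out = interpolate_bad_channels(rec, cap64, [bad])
        err = abs(out.data[10, 0] - v[10])
        assert err < 0.05 * np.ptp(v)

    def test_no_bad_channels_identity(self, cap64):
        rng = np.random.default_rng(1)
        rec = ContinuousRecord(rng.normal(size=(64, 5)), 100.0, cap64.labels,
                               ["uV"] * 64)
        out = interpolate_bad_channels(rec, cap64, [])
        assert np.array_equal(out.data, rec.data)

    def test_good_channels_untouched(self, cap64):
        rng = np.random.default_rng(2)
        rec = ContinuousRecord(rng.normal(size=(64, 5)), 100.0, cap64.labels,
                               ["uV"] * 64)
        out = interpolate_bad_channels(rec, cap64, [cap64.labels[0]])
        assert np.array_equal(out.data[1:], rec.data[1:])

    def test_too_few_good_channels(self, cap64):
        rec = ContinuousRecord(np.zeros((64, 3)), 100.0, cap64.labels,
                               ["uV"] * 64)
        with pytest.raises(ParameterError):
            interpolate_bad_channels(rec, cap64, cap64.labels[:61])
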