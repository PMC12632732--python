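"""EEG preprocessing, epoching, averaging, and peak extraction."""

import numpy as np
import pandas as pd
import pytest

from mobikit.erp import (
    ComponentSpec, ContinuousEEG, DEFAULT_COMPONENTS, ERPAverage,
    average_reference, bandpass_filter, design_bandpass, difference_wave,
    epoch, epoch_sample_grid, extract_peak, flag_bad_channels,
    grand_average, interpolate_bad_channels, participant_average,
    spline_interpolation_matrix, topographic_window_mean,
)
from mobikit.montage import make_montage

FS = 512.0


def sine_eeg(freqs, n_ch=3, seconds=8.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    data = np.vstack([np.sin(2 * np.pi * f * t) for f in freqs[:n_ch]])
    labels = [f"ch{i}" for i in range(data.shape[0])]
    return ContinuousEEG(data, fs, labels), t


class TestBandpass:
    def test_passband_sine_preserved_amplitude_and_phase(self):
        eeg, t = sine_eeg([10.0], n_ch=1)
        out = bandpass_filter(eeg, transition_low=2.0)
        mid = slice(1024, -1024)  # avoid edge transients
        amp = np.ptp(out.data[0, mid]) / 2
        assert amp == pytest.approx(1.0, rel=0.05)
        # zero-phase: peak positions coincide with the input
        ref = np.sin(2 * np.pi * 10.0 * t)
        lag = np.argmax(np.correlate(out.data[0, mid], ref[mid], "full"))
        assert lag == len(ref[mid]) - 1

    def test_stopband_sine_attenuated_20db(self):
        # evaluate the designed kernel's response directly at 60 Hz
        kernel = design_bandpass(FS, transition_low=2.0)
        w = np.exp(-2j * np.pi * 60.0 / FS * np.arange(len(kernel)))
        gain = abs(np.sum(kernel * w)) ** 2  # forward-backward squares it
        assert 20 * np.log10(gain) < -20.0

    def test_dc_rejected(self):
        # the narrow default transition (0.25 Hz) is what actually
        # suppresses DC; it needs a recording longer than its kernel
        eeg = ContinuousEEG(np.full((1, 16384), 7.0), FS, ["ch0"])
        out = bandpass_filter(eeg)
        mid = out.data[0, 7000:9000]
        assert np.abs(mid).max() < 0.7  # >= 20 dB down from 7 uV

    def test_too_short_recording_rejected(self):
        eeg = ContinuousEEG(np.zeros((1, 100)), FS, ["ch0"])
        with pytest.raises(ValueError, match="kernel"):
            bandpass_filter(eeg, transition_low=2.0)


class TestAverageReference:
    def test_antisymmetric_pair_unchanged(self):
        eeg = ContinuousEEG(np.array([[1.0, 2.0], [-1.0, -2.0]]), FS, ["a", "b"])
        np.testing.assert_allclose(average_reference(eeg).data, eeg.data)

    def test_common_mode_removed(self):
        eeg = ContinuousEEG(np.tile([[3.0, -1.0, 4.0]], (5, 1)), FS,
                            [f"c{i}" for i in range(5)])
        np.testing.assert_allclose(average_reference(eeg).data, 0.0, atol=1e-12)

    def test_column_sums_zero_and_idempotent(self, rng):
        eeg = ContinuousEEG(rng.standard_normal((6, 200)), FS,
                            [f"c{i}" for i in range(6)])
        once = average_reference(eeg)
        np.testing.assert_allclose(once.data.sum(axis=0), 0.0, atol=1e-10)
        twice = average_reference(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)


class TestSphericalSpline:
    def smooth_field(self, montage):
        # low-order harmonic: linear in the cartesian coordinates
        pos = montage.to_numpy()
        return 2.0 * pos[:, 2] + 0.5 * pos[:, 1] - 0.3 * pos[:, 0]

    def test_constant_field_reproduced(self):
        montage = make_montage()
        eeg = ContinuousEEG(np.full((64, 10), 4.2), FS,
                            list(montage.index), montage=montage)
        out = interpolate_bad_channels(eeg, ["Cz"])
        np.testing.assert_allclose(out.data[eeg.channel_index("Cz")], 4.2,
                                   rtol=1e-3)

    def test_leave_one_out_on_smooth_field(self):
        montage = make_montage()
        field = self.smooth_field(montage)
        data = np.tile(field[:, None], (1, 5))
        eeg = ContinuousEEG(data, FS, list(montage.index), montage=montage)
        for ch in ["Cz", "CPz", "C3"]:
            out = interpolate_bad_channels(eeg, [ch])
            i = eeg.channel_index(ch)
            err = abs(out.data[i, 0] - field[i]) / (abs(field[i]) + 1e-9)
            assert err < 0.05

    def test_matches_mne_interpolation_matrix(self):
        mne_interp = pytest.importorskip(
            "mne.channels.interpolation")._make_interpolation_matrix
        montage = make_montage()
        good = [lab for lab in montage.index if lab not in ("Cz", "Pz")]
        mine = spline_interpolation_matrix(
            montage.loc[good].to_numpy(), montage.loc[["Cz", "Pz"]].to_numpy())
        theirs = mne_interp(montage.loc[good].to_numpy(),
                            montage.loc[["Cz", "Pz"]].to_numpy())
        np.testing.assert_allclose(mine, theirs, atol=5e-3)

    def test_all_bad_rejected(self):
        montage = make_montage(["Fz", "Cz", "Pz", "Oz", "FCz"])
        eeg = ContinuousEEG(np.zeros((5, 4)), FS, list(montage.index),
                            montage=montage)
        with pytest.raises(ValueError):
            interpolate_bad_channels(eeg, list(montage.index))

    def test_flatline_channel_flagged(self, rng):
        data = rng.standard_normal((4, 500))
        data[2] = 0.0
        eeg = ContinuousEEG(data, FS, ["a", "b", "c", "d"])
        assert "c" in flag_bad_channels(eeg)


class TestEpoching:
    def test_grid_has_461_samples_at_512hz(self):
        start, n = epoch_sample_grid(512.0, (-100.0, 800.0))
        assert (start, n) == (-51, 461)
        assert start + n - 1 == 409  # last included sample index

    def test_constant_channel_zeroed_by_baseline(self):
        eeg = ContinuousEEG(np.full((1, 2048), 7.0), FS, ["FCz"])
        info = pd.DataFrame({"condition": ["S-NF-T"], "participant": ["p1"]})
        ep = epoch(eeg, np.array([2.0]), info)
        np.testing.assert_allclose(ep.data, 0.0, atol=1e-12)

    def test_event_near_edge_dropped(self):
        eeg = ContinuousEEG(np.zeros((1, 1024)), FS, ["FCz"])
        info = pd.DataFrame({"condition": ["S-NF-T", "S-NF-T"],
                             "participant": ["p1", "p1"]})
        with pytest.warns(UserWarning, match="dropped"):
            ep = epoch(eeg, np.array([0.05, 1.0]), info)
        assert ep.n_trials == 1

    def test_trials_sorted_by_condition_then_response(self):
        eeg = ContinuousEEG(np.zeros((1, 8192)), FS, ["FCz"])
        info = pd.DataFrame({
            "condition": ["W-NF-T", "S-NF-T", "S-NF-T"],
            "response_type": ["Hit", "Hit", "CorrectRejection"],
            "participant": ["p1"] * 3,
        })
        ep = epoch(eeg, np.array([2.0, 4.0, 6.0]), info)
        assert list(ep.trials["condition"]) == ["S-NF-T", "S-NF-T", "W-NF-T"]
        assert list(ep.trials["response_type"])[:2] == ["CorrectRejection", "Hit"]


class TestAveraging:
    def make_epochs(self, values, participants):
        n = len(values)
        data = np.zeros((1, 4, n))
        for j, v in enumerate(values):
            data[0, :, j] = v
        trials = pd.DataFrame({
            "condition": ["S-NF-T"] * n, "response_type": ["Hit"] * n,
            "group": ["TD"] * n, "participant": participants,
        })
        from mobikit.erp import EpochSet
        return EpochSet(data, np.arange(4) / FS, FS, ["FCz"], trials)

    def test_single_participant_identical_trials_idempotent(self):
        ep = self.make_epochs([3.0, 3.0], ["p1", "p1"])
        ga = grand_average(ep, ["condition"])[("S-NF-T",)]
        np.testing.assert_allclose(ga.data, 3.0)

    def test_participants_weighted_equally_regardless_of_trials(self):
        # p1 has 3 trials at 0, p2 one trial at 6: unweighted mean is 3
        ep = self.make_epochs([0.0, 0.0, 0.0, 6.0], ["p1", "p1", "p1", "p2"])
        ga = grand_average(ep, ["condition"])[("S-NF-T",)]
        np.testing.assert_allclose(ga.data, 3.0)

    def test_difference_wave_linearity(self):
        ep = self.make_epochs([1.0, 5.0], ["p1", "p1"])
        pa = participant_average(ep, ["condition"])
        a = pa[("p1", "S-NF-T")]
        b = ERPAverage(a.data + 2.0, a.times, a.sample_rate, a.labels)
        d = difference_wave(b, a)
        np.testing.assert_allclose(d.data, 2.0)
        with pytest.raises(ValueError):
            difference_wave(b, ERPAverage(np.zeros((1, 3)), a.times[:3],
                                          FS, a.labels))


class TestPeaks:
    def gaussian_avg(self, amp=5.0, lat_ms=240.0, electrode="FCz"):
        start, n = epoch_sample_grid(FS)
        times = (start + np.arange(n)) / FS
        labels = ["FCz", "CPz"]
        data = np.zeros((2, n))
        i = labels.index(electrode)
        data[i] = amp * np.exp(-((times * 1000 - lat_ms) ** 2) / (2 * 20.0**2))
        return ERPAverage(data, times, FS, labels)

    def test_constructed_gaussian_peak(self):
        avg = self.gaussian_avg()
        spec = next(s for s in DEFAULT_COMPONENTS if s.name == "P2")
        pk = extract_peak(avg, spec)
        assert pk.amplitude_uv == pytest.approx(5.0, abs=1e-3)
        assert abs(pk.latency_ms - 240.0) <= 1000.0 / FS
        assert not pk.boundary

    def test_monotone_ramp_flagged_as_boundary(self):
        start, n = epoch_sample_grid(FS)
        times = (start + np.arange(n)) / FS
        avg = ERPAverage(times[None, :] * 10.0, times, FS, ["FCz"])
        spec = ComponentSpec("P2", "FCz", (200.0, 280.0), +1, 25.0)
        pk = extract_peak(avg, spec)
        assert pk.boundary

    def test_group_window_override_accepted(self):
        avg = self.gaussian_avg(amp=6.0, lat_ms=400.0, electrode="CPz")
        spec = next(s for s in DEFAULT_COMPONENTS if s.name == "P3")
        pk = extract_peak(avg, spec, window_ms=(363.0, 463.0))
        assert pk.amplitude_uv == pytest.approx(6.0, abs=0.01)  # grid offset

    def test_negative_polarity_takes_minimum(self):
        avg = self.gaussian_avg(amp=-4.0, lat_ms=330.0)
        spec = next(s for s in DEFAULT_COMPONENTS if s.name == "N2")
        pk = extract_peak(avg, spec)
        assert pk.amplitude_uv == pytest.approx(-4.0, abs=1e-3)

    def test_missing_electrode_raises(self):
        avg = self.gaussian_avg()
        with pytest.raises(KeyError):
            extract_peak(avg, ComponentSpec("P3", "POz", (350, 500), +1, 50))


class TestTopography:
    def test_constant_field_mean(self):
        start, n = epoch_sample_grid(FS)
        times = (start + np.arange(n)) / FS
        avg = ERPAverage(np.full((3, n), 2.5), times, FS, ["a", "b", "c"])
        vals = topographic_window_mean(avg, 300.0, 25.0)
        np.testing.assert_allclose(vals.to_numpy(), 2.5)

    def test_zero_halfwidth_is_nearest_sample(self):
        start, n = epoch_sample_grid(FS)
        times = (start + np.arange(n)) / FS
        data = np.arange(n, dtype=float)[None, :]
        avg = ERPAverage(data, times, FS, ["a"])
        j = int(np.argmin(np.abs(times * 1000 - 300.0)))
        assert topographic_window_mean(avg, 300.0, 0.0).iloc[0] == j

    def test_sequence_of_ten_50ms_segments(self):
        start, n = epoch_sample_grid(FS)
        times = (start + np.arange(n)) / FS
        avg = ERPAverage(np.zeros((2, n)), times, FS, ["a", "b"])
        centers = np.arange(125.0, 600.0, 50.0)  # 125, 175, ..., 575
        maps = [topographic_window_mean(avg, c, 25.0) for c in centers]
        assert len(maps) == 10


class TestPipelineLinearity:
    def test_processing_commutes_with_scaling(self, rng):
        data = rng.standard_normal((3, 4096))
        labels = ["a", "b", "c"]
        info = pd.DataFrame({"condition": ["S-NF-T"] * 2,
                             "participant": ["p1"] * 2})
        onsets = np.array([2.0, 5.0])

        def process(x):
            eeg = ContinuousEEG(x, FS, labels)
            eeg = bandpass_filter(eeg, transition_low=4.0)
            eeg = average_reference(eeg)
            ep = epoch(eeg, onsets, info)
            return grand_average(ep, ["condition"])[("S-NF-T",)].data

        np.testing.assert_allclose(process(3.0 * data), 3.0 * process(data),
                                   rtol=1e-9, atol=1e-9)
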