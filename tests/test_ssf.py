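import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegaad.montage import ElectrodeMontage, project_montage
from eegaad.recording import EEGRecording
from eegaad.ssf import (DecisionWindowSpec, FrequencyBand, SSFMap, band_power,
                        extract_ssf, hemifield_means, interpolate_map,
                        load_maps, normalize_map, preprocess_recording,
                        save_maps, segment_windows)


def make_rec(data, fs, label=None):
    return EEGRecording(data=data, fs=fs,
                        channel_names=[f"ch{i}" for i in range(len(data))],
                        label=label)


class TestPreprocess:
    def test_zscore_postcondition(self, rng):
        rec = make_rec(rng.standard_normal((4, 1400)) * 30 + 5, fs=140.0)
        out = preprocess_recording(rec, 0.5, 70.0)
        assert out.fs == 70.0
        np.testing.assert_allclose(out.data.mean(axis=1), 0, atol=1e-8)
        np.testing.assert_allclose(out.data.std(axis=1), 1, atol=1e-6)

    def test_antialias_attenuation(self):
        # 10 Hz passband tone + 40 Hz out-of-band tone at fs 8192; after
        # decimation to 70 Hz the 40 Hz line (alias at 30 Hz) must be at
        # least 20 dB below the passband line. Oracle: direct FFT band
        # powers of the output (z-scoring rescales both lines equally).
        fs = 8192.0
        t = np.arange(int(8 * fs)) / fs
        sig = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 40 * t)
        rec = make_rec(np.vstack([sig, sig]), fs=fs)
        out = preprocess_recording(rec, 0.5, 70.0)
        p10 = band_power(out, FrequencyBand(9, 11))
        p_alias = band_power(out, FrequencyBand(29, 31))
        assert np.all(p_alias / p10 < 1e-2)

    def test_zero_variance_channel_warns_and_zeros(self):
        data = np.vstack([np.zeros(700), np.random.default_rng(0).standard_normal(700)])
        rec = make_rec(data, fs=70.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = preprocess_recording(rec, 0.5, 70.0)
        np.testing.assert_array_equal(out.data[0], 0.0)
        assert np.isfinite(out.data).all()

    def test_upsampling_rejected(self):
        rec = make_rec(np.zeros((2, 100)), fs=50.0)
        with pytest.raises(ValueError, match="upsampling"):
            preprocess_recording(rec, 0.5, 70.0)

    def test_cutoff_above_nyquist_rejected(self):
        rec = make_rec(np.zeros((2, 100)), fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess_recording(rec, 40.0, 70.0)


class TestSegmentWindows:
    def test_paper_test_window_count(self):
        # 576 s (20% of 48 min) at 70 Hz, 0.1 s windows, no overlap -> 5760
        rec = make_rec(np.zeros((2, int(576 * 70))), fs=70.0)
        wins = segment_windows(rec, DecisionWindowSpec(0.1, overlap=0.0))
        assert len(wins) == 5760

    def test_single_window_when_exact_fit(self):
        rec = make_rec(np.zeros((2, 70)), fs=70.0)
        wins = segment_windows(rec, DecisionWindowSpec(1.0, overlap=0.75))
        assert len(wins) == 1

    def test_eleven_windows_60s_10s_half_overlap(self):
        # floor((60-10)/5)+1 = 11 by direct enumeration
        rec = make_rec(np.zeros((2, 60 * 70)), fs=70.0, label="left")
        wins = segment_windows(rec, DecisionWindowSpec(10.0, overlap=0.5))
        assert len(wins) == 11
        assert [w.window_index for w in wins] == list(range(11))
        assert all(w.label == "left" for w in wins)

    def test_window_too_long_raises(self):
        rec = make_rec(np.zeros((2, 50)), fs=70.0)
        with pytest.raises(ValueError, match="longer than"):
            segment_windows(rec, DecisionWindowSpec(10.0))

    def test_windows_view_correct_samples(self):
        data = np.tile(np.arange(20.0), (2, 1))
        rec = make_rec(data, fs=10.0)
        wins = segment_windows(rec, DecisionWindowSpec(1.0, overlap=0.5))
        np.testing.assert_array_equal(wins[1].data[0], np.arange(5.0, 15.0))

    @given(st.integers(2, 1000), st.integers(1, 200), st.integers(1, 100))
    @settings(max_examples=200, deadline=None)
    def test_count_matches_enumeration(self, n_samples, length, step):
        # brute-force enumeration of valid start offsets
        if length > n_samples:
            return
        expected = len(range(0, n_samples - length + 1, step))
        count = (n_samples - length) // step + 1
        assert count == expected

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            DecisionWindowSpec(0.0)
        with pytest.raises(ValueError):
            DecisionWindowSpec(1.0, overlap=1.0)


class TestBandPower:
    def test_zero_signal(self):
        rec = make_rec(np.zeros((3, 700)), fs=70.0)
        np.testing.assert_array_equal(band_power(rec, FrequencyBand(8, 13)), 0.0)

    def test_parseval_disjoint_cover(self, rng):
        rec = make_rec(rng.standard_normal((3, 701)), fs=70.0)
        edges = [0.0, 5.0, 13.0, 20.0, 35.0]
        total = np.zeros(3)
        freqs = np.fft.rfftfreq(701, d=1 / 70.0)
        for lo, hi in zip(edges[:-1], edges[1:]):
            # half-open cover: exclude the upper edge bin except for the last
            hi_adj = hi - 1e-9 if hi != edges[-1] else hi
            sel = FrequencyBand(max(lo, 0.01), hi_adj)  # 0.01 keeps DC out
            total += band_power(rec, sel)
        # add the DC bin (excluded because FrequencyBand needs low > 0)
        dc = np.abs(np.fft.rfft(rec.data, axis=1)[:, 0] / 701) ** 2
        total += dc
        ms = np.mean(rec.data**2, axis=1)
        np.testing.assert_allclose(total, ms, rtol=1e-9)

    def test_sinusoid_time_domain_oracle(self):
        # unit-amplitude 10 Hz sinusoid, fs 70, 10 s: alpha power equals the
        # signal's total power A^2/2 = 0.5; (20, 30) Hz power is ~0
        fs, dur = 70.0, 10.0
        t = np.arange(int(fs * dur)) / fs
        sig = np.sin(2 * np.pi * 10.0 * t)
        rec = make_rec(np.vstack([sig, 2 * sig]), fs=fs)
        alpha = band_power(rec, FrequencyBand(8, 13))
        oracle = np.var(np.vstack([sig, 2 * sig]), axis=1)
        np.testing.assert_allclose(alpha, oracle, rtol=0.01)
        assert alpha[0] == pytest.approx(0.5, rel=0.01)
        np.testing.assert_array_less(band_power(rec, FrequencyBand(20, 30)), 1e-6)

    def test_empty_band_raises(self):
        rec = make_rec(np.zeros((2, 10)), fs=70.0)  # resolution 7 Hz
        with pytest.raises(ValueError, match="no FFT bins"):
            band_power(rec, FrequencyBand(8, 13))

    def test_band_above_nyquist_raises(self):
        rec = make_rec(np.zeros((2, 700)), fs=70.0)
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(rec, FrequencyBand(30, 40))

    def test_too_short_window_raises(self):
        rec = make_rec(np.zeros((2, 1)), fs=70.0)
        with pytest.raises(ValueError, match="2 samples"):
            band_power(rec, FrequencyBand(8, 13))


class TestInterpolateMap:
    def test_constant_field(self, projected64):
        grid = interpolate_map(np.full(64, 3.25), projected64)
        assert grid.shape == (28, 28)
        in_hull = grid != 0.0
        assert in_hull.sum() > 100
        np.testing.assert_allclose(grid[in_hull], 3.25, atol=1e-9)

    def test_linear_field_oracle(self, projected64):
        # Clough-Tocher reproduces linear fields: direct plane evaluation
        a, b = 1.7, -0.9
        u, w = projected64.pos2d[:, 0], projected64.pos2d[:, 1]
        vals = a * u + b * w
        grid = interpolate_map(vals, projected64, fill=np.nan)
        r = 1.05 * np.max(np.linalg.norm(projected64.pos2d, axis=1))
        us = np.linspace(-r, r, 28)
        vs = np.linspace(r, -r, 28)
        uu, vv = np.meshgrid(us, vs)
        expected = a * uu + b * vv
        mask = ~np.isnan(grid)
        np.testing.assert_allclose(grid[mask], expected[mask], atol=1e-6)

    def test_node_coincident_with_electrode(self):
        # place electrodes so one lands exactly on a grid node
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0],
                        [0.0, -1.0]])
        m = ElectrodeMontage(names=list("abcde"),
                             pos3d=np.column_stack([pts, np.ones(5)]))
        m.pos2d = pts
        vals = np.array([5.0, 1.0, 2.0, 3.0, 4.0])
        grid = interpolate_map(vals, m, grid_n=29)  # odd: node at (0,0)
        center = grid[14, 14]
        assert center == pytest.approx(5.0, abs=1e-9)

    def test_permutation_invariance(self, projected64, rng):
        vals = rng.standard_normal(64)
        grid = interpolate_map(vals, projected64)
        perm = rng.permutation(64)
        shuffled = ElectrodeMontage(
            names=[projected64.names[i] for i in perm],
            pos3d=projected64.pos3d[perm],
        )
        shuffled.pos2d = projected64.pos2d[perm]
        grid2 = interpolate_map(vals[perm], shuffled)
        # triangulation tie-breaking differs slightly with point order
        np.testing.assert_allclose(grid, grid2, atol=1e-6)

    def test_requires_projection(self, montage64):
        with pytest.raises(ValueError, match="project_montage"):
            interpolate_map(np.zeros(64), montage64)

    def test_collinear_electrodes_fail(self):
        pts = np.column_stack([np.linspace(-1, 1, 5), np.zeros(5)])
        m = ElectrodeMontage(names=list("abcde"),
                             pos3d=np.column_stack([pts, np.ones(5)]))
        m.pos2d = pts
        with pytest.raises(ValueError, match="triangulation"):
            interpolate_map(np.zeros(5), m)


class TestNormalizeMap:
    def test_range_and_invertibility(self, rng):
        grid = rng.standard_normal((28, 28)) * 7 + 3
        scaled, info = normalize_map(grid)
        assert scaled.min() == pytest.approx(-1)
        assert scaled.max() == pytest.approx(1)
        back = (scaled + 1) / 2 * (info["vmax"] - info["vmin"]) + info["vmin"]
        np.testing.assert_allclose(back, grid, atol=1e-12)

    def test_degenerate_constant_map(self):
        scaled, info = normalize_map(np.full((28, 28), 4.0))
        np.testing.assert_array_equal(scaled, 0.0)
        assert info["degenerate"]


class TestExtractSSF:
    def test_window_count_and_labels(self, montage64, rng):
        data = rng.standard_normal((64, 60 * 70))
        rec = EEGRecording(data=data, fs=70.0, channel_names=montage64.names,
                          label="right", subject_id="S7", trial_id="T3")
        maps = extract_ssf(rec, DecisionWindowSpec(10.0, 0.5),
                           FrequencyBand(8, 13), montage64)
        assert len(maps) == 11
        assert all(m.grid.shape == (28, 28) for m in maps)
        assert all(m.label == "right" for m in maps)
        assert [m.window_index for m in maps] == list(range(11))
        assert all(m.subject_id == "S7" and m.trial_id == "T3" for m in maps)
        assert all(np.abs(m.grid).max() <= 1.0 for m in maps)

    def test_zero_eeg_gives_zero_maps(self, montage64):
        rec = EEGRecording(data=np.zeros((64, 140)), fs=70.0,
                          channel_names=montage64.names, label="left")
        maps = extract_ssf(rec, DecisionWindowSpec(2.0, 0.0),
                           FrequencyBand(8, 13), montage64)
        assert len(maps) == 1
        np.testing.assert_array_equal(maps[0].grid, 0.0)
        assert maps[0].scale_info["degenerate"]

    def test_deterministic_bit_identical(self, montage64, rng):
        data = rng.standard_normal((64, 280))
        rec = EEGRecording(data=data, fs=70.0, channel_names=montage64.names)
        kw = dict(spec=DecisionWindowSpec(2.0, 0.5), band=FrequencyBand(8, 13),
                  montage=montage64)
        a = extract_ssf(rec, **kw)
        b = extract_ssf(rec, **kw)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.grid, mb.grid)

    def test_class_difference_has_opposite_hemifield_signs(self, highsnr_maps):
        maps, _ = highsnr_maps
        mean_l = np.mean([m.grid for m in maps if m.label == "left"], axis=0)
        mean_r = np.mean([m.grid for m in maps if m.label == "right"], axis=0)
        diff_left_hemi, diff_right_hemi = hemifield_means(mean_l - mean_r)
        assert diff_left_hemi * diff_right_hemi < 0

    def test_channel_mismatch_raises(self, montage64, rng):
        rec = make_recording_with_names(rng, ["x", "y", "z", "w"])
        with pytest.raises(ValueError, match="montage"):
            extract_ssf(rec, DecisionWindowSpec(1.0), FrequencyBand(8, 13),
                        montage64)


def make_recording_with_names(rng, names):
    return EEGRecording(data=rng.standard_normal((len(names), 140)), fs=70.0,
                        channel_names=names)


class TestMapIO:
    def test_hdf5_roundtrip(self, tmp_path, highsnr_maps):
        maps, _ = highsnr_maps
        path = tmp_path / "maps.h5"
        save_maps(maps, path)
        loaded = load_maps(path)
        assert len(loaded) == len(maps)
        for a, b in zip(maps, loaded):
            np.testing.assert_array_equal(a.grid, b.grid)
            assert a.label == b.label
            assert a.subject_id == b.subject_id
            assert a.window_index == b.window_index

    def test_unlabeled_maps_roundtrip(self, tmp_path):
        maps = [SSFMap(grid=np.zeros((28, 28)))]
        save_maps(maps, tmp_path / "m.h5")
        assert load_maps(tmp_path / "m.h5")[0].label is None
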