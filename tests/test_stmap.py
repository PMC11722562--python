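"""STMap construction, resampling, augmentation and container I/O."""

import numpy as np
import pytest

from multiphys.stmap import (
    AugmentConfig,
    FrameSequence,
    STMap,
    augment,
    export_png,
    frames_to_stmap,
    load_sample,
    read_vitals_csv,
    resample_30hz,
    resize_stmap,
    save_sample,
    write_vitals_csv,
)


def gray_video(n_frames=10, size=16, level=128):
    frames = np.full((n_frames, size, size, 3), level, dtype=np.uint8)
    t = np.arange(n_frames) / 30.0
    return FrameSequence(frames=frames, timestamps=t)


class TestFramesToStmap:
    def test_uniform_video_degenerate_rows(self):
        with pytest.warns(UserWarning, match="constant"):
            m = frames_to_stmap(gray_video(), grid=(2, 2))
        assert m.values.shape == (4, 10, 3)
        assert np.all(m.values == 0.5)

    def test_width_equals_frame_count(self):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 255, size=(25, 8, 8, 3), dtype=np.uint8)
        fs = FrameSequence(frames=frames, timestamps=np.arange(25) / 30.0)
        m = frames_to_stmap(fs, grid=(2, 2))
        assert m.values.shape == (4, 25, 3)
        assert m.roi_count == 4

    def test_sine_block_recovers_waveform_and_frequency(self):
        # green channel 100 + 10 sin(2 pi 1.2 t) at 30 fps in a single block
        fps, T = 30.0, 256
        t = np.arange(T) / fps
        sig = 100 + 10 * np.sin(2 * np.pi * 1.2 * t)
        frames = np.zeros((T, 4, 4, 3))
        frames[:, :, :, 1] = sig[:, None, None]
        fs = FrameSequence(frames=frames.astype(np.uint8), timestamps=t)
        with pytest.warns(UserWarning):  # red/blue channels are constant
            m = frames_to_stmap(fs, grid=(1, 1))
        row = m.values[0, :, 1]
        # min-max of a sinusoid: (sin + 1) / 2, up to uint8 quantization
        expected = (np.sin(2 * np.pi * 1.2 * t - np.pi / 2) + 1) / 2  # phase per min position
        # compare spectra instead of phase bookkeeping: peak bin at 1.2 Hz
        spec = np.abs(np.fft.rfft(row - row.mean()))
        freqs = np.fft.rfftfreq(T, 1 / fps)
        assert freqs[np.argmax(spec)] == pytest.approx(1.2, abs=fps / T)
        assert row.min() == pytest.approx(0.0) and row.max() == pytest.approx(1.0)

    def test_dominant_frequency_preserved_over_band(self):
        fps, T = 30.0, 256
        t = np.arange(T) / fps
        rng = np.random.default_rng(3)
        for f in rng.uniform(0.7, 3.0, size=20):
            sig = 120 + 30 * np.sin(2 * np.pi * f * t)
            frames = np.repeat(sig[:, None, None, None], 3, axis=3)
            frames = np.broadcast_to(frames, (T, 4, 4, 3)).astype(np.uint8)
            m = frames_to_stmap(FrameSequence(frames=frames, timestamps=t), grid=(2, 2))
            row = m.values[0, :, 1]
            spec = np.abs(np.fft.rfft(row - row.mean()))
            freqs = np.fft.rfftfreq(T, 1 / fps)
            assert abs(freqs[np.argmax(spec)] - f) <= fps / T

    def test_grid_must_tile_roi(self):
        with pytest.raises(ValueError):
            frames_to_stmap(gray_video(size=10), grid=(3, 3))


class TestResample:
    def test_identity_on_uniform_30hz(self):
        t = np.arange(64) / 30.0
        v = np.sin(t * 3.0)
        grid, out = resample_30hz(t, v)
        assert np.allclose(grid, t, atol=1e-12)
        assert np.allclose(out, v, atol=1e-9)

    def test_linear_ramp_reproduced_exactly(self):
        t = np.arange(32) / 15.0
        v = 2.5 * t - 1.0
        grid, out = resample_30hz(t, v)
        assert np.allclose(out, 2.5 * grid - 1.0, atol=1e-12)

    def test_cubic_polynomial_reproduced(self):
        t = np.arange(16) / 10.0
        v = t**3 - 2 * t**2 + 0.5 * t
        grid, out = resample_30hz(t, v)
        assert np.allclose(out, grid**3 - 2 * grid**2 + 0.5 * grid, atol=1e-9)

    def test_sine_at_25hz_accurate_to_1e3(self):
        t = np.arange(0, 4.0, 1 / 25.0)
        v = np.sin(2 * np.pi * 2.0 * t)
        grid, out = resample_30hz(t, v)
        err = np.abs(out - np.sin(2 * np.pi * 2.0 * grid))
        interior = (grid > t[0] + 0.5) & (grid < t[-1] - 0.5)
        assert err[interior].max() < 1e-3
        # boundary panels of a not-a-knot spline are slightly less accurate
        assert err.max() < 2e-3

    def test_duplicate_timestamps_rejected(self):
        t = np.array([0.0, 0.1, 0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            resample_30hz(t, np.zeros(5))

    def test_needs_four_samples(self):
        with pytest.raises(ValueError):
            resample_30hz(np.array([0.0, 0.1, 0.2]), np.zeros(3))


class TestAugment:
    def map_(self, rng):
        return STMap(values=rng.random((8, 32, 3)), rate=30.0)

    def test_no_op_config_is_identity(self, rng):
        cfg = AugmentConfig(jitter_brightness=0, jitter_contrast=0,
                            jitter_saturation=0, blur_sigma_range=(0, 0))
        m = self.map_(rng)
        assert np.allclose(augment(m, cfg).values, m.values, atol=1e-12)

    def test_same_seed_reproduces(self, rng):
        m = self.map_(rng)
        cfg = AugmentConfig(seed=42)
        a1, a2 = augment(m, cfg), augment(m, cfg)
        assert np.array_equal(a1.values, a2.values)

    def test_output_in_unit_interval_and_shape_kept(self, rng):
        m = self.map_(rng)
        for seed in range(100):
            out = augment(m, AugmentConfig(jitter_brightness=0.5, jitter_contrast=0.5,
                                           jitter_saturation=0.5, blur_sigma_range=(0, 2), seed=seed))
            assert out.values.shape == m.values.shape
            assert out.rate == m.rate and out.roi_count == m.roi_count
            assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_invalid_jitter_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(jitter_brightness=0.6)


class TestIO:
    def test_hdf5_roundtrip(self, tmp_path, rng):
        m = STMap(values=rng.random((8, 32, 3)), rate=30.0)
        bvp = rng.standard_normal(32)
        path = tmp_path / "s.h5"
        save_sample(path, m, hr=72.0, spo2=97.0, rr=15.0, bvp=bvp, seed=9)
        m2, labels = load_sample(path)
        assert np.allclose(m2.values, m.values, atol=1e-6)
        assert labels["hr"] == pytest.approx(72.0)
        assert labels["seed"] == 9
        assert np.allclose(labels["bvp"], bvp, atol=1e-6)

    def test_png_export(self, tmp_path, rng):
        from PIL import Image

        m = STMap(values=rng.random((8, 32, 3)), rate=30.0)
        path = tmp_path / "m.png"
        export_png(path, m)
        img = Image.open(path)
        assert img.size == (32, 8) and img.mode == "RGB"

    def test_vitals_csv_roundtrip(self, tmp_path, rng):
        t = np.arange(30) / 30.0
        bvp = rng.standard_normal(30)
        path = tmp_path / "v.csv"
        write_vitals_csv(path, t, bvp, hr=72.0)
        df = read_vitals_csv(path)
        assert list(df.columns) == ["t_sec", "bvp", "hr"]
        assert np.allclose(df["bvp"], bvp)

    def test_resize_to_network_shape(self, rng):
        m = STMap(values=rng.random((10, 100, 3)), rate=30.0)
        out = resize_stmap(m, (64, 256))
        assert out.values.shape == (64, 256, 3)

    def test_load_frame_dir_roundtrip(self, tmp_path, rng):
        from PIL import Image

        from multiphys.stmap import load_frame_dir

        frames = rng.integers(0, 255, size=(5, 8, 8, 3), dtype=np.uint8)
        for i, f in enumerate(frames):
            Image.fromarray(f, mode="RGB").save(tmp_path / f"frame_{i:03d}.png")
        fs = load_frame_dir(tmp_path, fps=30.0)
        assert np.array_equal(fs.frames, frames)  # PNG is lossless
        assert np.allclose(fs.timestamps, np.arange(5) / 30.0)

    def test_window_stmap_nonoverlapping(self, rng):
        from multiphys.stmap import window_stmap

        m = STMap(values=rng.random((4, 70, 3)), rate=30.0)
        wins = window_stmap(m, width=32)
        assert len(wins) == 2  # trailing 6 frames dropped
        assert all(w.values.shape == (4, 32, 3) for w in wins)
        assert np.array_equal(wins[1].values, m.values[:, 32:64])
        halfstep = window_stmap(m, width=32, overlap=16)
        assert len(halfstep) == 3
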