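"""Virtual scanning: PSF rendering, envelope/B/M-mode formation,
multi-cycle composition and noise."""

import numpy as np
import pytest

import pulsart as pa
from pulsart.estimate import track_echo_shift
from pulsart.scanner import depth_axis_mm, n_rf_samples


def _single_scatterer_map(geometry, x=0.0, y=0.0, z=20.0, amp=1.0):
    pos = np.array([[x, y, z]])
    return pa.ScattererMap(pos, np.array([amp]), pa.classify_layer(pos, geometry), geometry)


@pytest.fixture()
def shallow_scan():
    return pa.ScanConfig(n_lines=1, depth_range_mm=(0.0, 30.0))


class TestConfig:
    def test_default_scan_grid_spans_image_width(self):
        scan = pa.ScanConfig()
        assert scan.n_lines == 160
        assert scan.line_spacing_mm == 0.0625
        assert scan.image_width_mm == pytest.approx(10.0, abs=1e-9)
        assert np.allclose(np.diff(scan.line_x_mm), 0.0625)

    def test_pitch_consistency_enforced(self):
        with pytest.raises(Exception):
            pa.TransducerConfig(pitch_mm=0.5)

    def test_depth_axis_step(self, default_transducer):
        scan = pa.ScanConfig()
        axis = depth_axis_mm(default_transducer, scan)
        assert axis[0] == pytest.approx(11.0)
        assert np.diff(axis)[0] == pytest.approx(1540e3 / (2 * 40e6), rel=1e-12)


class TestRender:
    def test_echo_at_expected_delay(self, default_geometry, default_transducer, shallow_scan):
        z = 20.0
        smap = _single_scatterer_map(default_geometry, z=z)
        rf = pa.render_rf_frame(smap, default_transducer, shallow_scan)
        env = pa.envelope(rf)
        expected = round(2 * z / (1540e3) * 40e6)
        assert abs(int(env[0].argmax()) - expected) <= 1

    def test_superposition_cancels(self, default_geometry, default_transducer, shallow_scan):
        pos = np.array([[0.0, 0.0, 20.0], [0.0, 0.0, 20.0]])
        smap = pa.ScattererMap(
            pos, np.array([1.0, -1.0]), pa.classify_layer(pos, default_geometry), default_geometry
        )
        rf = pa.render_rf_frame(smap, default_transducer, shallow_scan)
        assert np.abs(rf).max() == 0.0

    def test_linearity_in_amplitudes(self, default_geometry, default_transducer, shallow_scan):
        smap = _single_scatterer_map(default_geometry, amp=1.0)
        doubled = _single_scatterer_map(default_geometry, amp=2.0)
        rf1 = pa.render_rf_frame(smap, default_transducer, shallow_scan)
        rf2 = pa.render_rf_frame(doubled, default_transducer, shallow_scan)
        assert np.allclose(rf2, 2.0 * rf1, rtol=1e-12)

    def test_empty_map_renders_zero_frame(self, default_geometry, default_transducer, shallow_scan):
        smap = pa.ScattererMap(
            np.empty((0, 3)), np.empty(0), np.empty(0, dtype=np.int8), default_geometry
        )
        rf = pa.render_rf_frame(smap, default_transducer, shallow_scan)
        assert rf.shape == (1, n_rf_samples(default_transducer, shallow_scan))
        assert np.all(rf == 0)

    def test_out_of_range_scatterer_excluded(self, default_geometry, default_transducer):
        scan = pa.ScanConfig(n_lines=1, depth_range_mm=(11.0, 29.0))
        smap = _single_scatterer_map(default_geometry, z=40.0)
        rf = pa.render_rf_frame(smap, default_transducer, scan)
        assert np.all(rf == 0)

    def test_determinism_bitwise(self, default_geometry, default_transducer):
        scan = pa.ScanConfig(n_lines=4)
        smap = pa.generate_scatterers(
            default_geometry, pa.LayerScattering(), default_transducer, 1.0, seed=0
        )
        a = pa.render_rf_frame(smap, default_transducer, scan)
        b = pa.render_rf_frame(smap, default_transducer, scan)
        assert np.array_equal(a, b)

    def test_axial_shift_fidelity(self, default_geometry, default_transducer):
        """Displacing all scatterers by dz moves the correlation peak by
        2 dz / c * fs samples — the basis of echo-shift tracking."""
        scan = pa.ScanConfig(n_lines=1)
        rng = np.random.default_rng(5)
        n = 400
        pos = np.column_stack(
            [rng.uniform(-1, 1, n), rng.uniform(-1, 1, n), rng.uniform(18, 24, n)]
        )
        smap = pa.ScattererMap(
            pos, rng.standard_normal(n), pa.classify_layer(pos, default_geometry), default_geometry
        )
        dz = 0.05  # mm, below half a wavelength
        moved = smap.with_positions(pos + np.array([0.0, 0.0, dz]))
        rf_a = pa.render_rf_frame(smap, default_transducer, scan)
        rf_b = pa.render_rf_frame(moved, default_transducer, scan)
        d_um, corr = track_echo_shift(rf_a[0], rf_b[0], 550, 64, 10, 19.25)
        assert corr > 0.9
        assert d_um == pytest.approx(dz * 1000, abs=2.0)

    def test_wall_boundary_echoes_visible_on_midline(
        self, default_geometry, default_transducer
    ):
        """The lumen-intima and media-adventitia interfaces of both walls
        produce local envelope maxima (the double-line signature)."""
        scan = pa.ScanConfig(n_lines=5)
        geometry = pa.ArteryGeometry(block_x_mm=(-1.5, 1.5), block_y_mm=(-1.5, 1.5))
        smap = pa.generate_scatterers(
            geometry, pa.LayerScattering(), default_transducer, 10.0, seed=11
        )
        rf = pa.render_rf_frame(smap, default_transducer, scan)
        env = pa.envelope(rf).mean(axis=0)
        from scipy import ndimage

        env = ndimage.gaussian_filter1d(env, 3)
        depth = depth_axis_mm(default_transducer, scan)

        def band_max(lo, hi):
            return env[(depth > lo) & (depth < hi)].max()

        def band_min(lo, hi):
            return env[(depth > lo) & (depth < hi)].min()

        # distal wall: bright lumen-intima and adventitia lines separated
        # by the hypoechoic media; mirrored on the proximal side
        assert band_max(19.85, 20.25) > 1.5 * band_min(20.3, 20.6)
        assert band_max(20.65, 21.05) > 1.5 * band_min(20.3, 20.6)
        assert band_max(14.75, 15.15) > 1.5 * band_min(14.4, 14.7)
        assert band_max(13.95, 14.35) > 1.5 * band_min(14.4, 14.7)
        # the anechoic lumen is far darker than the wall echoes
        assert band_max(19.85, 20.25) > 5 * band_max(16.5, 18.5)


class TestEnvelopeAndBmode:
    def test_zero_line_zero_envelope(self):
        assert np.all(pa.envelope(np.zeros((2, 64))) == 0)

    def test_pure_tone_constant_envelope(self):
        t = np.arange(512) / 40e6
        rf = np.cos(2 * np.pi * 5e6 * t)[None, :]
        env = pa.envelope(rf)
        core = env[0, 64:-64]
        assert np.allclose(core, 1.0, atol=0.01)

    def test_envelope_bounds_rf(self):
        rng = np.random.default_rng(0)
        rf = rng.standard_normal((3, 256))
        assert np.all(pa.envelope(rf) >= np.abs(rf) - 1e-9)

    def test_bmode_max_is_zero_db_and_clipped(self):
        rng = np.random.default_rng(1)
        rf = rng.standard_normal((4, 256))
        img = pa.bmode(rf)
        assert img.max() == pytest.approx(0.0)
        assert img.min() >= -73.0

    def test_bmode_monotone_in_envelope(self):
        rf = np.zeros((1, 400))
        t = np.arange(400) / 40e6
        rf[0] = np.cos(2 * np.pi * 5e6 * t) * np.linspace(0.1, 1.0, 400)
        img = pa.bmode(rf)
        assert img[0, 350] > img[0, 60]

    def test_all_zero_frame_rejected(self):
        with pytest.raises(ValueError):
            pa.bmode(np.zeros((2, 64)))


class TestMmodeAndComposition:
    def _tiny_sequence(self, n_frames=3):
        rng = np.random.default_rng(0)
        frames = np.repeat(rng.standard_normal((1, 2, 128)), n_frames, axis=0)
        return pa.RFSequence(
            frames=frames,
            fs_hz=40e6,
            line_x_mm=np.array([0.0, 0.0625]),
            depth_mm=11.0 + np.arange(128) * 0.01925,
            frame_rate_hz=52.0,
        )

    def test_static_sequence_gives_identical_mmode_columns(self):
        seq = self._tiny_sequence()
        img = pa.mmode(seq, 0)
        assert img.shape == (128, 3)
        assert np.allclose(img[:, 0], img[:, 1])

    def test_single_frame_mmode_single_column(self):
        seq = self._tiny_sequence(n_frames=1)
        assert pa.mmode(seq, 1).shape == (128, 1)

    def test_line_index_out_of_range(self):
        with pytest.raises(IndexError):
            pa.mmode(self._tiny_sequence(), 5)

    def test_compose_cycles_identity_and_tiling(self):
        seq = self._tiny_sequence(n_frames=4)
        assert pa.compose_cycles(seq, 1) is seq
        tiled = pa.compose_cycles(seq, 3)
        assert tiled.n_frames == 12
        for f in range(12):
            assert np.array_equal(tiled.frames[f], seq.frames[f % 4])

    def test_add_noise_power_at_zero_db(self):
        seq = self._tiny_sequence(n_frames=2)
        noisy = pa.add_noise(seq, snr_db=0.0, seed=4)
        noise = noisy.frames[0] - seq.frames[0]
        p_sig = np.mean(seq.frames[0] ** 2)
        assert np.mean(noise**2) == pytest.approx(p_sig, rel=0.3)

    def test_add_noise_seeded_and_finite_snr_required(self):
        seq = self._tiny_sequence()
        a = pa.add_noise(seq, 10.0, seed=1)
        b = pa.add_noise(seq, 10.0, seed=1)
        assert np.array_equal(a.frames, b.frames)
        with pytest.raises(ValueError):
            pa.add_noise(seq, np.inf)

    def test_sequence_hdf5_roundtrip(self, tmp_path):
        seq = self._tiny_sequence()
        path = tmp_path / "rf.h5"
        seq.to_hdf5(path)
        back = pa.RFSequence.from_hdf5(path)
        assert np.array_equal(back.frames, seq.frames)
        assert back.fs_hz == seq.fs_hz
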