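"""Displacement estimators: windowed 1D cross-correlation, optical flow
(Horn–Schunck + Liu–Shen) and semi-Lagrangian accumulation."""

import numpy as np
import pytest
from scipy import ndimage

import pulsart as pa
from pulsart.estimate import (
    DisplacementField,
    OOFParams,
    _ncc_lags,
    accumulate,
    track_echo_shift,
)

AXIAL_UM = 1540e3 / (2 * 40e6) * 1000  # ~19.25 um per RF sample


def _speckle_image(shape=(60, 200), seed=0):
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.rayleigh(size=shape), 1.5)
    return (img - img.min()) / np.ptp(img) * 255.0


def _rf_line(n=1024, seed=0):
    """Band-limited speckle-like RF line (5 MHz carrier at 40 MHz fs)."""
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n)
    t = np.arange(n) / 40e6
    carrier = np.cos(2 * np.pi * 5e6 * t)
    return ndimage.gaussian_filter1d(noise, 3) * carrier


def _sequence_from_lines(lines):
    frames = np.stack([np.asarray(l)[None, :] for l in lines])
    return pa.RFSequence(
        frames=frames,
        fs_hz=40e6,
        line_x_mm=np.array([0.0]),
        depth_mm=11.0 + np.arange(frames.shape[-1]) * AXIAL_UM / 1000,
        frame_rate_hz=52.0,
    )


class TestCC1D:
    def test_identical_frames_give_zero(self):
        line = _rf_line()
        seq = _sequence_from_lines([line, line])
        field = pa.cc1d_interframe(seq)
        # interior windows only: edge windows see the zero padding; the
        # parabolic sub-sample refinement leaves micrometre-scale jitter
        interior = field.interframe_axial_um[0, 0, 2:-2][field.valid[0, 0, 2:-2]]
        assert np.abs(np.median(interior)) < 0.1
        assert np.abs(interior).max() < 2.0  # a tenth of a sample
        assert field.valid.mean() > 0.9

    def test_four_sample_shift_is_77um(self):
        line = _rf_line()
        seq = _sequence_from_lines([line, np.roll(line, 4)])
        field = pa.cc1d_interframe(seq)
        good = field.valid[0, 0, 2:-2]
        est = field.interframe_axial_um[0, 0, 2:-2][good]
        assert np.median(est) == pytest.approx(4 * AXIAL_UM, abs=1.0)

    def test_shift_beyond_half_wavelength_flagged_invalid(self):
        # 0.2 mm ~ 10.4 samples, beyond the lambda/2 = 154 um bound
        line = _rf_line()
        shift = int(round(0.2 * 1000 / AXIAL_UM))
        seq = _sequence_from_lines([line, np.roll(line, shift)])
        field = pa.cc1d_interframe(seq)
        assert field.valid[0, 0, 2:-2].mean() < 0.2

    def test_zero_variance_window_invalid_not_fatal(self):
        line = _rf_line()
        dead = line.copy()
        dead[:200] = 0.0
        seq = _sequence_from_lines([dead, dead])
        field = pa.cc1d_interframe(seq)
        assert not field.valid[0, 0, 0]

    def test_subsample_accuracy_on_rendered_speckle(
        self, default_geometry, default_transducer
    ):
        """Rigid sub-half-wavelength shifts of real rendered RF are
        recovered to better than a tenth of a sample."""
        scan = pa.ScanConfig(n_lines=1)
        rng = np.random.default_rng(8)
        n = 600
        pos = np.column_stack(
            [rng.uniform(-1, 1, n), rng.uniform(-1, 1, n), rng.uniform(12, 28, n)]
        )
        smap = pa.ScattererMap(
            pos, rng.standard_normal(n), pa.classify_layer(pos, default_geometry), default_geometry
        )
        dz = 0.04  # mm
        moved = smap.with_positions(pos + [0.0, 0.0, dz])
        rf_a = pa.render_rf_frame(smap, default_transducer, scan)
        rf_b = pa.render_rf_frame(moved, default_transducer, scan)
        seq = _sequence_from_lines([rf_a[0], rf_b[0]])
        field = pa.cc1d_interframe(seq)
        est = field.interframe_axial_um[0, 0][field.valid[0, 0]]
        assert np.median(est) == pytest.approx(dz * 1000, abs=AXIAL_UM / 10)

    def test_ncc_normalization_bounds(self):
        rng = np.random.default_rng(0)
        win = rng.standard_normal(64)
        seg = rng.standard_normal(64 + 16)
        corr = _ncc_lags(win, seg)
        assert np.all(np.abs(corr) <= 1.0 + 1e-9)
        perfect = _ncc_lags(win, np.concatenate([np.zeros(8), win, np.zeros(8)]))
        assert perfect.max() == pytest.approx(1.0, abs=1e-9)


class TestTrackEchoShift:
    def test_integer_shift_recovered(self):
        line = _rf_line(seed=3)
        d, corr = track_echo_shift(line, np.roll(line, 4), 512, 64, 10, AXIAL_UM)
        assert d == pytest.approx(4 * AXIAL_UM, abs=0.5)
        assert corr == pytest.approx(1.0, abs=1e-6)

    def test_multi_wavelength_shift_resolved_by_envelope(self):
        # 20 samples is 2.5 carrier wavelengths: plain argmax may pick a
        # neighbouring cycle, the envelope prior must not
        line = _rf_line(seed=4)
        d, _ = track_echo_shift(line, np.roll(line, 20), 512, 64, 30, AXIAL_UM)
        assert d == pytest.approx(20 * AXIAL_UM, abs=1.0)


class TestOOFPreprocess:
    def test_display_mapping_endpoints_and_midpoint(self):
        t = np.arange(4096) / 40e6
        carrier = np.cos(2 * np.pi * 5e6 * t)
        amp = np.ones(4096)
        amp[1000:1400] = 10 ** (-45 / 20.0)  # -45 dB plateau
        img = pa.oof_preprocess((amp * carrier)[None, :])
        assert img.max() == pytest.approx(255.0)
        # -45 dB sits at the midpoint of the [-90, 0] dB -> [0, 255] map
        assert img[0, 1100:1300].mean() == pytest.approx(127.5, abs=3.0)
        assert img.min() >= 0.0 and img.max() <= 255.0
        # regions below the floor map exactly to 0
        floored = pa.oof_preprocess((amp * carrier)[None, :], floor_db=-20.0)
        assert floored[0, 1100:1300].min() == 0.0

    def test_all_zero_frame_rejected(self):
        with pytest.raises(ValueError):
            pa.oof_preprocess(np.zeros((2, 64)))


class TestOpticalFlow:
    def test_identical_images_give_zero_flow(self):
        img = _speckle_image()
        f0, f1 = pa.optical_flow(img, img)
        assert np.abs(f0).max() < 1e-6
        assert np.abs(f1).max() < 1e-6

    @pytest.mark.parametrize("shift,axis", [(1, 1), (2, 0), (3, 1)])
    def test_translation_recovery(self, shift, axis):
        img = _speckle_image()
        moved = np.roll(img, shift, axis=axis)
        f0, f1 = pa.optical_flow(img, moved)
        interior = (slice(10, -10), slice(20, -20))
        main = (f0 if axis == 0 else f1)[interior].mean()
        other = (f1 if axis == 0 else f0)[interior].mean()
        assert main == pytest.approx(shift, rel=0.1)
        assert abs(other) < 0.1 * shift

    def test_lateral_shift_dominates_lateral_component(self):
        img = _speckle_image(seed=5)
        moved = np.roll(img, 2, axis=0)
        f_lat, f_ax = pa.optical_flow(img, moved)
        interior = (slice(10, -10), slice(20, -20))
        assert np.abs(f_lat[interior]).mean() > 5 * np.abs(f_ax[interior]).mean()

    def test_agrees_with_independent_tvl1_estimator(self):
        """Cross-check against scikit-image's TV-L1 optical flow on the
        same speckle translation."""
        from skimage.registration import optical_flow_tvl1

        img = _speckle_image(seed=7)
        moved = np.roll(img, 1, axis=1)
        _, ours = pa.optical_flow(img, moved)
        v, u = optical_flow_tvl1(img / 255.0, moved / 255.0)
        interior = (slice(10, -10), slice(20, -20))
        assert ours[interior].mean() == pytest.approx(1.0, rel=0.1)
        assert u[interior].mean() == pytest.approx(1.0, rel=0.15)
        assert ours[interior].mean() == pytest.approx(u[interior].mean(), rel=0.2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pa.optical_flow(np.zeros((4, 4)), np.zeros((5, 5)))


def _field_from_interframe(interframe, depth0=11.0, dz=0.308):
    n_pairs, nl, nw = interframe.shape
    return DisplacementField(
        line_x_mm=np.arange(nl) * 0.0625,
        depth_mm=depth0 + np.arange(nw) * dz,
        frame_rate_hz=52.0,
        interframe_axial_um=interframe,
        interframe_lateral_um=np.zeros_like(interframe),
        valid=np.ones(interframe.shape, dtype=bool),
        estimator="synthetic",
    )


class TestAccumulate:
    def test_constant_field_sums(self):
        field = _field_from_interframe(np.full((5, 1, 10), 10.0))
        accumulate(field)
        assert np.allclose(field.accumulated_axial_um[0], 0.0)
        assert np.allclose(field.accumulated_axial_um[-1], 50.0)

    def test_alternating_field_returns_to_zero(self):
        steps = np.zeros((6, 1, 10))
        steps[::2] = 12.0
        steps[1::2] = -12.0
        field = _field_from_interframe(steps)
        accumulate(field)
        assert np.allclose(field.accumulated_axial_um[-1], 0.0, atol=1e-9)

    def test_linear_in_depth_field_matches_trajectory_integral(self):
        """For d(z) = k (z - z0) the advected trajectory grows
        geometrically; naive fixed-grid summation would not."""
        depth0, dz, nw = 11.0, 0.308, 40
        k = 0.02  # um of displacement per um of depth offset... per mm
        depths = depth0 + np.arange(nw) * dz
        # inter-frame displacement in um as a function of depth
        steps = np.tile(1000 * k * (depths - depth0)[None, None, :], (10, 1, 1))
        field = _field_from_interframe(steps, depth0, dz)
        accumulate(field)
        j = 25
        z = depths[j]
        expected = (depth0 + (z - depth0) * (1 + k) ** 10 - z) * 1000
        got = field.accumulated_axial_um[-1, 0, j]
        assert got == pytest.approx(expected, rel=0.01)

    def test_trajectory_leaving_grid_is_masked(self):
        steps = np.full((4, 1, 6), 800.0)  # 0.8 mm per pair, grid ~1.5 mm
        field = _field_from_interframe(steps)
        accumulate(field)
        assert not field.accumulated_valid[-1].all()
        assert field.accumulated_valid[0].all()

    def test_invalid_window_propagates(self):
        steps = np.full((3, 1, 6), 5.0)
        field = _field_from_interframe(steps)
        field.valid[1, 0, 2] = False
        accumulate(field)
        assert field.accumulated_valid[1, 0, 2]
        assert not field.accumulated_valid[2, 0, 2]
        assert not field.accumulated_valid[3, 0, 2]

    def test_long_form_export(self):
        field = _field_from_interframe(np.full((2, 2, 3), 1.0))
        accumulate(field)
        df = field.to_dataframe()
        assert len(df) == 3 * 2 * 3
        assert set(df.columns) >= {"frame", "line_x_mm", "depth_mm", "axial_um", "lateral_um", "valid"}
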