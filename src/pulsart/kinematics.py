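"""Animate the static phantom over one cardiac cycle.

Wall motion model
-----------------
Radial motion: every non-lumen scatterer moves along the outward radial
unit vector in the (elevation, depth) plane by half the diameter-change
waveform, attenuated exponentially with its distance from the lumen
radius::

    slope_radial(y) = 1                     for y = r_l
                      exp(-b1 (y - r_l))    for y > r_l

Longitudinal motion: scatterers translate along the artery axis (+x) by
the full longitudinal waveform; the intima–media complex moves as a plate
(slope 1) and the decay starts at the media–adventitia boundary with a
much steeper constant::

    slope_longitudinal(y) = 1                      for r_l <= y <= r_ma
                            exp(-b2 (y - r_ma))    for y > r_ma

Slopes are evaluated at the *static* (reference) radial coordinate and
frame positions are reference + total displacement, which makes the
animation frame-order independent and matches the use of a fixed
theoretical pattern as the error reference.  Proximal/distal symmetry is
exact.  Lumen scatterers (if any) stay static and the lumen is a cylinder
of variable diameter ``D(f) = D0 + d_radial(f)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .config import ArteryGeometry, SlopeParams
from .phantom import ScattererMap, radial_distance
from .waveforms import MotionWaveform


class ContractViolation(ValueError):
    """Raised when an operation is evaluated inside the lumen."""


def slope_radial(
    y_mm: np.ndarray | float, params: SlopeParams, geometry: ArteryGeometry
) -> np.ndarray | float:
    """Radial-motion decrement factor at radial distance ``y_mm``.

    Equals 1 at the lumen radius and decays as ``exp(-b1 (y - r_l))``
    beyond it; strictly decreasing with depth into the tissue.
    """
    y = np.asarray(y_mm, dtype=float)
    r_l = geometry.lumen_radius_mm
    if np.any(y < r_l - 1e-12):
        raise ContractViolation("slope_radial is undefined inside the lumen")
    out = np.exp(-params.b1_per_mm * np.maximum(y - r_l, 0.0))
    return float(out) if np.isscalar(y_mm) else out


def slope_longitudinal(
    y_mm: np.ndarray | float, params: SlopeParams, geometry: ArteryGeometry
) -> np.ndarray | float:
    """Longitudinal-motion decrement factor at radial distance ``y_mm``.

    1 across the intima–media complex plateau (``r_l <= y <= r_ma``), then
    ``exp(-b2 (y - r_ma))``; continuous at the boundary.
    """
    y = np.asarray(y_mm, dtype=float)
    r_l = geometry.lumen_radius_mm
    r_ma = geometry.media_adventitia_radius_mm
    if np.any(y < r_l - 1e-12):
        raise ContractViolation("slope_longitudinal is undefined inside the lumen")
    out = np.exp(-params.b2_per_mm * np.maximum(y - r_ma, 0.0))
    return float(out) if np.isscalar(y_mm) else out


@dataclass
class DynamicPhantom:
    """Scatterer positions per frame, sharing amplitudes and labels.

    ``positions_per_frame`` has shape (n_frames, n, 3); amplitudes and
    layer labels are those of the static map (motion moves scatterers,
    never creates or destroys them).
    """

    static: ScattererMap
    positions_per_frame: np.ndarray
    waveform: MotionWaveform
    slopes: SlopeParams
    lag_one_frame: bool = False

    @property
    def n_frames(self) -> int:
        return self.positions_per_frame.shape[0]

    @property
    def geometry(self) -> ArteryGeometry:
        return self.static.geometry

    def frame(self, f: int) -> ScattererMap:
        return self.static.with_positions(self.positions_per_frame[f])

    @property
    def lumen_diameter_per_frame_mm(self) -> np.ndarray:
        """Variable lumen diameter D(f) = D0 + d_radial(f).

        With ``lag_one_frame`` the waveform enters with a one-frame delay
        (the alternative indexing convention); default is same-frame.
        """
        d = self.waveform.d_radial_um
        if self.lag_one_frame:
            d = np.concatenate([[d[0]], d[:-1]])
        return self.geometry.lumen_diameter_mm + d / 1000.0

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("positions_per_frame", data=self.positions_per_frame)
            fh.create_dataset("amplitudes", data=self.static.amplitudes)
            fh.create_dataset("layer_labels", data=self.static.layer_labels)
            fh.create_dataset("static_positions", data=self.static.positions)
            fh.create_dataset("d_radial_um", data=self.waveform.d_radial_um)
            fh.create_dataset("d_longitudinal_um", data=self.waveform.d_longitudinal_um)
            fh.attrs["frame_rate_hz"] = self.waveform.frame_rate_hz
            fh.attrs["b1_per_mm"] = self.slopes.b1_per_mm
            fh.attrs["b2_per_mm"] = self.slopes.b2_per_mm
            fh.attrs["center_depth_mm"] = self.geometry.center_depth_mm


def animate(
    static: ScattererMap,
    waveform: MotionWaveform,
    params: SlopeParams,
    geometry: ArteryGeometry | None = None,
    lag_one_frame: bool = False,
) -> DynamicPhantom:
    """Apply the radial + longitudinal motion model to the static map.

    For each frame ``f`` and non-lumen scatterer with reference radial
    coordinate ``y0`` the new radial distance is
    ``y0 + d_radial(f)/2 * slope_radial(y0)`` (displacement along the
    outward radial unit vector) and the new lateral position
    ``x0 + d_longitudinal(f) * slope_longitudinal(y0)``.  Positive
    ``d_radial`` means diameter increase (walls move apart); positive
    ``d_longitudinal`` points along +x.

    ``lag_one_frame`` applies the waveform with a one-frame delay to the
    lumen diameter bookkeeping only (an alternative indexing convention;
    default off).

    Raises
    ------
    ValueError
        If the inward excursion would push a wall scatterer across the
        artery axis (non-physical inversion).
    """
    if geometry is None:
        geometry = static.geometry
    if waveform.n_frames < 2:
        raise ValueError("waveform must have at least 2 frames")

    pos0 = static.positions
    wall = ~static.layer_mask("lumen")
    y0 = radial_distance(pos0, geometry)

    # outward radial unit vectors in the (y, z - center) plane
    ey = pos0[:, 1] / np.where(y0 > 0, y0, 1.0)
    ez = (pos0[:, 2] - geometry.center_depth_mm) / np.where(y0 > 0, y0, 1.0)

    s_rad = np.zeros_like(y0)
    s_lon = np.zeros_like(y0)
    s_rad[wall] = slope_radial(y0[wall], params, geometry)
    s_lon[wall] = slope_longitudinal(y0[wall], params, geometry)

    d_r_mm = waveform.d_radial_um / 2000.0  # half displacement per wall, mm
    d_l_mm = waveform.d_longitudinal_um / 1000.0

    min_excursion = d_r_mm.min()
    if wall.any():
        min_radius = (y0[wall] + min_excursion * s_rad[wall]).min()
        if min_radius <= 0:
            raise ValueError(
                "waveform amplitude would move a wall scatterer across the "
                "artery axis; reduce the peak-to-peak level"
            )

    frames = np.empty((waveform.n_frames, static.n, 3))
    for f in range(waveform.n_frames):
        dr = d_r_mm[f] * s_rad  # zero for lumen scatterers
        dl = d_l_mm[f] * s_lon
        frames[f, :, 0] = pos0[:, 0] + dl
        frames[f, :, 1] = pos0[:, 1] + dr * ey
        frames[f, :, 2] = pos0[:, 2] + dr * ez
    return DynamicPhantom(static, frames, waveform, params, lag_one_frame=lag_one_frame)


def reference_radius(
    y_observed_mm: float,
    frame: int,
    waveform: MotionWaveform,
    params: SlopeParams,
    geometry: ArteryGeometry,
    n_iter: int = 20,
) -> float:
    """Invert the radial motion map: reference ``y0`` of the material point
    observed at radial distance ``y_observed_mm`` at ``frame``.

    Solves ``y0 + d_radial(frame)/2 * slope_radial(y0) = y_obs`` by fixed
    point iteration (the displacement is small and slowly varying, so this
    converges in a few steps).  Returns NaN if the point maps inside the
    lumen.
    """
    d_mm = waveform.d_radial_um[frame] / 2000.0
    y0 = float(y_observed_mm)
    for _ in range(n_iter):
        if y0 < geometry.lumen_radius_mm:
            y0 = geometry.lumen_radius_mm
        y0 = y_observed_mm - d_mm * slope_radial(y0, params, geometry)
    if y0 < geometry.lumen_radius_mm - 1e-9:
        return float("nan")
    return y0


def ground_truth_displacement(
    z_mm: float,
    x_mm: float,
    frame: int,
    geometry: ArteryGeometry,
    params: SlopeParams,
    waveform: MotionWaveform,
    ref_frame: int = 0,
) -> tuple[float, float]:
    """Analytic displacement of the scatterer whose *reference* position is
    (x, y=0, z), at ``frame`` relative to ``ref_frame``.

    Returns ``(dz_um, dx_um)``: the depth (axial) displacement, signed
    positive toward larger depth, and the lateral displacement along +x.
    This is the reference signal for the NRMSE evaluation.  Points inside
    the lumen are undefined and return NaN.
    """
    y0 = abs(z_mm - geometry.center_depth_mm)
    if y0 < geometry.lumen_radius_mm:
        return (float("nan"), float("nan"))
    sgn = 1.0 if z_mm >= geometry.center_depth_mm else -1.0
    dd_r = waveform.d_radial_um[frame] - waveform.d_radial_um[ref_frame]
    dd_l = waveform.d_longitudinal_um[frame] - waveform.d_longitudinal_um[ref_frame]
    dz = sgn * dd_r / 2.0 * slope_radial(y0, params, geometry)
    dx = dd_l * slope_longitudinal(y0, params, geometry)
    return (float(dz), float(dx))
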