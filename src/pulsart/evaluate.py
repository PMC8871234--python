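"""Estimator accuracy versus the analytic ground truth.

The error metric is the NRMSE: the root-mean-square difference over time
between an estimated and the theoretically defined displacement waveform
at one spatial point, normalized by the standard deviation of the
theoretical waveform.  Profiles are evaluated on the midline scan line at
a set of axial positions (by default 19 positions from 11 to 29 mm), and
summarized as medians over the proximal (14–15 mm) and distal (20–21 mm)
wall bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ArteryGeometry, SlopeParams
from .estimate import DisplacementField
from .kinematics import (
    ground_truth_displacement,
    reference_radius,
    slope_longitudinal,
    slope_radial,
)
from .waveforms import MotionWaveform

#: Axial bands (mm) bracketing the proximal and distal wall, per the
#: default geometry (walls span 14-15 and 20-21 mm).
WALL_BANDS = ((14.0, 15.0), (20.0, 21.0))

#: Representative mid-wall midline points (one selected point per wall),
#: used for point-wise waveform comparisons between estimators and
#: against theory.
WALL_POINTS_MM = (14.5, 20.5)

#: Default midline evaluation layout: 19 axial positions, 11 to 29 mm.
MIDLINE_POSITIONS_MM = np.linspace(11.0, 29.0, 19)


def nrmse(estimated_um: np.ndarray, theoretical_um: np.ndarray) -> float:
    """RMS(est - theo) / std(theo); dimensionless, >= 0.

    Undefined (raises) for a constant theoretical series.
    """
    est = np.asarray(estimated_um, dtype=float).ravel()
    theo = np.asarray(theoretical_um, dtype=float).ravel()
    if len(est) != len(theo) or len(est) < 2:
        raise ValueError("series must have equal length >= 2")
    std = theo.std()
    if std == 0:
        raise ValueError("NRMSE is undefined for a constant theoretical series")
    return float(np.sqrt(np.mean((est - theo) ** 2)) / std)


@dataclass
class NRMSEProfile:
    """Per-axial-position NRMSE along the midline for one channel/run."""

    positions_mm: np.ndarray
    values: np.ndarray  # NaN where the estimate is unavailable
    channel: str  # "radial" | "longitudinal"
    estimator: str
    peak_to_peak_mm: float | None = None
    waveform_id: str | None = None

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_mm.shape != self.values.shape:
            raise ValueError("positions and values must align")


def theoretical_series(
    z_grid_mm: float,
    geometry: ArteryGeometry,
    params: SlopeParams,
    waveform: MotionWaveform,
    channel: str,
) -> np.ndarray:
    """Accumulated theoretical displacement (um, relative to frame 0) of
    the material point observed at midline depth ``z_grid_mm`` at frame 0.

    The estimators track the scatterers initially at the grid point, so
    the reference radial coordinate is obtained by inverting the frame-0
    radial motion map (Lagrangian truth).  Returns NaN series for points
    inside the lumen.
    """
    y_f0 = abs(z_grid_mm - geometry.center_depth_mm)
    n = waveform.n_frames
    lumen_r0 = geometry.lumen_radius_mm + waveform.d_radial_um[0] / 2000.0
    if y_f0 < lumen_r0:
        return np.full(n, np.nan)
    y0 = reference_radius(y_f0, 0, waveform, params, geometry)
    if not np.isfinite(y0):
        return np.full(n, np.nan)
    sgn = 1.0 if z_grid_mm >= geometry.center_depth_mm else -1.0
    if channel == "radial":
        s = slope_radial(y0, params, geometry)
        return sgn * (waveform.d_radial_um - waveform.d_radial_um[0]) / 2.0 * s
    if channel == "longitudinal":
        s = slope_longitudinal(y0, params, geometry)
        return (waveform.d_longitudinal_um - waveform.d_longitudinal_um[0]) * s
    raise ValueError("channel must be 'radial' or 'longitudinal'")


def midline_profile(
    disp: DisplacementField,
    geometry: ArteryGeometry,
    params: SlopeParams,
    waveform: MotionWaveform,
    channel: str = "radial",
    positions_mm: np.ndarray | None = None,
    min_valid_fraction: float = 0.9,
    peak_to_peak_mm: float | None = None,
    waveform_id: str | None = None,
) -> NRMSEProfile:
    """NRMSE per axial position at the central scan line over the cycle.

    Positions whose estimator mask is invalid (more than
    ``1 - min_valid_fraction`` of frames missing), or whose theoretical
    reference is undefined (lumen), are NaN.
    """
    if disp.accumulated_axial_um is None:
        raise ValueError("accumulate the displacement field first")
    if positions_mm is None:
        positions_mm = MIDLINE_POSITIONS_MM
    positions_mm = np.asarray(positions_mm, dtype=float)
    li = disp.midline_index
    values = np.full(len(positions_mm), np.nan)
    est_all = (
        disp.accumulated_axial_um if channel == "radial" else disp.accumulated_lateral_um
    )
    for i, z in enumerate(positions_mm):
        wi = int(np.argmin(np.abs(disp.depth_mm - z)))
        if abs(disp.depth_mm[wi] - z) > max(
            2.0 * np.mean(np.diff(disp.depth_mm)) if len(disp.depth_mm) > 1 else np.inf,
            0.5,
        ):
            continue
        theo = theoretical_series(disp.depth_mm[wi], geometry, params, waveform, channel)
        if not np.all(np.isfinite(theo)) or theo.std() == 0:
            continue
        est = est_all[:, li, wi]
        ok = disp.accumulated_valid[:, li, wi]
        if ok.mean() < min_valid_fraction:
            continue
        values[i] = nrmse(est[ok], theo[ok])
    return NRMSEProfile(
        positions_mm,
        values,
        channel=channel,
        estimator=disp.estimator,
        peak_to_peak_mm=peak_to_peak_mm,
        waveform_id=waveform_id,
    )


def band_median(
    profile: NRMSEProfile,
    bands: tuple[tuple[float, float], ...] = WALL_BANDS,
) -> dict[tuple[float, float], float]:
    """Median of valid NRMSE values within each axial band.

    Bands with no valid entries map to NaN (mirroring the "not available"
    gaps of ambiguous estimates); invalid samples are excluded rather than
    imputed.
    """
    out = {}
    for lo, hi in bands:
        sel = (profile.positions_mm >= lo) & (profile.positions_mm <= hi)
        vals = profile.values[sel]
        vals = vals[np.isfinite(vals)]
        out[(lo, hi)] = float(np.median(vals)) if len(vals) else float("nan")
    return out


def invalid_fraction(
    disp: DisplacementField,
    bands: tuple[tuple[float, float], ...] = WALL_BANDS,
    line_indices: np.ndarray | None = None,
) -> float:
    """Fraction of inter-frame estimates flagged invalid within the wall
    bands (the 'white gap' statistic of the ambiguity analysis)."""
    sel = np.zeros(len(disp.depth_mm), dtype=bool)
    for lo, hi in bands:
        sel |= (disp.depth_mm >= lo) & (disp.depth_mm <= hi)
    v = disp.valid[:, :, sel]
    if line_indices is not None:
        v = disp.valid[:, np.asarray(line_indices, int), :][:, :, sel]
    return float(1.0 - v.mean())


def error_report(runs: list[dict]) -> pd.DataFrame:
    """Long-form summary table over a (waveform x level x estimator) grid.

    Each run dict carries ``waveform_id``, ``peak_to_peak_mm``,
    ``estimator``, ``channel``, an :class:`NRMSEProfile` under
    ``profile`` and optionally ``invalid_fraction``.  One row per run and
    band: median NRMSE and percentage of invalid estimates.  Gaps in a
    partial grid are simply absent rows.
    """
    rows = []
    for run in runs:
        profile: NRMSEProfile = run["profile"]
        medians = band_median(profile)
        for (lo, hi), med in medians.items():
            rows.append(
                {
                    "waveform_id": run.get("waveform_id", profile.waveform_id),
                    "peak_to_peak_mm": run.get("peak_to_peak_mm", profile.peak_to_peak_mm),
                    "estimator": run.get("estimator", profile.estimator),
                    "channel": run.get("channel", profile.channel),
                    "band_mm": f"{lo:g}-{hi:g}",
                    "median_nrmse": med,
                    "invalid_percent": 100.0 * run.get("invalid_fraction", 0.0),
                }
            )
    return pd.DataFrame(rows)
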