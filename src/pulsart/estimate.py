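"""Motion estimation from simulated RF data.

Two estimators are provided, mirroring the validation study design:

* **1DCC** — windowed normalized 1D cross-correlation along each RF line
  with parabolic sub-sample refinement.  It recovers axial (radial)
  motion only and is ambiguous once the inter-frame shift exceeds half a
  wavelength; such windows are flagged invalid rather than guessed.
* **OOF** — dense 2D optical flow on 0–255 log-envelope images: a
  coarse-to-fine Horn–Schunck solution (regularizer ``lambda1``) provides
  the initial field, refined by the Liu–Shen physics-based estimator
  (regularizer ``lambda2``) whose data term conserves ``I_t + div(I u)``.

Inter-frame fields are integrated into accumulated displacement relative
to frame 0 by semi-Lagrangian advection: each grid point's trajectory is
advected by its accumulated motion before the next inter-frame estimate
is sampled, respecting the fact that moving scatterers change their
coordinates.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage

from .config import TransducerConfig
from .scanner import RFSequence, envelope


# --------------------------------------------------------------------------
# containers


@dataclass
class OOFParams:
    """Optical-flow estimator parameters.

    ``size_filter`` is the pre-smoothing Gaussian size in pixels (applied
    as sigma = size_filter / 2); ``lambda1`` the Horn–Schunck smoothness
    weight, ``lambda2`` the Liu–Shen weight; ``floor_db`` the envelope
    floor of the 0–255 display normalization.
    """

    size_filter: float = 4.0
    lambda1: float = 120.0
    lambda2: float = 3000.0
    floor_db: float = -90.0
    pyramid_levels: int = 2
    hs_max_iter: int = 300
    ls_max_iter: int = 120
    refinement_passes: int = 3
    tol: float = 1e-4
    ls_relaxation: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("regularizers must be positive")


@dataclass
class DisplacementField:
    """Inter-frame and accumulated displacement on a (line x depth) grid.

    ``interframe_*`` arrays have shape (n_pairs, n_lines, n_windows) in
    micrometres; ``valid`` marks windows whose estimate is trustworthy
    (1DCC ambiguity / dead windows are False).  ``accumulated_*`` (shape
    (n_frames, ...)) is filled by :func:`accumulate`;
    ``accumulated[0] == 0`` everywhere by construction.
    """

    line_x_mm: np.ndarray
    depth_mm: np.ndarray
    frame_rate_hz: float
    interframe_axial_um: np.ndarray
    interframe_lateral_um: np.ndarray
    valid: np.ndarray
    estimator: str
    params: dict = field(default_factory=dict)
    accumulated_axial_um: np.ndarray | None = None
    accumulated_lateral_um: np.ndarray | None = None
    accumulated_valid: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return self.interframe_axial_um.shape[0]

    @property
    def midline_index(self) -> int:
        return int(np.argmin(np.abs(self.line_x_mm)))

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            for name in (
                "line_x_mm",
                "depth_mm",
                "interframe_axial_um",
                "interframe_lateral_um",
                "valid",
            ):
                fh.create_dataset(name, data=getattr(self, name))
            for name in (
                "accumulated_axial_um",
                "accumulated_lateral_um",
                "accumulated_valid",
            ):
                value = getattr(self, name)
                if value is not None:
                    fh.create_dataset(name, data=value)
            fh.attrs["frame_rate_hz"] = self.frame_rate_hz
            fh.attrs["estimator"] = self.estimator

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form (frame, line, depth, axial_um, lateral_um, valid)."""
        if self.accumulated_axial_um is None:
            raise ValueError("accumulate the field first")
        nf, nl, nw = self.accumulated_axial_um.shape
        f, l, w = np.meshgrid(
            np.arange(nf), np.arange(nl), np.arange(nw), indexing="ij"
        )
        return pd.DataFrame(
            {
                "frame": f.ravel(),
                "line_x_mm": self.line_x_mm[l.ravel()],
                "depth_mm": self.depth_mm[w.ravel()],
                "axial_um": self.accumulated_axial_um.ravel(),
                "lateral_um": self.accumulated_lateral_um.ravel(),
                "valid": self.accumulated_valid.ravel(),
            }
        )


def window_centers(
    depth_mm: np.ndarray, window_samples: int, hop_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and centre depths of the analysis windows."""
    n = len(depth_mm)
    starts = np.arange(0, n - window_samples + 1, hop_samples)
    centers = depth_mm[starts + window_samples // 2]
    return starts, centers


# --------------------------------------------------------------------------
# 1D cross-correlation


def _ncc_lags(win: np.ndarray, seg: np.ndarray, taper: np.ndarray | None = None) -> np.ndarray:
    """Normalized cross-correlation of ``win`` against every lag of ``seg``.

    ``seg`` must be ``len(win) + 2 * search`` long; returns 2*search + 1
    correlation values.  ``taper`` (e.g. a Hann window) concentrates the
    match on the window centre, shrinking the effective footprint.
    """
    w = win - win.mean()
    if taper is not None:
        w = w * taper
    nw = np.linalg.norm(w)
    n_lags = len(seg) - len(win) + 1
    out = np.empty(n_lags)
    if nw == 0:
        return np.zeros(n_lags)
    # sliding sums for local mean/energy of the segment
    c1 = np.concatenate([[0.0], np.cumsum(seg)])
    c2 = np.concatenate([[0.0], np.cumsum(seg**2)])
    W = len(win)
    sums = c1[W:] - c1[:-W]
    sq = c2[W:] - c2[:-W]
    var = sq - sums**2 / W
    var = np.maximum(var, 0.0)
    dots = np.correlate(seg, w, mode="valid")
    denom = nw * np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, dots / denom, 0.0)
    return out


def _parabolic(corr: np.ndarray, k: int) -> float:
    """Sub-sample peak refinement by a parabola through three points."""
    if k <= 0 or k >= len(corr) - 1:
        return 0.0
    c0, c1, c2 = corr[k - 1], corr[k], corr[k + 1]
    denom = c0 - 2.0 * c1 + c2
    if denom >= 0:
        return 0.0
    delta = 0.5 * (c0 - c2) / denom
    return float(np.clip(delta, -1.0, 1.0))


def track_echo_shift(
    line_a: np.ndarray,
    line_b: np.ndarray,
    center_sample: int,
    window_samples: int,
    search_samples: int,
    axial_sample_um: float,
) -> tuple[float, float]:
    """Echo time-shift between two RF lines at one depth window.

    Returns ``(displacement_um, peak_correlation)``; positive displacement
    means the echo moved to larger depth.  Intended for tracking large
    (multi-wavelength) shifts between distant frames: the RF carrier makes
    direct correlation ambiguous beyond half a wavelength, so the envelope
    (carrier-free) correlation supplies a coarse estimate and the RF
    correlation peak nearest to it is refined to sub-sample precision.
    """
    s0 = center_sample - window_samples // 2
    if s0 < 0 or s0 + window_samples > len(line_a):
        raise ValueError("window does not fit inside the line")
    lo = s0 - search_samples
    hi = s0 + window_samples + search_samples
    if lo < 0 or hi > len(line_b):
        raise ValueError("search segment does not fit inside the line")
    win = line_a[s0 : s0 + window_samples]
    seg = line_b[lo:hi]
    env_corr = _ncc_lags(envelope(win), envelope(seg))
    k_env = int(np.argmax(env_corr))
    corr = _ncc_lags(win, seg)
    # candidate RF peaks are spaced one carrier wavelength apart; take the
    # local maximum closest to the envelope (carrier-free) estimate
    interior = np.arange(1, len(corr) - 1)
    peaks = interior[
        (corr[interior] >= corr[interior - 1]) & (corr[interior] >= corr[interior + 1])
    ]
    if len(peaks) == 0:
        k = int(np.argmax(corr))
    else:
        k = int(peaks[np.argmin(np.abs(peaks - k_env))])
    shift = k - search_samples + _parabolic(corr, k)
    return shift * axial_sample_um, float(corr[k])


def cc1d_interframe(
    sequence: RFSequence,
    window_samples: int = 64,
    hop_samples: int = 16,
    search_samples: int | None = None,
    ambiguity_um: float | None = None,
    min_correlation: float = 0.25,
    line_indices: np.ndarray | None = None,
) -> DisplacementField:
    """Windowed 1DCC axial displacement between consecutive frames.

    Defaults follow the standard speckle-tracking recipe: window of two
    pulse lengths, 75 % overlap, search bounded by the half-wavelength
    ambiguity limit of phase-sensitive echo tracking.  A window is flagged
    invalid when its correlation peak sits at the search boundary, the
    implied shift reaches the lambda/2 bound, the window has (near) zero
    variance, the peak correlation is weak, or the carrier-free envelope
    correlation disagrees with the RF peak by more than a quarter
    wavelength — the signature of the RF peak having aliased onto a
    neighbouring carrier cycle when the true motion exceeds lambda/2.
    """
    axial_um = sequence.axial_sample_mm * 1000.0
    if ambiguity_um is None:
        # lambda/2 bound; the centre frequency is not stored on the
        # sequence, so default to the 5 MHz array (154 um) unless given
        ambiguity_um = 154.0
    if search_samples is None:
        search_samples = int(np.ceil(ambiguity_um / axial_um))
    if line_indices is None:
        line_indices = np.arange(sequence.n_lines)
    line_indices = np.asarray(line_indices, dtype=int)

    starts, centers = window_centers(sequence.depth_mm, window_samples, hop_samples)
    n_pairs = sequence.n_frames - 1
    shape = (n_pairs, len(line_indices), len(starts))
    disp = np.zeros(shape)
    valid = np.ones(shape, dtype=bool)

    # envelope disagreement beyond lambda/4 flags carrier-cycle aliasing
    alias_samples = 0.5 * ambiguity_um / axial_um

    for p in range(n_pairs):
        fa = sequence.frames[p]
        fb = sequence.frames[p + 1]
        for li, line in enumerate(line_indices):
            a = fa[line]
            b = fb[line]
            env_a = envelope(a)
            env_b = envelope(b)
            b_pad = np.pad(b, search_samples)
            env_b_pad = np.pad(env_b, search_samples)
            for wi, s0 in enumerate(starts):
                win = a[s0 : s0 + window_samples]
                if np.ptp(win) == 0:
                    valid[p, li, wi] = False
                    continue
                seg = b_pad[s0 : s0 + window_samples + 2 * search_samples]
                corr = _ncc_lags(win, seg)
                k = int(np.argmax(corr))
                if k == 0 or k == len(corr) - 1 or corr[k] < min_correlation:
                    valid[p, li, wi] = False
                    continue
                env_seg = env_b_pad[s0 : s0 + window_samples + 2 * search_samples]
                env_corr = _ncc_lags(env_a[s0 : s0 + window_samples], env_seg)
                k_env = int(np.argmax(env_corr))
                if k_env == 0 or k_env == len(env_corr) - 1:
                    valid[p, li, wi] = False  # true motion beyond the search
                elif abs(k_env - k) > alias_samples:
                    valid[p, li, wi] = False
                shift = k - search_samples + _parabolic(corr, k)
                d_um = shift * axial_um
                if abs(d_um) >= 0.95 * ambiguity_um:
                    valid[p, li, wi] = False
                disp[p, li, wi] = d_um

    return DisplacementField(
        line_x_mm=sequence.line_x_mm[line_indices],
        depth_mm=centers,
        frame_rate_hz=sequence.frame_rate_hz,
        interframe_axial_um=disp,
        interframe_lateral_um=np.zeros_like(disp),
        valid=valid,
        estimator="1dcc",
        params={
            "window_samples": window_samples,
            "hop_samples": hop_samples,
            "search_samples": search_samples,
            "ambiguity_um": ambiguity_um,
        },
    )


# --------------------------------------------------------------------------
# optical flow (Horn-Schunck initial field + Liu-Shen refinement)


def oof_preprocess(rf_frame: np.ndarray, floor_db: float = -90.0) -> np.ndarray:
    """RF frame -> 0-255 log-envelope image for optical flow.

    The RF is normalized to unit peak, envelope-detected, expressed in dB,
    floored at ``floor_db`` and mapped linearly onto [0, 255].
    """
    rf = np.asarray(rf_frame, dtype=float)
    peak = np.abs(rf).max()
    if peak == 0:
        raise ValueError("cannot preprocess an all-zero frame")
    env = envelope(rf / peak)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / env.max())
    db = np.maximum(db, floor_db)
    return (db - floor_db) * (255.0 / -floor_db)


_HS_KERNEL = np.array(
    [[1 / 12, 1 / 6, 1 / 12], [1 / 6, 0.0, 1 / 6], [1 / 12, 1 / 6, 1 / 12]]
)


def _gradients(a: np.ndarray, b: np.ndarray):
    avg = 0.5 * (a + b)
    g0, g1 = np.gradient(avg)
    return g0, g1, b - a


def _horn_schunck_level(
    a: np.ndarray,
    b: np.ndarray,
    lam: float,
    max_iter: int,
    tol: float,
    u0: np.ndarray,
    u1: np.ndarray,
):
    g0, g1, gt = _gradients(a, b)
    denom = lam + g0**2 + g1**2
    for _ in range(max_iter):
        m0 = ndimage.convolve(u0, _HS_KERNEL, mode="nearest")
        m1 = ndimage.convolve(u1, _HS_KERNEL, mode="nearest")
        t = (g0 * m0 + g1 * m1 + gt) / denom
        new0 = m0 - g0 * t
        new1 = m1 - g1 * t
        delta = max(np.abs(new0 - u0).mean(), np.abs(new1 - u1).mean())
        u0, u1 = new0, new1
        if delta < tol:
            break
    return u0, u1


def _warp(img: np.ndarray, flow0: np.ndarray, flow1: np.ndarray) -> np.ndarray:
    """Sample ``img`` at x + flow (backward warp toward the first frame)."""
    n0, n1 = img.shape
    i0, i1 = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    return ndimage.map_coordinates(
        img, [i0 + flow0, i1 + flow1], order=1, mode="nearest"
    )


def _resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    factors = (shape[0] / img.shape[0], shape[1] / img.shape[1])
    return ndimage.zoom(img, factors, order=1, mode="nearest", grid_mode=True)


def _shift(a: np.ndarray, d: int, axis: int) -> np.ndarray:
    """Shift with edge replication (value of neighbour d steps along axis)."""
    out = np.roll(a, -d, axis=axis)
    if axis == 0:
        if d > 0:
            out[-d:, :] = a[-1:, :]
        elif d < 0:
            out[:-d, :] = a[:1, :]
    else:
        if d > 0:
            out[:, -d:] = a[:, -1:]
        elif d < 0:
            out[:, :-d] = a[:, :1]
    return out


def _d_central(a: np.ndarray, axis: int) -> np.ndarray:
    return 0.5 * (_shift(a, 1, axis) - _shift(a, -1, axis))


def _liu_shen(
    a: np.ndarray,
    b: np.ndarray,
    lam: float,
    max_iter: int,
    tol: float,
    omega: float = 1.0,
):
    """Liu–Shen physics-based refinement (zero initial field).

    Minimizes ``integral (I_t + div(I u))^2 + lam (|grad u0|^2 + |grad
    u1|^2)`` for the correction flow between ``a`` and the (already
    warped) ``b``.  Discretization: central differences for first
    derivatives, a compact flux stencil for the ``div(I^2 grad)`` terms
    and a 4-neighbour Laplacian; solved by damped Jacobi iteration.
    """
    I = 0.5 * (a + b)
    It = b - a
    P = I * I
    # face-centred I^2 for the compact flux stencil, per axis
    Pe0 = 0.5 * (P + _shift(P, 1, 0))
    Pw0 = 0.5 * (P + _shift(P, -1, 0))
    Pe1 = 0.5 * (P + _shift(P, 1, 1))
    Pw1 = 0.5 * (P + _shift(P, -1, 1))
    I0 = _d_central(I, 0)
    I1 = _d_central(I, 1)
    C0_static = _d_central(I * It, 0)
    C1_static = _d_central(I * It, 1)
    den0 = 4.0 * lam + Pe0 + Pw0
    den1 = 4.0 * lam + Pe1 + Pw1
    u0 = np.zeros_like(I)
    u1 = np.zeros_like(I)

    def flux(u, Pe, Pw, axis):
        return Pe * (_shift(u, 1, axis) - u) - Pw * (u - _shift(u, -1, axis))

    def s4(u):
        return _shift(u, 1, 0) + _shift(u, -1, 0) + _shift(u, 1, 1) + _shift(u, -1, 1)

    for _ in range(max_iter):
        cross0 = _d_central(I * _d_central(I * u1, 1), 0)
        cross1 = _d_central(I * _d_central(I * u0, 0), 1)
        adv0 = _d_central(I * I0 * u0, 0)  # off-diagonal in the stencil sense
        adv1 = _d_central(I * I1 * u1, 1)
        off0 = flux(u0, Pe0, Pw0, 0) + (Pe0 + Pw0) * u0
        off1 = flux(u1, Pe1, Pw1, 1) + (Pe1 + Pw1) * u1
        new0 = (lam * s4(u0) + C0_static + cross0 + adv0 + off0) / den0
        new1 = (lam * s4(u1) + C1_static + cross1 + adv1 + off1) / den1
        new0 = (1 - omega) * u0 + omega * new0
        new1 = (1 - omega) * u1 + omega * new1
        delta = max(np.abs(new0 - u0).mean(), np.abs(new1 - u1).mean())
        u0, u1 = new0, new1
        if delta < tol:
            break
    return u0, u1


def optical_flow(
    img_a: np.ndarray, img_b: np.ndarray, params: OOFParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Dense flow from ``img_a`` to ``img_b`` (0-255 images), in pixels.

    Returns ``(flow_axis0, flow_axis1)``.  A Gaussian pre-filter of sigma
    ``size_filter / 2`` is applied; the Horn–Schunck field is computed
    coarse-to-fine, then refined at full resolution by the Liu–Shen
    estimator.  If an iteration cap is reached before the mean-update
    tolerance, the best iterate so far is returned.
    """
    params = params if params is not None else OOFParams()
    if img_a.shape != img_b.shape:
        raise ValueError("images must share a shape")
    sigma = params.size_filter / 2.0
    a = ndimage.gaussian_filter(np.asarray(img_a, float), sigma)
    b = ndimage.gaussian_filter(np.asarray(img_b, float), sigma)

    # coarse-to-fine Horn-Schunck initial field
    shapes = [a.shape]
    for _ in range(params.pyramid_levels - 1):
        prev = shapes[-1]
        nxt = (max(prev[0] // 2, 8), max(prev[1] // 2, 8))
        if nxt == prev:
            break
        shapes.append(nxt)
    u0 = np.zeros(shapes[-1])
    u1 = np.zeros(shapes[-1])
    for level, shape in enumerate(reversed(shapes)):
        al = _resize(a, shape)
        bl = _resize(b, shape)
        if level > 0:
            scale0 = shape[0] / u0.shape[0]
            scale1 = shape[1] / u0.shape[1]
            u0 = _resize(u0, shape) * scale0
            u1 = _resize(u1, shape) * scale1
        bw = _warp(bl, u0, u1)
        d0, d1 = _horn_schunck_level(
            al, bw, params.lambda1, params.hs_max_iter, params.tol,
            np.zeros(shape), np.zeros(shape),
        )
        u0, u1 = u0 + d0, u1 + d1

    # Liu-Shen refinement at full resolution on the warped residual pair;
    # repeated warp-and-refine passes counteract the regularization bias
    # on sub-pixel motion (each pass estimates the residual of the last)
    for _ in range(max(params.refinement_passes, 1)):
        bw = _warp(b, u0, u1)
        d0, d1 = _liu_shen(
            a, bw, params.lambda2, params.ls_max_iter, params.tol, params.ls_relaxation
        )
        u0, u1 = u0 + d0, u1 + d1
    return u0, u1


def oof_interframe(
    sequence: RFSequence,
    params: OOFParams | None = None,
    window_samples: int = 64,
    hop_samples: int = 16,
    lateral_footprint: int = 7,
) -> DisplacementField:
    """Optical-flow displacement between consecutive frames, sampled onto
    the same (line x window) grid the 1DCC estimator uses.

    Images are (lines x samples); axis 0 flow is lateral (line pitch per
    pixel), axis 1 flow axial (c/(2 fs) per pixel).  The anisotropic pixel
    sizes are respected in the micrometre conversion.
    """
    params = params if params is not None else OOFParams()
    axial_um = sequence.axial_sample_mm * 1000.0
    if len(sequence.line_x_mm) > 1:
        lateral_um = float(np.mean(np.diff(sequence.line_x_mm))) * 1000.0
    else:
        lateral_um = 0.0
    starts, centers = window_centers(sequence.depth_mm, window_samples, hop_samples)
    cols = starts + window_samples // 2
    n_pairs = sequence.n_frames - 1
    nl = sequence.n_lines
    disp_ax = np.zeros((n_pairs, nl, len(starts)))
    disp_lat = np.zeros_like(disp_ax)
    valid = np.ones(disp_ax.shape, dtype=bool)

    images = [oof_preprocess(sequence.frames[f], params.floor_db) for f in range(sequence.n_frames)]
    for p in range(n_pairs):
        flow_lat, flow_ax = optical_flow(images[p], images[p + 1], params)
        # echo-energy-weighted average over the same footprint as the
        # correlation windows: the display image is log-compressed, so
        # convert back to linear amplitude squared - the same weighting a
        # normalized-correlation window applies implicitly - lest silent
        # or dim tissue dilute the sampled wall motion
        db = images[p] * (-params.floor_db / 255.0) + params.floor_db
        weight = 10.0 ** (db / 10.0) + 1e-12
        # the artery axis runs along the scan direction, so the true
        # motion field is constant across nearby lines; a modest lateral
        # footprint averages estimator noise without model bias.  The
        # axial footprint differs per channel: the radial channel matches
        # the 1DCC correlation window, while the longitudinal field
        # decays much faster with depth, so its axial footprint is kept
        # to about one pulse length to avoid mixing in collapsed motion.
        size_ax = (lateral_footprint, window_samples)
        size_lat = (lateral_footprint, max(window_samples // 4, 4))
        norm_ax = ndimage.uniform_filter(weight, size=size_ax)
        norm_lat = ndimage.uniform_filter(weight, size=size_lat)
        smooth_ax = ndimage.uniform_filter(flow_ax * weight, size=size_ax) / norm_ax
        smooth_lat = ndimage.uniform_filter(flow_lat * weight, size=size_lat) / norm_lat
        disp_ax[p] = smooth_ax[:, cols] * axial_um
        disp_lat[p] = smooth_lat[:, cols] * lateral_um

    return DisplacementField(
        line_x_mm=sequence.line_x_mm,
        depth_mm=centers,
        frame_rate_hz=sequence.frame_rate_hz,
        interframe_axial_um=disp_ax,
        interframe_lateral_um=disp_lat,
        valid=valid,
        estimator="oof",
        params={
            "size_filter": params.size_filter,
            "lambda1": params.lambda1,
            "lambda2": params.lambda2,
            "floor_db": params.floor_db,
        },
    )


# --------------------------------------------------------------------------
# accumulation


def accumulate(field: DisplacementField) -> DisplacementField:
    """Integrate inter-frame estimates into accumulated displacement
    relative to frame 0 by semi-Lagrangian advection.

    For every grid point the trajectory position (reference + accumulated
    displacement so far) is used to sample the next inter-frame field by
    bilinear interpolation; trajectories leaving the grid, or crossing an
    invalid window, are masked from that frame on.
    """
    n_pairs, nl, nw = field.interframe_axial_um.shape
    acc_ax = np.zeros((n_pairs + 1, nl, nw))
    acc_lat = np.zeros_like(acc_ax)
    acc_ok = np.ones(acc_ax.shape, dtype=bool)

    depth = field.depth_mm
    lines = field.line_x_mm
    dz = float(np.mean(np.diff(depth))) if nw > 1 else 1.0
    dx = float(np.mean(np.diff(lines))) if nl > 1 else 1.0
    L, W = np.meshgrid(np.arange(nl, dtype=float), np.arange(nw, dtype=float), indexing="ij")

    for p in range(n_pairs):
        # trajectory position in fractional grid indices
        gi_l = L + (acc_lat[p] / 1000.0) / dx
        gi_w = W + (acc_ax[p] / 1000.0) / dz
        inside = (gi_l >= 0) & (gi_l <= nl - 1) & (gi_w >= 0) & (gi_w <= nw - 1)
        # replace invalid entries (e.g. dead anechoic-lumen windows hold
        # zeros) with the nearest valid value so bilinear interpolation
        # next to them is not dragged toward zero; validity is still
        # propagated through the mask below
        pair_ax = field.interframe_axial_um[p]
        pair_lat = field.interframe_lateral_um[p]
        if not field.valid[p].all() and field.valid[p].any():
            _, (il, iw) = ndimage.distance_transform_edt(
                ~field.valid[p], return_indices=True
            )
            pair_ax = pair_ax[il, iw]
            pair_lat = pair_lat[il, iw]
        d_ax = ndimage.map_coordinates(pair_ax, [gi_l, gi_w], order=1, mode="nearest")
        d_lat = ndimage.map_coordinates(pair_lat, [gi_l, gi_w], order=1, mode="nearest")
        ok_here = ndimage.map_coordinates(
            field.valid[p].astype(float), [gi_l, gi_w], order=0, mode="nearest"
        ) > 0.5
        acc_ok[p + 1] = acc_ok[p] & inside & ok_here
        acc_ax[p + 1] = acc_ax[p] + d_ax
        acc_lat[p + 1] = acc_lat[p] + d_lat

    field.accumulated_axial_um = acc_ax
    field.accumulated_lateral_um = acc_lat
    field.accumulated_valid = acc_ok
    return field


# --------------------------------------------------------------------------
# wall-trace measurements on M-mode style data


def echo_shift_between_frames(
    sequence: RFSequence,
    line_index: int,
    center_sample: int,
    frame_a: int,
    frame_b: int,
    window_samples: int = 64,
    search_samples: int = 30,
    step_search_samples: int = 16,
) -> float:
    """Echo displacement (um) between two arbitrary frames at one window.

    Two-stage tracking for multi-wavelength shifts: the intermediate
    frames are tracked pairwise (with window re-centring) to build a
    carrier-cycle prior, then a drift-free direct ``frame_a -> frame_b``
    correlation is resolved to the RF peak nearest that prior.
    """
    lines = sequence.frames[:, line_index, :]
    axial_um = sequence.axial_sample_mm * 1000.0
    n = lines.shape[-1]
    w, s = window_samples, search_samples
    step = 1 if frame_b >= frame_a else -1
    pos = 0.0
    for f in range(frame_a, frame_b, step):
        c = int(
            np.clip(
                round(center_sample + pos / axial_um),
                w // 2 + step_search_samples,
                n - w + w // 2 - step_search_samples,
            )
        )
        d_um, _ = track_echo_shift(
            lines[f], lines[f + step], c, w, step_search_samples, axial_um
        )
        pos += d_um
    c0 = int(np.clip(center_sample, w // 2 + s, n - w + w // 2 - s))
    win = lines[frame_a][c0 - w // 2 : c0 - w // 2 + w]
    seg = np.pad(lines[frame_b], s)[c0 - w // 2 : c0 - w // 2 + w + 2 * s]
    corr = _ncc_lags(win, seg)
    interior = np.arange(1, len(corr) - 1)
    pk = interior[
        (corr[interior] >= corr[interior - 1]) & (corr[interior] >= corr[interior + 1])
    ]
    if len(pk) == 0:
        k = int(np.argmax(corr))
    else:
        k = int(pk[np.argmin(np.abs((pk - s) * axial_um - pos))])
    return (k - s + _parabolic(corr, k)) * axial_um


def wall_separation_trace(
    sequence: RFSequence,
    transducer: TransducerConfig,
    center_depth_mm: float,
    lumen_radius_mm: float,
    line_index=None,
    window_mm: float = 0.6,
    search_mm: float = 0.75,
    interface_offset_mm: float = 0.2,
) -> np.ndarray:
    """Proximal-distal wall separation change over the cycle, in um.

    One correlation window is anchored on each lumen-intima interface
    echo, centred ``interface_offset_mm`` toward the lumen from the
    nominal interface depth so its content is dominated by the innermost
    (fastest-moving) wall layer.  Tracking is two-stage:

    1. inter-frame correlation with window re-centring builds a
       cycle-unambiguous but drift-prone trajectory prior;
    2. a drift-free direct frame0->f correlation is resolved to the RF
       carrier cycle nearest that prior.

    Element f of the result is ``dz_distal(f) - dz_proximal(f)`` relative
    to frame 0; for a diameter-change waveform this is the M-mode wall
    separation change.  ``line_index`` may be a sequence of indices, in
    which case the per-frame median over the per-line traces is returned
    (multi-line M-mode reading, robust to speckle-realization noise and
    occasional carrier slips on a single line).
    """
    if line_index is None:
        line_index = sequence.midline_index
    if np.ndim(line_index) > 0:
        traces = [
            wall_separation_trace(
                sequence,
                transducer,
                center_depth_mm,
                lumen_radius_mm,
                line_index=int(li),
                window_mm=window_mm,
                search_mm=search_mm,
                interface_offset_mm=interface_offset_mm,
            )
            for li in np.asarray(line_index).ravel()
        ]
        return np.median(traces, axis=0)
    lines = sequence.frames[:, line_index, :]
    depth = sequence.depth_mm
    axial_mm = transducer.axial_sample_mm
    axial_um = axial_mm * 1000.0
    w = max(int(round(window_mm / axial_mm)), 16)
    s = max(int(round(search_mm / axial_mm)), 8)
    s_step = max(int(round(0.31 / axial_mm)), 8)
    z_prox = center_depth_mm - lumen_radius_mm + interface_offset_mm
    z_dist = center_depth_mm + lumen_radius_mm - interface_offset_mm
    if z_prox - window_mm < depth[0] or z_dist + window_mm > depth[-1]:
        raise ValueError("wall interfaces outside the scanned depth range")
    acc = np.zeros((sequence.n_frames, 2))
    for side, zc in enumerate((z_prox, z_dist)):
        c0 = int(np.clip(np.argmin(np.abs(depth - zc)), w // 2 + s, len(depth) - w - s))
        # stage 1: cycle-unambiguous trajectory prior
        prior = np.zeros(sequence.n_frames)
        pos = 0.0
        for f in range(1, sequence.n_frames):
            c = int(np.clip(round(c0 + pos / axial_um), w // 2 + s_step, len(depth) - w - s_step))
            d_um, _ = track_echo_shift(lines[f - 1], lines[f], c, w, s_step, axial_um)
            pos += d_um
            prior[f] = pos
        # stage 2: drift-free direct measurement, carrier cycle from prior
        win = lines[0][c0 - w // 2 : c0 - w // 2 + w]
        for f in range(1, sequence.n_frames):
            seg = np.pad(lines[f], s)[c0 - w // 2 : c0 - w // 2 + w + 2 * s]
            corr = _ncc_lags(win, seg)
            interior = np.arange(1, len(corr) - 1)
            pk = interior[
                (corr[interior] >= corr[interior - 1])
                & (corr[interior] >= corr[interior + 1])
            ]
            if len(pk) == 0:
                k = int(np.argmax(corr))
            else:
                k = int(pk[np.argmin(np.abs((pk - s) * axial_um - prior[f]))])
            acc[f, side] = (k - s + _parabolic(corr, k)) * axial_um
    return acc[:, 1] - acc[:, 0]
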