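"""Single-cycle radial and longitudinal motion waveforms.

Two sources are supported: measured displacement traces (band-pass
filtered, detrended, one cycle selected and resampled to the imaging frame
grid) and a built-in surrogate generator producing in-vivo-like cardiac
morphologies when no measurement is available.

Conventions: the radial channel is the *total* proximal-to-distal
diameter-change displacement in micrometres (each wall moves by half of
it); the longitudinal channel is the IMC displacement along the artery
axis.  Channels are zero-mean (detrended) and peak-to-peak normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal


@dataclass
class MotionWaveform:
    """One cardiac cycle of radial + longitudinal displacement, per frame."""

    d_radial_um: np.ndarray
    d_longitudinal_um: np.ndarray
    frame_rate_hz: float = 52.0
    provenance: str = "surrogate"

    def __post_init__(self) -> None:
        self.d_radial_um = np.asarray(self.d_radial_um, dtype=float).ravel()
        self.d_longitudinal_um = np.asarray(self.d_longitudinal_um, dtype=float).ravel()
        if len(self.d_radial_um) != len(self.d_longitudinal_um):
            raise ValueError("radial and longitudinal channels must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.d_radial_um)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    @property
    def peak_to_peak_um(self) -> tuple[float, float]:
        return (float(np.ptp(self.d_radial_um)), float(np.ptp(self.d_longitudinal_um)))

    def scaled(self, pp_radial_mm: float | None, pp_longitudinal_mm: float | None) -> "MotionWaveform":
        """Peak-to-peak renormalized copy (``None`` keeps a channel as is)."""
        d_r = self.d_radial_um
        d_l = self.d_longitudinal_um
        if pp_radial_mm is not None:
            d_r = normalize_peak_to_peak(d_r, pp_radial_mm)
        if pp_longitudinal_mm is not None:
            d_l = normalize_peak_to_peak(d_l, pp_longitudinal_mm)
        return MotionWaveform(d_r, d_l, self.frame_rate_hz, self.provenance)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_s": self.times_s,
                "radial_um": self.d_radial_um,
                "longitudinal_um": self.d_longitudinal_um,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "measured") -> "MotionWaveform":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError("waveform CSV needs at least two samples")
        frame_rate = 1.0 / float(np.mean(np.diff(t)))
        return cls(
            df["radial_um"].to_numpy(),
            df["longitudinal_um"].to_numpy(),
            frame_rate_hz=frame_rate,
            provenance=provenance,
        )


def preprocess_measured(
    signal_um: np.ndarray,
    fs_hz: float,
    band_hz: tuple[float, float] = (0.5, 8.0),
    order: int = 4,
) -> np.ndarray:
    """Band-pass and detrend a measured displacement trace.

    A Butterworth band-pass (default 0.5–8 Hz, order 4) is applied
    forward–backward for zero phase distortion, then the mean is
    subtracted.  Being an IIR filter applied twice, the effective
    magnitude response is squared; the pass band comfortably preserves
    cardiac-cycle content at normal heart rates.
    """
    x = np.asarray(signal_um, dtype=float).ravel()
    if fs_hz <= 2 * band_hz[1]:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    sos = signal.butter(order, band_hz, btype="bandpass", fs=fs_hz, output="sos")
    # settling length of the forward-backward pass
    padlen = 3 * (2 * order + 1)
    if len(x) <= 3 * padlen:
        warnings.warn(
            "signal shorter than 3x the filter settling length; "
            "using reflective padding",
            stacklevel=2,
        )
        pad = len(x) - 1
        x_pad = np.pad(x, pad, mode="reflect")
        y = signal.sosfiltfilt(sos, x_pad, padlen=min(padlen, len(x_pad) - 2))
        y = y[pad : pad + len(x)]
    else:
        y = signal.sosfiltfilt(sos, x)
    return y - y.mean()


def filter_response(
    freq_hz: float | np.ndarray,
    fs_hz: float,
    band_hz: tuple[float, float] = (0.5, 8.0),
    order: int = 4,
) -> np.ndarray:
    """Zero-phase (forward-backward) magnitude response of the band-pass.

    Independent oracle for amplitude preservation/attenuation checks.
    """
    sos = signal.butter(order, band_hz, btype="bandpass", fs=fs_hz, output="sos")
    w, h = signal.sosfreqz(sos, worN=np.atleast_1d(np.asarray(freq_hz, float)), fs=fs_hz)
    return np.abs(h) ** 2  # filtfilt applies the filter twice


def select_cycle(
    signal_um: np.ndarray, start_index: int, end_index: int, n_frames: int = 45
) -> np.ndarray:
    """Extract one cardiac cycle and resample it to the imaging frame grid.

    ``[start_index, end_index)`` is cut out and band-limited-resampled (FFT
    method) to exactly ``n_frames`` samples — the frame count is fixed by
    the imaging frame rate, not by the waveform sampling.
    """
    x = np.asarray(signal_um, dtype=float).ravel()
    if not 0 <= start_index < end_index <= len(x):
        raise ValueError("invalid cycle indices")
    segment = x[start_index:end_index]
    if len(segment) == n_frames:
        return segment.copy()
    return signal.resample(segment, n_frames)


def normalize_peak_to_peak(signal_um: np.ndarray, level_mm: float) -> np.ndarray:
    """Linearly rescale a signal so max - min equals ``level_mm`` (in um).

    Shape preserving (pure scaling about the mean; the time axis is never
    normalized).  Constant signals cannot be normalized.
    """
    x = np.asarray(signal_um, dtype=float).ravel()
    ptp = np.ptp(x)
    if ptp == 0:
        raise ValueError("cannot peak-to-peak normalize a constant signal")
    mean = x.mean()
    return (x - mean) * (level_mm * 1000.0 / ptp) + mean


def surrogate_waveform(
    kind: str,
    n_frames: int = 45,
    frame_rate_hz: float = 52.0,
    peak_time_s: float = 8.0 / 52.0,
    rise_start_s: float | None = None,
    decay_tau_s: float = 0.18,
    dicrotic_amplitude: float = 0.15,
    dicrotic_time_s: float = 0.38,
    dicrotic_width_s: float = 0.06,
    foot_amplitude: float = 0.03,
    bidirectional: bool | None = None,
    retrograde_amplitude: float = 0.5,
    retrograde_time_s: float = 0.45,
    retrograde_width_s: float = 0.10,
) -> np.ndarray:
    """Surrogate single-cycle displacement morphology (unit scale).

    The radial kind has a strict minimum at frame 0, a steep late-systolic
    upstroke peaking at ``peak_time_s`` (default frame 8, i.e. t ~ 0.154 s
    at 52 fps, so M-mode extremes fall at t1 = 0 and t2 ~ 0.15 s), an
    exponential diastolic decay and an optional dicrotic bump.  The
    longitudinal kind rises more gently (peak ~0.25 s) and is by default
    bidirectional: an antegrade systolic lobe followed by a retrograde
    excursion, per the consensus waveform types.

    Returns the raw (not detrended, not normalized) shape; callers detrend
    and scale.  Deterministic for a given parameter set.
    """
    if kind not in ("radial", "longitudinal"):
        raise ValueError("kind must be 'radial' or 'longitudinal'")
    if kind == "longitudinal":
        if bidirectional is None:
            bidirectional = True
        # gentler, later systolic excursion for the longitudinal channel
        peak_time_s = max(peak_time_s, 0.25)
        if rise_start_s is None:
            rise_start_s = 0.05
        dicrotic_amplitude = 0.0
    else:
        bidirectional = bool(bidirectional)
        if rise_start_s is None:
            rise_start_s = 5.0 / 52.0
    if not 0.0 <= rise_start_s < peak_time_s:
        raise ValueError("need 0 <= rise_start_s < peak_time_s")
    if not 0.0 <= foot_amplitude < 0.5:
        raise ValueError("foot_amplitude out of range")
    if dicrotic_amplitude < 0 or retrograde_amplitude < 0:
        raise ValueError("morphology amplitudes must be non-negative")

    t = np.arange(n_frames) / frame_rate_hz
    g = np.zeros(n_frames)
    pre = t <= rise_start_s
    if rise_start_s > 0:
        g[pre] = foot_amplitude * (t[pre] / rise_start_s) ** 2
    rise = (t > rise_start_s) & (t <= peak_time_s)
    phase = (t[rise] - rise_start_s) / (peak_time_s - rise_start_s)
    if kind == "radial":
        # asymmetric systolic upstroke: slow take-off, fastest excursion in
        # the middle third, rounding off into the peak — monotone cubic
        # through the control points below
        from scipy.interpolate import PchipInterpolator

        upstroke = PchipInterpolator([0.0, 1 / 3, 2 / 3, 1.0], [0.0, 0.35, 0.85, 1.0])
        g[rise] = foot_amplitude + (1 - foot_amplitude) * upstroke(phase)
    else:
        g[rise] = foot_amplitude + (1 - foot_amplitude) * 0.5 * (1 - np.cos(np.pi * phase))
    fall = t > peak_time_s
    decay = np.exp(-(t[fall] - peak_time_s) / decay_tau_s)
    g[fall] = foot_amplitude + (1 - foot_amplitude) * decay
    if dicrotic_amplitude > 0:
        g[fall] += dicrotic_amplitude * np.exp(
            -(((t[fall] - dicrotic_time_s) / dicrotic_width_s) ** 2)
        )
    if bidirectional:
        g -= retrograde_amplitude * np.exp(
            -(((t - retrograde_time_s) / retrograde_width_s) ** 2)
        )
    return g


def make_surrogate_motion(
    pp_radial_mm: float = 1.0,
    pp_longitudinal_mm: float | None = None,
    n_frames: int = 45,
    frame_rate_hz: float = 52.0,
    radial_kwargs: dict | None = None,
    longitudinal_kwargs: dict | None = None,
) -> MotionWaveform:
    """Detrended, peak-to-peak-normalized surrogate motion waveform.

    ``pp_longitudinal_mm`` defaults to the radial level (the reference
    normalization applies the same level to both channels).
    """
    if pp_longitudinal_mm is None:
        pp_longitudinal_mm = pp_radial_mm
    d_r = surrogate_waveform("radial", n_frames, frame_rate_hz, **(radial_kwargs or {}))
    d_l = surrogate_waveform(
        "longitudinal", n_frames, frame_rate_hz, **(longitudinal_kwargs or {})
    )
    d_r = normalize_peak_to_peak(d_r - d_r.mean(), pp_radial_mm)
    d_l = normalize_peak_to_peak(d_l - d_l.mean(), pp_longitudinal_mm)
    return MotionWaveform(d_r, d_l, frame_rate_hz, provenance="surrogate")
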