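"""Configuration objects for the artery phantom and the virtual scanner.

All geometric quantities are in millimetres, frequencies in hertz and the
speed of sound in metres per second.  The transducer defaults describe a
5 MHz 128-element linear array (Hanning-modulated two-cycle excitation,
Hanning apodization, 40 MHz sampling) and the scan defaults a 160-line,
0.0625 mm pitch sweep imaged at 52 frames per second with 45 frames per
cardiac cycle.

The coordinate convention used throughout the package:

* ``x`` — lateral scan direction, which coincides with the artery's
  longitudinal axis;
* ``y`` — elevation (out of the imaging plane);
* ``z`` — depth below the transducer face (the beam axis).

The artery axis runs along ``x`` at ``y = 0``, ``z = center_depth_mm``,
so radial wall motion lives in the imaging plane and longitudinal wall
motion is a pure ``x`` translation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration object is non-physical or inconsistent."""


@dataclass(frozen=True)
class ArteryGeometry:
    """Three-layer artery (intima, media, adventitia) in a tissue block.

    The wall is modelled as concentric pipes around the artery axis.  The
    single intima–media complex (IMC) thickness is split into an intima and
    a media sub-layer by ``intima_fraction`` (default 1:6 intima:media, a
    typical histological ratio).
    """

    lumen_diameter_mm: float = 5.0
    imc_thickness_mm: float = 0.7
    adventitia_thickness_mm: float = 0.3
    center_depth_mm: float = 17.5
    intima_fraction: float = 1.0 / 7.0
    block_x_mm: tuple[float, float] = (-5.0, 5.0)
    block_y_mm: tuple[float, float] = (-2.0, 2.0)
    block_z_mm: tuple[float, float] = (11.0, 29.0)

    def __post_init__(self) -> None:
        if self.lumen_diameter_mm <= 0:
            raise ConfigurationError("lumen diameter must be positive")
        if self.imc_thickness_mm <= 0 or self.adventitia_thickness_mm <= 0:
            raise ConfigurationError("layer thicknesses must be positive")
        if not 0.0 < self.intima_fraction < 1.0:
            raise ConfigurationError("intima_fraction must lie in (0, 1)")
        for lo, hi in (self.block_x_mm, self.block_y_mm, self.block_z_mm):
            if hi <= lo:
                raise ConfigurationError("block extents must be increasing")

    @property
    def lumen_radius_mm(self) -> float:
        """Initial lumen radius r_l."""
        return self.lumen_diameter_mm / 2.0

    @property
    def intima_outer_radius_mm(self) -> float:
        return self.lumen_radius_mm + self.intima_fraction * self.imc_thickness_mm

    @property
    def media_adventitia_radius_mm(self) -> float:
        """Radius of the media–adventitia boundary r_ma."""
        return self.lumen_radius_mm + self.imc_thickness_mm

    @property
    def outer_wall_radius_mm(self) -> float:
        return self.media_adventitia_radius_mm + self.adventitia_thickness_mm

    @property
    def block_volume_mm3(self) -> float:
        sx = self.block_x_mm[1] - self.block_x_mm[0]
        sy = self.block_y_mm[1] - self.block_y_mm[0]
        sz = self.block_z_mm[1] - self.block_z_mm[0]
        return sx * sy * sz


#: Canonical layer ordering used for integer label codes everywhere.
LAYERS = ("lumen", "intima", "media", "adventitia", "surrounding")


@dataclass(frozen=True)
class LayerScattering:
    """Per-layer scattering-strength variances (dimensionless).

    Scatterer amplitudes are drawn from ``Normal(0, variance)`` of the layer
    the scatterer falls in.  The lumen defaults to 0 (anechoic blood).  The
    non-lumen defaults mimic the typical B-scan double-line wall appearance:
    bright intima and adventitia separated by a hypoechoic media, with
    mid-level surrounding tissue.
    """

    lumen: float = 0.0
    intima: float = 1.0
    media: float = 0.1
    adventitia: float = 0.8
    surrounding: float = 0.35

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.as_array()):
            raise ConfigurationError("layer variances must be non-negative")

    def as_array(self) -> np.ndarray:
        """Variances in :data:`LAYERS` order."""
        return np.array([getattr(self, name) for name in LAYERS], dtype=float)


@dataclass(frozen=True)
class TransducerConfig:
    """Linear-array transducer parameterization.

    Defaults follow the virtual-scanning parameter table of the framework:
    5 MHz centre frequency, 128 elements, two-cycle Hanning-modulated
    excitation, 0.279 mm element width, 0.025 mm kerf, 0.304 mm pitch,
    4 mm element height, 16 mm elevation lens focus, 15.5 mm transmit
    focus, F-numbers 3 (tx) / 1.7 (rx), Hanning apodization, 40 MHz
    sampling, 1540 m/s.
    """

    center_frequency_hz: float = 5e6
    n_elements: int = 128
    n_excitation_cycles: int = 2
    element_height_mm: float = 4.0
    element_width_mm: float = 0.279
    kerf_mm: float = 0.025
    pitch_mm: float = 0.304
    elevation_focus_mm: float = 16.0
    tx_focus_mm: float = 15.5
    f_number_tx: float = 3.0
    f_number_rx: float = 1.7
    apodization: str = "hanning"
    fs_hz: float = 40e6
    c_m_s: float = 1540.0

    def __post_init__(self) -> None:
        if self.center_frequency_hz <= 0 or self.fs_hz <= 0 or self.c_m_s <= 0:
            raise ConfigurationError("frequencies and sound speed must be positive")
        if self.f_number_tx <= 0 or self.f_number_rx <= 0:
            raise ConfigurationError("F-numbers must be positive")
        if self.n_excitation_cycles < 1:
            raise ConfigurationError("excitation must contain at least one cycle")
        if abs(self.pitch_mm - (self.element_width_mm + self.kerf_mm)) > 1e-6:
            raise ConfigurationError("pitch must equal element width + kerf")
        if self.fs_hz <= 4 * self.center_frequency_hz:
            raise ConfigurationError("sampling rate must exceed 4 x f0")

    @property
    def c_mm_s(self) -> float:
        return self.c_m_s * 1000.0

    @property
    def wavelength_mm(self) -> float:
        return self.c_mm_s / self.center_frequency_hz

    @property
    def pulse_length_mm(self) -> float:
        """Spatial extent of the two-way excitation, n_cycles x wavelength."""
        return self.n_excitation_cycles * self.wavelength_mm

    @property
    def pulse_duration_s(self) -> float:
        return self.n_excitation_cycles / self.center_frequency_hz

    @property
    def axial_sample_mm(self) -> float:
        """Depth spanned by one RF sample, c / (2 fs)."""
        return self.c_mm_s / (2.0 * self.fs_hz)

    @property
    def half_wavelength_um(self) -> float:
        """The lambda/2 inter-frame ambiguity bound of echo tracking, in um."""
        return self.wavelength_mm / 2.0 * 1000.0


@dataclass(frozen=True)
class ScanConfig:
    """Scan-grid layout: echo lines, depth range and frame timing."""

    n_lines: int = 160
    line_spacing_mm: float = 0.0625
    depth_range_mm: tuple[float, float] = (11.0, 29.0)
    n_frames_per_cycle: int = 45
    frame_rate_hz: float = 52.0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ConfigurationError("need at least one scan line")
        if self.depth_range_mm[1] <= self.depth_range_mm[0]:
            raise ConfigurationError("depth range must be increasing")
        if self.n_frames_per_cycle < 1 or self.frame_rate_hz <= 0:
            raise ConfigurationError("frame layout must be positive")

    @property
    def image_width_mm(self) -> float:
        return self.n_lines * self.line_spacing_mm

    @property
    def line_x_mm(self) -> np.ndarray:
        """Lateral line positions, centred on x = 0."""
        return (np.arange(self.n_lines) - (self.n_lines - 1) / 2.0) * self.line_spacing_mm


@dataclass(frozen=True)
class SlopeParams:
    """Exponential decay of wall motion into the surrounding tissue.

    ``b1`` (default 0.17 mm^-1) governs the radial-motion decay away from
    the lumen radius; ``b2`` (default 1.08 mm^-1) the much steeper
    longitudinal-motion decay beyond the media–adventitia boundary.
    """

    b1_per_mm: float = 0.17
    b2_per_mm: float = 1.08

    def __post_init__(self) -> None:
        if self.b1_per_mm <= 0 or self.b2_per_mm <= 0:
            raise ConfigurationError("decay slopes must be positive")


def _asdict(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _fromdict(cls, d: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in d.items():
        if k not in fields:
            raise ConfigurationError(f"unknown {cls.__name__} field: {k!r}")
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


_SECTIONS = {
    "geometry": ArteryGeometry,
    "scattering": LayerScattering,
    "transducer": TransducerConfig,
    "scan": ScanConfig,
    "slopes": SlopeParams,
}


def save_config(path, **sections) -> None:
    """Write named config dataclasses (geometry=..., scan=...) to YAML."""
    payload = {name: _asdict(obj) for name, obj in sections.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path) -> dict:
    """Load a YAML config file into dataclass instances per known section.

    Unknown top-level sections are returned verbatim.
    """
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    out = {}
    for name, value in payload.items():
        cls = _SECTIONS.get(name)
        out[name] = _fromdict(cls, value) if cls is not None else value
    return out
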