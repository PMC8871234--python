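"""Static 3D scatterer map of the artery wall and surrounding tissue.

The phantom is a rectangular tissue block filled with point scatterers at a
density of (by default) 10 per resolution cell of the imaging system — the
classical threshold for a fully developed speckle pattern.  Each scatterer
is classified into a layer (lumen, intima, media, adventitia, surrounding)
by its radial distance from the artery axis and receives a zero-mean
Gaussian scattering strength whose variance is the layer's backscatter
variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from .config import (
    LAYERS,
    ArteryGeometry,
    ConfigurationError,
    LayerScattering,
    TransducerConfig,
)


class ResourceError(RuntimeError):
    """Raised when a requested phantom would exceed the scatterer budget."""


#: Hard guard against accidentally enormous phantoms.
MAX_SCATTERERS = 5_000_000


@dataclass(frozen=True)
class ResolutionCell:
    """Axial x lateral x elevation dimensions of one resolution cell, mm."""

    axial_mm: float
    lateral_mm: float
    elevation_mm: float

    @property
    def volume_mm3(self) -> float:
        return self.axial_mm * self.lateral_mm * self.elevation_mm


def resolution_cell_volume(transducer: TransducerConfig) -> ResolutionCell:
    """Resolution-cell dimensions of the imaging system.

    The axial dimension is half the two-way pulse length
    (``n_cycles * lambda / 2``), the lateral dimension the receive-focus
    beamwidth ``F#_rx * lambda`` and the elevation dimension the
    elevation-focus beamwidth ``elevation_focus * lambda / element_height``.
    All three are configuration-derived closed forms, used only to set the
    scatterer density; the scanner's beam model is depth dependent.
    """
    lam = transducer.wavelength_mm
    axial = transducer.n_excitation_cycles * lam / 2.0
    lateral = transducer.f_number_rx * lam
    elevation = transducer.elevation_focus_mm * lam / transducer.element_height_mm
    return ResolutionCell(axial, lateral, elevation)


def classify_layer(
    positions: np.ndarray, geometry: ArteryGeometry
) -> np.ndarray:
    """Classify positions into layer label codes (indices into :data:`LAYERS`).

    The radial coordinate is the distance from the artery axis in the
    (elevation, depth) plane, ``sqrt(y^2 + (z - center_depth)^2)``; the
    lateral coordinate ``x`` runs along the artery and is ignored.  Radial
    intervals are half-open with the boundary point assigned to the outer
    layer (a point exactly at the lumen radius is intima).

    Parameters
    ----------
    positions : (n, 3) or (3,) array
        ``(x, y, z)`` coordinates in mm.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    y = np.hypot(pos[:, 1], pos[:, 2] - geometry.center_depth_mm)
    edges = np.array(
        [
            geometry.lumen_radius_mm,
            geometry.intima_outer_radius_mm,
            geometry.media_adventitia_radius_mm,
            geometry.outer_wall_radius_mm,
        ]
    )
    labels = np.searchsorted(edges, y, side="right").astype(np.int8)
    if np.ndim(positions) == 1:
        return labels[0]
    return labels


def radial_distance(positions: np.ndarray, geometry: ArteryGeometry) -> np.ndarray:
    """Distance of each position from the artery axis, in mm."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    return np.hypot(pos[:, 1], pos[:, 2] - geometry.center_depth_mm)


@dataclass
class ScattererMap:
    """Point-scatterer cloud: positions, scattering strengths, layer labels.

    ``positions`` is ``(n, 3)`` in mm with columns ``(x, y, z)``;
    ``amplitudes`` the Gaussian scattering strengths; ``layer_labels`` the
    integer codes into :data:`LAYERS` assigned at construction time.
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    layer_labels: np.ndarray
    geometry: ArteryGeometry
    seed: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float).ravel()
        self.layer_labels = np.asarray(self.layer_labels, dtype=np.int8).ravel()
        if not (len(self.positions) == len(self.amplitudes) == len(self.layer_labels)):
            raise ValueError("positions, amplitudes and labels must have equal length")

    @property
    def n(self) -> int:
        return len(self.amplitudes)

    def layer_mask(self, layer: str) -> np.ndarray:
        return self.layer_labels == LAYERS.index(layer)

    def with_positions(self, positions: np.ndarray) -> "ScattererMap":
        """A moved copy sharing amplitudes and labels (motion never
        creates or destroys scatterers)."""
        return ScattererMap(
            positions=np.asarray(positions, float),
            amplitudes=self.amplitudes,
            layer_labels=self.layer_labels,
            geometry=self.geometry,
            seed=self.seed,
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("positions", data=self.positions)
            fh.create_dataset("amplitudes", data=self.amplitudes)
            fh.create_dataset("layer_labels", data=self.layer_labels)
            if self.seed is not None:
                fh.attrs["seed"] = self.seed
            for key in (
                "lumen_diameter_mm",
                "imc_thickness_mm",
                "adventitia_thickness_mm",
                "center_depth_mm",
                "intima_fraction",
            ):
                fh.attrs[key] = getattr(self.geometry, key)
            fh.attrs["block_x_mm"] = self.geometry.block_x_mm
            fh.attrs["block_y_mm"] = self.geometry.block_y_mm
            fh.attrs["block_z_mm"] = self.geometry.block_z_mm

    @classmethod
    def from_hdf5(cls, path) -> "ScattererMap":
        with h5py.File(path, "r") as fh:
            geometry = ArteryGeometry(
                lumen_diameter_mm=float(fh.attrs["lumen_diameter_mm"]),
                imc_thickness_mm=float(fh.attrs["imc_thickness_mm"]),
                adventitia_thickness_mm=float(fh.attrs["adventitia_thickness_mm"]),
                center_depth_mm=float(fh.attrs["center_depth_mm"]),
                intima_fraction=float(fh.attrs["intima_fraction"]),
                block_x_mm=tuple(fh.attrs["block_x_mm"]),
                block_y_mm=tuple(fh.attrs["block_y_mm"]),
                block_z_mm=tuple(fh.attrs["block_z_mm"]),
            )
            return cls(
                positions=fh["positions"][...],
                amplitudes=fh["amplitudes"][...],
                layer_labels=fh["layer_labels"][...],
                geometry=geometry,
                seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
            )


def generate_scatterers(
    geometry: ArteryGeometry,
    scattering: LayerScattering,
    transducer: TransducerConfig,
    density_per_cell: float = 10.0,
    seed: int | None = 0,
    max_scatterers: int = MAX_SCATTERERS,
) -> ScattererMap:
    """Generate the static scatterer map of the tissue block.

    The scatterer count is ``round(density_per_cell * block_volume /
    cell_volume)``; positions are uniform in the block, and each scatterer's
    amplitude is drawn from ``Normal(0, variance_of_its_layer)``.  Fully
    reproducible for a given ``seed``.

    Raises
    ------
    ResourceError
        If the implied count exceeds ``max_scatterers``.
    """
    if density_per_cell < 1:
        raise ConfigurationError("density_per_cell must be >= 1")
    cell = resolution_cell_volume(transducer)
    n = int(round(density_per_cell * geometry.block_volume_mm3 / cell.volume_mm3))
    if n > max_scatterers:
        raise ResourceError(
            f"requested {n} scatterers exceeds the budget of {max_scatterers}; "
            "reduce the block extent or the density"
        )
    rng = np.random.default_rng(seed)
    lows = np.array([geometry.block_x_mm[0], geometry.block_y_mm[0], geometry.block_z_mm[0]])
    highs = np.array([geometry.block_x_mm[1], geometry.block_y_mm[1], geometry.block_z_mm[1]])
    positions = rng.uniform(lows, highs, size=(n, 3))
    labels = classify_layer(positions, geometry)
    std_per_layer = np.sqrt(scattering.as_array())
    amplitudes = rng.standard_normal(n) * std_per_layer[labels]
    return ScattererMap(positions, amplitudes, labels, geometry, seed=seed)


def layer_volume_fractions(geometry: ArteryGeometry) -> np.ndarray:
    """Analytic volume fraction of each layer within the tissue block.

    The artery is a cylinder along x; its cross-section may be clipped by
    the block's elevation (y) extent, which is accounted for exactly.
    The depth extent is assumed to contain the artery (true for the
    defaults).  Used as the oracle for label-proportion checks.
    """
    sx = geometry.block_x_mm[1] - geometry.block_x_mm[0]
    y_lo, y_hi = geometry.block_y_mm

    def clipped_disc_area(r: float) -> float:
        # area of a disc of radius r intersected with the strip y in [y_lo, y_hi]
        def antiderivative(t: float) -> float:
            t = float(np.clip(t, -r, r))
            return t * np.sqrt(max(r * r - t * t, 0.0)) + r * r * np.arcsin(t / r)

        return antiderivative(y_hi) - antiderivative(y_lo)

    radii = [
        geometry.lumen_radius_mm,
        geometry.intima_outer_radius_mm,
        geometry.media_adventitia_radius_mm,
        geometry.outer_wall_radius_mm,
    ]
    areas = np.array([clipped_disc_area(r) for r in radii])
    shell = np.diff(np.concatenate([[0.0], areas]))
    vol = shell * sx
    total = geometry.block_volume_mm3
    return np.append(vol, total - vol.sum()) / total


def variance_from_bscan(
    image: np.ndarray,
    roi_points: list[tuple[int, int, str]],
    reference_variance: float = 1.0,
    defaults: LayerScattering | None = None,
) -> LayerScattering:
    """Scale per-layer scattering variances from B-scan brightness.

    The mean 0–255 brightness over each layer's region-of-interest points is
    taken as proportional to the layer's backscatter variance; the brightest
    layer is mapped to ``reference_variance``.  Layers without ROI points
    fall back to ``defaults`` (and a warning is emitted).
    """
    img = np.asarray(image, dtype=float)
    if img.min() < 0 or img.max() > 255:
        raise ValueError("image values must lie in [0, 255]")
    defaults = defaults if defaults is not None else LayerScattering()
    means: dict[str, float] = {}
    for row, col, layer in roi_points:
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        means.setdefault(layer, 0.0)
    sums = {k: [0.0, 0] for k in means}
    for row, col, layer in roi_points:
        sums[layer][0] += img[row, col]
        sums[layer][1] += 1
    means = {k: s / c for k, (s, c) in sums.items()}
    missing = [l for l in LAYERS if l not in means]
    if missing:
        warnings.warn(
            f"no ROI points for layers {missing}; using configured defaults",
            stacklevel=2,
        )
    peak = max(means.values()) if means else 0.0
    values = {}
    for layer in LAYERS:
        if layer in means and peak > 0:
            values[layer] = reference_variance * means[layer] / peak
        else:
            values[layer] = getattr(defaults, layer)
    return LayerScattering(**values)
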