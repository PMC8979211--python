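"""Synthetic phantom and beam-model generator.

Stands in for patient CT, contours and base beam data: builds a 3-D voxel
grid with target and organ-at-risk (OAR) masks, a raster-scan spot layout
for two nearly opposed fields, the sparse dose-influence matrix ``d_ij``
(Gy per particle from rasterpoint *j* to voxel *i*), and per-spot-per-voxel
radiosensitivity tables (``alpha_ij``, ``sqrt(beta_ij)``) whose alpha rises
toward the Bragg peak, emulating the output of a track-structure model.

The depth-dose curve is a parametric surrogate (entrance plateau plus a
Gaussian peak of unit height with a sharp distal falloff), not a physical
Bragg model: the optimizer only ever consumes ``d_ij``, so any kernel with
the right qualitative shape exercises the same code paths.

Geometry conventions: 0-based voxel indices, voxel centers at
``origin + (index + 0.5) * spacing`` (mm), flat indices in C order, all
doses in Gy per fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .dose import DoseCorrelationMatrix, MixedFieldTable, PhotonResponse

__all__ = [
    "VoxelGrid",
    "VOIMask",
    "FieldMeta",
    "RasterLayout",
    "BeamKernelParams",
    "PhantomScenario",
    "SCENARIO_NAMES",
    "build_phantom",
    "default_kernel_params",
    "depth_dose",
    "build_dose_matrix",
    "build_radiosensitivity",
]

SCENARIO_NAMES = ("wrapped_serial", "single_gland", "two_glands_multi_oar")


class ConfigurationError(ValueError):
    """Invalid scenario / plan configuration."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel grid (shape in voxels, spacing and origin in mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ConfigurationError(f"grid shape must be three entries >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"grid spacing must be positive, got {self.spacing}")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def centers(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel-center coordinates in mm, C order."""
        axes = [
            self.origin[k] + (np.arange(self.shape[k]) + 0.5) * self.spacing[k]
            for k in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def center_mm(self) -> np.ndarray:
        return np.asarray(self.origin) + 0.5 * np.asarray(self.shape) * np.asarray(self.spacing)

    def flat_index(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return np.ravel_multi_index((ijk[:, 0], ijk[:, 1], ijk[:, 2]), self.shape)


@dataclass(frozen=True)
class VOIMask:
    """A named volume of interest as a set of flat voxel indices."""

    name: str
    role: str  # "target" | "oar"
    voxel_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.voxel_indices, dtype=np.intp))
        object.__setattr__(self, "voxel_indices", idx)
        if self.role not in ("target", "oar"):
            raise ConfigurationError(f"VOI role must be 'target' or 'oar', got {self.role!r}")
        if idx.size < 1:
            raise ConfigurationError(f"VOI {self.name!r} is empty")

    @property
    def M(self) -> int:
        return int(self.voxel_indices.size)


@dataclass(frozen=True)
class FieldMeta:
    """One scanned field: couch angle and in-plane beam direction."""

    couch_angle_deg: float
    direction: np.ndarray  # unit vector, beam travel direction
    lateral_axis: np.ndarray  # in-plane unit vector orthogonal to direction

    @classmethod
    def from_angle(cls, couch_angle_deg: float) -> "FieldMeta":
        th = np.deg2rad(couch_angle_deg)
        d = np.array([np.cos(th), np.sin(th), 0.0])
        e = np.array([-np.sin(th), np.cos(th), 0.0])
        return cls(couch_angle_deg, d, e)


@dataclass(frozen=True)
class RasterLayout:
    """All rasterpoints (spots) of a plan.

    ``spots`` columns: field id, lateral position (mm, along the field's
    lateral axis through the grid center), energy-layer index into
    ``BeamKernelParams.peak_depth_per_layer``.
    """

    fields_meta: tuple[FieldMeta, ...]
    spot_field: np.ndarray  # (J,) int
    spot_lateral_mm: np.ndarray  # (J,) float
    spot_layer: np.ndarray  # (J,) int

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ConfigurationError("raster layout needs at least one spot")
        for f in self.fields_meta:
            if not np.isclose(np.linalg.norm(f.direction), 1.0):
                raise ConfigurationError("field direction vectors must be unit norm")

    @property
    def J(self) -> int:
        return int(np.asarray(self.spot_field).size)


@dataclass(frozen=True)
class BeamKernelParams:
    """Parametric pencil-beam kernel.

    peak_depth_per_layer : mm, Bragg-peak depth of each energy layer
        (measured from the field reference point, see build_dose_matrix).
    lateral_sigma : mm, Gaussian lateral spread.
    entrance_plateau_fraction : entrance dose relative to peak, in (0, 1].
    peak_sigma_depth : mm, Gaussian width of the peak (proximal side); the
        distal falloff uses half this width.
    kernel_cutoff_sigmas : lateral distances beyond this many sigma
        contribute exactly zero dose.
    dose_constant : Gy per particle at the peak voxel of a unit-weight spot.
    """

    peak_depth_per_layer: np.ndarray
    lateral_sigma: float = 4.0
    entrance_plateau_fraction: float = 0.3
    peak_sigma_depth: float = 3.0
    kernel_cutoff_sigmas: float = 3.0
    dose_constant: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "peak_depth_per_layer", np.asarray(self.peak_depth_per_layer, dtype=float)
        )
        if self.lateral_sigma <= 0:
            raise ConfigurationError("lateral_sigma must be positive")
        if not (0 < self.entrance_plateau_fraction <= 1):
            raise ConfigurationError("entrance_plateau_fraction must be in (0, 1]")
        if self.kernel_cutoff_sigmas < 2:
            raise ConfigurationError("kernel_cutoff_sigmas must be >= 2")


@dataclass(frozen=True)
class PhantomScenario:
    grid: VoxelGrid
    vois: tuple[VOIMask, ...]
    layout: RasterLayout
    seed: int

    def __post_init__(self) -> None:
        n_targets = sum(1 for v in self.vois if v.role == "target")
        if n_targets != 1:
            raise ConfigurationError(f"scenario must have exactly one target VOI, got {n_targets}")

    @property
    def target(self) -> VOIMask:
        return next(v for v in self.vois if v.role == "target")

    @property
    def oars(self) -> tuple[VOIMask, ...]:
        return tuple(v for v in self.vois if v.role == "oar")

    def voi(self, name: str) -> VOIMask:
        for v in self.vois:
            if v.name == name:
                return v
        raise KeyError(f"no VOI named {name!r}")


def depth_dose(depth, layer: int, params: BeamKernelParams):
    """Relative depth-dose of one energy layer (unit height at the peak).

    Proximal of the peak: ``plateau + (1 - plateau) * gauss(depth - peak)``;
    distal: a sharper Gaussian falloff (half the proximal width). Continuous
    in depth, equal to 1 at the peak.
    """
    depth = np.asarray(depth, dtype=float)
    if np.any(depth < 0):
        raise ValueError("depth must be >= 0")
    peak = float(params.peak_depth_per_layer[layer])
    p = params.entrance_plateau_fraction
    sig = params.peak_sigma_depth
    sig_dist = 0.5 * sig
    delta = depth - peak
    proximal = p + (1.0 - p) * np.exp(-0.5 * (delta / sig) ** 2)
    distal = np.exp(-0.5 * (delta / sig_dist) ** 2)
    return np.where(delta <= 0, proximal, distal)


def _box(grid: VoxelGrid, x: tuple[int, int], y: tuple[int, int], z: tuple[int, int]) -> np.ndarray:
    ii, jj, kk = np.meshgrid(
        np.arange(*x), np.arange(*y), np.arange(*z), indexing="ij"
    )
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    return grid.flat_index(ijk)


# Field angles follow the two-nearly-opposed arrangement typical of skull
# base plans (couch angles -100 deg and 75 deg): both beams travel mostly
# along +-y, so +-x is the lateral direction where the gland OARs sit.
_FIELD_ANGLES = (-100.0, 75.0)
_LAYER_SPACING_MM = 5.0
_SOURCE_DISTANCE_MM = 100.0


def default_kernel_params(phantom: "PhantomScenario", **overrides) -> BeamKernelParams:
    """Kernel parameters with energy layers covering the target depth span.

    One layer per 5 mm of target depth span per field; layers of the two
    fields are concatenated into a single global list (spots reference it
    by index).
    """
    grid = phantom.grid
    centers = grid.centers()[phantom.target.voxel_indices]
    center = grid.center_mm()
    depths: list[np.ndarray] = []
    for f in phantom.layout.fields_meta:
        ref = center - f.direction * _SOURCE_DISTANCE_MM
        d = (centers - ref) @ f.direction
        span = d.max() - d.min()
        n_layers = max(2, int(np.ceil(span / _LAYER_SPACING_MM)) + 1)
        depths.append(np.linspace(d.min(), d.max(), n_layers))
    return BeamKernelParams(peak_depth_per_layer=np.concatenate(depths), **overrides)


def _make_layout(grid: VoxelGrid, target: VOIMask) -> tuple[RasterLayout, BeamKernelParams]:
    fields = tuple(FieldMeta.from_angle(a) for a in _FIELD_ANGLES)
    centers = grid.centers()[target.voxel_indices]
    center = grid.center_mm()
    lateral_step = grid.spacing[0]

    spot_field, spot_lat, spot_layer = [], [], []
    peak_depths: list[np.ndarray] = []
    layer_offset = 0
    for fid, f in enumerate(fields):
        ref = center - f.direction * _SOURCE_DISTANCE_MM
        d = (centers - ref) @ f.direction
        span = d.max() - d.min()
        n_layers = max(2, int(np.ceil(span / _LAYER_SPACING_MM)) + 1)
        peak_depths.append(np.linspace(d.min(), d.max(), n_layers))
        lat = (centers - center) @ f.lateral_axis
        lat_positions = np.arange(
            np.floor(lat.min() / lateral_step), np.ceil(lat.max() / lateral_step) + 1
        ) * lateral_step
        for layer in range(n_layers):
            for pos in lat_positions:
                spot_field.append(fid)
                spot_lat.append(pos)
                spot_layer.append(layer_offset + layer)
        layer_offset += n_layers

    layout = RasterLayout(
        fields_meta=fields,
        spot_field=np.asarray(spot_field, dtype=np.intp),
        spot_lateral_mm=np.asarray(spot_lat, dtype=float),
        spot_layer=np.asarray(spot_layer, dtype=np.intp),
    )
    params = BeamKernelParams(peak_depth_per_layer=np.concatenate(peak_depths))
    return layout, params


def build_phantom(scenario_name: str, seed: int) -> PhantomScenario:
    """Build one of the canned geometries.

    ``wrapped_serial``
        C-shaped target wrapped around a thin serial OAR (cord), the
        complex-anatomy case.
    ``single_gland``
        Box target with one lateral parallel OAR (gland).
    ``two_glands_multi_oar``
        Box target with two lateral glands plus two small serial OARs in
        the beam paths (cord, stem).

    Deterministic for a fixed (scenario_name, seed); the seed also drives
    the small per-spot variability of the radiosensitivity tables.
    """
    if scenario_name not in SCENARIO_NAMES:
        raise ConfigurationError(
            f"unknown scenario {scenario_name!r}; expected one of {SCENARIO_NAMES}"
        )
    grid = VoxelGrid(shape=(25, 25, 3), spacing=(2.0, 2.0, 2.0))

    vois: list[VOIMask]
    if scenario_name == "wrapped_serial":
        cord = _box(grid, (11, 14), (11, 14), (0, 3))
        ring = _box(grid, (7, 18), (7, 18), (0, 3))
        hole = _box(grid, (10, 15), (10, 15), (0, 3))
        opening = _box(grid, (10, 15), (14, 18), (0, 3))
        target_idx = np.setdiff1d(ring, np.union1d(hole, opening))
        vois = [
            VOIMask("target", "target", target_idx),
            VOIMask("cord", "oar", cord),
        ]
    else:
        target_idx = _box(grid, (8, 17), (8, 17), (0, 3))
        vois = [VOIMask("target", "target", target_idx)]
        vois.append(VOIMask("gland_right", "oar", _box(grid, (19, 24), (9, 16), (0, 3))))
        if scenario_name == "two_glands_multi_oar":
            vois.append(VOIMask("gland_left", "oar", _box(grid, (1, 6), (9, 16), (0, 3))))
            vois.append(VOIMask("cord", "oar", _box(grid, (11, 14), (19, 21), (0, 3))))
            vois.append(VOIMask("stem", "oar", _box(grid, (11, 14), (4, 6), (0, 3))))

    target = next(v for v in vois if v.role == "target")
    layout, _ = _make_layout(grid, target)
    return PhantomScenario(grid=grid, vois=tuple(vois), layout=layout, seed=int(seed))


def build_dose_matrix(
    phantom: PhantomScenario, params: BeamKernelParams | None = None
) -> DoseCorrelationMatrix:
    """Sparse voxel-by-rasterpoint dose-influence matrix.

    Each spot column is ``dose_constant * depth_dose * exp(-r^2 / 2 sigma^2)``
    along its field direction, with entries beyond ``cutoff * sigma`` lateral
    distance exactly zero. Also records, per nonzero entry, the signed depth
    offset of the voxel from the spot's Bragg peak (consumed by
    build_radiosensitivity).
    """
    if params is None:
        params = default_kernel_params(phantom)
    layout = phantom.layout
    if layout.J < 1:
        raise ConfigurationError("empty spot list")
    grid = phantom.grid
    centers = grid.centers()
    center = grid.center_mm()
    cutoff = params.kernel_cutoff_sigmas * params.lateral_sigma

    rows, cols, vals, offs = [], [], [], []
    for j in range(layout.J):
        f = layout.fields_meta[layout.spot_field[j]]
        ref = center - f.direction * _SOURCE_DISTANCE_MM
        rel = centers - ref
        depth = rel @ f.direction
        lat_vec = rel - depth[:, None] * f.direction[None, :]
        lat_vec = lat_vec - layout.spot_lateral_mm[j] * f.lateral_axis[None, :]
        r2 = np.einsum("ij,ij->i", lat_vec, lat_vec)
        mask = r2 <= cutoff * cutoff
        if not mask.any():
            continue
        dd = depth_dose(np.maximum(depth[mask], 0.0), int(layout.spot_layer[j]), params)
        w = dd * np.exp(-0.5 * r2[mask] / params.lateral_sigma**2)
        keep = w > 1e-12
        idx = np.flatnonzero(mask)[keep]
        rows.append(idx)
        cols.append(np.full(idx.size, j, dtype=np.intp))
        vals.append(params.dose_constant * w[keep])
        peak = params.peak_depth_per_layer[layout.spot_layer[j]]
        offs.append(depth[idx] - peak)

    if not rows:
        raise ConfigurationError("no spot deposits dose in the grid")
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    d = sp.coo_matrix(
        (np.concatenate(vals), (rows, cols)), shape=(grid.n_voxels, layout.J)
    ).tocsr()
    d.sum_duplicates()
    off = sp.coo_matrix(
        (np.concatenate(offs), (rows, cols)), shape=(grid.n_voxels, layout.J)
    ).tocsr()
    return DoseCorrelationMatrix(d=d, peak_offset_mm=off)


# Default photon linear-quadratic response: alpha_x, beta_x typical of a
# late-responding tissue; D_t is the LEM threshold where the survival curve
# turns purely linear with slope s_max = alpha_x + 2 beta_x D_t (the LQ
# slope at D_t, i.e. a C1 continuation).
DEFAULT_ALPHA_X = 0.1  # 1/Gy
DEFAULT_BETA_X = 0.05  # 1/Gy^2
DEFAULT_D_T = 30.0  # Gy

# Depth window (mm) over which alpha_ij relaxes from its Bragg-peak maximum
# back to the photon value; wider than the physical peak because the
# high-LET region extends proximally of the peak.
_ALPHA_RAMP_WIDTH_MM = 8.0


def build_radiosensitivity(
    phantom: PhantomScenario,
    matrix: DoseCorrelationMatrix,
    alpha_x: float = DEFAULT_ALPHA_X,
    beta_x: float = DEFAULT_BETA_X,
    rbe_contrast: float = 3.0,
) -> MixedFieldTable:
    """Per-entry radiosensitivity tables aligned with the dose matrix.

    ``alpha_ij`` ramps from ``alpha_x`` far from the Bragg peak up to
    ``rbe_contrast * alpha_x`` at the peak (Gaussian ramp in the depth
    offset recorded by build_dose_matrix, with a small seeded per-spot
    width variation); ``sqrt(beta_ij)`` is constant at ``sqrt(beta_x)``.
    ``rbe_contrast = 1`` yields a photon-equivalent table.
    """
    if alpha_x <= 0 or beta_x <= 0:
        raise ValueError("alpha_x and beta_x must be positive")
    if rbe_contrast < 1:
        raise ValueError("rbe_contrast must be >= 1")
    d = matrix.d
    if matrix.peak_offset_mm is None:
        raise ValueError("dose matrix lacks peak-offset data; rebuild with build_dose_matrix")
    off = matrix.peak_offset_mm

    rng = np.random.default_rng(phantom.seed)
    width_j = _ALPHA_RAMP_WIDTH_MM * (1.0 + 0.2 * (rng.random(phantom.layout.J) - 0.5))

    coo = d.tocoo()
    w = width_j[coo.col]
    ramp = np.exp(-0.5 * (off.tocoo().data / w) ** 2)
    alpha_vals = alpha_x * (1.0 + (rbe_contrast - 1.0) * ramp)

    alpha = d.copy()
    alpha.data = alpha_vals
    sqrt_beta = d.copy()
    sqrt_beta.data = np.full_like(alpha_vals, np.sqrt(beta_x))
    photon = PhotonResponse(alpha_x=alpha_x, beta_x=beta_x, D_t=DEFAULT_D_T)
    return MixedFieldTable(alpha=alpha, sqrt_beta=sqrt_beta, photon=photon)
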