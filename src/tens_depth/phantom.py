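"""Voxelized layered forearm phantom with surface electrodes and nerve paths.

The phantom is a concentric-cylinder surrogate of a forearm: an outer skin
shell, subcutaneous adipose tissue (SAT), muscle, cortical bone, cancellous
bone and a marrow core, embedded in air on a regular cell-centered voxel
grid.  Two gel-backed disc electrodes sit on the skin; their outermost gel
voxels become Dirichlet node sets for the field solver.  Nerve trajectories
are straight lines running parallel to the arm axis at a configurable depth
below the skin under the electrode midline.

Axis convention: x across the arm, y is the depth axis (electrodes on the
+y side), z runs along the arm.  All lengths are in millimetres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TissueTable",
    "VoxelGrid",
    "ElectrodeSpec",
    "NerveTrajectory",
    "PhantomConfig",
    "build_phantom",
    "place_electrodes",
    "make_nerve_trajectory",
    "DEFAULT_CONDUCTIVITIES",
]

# Tissue electrical conductivities in S/m (IT'IS low-frequency values).
DEFAULT_CONDUCTIVITIES: dict[str, float] = {
    "air": 0.0,
    "skin": 0.1482,
    "sat": 0.0776,
    "fat": 0.0776,
    "muscle": 0.4610,
    "cortical_bone": 0.0063,
    "cancellous_bone": 0.0804,
    "marrow": 0.1797,
    "tendon": 0.3675,
    "blood": 0.6624,
    "nerve": 0.3475,
    "gel": 1.7,
}


class PhantomError(ValueError):
    """Raised for invalid phantom, electrode or trajectory configurations."""


@dataclass(frozen=True)
class TissueTable:
    """Mapping from tissue name to electrical conductivity (S/m).

    Tissue names are assigned stable integer labels in insertion order;
    label 0 is always air.
    """

    conductivities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES)
    )

    def __post_init__(self) -> None:
        sigma = dict(self.conductivities)
        if "air" not in sigma:
            sigma = {"air": 0.0, **sigma}
        if sigma["air"] != 0.0:
            raise PhantomError("air conductivity must be exactly 0")
        for name, value in sigma.items():
            if not np.isfinite(value) or value < 0:
                raise PhantomError(f"conductivity of {name!r} must be finite and >= 0")
        # keep air first so that label 0 == air
        ordered = {"air": 0.0}
        ordered.update({k: float(v) for k, v in sigma.items() if k != "air"})
        object.__setattr__(self, "conductivities", ordered)

    @property
    def names(self) -> list[str]:
        return list(self.conductivities)

    def label(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise PhantomError(f"unknown tissue {name!r}") from None

    def conductivity(self, name: str) -> float:
        if name not in self.conductivities:
            raise PhantomError(f"unknown tissue {name!r}")
        return self.conductivities[name]

    def sigma_of_label(self) -> np.ndarray:
        """Conductivity lookup indexed by integer label."""
        return np.array(list(self.conductivities.values()), dtype=float)


@dataclass
class ElectrodeSpec:
    """Disc electrode: resistive gel column capped by an equipotential face.

    ``center`` is a point on the skin surface; the gel extends radially
    outward by ``gel_thickness + pad_thickness``.
    """

    center: tuple[float, float, float]
    polarity: str  # "anode" | "cathode"
    radius: float = 3.0
    gel_thickness: float = 2.0
    pad_thickness: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise PhantomError("electrode radius must be > 0")
        if self.total_thickness <= 0:
            raise PhantomError("electrode total thickness must be > 0")
        if self.polarity not in ("anode", "cathode"):
            raise PhantomError(f"polarity must be anode|cathode, got {self.polarity!r}")
        self.center = tuple(float(c) for c in self.center)

    @property
    def total_thickness(self) -> float:
        return self.gel_thickness + self.pad_thickness


@dataclass
class NerveTrajectory:
    """Straight sensor polyline for one nerve, ordered along the arm axis."""

    name: str
    points: np.ndarray  # (n, 3) mm
    depth: float  # mm below the skin surface

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise PhantomError("trajectory needs >= 2 points of shape (n, 3)")
        dz = np.diff(self.points[:, 2])
        if not np.all(dz > 0):
            raise PhantomError("trajectory points must be strictly ordered along z")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class VoxelGrid:
    """Regular cell-centered voxel grid of tissue labels and conductivities."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]  # mm
    origin: tuple[float, float, float]  # mm, center of voxel (0, 0, 0)
    tissue_label: np.ndarray  # int, shape ``shape``
    conductivity: np.ndarray  # S/m, shape ``shape``
    tissues: TissueTable
    meta: dict = field(default_factory=dict)
    anode_nodes: np.ndarray | None = None  # flat voxel indices, Dirichlet
    cathode_nodes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise PhantomError("grid spacing must be > 0 on all axes")
        if self.tissue_label.shape != self.shape:
            raise PhantomError("tissue_label shape mismatch")
        if self.conductivity.shape != self.shape:
            raise PhantomError("conductivity shape mismatch")

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Cell-center coordinates (mm) along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    def point_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices for points in mm (for interpolation)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        idx = self.point_to_index(points)
        upper = np.asarray(self.shape) - 1
        return np.all((idx >= 0) & (idx <= upper), axis=1)

    def tissue_volume(self, name: str) -> float:
        """Total volume (mm^3) of all voxels carrying the given tissue label."""
        lbl = self.tissues.label(name)
        return float(np.count_nonzero(self.tissue_label == lbl)) * self.voxel_volume

    def copy(self) -> "VoxelGrid":
        return dataclasses.replace(
            self,
            tissue_label=self.tissue_label.copy(),
            conductivity=self.conductivity.copy(),
            meta=dict(self.meta),
            anode_nodes=None if self.anode_nodes is None else self.anode_nodes.copy(),
            cathode_nodes=None if self.cathode_nodes is None else self.cathode_nodes.copy(),
        )


# Default layer stack from the skin inward; the remainder of the cylinder
# core is marrow.  Chosen so a 5.5 mm deep trajectory sits just inside muscle.
DEFAULT_LAYERS: tuple[tuple[str, float], ...] = (
    ("skin", 1.5),
    ("sat", 3.5),
    ("muscle", 15.0),
    ("cortical_bone", 5.0),
    ("cancellous_bone", 7.0),
)


@dataclass
class PhantomConfig:
    """Parameters of the concentric-cylinder forearm surrogate."""

    radius: float = 40.0  # mm
    length: float = 120.0  # mm
    spacing: float = 1.0  # mm, isotropic
    layers: Sequence[tuple[str, float]] = DEFAULT_LAYERS
    core_tissue: str = "marrow"
    air_margin: float = 4.0  # mm of air around the cylinder
    shape: str = "cylinder"  # "cylinder" | "box" (box: core tissue fills the grid)
    tissues: TissueTable = field(default_factory=TissueTable)


def build_phantom(config: PhantomConfig | None = None) -> VoxelGrid:
    """Voxelize the layered cylinder phantom.

    Returns a grid whose conductivities are populated from the tissue table;
    everything outside the cylinder is air.  Construction is deterministic.
    """
    cfg = config or PhantomConfig()
    table = cfg.tissues
    h = float(cfg.spacing)
    if h <= 0:
        raise PhantomError("spacing must be > 0")
    if cfg.radius <= 0 or cfg.length <= 0:
        raise PhantomError("radius and length must be > 0")
    thicknesses = [t for _, t in cfg.layers]
    if any(t <= 0 for t in thicknesses):
        raise PhantomError("layer thicknesses must be > 0")
    if sum(thicknesses) >= cfg.radius:
        raise PhantomError("layer thicknesses must sum to less than the radius")
    if cfg.layers and h > min(thicknesses):
        raise PhantomError(
            f"spacing {h} mm exceeds the thinnest layer "
            f"({min(thicknesses)} mm) and would erase it"
        )

    half_xy = cfg.radius + cfg.air_margin
    nx = ny = int(np.ceil(2 * half_xy / h))
    nz = int(np.ceil(cfg.length / h))
    origin = (-half_xy + h / 2, -half_xy + h / 2, h / 2)
    shape = (nx, ny, nz)

    label = np.zeros(shape, dtype=np.int16)  # air
    if cfg.shape == "box":
        label[:] = table.label(cfg.core_tissue)
    elif cfg.shape == "cylinder":
        x = origin[0] + h * np.arange(nx)
        y = origin[1] + h * np.arange(ny)
        r = np.hypot(x[:, None], y[None, :])
        # radius bands from the outside in
        section = np.zeros_like(r, dtype=np.int16)  # air
        inner = cfg.radius
        for name, thick in cfg.layers:
            band = (r <= inner) & (r > inner - thick)
            section[band] = table.label(name)
            inner -= thick
        section[r <= inner] = table.label(cfg.core_tissue)
        label[:] = section[:, :, None]
    else:
        raise PhantomError(f"unknown phantom shape {cfg.shape!r}")

    sigma = table.sigma_of_label()[label]
    meta = {
        "radius": cfg.radius,
        "length": cfg.length,
        "shape": cfg.shape,
        "layers": list(cfg.layers),
        "core_tissue": cfg.core_tissue,
    }
    return VoxelGrid(
        shape=shape,
        spacing=(h, h, h),
        origin=origin,
        tissue_label=label,
        conductivity=sigma,
        tissues=table,
        meta=meta,
    )


def default_montage(
    grid: VoxelGrid,
    separation: float = 20.0,
    radius: float = 3.0,
    thickness: float = 2.0,
) -> tuple[ElectrodeSpec, ElectrodeSpec]:
    """Two electrodes on the +y skin apex, ``separation`` mm apart along z."""
    R = grid.meta["radius"]
    zc = grid.meta["length"] / 2
    return (
        ElectrodeSpec((0.0, R, zc - separation / 2), "anode", radius, thickness),
        ElectrodeSpec((0.0, R, zc + separation / 2), "cathode", radius, thickness),
    )


def _gel_mask(grid: VoxelGrid, spec: ElectrodeSpec) -> np.ndarray:
    """Boolean mask of air voxels converted to gel for one electrode."""
    R = grid.meta["radius"]
    cx, cy, cz = spec.center
    c_r = float(np.hypot(cx, cy))
    if abs(c_r - R) > max(grid.spacing):
        raise PhantomError(
            f"electrode center {spec.center} is not on the skin surface (r={c_r:.2f})"
        )
    ux, uy = cx / c_r, cy / c_r  # outward radial direction at the center
    X, Y, Z = grid.coordinate_grids()
    r_xy = np.hypot(X, Y)
    d = np.stack([X - cx, Y - cy, Z - cz])
    along = d[0] * ux + d[1] * uy  # signed distance along the electrode axis
    lateral = np.sqrt(np.maximum(np.einsum("ixyz,ixyz->xyz", d, d) - along**2, 0.0))
    mask = (
        (lateral <= spec.radius)
        & (along > 0)  # outward side only, not the antipodal patch
        & (r_xy > R)
        & (r_xy <= R + spec.total_thickness)
        & (grid.tissue_label == grid.tissues.label("air"))
    )
    if not mask.any():
        raise PhantomError(f"electrode at {spec.center} produced no gel voxels")
    return mask


def place_electrodes(
    grid: VoxelGrid, montage: tuple[ElectrodeSpec, ElectrodeSpec]
) -> VoxelGrid:
    """Stamp gel voxels for both electrodes and record Dirichlet node sets.

    Gel voxels take the gel conductivity; the outermost gel shell of each
    electrode (its contact with the metal pad, which is not meshed) becomes
    the Dirichlet node set of that polarity.
    """
    a, b = montage
    if {a.polarity, b.polarity} != {"anode", "cathode"}:
        raise PhantomError("montage needs exactly one anode and one cathode")
    if grid.meta.get("shape") != "cylinder":
        raise PhantomError("electrode placement requires a cylinder phantom")
    R = grid.meta["radius"]
    length = grid.meta["length"]
    for spec in montage:
        if spec.center[2] - spec.radius < 0 or spec.center[2] + spec.radius > length:
            raise PhantomError("electrode footprint extends beyond the phantom")

    out = grid.copy()
    gel_label = out.tissues.label("gel")
    gel_sigma = out.tissues.conductivity("gel")
    X, Y, _ = out.coordinate_grids()
    r_xy = np.hypot(X, Y)
    masks = {}
    for spec in montage:
        mask = _gel_mask(grid, spec)
        masks[spec.polarity] = mask
    if (masks["anode"] & masks["cathode"]).any():
        raise PhantomError("electrodes overlap")
    for spec in montage:
        mask = masks[spec.polarity]
        out.tissue_label[mask] = gel_label
        out.conductivity[mask] = gel_sigma
        top = mask & (r_xy > R + spec.total_thickness - max(out.spacing))
        if not top.any():
            raise PhantomError(f"no contact-surface voxels for {spec.polarity}")
        nodes = np.flatnonzero(top.ravel())
        if spec.polarity == "anode":
            out.anode_nodes = nodes
        else:
            out.cathode_nodes = nodes
    out.meta["electrodes"] = [dataclasses.asdict(s) for s in montage]
    return out


def electrode_midline(grid: VoxelGrid) -> tuple[float, float, float]:
    """Skin-surface point halfway between the two electrode centers."""
    R = grid.meta["radius"]
    specs = grid.meta.get("electrodes")
    if specs:
        c = np.mean([s["center"] for s in specs], axis=0)
        r = np.hypot(c[0], c[1])
        return (c[0] * R / r, c[1] * R / r, c[2])
    return (0.0, R, grid.meta["length"] / 2)


def make_nerve_trajectory(
    grid: VoxelGrid,
    name: str = "median",
    depth: float = 5.5,
    point_spacing: float = 0.5,
    n_points: int | None = None,
    margin: float = 2.0,
) -> NerveTrajectory:
    """Straight nerve polyline ``depth`` mm below the skin under the midline.

    Points are spaced ``point_spacing`` mm apart (the node-of-Ranvier
    spacing of the fiber to be simulated) and run parallel to the arm axis,
    centered on the electrode midline.
    """
    R = grid.meta["radius"]
    length = grid.meta["length"]
    if not 0 < depth < R:
        raise PhantomError(f"depth {depth} mm outside the phantom (radius {R} mm)")
    if point_spacing <= 0:
        raise PhantomError("point_spacing must be > 0")
    mx, my, mz = electrode_midline(grid)
    r_mid = np.hypot(mx, my)
    # move radially inward from the skin point under the midline
    px = mx * (r_mid - depth) / r_mid
    py = my * (r_mid - depth) / r_mid
    if n_points is None:
        n_points = int(np.floor((length - 2 * margin) / point_spacing)) + 1
    if n_points < 2:
        raise PhantomError("trajectory needs >= 2 points")
    z = mz + point_spacing * (np.arange(n_points) - (n_points - 1) / 2)
    pts = np.column_stack([np.full(n_points, px), np.full(n_points, py), z])
    traj = NerveTrajectory(name=name, points=pts, depth=float(depth))
    if not grid.contains_points(pts).all():
        raise PhantomError("trajectory extends outside the grid")
    return traj
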