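"""Activating function from Hessian eigenvalues and volume of tissue activated.

The activating function (AF) of a voxel is the largest absolute eigenvalue
of the Hessian of the electric potential: the strongest second directional
derivative over all fiber orientations.  An AF isosurface threshold is
calibrated by sampling the AF along a titrated axon at its threshold
current; evaluating the AF field at a common current and masking voxels at
or above the calibrated threshold yields the volume of tissue activated
(VTA) and, from the mask, the activation depth below the skin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import linregress

from .phantom import NerveTrajectory, VoxelGrid
from .solver import MM_TO_M, PotentialField
from .protocol import TitrationResult

__all__ = [
    "AFField",
    "AFThreshold",
    "VTAResult",
    "AFError",
    "hessian_af",
    "calibrate_af_threshold",
    "vta",
    "vta_vs_pw",
    "activation_depth",
]


class AFError(ValueError):
    pass


@dataclass
class AFField:
    """Per-voxel activating-function magnitude in V/m^2."""

    grid: VoxelGrid
    af: np.ndarray  # (nx, ny, nz), >= 0
    reduction: str
    current_mA: float | None = None  # electrode current context of the field
    eigenvalues: np.ndarray | None = None  # (nx, ny, nz, 3), optional

    def scaled(self, factor: float) -> "AFField":
        """AF at a rescaled current (linear in the field for factor > 0)."""
        if factor <= 0:
            raise AFError("scale factor must be > 0")
        return replace(
            self,
            af=self.af * factor,
            current_mA=None if self.current_mA is None else self.current_mA * factor,
            eigenvalues=None if self.eigenvalues is None else self.eigenvalues * factor,
        )

    def at_current(self, target_mA: float) -> "AFField":
        if self.current_mA in (None, 0):
            raise AFError("AF field has no electrode-current context")
        return self.scaled(target_mA / self.current_mA)


@dataclass
class AFThreshold:
    """Calibrated AF isosurface level (V/m^2) with its calibration context."""

    value: float
    pw_us: float
    nerve: str
    current_mA: float  # threshold current at which the AF was evaluated

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise AFError("AF threshold must be positive")


@dataclass
class VTAResult:
    """Voxel mask of predicted activation with volume and depth summaries."""

    mask: np.ndarray  # bool, grid shape
    volume_mm3: float
    max_depth_mm: float | None  # None for an empty mask
    pw_us: float
    evaluation_current_mA: float
    af_threshold: float
    meta: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.mask.any()


def hessian_af(
    potential: PotentialField,
    reduction: str = "max_abs_eig",
    keep_eigenvalues: bool = False,
) -> AFField:
    """Activating function from the Hessian of the potential.

    Second central differences give the six unique Hessian entries; each
    voxel's symmetric 3x3 matrix is eigen-decomposed and reduced to a
    scalar.  Reductions: ``max_abs_eig`` (default), ``abs_trace``
    (|Laplacian|) and ``along_z`` (|d2/dz2|, the classic along-fiber
    activating function for a z-aligned axon).
    """
    grid = potential.grid
    if min(grid.shape) < 3:
        raise AFError("grid must span at least 3 voxels on every axis")
    if reduction not in ("max_abs_eig", "abs_trace", "along_z"):
        raise AFError(f"unknown AF reduction {reduction!r}")
    spac_m = [s * MM_TO_M for s in grid.spacing]
    grads = np.gradient(potential.phi, *spac_m, edge_order=1)
    hess = np.empty(grid.shape + (3, 3))
    for i in range(3):
        gi = np.gradient(grads[i], *spac_m, edge_order=1)
        for j in range(3):
            hess[..., i, j] = gi[j]
    hess = (hess + np.swapaxes(hess, -1, -2)) / 2  # enforce symmetry
    current = potential.info.get("current_mA")
    eigs = None
    if reduction == "abs_trace":
        af = np.abs(np.trace(hess, axis1=-2, axis2=-1))
    elif reduction == "along_z":
        af = np.abs(hess[..., 2, 2])
    else:
        eigs = np.linalg.eigvalsh(hess)
        af = np.abs(eigs).max(axis=-1)
    return AFField(
        grid=grid,
        af=af,
        reduction=reduction,
        current_mA=current,
        eigenvalues=eigs if keep_eigenvalues else None,
    )


def sample_af(af: AFField, trajectory: NerveTrajectory) -> np.ndarray:
    """Trilinear samples of the AF along a polyline."""
    grid = af.grid
    if not grid.contains_points(trajectory.points).all():
        raise AFError("trajectory exits the voxel grid")
    idx = grid.point_to_index(trajectory.points)
    return map_coordinates(af.af, idx.T, order=1, mode="nearest")


def calibrate_af_threshold(
    af: AFField,
    trajectory: NerveTrajectory,
    titration: TitrationResult,
) -> AFThreshold:
    """AF level that just activates the calibrated axon.

    ``af`` must be evaluated at the titrated threshold current for the
    pulse width in question; the threshold is the maximum AF seen along
    the axon trajectory at that current.
    """
    if af.current_mA is not None:
        expected = titration.threshold_mA
        if abs(af.current_mA - expected) > 1e-6 * max(abs(expected), 1.0):
            raise AFError(
                f"AF field current ({af.current_mA} mA) does not match the "
                f"titrated threshold current ({expected} mA)"
            )
    value = float(sample_af(af, trajectory).max())
    return AFThreshold(
        value=value,
        pw_us=titration.pw_us,
        nerve=trajectory.name,
        current_mA=titration.threshold_mA,
    )


# tissue classes excluded from the VTA: not biological targets
_NON_BIOLOGICAL = ("air", "gel")


def vta(
    af: AFField,
    threshold: AFThreshold,
    grid: VoxelGrid | None = None,
) -> VTAResult:
    """Mask of biological-tissue voxels whose AF reaches the threshold."""
    grid = grid or af.grid
    if af.current_mA is None:
        raise AFError("AF field has no electrode-current context")
    excluded = np.isin(
        grid.tissue_label,
        [grid.tissues.label(n) for n in _NON_BIOLOGICAL if n in grid.tissues.names],
    )
    mask = (af.af >= threshold.value) & ~excluded
    volume = float(np.count_nonzero(mask)) * grid.voxel_volume
    depth = _max_depth(mask, grid) if mask.any() else None
    return VTAResult(
        mask=mask,
        volume_mm3=volume,
        max_depth_mm=depth,
        pw_us=threshold.pw_us,
        evaluation_current_mA=af.current_mA,
        af_threshold=threshold.value,
        meta={"nerve": threshold.nerve, "calibration_current_mA": threshold.current_mA},
    )


def _max_depth(mask: np.ndarray, grid: VoxelGrid) -> float:
    """Greatest depth below the skin surface among masked voxels (mm)."""
    R = grid.meta.get("radius")
    X, Y, _ = grid.coordinate_grids()
    if R is not None:
        depth = R - np.hypot(X, Y)  # radial distance below the cylinder skin
    else:
        depth = Y.max() - Y  # box phantom: measured from the +y face
    return float(depth[mask].max())


def activation_depth(result: VTAResult, grid: VoxelGrid) -> float:
    """Maximum activation depth (mm below the skin) of a VTA mask."""
    if result.empty:
        raise AFError("activation depth undefined for an empty VTA mask")
    return _max_depth(result.mask, grid)


@dataclass
class VTALinearFit:
    slope: float  # mm^3 per us
    intercept: float  # mm^3
    r_squared: float
    n: int


def vta_vs_pw(results: list[VTAResult]) -> VTALinearFit:
    """Ordinary least-squares line through (pulse width, VTA volume)."""
    if len(results) < 3:
        raise AFError("need >= 3 pulse widths for the VTA-vs-PW fit")
    pw = np.array([r.pw_us for r in results], dtype=float)
    vol = np.array([r.volume_mm3 for r in results], dtype=float)
    fit = linregress(pw, vol)
    return VTALinearFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(results),
    )
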