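"""Ohmic quasi-static volume-conductor solver on the voxel grid.

Solves div(sigma grad phi) = 0 with Dirichlet voltages on the electrode
contact nodes and insulating (zero normal current) outer boundaries, using
a 7-point finite-difference discretization with harmonic-mean face
conductivities and a Jacobi-preconditioned conjugate-gradient solve.

Because the problem is linear, a single unit solve per montage is rescaled
to any target electrode current.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import LinearOperator, cg

from .phantom import VoxelGrid

__all__ = [
    "PotentialField",
    "EFieldMap",
    "CurrentReport",
    "SolverError",
    "solve_potential",
    "electric_field",
    "electrode_current",
    "scale_to_current",
]

MM_TO_M = 1e-3


class SolverError(RuntimeError):
    """Raised on non-convergence or an ill-posed electrode configuration."""


@dataclass
class PotentialField:
    """Scalar electric potential (V) per voxel on a solved grid.

    ``phi`` holds the solution on conductive voxels; air voxels carry the
    value of their nearest conductive voxel, which realizes the insulating
    (zero normal gradient) boundary for finite-difference post-processing.
    """

    grid: VoxelGrid
    phi: np.ndarray  # V, shape == grid.shape
    dirichlet: dict  # polarity -> {"nodes": flat idx, "value": V}
    info: dict = field(default_factory=dict)

    @property
    def anode_value(self) -> float:
        return self.dirichlet["anode"]["value"]

    @property
    def cathode_value(self) -> float:
        return self.dirichlet["cathode"]["value"]

    def scaled(self, factor: float) -> "PotentialField":
        dir_scaled = {
            k: {"nodes": v["nodes"], "value": v["value"] * factor}
            for k, v in self.dirichlet.items()
        }
        info = dict(self.info)
        info["scale_factor"] = info.get("scale_factor", 1.0) * factor
        return replace(self, phi=self.phi * factor, dirichlet=dir_scaled, info=info)


@dataclass
class EFieldMap:
    """Electric field E = -grad(phi) in V/m on the voxel grid."""

    grid: VoxelGrid
    components: np.ndarray  # (3, nx, ny, nz), V/m
    magnitude: np.ndarray  # (nx, ny, nz), V/m


@dataclass
class CurrentReport:
    anode_mA: float
    cathode_mA: float

    @property
    def imbalance(self) -> float:
        """|I_anode + I_cathode| / |I_anode| (should vanish at convergence)."""
        return abs(self.anode_mA + self.cathode_mA) / abs(self.anode_mA)


def _face_conductances(grid: VoxelGrid, axis: int) -> np.ndarray:
    """Conductance (S) of each interior face normal to ``axis``.

    Harmonic mean of the two adjacent voxel conductivities (zero if either
    side is air) times face area over center distance.
    """
    sig = grid.conductivity
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    s1 = sig[tuple(sl_lo)]
    s2 = sig[tuple(sl_hi)]
    hmean = np.zeros_like(s1)
    both = (s1 > 0) & (s2 > 0)
    hmean[both] = 2.0 * s1[both] * s2[both] / (s1[both] + s2[both])
    area = np.prod([grid.spacing[a] for a in range(3) if a != axis])
    return hmean * (area / grid.spacing[axis]) * MM_TO_M


def _dirichlet_from_grid(
    grid: VoxelGrid, anode_v: float, cathode_v: float
) -> dict:
    if grid.anode_nodes is None or grid.cathode_nodes is None:
        raise SolverError("grid has no electrode Dirichlet node sets; place electrodes first")
    return {
        "anode": {"nodes": grid.anode_nodes, "value": float(anode_v)},
        "cathode": {"nodes": grid.cathode_nodes, "value": float(cathode_v)},
    }


def _fill_air_nearest(phi: np.ndarray, conductive: np.ndarray) -> np.ndarray:
    """Copy the nearest conductive value into non-conductive voxels."""
    if conductive.all():
        return phi
    _, (ix, iy, iz) = ndimage.distance_transform_edt(
        ~conductive, return_indices=True
    )
    return phi[ix, iy, iz]


def solve_potential(
    grid: VoxelGrid,
    dirichlet: dict | None = None,
    anode_v: float = 1.0,
    cathode_v: float = -1.0,
    tol: float = 1e-8,
    maxiter: int = 200_000,
) -> PotentialField:
    """Solve the discrete conservation equations for the electric potential.

    Parameters
    ----------
    dirichlet
        Optional mapping ``{"anode": {"nodes": flat_idx, "value": V}, ...}``;
        by default the grid's recorded electrode node sets are used with
        ``anode_v`` / ``cathode_v`` volts applied.
    tol
        Relative residual of the conjugate-gradient solve.
    """
    if dirichlet is None:
        dirichlet = _dirichlet_from_grid(grid, anode_v, cathode_v)
    if not dirichlet.get("anode", {}).get("nodes", np.array([])).size:
        raise SolverError("empty anode node set")
    if not dirichlet.get("cathode", {}).get("nodes", np.array([])).size:
        raise SolverError("empty cathode node set")

    n_total = int(np.prod(grid.shape))
    conductive = grid.conductivity.ravel() > 0

    fixed_value = np.zeros(n_total)
    fixed_mask = np.zeros(n_total, dtype=bool)
    for spec in dirichlet.values():
        nodes = np.asarray(spec["nodes"], dtype=np.int64)
        if not conductive[nodes].all():
            raise SolverError("Dirichlet nodes must lie on conductive voxels")
        fixed_mask[nodes] = True
        fixed_value[nodes] = spec["value"]

    # restrict to the connected component(s) that touch a Dirichlet node
    comp, _ = ndimage.label(
        grid.conductivity > 0, structure=ndimage.generate_binary_structure(3, 1)
    )
    comp = comp.ravel()
    live_comps = np.unique(comp[fixed_mask])
    anode_comps = set(np.unique(comp[np.asarray(dirichlet["anode"]["nodes"])]))
    cathode_comps = set(np.unique(comp[np.asarray(dirichlet["cathode"]["nodes"])]))
    if not (anode_comps & cathode_comps):
        raise SolverError("anode and cathode are not connected by conductive tissue")
    active = conductive & np.isin(comp, live_comps)

    unknown = active & ~fixed_mask
    n_unk = int(unknown.sum())
    unk_id = -np.ones(n_total, dtype=np.int64)
    unk_id[unknown] = np.arange(n_unk)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n_unk)
    b = np.zeros(n_unk)
    strides = np.array(
        [grid.shape[1] * grid.shape[2], grid.shape[2], 1], dtype=np.int64
    )
    for axis in range(3):
        g = _face_conductances(grid, axis).ravel()
        # flat indices of the low-side voxel of every interior face
        sl = [slice(None)] * 3
        sl[axis] = slice(None, -1)
        base = np.arange(n_total, dtype=np.int64).reshape(grid.shape)[tuple(sl)].ravel()
        nbr = base + strides[axis]
        keep = g > 0
        p, q, gk = base[keep], nbr[keep], g[keep]
        for lo, hi in ((p, q), (q, p)):
            lo_unk = unk_id[lo]
            m = lo_unk >= 0
            np.add.at(diag, lo_unk[m], gk[m])
            hi_unk = unk_id[hi]
            mm = m & (hi_unk >= 0)
            rows.append(lo_unk[mm])
            cols.append(hi_unk[mm])
            vals.append(-gk[mm])
            mf = m & fixed_mask[hi]
            np.add.at(b, lo_unk[mf], gk[mf] * fixed_value[hi[mf]])

    rows.append(np.arange(n_unk))
    cols.append(np.arange(n_unk))
    vals.append(diag)
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unk, n_unk),
    )
    inv_diag = 1.0 / A.diagonal()
    M = LinearOperator((n_unk, n_unk), matvec=lambda v: inv_diag * v)
    x, cg_info = cg(A, b, rtol=tol, atol=0.0, maxiter=maxiter, M=M)
    if cg_info != 0:
        raise SolverError(f"conjugate-gradient solve did not converge (info={cg_info})")
    residual = float(np.linalg.norm(b - A @ x) / max(np.linalg.norm(b), 1e-300))

    phi = np.zeros(n_total)
    phi[unknown] = x
    phi[fixed_mask] = fixed_value[fixed_mask]
    phi = _fill_air_nearest(
        phi.reshape(grid.shape), active.reshape(grid.shape)
    )
    values = [s["value"] for s in dirichlet.values()]
    info = {"relative_residual": residual, "tol": tol, "n_unknowns": n_unk}
    fieldobj = PotentialField(grid=grid, phi=phi, dirichlet=dirichlet, info=info)
    lo, hi = min(values), max(values)
    eps = 1e-9 * (hi - lo)
    if phi.min() < lo - eps or phi.max() > hi + eps:
        raise SolverError("potential violates the discrete maximum principle")
    return fieldobj


def electric_field(potential: PotentialField) -> EFieldMap:
    """Negative gradient of the potential, in V/m.

    Central differences in the interior, one-sided at the grid boundary.
    The grid spacing is in mm, so gradients are scaled by 1/MM_TO_M once.
    """
    grid = potential.grid
    spacings_m = [s * MM_TO_M for s in grid.spacing]
    grads = np.gradient(potential.phi, *spacings_m, edge_order=1)
    comp = -np.stack(grads)
    air = grid.conductivity <= 0
    comp[:, air] = 0.0
    mag = np.sqrt(np.einsum("ixyz,ixyz->xyz", comp, comp))
    return EFieldMap(grid=grid, components=comp, magnitude=mag)


def electrode_current(potential: PotentialField) -> CurrentReport:
    """Net current (mA) through each electrode's Dirichlet contact nodes.

    Computed by summing the face conductance times the potential drop over
    every face joining a Dirichlet node to a non-Dirichlet conductive voxel;
    positive values mean current leaving the electrode into the tissue.
    """
    grid = potential.grid
    phi = potential.phi.ravel()
    n_total = phi.size
    strides = np.array(
        [grid.shape[1] * grid.shape[2], grid.shape[2], 1], dtype=np.int64
    )
    currents = {}
    for pol, spec in potential.dirichlet.items():
        nodes = np.asarray(spec["nodes"], dtype=np.int64)
        in_set = np.zeros(n_total, dtype=bool)
        in_set[nodes] = True
        total = 0.0
        for axis in range(3):
            g = _face_conductances(grid, axis).ravel()
            sl = [slice(None)] * 3
            sl[axis] = slice(None, -1)
            base = (
                np.arange(n_total, dtype=np.int64).reshape(grid.shape)[tuple(sl)].ravel()
            )
            nbr = base + strides[axis]
            for p, q in ((base, nbr), (nbr, base)):
                m = in_set[p] & ~in_set[q] & (g > 0)
                total += float(np.sum(g[m] * (phi[p[m]] - phi[q[m]])))
        currents[pol] = total * 1e3  # A -> mA
    return CurrentReport(anode_mA=currents["anode"], cathode_mA=currents["cathode"])


def scale_to_current(
    potential: PotentialField, target_mA: float
) -> tuple[PotentialField, EFieldMap]:
    """Rescale a solved field so the anode injects ``target_mA`` (linearity)."""
    report = electrode_current(potential)
    if report.anode_mA == 0:
        raise SolverError("cannot rescale a field with zero electrode current")
    factor = target_mA / report.anode_mA
    scaled = potential.scaled(factor)
    scaled.info["current_mA"] = target_mA
    return scaled, electric_field(scaled)
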