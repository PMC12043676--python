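"""Double-cable myelinated axon model driven by extracellular potentials.

Implements the McIntyre-Richardson-Grill (MRG) compartment chain: nodes of
Ranvier carrying fast Na+, persistent Na+, slow K+ and leak channels,
separated by ten passive internodal segments (MYSA, FLUT, 6 x STIN, FLUT,
MYSA) whose axolemma and myelin sheath form the two cables.  The
extracellular potential enters every compartment through the axial
difference terms, so a field sampled along a nerve trajectory can drive
the fiber directly.

Geometry and electrical constants follow the published MRG parameter sets
(fiber diameters 5.7-16.0 um) with linear interpolation in between.  The
``sensory`` variant keeps the published nodal constants; fiber-type
specific conductance overrides can be supplied explicitly.

Unit system: mV, ms, uF, mS, uA; compartment dimensions are stored in um
and converted to cm for areas and axial resistances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .phantom import NerveTrajectory
from .solver import PotentialField

__all__ = [
    "AxonModel",
    "MembraneTrace",
    "ExtracellularDrive",
    "AxonError",
    "build_axon",
    "sample_extracellular",
    "integrate",
    "detect_ap",
    "conduction_velocity",
]


class AxonError(RuntimeError):
    pass


# Published double-cable geometry, one row per fiber diameter (um):
# fiber diameter -> (axon diameter, node/MYSA diameter, FLUT/STIN diameter,
#                    node-to-node separation, FLUT length, myelin lamellae)
_GEOMETRY = {
    5.7: (3.4, 1.9, 3.4, 500.0, 35.0, 80),
    7.3: (4.6, 2.4, 4.6, 750.0, 38.0, 100),
    8.7: (5.8, 2.8, 5.8, 1000.0, 40.0, 110),
    10.0: (6.9, 3.3, 6.9, 1150.0, 46.0, 120),
    11.5: (8.1, 3.7, 8.1, 1250.0, 50.0, 130),
    12.8: (9.2, 4.2, 9.2, 1350.0, 54.0, 135),
    14.0: (9.5, 4.7, 9.5, 1400.0, 56.0, 140),
    15.0: (10.4, 5.0, 10.4, 1450.0, 58.0, 145),
    16.0: (10.9, 5.5, 10.9, 1500.0, 60.0, 150),
}

NODE_LENGTH = 1.0  # um
MYSA_LENGTH = 3.0  # um
SPACE_NODE = 0.002  # um, periaxonal space width
SPACE_MYSA = 0.002
SPACE_FLUT = 0.004
SPACE_STIN = 0.004
RHO_AXIAL = 70.0  # Ohm*cm, axoplasm and periaxonal space
CM_AXOLEMMA = 2.0  # uF/cm^2
MYELIN_CM_PER_LAMELLA = 0.1  # uF/cm^2 per membrane (2 per lamella)
MYELIN_GM_PER_LAMELLA = 0.001  # S/cm^2 per membrane
G_PAS_MYSA = 0.001  # S/cm^2
G_PAS_FLUT = 0.0001
G_PAS_STIN = 0.0001
E_PAS = -80.0  # mV
V_INIT = -80.0  # mV

# Nodal channel densities (S/cm^2) and reversal potentials (mV)
NODE_CHANNELS = {
    "gnaf": 3.0,
    "gnap": 0.01,
    "gks": 0.08,
    "gl": 0.007,
    "ena": 50.0,
    "ek": -90.0,
    "el": -90.0,
}

CELSIUS = 36.0
_Q10_MP = 2.2 ** ((CELSIUS - 20.0) / 10.0)
_Q10_H = 2.9 ** ((CELSIUS - 20.0) / 10.0)
_Q10_S = 3.0 ** ((CELSIUS - 36.0) / 10.0)

NODE, MYSA, FLUT, STIN = 0, 1, 2, 3


def _linterp(diameter: float, column: int) -> float:
    keys = np.array(sorted(_GEOMETRY))
    vals = np.array([_GEOMETRY[k][column] for k in keys])
    return float(np.interp(diameter, keys, vals))


@dataclass
class AxonModel:
    """Compartmentalized double-cable fiber with precomputed cable constants."""

    fiber_diameter: float  # um
    n_nodes: int
    variant: str
    # per-compartment geometry
    ctype: np.ndarray  # int codes NODE/MYSA/FLUT/STIN
    length: np.ndarray  # um
    diameter: np.ndarray  # um (axolemma)
    n_lamellae: int
    internode_sep: float  # um, node-to-node
    channels: dict = field(default_factory=lambda: dict(NODE_CHANNELS))
    # derived absolute electrical quantities (filled by build_axon)
    Cm: np.ndarray | None = None  # uF
    Cmy: np.ndarray | None = None  # uF
    gmy: np.ndarray | None = None  # mS
    gpas: np.ndarray | None = None  # mS (0 at nodes)
    ga: np.ndarray | None = None  # mS between k and k+1 (intracellular)
    gp: np.ndarray | None = None  # mS between k and k+1 (periaxonal)
    _rest: dict | None = None  # cached resting state

    @property
    def n_compartments(self) -> int:
        return len(self.ctype)

    @property
    def node_index(self) -> np.ndarray:
        return np.flatnonzero(self.ctype == NODE)

    @property
    def total_length(self) -> float:
        """um; equals (n_nodes - 1) * internode_sep + node length."""
        return float(self.length.sum())

    def compartment_offsets(self) -> np.ndarray:
        """Arclength (mm) of each compartment center from the fiber start."""
        edges = np.concatenate([[0.0], np.cumsum(self.length)])
        return (edges[:-1] + edges[1:]) / 2 * 1e-3

    def parameters(self) -> dict:
        """JSON-serializable audit dump of the parameterization."""
        return {
            "fiber_diameter_um": self.fiber_diameter,
            "n_nodes": self.n_nodes,
            "variant": self.variant,
            "internode_separation_um": self.internode_sep,
            "n_lamellae": self.n_lamellae,
            "node_length_um": NODE_LENGTH,
            "mysa_length_um": MYSA_LENGTH,
            "flut_length_um": float(self.length[self.ctype == FLUT][0]),
            "stin_length_um": float(self.length[self.ctype == STIN][0]),
            "node_diameter_um": float(self.diameter[self.ctype == NODE][0]),
            "axon_diameter_um": float(self.diameter[self.ctype == STIN][0]),
            "axial_resistivity_ohm_cm": RHO_AXIAL,
            "channels_S_per_cm2": self.channels,
            "celsius": CELSIUS,
        }


@dataclass
class ExtracellularDrive:
    """Extracellular potential (mV) per compartment at unit stimulus amplitude."""

    phi_mV: np.ndarray
    baseline_current_mA: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi_mV = np.asarray(self.phi_mV, dtype=float)
        if not np.all(np.isfinite(self.phi_mV)):
            raise AxonError("extracellular drive contains non-finite values")


@dataclass
class MembraneTrace:
    """Node transmembrane voltages over time."""

    time: np.ndarray  # ms
    vm: np.ndarray  # (n_t, n_nodes) mV
    resting_potential: float  # mV
    node_positions_mm: np.ndarray  # arclength of each node from fiber start

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


def build_axon(
    diameter: float = 5.7,
    n_nodes: int = 101,
    variant: str = "sensory",
    channel_overrides: dict | None = None,
) -> AxonModel:
    """Assemble the double-cable fiber and precompute its cable constants.

    ``diameter`` must lie within the published parameterization range
    (5.7-16.0 um); geometric parameters are interpolated linearly between
    the published sets.
    """
    keys = sorted(_GEOMETRY)
    if not keys[0] <= diameter <= keys[-1]:
        raise AxonError(
            f"fiber diameter {diameter} um outside supported range "
            f"[{keys[0]}, {keys[-1]}]"
        )
    if variant not in ("sensory", "motor"):
        raise AxonError(f"unknown fiber variant {variant!r}")
    if n_nodes < 21:
        raise AxonError("n_nodes must be >= 21 to support a propagating spike")

    axon_d = _linterp(diameter, 0)
    node_d = _linterp(diameter, 1)
    flut_d = _linterp(diameter, 2)
    deltax = _linterp(diameter, 3)
    flut_len = _linterp(diameter, 4)
    nl = int(round(_linterp(diameter, 5)))
    stin_len = (deltax - NODE_LENGTH - 2 * MYSA_LENGTH - 2 * flut_len) / 6.0
    if stin_len <= 0:
        raise AxonError("invalid geometry: non-positive STIN length")

    # compartment pattern: node + 10 internodal segments, repeated
    inter_types = [MYSA, FLUT] + [STIN] * 6 + [FLUT, MYSA]
    ctype = [NODE]
    for _ in range(n_nodes - 1):
        ctype += inter_types + [NODE]
    ctype = np.array(ctype, dtype=np.int8)

    length = np.empty(len(ctype))
    diam = np.empty(len(ctype))
    space = np.empty(len(ctype))
    for code, ln, dm, sp in (
        (NODE, NODE_LENGTH, node_d, SPACE_NODE),
        (MYSA, MYSA_LENGTH, node_d, SPACE_MYSA),
        (FLUT, flut_len, flut_d, SPACE_FLUT),
        (STIN, stin_len, axon_d, SPACE_STIN),
    ):
        sel = ctype == code
        length[sel] = ln
        diam[sel] = dm
        space[sel] = sp

    channels = dict(NODE_CHANNELS)
    if channel_overrides:
        unknown = set(channel_overrides) - set(channels)
        if unknown:
            raise AxonError(f"unknown channel parameters: {sorted(unknown)}")
        channels.update(channel_overrides)

    axon = AxonModel(
        fiber_diameter=diameter,
        n_nodes=n_nodes,
        variant=variant,
        ctype=ctype,
        length=length,
        diameter=diam,
        n_lamellae=nl,
        internode_sep=deltax,
        channels=channels,
    )

    um2_to_cm2 = 1e-8
    area_ax = np.pi * diam * length * um2_to_cm2  # axolemma area, cm^2
    area_my = np.pi * diameter * length * um2_to_cm2  # myelin surface, cm^2
    axon.Cm = CM_AXOLEMMA * area_ax  # uF

    is_node = ctype == NODE
    gmy_per_cm2 = MYELIN_GM_PER_LAMELLA / (2 * nl)
    cmy_per_cm2 = MYELIN_CM_PER_LAMELLA / (2 * nl)
    axon.Cmy = np.where(is_node, 0.0, cmy_per_cm2 * area_my) * 1.0
    axon.gmy = np.where(is_node, 1e10 * area_ax, gmy_per_cm2 * area_my) * 1e3  # mS
    gpas_per_cm2 = np.zeros(len(ctype))
    gpas_per_cm2[ctype == MYSA] = G_PAS_MYSA
    gpas_per_cm2[ctype == FLUT] = G_PAS_FLUT
    gpas_per_cm2[ctype == STIN] = G_PAS_STIN
    axon.gpas = gpas_per_cm2 * area_ax * 1e3  # mS

    # axial conductances: series of the two half-compartment resistances
    um_to_cm = 1e-4
    r_half_i = RHO_AXIAL * (length / 2 * um_to_cm) / (np.pi * (diam * um_to_cm) ** 2 / 4)
    area_peri = (
        np.pi * ((diam / 2 + space) ** 2 - (diam / 2) ** 2) * um2_to_cm2
    )  # cm^2
    r_half_p = RHO_AXIAL * (length / 2 * um_to_cm) / area_peri
    axon.ga = 1e3 / (r_half_i[:-1] + r_half_i[1:])  # mS
    axon.gp = 1e3 / (r_half_p[:-1] + r_half_p[1:])  # mS
    return axon


# ---------------------------------------------------------------------------
# nodal channel kinetics (rates in 1/ms, voltages in mV, 36 C)

def _exprel(x: np.ndarray) -> np.ndarray:
    """x / (1 - exp(-x)), stable near x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-6
    out[small] = 1.0 + x[small] / 2.0
    xs = x[~small]
    out[~small] = xs / (1.0 - np.exp(-xs))
    return out


def _rates(v: np.ndarray) -> dict[str, np.ndarray]:
    v = np.asarray(v, dtype=float)
    am = _Q10_MP * 6.57 * 10.3 * _exprel((v + 20.4) / 10.3)
    bm = _Q10_MP * 0.304 * 9.16 * _exprel(-(v + 25.7) / 9.16)
    ah = _Q10_H * 0.34 * 11.0 * _exprel(-(v + 114.0) / 11.0)
    bh = _Q10_H * 12.6 / (1.0 + np.exp(-(v + 31.8) / 13.4))
    ap = _Q10_MP * 0.0353 * 10.2 * _exprel((v + 27.0) / 10.2)
    bp = _Q10_MP * 0.000883 * 10.0 * _exprel(-(v + 34.0) / 10.0)
    as_ = _Q10_S * 0.3 / (1.0 + np.exp(-(v + 53.0) / 5.0))
    bs = _Q10_S * 0.03 / (1.0 + np.exp(-(v + 90.0)))
    return {"m": (am, bm), "h": (ah, bh), "p": (ap, bp), "s": (as_, bs)}


def _steady_gates(v: np.ndarray) -> dict[str, np.ndarray]:
    r = _rates(v)
    return {k: a / (a + b) for k, (a, b) in r.items()}


class _CableSystem:
    """Banded backward-Euler stepper for the two-potential cable system.

    Unknown ordering interleaves the transmembrane voltage V_k (axolemma)
    and the periaxonal-minus-extracellular voltage W_k, giving bandwidth 3.
    """

    def __init__(self, axon: AxonModel, dt: float):
        self.axon = axon
        self.dt = dt
        n = axon.n_compartments
        self.n = n
        ga, gp = axon.ga, axon.gp
        ga_sum = np.zeros(n)
        ga_sum[:-1] += ga
        ga_sum[1:] += ga
        gpa = gp + ga  # periaxonal row couples through both paths
        gpa_sum = np.zeros(n)
        gpa_sum[:-1] += gpa
        gpa_sum[1:] += gpa

        m = 2 * n
        ab = np.zeros((7, m))  # solve_banded layout, u = l = 3

        def put(i: np.ndarray, j: np.ndarray, v: np.ndarray) -> None:
            np.add.at(ab, (3 + i - j, j), v)

        k = np.arange(n)
        kl = np.arange(n - 1)  # pairs (kl, kl+1)
        # V rows
        put(2 * k, 2 * k, axon.Cm / dt + ga_sum + axon.gpas)
        put(2 * k, 2 * k + 1, ga_sum)
        put(2 * kl, 2 * kl + 2, -ga)
        put(2 * kl + 2, 2 * kl, -ga)
        put(2 * kl, 2 * kl + 3, -ga)
        put(2 * kl + 2, 2 * kl + 1, -ga)
        # W rows
        put(2 * k + 1, 2 * k + 1, axon.Cmy / dt + axon.gmy + gpa_sum)
        put(2 * k + 1, 2 * k, ga_sum)
        put(2 * kl + 1, 2 * kl + 3, -gpa)
        put(2 * kl + 3, 2 * kl + 1, -gpa)
        put(2 * kl + 1, 2 * kl + 2, -ga)
        put(2 * kl + 3, 2 * kl, -ga)
        self.ab_static = ab
        self.node_cols = 2 * axon.node_index
        self.ga_sum = ga_sum
        self.gpa = gpa

    def drive_vectors(self, e_unit: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Axial source terms from a unit extracellular profile (mV)."""
        ga, gpa, n = self.axon.ga, self.gpa, self.n
        de = np.diff(e_unit)
        dv = np.zeros(n)
        dv[:-1] += ga * de
        dv[1:] -= ga * de
        dw = np.zeros(n)
        dw[:-1] += gpa * de
        dw[1:] -= gpa * de
        return dv, dw

    def step(
        self,
        V: np.ndarray,
        W: np.ndarray,
        gates: dict[str, np.ndarray],
        e_scale: float,
        dv_unit: np.ndarray,
        dw_unit: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray]:
        axon, dt = self.axon, self.dt
        nodes = axon.node_index
        vn = V[nodes]
        # exponential-Euler gate update at the current voltage
        r = _rates(vn)
        for key, (a, b) in r.items():
            tau = 1.0 / (a + b)
            inf = a * tau
            gates[key] = inf + (gates[key] - inf) * np.exp(-dt / tau)

        ch = axon.channels
        area = np.pi * axon.diameter[nodes] * axon.length[nodes] * 1e-8  # cm^2
        gnaf = ch["gnaf"] * gates["m"] ** 3 * gates["h"] * area * 1e3  # mS
        gnap = ch["gnap"] * gates["p"] ** 3 * area * 1e3
        gks = ch["gks"] * gates["s"] * area * 1e3
        gl = ch["gl"] * area * 1e3
        g_ion = gnaf + gnap + gks + gl
        i_rev = (gnaf + gnap) * ch["ena"] + gks * ch["ek"] + gl * ch["el"]

        ab = self.ab_static.copy()
        ab[3, self.node_cols] += g_ion

        rhs = np.empty(2 * self.n)
        rhs[0::2] = axon.Cm / dt * V + axon.gpas * E_PAS + e_scale * dv_unit
        rhs[0::2][nodes] += i_rev
        rhs[1::2] = axon.Cmy / dt * W + e_scale * dw_unit
        x = solve_banded((3, 3), ab, rhs)
        return x[0::2], x[1::2]


def _resting_state(axon: AxonModel, dt: float = 0.005, settle_ms: float = 20.0) -> dict:
    """Integrate without stimulus until the coupled system is at rest."""
    if axon._rest is not None and abs(axon._rest["dt"] - dt) < 1e-12:
        return axon._rest
    sys = _CableSystem(axon, dt)
    n = axon.n_compartments
    V = np.full(n, V_INIT)
    W = np.zeros(n)
    gates = _steady_gates(V[axon.node_index])
    zeros = np.zeros(n)
    for _ in range(int(round(settle_ms / dt))):
        V, W = sys.step(V, W, gates, 0.0, zeros, zeros)
    rest = {"V": V, "W": W, "gates": gates, "dt": dt}
    axon._rest = rest
    return rest


def integrate(
    axon: AxonModel,
    drive: ExtracellularDrive | None,
    pulse,
    amplitude: float,
    duration: float = 3.5,
    dt: float = 0.0025,
) -> MembraneTrace:
    """Advance the double-cable equations under an extracellular stimulus.

    The extracellular potential of compartment k at time t is
    ``amplitude * a(t) * drive.phi_mV[k]`` where ``a`` is the pulse's
    normalized waveform.  ``pulse`` may be ``None`` together with
    ``drive=None`` for a stimulus-free run.
    """
    if dt > 0.005:
        raise AxonError("dt must be <= 0.005 ms for the nodal kinetics")
    if pulse is not None and duration < pulse.total_width_ms:
        raise AxonError("duration shorter than the stimulus pulse")
    n_steps = int(round(duration / dt))
    sys = _CableSystem(axon, dt)

    if drive is None:
        e_unit = np.zeros(axon.n_compartments)
    else:
        e_unit = np.asarray(drive.phi_mV, dtype=float)
        if e_unit.shape != (axon.n_compartments,):
            raise AxonError("drive length does not match compartment count")
    dv_unit, dw_unit = sys.drive_vectors(e_unit)

    rest = _resting_state(axon)
    V = rest["V"].copy()
    W = rest["W"].copy()
    gates = {k: v.copy() for k, v in rest["gates"].items()}
    resting_potential = float(np.mean(V[axon.node_index]))

    nodes = axon.node_index
    times = dt * np.arange(n_steps + 1)
    vm = np.empty((n_steps + 1, len(nodes)))
    vm[0] = V[nodes]
    for i in range(1, n_steps + 1):
        a_t = 0.0 if pulse is None else pulse.value_at(times[i])
        V, W = sys.step(V, W, gates, amplitude * a_t, dv_unit, dw_unit)
        vm[i] = V[nodes]
        if not np.all(np.abs(vm[i]) < 500.0):
            raise AxonError("membrane voltage exceeded 500 mV: numerical instability")
    offsets = axon.compartment_offsets()[nodes]
    return MembraneTrace(
        time=times,
        vm=vm,
        resting_potential=resting_potential,
        node_positions_mm=offsets,
    )


def sample_extracellular(
    potential: PotentialField,
    trajectory: NerveTrajectory,
    axon: AxonModel,
) -> ExtracellularDrive:
    """Trilinearly sample the potential (mV) at every compartment center.

    The fiber is centered on the trajectory; its compartment centers are
    mapped to points by arclength along the polyline.
    """
    from scipy.ndimage import map_coordinates

    pts = trajectory.points
    grid = potential.grid
    if not grid.contains_points(pts).all():
        raise AxonError("trajectory exits the voxel grid")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    ax_len_mm = axon.total_length * 1e-3
    if ax_len_mm > total + 1e-9:
        raise AxonError(
            f"axon ({ax_len_mm:.1f} mm) longer than the trajectory ({total:.1f} mm)"
        )
    s = axon.compartment_offsets() + (total - ax_len_mm) / 2  # centered
    coords = np.column_stack([np.interp(s, arclen, pts[:, a]) for a in range(3)])
    idx = grid.point_to_index(coords)
    phi_V = map_coordinates(potential.phi, idx.T, order=1, mode="nearest")
    current = potential.info.get("current_mA")
    return ExtracellularDrive(
        phi_mV=phi_V * 1e3,
        baseline_current_mA=current,
        meta={"trajectory": trajectory.name, "n_compartments": axon.n_compartments},
    )


def detect_ap(
    trace: MembraneTrace,
    level: float = 0.0,
    min_nodes: int = 3,
    min_propagation_nodes: int = 5,
) -> tuple[bool, dict]:
    """Detect a propagating action potential in a node-voltage trace.

    True iff the voltage crosses ``level`` upward at >= ``min_nodes``
    distinct nodes, at least one of which lies ``min_propagation_nodes`` or
    more nodes away from the initiation site (earliest crossing).
    """
    vm = trace.vm
    above = vm > level
    crossed = (~above[:-1] & above[1:]).any(axis=0)
    nodes = np.flatnonzero(crossed)
    detail: dict = {"spike_nodes": nodes, "spike_times": {}}
    if len(nodes) == 0:
        return False, detail
    t_cross = {}
    for node in nodes:
        rising = np.flatnonzero(~above[:-1, node] & above[1:, node])
        t_cross[int(node)] = float(trace.time[rising[0] + 1])
    detail["spike_times"] = t_cross
    init_node = min(t_cross, key=t_cross.get)
    detail["initiation_node"] = init_node
    ok = len(nodes) >= min_nodes and np.max(np.abs(nodes - init_node)) >= min_propagation_nodes
    return bool(ok), detail


def conduction_velocity(trace: MembraneTrace, level: float = 0.0) -> float:
    """Conduction velocity (m/s) from a node crossing-time regression.

    Uses nodes on one side of the initiation site, excluding the five nodes
    nearest the ends and the initiation region.
    """
    fired, detail = detect_ap(trace, level=level)
    if not fired:
        raise AxonError("no propagating action potential in the trace")
    t_cross = detail["spike_times"]
    init = detail["initiation_node"]
    nodes = np.array(sorted(t_cross))
    side = nodes[(nodes > init + 3) & (nodes < trace.vm.shape[1] - 5)]
    if len(side) < 5:
        side = nodes[(nodes < init - 3) & (nodes > 5)]
    if len(side) < 5:
        raise AxonError("too few propagating nodes for a velocity estimate")
    x_mm = trace.node_positions_mm[side]
    t_ms = np.array([t_cross[int(n)] for n in side])
    slope = np.polyfit(t_ms, x_mm, 1)[0]  # mm/ms == m/s
    return float(abs(slope))
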