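"""End-to-end orchestration: phantom -> field -> titration -> S-D -> AF/VTA.

One unit field solve per montage is reused for every amplitude by
linearity.  The VTA comparison across pulse widths is made at a common
evaluation current: the arithmetic mean of the threshold currents at the
shortest and longest pulse widths of the target nerve.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import af_vta, axon as axon_mod, io as io_mod, protocol, solver
from .config import RunConfig
from .phantom import (
    ElectrodeSpec,
    PhantomConfig,
    build_phantom,
    make_nerve_trajectory,
    place_electrodes,
)

__all__ = [
    "RunReport",
    "run_pipeline",
    "write_outputs",
    "round_half_up",
    "common_evaluation_current",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (so 10.725 -> 10.73, unlike banker's rounding)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def common_evaluation_current(short_mA: float, long_mA: float) -> float:
    """Arithmetic mean of the shortest- and longest-pulse threshold currents."""
    return (short_mA + long_mA) / 2.0


@dataclass
class RunReport:
    config: dict
    config_hash: str
    electrode_current_unit_mA: float
    current_imbalance: float
    sd_tables: dict[str, pd.DataFrame]  # nerve -> (pulse_width_us, threshold_mA)
    sd_fits: dict[str, dict]  # nerve -> {form: {rheobase_mA, chronaxie_us}}
    common_current_mA: float
    vta_table: pd.DataFrame  # target nerve, one row per pulse width
    vta_fit: dict
    timings_s: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def target_nerve(self) -> str:
        return self.meta["target_nerve"]

    @property
    def sd_table(self) -> pd.DataFrame:
        return self.sd_tables[self.target_nerve]


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, keep_fields: bool = False) -> RunReport:
    """Execute all stages in order; deterministic for a fixed config."""
    t_all = time.perf_counter()
    timings: dict[str, float] = {}

    def tick(stage: str, t0: float) -> float:
        timings[stage] = time.perf_counter() - t0
        return time.perf_counter()

    t0 = time.perf_counter()
    ph = config.phantom
    grid = build_phantom(
        PhantomConfig(
            radius=ph.radius, length=ph.length, spacing=ph.spacing, air_margin=ph.air_margin
        )
    )
    el = config.electrodes
    zc = ph.length / 2
    montage = (
        ElectrodeSpec((0.0, ph.radius, zc - el.separation / 2), "anode", el.radius, el.thickness),
        ElectrodeSpec((0.0, ph.radius, zc + el.separation / 2), "cathode", el.radius, el.thickness),
    )
    grid = place_electrodes(grid, montage)
    t0 = tick("phantom", t0)

    pot_unit = solver.solve_potential(grid, tol=config.solver.tol)
    report_unit = solver.electrode_current(pot_unit)
    t0 = tick("solve", t0)

    ax = axon_mod.build_axon(
        diameter=config.axon.diameter,
        n_nodes=config.axon.n_nodes,
        variant=config.axon.variant,
    )
    node_spacing_mm = ax.internode_sep * 1e-3
    baseline = config.titration.baseline_mA
    pot_base, _ = solver.scale_to_current(pot_unit, baseline)

    sd_tables: dict[str, pd.DataFrame] = {}
    sd_fits: dict[str, dict] = {}
    titrations: dict[str, list[protocol.TitrationResult]] = {}
    trajectories = {}
    for nerve in config.nerves:
        traj = make_nerve_trajectory(
            grid, name=nerve.name, depth=nerve.depth, point_spacing=node_spacing_mm
        )
        trajectories[nerve.name] = traj
        drive = axon_mod.sample_extracellular(pot_base, traj, ax)
        curve, results = protocol.sd_curve(
            ax,
            drive,
            config.pulse.widths_us,
            baseline_mA=baseline,
            interphase_ms=config.pulse.interphase_ms,
            polarity=config.pulse.polarity,
            tol=config.titration.tol,
            duration=config.titration.duration_ms,
            dt=config.titration.dt_ms,
        )
        titrations[nerve.name] = results
        sd_tables[nerve.name] = pd.DataFrame(
            {"pulse_width_us": curve.pw_us, "threshold_mA": curve.threshold_mA}
        )
        fits = {}
        for form in ("weiss", "lapicque"):
            f = protocol.fit_sd(curve, form=form)
            fits[form] = {
                "rheobase_mA": f.rheobase_mA,
                "chronaxie_us": f.chronaxie_us,
                "rms_residual_mA": float(np.sqrt(np.mean(f.residuals**2))),
            }
        sd_fits[nerve.name] = fits
    t0 = tick("titration", t0)

    target = config.nerves[0].name
    target_results = titrations[target]
    pw = np.asarray(config.pulse.widths_us, dtype=float)
    i_short = target_results[int(np.argmin(pw))].threshold_mA
    i_long = target_results[int(np.argmax(pw))].threshold_mA
    common_mA = common_evaluation_current(i_short, i_long)

    af_unit = af_vta.hessian_af(pot_unit)
    af_unit.current_mA = report_unit.anode_mA
    traj = trajectories[target]
    vta_rows = []
    vta_results = []
    for res in target_results:
        af_at_thr = af_unit.at_current(res.threshold_mA)
        thr = af_vta.calibrate_af_threshold(af_at_thr, traj, res)
        af_common = af_unit.at_current(common_mA)
        result = af_vta.vta(af_common, thr, grid)
        vta_results.append(result)
        vta_rows.append(
            {
                "pulse_width_us": res.pw_us,
                "threshold_current_mA": res.threshold_mA,
                "af_threshold_V_per_m2": thr.value,
                "vta_mm3": result.volume_mm3,
                "max_depth_mm": result.max_depth_mm,
            }
        )
    vta_table = pd.DataFrame(vta_rows).sort_values("pulse_width_us").reset_index(drop=True)
    ordered = sorted(vta_results, key=lambda r: r.pw_us)
    if len(ordered) >= 3:
        fit = af_vta.vta_vs_pw(ordered)
        vta_fit = {
            "slope_mm3_per_us": fit.slope,
            "intercept_mm3": fit.intercept,
            "r_squared": fit.r_squared,
        }
    else:  # a 2-point line is not a fit worth reporting
        vta_fit = {"slope_mm3_per_us": None, "intercept_mm3": None, "r_squared": None}
    t0 = tick("vta", t0)
    timings["total"] = time.perf_counter() - t_all

    report = RunReport(
        config=config.to_dict(),
        config_hash=_config_hash(config),
        electrode_current_unit_mA=report_unit.anode_mA,
        current_imbalance=report_unit.imbalance,
        sd_tables=sd_tables,
        sd_fits=sd_fits,
        common_current_mA=common_mA,
        vta_table=vta_table,
        vta_fit=vta_fit,
        timings_s=timings,
        meta={
            "target_nerve": target,
            "seed": config.seed,
            "axon_parameters": ax.parameters(),
            "solver_info": pot_unit.info,
        },
    )
    if keep_fields:
        report.meta["_fields"] = {
            "grid": grid,
            "potential_unit": pot_unit,
            "af_unit": af_unit,
            "vta_results": vta_results,
        }
    return report


def write_outputs(report: RunReport, out_dir: str | Path, vtk: bool = False) -> dict:
    """Write sd.csv, vta.csv and report.json (plus VTK fields on request)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    sd = report.sd_table
    paths["sd"] = out / "sd.csv"
    sd.to_csv(paths["sd"], index=False)
    paths["vta"] = out / "vta.csv"
    report.vta_table.to_csv(paths["vta"], index=False)
    payload = {
        "config_hash": report.config_hash,
        "seed": report.meta.get("seed"),
        "config": report.config,
        "electrode_current_unit_mA": report.electrode_current_unit_mA,
        "current_imbalance": report.current_imbalance,
        "sd_tables": {k: v.to_dict(orient="list") for k, v in report.sd_tables.items()},
        "sd_fits": report.sd_fits,
        "common_current_mA": report.common_current_mA,
        "vta_table": report.vta_table.to_dict(orient="list"),
        "vta_fit": report.vta_fit,
        "timings_s": report.timings_s,
        "units": {
            "pulse_width": "us",
            "current": "mA",
            "vta": "mm3",
            "depth": "mm",
            "af_threshold": "V/m2",
        },
    }
    paths["report"] = out / "report.json"
    io_mod.write_json(paths["report"], payload)
    if vtk and "_fields" in report.meta:
        fields = report.meta["_fields"]
        grid = fields["grid"]
        pot = fields["potential_unit"]
        af = fields["af_unit"]
        arrays = {
            "tissue_label": fields["grid"].tissue_label.astype(float),
            "phi_unit_V": pot.phi,
            "af_unit": af.af,
        }
        for r in fields["vta_results"]:
            arrays[f"vta_pw{int(r.pw_us)}us"] = r.mask.astype(float)
        paths["vtk"] = io_mod.write_vtk_structured_points(out / "fields.vtk", grid, arrays)
    return paths
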