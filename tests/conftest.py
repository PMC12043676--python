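import numpy as np
import pytest

from tens_depth.axon import ExtracellularDrive, build_axon
from tens_depth.config import RunConfig, config_from_dict
from tens_depth.phantom import (
    PhantomConfig,
    VoxelGrid,
    build_phantom,
    default_montage,
    place_electrodes,
)
from tens_depth.pipeline import run_pipeline

# reduced layer stack that fits a 25 mm cylinder (for fast solver tests)
SMALL_LAYERS = (
    ("skin", 1.5),
    ("sat", 2.5),
    ("muscle", 8.0),
    ("cortical_bone", 3.0),
    ("cancellous_bone", 3.0),
)


def muscle_box(nx=20, ny=20, nz=21, spacing=1.0) -> VoxelGrid:
    """Homogeneous muscle block filling the whole grid (no air)."""
    cfg = PhantomConfig(
        radius=(nx * spacing) / 2 - spacing,
        length=nz * spacing,
        spacing=spacing,
        layers=(),
        core_tissue="muscle",
        air_margin=spacing,
        shape="box",
    )
    g = build_phantom(cfg)
    assert g.shape[2] == nz
    return g


def face_dirichlet(grid: VoxelGrid, axis: int = 2, v_lo=-0.5, v_hi=0.5) -> dict:
    """Dirichlet node sets on the two opposing faces normal to ``axis``."""
    n = np.arange(np.prod(grid.shape)).reshape(grid.shape)
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = 0
    sl_hi[axis] = grid.shape[axis] - 1
    return {
        "cathode": {"nodes": n[tuple(sl_lo)].ravel(), "value": v_lo},
        "anode": {"nodes": n[tuple(sl_hi)].ravel(), "value": v_hi},
    }


@pytest.fixture(scope="session")
def axon41():
    return build_axon(5.7, 41)


@pytest.fixture(scope="session")
def point_drive(axon41):
    """Point-source-like extracellular profile peaking over the center node."""
    offs = axon41.compartment_offsets()
    center = offs[axon41.node_index[len(axon41.node_index) // 2]]
    r = np.sqrt((offs - center) ** 2 + 4.0)  # source 2 mm above the fiber
    return ExtracellularDrive(phi_mV=100.0 / r, baseline_current_mA=5.0)


@pytest.fixture(scope="session")
def small_phantom_solved():
    """Radius-25 phantom with electrodes and a unit field solve."""
    from tens_depth.solver import electrode_current, solve_potential

    g = build_phantom(PhantomConfig(radius=25.0, length=40.0, layers=SMALL_LAYERS))
    g = place_electrodes(g, default_montage(g))
    pot = solve_potential(g)
    return g, pot, electrode_current(pot)


@pytest.fixture(scope="session")
def mini_config():
    """Fast full-pipeline configuration (two pulse widths, short axon)."""
    return config_from_dict(
        {
            "phantom": {"length": 60.0},
            "pulse": {"widths_us": [30.0, 495.0]},
            "axon": {"n_nodes": 21},
        }
    )


@pytest.fixture(scope="session")
def default_report():
    """The spec-default desk-scale pipeline run (shared across tests)."""
    return run_pipeline(RunConfig(), keep_fields=True)
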