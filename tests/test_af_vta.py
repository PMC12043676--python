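import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tens_depth.af_vta import (
    AFError,
    AFField,
    AFThreshold,
    VTAResult,
    activation_depth,
    calibrate_af_threshold,
    hessian_af,
    sample_af,
    vta,
    vta_vs_pw,
)
from tens_depth.phantom import NerveTrajectory
from tens_depth.protocol import TitrationResult
from tens_depth.solver import PotentialField

from conftest import muscle_box


def field_on_box(phi, grid=None, current=None):
    grid = grid or muscle_box(20, 20, 20)
    info = {} if current is None else {"current_mA": current}
    return grid, PotentialField(grid=grid, phi=phi, dirichlet={}, info=info)


def straight_traj(z0=3.0, z1=17.0, x=0.0, y=0.0, n=29):
    z = np.linspace(z0, z1, n)
    return NerveTrajectory("test", np.column_stack([np.full(n, x), np.full(n, y), z]), 5.0)


class TestHessianAF:
    def test_quadratic_ridge(self):
        # phi = x^2 (x in m) -> Hessian eigenvalues (2, 0, 0), AF = 2
        grid = muscle_box(20, 20, 20)
        X, _, _ = grid.coordinate_grids()
        _, pot = field_on_box((X * 1e-3) ** 2, grid)
        af = hessian_af(pot, keep_eigenvalues=True)
        inner = af.af[2:-2, 2:-2, 2:-2]
        assert np.allclose(inner, 2.0, atol=1e-8)
        eigs = af.eigenvalues[2:-2, 2:-2, 2:-2]
        assert np.allclose(np.sort(eigs, axis=-1), [0.0, 0.0, 2.0], atol=1e-8)

    def test_affine_potential_zero_af(self):
        grid = muscle_box(20, 20, 20)
        X, Y, Z = grid.coordinate_grids()
        _, pot = field_on_box(1e-3 * (3 * X - 2 * Y + 0.5 * Z) + 0.1, grid)
        af = hessian_af(pot)
        assert np.abs(af.af).max() < 1e-10

    def test_point_source_second_radial_derivative(self):
        # oracle: for phi = k/r, the largest |eigenvalue| is 2k/r^3; the
        # central-difference error of that curvature is O((h/r)^2), so the
        # 5% band starts a few voxels out from the source
        grid = muscle_box(40, 40, 40)
        X, Y, Z = grid.coordinate_grids()
        c = np.array([grid.axis_coords(0)[19], grid.axis_coords(1)[19], grid.axis_coords(2)[19]])
        r_mm = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        r_m = np.maximum(r_mm, 0.3) * 1e-3
        k = 1e-4  # V*m
        _, pot = field_on_box(k / r_m, grid)
        af = hessian_af(pot)
        pred = 2 * k / r_m**3
        sel = (r_mm > 9.0) & (r_mm < 15.0)
        rel = np.abs(af.af[sel] - pred[sel]) / pred[sel]
        assert rel.max() < 0.05

    def test_along_z_reduction(self):
        grid = muscle_box(20, 20, 20)
        _, _, Z = grid.coordinate_grids()
        _, pot = field_on_box((Z * 1e-3) ** 2, grid)
        af = hessian_af(pot, reduction="along_z")
        assert np.allclose(af.af[2:-2, 2:-2, 2:-2], 2.0, atol=1e-8)

    def test_thin_grid_rejected(self):
        grid = muscle_box(20, 20, 20)
        import dataclasses

        thin = dataclasses.replace(
            grid,
            shape=(20, 20, 2),
            tissue_label=grid.tissue_label[:, :, :2],
            conductivity=grid.conductivity[:, :, :2],
        )
        _, pot = field_on_box(np.zeros((20, 20, 2)), thin)
        with pytest.raises(AFError, match="3 voxels"):
            hessian_af(pot)

    def test_unknown_reduction_rejected(self):
        _, pot = field_on_box(np.zeros((20, 20, 20)))
        with pytest.raises(AFError):
            hessian_af(pot, reduction="frobenius")

    @given(k=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=20, deadline=None)
    def test_af_linearity_property(self, k):
        grid = muscle_box(12, 12, 12)
        rng = np.random.default_rng(7)
        phi = rng.standard_normal(grid.shape)
        _, pot1 = field_on_box(phi, grid)
        _, potk = field_on_box(k * phi, grid)
        af1 = hessian_af(pot1).af
        afk = hessian_af(potk).af
        assert np.allclose(afk, k * af1, rtol=1e-9, atol=1e-12)

    def test_scaled_matches_recompute(self):
        grid = muscle_box(12, 12, 12)
        phi = np.random.default_rng(3).standard_normal(grid.shape)
        _, pot = field_on_box(phi, grid, current=2.0)
        af = hessian_af(pot)
        doubled = af.scaled(2.0)
        assert np.allclose(doubled.af, 2 * af.af)
        assert doubled.current_mA == 4.0


class TestCalibration:
    def _af(self, current=10.0):
        grid = muscle_box(20, 20, 20)
        X, Y, Z = grid.coordinate_grids()
        bump = np.exp(-(X**2 + Y**2 + (Z - 10) ** 2) / 30.0)
        af = AFField(grid=grid, af=1e5 * bump, reduction="max_abs_eig", current_mA=current)
        return grid, af

    def test_known_maximum_recovered(self):
        grid, af = self._af()
        traj = straight_traj()
        titr = TitrationResult(factor=2.0, baseline_mA=5.0, tol=0.01, pw_us=30.0)
        thr = calibrate_af_threshold(af, traj, titr)
        assert thr.value == pytest.approx(sample_af(af, traj).max())
        assert thr.current_mA == 10.0

    def test_doubling_current_doubles_threshold(self):
        grid, af = self._af(current=10.0)
        traj = straight_traj()
        t1 = TitrationResult(factor=2.0, baseline_mA=5.0, tol=0.01, pw_us=30.0)
        thr1 = calibrate_af_threshold(af, traj, t1)
        t2 = TitrationResult(factor=4.0, baseline_mA=5.0, tol=0.01, pw_us=30.0)
        thr2 = calibrate_af_threshold(af.scaled(2.0), traj, t2)
        assert thr2.value == pytest.approx(2 * thr1.value, rel=1e-12)

    def test_threshold_ratio_equals_current_ratio(self):
        # analogue of the published factor-of-11 AF threshold ratio
        grid, af_unit = self._af(current=1.0)
        traj = straight_traj()
        pairs = {}
        for pw, i_thr in ((30.0, 19.7), (495.0, 1.75)):
            titr = TitrationResult(factor=i_thr / 5.0, baseline_mA=5.0, tol=0.01, pw_us=pw)
            pairs[pw] = calibrate_af_threshold(af_unit.at_current(i_thr), traj, titr)
        ratio = pairs[30.0].value / pairs[495.0].value
        assert ratio == pytest.approx(19.7 / 1.75, rel=1e-12)

    def test_current_mismatch_rejected(self):
        grid, af = self._af(current=10.0)
        traj = straight_traj()
        titr = TitrationResult(factor=1.0, baseline_mA=5.0, tol=0.01, pw_us=30.0)  # 5 mA
        with pytest.raises(AFError, match="current"):
            calibrate_af_threshold(af, traj, titr)

    def test_trajectory_outside_grid_rejected(self):
        grid, af = self._af()
        traj = straight_traj(z0=-10.0, z1=40.0)
        titr = TitrationResult(factor=2.0, baseline_mA=5.0, tol=0.01, pw_us=30.0)
        with pytest.raises(AFError):
            calibrate_af_threshold(af, traj, titr)


class TestVTA:
    def _spherical_af(self, amp=100.0, s2=18.0):
        grid = muscle_box(40, 40, 40)
        X, Y, Z = grid.coordinate_grids()
        r2 = X**2 + Y**2 + (Z - 19.5) ** 2
        af = AFField(
            grid=grid, af=amp * np.exp(-r2 / (2 * s2)), reduction="max_abs_eig", current_mA=1.0
        )
        return grid, af, np.sqrt(r2)

    def test_threshold_above_max_gives_empty(self):
        grid, af, _ = self._spherical_af()
        thr = AFThreshold(value=1e9, pw_us=30.0, nerve="test", current_mA=1.0)
        res = vta(af, thr, grid)
        assert res.empty and res.volume_mm3 == 0.0 and res.max_depth_mm is None

    def test_spherical_volume_matches_analytic(self):
        grid, af, _ = self._spherical_af(amp=100.0, s2=18.0)
        theta = 30.0
        r_star = np.sqrt(2 * 18.0 * np.log(100.0 / theta))
        thr = AFThreshold(value=theta, pw_us=30.0, nerve="test", current_mA=1.0)
        res = vta(af, thr, grid)
        assert res.volume_mm3 == pytest.approx(4 / 3 * np.pi * r_star**3, rel=0.05)

    def test_volume_is_count_times_voxel_volume(self):
        grid, af, _ = self._spherical_af()
        thr = AFThreshold(value=30.0, pw_us=30.0, nerve="test", current_mA=1.0)
        res = vta(af, thr, grid)
        assert res.volume_mm3 == res.mask.sum() * grid.voxel_volume

    def test_lower_threshold_never_shrinks_mask(self):
        grid, af, _ = self._spherical_af()
        masks = []
        for theta in (60.0, 30.0, 10.0):
            thr = AFThreshold(value=theta, pw_us=30.0, nerve="t", current_mA=1.0)
            masks.append(vta(af, thr, grid).mask)
        assert np.all(masks[0] <= masks[1]) and np.all(masks[1] <= masks[2])

    def test_missing_current_context_rejected(self):
        grid, af, _ = self._spherical_af()
        af.current_mA = None
        thr = AFThreshold(value=30.0, pw_us=30.0, nerve="t", current_mA=1.0)
        with pytest.raises(AFError, match="current"):
            vta(af, thr, grid)

    def test_nonbiological_voxels_excluded(self):
        grid, af, _ = self._spherical_af()
        gel = grid.tissues.label("gel")
        grid.tissue_label[18:22, 18:22, 18:22] = gel
        thr = AFThreshold(value=30.0, pw_us=30.0, nerve="t", current_mA=1.0)
        res = vta(af, thr, grid)
        assert not res.mask[19, 19, 19]


class TestActivationDepth:
    def _result(self, mask, grid):
        return VTAResult(
            mask=mask,
            volume_mm3=float(mask.sum()) * grid.voxel_volume,
            max_depth_mm=None,
            pw_us=30.0,
            evaluation_current_mA=1.0,
            af_threshold=1.0,
        )

    def test_single_voxel_depth(self):
        from tens_depth.phantom import build_phantom, PhantomConfig

        grid = build_phantom(PhantomConfig(radius=25.0, length=20.0, layers=()))
        mask = np.zeros(grid.shape, dtype=bool)
        # voxel at x=0.5, y=20.5: r = hypot(0.5, 20.5), depth = 25 - r
        i = np.argmin(np.abs(grid.axis_coords(0) - 0.5))
        j = np.argmin(np.abs(grid.axis_coords(1) - 20.5))
        mask[i, j, 5] = True
        depth = activation_depth(self._result(mask, grid), grid)
        assert depth == pytest.approx(25.0 - np.hypot(0.5, 20.5))

    def test_two_blob_mask_takes_deeper(self):
        from tens_depth.phantom import build_phantom, PhantomConfig

        grid = build_phantom(PhantomConfig(radius=25.0, length=20.0, layers=()))
        X, Y, _ = grid.coordinate_grids()
        r = np.hypot(X, Y)
        shallow = (np.abs(r - 23.0) < 0.5) & (Y > 0)
        deep = (np.abs(r - 10.0) < 0.5) & (Y > 0)
        depth_s = activation_depth(self._result(shallow, grid), grid)
        both = shallow | deep
        depth_b = activation_depth(self._result(both, grid), grid)
        assert depth_b > depth_s
        assert depth_b == pytest.approx(activation_depth(self._result(deep, grid), grid))

    def test_empty_mask_rejected(self):
        grid = muscle_box(10, 10, 10)
        with pytest.raises(AFError, match="empty"):
            activation_depth(self._result(np.zeros(grid.shape, bool), grid), grid)


class TestVTAvsPW:
    def _results(self, pw, vols):
        grid_shape = (4, 4, 4)
        out = []
        for p, v in zip(pw, vols):
            mask = np.zeros(grid_shape, dtype=bool)
            out.append(
                VTAResult(
                    mask=mask,
                    volume_mm3=float(v),
                    max_depth_mm=None,
                    pw_us=float(p),
                    evaluation_current_mA=10.0,
                    af_threshold=1.0,
                )
            )
        return out

    def test_exact_linear_data(self):
        pw = [30, 88, 146, 262, 495, 600]
        vols = [10 + 3 * p for p in pw]
        fit = vta_vs_pw(self._results(pw, vols))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(10.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(AFError):
            vta_vs_pw(self._results([30, 495], [1, 2]))

    def test_noisy_slope_within_ci(self):
        rng = np.random.default_rng(42)
        pw = np.array([30.0, 88, 146, 262, 495] * 4)
        vols = (100 + 5.0 * pw) * (1 + 0.05 * rng.standard_normal(len(pw)))
        fit = vta_vs_pw(self._results(pw, vols))
        from scipy.stats import linregress

        se = linregress(pw, vols).stderr
        assert abs(fit.slope - 5.0) <= 1.96 * se + 1e-9
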