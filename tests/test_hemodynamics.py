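import numpy as np
import pytest

from flow4d.errors import UndefinedMetricError
from flow4d.geometry import make_idealized_geometry, voxelize
from flow4d.hemodynamics import (PlaneProbe, agreement_summary, compute_report,
                                 eddy_current_correct, kinetic_energy, pcmra,
                                 plane_stats, quadratic_basis, rmse, vorticity,
                                 wall_shear_stress)


def poiseuille_tube(spacing, diameter=4.0, length=20.0, v0=50.0):
    """Analytic parabolic profile sampled on a voxelized tube along x."""
    g = make_idealized_geometry("straight", diameter=diameter, length=length)
    mask = voxelize(g, spacing)
    R = diameter / 2.0
    zc = (np.arange(mask.shape[0]) + 0.5) * spacing + mask.origin[2]
    yc = (np.arange(mask.shape[1]) + 0.5) * spacing + mask.origin[1]
    Z, Y = np.meshgrid(zc, yc, indexing="ij")
    prof = v0 * np.maximum(1 - (Z ** 2 + Y ** 2) / R ** 2, 0.0)
    frame = np.zeros((3,) + mask.shape)
    frame[0] = prof[:, :, None] * mask.binary
    return frame, mask


class TestRmse:
    def test_identical_is_zero(self):
        a = np.random.default_rng(0).normal(size=(3, 6, 6, 6))
        assert rmse(a, a) == 0.0

    def test_hand_example(self):
        assert rmse(np.array([3.0, 4.0]), np.zeros(2)) == pytest.approx(
            np.sqrt(25 / 2))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(3, 5, 5, 5))
        b = rng.normal(size=(3, 5, 5, 5))
        mask = rng.random((5, 5, 5)) > 0.4
        total, n = 0.0, 0
        for c in range(3):
            for z in range(5):
                for y in range(5):
                    for x in range(5):
                        if mask[z, y, x]:
                            total += (a[c, z, y, x] - b[c, z, y, x]) ** 2
                            n += 1
        assert rmse(a, b, mask) == pytest.approx(np.sqrt(total / n), rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(UndefinedMetricError):
            rmse(np.zeros((3, 4, 4, 4)), np.zeros((3, 4, 4, 4)),
                 np.zeros((4, 4, 4), bool))


class TestPcmra:
    def test_zero_velocity(self):
        v = np.zeros((4, 3, 6, 6, 6))
        m = np.ones((4, 6, 6, 6))
        assert np.all(pcmra(v, m) == 0.0)

    def test_single_frame_value(self):
        v = np.zeros((1, 3, 4, 4, 4))
        v[0, 0] = 50.0
        assert pcmra(v, np.ones((1, 4, 4, 4)))[0, 0, 0] == pytest.approx(50.0)

    def test_linearity_in_magnitude(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(3, 3, 5, 5, 5))
        m = rng.random((3, 5, 5, 5))
        assert np.allclose(pcmra(v, 2 * m), 2 * pcmra(v, m))


class TestWss:
    def test_poiseuille_within_ten_percent(self):
        # tau = 2 mu V0 / R = 2 * 0.004 * 0.5 / 0.002 = 2 Pa, spacing = R/10
        frame, mask = poiseuille_tube(0.2)
        _, wss_mean = wall_shear_stress(frame, mask.fraction, 0.004, 0.2)
        assert wss_mean == pytest.approx(2.0, rel=0.10)

    def test_grid_convergence_monotone(self):
        errs = []
        for sp in (0.8, 0.4, 0.2):
            frame, mask = poiseuille_tube(sp)
            _, wss_mean = wall_shear_stress(frame, mask.fraction, 0.004, sp)
            errs.append(abs(wss_mean - 2.0))
        assert errs[0] > errs[1] > errs[2]

    def test_zero_flow_zero_stress(self):
        _, mask = poiseuille_tube(0.4)
        wss_map, wss_mean = wall_shear_stress(np.zeros((3,) + mask.shape),
                                              mask.fraction, 0.004, 0.4)
        assert wss_mean == 0.0 and np.all(wss_map == 0.0)

    def test_linear_in_viscosity(self):
        frame, mask = poiseuille_tube(0.4)
        _, a = wall_shear_stress(frame, mask.fraction, 0.004, 0.4)
        _, b = wall_shear_stress(frame, mask.fraction, 0.008, 0.4)
        assert b == pytest.approx(2 * a, rel=1e-9)

    def test_all_interior_mask_rejected(self):
        with pytest.raises(UndefinedMetricError):
            wall_shear_stress(np.zeros((3, 6, 6, 6)), np.ones((6, 6, 6), bool),
                              0.004, 0.5)


class TestVorticity:
    def _coords(self, n=16, spacing=1.0):
        c = (np.arange(n) + 0.5) * spacing
        return np.meshgrid(c, c, c, indexing="ij")

    def test_rigid_rotation(self):
        # Omega = (0,0,1) rad/s -> curl = (0,0,2), exact on interior
        Z, Y, X = self._coords()
        cc = Z.mean()
        frame = np.zeros((3, 16, 16, 16))
        frame[0] = -(Y - cc) * 1e-3 / 0.01   # mm -> m -> cm/s
        frame[1] = (X - cc) * 1e-3 / 0.01
        curl = vorticity(frame, 1.0)
        interior = (slice(1, -1),) * 3
        assert np.allclose(curl[2][interior], 2.0, atol=1e-12)
        assert np.allclose(curl[0][interior], 0.0, atol=1e-12)

    def test_uniform_translation_zero(self):
        frame = np.ones((3, 10, 10, 10)) * 7.0
        assert np.allclose(vorticity(frame, 1.0), 0.0)

    def test_shear(self):
        Z, Y, X = self._coords()
        frame = np.zeros((3, 16, 16, 16))
        frame[0] = Y * 1e-3 / 0.01  # u = (y*s, 0, 0), s = 1/s
        curl = vorticity(frame, 1.0)
        assert np.allclose(curl[2][1:-1, 1:-1, 1:-1], -1.0, atol=1e-12)


class TestKineticEnergy:
    def test_formula(self):
        # 1 m/s over 1 cm^3 at rho = 1060 -> 0.53 mJ
        frame = np.zeros((3, 10, 10, 10))
        frame[0] = 100.0
        mask = np.ones((10, 10, 10), bool)
        assert kinetic_energy(frame, mask, 1060.0, 1.0) == pytest.approx(0.53)

    def test_quadratic_in_speed(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(size=(3, 8, 8, 8))
        mask = rng.random((8, 8, 8)) > 0.5
        a = kinetic_energy(frame, mask, 1060.0, 0.5)
        b = kinetic_energy(2 * frame, mask, 1060.0, 0.5)
        assert b == pytest.approx(4 * a, rel=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        frame = rng.normal(size=(3, 4, 4, 4)) * 10
        mask = rng.random((4, 4, 4)) > 0.3
        total = 0.0
        for z in range(4):
            for y in range(4):
                for x in range(4):
                    if mask[z, y, x]:
                        v2 = sum((frame[c, z, y, x] * 0.01) ** 2 for c in range(3))
                        total += 0.5 * 1060.0 * v2 * (0.5e-3) ** 3
        assert kinetic_energy(frame, mask, 1060.0, 0.5) == pytest.approx(
            total * 1e3, rel=1e-12)


class TestPlaneStats:
    def test_flux_matches_inlet(self, steady_tube_field):
        fld = steady_tube_field
        probe = PlaneProbe(point=[10.0, 0.0, 0.0], normal=[1, 0, 0], extent=4.0,
                           label="mid")
        st = plane_stats(fld.velocity[0].astype(float), probe,
                         fld.mask.fraction, fld.spacing, origin=fld.mask.origin)
        assert st["flow"] == pytest.approx(3.0, rel=0.02)

    def test_reversed_normal_negates_flow(self, steady_tube_field):
        fld = steady_tube_field
        a = plane_stats(fld.velocity[0].astype(float),
                        PlaneProbe(point=[10.0, 0, 0], normal=[1, 0, 0], extent=4.0),
                        fld.mask.fraction, fld.spacing, origin=fld.mask.origin)
        b = plane_stats(fld.velocity[0].astype(float),
                        PlaneProbe(point=[10.0, 0, 0], normal=[-1, 0, 0], extent=4.0),
                        fld.mask.fraction, fld.spacing, origin=fld.mask.origin)
        assert b["flow"] == pytest.approx(-a["flow"], rel=1e-9)

    def test_max_velocity_is_peak(self, steady_tube_field):
        fld = steady_tube_field
        st = plane_stats(fld.velocity[0].astype(float),
                         PlaneProbe(point=[10.0, 0, 0], normal=[1, 0, 0], extent=4.0),
                         fld.mask.fraction, fld.spacing, origin=fld.mask.origin)
        assert st["max_velocity"] == pytest.approx(fld.velocity[0].max(), rel=0.05)

    def test_missing_intersection_rejected(self, steady_tube_field):
        fld = steady_tube_field
        probe = PlaneProbe(point=[10.0, 30.0, 30.0], normal=[1, 0, 0], extent=2.0)
        with pytest.raises(UndefinedMetricError):
            plane_stats(fld.velocity[0].astype(float), probe, fld.mask.fraction,
                        fld.spacing, origin=fld.mask.origin)


class TestEddyCurrent:
    def test_recovers_injected_quadratic(self):
        shape = (24, 24, 24)
        basis = quadratic_basis(shape)
        true_c = np.array([0.5, 0.3, -0.2, 0.1, 0.05, -0.08, 0.02, 0.3, -0.1, 0.15])
        vessel = np.zeros(shape, bool)
        vessel[10:14, 10:14, :] = True
        frame = np.zeros((3,) + shape)
        frame[0] = np.tensordot(true_c, basis, axes=1)
        corrected, coeffs = eddy_current_correct(frame, np.ones(shape),
                                                 vessel_mask=vessel)
        assert np.abs(coeffs[0] - true_c).max() < 0.01 * np.abs(true_c).max()
        amplitude = np.abs(frame[0]).max()
        assert np.sqrt((corrected[0][~vessel] ** 2).mean()) < 0.01 * amplitude

    def test_zero_offset_is_noop(self):
        shape = (16, 16, 16)
        rng = np.random.default_rng(0)
        frame = np.zeros((3,) + shape)
        vessel = np.zeros(shape, bool)
        vessel[6:10, 6:10, 6:10] = True
        frame[:, vessel] = rng.normal(size=(3, int(vessel.sum()))) * 20
        corrected, coeffs = eddy_current_correct(frame, np.ones(shape),
                                                 vessel_mask=vessel)
        assert np.abs(corrected - frame).max() < 1e-10

    def test_insufficient_background_warns(self):
        shape = (6, 6, 6)
        frame = np.zeros((3,) + shape)
        with pytest.warns(UserWarning):
            corrected, coeffs = eddy_current_correct(frame, np.ones(shape),
                                                     vessel_mask=np.ones(shape, bool))
        assert coeffs is None
        assert np.array_equal(corrected, frame)


class TestAgreement:
    def test_identical_series(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        s = agreement_summary(a, a)
        assert s["pearson_r"] == pytest.approx(1.0)
        assert s["bias"] == 0.0
        assert s["loa_lower"] == 0.0 and s["loa_upper"] == 0.0

    def test_constant_shift(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        s = agreement_summary(a, a + 1)
        assert s["bias"] == pytest.approx(-1.0)
        assert s["loa_lower"] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        a = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        b = np.array([2.0, 2.5, 3.0, 6.0, 7.0])
        d = a - b
        s = agreement_summary(a, b)
        assert s["bias"] == pytest.approx(d.mean())
        assert s["loa_upper"] == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert s["pearson_r"] == pytest.approx(np.corrcoef(a, b)[0, 1])

    def test_short_series_rejected(self):
        with pytest.raises(UndefinedMetricError):
            agreement_summary([1.0, 2.0], [1.0, 2.0])


def test_compute_report_schema(steady_tube_field):
    fld = steady_tube_field
    probe = PlaneProbe(point=[10.0, 0, 0], normal=[1, 0, 0], extent=4.0,
                       label="mid")
    rep = compute_report(fld.velocity.astype(float),
                         np.repeat(fld.mask.fraction[None], 1, 0),
                         fld.mask.binary, fld.spacing, fld.fluid,
                         probes=[probe], origin=fld.mask.origin)
    d = rep.to_dict()
    assert d["wss_mean"] > 0
    assert d["kinetic_energy"] > 0
    assert "mid" in d["planes"]
    assert rep.pcmra.shape == fld.shape
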