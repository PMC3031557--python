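"""Analytic optic-flow machinery: spherical closed forms against the 3-D
cross-product oracle, orthogonality of the six basis flow fields, cosine
tuning, restricted-domain sensors, and quadrature convergence."""
import numpy as np
import pytest

from lpnet import flow
from lpnet.flow import MotionAxis, SphericalDomain


def tangent_basis(az_deg, el_deg):
    ph, th = np.radians(az_deg), np.radians(el_deg)
    e_phi = np.stack([-np.sin(ph), np.cos(ph), np.zeros_like(ph)], axis=-1)
    e_theta = np.stack([-np.sin(th) * np.cos(ph), -np.sin(th) * np.sin(ph),
                        np.cos(th)], axis=-1)
    return e_phi, e_theta


class TestFlowFields:
    @pytest.mark.parametrize("kind", ["rotation", "translation"])
    def test_spherical_form_equals_vector_construction(self, kind):
        """The closed-form tangent components agree with the direct 3-D
        construction (cross product / tangential projection) at 1000
        random points and axes."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            d = rng.normal(size=3)
            axis = MotionAxis(kind, tuple(d / np.linalg.norm(d)),
                              magnitude=rng.uniform(0.5, 2.0))
            fld = (flow.rotational_flow(axis) if kind == "rotation"
                   else flow.translational_flow(axis, mu=1.7))
            az = rng.uniform(-180, 180, size=100)
            el = rng.uniform(-90, 90, size=100)
            f_ph, f_th = fld.components(az, el)
            vec = fld.vectors3d(az, el)
            e_phi, e_theta = tangent_basis(az, el)
            np.testing.assert_allclose(f_ph, np.sum(vec * e_phi, axis=-1),
                                       atol=1e-12)
            np.testing.assert_allclose(f_th, np.sum(vec * e_theta, axis=-1),
                                       atol=1e-12)

    def test_rotation_poles_are_still(self):
        yaw = flow.rotational_flow(MotionAxis("rotation", (0, 0, 1)))
        for el in (90.0, -90.0):
            f_ph, f_th = yaw.components(0.0, el)
            assert abs(f_ph) < 1e-12 and abs(f_th) < 1e-12

    def test_yaw_equator_flow_is_horizontal(self):
        yaw = flow.rotational_flow(MotionAxis("rotation", (0, 0, 1)))
        f_ph, f_th = yaw.components(0.0, 0.0)
        assert f_ph == pytest.approx(1.0)
        assert f_th == pytest.approx(0.0, abs=1e-12)

    def test_translation_focus_of_expansion_is_still(self):
        thrust = flow.translational_flow(MotionAxis("translation", (1, 0, 0)))
        f_ph, f_th = thrust.components(0.0, 0.0)
        assert abs(f_ph) < 1e-12 and abs(f_th) < 1e-12

    def test_translation_max_speed_on_orthogonal_circle(self):
        mu, v = 2.0, 1.5
        fld = flow.translational_flow(
            MotionAxis("translation", (1, 0, 0), magnitude=v), mu=mu)
        f_ph, f_th = fld.components(90.0, 0.0)
        assert np.hypot(f_ph, f_th) == pytest.approx(mu * v)

    def test_nearness_scales_translational_flow_only(self):
        t_axis = MotionAxis("translation", (0, 0, 1))
        f1 = flow.translational_flow(t_axis, mu=1.0)
        f2 = flow.translational_flow(t_axis, mu=2.0)
        az, el = np.array([30.0]), np.array([10.0])
        np.testing.assert_allclose(
            np.array(f2.components(az, el)),
            2.0 * np.array(f1.components(az, el)))


class TestInnerProduct:
    ROT = [MotionAxis("rotation", a) for a in ((1, 0, 0), (0, 1, 0), (0, 0, 1))]
    TRA = [MotionAxis("translation", a) for a in ((1, 0, 0), (0, 1, 0), (0, 0, 1))]

    def test_rotation_translation_orthogonality(self):
        """Any rotational flow is orthogonal to any translational flow."""
        for r in self.ROT:
            for t in self.TRA:
                ip = flow.inner_product(flow.rotational_flow(r),
                                        flow.translational_flow(t),
                                        spacing_deg=1.0)
                assert abs(ip) < 1e-6

    def test_six_dimensional_gram_matrix(self):
        """The three rotational and three translational basis flow fields
        have a diagonal Gram matrix with positive diagonal."""
        fields = ([flow.rotational_flow(r) for r in self.ROT]
                  + [flow.translational_flow(t) for t in self.TRA])
        gram = np.array([[flow.inner_product(f, g, spacing_deg=2.0)
                          for g in fields] for f in fields])
        off = gram - np.diag(np.diag(gram))
        assert np.all(np.abs(off) < 1e-6)
        np.testing.assert_allclose(np.diag(gram), 8.0 * np.pi / 3.0, rtol=1e-4)

    @pytest.mark.parametrize("gamma", [0, 30, 60, 90, 120, 180])
    def test_rotation_pair_follows_cosine_of_axis_angle(self, gamma):
        u = flow.rotational_flow(MotionAxis("rotation", (1, 0, 0)))
        w = flow.rotational_flow(
            MotionAxis.from_angles("rotation", gamma, 0.0))
        ip = flow.inner_product(u, w, spacing_deg=1.0)
        expected = 8.0 * np.pi / 3.0 * np.cos(np.radians(gamma))
        assert ip == pytest.approx(expected, abs=2e-4)

    def test_degenerate_domain_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SphericalDomain(eps_phi=np.pi)


class TestIdealSensors:
    def test_rotation_sensor_blind_to_all_translations(self):
        """The matched rotation filter's translational action field is zero
        for every translation axis, at any receptive-field size."""
        roll = MotionAxis("rotation", (1, 0, 0))
        for dom in (flow.FULL_SPHERE,
                    SphericalDomain(np.pi / 4, np.pi / 4),
                    SphericalDomain(0.3, 1.0)):
            peak = flow.sensor_norm_squared("rotation", dom)
            for az, el in ((0, 0), (90, 0), (0, 90), (45, -30)):
                probe = MotionAxis.from_angles("translation", az, el)
                q = flow.ideal_sensor_action_field(
                    "rotation", roll, probe, dom, method="quadrature",
                    spacing_deg=1.0)
                assert abs(q) <= 1e-6 * peak
                assert flow.ideal_sensor_action_field(
                    "rotation", roll, probe, dom) == 0.0

    def test_translation_sensor_blind_to_all_rotations(self):
        thrust = MotionAxis("translation", (1, 0, 0))
        dom = SphericalDomain(np.pi / 6, np.pi / 5)
        peak = flow.sensor_norm_squared("translation", dom)
        for az, el in ((0, 0), (90, 0), (0, 90), (-120, 40)):
            probe = MotionAxis.from_angles("rotation", az, el)
            q = flow.ideal_sensor_action_field(
                "translation", thrust, probe, dom, method="quadrature",
                spacing_deg=1.0)
            assert abs(q) <= 1e-6 * peak

    def test_full_sphere_cosine_tuning(self):
        """Normalized same-kind action field deviates from cos(gamma) by
        less than 1e-3 at 1-deg quadrature."""
        roll = MotionAxis("rotation", (1, 0, 0))
        norm2 = flow.sensor_norm_squared("rotation")
        for gamma in range(0, 181, 15):
            probe = MotionAxis.from_angles("rotation", gamma, 0.0)
            q = flow.ideal_sensor_action_field(
                "rotation", roll, probe, method="quadrature", spacing_deg=1.0)
            assert abs(q / norm2 - np.cos(np.radians(gamma))) < 1e-3

    @pytest.mark.parametrize("sensor_kind", ["rotation", "translation"])
    def test_restricted_domain_matches_closed_form(self, sensor_kind):
        """Windowing the receptive field to the quarter-sphere cap keeps the
        exact cosine law with the norm given by the closed form."""
        dom = SphericalDomain(np.pi / 4, np.pi / 4)
        sensor = MotionAxis(sensor_kind, (1, 0, 0))
        for gamma in (0.0, 40.0, 140.0):
            probe = MotionAxis.from_angles(sensor_kind, gamma, 0.0)
            cf = flow.ideal_sensor_action_field(sensor_kind, sensor, probe, dom)
            q = flow.ideal_sensor_action_field(
                sensor_kind, sensor, probe, dom, method="quadrature",
                spacing_deg=0.25)
            assert q == pytest.approx(cf, rel=1e-6)

    def test_quadrature_second_order_convergence(self):
        """Halving the quadrature spacing shrinks the error against the
        closed form by about 4x."""
        dom = SphericalDomain(np.pi / 4, np.pi / 4)
        sensor = MotionAxis("rotation", (1, 0, 0))
        probe = MotionAxis.from_angles("rotation", 40.0, 0.0)
        cf = flow.ideal_sensor_action_field("rotation", sensor, probe, dom)
        errs = [abs(flow.ideal_sensor_action_field(
            "rotation", sensor, probe, dom, method="quadrature",
            spacing_deg=sp) - cf) for sp in (4.0, 2.0, 1.0)]
        assert errs[0] / errs[1] > 3.5
        assert errs[1] / errs[2] > 3.5


class TestNumericActionField:
    def _grid(self, step=2.0):
        az = np.arange(-180.0, 180.0, step)
        el = np.arange(-88.0, 88.1, step)
        return az, el

    def test_sampled_roll_field_is_rotation_selective(self):
        """A receptive field equal to the sampled roll flow responds with
        cosine tuning to rotations and negligibly to any translation."""
        az, el = self._grid()
        mesh = np.meshgrid(az, el)
        roll = flow.rotational_flow(MotionAxis("rotation", (1, 0, 0)))
        h, v = roll.components(*mesh)
        peak = flow.numeric_action_field_of_field(
            h, v, az, el, MotionAxis("rotation", (1, 0, 0)))
        assert peak > 0
        for az_p, el_p in ((0, 0), (90, 0), (0, 90), (-45, 45)):
            probe = MotionAxis.from_angles("translation", az_p, el_p)
            val = flow.numeric_action_field_of_field(h, v, az, el, probe)
            assert abs(val) < 1e-3 * peak
        probe60 = MotionAxis.from_angles("rotation", 60.0, 0.0)
        val60 = flow.numeric_action_field_of_field(h, v, az, el, probe60)
        assert val60 / peak == pytest.approx(0.5, abs=1e-3)

    def test_sampled_thrust_field_is_translation_selective(self):
        az, el = self._grid()
        mesh = np.meshgrid(az, el)
        thrust = flow.translational_flow(MotionAxis("translation", (1, 0, 0)))
        h, v = thrust.components(*mesh)
        peak = flow.numeric_action_field_of_field(
            h, v, az, el, MotionAxis("translation", (1, 0, 0)))
        for az_p, el_p in ((0, 0), (90, 0), (0, 90)):
            probe = MotionAxis.from_angles("rotation", az_p, el_p)
            val = flow.numeric_action_field_of_field(h, v, az, el, probe)
            assert abs(val) < 1e-3 * peak

    def test_zero_field_gives_zero_everywhere(self):
        az, el = self._grid(10.0)
        z = np.zeros((len(el), len(az)))
        for kind in ("rotation", "translation"):
            probe = MotionAxis.from_angles(kind, 30.0, -20.0)
            assert flow.numeric_action_field_of_field(z, z, az, el, probe) == 0.0

    def test_grid_mismatch_rejected(self):
        az, el = self._grid(10.0)
        z = np.zeros((3, 3))
        with pytest.raises(ValueError, match="match"):
            flow.numeric_action_field_of_field(
                z, z, az, el, MotionAxis("rotation", (1, 0, 0)))
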