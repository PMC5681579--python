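import numpy as np
import pytest

from olfactomap import (
    CurrentSourceDensity,
    EAGRecording,
    FuniculusGeometry,
    compartmentize,
    csd_barycenter,
    csd_response_area,
    forward_matrix,
    forward_potentials,
    invert_csd,
    response_amplitude,
    spatial_spread,
    temporal_kernel,
)
from olfactomap.csd import _rect_integral

from .conftest import oracle_forward_matrix, random_geometry, riemann_rect_integral


class TestRectIntegral:
    def test_unit_square_centered_singularity(self):
        # closed form: 4·ln(1+√2) for the unit square with the singularity
        # at its center
        val = _rect_integral(np.array([-0.5]), np.array([0.5]), -0.5, 0.5)
        assert val[0] == pytest.approx(4 * np.log(1 + np.sqrt(2)), rel=1e-12)

    def test_far_field_point_source_limit(self):
        # a rectangle of area A at distance d >> diameter acts as A/d
        a = 0.05
        d = 20 * a * np.sqrt(2)
        val = _rect_integral(np.array([d - a / 2]), np.array([d + a / 2]), -a / 2, a / 2)
        assert val[0] == pytest.approx(a * a / d, rel=0.01)

    def test_singularity_on_edge_is_finite(self):
        val = _rect_integral(np.array([0.0]), np.array([1.0]), -0.5, 0.5)
        assert np.isfinite(val[0]) and val[0] > 0


class TestForwardMatrix:
    def test_entries_positive_and_diagonal_dominant(self, geom, fitted):
        m = fitted.forward_.matrix
        assert np.all(m > 0)
        # the compartment containing each electrode dominates its potential
        assert list(m.argmax(axis=1)) == list(range(geom.n_positions))

    def test_sigma_scaling(self, geom):
        comps = compartmentize(geom)
        m1 = forward_matrix(comps, geom.positions_mm, sigma=10.0).matrix
        m2 = forward_matrix(comps, geom.positions_mm, sigma=20.0).matrix
        np.testing.assert_allclose(m2, m1 / 2, rtol=1e-12)

    def test_mirror_symmetry(self, fitted):
        m = fitted.forward_.matrix
        np.testing.assert_allclose(m, m[::-1, ::-1], rtol=1e-6)

    def test_electrode_outside_funiculus_rejected(self, geom):
        comps = compartmentize(geom)
        with pytest.raises(ValueError):
            forward_matrix(comps, np.array([-0.1, 0.2, 0.4, 0.6]))

    def test_condition_number_moderate(self, fitted):
        assert fitted.condition_number_ < 1e8

    def test_matches_riemann_oracle(self):
        # every entry agrees with the independent quadrature oracle
        rng = np.random.default_rng(5)
        for _ in range(3):
            geom = random_geometry(rng)
            m = CurrentSourceDensity(geom).fit().forward_.matrix
            oracle = oracle_forward_matrix(geom)
            np.testing.assert_allclose(m, oracle, rtol=1e-3)

    def test_oracle_self_consistency(self):
        # the polar corner integration agrees with the Riemann sum on a
        # nonsingular rectangle evaluated both ways near the boundary
        near = riemann_rect_integral(0.1, 0.6, 0.3, 0.05, n=800)
        nearer = riemann_rect_integral(0.1, 0.6, 0.3, 0.05, n=1600)
        assert near == pytest.approx(nearer, rel=1e-4)


class TestInversion:
    def test_round_trip_random_sources(self, fitted):
        rng = np.random.default_rng(0)
        c = rng.uniform(-1, 1, size=(1000, 4))
        phi = forward_potentials(fitted.forward_, c)
        rec = invert_csd(fitted.forward_, phi)
        assert np.abs(rec - c).max() < 1e-9

    def test_zero_maps_to_zero(self, fitted):
        np.testing.assert_allclose(invert_csd(fitted.forward_, np.zeros(4)), 0.0)

    def test_linearity(self, fitted):
        rng = np.random.default_rng(1)
        c1, c2 = rng.normal(size=4), rng.normal(size=4)
        p = forward_potentials(fitted.forward_, 2.0 * c1 - 3.0 * c2)
        expected = 2.0 * forward_potentials(fitted.forward_, c1) - 3.0 * forward_potentials(
            fitted.forward_, c2
        )
        np.testing.assert_allclose(p, expected, rtol=1e-12)

    def test_dimension_mismatch(self, fitted):
        with pytest.raises(ValueError):
            forward_potentials(fitted.forward_, np.zeros(5))
        with pytest.raises(ValueError):
            invert_csd(fitted.forward_, np.zeros(3))


class TestResponseArea:
    def test_plateau_area(self):
        t = np.arange(1500) / 500.0
        src = np.where((t >= 1.0) & (t <= 2.5), -1.0, 0.0)[:, None]
        area = csd_response_area(src, t, 1.0)
        assert area[0] == pytest.approx(1.5, abs=2 / 500)

    def test_zero_timecourse(self):
        t = np.arange(1500) / 500.0
        np.testing.assert_allclose(csd_response_area(np.zeros((1500, 4)), t, 1.0), 0.0)

    def test_rectangle_height_times_duration(self):
        t = np.arange(1500) / 500.0
        h, d = 0.7, 0.8
        src = np.where((t >= 1.1) & (t < 1.1 + d), -h, 0.0)[:, None]
        area = csd_response_area(src, t, 1.0)
        assert area[0] == pytest.approx(h * d, abs=2 * h / 500)

    def test_requires_full_window(self):
        t = np.arange(600) / 500.0
        with pytest.raises(ValueError):
            csd_response_area(np.zeros((600, 4)), t, 0.5)


class TestBarycenter:
    positions = np.array([0.0, 1 / 3, 2 / 3, 1.0])

    @pytest.mark.parametrize(
        "areas, expected",
        [
            ([0, 0, 1, 0], 2 / 3),
            ([1, 1, 1, 1], 0.5),
            ([1, 0, 0, 1], 0.5),
        ],
    )
    def test_examples(self, areas, expected):
        assert csd_barycenter(np.array(areas), self.positions) == pytest.approx(expected)

    def test_negative_areas_do_not_pull(self):
        b = csd_barycenter(np.array([-5.0, 0.0, 1.0, 0.0]), self.positions)
        assert b == pytest.approx(2 / 3)

    def test_no_activation(self):
        with pytest.raises(ValueError):
            csd_barycenter(np.array([-1.0, 0.0, -0.2, 0.0]), self.positions)


class TestLocalizationAndSharpness:
    def _single_compartment_recording(self, fitted, k):
        c = np.zeros(4)
        c[k] = -1.0
        t = np.arange(1500) / 500.0
        kern = temporal_kernel(t, 1.0, 0.05, 0.4)
        phi = np.outer(kern, fitted.inverse_transform(c))
        return EAGRecording(traces=phi, stimulus_onset_s=1.0)

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_noiseless_source_recovered_without_leakage(self, geom, fitted, k):
        rec = self._single_compartment_recording(fitted, k)
        res = fitted.analyze(rec)
        leak = np.abs(np.delete(res.response_areas, k)).max() / abs(res.response_areas[k])
        assert leak < 1e-8
        assert res.barycenter_norm == pytest.approx(geom.positions_norm[k], abs=1e-12)

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_csd_more_spatially_restricted_than_eag(self, fitted, k):
        # activity confined to one compartment: the CSD spread collapses to
        # ~1 while raw EAG amplitudes bleed across electrode positions
        rec = self._single_compartment_recording(fitted, k)
        res = fitted.analyze(rec)
        amps = [
            response_amplitude(rec.traces[:, j], 1.0, 500.0)
            for j in range(rec.n_positions)
        ]
        assert spatial_spread(np.clip(res.response_areas, 0, None)) <= spatial_spread(amps)

    def test_sigma_invariance_of_barycenter_and_ratios(self):
        rng = np.random.default_rng(3)
        t = np.arange(1500) / 500.0
        kern = temporal_kernel(t, 1.0, 0.05, 0.4)
        barys, area_ratios = [], []
        for sigma in (0.1, 10.0, 1000.0):
            geom = FuniculusGeometry(0.6, 0.3, 0.25, sigma=sigma)
            est = CurrentSourceDensity(geom).fit()
            c = np.array([-0.1, -0.7, -0.2, -0.05])
            phi = np.outer(kern, est.inverse_transform(c))
            res = est.analyze(EAGRecording(traces=phi, stimulus_onset_s=1.0))
            barys.append(res.barycenter_norm)
            area_ratios.append(res.response_areas[1] / res.response_areas[2])
        np.testing.assert_allclose(barys, barys[0], rtol=1e-9)
        np.testing.assert_allclose(area_ratios, area_ratios[0], rtol=1e-9)


class TestEstimatorContract:
    def test_requires_fit_before_transform(self, geom):
        est = CurrentSourceDensity(geom)
        with pytest.raises(AttributeError):
            est.transform(np.zeros(4))

    def test_get_set_params_roundtrip(self, geom):
        est = CurrentSourceDensity(geom)
        params = est.get_params()
        est2 = CurrentSourceDensity(**params).fit()
        assert est2.forward_.matrix.shape == (4, 4)
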