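"""Inverse problem: component decomposition, weights, classification."""

import numpy as np
import pytest

from contourdyn.contour import GPRConfig, circle_samples, fit_contour
from contourdyn.fixtures import ellipse_points, make_fixture
from contourdyn.flows import aaf_speed, evolve_pure_flow
from contourdyn.inference import (
    ContourDynamicsModel,
    classify,
    correlate,
    goodness_of_fit,
    membrane_intensity,
    reference_area,
)
from contourdyn.simulate import ModelWeights

TWO_PI = 2.0 * np.pi


class TestReferenceArea:
    def test_constant_series(self):
        assert reference_area(np.full(20, 7.3)) == pytest.approx(7.3)

    def test_linear_interpolation_convention(self):
        assert reference_area(np.arange(1.0, 101.0)) == pytest.approx(1.99)

    def test_robust_to_single_low_outlier(self):
        series = np.concatenate([np.full(199, 100.0), [1.0]])
        assert reference_area(series) > 90.0

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            reference_area(np.array([1.0]))


class TestGoodnessAndClassification:
    def test_goodness_limits(self):
        assert goodness_of_fit(np.ones((4, 4))) == 1.0
        assert goodness_of_fit(-np.ones((4, 4))) == 0.0
        half = np.concatenate([np.ones(50), -np.ones(50)])
        assert goodness_of_fit(half) == pytest.approx(0.5)

    def test_classification_threshold_and_tie_rule(self):
        def w(apcsf):
            return ModelWeights(w_prot=4.0, w_apcsf=apcsf, w_aaf=1.0, a_ref=80.0)

        assert classify(w(0.0)) == "fan-shaped"
        assert classify(w(0.048)) == "amoeboid"
        assert classify(w(0.005)) == "amoeboid"  # tie goes to amoeboid


class TestDeterministicComponents:
    def test_circle_stack_at_reference_has_zero_components(self, circle80):
        model = ContourDynamicsModel([circle80] * 5, dt=1.0)
        chi = np.tile(circle80.theta, (5, 1))
        phi_c, phi_a = model._deterministic_shapes(chi, circle80.area)
        assert np.max(np.abs(phi_c)) < 2e-3
        assert np.max(np.abs(phi_a)) < 1e-9

    def test_ellipse_apcsf_sign_pattern(self, ellipse21):
        model = ContourDynamicsModel([ellipse21] * 2, dt=1.0)
        chi = np.tile(ellipse21.theta, (2, 1))
        phi_c, _ = model._deterministic_shapes(chi, ellipse21.area)
        kappa = ellipse21.curvature(ellipse21.theta)
        # retraction (negative) at the high-curvature vertices, expansion at
        # the flat sides
        assert phi_c[0][np.argmax(kappa)] < 0
        assert phi_c[0][np.argmin(kappa)] > 0

    def test_pure_aaf_stack_reproduces_generating_speed(self):
        ell = fit_contour(ellipse_points(6, 3), n_markers=64, n_dense=384)
        w_aaf, a_ref = 0.8, ell.area / 2
        seq = evolve_pure_flow(ell, "aaf", 6, 0.5, weight=w_aaf, a_ref=a_ref)
        model = ContourDynamicsModel(seq, dt=0.5)
        chi = np.tile(seq[0].theta, (len(seq), 1))
        _, phi_a = model._deterministic_shapes(chi, a_ref)
        truth = w_aaf * aaf_speed(seq[0].geometry(), seq[0].positions, a_ref)
        assert np.allclose(w_aaf * phi_a[0], truth, atol=1e-9)


@pytest.fixture(scope="module")
def fitted(short_track):
    model = ContourDynamicsModel.from_track(short_track)
    return model, model.fit(weights=short_track.weights)


class TestRoundTrip:

    def test_decomposition_identity_after_refinement(self, fitted):
        _, res = fitted
        k = res.kymographs
        assert np.array_equal(
            k["f"].values,
            k["f_prot"].values + k["f_apcsf"].values + k["f_aaf"].values,
        )

    def test_known_weights_recover_protrusion_component(self, fitted, short_track):
        _, res = fitted
        rho = np.corrcoef(res.f_prot.ravel(), short_track.f_prot.ravel())[0, 1]
        assert rho > 0.9

    def test_retraction_only_stack_yields_negligible_protrusion(self):
        init = ellipse_points(7.0, 4.0, 100)
        from contourdyn.simulate import SimulationConfig, simulate

        w = ModelWeights(w_prot=0.0, w_apcsf=0.1, w_aaf=1.0, a_ref=80.0)
        cfg = SimulationConfig(T=20.0, dt=0.5, n_markers=100, seed=1,
                               n_dense=384, initial_points=init)
        track = simulate(cfg, w)
        res = ContourDynamicsModel.from_track(track).fit(weights=w)
        assert np.sqrt(np.mean(res.f_prot**2)) < 0.05

    def test_misspecified_aaf_weight_creates_negative_bands(self, short_track):
        # halving w_AAF leaves retractions uncaptured, pushing f_prot negative
        true_w = short_track.weights
        res_good = ContourDynamicsModel.from_track(short_track).fit(weights=true_w)
        halved = ModelWeights(w_prot=true_w.w_prot, w_apcsf=true_w.w_apcsf,
                              w_aaf=0.5 * true_w.w_aaf, a_ref=true_w.a_ref)
        res_bad = ContourDynamicsModel.from_track(short_track).fit(weights=halved)
        assert res_bad.goodness < res_good.goodness - 0.02

    def test_estimated_x_prot_is_standardized(self, short_track):
        res = ContourDynamicsModel.from_track(short_track).fit()
        x = res.kymographs["x_prot"].values
        assert np.std(x, ddof=1) == pytest.approx(1.0, abs=1e-6)

    def test_static_stack_rejected(self, circle80):
        with pytest.raises(ValueError, match="static|degenerate"):
            ContourDynamicsModel([circle80] * 12, dt=1.0).fit()

    def test_summary_reports_key_quantities(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "A_ref" in text and "w_APCSF" in text and "goodness" in text


class TestFanShaped:
    def test_fan_fixture_has_persistent_concavity_and_zero_apcsf_weight(self):
        arch = make_fixture("fan_shaped", seed=7)
        model = ContourDynamicsModel(arch.contours, dt=4.0, n_markers=100)
        for c in model.contours:
            assert c.curvature(c.theta).min() < 0.0
        res = model.fit()
        assert res.weights.w_apcsf == 0.0
        assert res.label == "fan-shaped"


@pytest.fixture(scope="module")
def circle_stack():
    arch = make_fixture("circle", seed=0, n_frames=3, area=80.0)
    contours = [fit_contour(p, GPRConfig(0.6, 0.05), n_markers=80,
                            n_dense=384) for p in arch.contours]
    return arch, contours


class TestMembraneIntensity:

    def test_uniform_image_gives_constant_kymograph(self, circle_stack):
        _, contours = circle_stack
        shift = np.abs(np.vstack([c.positions for c in contours])).max() + 3
        shifted = [fit_contour(c.positions + shift, n_markers=64, n_dense=256)
                   for c in contours]
        images = np.ones((3, 120, 120))
        chi = np.tile(shifted[0].theta, (3, 1))
        kymo = membrane_intensity(images, shifted, chi, pixel_size=0.5)
        vals = kymo.values[np.isfinite(kymo.values)]
        assert vals.size > 0
        assert np.allclose(vals, vals[0])

    def test_gaussian_ridge_recovers_generating_field(self, circle_stack):
        arch, _ = circle_stack
        n_pts = arch.contours[0].shape[0]
        amp = 1.0 + 0.8 * np.cos(3 * TWO_PI * np.arange(n_pts) / n_pts)
        shifted, images, px = make_fixture(
            "fluorescence_band", seed=0, archive=arch, amplitude=amp
        )
        model = ContourDynamicsModel(shifted.contours, dt=1.0, n_markers=100)
        chi = np.tile(model.contours[0].theta, (3, 1))
        kymo = membrane_intensity(images, model.contours, chi, px)
        gen = np.tile(1.0 + 0.8 * np.cos(3 * model.contours[0].theta), (3, 1))
        assert correlate(gen, kymo) > 0.95

    def test_ellipse_outside_image_flagged_missing(self, circle_stack):
        _, contours = circle_stack
        images = np.ones((3, 5, 5))  # far smaller than the contour extent
        chi = np.tile(contours[0].theta, (3, 1))
        kymo = membrane_intensity(images, contours, chi, pixel_size=0.1)
        assert np.isnan(kymo.values).any()

    def test_zero_semi_axes_degrade_to_nearest_pixel(self, circle_stack):
        _, contours = circle_stack
        shift = np.abs(contours[0].positions).max() + 2
        shifted = [fit_contour(c.positions + shift, n_markers=32, n_dense=256)
                   for c in contours[:1]]
        rng = np.random.default_rng(3)
        images = rng.uniform(0.1, 1.0, (1, 200, 200))
        chi = np.tile(shifted[0].theta, (1, 1))
        kymo = membrane_intensity(images, shifted, chi, pixel_size=0.1,
                                  semi_axes=(0.0, 0.0))
        pos = shifted[0].position(chi[0])
        scale = np.percentile(images[0], 99.0)
        cols = (pos[:, 0] / 0.1 - 0.5).round().astype(int)
        rows = (pos[:, 1] / 0.1 - 0.5).round().astype(int)
        expect = np.minimum(images[0][rows, cols] / scale, 1.0)
        assert np.allclose(kymo.values[0], expect)


class TestCorrelate:
    def test_identical_and_negated(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 30))
        assert correlate(a, a) == pytest.approx(1.0)
        assert correlate(a, -a) == pytest.approx(-1.0)

    def test_independent_noise_is_uncorrelated(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(100, 100))
        b = rng.normal(size=(100, 100))
        assert abs(correlate(a, b)) < 0.05

    def test_missing_nodes_are_excluded(self):
        a = np.array([[1.0, 2.0, np.nan], [3.0, 4.0, 5.0]])
        b = 2 * a
        assert correlate(a, b) == pytest.approx(1.0)
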