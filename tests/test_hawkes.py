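"""Self-exciting protrusion process on the circle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import i0
from scipy.stats import kstest

from contourdyn.hawkes import (
    EventList,
    HawkesParams,
    background_intensity,
    intensity,
    normalized_poisson_kernel,
    protrusion_field,
    protrusion_row,
    sample_hawkes,
    sample_poisson,
    spatial_kernel,
    temporal_kernel,
    triggering_kernel,
)

TWO_PI = 2.0 * np.pi


class TestKernels:
    def test_normalized_poisson_kernel_values(self):
        assert normalized_poisson_kernel(1.3, 1.3, 0.7) == pytest.approx(1.0)
        assert normalized_poisson_kernel(np.pi, 0.0, 0.5) == pytest.approx(1.0 / 9.0)
        assert normalized_poisson_kernel(2.0, 0.5, 0.0) == pytest.approx(1.0)

    @given(st.floats(0, TWO_PI), st.floats(0, TWO_PI), st.floats(0, 0.95))
    def test_normalized_kernel_bounds(self, a, b, r):
        v = normalized_poisson_kernel(a, b, r)
        lo = ((1 - r) / (1 + r)) ** 2
        assert lo - 1e-12 <= v <= 1.0 + 1e-12

    def test_background_uniform_without_polarization(self):
        th = np.linspace(0, TWO_PI, 11)
        assert np.allclose(background_intensity(th, 2.0, 0.0), 2.0 / TWO_PI)

    @pytest.mark.parametrize("r_pol", [0.2, 0.5, 0.9])
    def test_background_normalizes_to_lambda0(self, r_pol):
        total, _ = quad(lambda t: background_intensity(t, 1.7, r_pol), 0, TWO_PI,
                        limit=200)
        assert abs(total - 1.7) < 1e-6

    def test_background_peaks_at_pi(self):
        th = np.linspace(0, TWO_PI, 10001)
        mu = background_intensity(th, 1.0, 0.5)
        assert abs(th[np.argmax(mu)] - np.pi) < 1e-3

    def test_temporal_kernel_integrates_to_branching_ratio(self):
        assert temporal_kernel(0.0, 0.4, 0.5) == 0.0
        total, _ = quad(lambda t: temporal_kernel(t, 0.4, 0.5), 0, 200)
        assert abs(total - 0.8) < 1e-8

    def test_spatial_kernel_is_von_mises(self):
        # g2(0) = e / (2*pi*I0(1)) for kappa = 1
        assert spatial_kernel(0.0, 1.0) == pytest.approx(np.e / (TWO_PI * i0(1.0)))
        total, _ = quad(lambda t: spatial_kernel(t, 100.0), -np.pi, np.pi)
        assert abs(total - 1.0) < 1e-6

    def test_triggering_kernel_is_separable_product(self):
        p = HawkesParams()
        v = triggering_kernel(3.0, 0.2, p)
        assert v == pytest.approx(
            temporal_kernel(3.0, p.alpha, p.beta) * spatial_kernel(0.2, p.kappa_m)
        )


class TestSampling:
    def test_supercritical_rejected_before_sampling(self):
        with pytest.raises(ValueError, match="supercritical"):
            sample_hawkes(HawkesParams(alpha=0.6, beta=0.5), 10.0, 0)

    def test_reproducible_and_sorted(self):
        p = HawkesParams()
        a = sample_hawkes(p, 50.0, 123)
        b = sample_hawkes(p, 50.0, 123)
        assert np.array_equal(a.t, b.t) and np.array_equal(a.theta, b.theta)
        assert np.all(np.diff(a.t) >= 0)
        assert np.all((a.theta >= 0) & (a.theta < TWO_PI))
        assert np.all(a.parent < np.arange(len(a)))  # parents precede children

    def test_alpha_zero_reduces_to_poisson_background(self):
        counts = [
            len(sample_hawkes(HawkesParams(alpha=0.0, lambda0=5.0), 20.0, s))
            for s in range(500)
        ]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 100.0) < 3 * se + 1e-9

    def test_poisson_variant_interevent_times_exponential(self):
        ev = sample_poisson(5.0, 0.0, 400.0, 7)
        gaps = np.diff(ev.t)
        assert kstest(gaps, "expon", args=(0, 1 / 5.0)).pvalue > 0.01

    def test_poisson_counts_uncorrelated_across_windows(self):
        ev = sample_poisson(5.0, 0.0, 500.0, 11)
        counts, _ = np.histogram(ev.t, bins=np.arange(0, 501, 5))
        c = counts - counts.mean()
        rho = (c[:-1] * c[1:]).mean() / c.var()
        assert abs(rho) < 3.0 / np.sqrt(len(counts))

    def test_polarized_events_cluster_around_pi(self):
        ev = sample_hawkes(HawkesParams(r_pol=0.5), 300.0, 3)
        hist, edges = np.histogram(ev.theta, bins=16, range=(0, TWO_PI))
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert np.pi / 2 < mode < 3 * np.pi / 2
        # unimodal up to counting noise: front half holds most events
        front = ((ev.theta > np.pi / 2) & (ev.theta < 3 * np.pi / 2)).mean()
        assert front > 0.5


class TestIntensityAndField:
    def test_intensity_without_events_is_background(self):
        p = HawkesParams(r_pol=0.3)
        ev = EventList(np.empty(0), np.empty(0), np.empty(0, int), np.empty(0, int))
        th = np.linspace(0, TWO_PI, 9)
        assert np.allclose(intensity(ev, 5.0, th, p),
                           background_intensity(th, p.lambda0, p.r_pol))

    def test_single_event_adds_one_kernel_term(self):
        p = HawkesParams()
        ev = EventList(np.array([2.0]), np.array([1.0]), np.zeros(1, int),
                       -np.ones(1, int))
        th = np.array([1.4])
        expected = background_intensity(th, p.lambda0, p.r_pol) + triggering_kernel(
            3.0, 0.4, p
        )
        assert np.allclose(intensity(ev, 5.0, th, p), expected)

    def test_intensity_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        p = HawkesParams(r_pol=0.4)
        n = 50
        t = np.sort(rng.uniform(0, 30, n))
        th = rng.uniform(0, TWO_PI, n)
        ev = EventList(t, th, np.zeros(n, int), -np.ones(n, int))
        grid = rng.uniform(0, TWO_PI, 7)
        lam = intensity(ev, 25.0, grid, p)
        brute = []
        for g in grid:
            s = float(background_intensity(g, p.lambda0, p.r_pol))
            for i in range(n):
                if t[i] < 25.0:
                    s += float(triggering_kernel(25.0 - t[i], g - th[i], p))
            brute.append(s)
        assert np.allclose(lam, brute, atol=1e-12)

    def test_protrusion_field_identities(self):
        p = HawkesParams()
        ev = sample_hawkes(p, 40.0, 5)
        grid = TWO_PI * np.arange(32) / 32
        ones = np.ones(32)
        row = protrusion_row(ev, 35.0, grid, ones, p)
        # with unit VMDR the field equals c_s * (lambda - mu)
        lam = intensity(ev, 35.0, grid, p)
        mu = background_intensity(grid, p.lambda0, p.r_pol)
        assert np.allclose(row, p.c_s * (lam - mu), atol=1e-10)
        assert np.all(row >= 0)
        # halving the VMDR doubles the field
        row2 = protrusion_row(ev, 35.0, grid, 0.5 * ones, p)
        assert np.allclose(row2, 2 * row)
        # no events in the past -> zero field
        assert np.allclose(protrusion_row(ev, 0.0, grid, ones, p), 0.0)

    def test_protrusion_field_grid_shape_and_vmdr_validation(self):
        p = HawkesParams()
        ev = sample_hawkes(p, 10.0, 1)
        times = np.array([2.0, 5.0, 9.0])
        grid = TWO_PI * np.arange(16) / 16
        field = protrusion_field(ev, times, grid, np.ones((3, 16)), p)
        assert field.shape == (3, 16)
        with pytest.raises(ValueError, match="positive"):
            protrusion_row(ev, 5.0, grid, np.zeros(16), p)

    def test_rotation_equivariance(self):
        p = HawkesParams()  # non-polarized background is rotation invariant
        ev = sample_hawkes(p, 30.0, 9)
        shift = 1.234
        ev_rot = EventList(ev.t, np.mod(ev.theta + shift, TWO_PI),
                           ev.generation, ev.parent)
        grid = TWO_PI * np.arange(24) / 24
        a = intensity(ev, 25.0, grid, p)
        b = intensity(ev_rot, 25.0, grid + shift, p)
        assert np.allclose(a, b, atol=1e-10)


class TestOUVariant:
    def test_ou_field_is_nonnegative_reproducible_and_mean_reverting(self):
        from contourdyn.hawkes import ou_protrusion_field

        times = 0.5 * np.arange(400)
        grid = TWO_PI * np.arange(32) / 32
        a = ou_protrusion_field(times, grid, seed=5)
        b = ou_protrusion_field(times, grid, seed=5)
        assert np.array_equal(a, b)
        assert np.all(a >= 0.0)
        assert a.shape == (400, 32)
        # mean reversion: long-run average near the configured mean
        assert abs(a.mean() - 0.64) < 0.15
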