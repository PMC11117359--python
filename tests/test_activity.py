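"""Circular KDE, Δ overlap coefficients, smoothed bootstrap."""

import math

import numpy as np
import pytest
from scipy.stats import vonmises

from camtrapniche.activity import (
    bootstrap_ci,
    classify_overlap,
    fit_circular_kde,
    overlap_delta,
    select_estimator,
    trigmoment_kappa,
    true_overlap,
)
from camtrapniche.simulate import GAZELLE_DIEL, ORYX_DIEL, VonMisesMixture, _hour

TWO_PI = 2 * math.pi


class TestCircularKde:
    def test_density_integrates_to_one(self, rng):
        dens = fit_circular_kde(rng.vonmises(1.0, 3.0, 120) % TWO_PI)
        assert dens.integral() == pytest.approx(1.0, abs=1e-3)

    def test_uniform_sample_near_flat(self, rng):
        dens = fit_circular_kde(rng.uniform(0, TWO_PI, 5000))
        flat = 1 / TWO_PI
        assert np.max(np.abs(dens.values - flat)) < 0.3 * flat

    def test_unimodal_mode_location(self, rng):
        dens = fit_circular_kde(rng.vonmises(math.pi, 8.0, 400) % TWO_PI)
        mode = dens.grid[np.argmax(dens.values)]
        step = dens.grid[1] - dens.grid[0]
        assert abs(mode - math.pi) <= step + 0.05

    def test_density_positive_at_data(self, rng):
        t = rng.vonmises(0.5, 5.0, 50) % TWO_PI
        dens = fit_circular_kde(t)
        assert (dens(t) > 0).all()

    def test_concentration_recovered_for_von_mises(self, rng):
        t = rng.vonmises(2.0, 4.0, 2000) % TWO_PI
        assert trigmoment_kappa(t) == pytest.approx(4.0, rel=0.15)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            fit_circular_kde(np.array([1.0]))

    def test_degenerate_sample_error(self):
        with pytest.raises(ValueError, match="jitter"):
            fit_circular_kde(np.full(10, 1.5))


class TestTrueOverlap:
    def test_identical_densities(self):
        f = lambda t: vonmises.pdf(t, 4, loc=1.0)
        assert true_overlap(f, f) == pytest.approx(1.0, abs=1e-6)

    def test_refinement_stable(self):
        f = lambda t: vonmises.pdf(t, 8, loc=0.0)
        g = lambda t: vonmises.pdf(t, 8, loc=2.0)
        coarse = true_overlap(f, g, n_points=2**12)
        fine = true_overlap(f, g, n_points=2**16)
        assert coarse == pytest.approx(fine, abs=1e-6)

    def test_disjoint_supports_zero(self):
        f = lambda t: np.where((t > 0) & (t < 1), 1.0, 0.0)
        g = lambda t: np.where((t > 2) & (t < 3), 1.0, 0.0)
        assert true_overlap(f, g) == pytest.approx(0.0, abs=1e-9)


class TestOverlapDelta:
    def test_estimator_selection_rule(self):
        assert select_estimator(50, 200) == "Dhat1"
        assert select_estimator(75, 75) == "Dhat4"
        assert select_estimator(200, 74) == "Dhat1"

    def test_self_overlap_is_one(self, rng):
        t = rng.vonmises(1.0, 4.0, 200) % TWO_PI
        assert overlap_delta(t, t).delta == pytest.approx(1.0, abs=1e-6)

    def test_antipodal_von_mises_near_truth(self, rng):
        a = rng.vonmises(0.0, 8.0, 1000) % TWO_PI
        b = rng.vonmises(math.pi, 8.0, 1000) % TWO_PI
        f = lambda t: vonmises.pdf(t, 8, loc=0.0)
        g = lambda t: vonmises.pdf(t, 8, loc=math.pi)
        truth = true_overlap(f, g)
        assert abs(overlap_delta(a, b).delta - truth) < 0.05

    def test_delta1_symmetric(self, rng):
        a = rng.vonmises(1.0, 3.0, 60) % TWO_PI
        b = rng.vonmises(2.5, 5.0, 40) % TWO_PI
        d_ab = overlap_delta(a, b, estimator="Dhat1").delta
        d_ba = overlap_delta(b, a, estimator="Dhat1").delta
        assert d_ab == pytest.approx(d_ba, abs=1e-10)

    def test_bounds_on_random_pairs(self, rng):
        """Δ ∈ [0,1] over a thousand random sample pairs of varied shape."""
        for _ in range(1000):
            n1, n2 = rng.integers(5, 60, size=2)
            a = rng.vonmises(rng.uniform(0, TWO_PI), rng.uniform(0.2, 10), n1) % TWO_PI
            b = rng.vonmises(rng.uniform(0, TWO_PI), rng.uniform(0.2, 10), n2) % TWO_PI
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            d = overlap_delta(a, b).delta
            assert 0.0 <= d <= 1.0

    def test_delta1_consistency_with_sample_size(self, rng):
        f = lambda t: vonmises.pdf(t, 6, loc=1.0)
        g = lambda t: vonmises.pdf(t, 6, loc=2.2)
        truth = true_overlap(f, g)
        errs = {}
        for n in (100, 1000):
            runs = [
                abs(
                    overlap_delta(
                        rng.vonmises(1.0, 6.0, n) % TWO_PI,
                        rng.vonmises(2.2, 6.0, n) % TWO_PI,
                        estimator="Dhat1",
                    ).delta
                    - truth
                )
                for _ in range(10)
            ]
            errs[n] = np.mean(runs)
        assert errs[1000] < errs[100]

    def test_bimodal_crepuscular_recovery(self, rng):
        """Dawn/dusk mixtures: mean |Δ̂4 − Δtrue| ≤ 0.06 at n=200 per species."""
        truth = true_overlap(ORYX_DIEL.pdf, GAZELLE_DIEL.pdf)
        errors = [
            abs(
                overlap_delta(
                    ORYX_DIEL.sample(200, rng), GAZELLE_DIEL.sample(200, rng)
                ).delta
                - truth
            )
            for _ in range(50)
        ]
        assert np.mean(errors) <= 0.06


class TestBootstrapCi:
    def test_deterministic_under_seed(self, rng):
        a = ORYX_DIEL.sample(80, rng)
        b = GAZELLE_DIEL.sample(80, rng)
        r1 = bootstrap_ci(a, b, resamples=200, seed=42)
        r2 = bootstrap_ci(a, b, resamples=200, seed=42)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_interval_brackets_estimate(self, rng):
        a = ORYX_DIEL.sample(100, rng)
        b = GAZELLE_DIEL.sample(100, rng)
        r = bootstrap_ci(a, b, resamples=200, seed=1)
        assert r.ci_low <= r.delta <= r.ci_high

    def test_identical_generators_high_upper_bound(self, rng):
        a = ORYX_DIEL.sample(200, rng)
        b = ORYX_DIEL.sample(200, rng)
        r = bootstrap_ci(a, b, resamples=300, seed=3)
        assert r.ci_high >= 0.9

    def test_too_few_resamples_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_ci(np.ones(5), np.ones(5), resamples=10)


class TestClassifyOverlap:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (0.83, "strong"),
            (0.76, "strong"),
            (0.75, "moderate"),
            (0.5, "moderate"),
            (0.49, "low"),
            (0.2, "low"),
            (0.0, "low"),
            (1.0, "strong"),
        ],
    )
    def test_thresholds(self, delta, expected):
        assert classify_overlap(delta) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_overlap(1.2)
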