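"""Emergence indices: moments, curvature functionals, bootstrap intervals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from groupedkde import GroupedSample
from groupedkde.density import density_estimate
from groupedkde.indices import (
    density_indices,
    fit_normal_mixture,
    indices_confidence_intervals,
    integrated_squared_derivative,
    moment_indices,
    rank_depths,
)
from groupedkde.kernels import gaussian_selfconv_derivative
from groupedkde.simulate import TruthSpec, simulate_grouped

SQRT_PI = math.sqrt(math.pi)


class TestMomentIndices:
    def test_two_point_mass(self):
        i1, i2 = moment_indices(GroupedSample(edges=[0, 2, 4], counts=[5, 5]))
        assert i1 == pytest.approx(0.5)
        assert i2 == pytest.approx(1.0)  # the kurtosis lower bound is attained

    def test_fine_binned_normal(self, fine_normal_sample):
        i1, i2 = moment_indices(fine_normal_sample)
        assert i1 == pytest.approx(0.1, rel=0.02)
        assert i2 == pytest.approx(3.0, rel=0.03)

    def test_edge_scaling_invariance(self, pooled_10mm):
        scaled = GroupedSample(edges=pooled_10mm.edges * 3.7, counts=pooled_10mm.counts)
        assert moment_indices(scaled) == pytest.approx(moment_indices(pooled_10mm))

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            moment_indices(GroupedSample(edges=[0, 1], counts=[9]))  # zero variance
        with pytest.raises(ValueError):
            moment_indices(GroupedSample(edges=[-2, 0, 2], counts=[5, 5]))  # zero mean

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(counts=st.lists(st.integers(0, 40), min_size=2, max_size=8))
    def test_kurtosis_lower_bound(self, counts):
        if sum(1 for c in counts if c > 0) < 2:
            return
        gs = GroupedSample(edges=np.arange(len(counts) + 1) + 1.0, counts=counts)
        _, i2 = moment_indices(gs)
        assert i2 >= 1.0 - 1e-12


class TestIntegratedSquaredDerivative:
    def test_single_bin_gaussian_roughness(self):
        gs = GroupedSample(edges=[-1, 1], counts=[10])
        assert integrated_squared_derivative(gs, 1, 1.0) == pytest.approx(1 / (4 * SQRT_PI))
        assert integrated_squared_derivative(gs, 2, 1.0) == pytest.approx(3 / (8 * SQRT_PI))

    @pytest.mark.parametrize("r", [1, 2])
    def test_matches_numerical_quadrature(self, pooled_10mm, r):
        h = 20.0
        x = np.linspace(-200, 900, 60_001)
        f = density_estimate(pooled_10mm, h, x)
        deriv = f
        for _ in range(r):
            deriv = np.gradient(deriv, x)
        numeric = np.trapezoid(deriv**2, x)
        assert integrated_squared_derivative(pooled_10mm, r, h) == pytest.approx(
            numeric, abs=1e-6
        )

    def test_matches_brute_force_double_sum(self, pooled_10mm):
        h = 17.0
        t, p = pooled_10mm.midpoints, pooled_10mm.probs
        brute = sum(
            p[i] * p[j] * gaussian_selfconv_derivative(t[i] - t[j], h, 4)
            for i in range(len(t))
            for j in range(len(t))
        )
        assert integrated_squared_derivative(pooled_10mm, 2, h) == pytest.approx(
            brute, abs=1e-12
        )

    def test_decreases_with_smoothing(self, pooled_10mm):
        vals = [
            integrated_squared_derivative(pooled_10mm, 1, h)
            for h in np.geomspace(3, 100, 10)
        ]
        assert np.all(np.diff(vals) < 0)

    def test_validation(self, pooled_10mm):
        with pytest.raises(ValueError):
            integrated_squared_derivative(pooled_10mm, 3, 1.0)
        with pytest.raises(ValueError):
            integrated_squared_derivative(pooled_10mm, 1, 0.0)


class TestDensityIndices:
    def test_normal_truth_recovered_by_plugin(self):
        gs, _ = simulate_grouped(
            TruthSpec("normal", {"mean": 100.0, "sd": 10.0}, 100_000, (60, (50, 150)), seed=4)
        )
        rep = density_indices(gs, method="plugin")
        assert rep.J1 == pytest.approx(1 / (4 * SQRT_PI), rel=0.15)
        assert rep.J2 == pytest.approx(3 / (8 * SQRT_PI), rel=0.15)

    def test_scale_equivariance(self, pooled_10mm):
        rep = density_indices(pooled_10mm, method="plugin")
        scaled = GroupedSample(edges=pooled_10mm.edges * 7.0, counts=pooled_10mm.counts)
        rep7 = density_indices(scaled, method="plugin")
        assert rep7.J1 == pytest.approx(rep.J1, rel=0.02)
        assert rep7.J2 == pytest.approx(rep.J2, rel=0.02)

    def test_np_and_mix_methods_run_seeded(self, pooled_10mm):
        r1 = density_indices(pooled_10mm, method="np", B=100, seed=8)
        r2 = density_indices(pooled_10mm, method="np", B=100, seed=8)
        assert (r1.J1, r1.J2) == (r2.J1, r2.J2)
        rm = density_indices(pooled_10mm, method="mix", nmix=2, B=50, seed=8)
        assert rm.J1 > 0 and rm.J2 > 0

    def test_mixture_em_increases_loglik(self, pooled_10mm):
        _, _, _, ll2 = fit_normal_mixture(pooled_10mm, ncomp=2)
        _, _, _, ll1 = fit_normal_mixture(pooled_10mm, ncomp=1)
        assert ll2 >= ll1 - 1e-6


class TestConfidenceIntervals:
    def test_intervals_contain_estimates_and_shrink(self):
        reps = {}
        for n, seed in ((400, 21), (4000, 22)):
            gs, _ = simulate_grouped(
                TruthSpec("normal", {"mean": 100.0, "sd": 10.0}, n, (25, (55, 145)), seed=seed)
            )
            reps[n] = indices_confidence_intervals(
                gs, method="plugin", B_conf=400, seed=seed
            )
        for rep in reps.values():
            for key in ("I1", "I2", "J1", "J2"):
                lo, hi = rep.ci[key]
                assert lo <= getattr(rep, key) <= hi
        for key in ("I1", "I2"):
            w_small = reps[400].ci[key][1] - reps[400].ci[key][0]
            w_big = reps[4000].ci[key][1] - reps[4000].ci[key][0]
            assert w_big < w_small

    def test_seed_determinism(self, pooled_10mm):
        a = indices_confidence_intervals(pooled_10mm, method="plugin", B_conf=150, seed=3)
        b = indices_confidence_intervals(pooled_10mm, method="plugin", B_conf=150, seed=3)
        assert a.ci == b.ci


def test_rank_depths_reports_winner(pooled_10mm):
    other = GroupedSample(edges=pooled_10mm.edges, counts=pooled_10mm.counts[::-1])
    ranked = rank_depths({"a": pooled_10mm, "b": other})
    assert set(ranked["favours"]) == {"I1", "I2", "J1", "J2"}
    assert ranked["winner"] in {"a", "b"}
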