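import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cytocline as cc
from cytocline.cline import (
    NoConvergentModelError,
    all_variants,
    DEFAULT_BOUNDS,
)
from conftest import simulate_bernoulli


def spec_strategy():
    """Random valid cline specs across all scaling/tail variants."""
    return st.builds(
        cc.ClineModelSpec,
        scaling=st.sampled_from(["none", "free"]),
        tails=st.sampled_from(["none", "left", "right", "mirror", "both"]),
        center=st.floats(0.05, 0.95),
        width=st.floats(0.01, 1.0),
        pmin=st.just(0.0),
        pmax=st.just(1.0),
        delta_l=st.floats(0.0, 0.5),
        delta_r=st.floats(0.0, 0.5),
        tau_l=st.floats(0.05, 1.0),
        tau_r=st.floats(0.05, 1.0),
    )


class TestClineProbability:
    def test_midpoint_is_half(self):
        spec = cc.ClineModelSpec(center=0.37, width=0.2)
        assert cc.cline_probability(0.37, spec) == pytest.approx(0.5)

    def test_closed_form_tanh_value(self):
        # x - c = width: p = (1 + tanh(2))/2
        spec = cc.ClineModelSpec(center=0.43, width=0.05)
        assert cc.cline_probability(0.48, spec) == pytest.approx(0.982014, abs=1e-6)

    def test_width_is_inverse_max_slope(self):
        # numerical max slope over a fine grid equals 1/w for the plain sigmoid
        for w in (0.05, 0.1, 0.5):
            spec = cc.ClineModelSpec(center=0.5, width=w)
            x = np.linspace(0, 1, 20001)
            slope = np.max(np.gradient(np.asarray(cc.cline_probability(x, spec)), x))
            assert slope == pytest.approx(1.0 / w, rel=1e-3)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(spec=spec_strategy())
    def test_monotone_and_bounded(self, spec):
        x = np.linspace(0, 1, 501)
        p = np.asarray(cc.cline_probability(x, spec))
        assert np.all(np.diff(p) >= -1e-12)
        assert p.min() >= spec.pmin - 1e-12 and p.max() <= spec.pmax + 1e-12

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(spec=spec_strategy())
    def test_continuity_at_tail_junctions(self, spec):
        eps = 1e-9
        for junction in (spec.center - spec.delta_l, spec.center + spec.delta_r):
            if 0 < junction < 1:
                lo = cc.cline_probability(junction - eps, spec)
                hi = cc.cline_probability(junction + eps, spec)
                assert abs(hi - lo) < 1e-6  # continuous through the junction


class TestLoglik:
    def test_single_bernoulli_at_center(self):
        d = cc.ClineData(np.array([0.5]), np.array([1.0]), "bernoulli")
        assert cc.loglik(d, cc.ClineModelSpec(center=0.5, width=0.1)) == pytest.approx(
            np.log(0.5)
        )

    def test_binomial2_heterozygote_at_center(self):
        # k=1 at p=0.5: ln 2 + 2 ln 0.5 = -ln 2
        d = cc.ClineData(np.array([0.5]), np.array([1.0]), "binomial2")
        assert cc.loglik(d, cc.ClineModelSpec(center=0.5, width=0.1)) == pytest.approx(
            -np.log(2.0)
        )

    def test_clamping_keeps_loglik_finite_at_boundary(self):
        d = cc.ClineData(np.zeros(10), np.zeros(10), "bernoulli")
        spec = cc.ClineModelSpec(center=0.99, width=0.001)
        ll = cc.loglik(d, spec)
        assert np.isfinite(ll) and ll <= 0.0

    def test_empty_data_rejected(self):
        d = cc.ClineData(np.array([]), np.array([]), "bernoulli")
        with pytest.raises(ValueError):
            cc.loglik(d, cc.ClineModelSpec())

    def test_gaussian_profile_matches_direct_formula(self, rng):
        x = rng.uniform(0, 1, 50)
        y = rng.uniform(0, 1, 50)
        d = cc.ClineData(x, y, "gaussian")
        spec = cc.ClineModelSpec(center=0.5, width=0.3)
        resid = y - np.asarray(cc.cline_probability(x, spec))
        s2 = np.mean(resid**2)
        expected = -0.5 * len(x) * (np.log(2 * np.pi * s2) + 1.0)
        assert cc.loglik(d, spec) == pytest.approx(expected)


class TestFitCline:
    def test_recovers_center_of_steep_cline(self, steep_cline_spec):
        d = simulate_bernoulli(steep_cline_spec, 300, seed=42)
        f = cc.fit_cline(d, seed=1)
        assert f.converged
        assert abs(f.spec.center - 0.43) < 0.05

    def test_same_seed_is_bit_identical(self, steep_cline_spec):
        d = simulate_bernoulli(steep_cline_spec, 120, seed=5)
        f1 = cc.fit_cline(d, n_starts=8, seed=9)
        f2 = cc.fit_cline(d, n_starts=8, seed=9)
        assert f1 == f2

    def test_perfect_step_hits_width_bound_with_flag(self):
        x = np.linspace(0, 1, 100)
        y = (x > 0.5).astype(float)
        f = cc.fit_cline(cc.ClineData(x, y, "bernoulli"), n_starts=8, seed=0)
        assert f.spec.width == pytest.approx(DEFAULT_BOUNDS["width"][0], abs=1e-6)
        assert f.boundary

    def test_degenerate_all_identical_flags_boundary_not_raises(self):
        x = np.linspace(0, 1, 30)
        f = cc.fit_cline(cc.ClineData(x, np.ones(30), "bernoulli"), n_starts=4, seed=0)
        assert f.boundary

    def test_grid_search_never_beats_optimizer(self, rng):
        # small-n exhaustive oracle over (c, w)
        for inst in range(4):
            n = int(rng.integers(4, 13))
            x = rng.uniform(0, 1, n)
            y = (rng.random(n) < 0.5).astype(float)
            d = cc.ClineData(x, y, "bernoulli")
            f = cc.fit_cline(d, n_starts=20, seed=inst)
            grid = max(
                cc.loglik(d, cc.ClineModelSpec(center=c, width=w))
                for c in np.linspace(0.01, 0.99, 50)
                for w in np.linspace(1e-3, 2, 50)
            )
            assert grid <= f.loglik + 1e-6


class TestSupportInterval:
    def test_contains_mle_and_brackets_tighten_with_n(self, steep_cline_spec):
        widths = []
        for n in (100, 400):
            d = simulate_bernoulli(steep_cline_spec, n, seed=77)
            f = cc.fit_cline(d, n_starts=8, seed=1)
            lo, hi = cc.support_interval(d, f, "center")
            assert lo <= f.spec.center <= hi
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_non_converged_fit_rejected(self, steep_cline_spec):
        import dataclasses

        d = simulate_bernoulli(steep_cline_spec, 50, seed=3)
        f = cc.fit_cline(d, n_starts=4, seed=1)
        bad = dataclasses.replace(f, converged=False)
        with pytest.raises(ValueError):
            cc.support_interval(d, bad, "center")

    def test_flat_likelihood_spans_bound(self):
        # nearly uninformative data: interval for width reaches the box bound
        x = np.array([0.0, 1.0, 0.0, 1.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        d = cc.ClineData(x, y, "bernoulli")
        f = cc.fit_cline(d, n_starts=8, seed=0)
        lo, hi = cc.support_interval(d, f, "center")
        # with two perfectly separated ends, any center fits: full bound
        assert lo == pytest.approx(DEFAULT_BOUNDS["center"][0], abs=1e-3)
        assert hi == pytest.approx(DEFAULT_BOUNDS["center"][1], abs=1e-3)


class TestSelectModel:
    def test_single_variant_returned(self, steep_cline_spec):
        d = simulate_bernoulli(steep_cline_spec, 100, seed=2)
        f = cc.select_model(d, [("none", "none")], n_starts=6, seed=1)
        assert (f.spec.scaling, f.spec.tails) == ("none", "none")

    def test_returned_aic_is_minimum_over_candidates(self, steep_cline_spec):
        d = simulate_bernoulli(steep_cline_spec, 100, seed=2)
        variants = [("none", "none"), ("free", "none"), ("none", "mirror")]
        fits = [
            cc.fit_cline(d, s, t, n_starts=6, seed=1) for s, t in variants
        ]
        best = cc.select_model(d, variants, n_starts=6, seed=1)
        assert best.aic == pytest.approx(min(f.aic for f in fits if f.converged))

    def test_parsimony_under_tails_none_truth(self, steep_cline_spec):
        # data simulated without tails should rarely need the both-tails model
        simpler = 0
        for s in range(10):
            d = simulate_bernoulli(steep_cline_spec, 200, seed=1000 + s)
            best = cc.select_model(
                d, [("none", "none"), ("none", "both")], n_starts=6, seed=s
            )
            both = cc.fit_cline(d, "none", "both", n_starts=6, seed=s)
            if best.spec.k <= both.spec.k:
                simpler += 1
        assert simpler >= 9

    def test_aic_identity(self, steep_cline_spec):
        d = simulate_bernoulli(steep_cline_spec, 80, seed=6)
        f = cc.fit_cline(d, "free", "mirror", n_starts=6, seed=1)
        assert f.aic == pytest.approx(2 * f.spec.k - 2 * f.loglik)
        assert f.spec.k == 6  # c, w, pmin, pmax, delta, tau

    def test_all_variants_enumeration(self):
        assert len(all_variants()) == 15
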