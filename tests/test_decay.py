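"""Dissipation-curve fitting against closed forms and a grid-search oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nstwindow.decay import (
    DecayFit,
    DecayFitError,
    fit_first_order_decay,
    flattening_day,
    half_life,
    predict,
    r_squared,
)


def grid_search_sse(points, c0_grid, k_grid):
    """Independent brute-force oracle: best SSE on a (c0, k) grid."""
    pts = np.asarray(points, dtype=float)
    t, y = pts[:, 0], pts[:, 1]
    best = np.inf
    for c0 in c0_grid:
        resid = y[None, :] - c0 * np.exp(-np.outer(k_grid, t))
        sse = (resid ** 2).sum(axis=1).min()
        best = min(best, float(sse))
    return best


def sse(points, fit):
    pts = np.asarray(points, dtype=float)
    return float(((pts[:, 1] - predict(fit, pts[:, 0])) ** 2).sum())


class TestFit:
    def test_noiseless_exact_recovery(self):
        t = np.arange(0, 21, 2, dtype=float)
        pts = np.c_[t, 10.0 * np.exp(-0.2 * t)]
        fit = fit_first_order_decay(pts)
        assert fit.c0 == pytest.approx(10.0, abs=1e-6)
        assert fit.k == pytest.approx(0.2, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_no_decay(self):
        pts = [(d, 5.0) for d in (0, 5, 10, 15)]
        fit = fit_first_order_decay(pts)
        assert abs(fit.k) <= 1e-8
        assert fit.c0 == pytest.approx(5.0, abs=1e-8)
        assert fit.r2 == pytest.approx(0.0)

    def test_matches_grid_oracle(self):
        """On the halving series the LM fit's SSE is at least as good as a
        dense 400x400 brute-force grid's."""
        pts = [(0, 8.0), (5, 4.0), (10, 2.0), (15, 1.0)]
        fit = fit_first_order_decay(pts)
        oracle = grid_search_sse(
            pts, np.linspace(0.0, 16.0, 400), np.linspace(0.0, 1.0, 400)
        )
        assert sse(pts, fit) <= oracle + 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        c0=st.floats(0.5, 50.0),
        k=st.floats(0.02, 0.5),
        seed=st.integers(0, 10_000),
    )
    def test_oracle_equivalence_on_noisy_series(self, c0, k, seed):
        """Property: on any short noisy series the fit never loses to the
        grid oracle by more than the tolerance."""
        rng = np.random.default_rng(seed)
        t = np.sort(rng.choice(np.arange(0, 40), size=8, replace=False)).astype(float)
        y = c0 * np.exp(-k * t) * rng.lognormal(0.0, 0.2, t.size)
        pts = np.c_[t, y]
        fit = fit_first_order_decay(pts)
        oracle = grid_search_sse(
            pts, np.linspace(0.0, 2 * y.max(), 400), np.linspace(0.0, 1.0, 400)
        )
        assert sse(pts, fit) <= oracle + 1e-6

    def test_rejects_insufficient_data(self):
        with pytest.raises(DecayFitError, match="3 points"):
            fit_first_order_decay([(0, 1.0), (1, 0.5)])
        with pytest.raises(DecayFitError, match="distinct dpp"):
            fit_first_order_decay([(5, 1.0), (5, 0.5), (5, 0.2)])
        with pytest.raises(DecayFitError, match="negative"):
            fit_first_order_decay([(0, 1.0), (5, -0.5), (10, 0.2)])

    def test_error_names_series(self):
        with pytest.raises(DecayFitError, match="2015.*high.*root"):
            fit_first_order_decay([(0, 1.0)], series=("2015", "high", "root"))

    def test_parameter_recovery_small(self):
        """Moderate lognormal noise: median relative error of both parameters
        across 30 replicate series stays below 10%."""
        rng = np.random.default_rng(20150505)
        t = np.arange(0, 24, 3, dtype=float)  # 8 dates spanning ~1.5 DT50s
        errs_k, errs_c0 = [], []
        for _ in range(30):
            y_exp = 16.0 * np.exp(-0.16 * t)
            # 5 plants per date, plot-date means
            y = np.mean(
                y_exp[:, None] * rng.lognormal(
                    -0.5 * np.log(1.09), np.sqrt(np.log(1.09)), (t.size, 5)
                ),
                axis=1,
            )
            fit = fit_first_order_decay(np.c_[t, y])
            errs_k.append(abs(fit.k - 0.16) / 0.16)
            errs_c0.append(abs(fit.c0 - 16.0) / 16.0)
        assert np.median(errs_k) < 0.10
        assert np.median(errs_c0) < 0.10


class TestRSquared:
    def test_perfect_fit_is_one(self):
        t = np.arange(6.0)
        pts = np.c_[t, 3.0 * np.exp(-0.3 * t)]
        assert r_squared(pts, DecayFit(3.0, 0.3, 1.0, 6)) == pytest.approx(1.0, abs=1e-12)

    def test_mean_prediction_is_zero(self):
        """A flat fit at the series mean explains nothing."""
        pts = [(0.0, 2.0), (1.0, 4.0)]
        fit = DecayFit(c0=3.0, k=0.0, r2=0.0, n_points=2)
        assert r_squared(pts, fit) == pytest.approx(0.0, abs=1e-12)

    def test_hand_series(self):
        """{(0,8),(5,4),(10,2)} with c0=8, k=ln2/5: residuals are exactly 0,
        so R2 = 1; perturbing c0 to 9 gives the hand-computed value."""
        pts = [(0, 8.0), (5, 4.0), (10, 2.0)]
        fit = DecayFit(8.0, math.log(2) / 5, 1.0, 3)
        assert r_squared(pts, fit) == pytest.approx(1.0, abs=1e-12)
        fit9 = DecayFit(9.0, math.log(2) / 5, 1.0, 3)
        # residuals: 8-9, 4-4.5, 2-2.25 -> SSres = 1 + 0.25 + 0.0625
        # SStot about mean 14/3: (8-14/3)^2+(4-14/3)^2+(2-14/3)^2 = 56/9... by hand:
        ss_res = 1.0 + 0.25 + 0.0625
        mean = 14.0 / 3.0
        ss_tot = (8 - mean) ** 2 + (4 - mean) ** 2 + (2 - mean) ** 2
        assert r_squared(pts, fit9) == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)

    def test_zero_variance_is_explicit_error(self):
        with pytest.raises(DecayFitError, match="variance"):
            r_squared([(0, 5.0), (1, 5.0)], DecayFit(5.0, 0.0, 0.0, 2))


class TestDerivedQuantities:
    def test_flattening_closed_form(self):
        fit = DecayFit(c0=10.0, k=0.15, r2=1.0, n_points=5)
        assert flattening_day(fit, 0.05) == pytest.approx(math.log(20) / 0.15)
        assert flattening_day(fit, 0.05) == pytest.approx(19.97, abs=0.01)

    def test_flattening_limits_and_scaling(self):
        fit = DecayFit(10.0, 0.2, 1.0, 5)
        assert flattening_day(fit, 0.999999) == pytest.approx(0.0, abs=1e-5)
        assert flattening_day(DecayFit(10.0, 0.4, 1.0, 5), 0.05) == pytest.approx(
            flattening_day(fit, 0.05) / 2.0
        )

    def test_no_flattening_when_no_decay(self):
        assert flattening_day(DecayFit(5.0, 0.0, 0.0, 5), 0.05) == math.inf
        assert flattening_day(DecayFit(5.0, -0.01, 0.0, 5), 0.05) == math.inf

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        k1=st.floats(0.01, 1.0), k2=st.floats(0.01, 1.0),
        f1=st.floats(0.01, 0.99), f2=st.floats(0.01, 0.99),
    )
    def test_flattening_monotone_in_k_and_f(self, k1, k2, f1, f2):
        if k1 > k2:
            assert flattening_day(k1, f1) < flattening_day(k2, f1) or k1 == k2
        if f1 > f2:
            assert flattening_day(k1, f1) < flattening_day(k1, f2) or f1 == f2

    def test_half_life_values(self):
        assert half_life(0.0693) == pytest.approx(10.0, abs=0.01)
        assert half_life(math.log(2)) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            half_life(0.0)

    def test_half_life_plugback(self):
        """C(DT50) = C0/2 under the fitted model."""
        t = np.arange(0, 30, 3, dtype=float)
        fit = fit_first_order_decay(np.c_[t, 12.0 * np.exp(-0.11 * t)])
        assert predict(fit, fit.half_life) == pytest.approx(fit.c0 / 2.0, rel=1e-9)
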