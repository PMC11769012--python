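"""Double-logistic fitting and phenological metric extraction."""

import numpy as np
import pytest

from marshphen.errors import UnfitPixelError
from marshphen.phenology import (
    DoubleLogisticFit,
    dl_evaluate,
    double_logistic,
    extract_pheno_metrics,
    fit_double_logistic,
)
from marshphen.synthetic import DEFAULT_OPTICAL_DATES

TRUE = dict(x1=150.0, x2=10.0, x3=300.0, x4=12.0, c0=0.1, c1=0.6)


def _fit(**kw):
    params = dict(TRUE, rss=0.0, n_obs=0, converged=True)
    params.update(kw)
    return DoubleLogisticFit(**params)


def _sample(days, rng=None, noise=0.0, **kw):
    p = dict(TRUE, **kw)
    vals = p["c0"] + p["c1"] * double_logistic(days, p["x1"], p["x2"], p["x3"], p["x4"])
    if noise:
        vals = vals + noise * rng.standard_normal(len(days))
    return vals


class TestEvaluate:
    def test_left_logistic_midpoint(self):
        # at t = x1 with the limbs far apart the second sigmoid vanishes
        fit = _fit(c0=0.0, c1=1.0)
        assert dl_evaluate(TRUE["x1"], fit) == pytest.approx(0.5, abs=1e-5)

    def test_coincident_inflections_cancel(self):
        fit = _fit(x1=200.0, x3=200.0, x2=10.0, x4=10.0, c0=0.25)
        t = np.linspace(1, 365, 50)
        np.testing.assert_allclose(dl_evaluate(t, fit), 0.25, atol=1e-12)

    def test_limits_are_baseline(self):
        fit = _fit()
        assert dl_evaluate(-1e6, fit) == pytest.approx(TRUE["c0"])
        assert dl_evaluate(1e6, fit) == pytest.approx(TRUE["c0"])


class TestFit:
    def test_noiseless_recovery(self):
        days = np.asarray(DEFAULT_OPTICAL_DATES, dtype=float)
        fit = fit_double_logistic(days=days, values=_sample(days))
        assert fit.converged
        assert fit.x1 == pytest.approx(TRUE["x1"], abs=1.0)
        assert fit.x3 == pytest.approx(TRUE["x3"], abs=1.0)
        assert fit.c1 == pytest.approx(TRUE["c1"], rel=0.01)
        assert fit.c0 == pytest.approx(TRUE["c0"], abs=0.01)

    def test_noisy_sos_eos_rmse(self, rng):
        """sd-0.05 noise over replicate pixels keeps SOS/EOS RMSE small."""
        days = np.asarray(DEFAULT_OPTICAL_DATES, dtype=float)
        sos_err, eos_err = [], []
        for _ in range(30):
            fit = fit_double_logistic(days=days, values=_sample(days, rng, noise=0.05))
            m = extract_pheno_metrics(fit)
            sos_err.append(m.sos - TRUE["x1"])
            eos_err.append(m.eos - TRUE["x3"])
        assert np.sqrt(np.mean(np.square(sos_err))) <= 5.0
        assert np.sqrt(np.mean(np.square(eos_err))) <= 5.0

    def test_constant_series_flagged(self):
        days = np.asarray(DEFAULT_OPTICAL_DATES, dtype=float)
        fit = fit_double_logistic(days=days, values=np.full(days.size, 0.21))
        assert not fit.converged
        assert fit.flag == "no_seasonality"

    def test_too_few_observations(self):
        with pytest.raises(UnfitPixelError):
            fit_double_logistic(days=np.arange(1.0, 6.0), values=np.zeros(5))

    def test_rss_not_worse_than_initial_guess(self, rng):
        days = np.asarray(DEFAULT_OPTICAL_DATES, dtype=float)
        values = _sample(days, rng, noise=0.08)
        init = np.array([120.0, 15.0, 280.0, 15.0, 0.1, 0.5])
        fit = fit_double_logistic(days=days, values=values, init=init)
        rss0 = np.sum((init[4] + init[5] * double_logistic(days, *init[:4]) - values) ** 2)
        assert fit.rss <= rss0 + 1e-9


class TestMetrics:
    def test_sos_eos_near_inflections_when_separated(self):
        m = extract_pheno_metrics(_fit())
        assert m.sos == pytest.approx(TRUE["x1"], abs=0.5)
        assert m.eos == pytest.approx(TRUE["x3"], abs=0.5)
        # the opposing sigmoid leaves a ~0.2% residual at each extremum
        assert m.bv == pytest.approx(TRUE["c0"], abs=3e-3)
        assert m.mv == pytest.approx(TRUE["c0"] + TRUE["c1"], abs=3e-3)

    def test_roi_matches_closed_form(self):
        # 20->80% span of a lone logistic is x2*ln(16) on each side of x1,
        # so ROI = 0.6*c1 / (2*x2*ln4) = 0.36/27.726 for c1=0.6, x2=10
        m = extract_pheno_metrics(_fit())
        span = 2.0 * TRUE["x2"] * np.log(4.0)
        assert m.roi == pytest.approx(0.6 * TRUE["c1"] / span, rel=0.01)

    def test_symmetric_fit_has_equal_rates(self):
        m = extract_pheno_metrics(_fit(x4=TRUE["x2"]))
        assert m.roi == pytest.approx(m.rod, rel=1e-3)
        assert m.rod > 0

    def test_threshold_monotonicity(self):
        lo = extract_pheno_metrics(_fit(), threshold=0.3)
        hi = extract_pheno_metrics(_fit(), threshold=0.7)
        assert lo.sos < hi.sos
        assert lo.eos > hi.eos

    def test_constant_offset_shifts_only_bv_mv(self):
        base = extract_pheno_metrics(_fit())
        shifted = extract_pheno_metrics(_fit(c0=TRUE["c0"] + 0.1))
        assert shifted.bv == pytest.approx(base.bv + 0.1, abs=1e-6)
        assert shifted.mv == pytest.approx(base.mv + 0.1, abs=1e-6)
        assert shifted.sos == pytest.approx(base.sos, abs=0.11)
        assert shifted.eos == pytest.approx(base.eos, abs=0.11)
        assert shifted.roi == pytest.approx(base.roi, rel=1e-3)
        assert shifted.rod == pytest.approx(base.rod, rel=1e-3)

    def test_curve_bounded_by_bv_mv(self):
        fit = _fit(x2=25.0, x4=30.0)
        m = extract_pheno_metrics(fit)
        curve = dl_evaluate(np.arange(1.0, 366.0), fit)
        assert np.all(curve >= m.bv - 1e-9)
        assert np.all(curve <= m.mv + 1e-9)

    def test_unconverged_fit_rejected(self):
        with pytest.raises(UnfitPixelError):
            extract_pheno_metrics(_fit(converged=False))
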