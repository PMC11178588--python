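"""Mono-exponential time-activity fitting and time-integrated activity."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import least_squares

from acdose.errors import (
    InvalidInputError,
    NonDecayingTACError,
    NonPhysicalKineticsError,
)
from acdose.kinetics import (
    MonoExpFit,
    TimeActivityPoint,
    biological_half_life,
    fit_monoexp,
    time_integrated_activity,
)

LN2 = math.log(2.0)


def _points(pairs):
    return [TimeActivityPoint(t, a) for t, a in pairs]


def _generic_nls(pairs):
    """Independent oracle: plain nonlinear least squares on the exponential."""
    t = np.array([p[0] for p in pairs])
    a = np.array([p[1] for p in pairs])

    def resid(theta):
        return theta[0] * np.exp(-LN2 / theta[1] * t) - a

    sol = least_squares(resid, x0=[a[0] * 2, 30.0], xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return sol.x


class TestTwoPointFit:
    def test_halving_over_one_interval(self):
        fit = fit_monoexp(_points([(24.0, 100.0), (48.0, 50.0)]))
        assert fit.t_eff == pytest.approx(24.0, rel=1e-12)
        assert fit.a_t0 == pytest.approx(200.0, rel=1e-12)
        assert fit.residual_norm == 0.0

    def test_slow_clearance_closed_form(self):
        fit = fit_monoexp(_points([(24.0, 100.0), (48.0, 75.0)]))
        expected = 24.0 * LN2 / math.log(100.0 / 75.0)
        assert fit.t_eff == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(57.8, abs=0.1)

    @pytest.mark.parametrize(
        "pairs",
        [
            [(24.0, 100.0), (48.0, 50.0)],
            [(24.0, 100.0), (48.0, 75.0)],
            [(24.0, 3.2e5), (48.0, 1.1e5)],
        ],
    )
    def test_closed_form_matches_generic_least_squares(self, pairs):
        fit = fit_monoexp(_points(pairs))
        a0, teff = _generic_nls(pairs)
        assert fit.a_t0 == pytest.approx(a0, rel=1e-8)
        assert fit.t_eff == pytest.approx(teff, rel=1e-8)

    def test_non_decaying_rejected(self):
        with pytest.raises(NonDecayingTACError):
            fit_monoexp(_points([(24.0, 100.0), (48.0, 100.0)]))
        with pytest.raises(NonDecayingTACError):
            fit_monoexp(_points([(24.0, 100.0), (48.0, 130.0)]))

    def test_duplicate_times_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_monoexp(_points([(24.0, 100.0), (24.0, 90.0)]))


class TestMultiPointFit:
    def test_noiseless_series_exact_recovery(self):
        truth_a0, truth_teff = 1234.0, 31.5
        pairs = [(t, truth_a0 * 2 ** (-t / truth_teff)) for t in (6.0, 24.0, 48.0)]
        fit = fit_monoexp(_points(pairs))
        assert fit.a_t0 == pytest.approx(truth_a0, rel=1e-9)
        assert fit.t_eff == pytest.approx(truth_teff, rel=1e-9)
        assert fit.n_points == 3

    def test_noisy_series_matches_generic_least_squares(self):
        rng = np.random.default_rng(11)
        pairs = [
            (t, 500.0 * 2 ** (-t / 28.0) * rng.lognormal(0, 0.05))
            for t in (4.0, 24.0, 48.0, 72.0)
        ]
        fit = fit_monoexp(_points(pairs))
        a0, teff = _generic_nls(pairs)
        assert fit.a_t0 == pytest.approx(a0, rel=1e-7)
        assert fit.t_eff == pytest.approx(teff, rel=1e-7)


def test_parameter_recovery_is_median_unbiased():
    """Two-point fits at {24, 48} h under 10% multiplicative lognormal noise:
    the half-life estimator is median-unbiased and the median absolute
    relative error stays below the noise-propagated bound."""
    from acdose.synth import simulate_voi_tac

    truth_teff, truth_a0, cv = 24.0, 1000.0, 0.10
    estimates = []
    for i in range(500):
        pts = simulate_voi_tac(truth_a0, truth_teff, (24.0, 48.0), cv, seed=42, stream_keys=(i,))
        try:
            estimates.append(fit_monoexp(pts).t_eff)
        except NonDecayingTACError:
            estimates.append(np.inf)
    estimates = np.array(estimates)
    finite = estimates[np.isfinite(estimates)]
    assert len(finite) > 480
    # propagated bound: T̂ = Δt·ln2/(ln2 + ε), ε ~ N(0, √2·σ_log)
    sigma_log = math.sqrt(math.log(1 + cv**2))
    median_bound = 0.6745 * math.sqrt(2) * sigma_log / LN2
    rel_err = np.abs(finite - truth_teff) / truth_teff
    assert np.median(rel_err) < median_bound * 1.25
    # median-unbiasedness: the sample median sits at the truth within MC error
    assert abs(np.median(estimates) - truth_teff) / truth_teff < 0.02


class TestHalfLifeDecomposition:
    def test_equal_rates(self, chain):
        ac = chain["Ac-225"]
        d = biological_half_life(ac.half_life / 2.0, ac)
        assert d.t_bio == pytest.approx(ac.half_life, rel=1e-12)
        assert 1.0 / d.t_eff == pytest.approx(1.0 / d.t_bio + 1.0 / d.t_phys, rel=1e-9)

    def test_kidney_like_value(self, chain):
        d = biological_half_life(27.0, chain["Ac-225"])
        assert d.t_bio == pytest.approx(1.0 / (1.0 / 27.0 - 1.0 / 238.08), rel=1e-6)
        assert d.t_bio == pytest.approx(30.5, abs=0.1)

    def test_vanishing_clearance_limit(self, chain):
        ac = chain["Ac-225"]
        d = biological_half_life(ac.half_life * (1 - 1e-9), ac)
        assert d.t_bio > 1e6  # essentially physical decay only

    def test_unphysical_rejected(self, chain):
        ac = chain["Ac-225"]
        with pytest.raises(NonPhysicalKineticsError):
            biological_half_life(ac.half_life, ac)
        with pytest.raises(NonPhysicalKineticsError):
            biological_half_life(300.0, ac)


class TestTimeIntegratedActivity:
    def test_unit_construction(self):
        fit = MonoExpFit(a_t0=LN2, t_eff=1.0, n_points=2, residual_norm=0.0)
        assert time_integrated_activity(fit) == pytest.approx(1.0, rel=1e-12)

    def test_matches_numerical_quadrature(self):
        fit = MonoExpFit(a_t0=200.0, t_eff=24.0, n_points=2, residual_norm=0.0)
        closed = time_integrated_activity(fit)
        numeric, _ = quad(fit.activity, 0.0, np.inf)
        assert closed == pytest.approx(numeric, rel=1e-8)
        assert closed == pytest.approx(200.0 * 24.0 / LN2, rel=1e-12)

    def test_linearity_in_amplitude(self):
        f1 = MonoExpFit(100.0, 24.0, 2, 0.0)
        f2 = MonoExpFit(200.0, 24.0, 2, 0.0)
        assert time_integrated_activity(f2) == pytest.approx(2 * time_integrated_activity(f1), rel=1e-12)

    def test_deferred_lower_bound(self):
        fit = MonoExpFit(200.0, 24.0, 2, 0.0)
        from_24 = time_integrated_activity(fit, from_time=24.0)
        assert from_24 == pytest.approx(time_integrated_activity(fit) / 2.0, rel=1e-12)
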