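"""Sampling, closed-form moments, and fitting of the service-time families."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screensim import (
    DistributionSpec,
    Family,
    analytic_mean,
    analytic_sd,
    fit_distribution,
    lognormal_underlying,
    sample,
)
from screensim.distributions import to_scipy
from screensim.errors import (
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
)


@pytest.mark.parametrize(
    "spec, mean, sd",
    [
        (DistributionSpec(Family.UNIF, (5, 10)), 7.5, 5 / math.sqrt(12)),
        (DistributionSpec(Family.UNIF, (15, 30)), 22.5, 15 / math.sqrt(12)),
        (DistributionSpec(Family.ERLA, (1.23, 2), offset=1.0), 1 + 2.46, 1.23 * math.sqrt(2)),
        (DistributionSpec(Family.EXPO, (0.626,), offset=0.999), 1.625, 0.626),
        (DistributionSpec(Family.LOGN, (3.42, 1.37), offset=1.0), 4.42, 1.37),
        (DistributionSpec(Family.GAMM, (1.41, 5.12), offset=1.0), 1 + 7.2192, 1.41 * math.sqrt(5.12)),
        (
            DistributionSpec(Family.BETA, (1.35, 2.55), offset=0.999, scale=29),
            0.999 + 29 * 1.35 / 3.90,
            29 * math.sqrt(1.35 * 2.55 / (3.90**2 * 4.90)),
        ),
    ],
)
def test_closed_form_moments(spec, mean, sd):
    assert analytic_mean(spec) == pytest.approx(mean, abs=1e-9)
    assert analytic_sd(spec) == pytest.approx(sd, abs=1e-9)


def test_sampled_mean_matches_closed_form_all_stations(model, rng):
    """For every station law, 10^6 seeded draws agree with the closed-form
    mean within 4 standard errors (and exactly reproduce the published
    examples H -> 4.42 and J -> 8.22 at the printed precision)."""
    for code, spec in model.service.items():
        if spec is None:
            continue
        draws = np.asarray(sample(spec, rng, size=1_000_000))
        se = draws.std() / 1000.0
        assert abs(draws.mean() - analytic_mean(spec)) < 4 * se, code
        assert draws.min() >= spec.offset


def test_published_sample_mean_examples(model, rng):
    h = np.asarray(sample(model.service["H"], rng, size=1_000_000))
    assert h.mean() == pytest.approx(4.42, abs=0.01)
    j = np.asarray(sample(model.service["J"], rng, size=1_000_000))
    assert j.mean() == pytest.approx(8.22, abs=0.02)


def test_uniform_support_and_determinism(rng):
    spec = DistributionSpec(Family.UNIF, (5, 10))
    draws = np.asarray(sample(spec, rng, size=10_000))
    assert draws.min() >= 5 and draws.max() <= 10
    a = sample(spec, np.random.default_rng(5), size=100)
    b = sample(spec, np.random.default_rng(5), size=100)
    np.testing.assert_array_equal(a, b)


class TestLognormalUnderlying:
    def test_inverts_moment_formulas(self):
        mu, sigma = lognormal_underlying(3.42, 1.37)
        assert sigma**2 == pytest.approx(math.log(1 + (1.37 / 3.42) ** 2), abs=1e-12)
        assert sigma**2 == pytest.approx(0.1489, abs=5e-4)
        assert mu == pytest.approx(1.1555, abs=5e-4)

    def test_zero_sd_degenerates_to_point_mass(self):
        mu, sigma = lognormal_underlying(7.0, 0.0)
        assert sigma == 0.0 and mu == math.log(7.0)

    @given(
        m=st.floats(0.1, 50), cv=st.floats(0.0, 3.0)
    )
    @settings(max_examples=50, derandomize=True)
    def test_round_trip_recovers_arithmetic_moments(self, m, cv):
        s = m * cv
        mu, sigma = lognormal_underlying(m, s)
        back_m = math.exp(mu + sigma**2 / 2)
        back_s = back_m * math.sqrt(math.expm1(sigma**2))
        assert back_m == pytest.approx(m, rel=1e-9)
        assert back_s == pytest.approx(s, rel=1e-9, abs=1e-9)


@pytest.mark.parametrize(
    "family, params, kwargs",
    [
        (Family.UNIF, (10, 5), {}),
        (Family.ERLA, (-1.0, 2), {}),
        (Family.ERLA, (1.0, 2.5), {}),
        (Family.EXPO, (0.0,), {}),
        (Family.LOGN, (-3.42, 1.37), {}),
        (Family.LOGN, (3.42, -1.0), {}),
        (Family.BETA, (1.35, 2.55), {}),  # missing scale
        (Family.GAMM, (1.41, -5.12), {}),
    ],
)
def test_invalid_parameters_rejected(family, params, kwargs):
    with pytest.raises(ParameterError):
        DistributionSpec(family, params, **kwargs)


def test_spec_serialization_round_trip(model):
    for spec in model.service.values():
        if spec is None:
            continue
        assert DistributionSpec.from_dict(spec.to_dict()) == spec


class TestFitting:
    def test_lognormal_recovery(self, model):
        """1305 draws of the ECG law select LOGN and recover the 4.42 mean."""
        rng = np.random.default_rng(400)
        draws = np.asarray(sample(model.service["H"], rng, size=1305))
        spec, report = fit_distribution(draws)
        assert spec.family is Family.LOGN
        assert analytic_mean(spec) == pytest.approx(4.42, abs=0.15)
        assert set(report) == {f.value for f in Family}

    def test_uniform_recovery(self):
        rng = np.random.default_rng(301)
        draws = rng.uniform(15, 30, size=10_000)
        spec, _ = fit_distribution(draws)
        assert spec.family is Family.UNIF
        assert spec.params[0] == pytest.approx(15, abs=0.2)
        assert spec.params[1] == pytest.approx(30, abs=0.2)

    def test_selected_mean_near_sample_mean(self, model, rng):
        for code in ("G", "J", "N"):
            draws = np.asarray(sample(model.service[code], rng, size=2000))
            spec, _ = fit_distribution(draws)
            se = draws.std() / math.sqrt(len(draws))
            assert abs(analytic_mean(spec) - draws.mean()) < 2 * se

    def test_refit_stability(self, model):
        """Fit -> sample -> refit keeps the selected family on >= 95% of seeds."""
        rng = np.random.default_rng(11)
        base = np.asarray(sample(model.service["L"], rng, size=5000))
        first, _ = fit_distribution(base)
        same = 0
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            redraw = np.asarray(sample(first, r, size=5000))
            refit, _ = fit_distribution(redraw)
            same += refit.family is first.family
        assert same >= 19

    def test_insufficient_and_degenerate_data(self):
        with pytest.raises(InsufficientDataError):
            fit_distribution([1.0] * 10)
        with pytest.raises(DegenerateDataError):
            fit_distribution([5.0] * 100)

    def test_fitted_cdf_matches_spec(self, model, rng):
        """to_scipy agrees with the sampler: empirical CDF of draws tracks
        the frozen distribution (KS < 0.02 at n = 10^4)."""
        from scipy import stats as sps

        for code in ("D", "H", "O"):
            spec = model.service[code]
            draws = np.asarray(sample(spec, rng, size=10_000))
            ks = sps.kstest(draws, to_scipy(spec).cdf).statistic
            assert ks < 0.02, code
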