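"""Distribution families: sampling, pdfs, entropies, asymptotic oracle."""

import math

import numpy as np
import pytest
from scipy import integrate

from inventropy import (DistributionSpec, FAMILIES, asymptotic_invariant_entropy,
                        exact_entropy, make_spec, pdf, sample)


def test_sampling_deterministic():
    spec = DistributionSpec("normal")
    a = sample(spec, 100, 42)
    b = sample(spec, 100, 42)
    c = sample(spec, 100, 43)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


def test_uniform_sample_mean():
    x = sample(DistributionSpec("uniform"), 100_000, 0)
    assert x.mean() == pytest.approx(0.5, abs=0.01)


def test_arcsine_sample_cdf_at_half():
    """Empirical CDF at 0.5 vs (2/pi) arcsin(sqrt(0.5)) = 0.5."""
    x = sample(DistributionSpec("arcsine"), 100_000, 1)
    assert np.mean(x <= 0.5) == pytest.approx(0.5, abs=0.01)


def test_levy_sample_matches_inverse_square_normal_law():
    """Levy(0,1) is the law of 1/Z^2: compare CDF at the median of
    1/Z^2 via the known relation F(x) = 2(1 - Phi(1/sqrt(x)))."""
    from scipy.stats import norm
    x = sample(DistributionSpec("levy"), 100_000, 2)
    for q in (1.0, 5.0):
        expected = 2 * (1 - norm.cdf(1 / math.sqrt(q)))
        assert np.mean(x <= q) == pytest.approx(expected, abs=0.01)


@pytest.mark.parametrize("family", FAMILIES)
def test_pdf_integrates_to_one(family):
    spec = DistributionSpec(family)
    fz = spec.frozen()
    lo, hi = fz.support()
    val, err = integrate.quad(lambda t: pdf(spec, t), lo, hi, limit=400)
    assert val == pytest.approx(1.0, abs=1e-6)


def test_pdf_point_values():
    assert pdf(DistributionSpec("normal"), 0.0) == pytest.approx(
        1 / math.sqrt(2 * math.pi))
    assert pdf(DistributionSpec("exponential"), 0.0) == pytest.approx(1.0)
    assert pdf(DistributionSpec("uniform"), 1.5) == 0.0  # outside support


def test_exact_entropy_closed_forms():
    assert exact_entropy(DistributionSpec("normal")) == pytest.approx(
        0.5 * math.log(2 * math.pi * math.e))
    assert exact_entropy(DistributionSpec("uniform")) == pytest.approx(0.0)
    assert exact_entropy(DistributionSpec("exponential")) == pytest.approx(1.0)


@pytest.mark.parametrize("family", FAMILIES)
def test_exact_entropy_matches_quadrature(family):
    """Closed forms (where used) against scipy's independent
    quadrature/known entropy for the same frozen distribution."""
    spec = DistributionSpec(family)
    with np.errstate(over="ignore", under="ignore"):
        ref = float(spec.frozen().entropy())
    assert exact_entropy(spec) == pytest.approx(ref, abs=1e-6)


def test_invalid_params_rejected():
    with pytest.raises(ValueError, match="b > a"):
        DistributionSpec("uniform", {"a": 1.0, "b": 0.0})
    with pytest.raises(ValueError, match="unknown family"):
        DistributionSpec("beta")
    with pytest.raises(ValueError, match="unknown parameters"):
        DistributionSpec("normal", {"scale": 2.0})


def test_make_spec_positional():
    spec = make_spec("normal", 1.0, 2.0)
    assert spec.params == {"mu": 1.0, "sigma": 2.0}


def test_oracle_uniform_closed_form():
    """Constant density closes the median equation: t* = ln 2."""
    res = asymptotic_invariant_entropy(DistributionSpec("uniform"))
    assert res.t_star == pytest.approx(math.log(2), abs=1e-8)
    assert res.h_c_asymptotic == pytest.approx(
        math.log(2) - math.log(math.log(2)), abs=1e-8)


def test_oracle_exponential_reduced_equation():
    """For Exp(1) the median equation reduces to (1-e^-t)/t = 1/2;
    verify our root against an independent bisection of that form."""
    lo, hi = 1.0, 2.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if (1 - math.exp(-mid)) / mid > 0.5:
            lo = mid
        else:
            hi = mid
    res = asymptotic_invariant_entropy(DistributionSpec("exponential"))
    assert res.t_star == pytest.approx((lo + hi) / 2, abs=1e-6)
    assert res.h_c_asymptotic == pytest.approx(1.2269, abs=1e-3)


def test_oracle_laplace_equals_exponential():
    """t*_laplace = 2 t*_exp and h_laplace = h_exp + ln 2, so the two
    families share the same asymptotic invariant entropy."""
    e = asymptotic_invariant_entropy(DistributionSpec("exponential"))
    l = asymptotic_invariant_entropy(DistributionSpec("laplace"))
    assert l.t_star == pytest.approx(2 * e.t_star, abs=1e-6)
    assert l.h_c_asymptotic == pytest.approx(e.h_c_asymptotic, abs=1e-6)


def test_oracle_identity_and_positivity():
    for family in ("arcsine", "cauchy", "levy"):
        res = asymptotic_invariant_entropy(DistributionSpec(family))
        assert res.t_star > 0
        assert res.h_c_asymptotic == pytest.approx(
            math.log(2) + res.h_exact - math.log(res.t_star), abs=1e-12)


def test_oracle_requires_k1():
    with pytest.raises(ValueError, match="k = 1"):
        asymptotic_invariant_entropy(DistributionSpec("uniform"), k=2)


def test_family_ordering():
    """Families order by local unpredictability: arcsine < uniform <
    normal < exponential < cauchy < levy."""
    hs = [asymptotic_invariant_entropy(DistributionSpec(f)).h_c_asymptotic
          for f in ("arcsine", "uniform", "normal", "exponential",
                    "cauchy", "levy")]
    assert hs == sorted(hs)


@pytest.mark.parametrize("family,param,values", [
    ("normal", "sigma", (0.5, 1.0, 3.0)),
    ("uniform", "b", (0.5, 1.0, 3.0)),
    ("exponential", "lam", (0.5, 1.0, 3.0)),
])
def test_parameter_independence_of_invariant_entropy(family, param, values):
    """Scale parameters leave the simulated invariant entropy unchanged
    within sampling noise (50 replicates, n=10,000)."""
    from inventropy import invariant_entropy
    means, ses = [], []
    for i, v in enumerate(values):
        spec = DistributionSpec(family, {param: v})
        vals = [invariant_entropy(sample(spec, 10_000, 7000 + 100 * i + r)).value
                for r in range(50)]
        means.append(np.mean(vals))
        ses.append(np.std(vals, ddof=1) / math.sqrt(len(vals)))
    # 3 SE on each of the 9 pairwise contrasts keeps the familywise
    # false-alarm rate low while still resolving ~0.008 nats
    for i in range(len(values)):
        for j in range(i + 1, len(values)):
            se = math.hypot(ses[i], ses[j])
            assert abs(means[i] - means[j]) <= 3 * se
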