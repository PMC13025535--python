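"""The 14 validation distribution families.

Each family provides seeded sampling, pdf evaluation, exact differential
entropy (closed form where standard, quadrature otherwise), and a
semi-analytic oracle for the large-N limit of the invariant entropy.

The oracle rests on the asymptotic law of 1-NN distances: at a point
with density f, the nearest-neighbor distance in a sample of size N is
approximately exponential with rate 2 N f, so the median d satisfies
E_f[exp(-2 N m f(X))] = 1/2. Writing t = 2 N m, the stabilized scale
N*m converges and t* solves

    g(t) = E_f[exp(-t f(X))] - 1/2 = 0,

with g strictly decreasing from 1/2 to -1/2. The stabilized invariant
entropy then converges to

    h_c(f) = ln 2 + h(f) - ln t*.

For the uniform this closes: f = 1/(b-a) gives t* = ln 2 and
h_c = ln 2 - ln ln 2 ~ 1.0597. For the exponential the median equation
reduces to (1 - e^-t)/t = 1/2. The Laplace has t* twice the
exponential's and h larger by ln 2, so its h_c coincides with the
exponential's exactly. All quadrature is done in the probability scale
u = F(x), which maps heavy tails and edge singularities to a bounded,
well-behaved integrand on [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import integrate, optimize, stats

__all__ = ["FAMILIES", "DistributionSpec", "OracleResult", "make_spec",
           "sample", "pdf", "exact_entropy", "asymptotic_invariant_entropy"]

_EULER = float(np.euler_gamma)


def _check(cond: bool, family: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid parameters for {family}: {msg}")


# family -> (ordered (name, default) params, frozen-scipy builder, validator)
_REGISTRY: dict[str, tuple[tuple[tuple[str, float], ...], object, object]] = {
    "arcsine": ((("a", 0.0), ("b", 1.0)),
                lambda p: stats.arcsine(loc=p["a"], scale=p["b"] - p["a"]),
                lambda p: _check(p["b"] > p["a"], "arcsine", "need b > a")),
    "uniform": ((("a", 0.0), ("b", 1.0)),
                lambda p: stats.uniform(loc=p["a"], scale=p["b"] - p["a"]),
                lambda p: _check(p["b"] > p["a"], "uniform", "need b > a")),
    "semicircle": ((("r", 1.0),),
                   lambda p: stats.semicircular(scale=p["r"]),
                   lambda p: _check(p["r"] > 0, "semicircle", "need r > 0")),
    "triangular": ((("a", 0.0), ("b", 1.0), ("c", 0.5)),
                   lambda p: stats.triang(c=(p["c"] - p["a"]) / (p["b"] - p["a"]),
                                          loc=p["a"], scale=p["b"] - p["a"]),
                   lambda p: _check(p["a"] <= p["c"] <= p["b"] and p["b"] > p["a"],
                                    "triangular", "need a <= c <= b, b > a")),
    # raised cosine on [mu - s, mu + s]; scipy's support is [-pi, pi]
    "cosine": ((("mu", 0.5), ("s", 1.0)),
               lambda p: stats.cosine(loc=p["mu"], scale=p["s"] / math.pi),
               lambda p: _check(p["s"] > 0, "cosine", "need s > 0")),
    "normal": ((("mu", 0.0), ("sigma", 1.0)),
               lambda p: stats.norm(loc=p["mu"], scale=p["sigma"]),
               lambda p: _check(p["sigma"] > 0, "normal", "need sigma > 0")),
    "rayleigh": ((("sigma", 1.0),),
                 lambda p: stats.rayleigh(scale=p["sigma"]),
                 lambda p: _check(p["sigma"] > 0, "rayleigh", "need sigma > 0")),
    # nu=1 (half-normal) is the package default for "standard parameters"
    "chi": ((("nu", 1.0),),
            lambda p: stats.chi(df=p["nu"]),
            lambda p: _check(p["nu"] > 0, "chi", "need nu > 0")),
    "gumbel": ((("mu", 0.0), ("beta", 1.0)),
               lambda p: stats.gumbel_r(loc=p["mu"], scale=p["beta"]),
               lambda p: _check(p["beta"] > 0, "gumbel", "need beta > 0")),
    "logistic": ((("mu", 0.0), ("s", 1.0)),
                 lambda p: stats.logistic(loc=p["mu"], scale=p["s"]),
                 lambda p: _check(p["s"] > 0, "logistic", "need s > 0")),
    "exponential": ((("lam", 1.0),),
                    lambda p: stats.expon(scale=1.0 / p["lam"]),
                    lambda p: _check(p["lam"] > 0, "exponential", "need lam > 0")),
    "laplace": ((("mu", 0.0), ("b", 1.0)),
                lambda p: stats.laplace(loc=p["mu"], scale=p["b"]),
                lambda p: _check(p["b"] > 0, "laplace", "need b > 0")),
    "cauchy": ((("mu", 0.0), ("sigma", 1.0)),
               lambda p: stats.cauchy(loc=p["mu"], scale=p["sigma"]),
               lambda p: _check(p["sigma"] > 0, "cauchy", "need sigma > 0")),
    "levy": ((("mu", 0.0), ("c", 1.0)),
             lambda p: stats.levy(loc=p["mu"], scale=p["c"]),
             lambda p: _check(p["c"] > 0, "levy", "need c > 0")),
}

FAMILIES: tuple[str, ...] = tuple(_REGISTRY)


@dataclass(frozen=True)
class DistributionSpec:
    """A named family plus its parameters."""

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in _REGISTRY:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {list(FAMILIES)}")
        defaults, _, validate = _REGISTRY[self.family]
        names = [n for n, _ in defaults]
        unknown = set(self.params) - set(names)
        if unknown:
            raise ValueError(f"unknown parameters {sorted(unknown)} for "
                             f"{self.family}; expected {names}")
        full = {n: float(self.params.get(n, dflt)) for n, dflt in defaults}
        object.__setattr__(self, "params", full)
        validate(full)

    def frozen(self):
        """Frozen scipy.stats distribution for this spec."""
        return _REGISTRY[self.family][1](self.params)


def make_spec(family: str, *args: float, **kwargs: float) -> DistributionSpec:
    """Build a spec from positional params in the family's natural order."""
    defaults, _, _ = _REGISTRY.get(family, ((), None, None))
    names = [n for n, _ in defaults]
    if len(args) > len(names):
        raise ValueError(f"{family} takes at most {len(names)} parameters")
    params = dict(zip(names, args))
    params.update(kwargs)
    return DistributionSpec(family, params)


@dataclass(frozen=True)
class OracleResult:
    """Asymptotic invariant entropy and its ingredients.

    t_star is the root of E_f[exp(-t f(X))] = 1/2, i.e. the large-N
    limit of 2 N x (median 1-NN distance); h_exact the differential
    entropy of the family in nats; h_c_asymptotic = ln2 + h_exact - ln t_star.
    """

    t_star: float
    h_exact: float
    h_c_asymptotic: float


def sample(spec: DistributionSpec, n: int, seed: int) -> np.ndarray:
    """Draw n reproducible samples (same (spec, n, seed) -> same output)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return np.asarray(spec.frozen().rvs(size=n, random_state=rng), dtype=float)


def pdf(spec: DistributionSpec, x) -> np.ndarray | float:
    """Density at x (0 outside the support)."""
    with np.errstate(over="ignore", under="ignore"):
        return spec.frozen().pdf(x)


# closed forms; anything absent falls back to scipy's entropy()
_CLOSED_FORM = {
    "uniform": lambda p: math.log(p["b"] - p["a"]),
    "arcsine": lambda p: math.log(math.pi * (p["b"] - p["a"]) / 4.0),
    "triangular": lambda p: 0.5 + math.log((p["b"] - p["a"]) / 2.0),
    "normal": lambda p: 0.5 * math.log(2.0 * math.pi * math.e * p["sigma"] ** 2),
    "exponential": lambda p: 1.0 - math.log(p["lam"]),
    "laplace": lambda p: 1.0 + math.log(2.0 * p["b"]),
    "cauchy": lambda p: math.log(4.0 * math.pi * p["sigma"]),
    "logistic": lambda p: 2.0 + math.log(p["s"]),
    "rayleigh": lambda p: 1.0 + math.log(p["sigma"] / math.sqrt(2.0)) + _EULER / 2.0,
    "gumbel": lambda p: math.log(p["beta"]) + _EULER + 1.0,
}


def exact_entropy(spec: DistributionSpec) -> float:
    """Differential entropy in nats (closed form or quadrature)."""
    fn = _CLOSED_FORM.get(spec.family)
    if fn is not None:
        return float(fn(spec.params))
    with np.errstate(over="ignore", under="ignore"):
        return float(spec.frozen().entropy())


def _median_equation(t: float, fz) -> float:
    """g(t) = E_f[exp(-t f(X))] - 1/2, integrated in probability scale."""
    def integrand(u):
        with np.errstate(over="ignore", under="ignore"):
            return math.exp(-t * float(fz.pdf(fz.ppf(u))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, 1.0, limit=200, epsabs=1e-10)
    return val - 0.5


def asymptotic_invariant_entropy(spec: DistributionSpec, k: int = 1) -> OracleResult:
    """Large-N invariant entropy oracle (k must be 1).

    Solves the median equation for t* by bracketed root-finding (g
    decreases strictly from 1/2 at t=0 to -1/2) and returns
    ln2 + h_exact - ln t*.
    """
    if k != 1:
        raise ValueError("the asymptotic oracle is defined for k = 1 only")
    fz = spec.frozen()
    hi = 1.0
    for _ in range(60):
        if _median_equation(hi, fz) <= 0.0:
            break
        hi *= 2.0
    else:
        raise RuntimeError("failed to bracket the median-equation root")
    t_star = float(optimize.brentq(_median_equation, 1e-12, hi, args=(fz,),
                                   xtol=1e-12, rtol=1e-12))
    h = exact_entropy(spec)
    return OracleResult(t_star=t_star, h_exact=h,
                        h_c_asymptotic=math.log(2.0) + h - math.log(t_star))
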