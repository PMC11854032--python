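"""The new Lomax-Weibull (NLW) lifetime distribution.

Composing a Weibull transformer with the exponentiated reciprocal hazard
(the Mills-ratio power ``m(x)^c = ((x + lam)/theta)^c``) of a Lomax
baseline yields the five-parameter cdf

    F(x) = 1 - exp(-alpha * ((x + lam)/theta)**(c*beta)),   x >= -lam.

The density covers symmetric, right/left-skewed and inverted-J shapes and
the hazard ``(alpha*beta*c/theta) * ((x+lam)/theta)**(c*beta - 1)`` is
increasing, decreasing or constant as ``c*beta`` is above, below or equal
to one.  The parameterization is redundant: the distribution depends on
``(alpha, beta, theta, c)`` only through the shape ``k = c*beta`` and the
rate ``s = alpha / theta**k`` (so it is a three-parameter Weibull with
location ``-lam``, shape ``k`` and scale ``(1/s)**(1/k)``).  Estimation
code should judge recovery on the identifiable triple ``(lam, k, s)``.

``logpdf`` is the primitive (``pdf = exp(logpdf)``): likelihoods and
Anderson-Darling sums need log-space stability for extreme parameters.
The survival function is evaluated directly from its closed form, never
as ``1 - cdf``, to preserve tail precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NLWParams", "DataSample", "cdf", "pdf", "logpdf", "sf", "hazard",
           "quantile", "median", "rvs"]


@dataclass(frozen=True)
class NLWParams:
    """Parameter vector (alpha, beta, lam, theta, c) of the NLW distribution.

    alpha, beta : baseline Weibull rate and shape, > 0
    lam         : location shift; support is [-lam, inf)
    theta       : scale of the Lomax reciprocal hazard, > 0
    c           : exponent of the reciprocal hazard, > 0
    """

    alpha: float
    beta: float
    lam: float
    theta: float
    c: float

    def __post_init__(self) -> None:
        vals = (self.alpha, self.beta, self.lam, self.theta, self.c)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite parameter in {vals}")
        for name in ("alpha", "beta", "theta", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def shape(self) -> float:
        """Identifiable Weibull shape k = c * beta."""
        return self.c * self.beta

    @property
    def rate(self) -> float:
        """Identifiable Weibull rate s = alpha / theta**k."""
        with np.errstate(over="ignore", under="ignore", divide="ignore"):
            return self.alpha / self.theta ** self.shape

    @property
    def support_lower(self) -> float:
        return -self.lam

    def identifiable(self) -> dict[str, float]:
        """The identifiable functionals (lam, k, s) that determine the cdf."""
        return {"lam": self.lam, "k": self.shape, "s": self.rate}

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.lam, self.theta, self.c])

    @classmethod
    def from_array(cls, v) -> "NLWParams":
        a, b, l, t, c = (float(x) for x in v)
        return cls(a, b, l, t, c)


@dataclass
class DataSample:
    """A named univariate sample of finite real observations."""

    values: np.ndarray
    name: str = ""
    _sorted: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        if v.ndim != 1:
            raise ValueError("DataSample requires a 1-d vector")
        if v.size < 1:
            raise ValueError("DataSample requires at least one observation")
        if not np.all(np.isfinite(v)):
            raise ValueError("DataSample values must all be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def sorted(self) -> np.ndarray:
        # stable sort so ties keep their original order
        if self._sorted is None:
            self._sorted = np.sort(self.values, kind="stable")
        return self._sorted


def _check_x(x):
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite evaluation point")
    return x


def _scaled(p: NLWParams, x: np.ndarray) -> np.ndarray:
    """y = (x + lam)/theta, clipped at the lower support endpoint."""
    return np.maximum((x + p.lam) / p.theta, 0.0)


def cdf(p: NLWParams, x) -> np.ndarray | float:
    """F(x) = 1 - exp(-alpha ((x+lam)/theta)^(c beta)); 0 below support."""
    x = _check_x(x)
    out = -np.expm1(-p.alpha * _scaled(p, x) ** p.shape)
    return out if out.ndim else float(out)


def sf(p: NLWParams, x) -> np.ndarray | float:
    """Survival S(x) = exp(-alpha ((x+lam)/theta)^(c beta)), computed directly."""
    x = _check_x(x)
    out = np.exp(-p.alpha * _scaled(p, x) ** p.shape)
    return out if out.ndim else float(out)


def logpdf(p: NLWParams, x) -> np.ndarray | float:
    """Log-density; -inf below support.

    At x == -lam the density diverges when c*beta < 1 (logpdf +inf) and
    vanishes when c*beta > 1 (logpdf -inf); for c*beta == 1 it equals
    log(alpha*beta*c/theta).
    """
    x = _check_x(x)
    k = p.shape
    y = (np.asarray(x) + p.lam) / p.theta
    const = np.log(p.alpha * p.beta * p.c / p.theta)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        logy = np.log(np.maximum(y, 0.0))
        if k == 1.0:
            out = np.where(y >= 0, const - p.alpha * np.maximum(y, 0.0), -np.inf)
        else:
            out = const + (k - 1.0) * logy - p.alpha * np.maximum(y, 0.0) ** k
            out = np.where(y < 0, -np.inf, out)
    return out if out.ndim else float(out)


def pdf(p: NLWParams, x) -> np.ndarray | float:
    """Density f(x) = exp(logpdf(x)); +inf sentinel at x=-lam when c*beta<1."""
    lp = np.asarray(logpdf(p, x))
    with np.errstate(over="ignore"):
        out = np.exp(lp)
    return out if out.ndim else float(out)


def hazard(p: NLWParams, x) -> np.ndarray | float:
    """Hazard (alpha*beta*c/theta) ((x+lam)/theta)^(c beta - 1); needs x > -lam."""
    x = _check_x(x)
    if np.any(x <= -p.lam):
        raise ValueError("hazard is defined only for x > -lam")
    y = (x + p.lam) / p.theta
    out = (p.alpha * p.beta * p.c / p.theta) * y ** (p.shape - 1.0)
    return out if out.ndim else float(out)


def quantile(p: NLWParams, q) -> np.ndarray | float:
    """Inverse cdf: x_q = theta * (-ln(1-q)/alpha)^(1/(c beta)) - lam, 0 <= q < 1."""
    q = np.asarray(q, dtype=float)
    if np.any(~np.isfinite(q)) or np.any(q < 0) or np.any(q >= 1):
        raise ValueError("quantile level must lie in [0, 1)")
    out = p.theta * (-np.log1p(-q) / p.alpha) ** (1.0 / p.shape) - p.lam
    return out if out.ndim else float(out)


def median(p: NLWParams) -> float:
    """theta * (ln 2 / alpha)^(1/(c beta)) - lam."""
    return float(p.theta * (np.log(2.0) / p.alpha) ** (1.0 / p.shape) - p.lam)


def rvs(p: NLWParams, n: int, seed=None) -> np.ndarray:
    """Draw n values by inverse-transform sampling of uniform variates.

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a
    ``numpy.random.Generator``; the same seed reproduces the same vector.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=int(n))
    return p.theta * (-np.log1p(-u) / p.alpha) ** (1.0 / p.shape) - p.lam
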