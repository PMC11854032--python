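"""Goodness-of-fit engine: information criteria, Kolmogorov-Smirnov and
Anderson-Darling statistics, and the competing lifetime models.

Information criteria follow the small-sample conventions that make the
four reported model-comparison tables internally consistent:

    AIC  = 2k - 2l
    BIC  = k ln(n) - 2l
    CAIC = AIC + 2k(k+1)/(n - k - 1)   (corrected AIC)
    HQIC = 2k ln(ln n) - 2l

The K-S p-value uses the asymptotic Kolmogorov distribution of sqrt(n) D
with estimated parameters plugged in (no Lilliefors correction), and the
A-D statistic is the plug-in A^2 without small-sample modification.

Competitors: the two-parameter Lomax plus the truncated Weibull power
Lomax (TWPL), odd Lomax inverse Weibull (OLIW) and exponentiated
generalized modified Weibull (EGMW), each fitted by multistart MLE.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import kolmogorov

from . import estimation, nlw
from .estimation import FitOptions, FitResult
from .nlw import DataSample, NLWParams

__all__ = ["GoFReport", "CompetitorModel", "info_criteria", "ks_statistic",
           "ad_statistic", "evaluate_model", "nlw_report", "gof_report",
           "report_frame", "reports_to_json", "reports_from_json",
           "fit_competitor", "COMPETITORS", "LOMAX", "TWPL", "OLIW", "EGMW"]

logger = logging.getLogger(__name__)

_CLIP = 1e-300


def info_criteria(neg_loglik: float, k: int, n: int) -> tuple[float, float, float, float]:
    """(AIC, BIC, CAIC, HQIC) from a negative log-likelihood, k parameters
    and n observations.  CAIC needs n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"CAIC undefined: need n > k + 1, got n={n}, k={k}")
    aic = 2.0 * k + 2.0 * neg_loglik
    bic = k * np.log(n) + 2.0 * neg_loglik
    caic = aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    hqic = 2.0 * k * np.log(np.log(n)) + 2.0 * neg_loglik
    return aic, bic, caic, hqic


def ks_statistic(data: DataSample, cdf: Callable[[np.ndarray], np.ndarray]
                 ) -> tuple[float, float]:
    """Two-sided one-sample K-S statistic and asymptotic p-value.

    D = max_i max(i/n - F(x_(i)), F(x_(i)) - (i-1)/n) on the sorted sample.
    """
    xs = data.sorted
    n = data.n
    F = np.asarray(cdf(xs), dtype=float)
    i = np.arange(1, n + 1)
    d = max(np.max(i / n - F), np.max(F - (i - 1) / n))
    return float(d), float(kolmogorov(np.sqrt(n) * d))


def ad_statistic(data: DataSample, cdf: Callable[[np.ndarray], np.ndarray]) -> float:
    """Anderson-Darling A^2 = -n - (1/n) sum (2i-1)[ln F(x_(i)) + ln(1-F(x_(n+1-i)))].

    Degenerate F values (0 or 1) are clipped with a logged warning.
    """
    xs = data.sorted
    n = data.n
    F = np.asarray(cdf(xs), dtype=float)
    if np.any(F <= 0) or np.any(F >= 1):
        logger.warning("A-D: model cdf hit 0 or 1 at a data point; clipping")
        F = np.clip(F, _CLIP, 1.0 - 1e-16)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(F) + np.log1p(-F[::-1]))))


@dataclass
class GoFReport:
    """One model's row of a goodness-of-fit comparison table."""

    model: str
    neg_loglik: float
    aic: float
    bic: float
    caic: float
    hqic: float
    ks_stat: float
    ks_pvalue: float
    ad_stat: float
    k_params: int
    n_obs: int
    note: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "model", "neg_loglik", "aic", "bic", "caic", "hqic",
            "ks_stat", "ks_pvalue", "ad_stat", "k_params", "n_obs", "note")}

    @classmethod
    def from_dict(cls, d: dict) -> "GoFReport":
        return cls(**d)


def evaluate_model(name: str, data: DataSample,
                   cdf: Callable[[np.ndarray], np.ndarray],
                   neg_loglik: float, k_params: int, note: str = "") -> GoFReport:
    """Assemble a GoFReport from a fitted or fixed-parameter model."""
    aic, bic, caic, hqic = info_criteria(neg_loglik, k_params, data.n)
    ks, pval = ks_statistic(data, cdf)
    ad = ad_statistic(data, cdf)
    return GoFReport(model=name, neg_loglik=float(neg_loglik), aic=aic, bic=bic,
                     caic=caic, hqic=hqic, ks_stat=ks, ks_pvalue=pval,
                     ad_stat=ad, k_params=k_params, n_obs=data.n, note=note)


def nlw_report(data: DataSample, params: NLWParams, name: str = "NLW",
               note: str = "") -> GoFReport:
    """GoF row for the NLW at fixed parameters (no refit)."""
    negll = estimation.neg_log_likelihood(params, data)
    return evaluate_model(name, data, lambda x: nlw.cdf(params, x),
                          negll, 5, note=note)


# ---------------------------------------------------------------------------
# competitor models


@dataclass(frozen=True)
class CompetitorModel:
    """A competing lifetime distribution given by cdf/logpdf over a positive
    parameter vector, fitted by multistart MLE in log coordinates."""

    name: str
    k_params: int
    cdf: Callable[[np.ndarray, np.ndarray], np.ndarray] = field(repr=False)
    logpdf: Callable[[np.ndarray, np.ndarray], np.ndarray] = field(repr=False)
    start: tuple[float, ...] = ()


def _lomax_cdf(v, x):
    theta, lam = v
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    return -np.expm1(-theta * np.log1p(x / lam))


def _lomax_logpdf(v, x):
    theta, lam = v
    x = np.asarray(x, dtype=float)
    out = np.log(theta / lam) - (theta + 1.0) * np.log1p(x / lam)
    return np.where(x >= 0, out, -np.inf)


LOMAX = CompetitorModel("Lomax", 2, _lomax_cdf, _lomax_logpdf, start=(1.0, 1.0))


def _twpl_cdf(v, x):
    # unit-truncated-Weibull generator over a power-Lomax baseline:
    # F = (1 - exp(-G^lam)) / (1 - e^-1), G = 1 - (1 + x^beta/gamma)^-alpha
    alpha, beta, gamma, lam = v
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    G = -np.expm1(-alpha * np.log1p(x ** beta / gamma))
    return -np.expm1(-G ** lam) / (-np.expm1(-1.0))


def _twpl_logpdf(v, x):
    alpha, beta, gamma, lam = v
    x = np.asarray(x, dtype=float)
    pos = x > 0
    xp = np.where(pos, x, 1.0)
    G = -np.expm1(-alpha * np.log1p(xp ** beta / gamma))
    G = np.clip(G, _CLIP, 1.0)
    logg = (np.log(alpha * beta / gamma) + (beta - 1.0) * np.log(xp)
            - (alpha + 1.0) * np.log1p(xp ** beta / gamma))
    out = (np.log(lam) + (lam - 1.0) * np.log(G) - G ** lam + logg
           - np.log(-np.expm1(-1.0)))
    return np.where(pos, out, -np.inf)


TWPL = CompetitorModel("TWPL", 4, _twpl_cdf, _twpl_logpdf,
                       start=(1.0, 1.0, 1.0, 1.0))


def _oliw_cdf(v, x):
    # odd Lomax generator over an inverse-Weibull baseline:
    # F = 1 - beta^alpha (beta + G/(1-G))^-alpha, G = exp(-theta x^-lam)
    alpha, beta, lam, theta = v
    x = np.asarray(x, dtype=float)
    pos = x > 0
    xp = np.where(pos, x, 1.0)
    G = np.exp(-theta * xp ** (-lam))
    u = G / np.maximum(1.0 - G, _CLIP)
    out = -np.expm1(alpha * (np.log(beta) - np.log(beta + u)))
    return np.where(pos, out, 0.0)


def _oliw_logpdf(v, x):
    alpha, beta, lam, theta = v
    x = np.asarray(x, dtype=float)
    pos = x > 0
    xp = np.where(pos, x, 1.0)
    logG = -theta * xp ** (-lam)
    G = np.exp(logG)
    one_m = np.maximum(-np.expm1(logG), _CLIP)
    u = G / one_m
    logg = np.log(theta * lam) - (lam + 1.0) * np.log(xp) + logG
    out = (np.log(alpha) + alpha * np.log(beta)
           - (alpha + 1.0) * np.log(beta + u) + logg - 2.0 * np.log(one_m))
    return np.where(pos, out, -np.inf)


OLIW = CompetitorModel("OLIW", 4, _oliw_cdf, _oliw_logpdf,
                       start=(1.0, 1.0, 1.0, 1.0))


def _egmw_cdf(v, x):
    # F = (1 - exp(-alpha (theta x + mu x^lam)))^beta
    alpha, theta, mu, lam, beta = v
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    E = -np.expm1(-alpha * (theta * x + mu * x ** lam))
    return E ** beta


def _egmw_logpdf(v, x):
    alpha, theta, mu, lam, beta = v
    x = np.asarray(x, dtype=float)
    pos = x > 0
    xp = np.where(pos, x, 1.0)
    g = alpha * (theta * xp + mu * xp ** lam)
    E = np.clip(-np.expm1(-g), _CLIP, 1.0)
    out = (np.log(beta) + (beta - 1.0) * np.log(E) - g
           + np.log(alpha * (theta + mu * lam * xp ** (lam - 1.0))))
    return np.where(pos, out, -np.inf)


EGMW = CompetitorModel("EGMW", 5, _egmw_cdf, _egmw_logpdf,
                       start=(1.0, 1.0, 1.0, 1.0, 1.0))

COMPETITORS = {m.name.lower(): m for m in (LOMAX, TWPL, OLIW, EGMW)}


def fit_competitor(model: CompetitorModel, data: DataSample,
                   opts: FitOptions | None = None) -> tuple[np.ndarray, float, bool]:
    """Multistart MLE of a competitor; returns (params, negloglik, converged)."""
    opts = opts or FitOptions()
    x = data.values

    def negll_z(z):
        with np.errstate(all="ignore"):
            v = np.exp(np.clip(z, -200.0, 200.0))
            lp = model.logpdf(v, x)
            if not np.all(np.isfinite(lp)):
                return np.inf
            return float(-np.sum(lp))

    rng = np.random.default_rng(opts.seed)
    z_base = np.log(np.asarray(model.start, dtype=float))
    starts = [z_base] + [z_base + rng.normal(scale=1.0, size=z_base.size)
                         for _ in range(opts.n_starts - 1)]
    best_z, best_val = None, np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for z0 in starts:
            try:
                r = optimize.minimize(negll_z, z0, method="Nelder-Mead",
                                      options={"maxiter": opts.max_iter,
                                               "xatol": 1e-10, "fatol": 1e-12})
            except Exception:
                continue
            if np.isfinite(r.fun) and r.fun < best_val:
                best_val, best_z = float(r.fun), r.x
    if best_z is None:
        return np.full(model.k_params, np.nan), np.inf, False
    v = np.exp(best_z)
    return v, negll_z(best_z), True


# ---------------------------------------------------------------------------
# report assembly

ModelEntry = "NLWParams | FitResult | CompetitorModel | tuple[CompetitorModel, Sequence[float]]"


def gof_report(data: DataSample, models: Sequence,
               opts: FitOptions | None = None) -> list[GoFReport]:
    """One GoFReport per model, sorted by AIC ascending.

    Each entry of ``models`` is one of: an :class:`NLWParams` (NLW at
    fixed parameters), a :class:`FitResult` (NLW at fitted parameters),
    a :class:`CompetitorModel` (fitted here by MLE), or a
    ``(CompetitorModel, params)`` pair (fixed parameters).  Fit failures
    become flagged rows instead of being dropped.
    """
    if len(models) == 0:
        raise ValueError("at least one model is required")
    reports: list[GoFReport] = []
    for m in models:
        if isinstance(m, NLWParams):
            reports.append(nlw_report(data, m))
        elif isinstance(m, FitResult):
            if m.params is None:
                reports.append(GoFReport("NLW", np.inf, np.inf, np.inf, np.inf,
                                         np.inf, np.nan, np.nan, np.nan, 5,
                                         data.n, note="fit failed"))
            else:
                reports.append(nlw_report(data, m.params,
                                          name=f"NLW[{m.method}]"))
        elif isinstance(m, CompetitorModel):
            v, negll, ok = fit_competitor(m, data, opts)
            if not ok:
                reports.append(GoFReport(m.name, np.inf, np.inf, np.inf, np.inf,
                                         np.inf, np.nan, np.nan, np.nan,
                                         m.k_params, data.n, note="fit failed"))
            else:
                reports.append(evaluate_model(
                    m.name, data, lambda x, m=m, v=v: m.cdf(v, x),
                    negll, m.k_params))
        else:
            model, v = m
            v = np.asarray(v, dtype=float)
            negll = float(-np.sum(model.logpdf(v, data.values)))
            reports.append(evaluate_model(
                model.name, data, lambda x, model=model, v=v: model.cdf(v, x),
                negll, model.k_params))
    reports.sort(key=lambda r: r.aic)
    return reports


_COLUMNS = ["model", "negloglik", "AIC", "BIC", "CAIC", "HQIC",
            "KS", "KS_pvalue", "AD"]


def report_frame(reports: Sequence[GoFReport]) -> pd.DataFrame:
    """Tabular view with the report-writer column contract."""
    rows = [{"model": r.model, "negloglik": r.neg_loglik, "AIC": r.aic,
             "BIC": r.bic, "CAIC": r.caic, "HQIC": r.hqic, "KS": r.ks_stat,
             "KS_pvalue": r.ks_pvalue, "AD": r.ad_stat} for r in reports]
    return pd.DataFrame(rows, columns=_COLUMNS)


def reports_to_json(reports: Sequence[GoFReport], **kw) -> str:
    return json.dumps([r.to_dict() for r in reports], **kw)


def reports_from_json(s: str) -> list[GoFReport]:
    return [GoFReport.from_dict(d) for d in json.loads(s)]
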