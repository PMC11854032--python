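"""Monte Carlo harness comparing the five NLW estimation methods.

For each sample size in a grid, ``reps`` samples are drawn from a known
truth by inverse-transform sampling; every requested method is fitted to
the *same* replicate sample, and the mean estimate, bias and mean squared
error are aggregated per raw parameter and per identifiable functional
(lam, k = c*beta, s = alpha/theta**k).  Bias and MSE average over Monte
Carlo replicates.  Per-replicate fit failures (including non-finite
estimates) are counted and excluded from the aggregates, never fatal.

Replicate seeds derive from a single ``numpy.random.SeedSequence`` spawn,
so results are fully deterministic given the scenario seed and identical
whichever subset of methods is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import estimation, nlw
from .estimation import METHODS, FitOptions
from .nlw import NLWParams

__all__ = ["PARAMETER_SETS", "Scenario", "SimStudyResult",
           "bias_mse", "run_scenario", "summary_table"]

# The four simulation truth vectors (alpha, beta, lam, theta, c).
PARAMETER_SETS = {
    "I": NLWParams(alpha=1.65, beta=1.98, lam=0.055, theta=0.59, c=2.5),
    "II": NLWParams(alpha=1.9, beta=1.2, lam=0.07, theta=2.5, c=1.9),
    "III": NLWParams(alpha=1.4, beta=1.2, lam=0.117, theta=1.27, c=1.45),
    "IV": NLWParams(alpha=26.4, beta=15.2, lam=11.7, theta=12.77, c=33.45),
}

_RAW = ("alpha", "lam", "theta", "beta", "c")
_FUNCTIONALS = ("lam", "cbeta", "rate")


@dataclass(frozen=True)
class Scenario:
    """One simulation design cell: truth, sample-size grid, methods, seed."""

    truth: NLWParams
    n_grid: tuple[int, ...] = (20, 50, 100, 200, 300, 500)
    reps: int = 1000
    methods: tuple[str, ...] = METHODS
    seed: int = 0
    set_id: str = ""

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if any(n < 5 for n in self.n_grid):
            raise ValueError("sample sizes below 5 are not supported")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; choose from {METHODS}")

    @classmethod
    def from_set(cls, set_id: str, **kw) -> "Scenario":
        if set_id not in PARAMETER_SETS:
            raise KeyError(f"unknown parameter set {set_id!r}; "
                           f"available: {', '.join(PARAMETER_SETS)}")
        return cls(truth=PARAMETER_SETS[set_id], set_id=set_id, **kw)


@dataclass
class SimStudyResult:
    """Aggregated estimate / bias / MSE (mean and median SE) per cell."""

    scenario: Scenario
    table: pd.DataFrame            # raw parameters, long format
    functionals: pd.DataFrame      # identifiable functionals, long format
    reps_completed: dict = field(default_factory=dict)   # (n, method) -> count
    failure_count: dict = field(default_factory=dict)    # (n, method) -> count


def bias_mse(estimates, truth: float) -> tuple[float, float]:
    """(mean(est) - truth, mean((est - truth)^2)) over Monte Carlo replicates."""
    e = np.asarray(estimates, dtype=float)
    if e.size == 0:
        raise ValueError("bias_mse needs at least one estimate")
    return float(np.mean(e) - truth), float(np.mean((e - truth) ** 2))


def _estimates_of(params: NLWParams) -> dict[str, float]:
    d = {k: getattr(params, k) for k in _RAW}
    ident = params.identifiable()
    d["cbeta"] = ident["k"]
    d["rate"] = ident["s"]
    return d


def run_scenario(s: Scenario, fit_opts: FitOptions | None = None) -> SimStudyResult:
    """Run the full Monte Carlo grid for one scenario.

    ``fit_opts.seed`` is re-derived per replicate so multistart
    perturbations are reproducible; the same replicate datasets are used
    by every method.
    """
    base_opts = fit_opts or FitOptions(n_starts=2, max_iter=1500)
    truth_vals = _estimates_of(s.truth)
    root = np.random.SeedSequence(s.seed)
    cell_seeds = root.spawn(len(s.n_grid))

    rows, frows = [], []
    reps_completed: dict = {}
    failure_count: dict = {}
    for n, cell_ss in zip(s.n_grid, cell_seeds):
        rep_seeds = cell_ss.spawn(s.reps)
        samples = [nlw.rvs(s.truth, n, seed=np.random.default_rng(ss))
                   for ss in rep_seeds]
        for method in s.methods:
            ests: dict[str, list[float]] = {k: [] for k in truth_vals}
            fails = 0
            for rep, sample in enumerate(samples):
                data = nlw.DataSample(sample)
                opts = replace(base_opts,
                               seed=int(rep_seeds[rep].generate_state(1)[0]
                                        % (2 ** 31)))
                res = estimation.fit(data, method, opts)
                if (not res.converged or res.params is None
                        or not all(np.isfinite(v) for v in
                                   _estimates_of(res.params).values())):
                    fails += 1
                    continue
                for k, v in _estimates_of(res.params).items():
                    ests[k].append(v)
            done = s.reps - fails
            reps_completed[(n, method)] = done
            failure_count[(n, method)] = fails
            for param, out in [(q, rows) for q in _RAW] + \
                              [(q, frows) for q in _FUNCTIONALS]:
                if done == 0:
                    est = bias = mse = medse = np.nan
                else:
                    bias, mse = bias_mse(ests[param], truth_vals[param])
                    est = float(np.mean(ests[param]))
                    medse = float(np.median(
                        (np.asarray(ests[param]) - truth_vals[param]) ** 2))
                out.append({"set": s.set_id, "n": n, "method": method,
                            "parameter": param, "est": est, "bias": bias,
                            "mse": mse, "medse": medse})

    cols = ["set", "n", "method", "parameter", "est", "bias", "mse", "medse"]
    return SimStudyResult(scenario=s,
                          table=pd.DataFrame(rows, columns=cols),
                          functionals=pd.DataFrame(frows, columns=cols),
                          reps_completed=reps_completed,
                          failure_count=failure_count)


def summary_table(r: SimStudyResult, functionals: bool = False) -> pd.DataFrame:
    """Long-format summary (columns set, n, method, parameter, est, bias, mse).

    By default the five raw parameters; ``functionals=True`` appends the
    identifiable-functional rows.
    """
    if functionals:
        return pd.concat([r.table, r.functionals], ignore_index=True)
    return r.table.copy()
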