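"""Kinetic model of the initial RNA-adsorption stage.

After mixing, anionic RNA molecules stick sequentially and irreversibly
onto cationic liposomes.  The minimal sequential scheme whose
population law is exactly geometric at every time is the pure-birth
process with rates proportional to (k + 1): a liposome holding k RNA
molecules acquires the next one at rate lambda0 * (k + 1).  At
equilibrium (mean load equal to the RNA-to-liposome ratio r0/L0) the
RNA-per-liposome distribution is geometric on {0, 1, 2, ...} -- the
discrete analog of the exponential law -- with the same result obtained
model-independently from the maximum-entropy principle under a mean
constraint.  A constant-rate variant (whose law is Poisson, not
geometric) is kept as a documented negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AdsorptionModel",
    "RnaLoadDistribution",
    "AdsorptionResult",
    "MeanRatioFit",
    "equilibrium_distribution",
    "maxent_distribution",
    "simulate_adsorption",
    "fit_mean_vs_ratio",
]

RATE_RULES = ("linear", "constant")


class UnreachableTargetError(RuntimeError):
    """Raised when the requested stopping mean cannot be reached."""


@dataclass
class AdsorptionModel:
    """Birth-process parameters for RNA adsorption onto liposomes.

    r0, L0       initial RNA-molecule and liposome counts (set the target
                 mean load <n> = r0/L0);
    lambda0      base adsorption rate (per unit time);
    rate_rule    "linear": rate lambda0*(k+1) for a liposome holding k RNAs
                 (time-t law geometric); "constant": rate lambda0
                 (time-t law Poisson; negative control).
    """

    r0: float
    L0: float
    lambda0: float = 1.0
    rate_rule: str = "linear"

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.L0 <= 0:
            raise ValueError("r0 and L0 must be positive")
        if self.lambda0 < 0:
            raise ValueError("lambda0 must be non-negative")
        if self.rate_rule not in RATE_RULES:
            raise ValueError(f"rate_rule must be one of {RATE_RULES}")

    @property
    def target_mean(self) -> float:
        return self.r0 / self.L0


@dataclass
class RnaLoadDistribution:
    """RNA-per-liposome law: pmf on integers or pdf on the half line."""

    support: np.ndarray
    weights: np.ndarray
    mean: float
    form: str  # "discrete" | "continuum"

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.support.shape != self.weights.shape:
            raise ValueError("support and weights must align")
        if np.any(self.weights < 0):
            raise ValueError("negative probability weight")
        if self.form == "discrete":
            total = self.weights.sum()
            got_mean = float(self.support @ self.weights)
        elif self.form == "continuum":
            total = float(np.trapezoid(self.weights, self.support))
            got_mean = float(np.trapezoid(self.support * self.weights, self.support))
        else:
            raise ValueError("form must be 'discrete' or 'continuum'")
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"law does not normalize: total {total!r}")
        # continuum grids carry quadrature error; discrete must be tight
        mean_tol = 1e-8 if self.form == "discrete" else 1e-4 * max(1.0, self.mean)
        if abs(got_mean - self.mean) > mean_tol:
            raise ValueError(f"stated mean {self.mean} != computed {got_mean}")

    def survival(self, x: np.ndarray) -> np.ndarray:
        """P(X > x) by summation/quadrature on the stored support."""
        x = np.asarray(x, dtype=float)
        if self.form == "discrete":
            cdf = np.cumsum(self.weights)
            idx = np.searchsorted(self.support, x, side="right")
            return 1.0 - np.where(idx > 0, cdf[np.clip(idx - 1, 0, None)], 0.0)
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (self.weights[1:] + self.weights[:-1]) * np.diff(self.support))])
        return 1.0 - np.interp(x, self.support, cdf, left=0.0, right=1.0)

    def entropy(self) -> float:
        w = self.weights[self.weights > 0]
        if self.form == "discrete":
            return float(-(w * np.log(w)).sum())
        raise NotImplementedError("entropy implemented for the discrete form")


def _geometric_support(mean: float, tail_mass: float) -> int:
    """Smallest n such that the geometric tail beyond n is < tail_mass."""
    q = mean / (1.0 + mean)
    if q == 0.0:
        return 1
    return max(2, int(np.ceil(np.log(tail_mass) / np.log(q))) + 2)


def equilibrium_distribution(mean: float, form: str = "discrete",
                             tail_mass: float = 1e-12) -> RnaLoadDistribution:
    """Equilibrium RNA-per-liposome law with the given mean.

    discrete:   geometric on {0,1,2,...}, P(n) = (1/(1+m)) (m/(1+m))**n;
    continuum:  exponential density (1/m) exp(-n/m) -- the large-mean
                limit of the geometric law, used against intensity data.
    """
    if mean < 0:
        raise ValueError("mean must be non-negative")
    if form == "discrete":
        if mean == 0.0:
            return RnaLoadDistribution(np.array([0.0]), np.array([1.0]), 0.0, "discrete")
        nmax = _geometric_support(mean, tail_mass)
        n = np.arange(nmax + 1, dtype=float)
        p = mean / (1.0 + mean)
        pmf = np.exp(n * np.log(p) - np.log1p(mean))
        pmf[-1] += 1.0 - pmf.sum()          # fold residual tail into the last atom
        stated = float(n @ pmf)
        return RnaLoadDistribution(n, pmf, stated, "discrete")
    if form == "continuum":
        if mean <= 0:
            raise ValueError("continuum form requires mean > 0")
        x = np.linspace(0.0, mean * np.log(1.0 / tail_mass), 20001)
        pdf = np.exp(-x / mean) / mean
        area = np.trapezoid(pdf, x)
        pdf = pdf / area
        m = float(np.trapezoid(x * pdf, x))
        return RnaLoadDistribution(x, pdf, m, "continuum")
    raise ValueError("form must be 'discrete' or 'continuum'")


def maxent_distribution(mean: float, tail_mass: float = 1e-12,
                        tol: float = 1e-13) -> RnaLoadDistribution:
    """Maximum-entropy law on {0..nmax} with a fixed mean.

    The entropy maximizer under normalization and a mean constraint is the
    exponential family p_n = exp(-beta*n)/Z; the single dual variable beta
    is found by bracketed root-finding on the mean (a numerically exact
    solution of the constrained maximization).  On the non-negative
    integers this coincides with the geometric law of
    :func:`equilibrium_distribution` up to the support truncation.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    nmax = _geometric_support(mean, tail_mass)
    n = np.arange(nmax + 1, dtype=float)

    def weights_of(beta: float) -> np.ndarray:
        a = -beta * n
        return np.exp(a - a.max())       # stabilized exponential family

    def mean_of(beta: float) -> float:
        w = weights_of(beta)
        return float((n @ w) / w.sum())

    # bracket: beta -> +inf gives mean 0; beta -> -inf gives mean nmax
    lo, hi = -50.0, 50.0
    if not (mean_of(hi) < mean < mean_of(lo)):
        raise RuntimeError("max-ent dual could not be bracketed; "
                           f"mean={mean}, support 0..{nmax}")
    beta = optimize.brentq(lambda b: mean_of(b) - mean, lo, hi, xtol=tol)
    w = weights_of(beta)
    pmf = w / w.sum()
    return RnaLoadDistribution(n, pmf, float(n @ pmf), "discrete")


# --------------------------------------------------------------------------
# stochastic simulation
# --------------------------------------------------------------------------

@dataclass
class AdsorptionResult:
    """Final per-liposome counts plus the (time-ordered) event log."""

    counts: np.ndarray
    events: pd.DataFrame      # columns: time, liposome, new_count
    stop_time: float
    model: AdsorptionModel

    @property
    def empirical_mean(self) -> float:
        return float(self.counts.mean())


def simulate_adsorption(model: AdsorptionModel, n_liposomes: int,
                        seed: int | np.random.Generator = 0,
                        stop: str = "target_mean", t_end: float | None = None,
                        finite_pool: bool = False,
                        max_events: int = 50_000_000) -> AdsorptionResult:
    """Exact stochastic simulation of the adsorption birth process.

    Each liposome evolves as an independent pure-birth process; per-liposome
    event streams are generated in vectorized rounds and merged into a
    global time-ordered log.  ``stop="target_mean"`` truncates the merged
    log at the first event where the empirical mean load reaches r0/L0
    (so the stated equilibrium mean holds exactly up to 1/n granularity);
    ``stop="time"`` keeps all events with time <= ``t_end``.  With
    ``finite_pool=True`` the number of adsorption events is additionally
    capped at the share of the RNA pool owned by the simulated subsample,
    r0 * n_liposomes / L0.
    """
    if n_liposomes < 1:
        raise ValueError("n_liposomes must be >= 1")
    if stop not in ("target_mean", "time"):
        raise ValueError("stop must be 'target_mean' or 'time'")
    if stop == "time" and (t_end is None or t_end < 0):
        raise ValueError("stop='time' requires t_end >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    target_events = None
    if stop == "target_mean":
        target_events = int(np.ceil(model.target_mean * n_liposomes))
        if target_events == 0:
            return AdsorptionResult(np.zeros(n_liposomes, dtype=np.int64),
                                    _empty_events(), 0.0, model)
        if model.lambda0 == 0.0:
            raise UnreachableTargetError("lambda0 = 0: target mean unreachable")
        if target_events > max_events:
            raise UnreachableTargetError(
                f"target mean needs {target_events} events > max_events={max_events}")

    pool_cap = None
    if finite_pool:
        pool_cap = int(np.floor(model.r0 * n_liposomes / model.L0))

    if model.lambda0 == 0.0:
        return AdsorptionResult(np.zeros(n_liposomes, dtype=np.int64),
                                _empty_events(), float(t_end or 0.0), model)

    # horizon: expected mean load at time T is exp(l*T)-1 (linear rule)
    # or l*T (constant rule); start with a margin and extend on demand.
    lam = model.lambda0
    if stop == "time":
        horizon = float(t_end)
    else:
        m_goal = 2.0 * model.target_mean + 5.0
        horizon = (np.log1p(m_goal) / lam if model.rate_rule == "linear"
                   else m_goal / lam)

    # no liposome can ever hold more than the whole simulated pool share
    per_lipo_cap = pool_cap if pool_cap is not None else np.iinfo(np.int64).max

    times = np.zeros(n_liposomes)          # per-liposome clock
    loads = np.zeros(n_liposomes, dtype=np.int64)
    ev_time: list[np.ndarray] = []
    ev_lipo: list[np.ndarray] = []
    total_events = 0
    while True:
        # vectorized rounds: all liposomes whose clock is inside the horizon
        # draw their next waiting time simultaneously
        while True:
            active = (times <= horizon) & (loads < per_lipo_cap)
            if not active.any():
                break
            rates = (lam * (loads[active] + 1.0) if model.rate_rule == "linear"
                     else np.full(active.sum(), lam))
            waits = rng.exponential(1.0 / rates)
            t_new = times[active] + waits
            accept = t_new <= horizon
            idx = np.flatnonzero(active)
            acc_idx = idx[accept]
            times[idx] = np.where(accept, t_new, np.inf)
            if acc_idx.size:
                loads[acc_idx] += 1
                ev_time.append(t_new[accept])
                ev_lipo.append(acc_idx)
                total_events += acc_idx.size
            if total_events > max_events:
                raise UnreachableTargetError("event budget exhausted")
        if stop == "time" or total_events >= target_events:
            break
        # not enough events yet: extend the horizon (memoryless continuation)
        times[np.isinf(times)] = horizon
        horizon *= 1.5

    if total_events == 0:
        return AdsorptionResult(np.zeros(n_liposomes, dtype=np.int64),
                                _empty_events(), float(horizon if stop == "time" else 0.0),
                                model)

    all_t = np.concatenate(ev_time)
    all_l = np.concatenate(ev_lipo)
    order = np.argsort(all_t, kind="stable")
    all_t, all_l = all_t[order], all_l[order]
    n_keep = all_t.size
    if target_events is not None:
        n_keep = min(n_keep, target_events)
    if pool_cap is not None:
        n_keep = min(n_keep, pool_cap)
    all_t, all_l = all_t[:n_keep], all_l[:n_keep]

    counts = np.bincount(all_l, minlength=n_liposomes).astype(np.int64)
    new_count = _running_count(all_l, n_liposomes)
    events = pd.DataFrame({"time": all_t, "liposome": all_l, "new_count": new_count})
    stop_time = float(all_t[-1]) if n_keep else 0.0
    if stop == "time":
        stop_time = float(t_end)
    return AdsorptionResult(counts, events, stop_time, model)


def _running_count(lipo_ids: np.ndarray, n: int) -> np.ndarray:
    seen = np.zeros(n, dtype=np.int64)
    out = np.empty(lipo_ids.size, dtype=np.int64)
    for i, l in enumerate(lipo_ids):
        seen[l] += 1
        out[i] = seen[l]
    return out


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({"time": pd.Series(dtype=float),
                         "liposome": pd.Series(dtype=np.int64),
                         "new_count": pd.Series(dtype=np.int64)})


# --------------------------------------------------------------------------
# linear mean-vs-ratio fit
# --------------------------------------------------------------------------

@dataclass
class MeanRatioFit:
    slope: float
    intercept: float
    r2: float
    slope_se: float
    intercept_se: float
    intercept_consistent_with_zero: bool
    n: int
    diagnostics: dict = field(default_factory=dict)


def fit_mean_vs_ratio(table) -> MeanRatioFit:
    """Least-squares line through (mass ratio, mean load/intensity) pairs.

    The adsorption model predicts the mean RNA load per liposome grows
    linearly with the RNA-to-liposome mass ratio with zero intercept; the
    fit reports whether the intercept is consistent with 0 at the 95%
    level (two-sided t test).
    """
    if isinstance(table, pd.DataFrame):
        cols = list(table.columns)
        if not {"ratio", "mean"}.issubset(cols):
            raise ValueError("DataFrame input needs columns 'ratio' and 'mean'")
        x = table["ratio"].to_numpy(dtype=float)
        y = table["mean"].to_numpy(dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("table must be (ratio, mean) pairs")
        x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct ratio levels")
    res = stats.linregress(x, y)
    dof = x.size - 2
    if res.intercept_stderr > 0:
        tcrit = stats.t.ppf(0.975, dof)
        zero_ok = bool(abs(res.intercept) <= tcrit * res.intercept_stderr)
    else:
        zero_ok = bool(abs(res.intercept) < 1e-12)
    return MeanRatioFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue ** 2), slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        intercept_consistent_with_zero=zero_ok, n=int(x.size))
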