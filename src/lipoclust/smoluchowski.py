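"""Smoluchowski coagulation kinetics for liposome-cluster growth.

Irreversible pairwise aggregation of clusters is described by the
coagulation system

    dn_k/dt = 1/2 * sum_{i+j=k} K_ij n_i n_j  -  n_k * sum_j K_kj n_j,

where ``n_k`` is the number concentration of clusters containing ``k``
monomers and ``K_ij`` is the aggregation kernel.  This module provides

* the closed-form solution for the constant kernel and a monodisperse
  initial condition,
* the Brownian (diffusive) encounter kernel with a fractal radius law,
* deterministic integration of the truncated system,
* the exact finite-population stochastic counterpart
  (Marcus-Lushnikov process, simulated with the Gillespie algorithm),
* the change of variables from cluster-size law to radius-of-gyration
  law, dynamic-scaling (collapse) diagnostics, and growth-curve fits.

Internally, time for the constant kernel is naturally measured in units
of the growth timescale tau = 2 / (K * n0): with x = t/tau the scaled
size distribution n_k/N is geometric with mean 1 + x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "ClusterStateVector",
    "KernelSpec",
    "SmoluchowskiFit",
    "GillespieResult",
    "constant_kernel_solution",
    "brownian_kernel",
    "integrate_ode",
    "simulate_gillespie",
    "rg_distribution_from_counts",
    "exponential_size_density",
    "sample_cluster_sizes",
    "fit_growth",
    "collapse_statistic",
]


class TruncationError(RuntimeError):
    """Raised when the truncated ODE system leaks mass beyond tolerance."""


# --------------------------------------------------------------------------
# state and kernel
# --------------------------------------------------------------------------

@dataclass
class ClusterStateVector:
    """Cluster-size census at one time point.

    ``counts[k-1]`` is the number (concentration) of k-mers, k = 1..kmax.
    """

    t: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D array indexed by k-1")
        if np.any(self.counts < -1e-12):
            raise ValueError("negative cluster counts")

    @property
    def k_values(self) -> np.ndarray:
        return np.arange(1, self.counts.size + 1)

    @property
    def N(self) -> float:
        """Total number of clusters."""
        return float(self.counts.sum())

    @property
    def M(self) -> float:
        """Total monomer mass sum_k k*n_k (conserved)."""
        return float(np.dot(self.k_values, self.counts))

    @property
    def mean_size(self) -> float:
        n = self.N
        return self.M / n if n > 0 else np.nan


@dataclass
class KernelSpec:
    """Aggregation kernel K(i, j).

    kind:
        "constant"  K = K0 for all pairs;
        "brownian"  diffusive encounter kernel with fractal radius law
                    R_k = R1 * k**(1/d_f);
        "patchy"    constant kernel thinned by the patchy-binding factor
                    4 f (1 - f) (size-independent).
    thermal_group:
        k_B*T/eta prefactor group of the Brownian kernel (volume/time).
    """

    kind: str = "constant"
    K0: float = 1.0
    thermal_group: float = 1.0
    d_f: float = 2.0
    R1: float = 1.0
    coverage_f: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "brownian", "patchy"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.K0 < 0 or self.thermal_group < 0 or self.R1 <= 0:
            raise ValueError("kernel parameters must be non-negative (R1 > 0)")
        if self.kind == "brownian" and not (1.0 < self.d_f <= 3.0):
            raise ValueError("brownian kernel requires d_f in (1, 3]")
        if self.kind == "patchy":
            if self.coverage_f is None or not (0.0 <= self.coverage_f <= 1.0):
                raise ValueError("patchy kernel requires coverage_f in [0, 1]")

    @property
    def size_independent(self) -> bool:
        return self.kind in ("constant", "patchy")

    def effective_constant(self) -> float:
        """Pair rate for size-independent kernels."""
        if self.kind == "constant":
            return self.K0
        if self.kind == "patchy":
            f = self.coverage_f
            return self.K0 * 4.0 * f * (1.0 - f)
        raise ValueError("kernel is size-dependent")

    def rate(self, i, j) -> np.ndarray | float:
        """K(i, j) for scalar or array monomer counts."""
        i = np.asarray(i, dtype=float)
        j = np.asarray(j, dtype=float)
        if np.any(i < 1) or np.any(j < 1):
            raise ValueError("cluster sizes must be >= 1")
        if self.size_independent:
            out = np.broadcast_to(self.effective_constant(), np.broadcast_shapes(i.shape, j.shape))
            return float(out) if out.ndim == 0 else np.array(out)
        return brownian_kernel(i, j, self)

    def matrix(self, kmax: int) -> np.ndarray:
        k = np.arange(1, kmax + 1)
        return np.asarray(self.rate(k[:, None], k[None, :]), dtype=float)


def brownian_kernel(i, j, spec: KernelSpec):
    """Brownian encounter kernel K(i,j) = (2/3)(kT/eta)(R_i+R_j)(1/R_i+1/R_j).

    Cluster radii follow the fractal law R_k = R1 * k**(1/d_f).  The kernel
    is symmetric and exactly size-independent on the diagonal:
    K(i, i) = (8/3) * thermal_group for every i -- the weak size dependence
    off the diagonal is what justifies the constant-kernel approximation.
    """
    i = np.asarray(i, dtype=float)
    j = np.asarray(j, dtype=float)
    if np.any(i < 1) or np.any(j < 1):
        raise ValueError("cluster sizes must be >= 1")
    if not (1.0 < spec.d_f <= 3.0):
        raise ValueError("d_f must lie in (1, 3]")
    ri = spec.R1 * i ** (1.0 / spec.d_f)
    rj = spec.R1 * j ** (1.0 / spec.d_f)
    out = (2.0 / 3.0) * spec.thermal_group * (ri + rj) * (1.0 / ri + 1.0 / rj)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# analytic constant-kernel solution
# --------------------------------------------------------------------------

def constant_kernel_solution(n0: float, K: float, t: float,
                             kmax: int | None = None,
                             tail_mass: float = 1e-8) -> ClusterStateVector:
    """Closed-form k-mer concentrations for the constant kernel.

    Starting from a monodisperse state (all mass in monomers, concentration
    ``n0``), with x = t/tau and tau = 2/(K*n0):

        n_k(t) = n0 * x**(k-1) / (1+x)**(k+1)

    hence N(t) = n0/(1+x), mean size 1+x, and n_k/N geometric with
    mean 1+x.  ``kmax`` is chosen adaptively so the truncated tail carries
    less than ``tail_mass`` of the total mass.
    """
    if n0 <= 0 or K <= 0:
        raise ValueError("n0 and K must be positive")
    if t < 0:
        raise ValueError("t must be non-negative")
    tau = 2.0 / (K * n0)
    x = t / tau
    if kmax is None:
        # mass tail of the geometric law: grow until the represented mass
        # captures all but `tail_mass` of n0
        kmax = 64
        while _constant_kernel_counts(n0, x, kmax) @ np.arange(1, kmax + 1) \
                < n0 * (1.0 - tail_mass) and kmax < 2 ** 22:
            kmax *= 2
    counts = _constant_kernel_counts(n0, x, kmax)
    return ClusterStateVector(t=t, counts=counts)


def _constant_kernel_counts(n0: float, x: float, kmax: int) -> np.ndarray:
    k = np.arange(1, kmax + 1)
    if x == 0.0:
        counts = np.zeros(kmax)
        counts[0] = n0
        return counts
    log_nk = np.log(n0) + (k - 1) * np.log(x) - (k + 1) * np.log1p(x)
    return np.exp(log_nk)


# --------------------------------------------------------------------------
# deterministic integration of the truncated system
# --------------------------------------------------------------------------

def integrate_ode(kernel: KernelSpec, initial: ClusterStateVector,
                  t_grid: Sequence[float], kmax: int | None = None,
                  rtol: float = 1e-10, mass_tol: float = 1e-6,
                  max_kmax: int = 1 << 14) -> list[ClusterStateVector]:
    """Integrate the truncated Smoluchowski system on ``t_grid``.

    The truncation is audited through mass conservation: coalescence
    products with i + j > kmax are dropped by the truncation, which shows
    up as mass loss.  If the relative mass drift along the trajectory
    exceeds ``mass_tol``, kmax is doubled and the integration repeated;
    failure to converge raises :class:`TruncationError`.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise ValueError("t_grid must be a non-empty 1-D sequence")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid[0] < initial.t:
        raise ValueError("t_grid starts before the initial state")

    if kmax is None:
        kmax = max(64, initial.counts.size)
    m0 = initial.M
    while True:
        n_init = np.zeros(kmax)
        n_init[: initial.counts.size] = initial.counts
        Kmat = kernel.matrix(kmax)
        ksum = np.add.outer(np.arange(kmax), np.arange(kmax)) + 2  # i + j
        in_range = ksum <= kmax

        def rhs(_t: float, n: np.ndarray) -> np.ndarray:
            pair = Kmat * np.outer(n, n)
            gains = np.bincount(ksum[in_range] - 1, weights=pair[in_range],
                                minlength=kmax + 1)[:kmax]
            loss = n * (Kmat @ n)
            return 0.5 * gains - loss

        sol = integrate.solve_ivp(
            rhs, (float(initial.t), float(t_grid[-1])), n_init,
            t_eval=t_grid, method="LSODA", rtol=rtol,
            atol=m0 * 1e-16 / kmax)
        if not sol.success:
            raise TruncationError(f"ODE integration failed: {sol.message}")
        k_arr = np.arange(1, kmax + 1)
        masses = k_arr @ sol.y
        drift = np.max(np.abs(masses - m0)) / m0
        if drift <= mass_tol:
            break
        if kmax >= max_kmax:
            raise TruncationError(
                f"mass drift {drift:.2e} > {mass_tol:.0e} at kmax={kmax}; "
                "increase max_kmax")
        kmax *= 2

    out = []
    for idx, t in enumerate(t_grid):
        counts = np.clip(sol.y[:, idx], 0.0, None)
        out.append(ClusterStateVector(t=float(t), counts=counts))
    return out


# --------------------------------------------------------------------------
# exact stochastic simulation (Marcus-Lushnikov / Gillespie)
# --------------------------------------------------------------------------

@dataclass
class GillespieResult:
    """Event times plus cluster-size censuses at requested snapshot times."""

    event_times: np.ndarray
    snapshots: list[ClusterStateVector] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)


def simulate_gillespie(kernel: KernelSpec, N0: int, volume: float = 1.0,
                       t_end: float = 1.0, seed: int | np.random.Generator = 0,
                       snapshot_times: Sequence[float] | None = None
                       ) -> GillespieResult:
    """Exact stochastic coagulation of ``N0`` monomers in a volume.

    Each unordered cluster pair (a, b) coalesces with propensity
    K(k_a, k_b)/volume; waiting times between events are exponential with
    the summed propensity.  Mass is conserved exactly at every event.
    Size-independent kernels use an O(1)-per-event particle-list sampler
    (any pair is equally likely); size-dependent kernels use the direct
    method over (i, j) size classes.
    """
    if N0 < 2:
        raise ValueError("N0 must be >= 2")
    if volume <= 0 or t_end < 0:
        raise ValueError("volume must be positive and t_end non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    snap_t = np.asarray([] if snapshot_times is None else snapshot_times, dtype=float)
    if snap_t.size and (np.any(np.diff(snap_t) <= 0) or snap_t[0] < 0):
        raise ValueError("snapshot_times must be non-negative and increasing")

    if kernel.size_independent:
        return _gillespie_uniform(kernel.effective_constant(), N0, volume,
                                  t_end, rng, snap_t)
    return _gillespie_classes(kernel, N0, volume, t_end, rng, snap_t)


def _census(sizes: np.ndarray, n_active: int) -> np.ndarray:
    return np.bincount(sizes[:n_active], minlength=int(sizes[:n_active].max()) + 1)[1:]


def _gillespie_uniform(Keff: float, N0: int, volume: float, t_end: float,
                       rng: np.random.Generator, snap_t: np.ndarray) -> GillespieResult:
    sizes = np.ones(N0, dtype=np.int64)
    n = N0
    t = 0.0
    events: list[float] = []
    snapshots: list[ClusterStateVector] = []
    snap_idx = 0

    def take_snapshots_until(time: float) -> None:
        nonlocal snap_idx
        while snap_idx < snap_t.size and snap_t[snap_idx] <= time:
            snapshots.append(ClusterStateVector(
                t=float(snap_t[snap_idx]),
                counts=_census(sizes, n).astype(float)))
            snap_idx += 1

    while n > 1:
        total = Keff * n * (n - 1) / (2.0 * volume)
        if total <= 0:
            break
        t_next = t + rng.exponential(1.0 / total)
        if t_next > t_end:
            break
        take_snapshots_until(t_next)
        a = int(rng.integers(n))
        b = int(rng.integers(n - 1))
        if b >= a:
            b += 1
        sizes[a] += sizes[b]
        sizes[b] = sizes[n - 1]
        n -= 1
        t = t_next
        events.append(t)
    take_snapshots_until(t_end)
    # remaining snapshots past the last event (state frozen)
    while snap_idx < snap_t.size:
        snapshots.append(ClusterStateVector(
            t=float(snap_t[snap_idx]), counts=_census(sizes, n).astype(float)))
        snap_idx += 1
    return GillespieResult(event_times=np.asarray(events), snapshots=snapshots)


def _gillespie_classes(kernel: KernelSpec, N0: int, volume: float, t_end: float,
                       rng: np.random.Generator, snap_t: np.ndarray) -> GillespieResult:
    counts = np.zeros(N0 + 1, dtype=np.int64)  # counts[k] = number of k-mers
    counts[1] = N0
    kmax_cur = 1
    t = 0.0
    events: list[float] = []
    snapshots: list[ClusterStateVector] = []
    snap_idx = 0
    Kmat = kernel.matrix(N0)  # K(i, j) for i, j = 1..N0

    def take_snapshots_until(time: float) -> None:
        nonlocal snap_idx
        while snap_idx < snap_t.size and snap_t[snap_idx] <= time:
            snapshots.append(ClusterStateVector(
                t=float(snap_t[snap_idx]),
                counts=counts[1:kmax_cur + 1].astype(float)))
            snap_idx += 1

    while counts.sum() > 1:
        m = kmax_cur
        c = counts[1:m + 1].astype(float)
        A = Kmat[:m, :m] * np.outer(c, c)
        np.fill_diagonal(A, np.diag(Kmat[:m, :m]) * c * (c - 1.0))
        iu = np.triu_indices(m)
        props = A[iu] / volume
        props[iu[0] == iu[1]] /= 2.0  # unordered same-size pairs
        total = props.sum()
        if total <= 0:
            break
        t_next = t + rng.exponential(1.0 / total)
        if t_next > t_end:
            break
        take_snapshots_until(t_next)
        choice = rng.choice(props.size, p=props / total)
        i = int(iu[0][choice]) + 1
        j = int(iu[1][choice]) + 1
        counts[i] -= 1
        counts[j] -= 1
        counts[i + j] += 1
        kmax_cur = max(kmax_cur, i + j)
        t = t_next
        events.append(t)
    take_snapshots_until(t_end)
    while snap_idx < snap_t.size:
        snapshots.append(ClusterStateVector(
            t=float(snap_t[snap_idx]), counts=counts[1:kmax_cur + 1].astype(float)))
        snap_idx += 1
    return GillespieResult(event_times=np.asarray(events), snapshots=snapshots)


# --------------------------------------------------------------------------
# radius-of-gyration law and dynamic scaling
# --------------------------------------------------------------------------

def exponential_size_density(mean: float) -> Callable[[np.ndarray], np.ndarray]:
    """Continuum exponential cluster-size density with the given mean."""
    if mean <= 0:
        raise ValueError("mean must be positive")

    def pdf(k: np.ndarray) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        out = np.where(k >= 0, np.exp(-np.clip(k, 0, None) / mean) / mean, 0.0)
        return out

    return pdf


def rg_distribution_from_counts(size_density, a: float, d_f: float,
                                r_grid: np.ndarray | None = None,
                                norm_tol: float = 1e-6):
    """Map a cluster-size law to a radius-of-gyration density.

    With the fractal radius law R(k) = a * k**(1/d_f), a continuum size
    density P_k transforms as

        P_R(R) = P_k(k(R)) * dk/dR,   k(R) = (R/a)**d_f.

    For an exponential P_k this is a Weibull-form density with shape d_f.
    ``size_density`` is either a callable continuum pdf over k >= 0, or a
    discrete pmf array over k = 1, 2, ... (interpolated linearly onto the
    continuum).  Returns ``(r_grid, density)`` with the density numerically
    renormalized to integrate to 1.
    """
    if d_f <= 0:
        raise ValueError("d_f must be positive")
    if a <= 0:
        raise ValueError("monomer scale a must be positive")

    if callable(size_density):
        pdf_k = size_density
        k_hi = _density_upper_k(pdf_k)
    else:
        pmf = np.asarray(size_density, dtype=float)
        if pmf.ndim != 1 or pmf.size < 2 or np.any(pmf < 0):
            raise ValueError("discrete size law must be a non-negative 1-D pmf over k>=1")
        k_nodes = np.arange(1, pmf.size + 1, dtype=float)
        raw = lambda k: np.interp(np.asarray(k, dtype=float), k_nodes, pmf,
                                  left=0.0, right=0.0)
        area = np.trapezoid(raw(np.linspace(1, pmf.size, 4 * pmf.size)),
                            np.linspace(1, pmf.size, 4 * pmf.size))
        if area <= 0:
            raise ValueError("size law has zero mass")
        pdf_k = lambda k: raw(k) / area
        k_hi = float(pmf.size)

    if r_grid is None:
        r_grid = np.linspace(0.0, a * k_hi ** (1.0 / d_f), 2048)
    r_grid = np.asarray(r_grid, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        k_of_r = (r_grid / a) ** d_f
        jac = d_f * r_grid ** (d_f - 1.0) / a ** d_f
    dens = pdf_k(k_of_r) * jac
    dens = np.where(np.isfinite(dens), dens, 0.0)
    area = np.trapezoid(dens, r_grid)
    if area <= 0:
        raise ValueError("transformed density has zero mass on the grid")
    if abs(area - 1.0) > max(norm_tol, 0.05):
        # grid too coarse/narrow to capture the law faithfully
        raise ValueError(f"transformed density integrates to {area:.4f}; widen r_grid")
    return r_grid, dens / area


def _density_upper_k(pdf_k, q: float = 1.0 - 1e-9) -> float:
    """Crude upper quantile of a continuum size density (for grid limits)."""
    k = 1.0
    grid = np.linspace(0, k, 512)
    while np.trapezoid(pdf_k(grid), grid) < q and k < 1e9:
        k *= 2
        grid = np.linspace(0, k, 4096)
    return k


def sample_cluster_sizes(state: ClusterStateVector, n: int,
                         rng: np.random.Generator,
                         smooth: bool = False) -> np.ndarray:
    """Draw ``n`` cluster sizes from a census, with optional lattice smoothing.

    With ``smooth=True`` a U(-1/2, 1/2) jitter is added (smoothed bootstrap):
    measured cluster sizes and radii are continuous quantities while the
    simulated census lives on the integer lattice.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w = state.counts / state.N
    ks = rng.choice(state.k_values, size=n, p=w).astype(float)
    if smooth:
        ks = np.clip(ks + rng.uniform(-0.5, 0.5, size=n), 0.5, None)
    return ks


def collapse_statistic(samples_by_time: Sequence[np.ndarray]) -> float:
    """Dynamic-scaling diagnostic: max pairwise KS distance of scaled samples.

    Each sample set is divided by its own mean; the statistic is the maximum
    two-sample Kolmogorov-Smirnov distance over all pairs of time points.
    Small values indicate that the distribution, rescaled by its mean, is
    time-invariant (dynamic scaling).
    """
    sets = [np.asarray(s, dtype=float) for s in samples_by_time]
    if len(sets) < 2:
        raise ValueError("need samples from at least two time points")
    scaled = []
    for s in sets:
        if s.size < 2:
            raise ValueError("each time point needs at least two samples")
        m = s.mean()
        if m <= 0:
            raise ValueError("sample means must be positive for scaling")
        scaled.append(s / m)
    stat = 0.0
    for i in range(len(scaled)):
        for j in range(i + 1, len(scaled)):
            stat = max(stat, stats.ks_2samp(scaled[i], scaled[j]).statistic)
    return float(stat)


# --------------------------------------------------------------------------
# growth-curve fits
# --------------------------------------------------------------------------

@dataclass
class SmoluchowskiFit:
    """Fitted growth parameters.

    tau   growth timescale from N(t) = n0 / (1 + t/tau)
    n0    initial cluster concentration from the same fit
    z     late-time power-law exponent of mean R_g (R_g ~ a * t**z)
    a     power-law prefactor (monomer R_g scale, µm)
    """

    tau: float | None = None
    n0: float | None = None
    z: float | None = None
    a: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive")


def fit_growth(t: Sequence[float], N: Sequence[float] | None = None,
               mean_rg: Sequence[float] | None = None,
               late_window: float | None = None) -> SmoluchowskiFit:
    """Fit the growth timescale and/or the power-law growth exponent.

    * ``N`` given: nonlinear least squares of N(t) = n0/(1 + t/tau).
    * ``mean_rg`` given: log-log ordinary least squares of mean R_g vs t
      over the late-time window t >= ``late_window`` (default: 3*tau_hat
      when the N-fit is available, otherwise all strictly positive t).
    """
    t = np.asarray(t, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 time points")
    if N is None and mean_rg is None:
        raise ValueError("provide N and/or mean_rg")
    fitres = SmoluchowskiFit()

    if N is not None:
        N = np.asarray(N, dtype=float)
        if N.size != t.size:
            raise ValueError("N and t must have equal length")
        n0_guess = float(N.max())
        # crude tau guess: time at which N halves
        half = np.argmin(np.abs(N - n0_guess / 2))
        tau_guess = float(t[half]) if t[half] > 0 else float(t[t > 0].min() if np.any(t > 0) else 1.0)
        popt, pcov = optimize.curve_fit(
            lambda tt, n0, tau: n0 / (1.0 + tt / tau), t, N,
            p0=(n0_guess, max(tau_guess, 1e-12)), maxfev=10000)
        fitres.n0, fitres.tau = float(popt[0]), float(popt[1])
        resid = N - popt[0] / (1.0 + t / popt[1])
        ss_tot = float(np.sum((N - N.mean()) ** 2))
        fitres.diagnostics["N_fit_r2"] = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
        fitres.diagnostics["N_fit_se"] = np.sqrt(np.diag(pcov)).tolist()

    if mean_rg is not None:
        rg = np.asarray(mean_rg, dtype=float)
        if rg.size != t.size:
            raise ValueError("mean_rg and t must have equal length")
        if late_window is None:
            late_window = 3.0 * fitres.tau if fitres.tau is not None else 0.0
        sel = (t > 0) & (t >= late_window) & (rg > 0) & np.isfinite(rg)
        if sel.sum() < 3:
            raise ValueError("fewer than 3 usable points in the late-time window")
        res = stats.linregress(np.log(t[sel]), np.log(rg[sel]))
        fitres.z = float(res.slope)
        fitres.a = float(np.exp(res.intercept))
        fitres.diagnostics.update(
            powerlaw_window_start=float(late_window),
            powerlaw_n_points=int(sel.sum()),
            powerlaw_r2=float(res.rvalue ** 2),
            powerlaw_slope_se=float(res.stderr),
        )
    return fitres
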