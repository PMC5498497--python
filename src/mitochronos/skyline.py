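"""Bayesian skyline inference of effective female population size.

Given a dated genealogy (coalescent event times in years before present,
plus sampling times for dated tips), the classic skyline model groups the
coalescent intervals into ``m`` contiguous groups, each with its own
constant Ne, and samples group sizes and sizes-of-Ne by Metropolis–Hastings
under a log-uniform Ne prior. For mtDNA the coalescent Ne is directly the
effective number of females; times are converted to generations with the
generation time (6 years for buffalo by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class Genealogy:
    """Coalescent event times and tip sampling times, in years before present."""

    coal_times: list[float]
    sample_times: list[float]
    n_tips: int

    def __post_init__(self) -> None:
        self.coal_times = sorted(float(t) for t in self.coal_times)
        self.sample_times = sorted(float(t) for t in self.sample_times)
        if len(self.sample_times) != self.n_tips:
            raise ValueError("need one sampling time per tip")
        if len(self.coal_times) != self.n_tips - 1:
            raise ValueError("a genealogy of n tips has exactly n-1 coalescences")
        if any(t < 0 for t in self.coal_times + self.sample_times):
            raise ValueError("times must be non-negative")
        # lineage count check: >=2 active at each coalescence
        for k, t in zip(self._lineages_at_coalescences(), self.coal_times):
            if k < 2:
                raise ValueError(f"fewer than 2 active lineages at coalescence {t}")

    def _lineages_at_coalescences(self) -> list[int]:
        out = []
        for i, t in enumerate(self.coal_times):
            sampled = sum(1 for s in self.sample_times if s <= t)
            out.append(sampled - i)
        return out

    @property
    def span(self) -> float:
        return self.coal_times[-1]


def genealogy_from_tree(tree) -> Genealogy:
    """Extract coalescent/sampling times (years) from a dated tree."""
    coal = [n.age for n in tree.postorder() if not n.is_leaf]
    tips = [(n.age if n.age is not None else n.tip_age) for n in tree.leaves()]
    if any(a is None for a in coal):
        raise ValueError("tree is not dated; run the clock first")
    return Genealogy(coal, tips, len(tips))


@dataclass
class PiecewiseConstant:
    """Ne(t): values[i] on [times[i], times[i+1]); times[0] must be 0."""

    times: np.ndarray  # ascending, generations (or any unit), starts at 0
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times[0] != 0 or len(self.times) != len(self.values):
            raise ValueError("need times starting at 0, one value per interval")

    def at(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.values[idx])


def coalescent_loglik(
    gen: Genealogy, pop_fn: PiecewiseConstant, generation_time: float = 6.0
) -> float:
    """Log density of the genealogy under a piecewise-constant coalescent.

    Σ over inter-event intervals of −k(k−1)/(2Ne)·Δτ plus −log Ne at every
    coalescence, with k the active lineage count and τ in generations.
    Nonpositive Ne yields −inf (an MCMC rejection, not an exception).
    """
    g = generation_time
    coal = [t / g for t in gen.coal_times]
    samp = [t / g for t in gen.sample_times]
    events = sorted(
        [(t, +1) for t in samp] + [(t, -1) for t in coal], key=lambda e: (e[0], -e[1])
    )
    breaks = sorted(set([e[0] for e in events]) | set(pop_fn.times.tolist()))
    ll = 0.0
    k = 0
    ei = 0
    prev = 0.0
    for t in breaks:
        if t > prev:
            # Ne and the lineage count k are both constant on [prev, t)
            ne = pop_fn.at(prev)
            if ne <= 0:
                return -math.inf
            ll -= k * (k - 1) / (2.0 * ne) * (t - prev)
        while ei < len(events) and events[ei][0] == t:
            _, kind = events[ei]
            if kind == +1:
                k += 1
            else:
                ne = pop_fn.at(t)
                if ne <= 0:
                    return -math.inf
                ll -= math.log(ne)
                k -= 1
            ei += 1
        prev = t
    return ll


@dataclass
class SkylineTrajectory:
    times: np.ndarray  # years before present, ascending from 0
    median_Nef: np.ndarray
    hpd_lower: np.ndarray
    hpd_upper: np.ndarray
    group_boundaries: list[float]  # years, posterior-mean group ends
    generation_time: float
    ess: float
    converged: bool
    samples: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_years": self.times,
                "median_Nef": self.median_Nef,
                "hpd_lower": self.hpd_lower,
                "hpd_upper": self.hpd_upper,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def at(self, time_years: float) -> tuple[float, float, float]:
        """(median, hpd_lo, hpd_hi) interpolated at a time in years."""
        if not (self.times[0] <= time_years <= self.times[-1]):
            raise ValueError(f"time {time_years} outside the trajectory span")
        m = float(np.interp(time_years, self.times, self.median_Nef))
        lo = float(np.interp(time_years, self.times, self.hpd_lower))
        hi = float(np.interp(time_years, self.times, self.hpd_upper))
        return m, lo, hi

    def plot(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        ax.fill_between(self.times / 1000.0, self.hpd_lower, self.hpd_upper,
                        alpha=0.3, label="95% HPD")
        ax.plot(self.times / 1000.0, self.median_Nef, "k-", label="median")
        ax.set_xlabel("Kya")
        ax.set_ylabel("effective number of females")
        ax.set_yscale("log")
        ax.invert_xaxis()
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    m = max(1, int(math.ceil(mass * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def effective_sample_size(trace: np.ndarray) -> float:
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < 10 or np.allclose(x, x[0]):
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * x.var())
    # Geyer initial positive sequence truncation
    s = 0.0
    for lag in range(1, n // 2):
        pair = acf[2 * lag - 1] + acf[2 * lag] if 2 * lag < n else acf[2 * lag - 1]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def run_skyline_mcmc(
    gen: Genealogy,
    m_groups: int = 10,
    iters: int = 500_000,
    thin: int = 100,
    seed: int = 0,
    generation_time: float = 6.0,
    burnin_frac: float = 0.10,
    prior_bounds: tuple[float, float] = (1e-2, 1e9),
    grid_points: int = 100,
    keep_samples: bool = False,
) -> SkylineTrajectory:
    """Metropolis–Hastings sampling of the skyline posterior.

    Proposals: log-scale random walk on one Ne (acceptance reduces to the
    likelihood ratio under the log-uniform prior) and shifts of one interval
    between adjacent groups. Returns post-burn-in medians and 95% HPDs on a
    uniform grid over [0, TMRCA] in years; an effective sample size of the
    log-likelihood trace below 100 flags non-convergence (with a warning).
    """
    n_int = gen.n_tips - 1
    if not (1 <= m_groups <= n_int):
        raise ValueError("m_groups must be between 1 and n_tips - 1")
    rng = np.random.default_rng(seed)
    lo, hi = prior_bounds

    coal_gen = np.array(gen.coal_times) / generation_time
    # initial state: equal group sizes; Ne from the mean pairwise coalescent time
    sizes = [n_int // m_groups] * m_groups
    for i in range(n_int - sum(sizes)):
        sizes[i] += 1
    ne0 = float(np.clip(np.mean(coal_gen), lo * 10, hi / 10))
    nes = [ne0] * m_groups

    def boundaries(szs) -> np.ndarray:
        ends = np.cumsum(szs)[:-1]
        return np.concatenate([[0.0], coal_gen[ends - 1]])

    def loglik(szs, vals) -> float:
        pop = PiecewiseConstant(boundaries(szs), np.array(vals))
        return coalescent_loglik(gen, pop, generation_time)

    cur_ll = loglik(sizes, nes)
    grid = np.linspace(0.0, gen.span, grid_points)
    kept_traj = []
    kept_ll = []
    kept_bounds = []
    n_keep_start = int(burnin_frac * iters)
    for it in range(iters):
        if m_groups > 1 and rng.random() < 0.3:
            j = int(rng.integers(0, m_groups - 1))
            delta = 1 if rng.random() < 0.5 else -1
            new_sizes = list(sizes)
            new_sizes[j] -= delta
            new_sizes[j + 1] += delta
            if min(new_sizes) < 1:
                continue
            new_ll = loglik(new_sizes, nes)
            if math.log(rng.random()) < new_ll - cur_ll:
                sizes, cur_ll = new_sizes, new_ll
        else:
            j = int(rng.integers(0, m_groups))
            prop = nes[j] * math.exp(rng.uniform(-0.7, 0.7))
            if not (lo <= prop <= hi):
                continue
            new_nes = list(nes)
            new_nes[j] = prop
            new_ll = loglik(sizes, new_nes)
            if math.log(rng.random()) < new_ll - cur_ll:
                nes, cur_ll = new_nes, new_ll
        if it >= n_keep_start and it % thin == 0:
            b = boundaries(sizes) * generation_time  # years
            idx = np.clip(np.searchsorted(b, grid, side="right") - 1, 0, m_groups - 1)
            kept_traj.append(np.array(nes)[idx])
            kept_ll.append(cur_ll)
            kept_bounds.append(np.append(b[1:], gen.span))
    samples = np.array(kept_traj)
    ess = effective_sample_size(np.array(kept_ll))
    converged = ess >= 100
    if not converged:
        logger.warning("skyline MCMC may not have converged (loglik ESS %.1f < 100)", ess)
    median = np.median(samples, axis=0)
    hpd = np.array([hpd_interval(samples[:, j]) for j in range(samples.shape[1])])
    return SkylineTrajectory(
        times=grid,
        median_Nef=median,
        hpd_lower=hpd[:, 0],
        hpd_upper=hpd[:, 1],
        group_boundaries=list(np.mean(np.array(kept_bounds), axis=0)),
        generation_time=generation_time,
        ess=ess,
        converged=converged,
        samples=samples if keep_samples else None,
    )


def detect_trend_phases(
    traj: SkylineTrajectory,
    epochs: list[tuple[float, float]],
    flat_tol: float = 0.05,
) -> list[str]:
    """Sign of the median-trajectory change across each (start, end) epoch.

    Epochs are (recent, old) times in years before present. 'increase' means
    the median grows toward the present across the epoch; changes smaller
    than ``flat_tol`` (relative) are 'flat'.
    """
    out = []
    for start, end in epochs:
        if start > end:
            start, end = end, start
        recent, _, _ = traj.at(start)
        old, _, _ = traj.at(end)
        if old <= 0:
            out.append("flat")
            continue
        rel = (recent - old) / old
        if abs(rel) < flat_tol:
            out.append("flat")
        elif rel > 0:
            out.append("increase")
        else:
            out.append("decrease")
    return out
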