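import math

import numpy as np
import pytest

from mitochronos.skyline import (
    Genealogy,
    PiecewiseConstant,
    coalescent_loglik,
    detect_trend_phases,
    effective_sample_size,
    genealogy_from_tree,
    hpd_interval,
    run_skyline_mcmc,
)


def oracle_loglik(gen, pop, g):
    """Independent midpoint-count reimplementation of the skyline density."""
    coal = [t / g for t in gen.coal_times]
    samp = [t / g for t in gen.sample_times]
    breaks = sorted(set(coal) | set(samp) | set(pop.times.tolist()))
    ll = 0.0
    for a, b in zip(breaks, breaks[1:]):
        mid = 0.5 * (a + b)
        k = sum(1 for s in samp if s < mid) - sum(1 for c in coal if c < mid)
        ll -= k * (k - 1) / (2.0 * pop.at(mid)) * (b - a)
    for t in coal:
        ll -= math.log(pop.at(t))
    return ll


def _random_genealogy(rng, n=None):
    n = n or int(rng.integers(3, 12))
    coal = np.sort(rng.uniform(10, 5000, size=n - 1))
    samp = [0.0] * n
    if rng.random() < 0.5:  # throw in an ancient tip below the first event
        samp[-1] = float(rng.uniform(0, coal[0]))
    return Genealogy(list(coal), samp, n)


# ---------------------------------------------------------------------------
# likelihood


def test_two_tip_closed_form():
    g = 6.0
    gen = Genealogy([600.0], [0.0, 0.0], 2)
    pop = PiecewiseConstant([0.0], [100.0])
    # tau = 100 generations: -tau/Ne - log Ne, maximized at Ne = tau
    assert coalescent_loglik(gen, pop, g) == pytest.approx(-1.0 - math.log(100.0))
    better = coalescent_loglik(gen, PiecewiseConstant([0.0], [100.0]), g)
    worse = coalescent_loglik(gen, PiecewiseConstant([0.0], [30.0]), g)
    assert better > worse


def test_no_event_interval_is_pure_survival():
    # three lineages waiting over [0, tau) contribute -3·Δτ/Ne... via k(k-1)/2
    gen = Genealogy([1200.0, 2400.0], [0.0, 0.0, 0.0], 3)
    pop = PiecewiseConstant([0.0], [50.0])
    g = 6.0
    expected = (
        -3 * (200.0) / 50.0          # k=3 over 200 generations
        - math.log(50.0)
        - 1 * (200.0) / 50.0         # k=2 over the next 200
        - math.log(50.0)
    )
    assert coalescent_loglik(gen, pop, g) == pytest.approx(expected)


def test_nonpositive_ne_gives_minus_infinity_not_exception():
    gen = Genealogy([600.0], [0.0, 0.0], 2)
    assert coalescent_loglik(gen, PiecewiseConstant([0.0], [-5.0]), 6.0) == -math.inf


def test_likelihood_matches_independent_oracle():
    rng = np.random.default_rng(99)
    for _ in range(25):
        gen = _random_genealogy(rng)
        times = np.sort(np.concatenate([[0.0], rng.uniform(1, 800, size=3)]))
        pop = PiecewiseConstant(times, rng.uniform(10, 1e4, size=4))
        a = coalescent_loglik(gen, pop, 6.0)
        b = oracle_loglik(gen, pop, 6.0)
        assert a == pytest.approx(b, abs=1e-10)


def test_genealogy_validation():
    with pytest.raises(ValueError):
        Genealogy([100.0], [0.0, 0.0, 0.0], 3)  # n-1 coalescences required
    with pytest.raises(ValueError):
        Genealogy([100.0, 50.0], [0.0, 200.0, 200.0], 3)  # <2 lineages at t=50


# ---------------------------------------------------------------------------
# MCMC


def test_seeded_runs_are_identical():
    rng = np.random.default_rng(5)
    gen = _random_genealogy(rng, n=10)
    a = run_skyline_mcmc(gen, m_groups=3, iters=3000, thin=10, seed=42)
    b = run_skyline_mcmc(gen, m_groups=3, iters=3000, thin=10, seed=42)
    assert np.array_equal(a.median_Nef, b.median_Nef)
    assert np.array_equal(a.hpd_lower, b.hpd_lower)


def test_single_group_median_matches_quadrature_posterior():
    from mitochronos.synthetic_data import DemographicModel, simulate_genealogy

    dm = DemographicModel(epochs=[(0, math.inf, 1000.0)])
    gen, _ = simulate_genealogy(dm, 40, seed=8)
    traj = run_skyline_mcmc(gen, m_groups=1, iters=25_000, thin=10, seed=3)
    # numerical posterior for the single Ne under the log-uniform prior
    nes = np.geomspace(1e-2, 1e9, 20_000)
    logpost = np.array([
        coalescent_loglik(gen, PiecewiseConstant([0.0], [ne]), 6.0) for ne in nes
    ]) - np.log(nes)
    w = np.exp(logpost - logpost.max())
    cdf = np.cumsum(w * np.gradient(nes))
    cdf /= cdf[-1]
    median_quad = float(np.interp(0.5, cdf, nes))
    assert traj.median_Nef[0] == pytest.approx(median_quad, rel=0.05)


def test_time_rescaling_invariance():
    rng = np.random.default_rng(12)
    gen = _random_genealogy(rng, n=12)
    c = 3.0
    scaled = Genealogy([t * c for t in gen.coal_times],
                       [t * c for t in gen.sample_times], gen.n_tips)
    a = run_skyline_mcmc(gen, m_groups=2, iters=4000, thin=20, seed=1,
                         generation_time=6.0)
    b = run_skyline_mcmc(scaled, m_groups=2, iters=4000, thin=20, seed=1,
                         generation_time=6.0 * c)
    assert np.allclose(a.median_Nef, b.median_Nef)
    assert np.allclose(b.times, a.times * c)


def test_prior_bounds_smoke():
    from mitochronos.synthetic_data import DemographicModel, simulate_genealogy

    dm = DemographicModel(epochs=[(0, math.inf, 1000.0)])
    gen, _ = simulate_genealogy(dm, 50, seed=21)
    base = run_skyline_mcmc(gen, m_groups=1, iters=20_000, thin=10, seed=2,
                            prior_bounds=(1e-2, 1e9))
    wide = run_skyline_mcmc(gen, m_groups=1, iters=20_000, thin=10, seed=2,
                            prior_bounds=(1e-4, 1e11))
    assert wide.median_Nef[0] == pytest.approx(base.median_Nef[0], rel=0.05)


def test_m_groups_bounds():
    gen = Genealogy([100.0, 200.0], [0.0] * 3, 3)
    with pytest.raises(ValueError):
        run_skyline_mcmc(gen, m_groups=5, iters=100, thin=10)


# ---------------------------------------------------------------------------
# summaries


def test_hpd_interval_is_shortest():
    x = np.concatenate([np.zeros(97), [50.0, 60.0, 70.0]])
    lo, hi = hpd_interval(x, 0.95)
    assert (lo, hi) == (0.0, 0.0)
    # uniform samples: the shortest 95% interval has width 0.95 of the range
    # (its position is tie-broken arbitrarily)
    sym = np.linspace(-1, 1, 1001)
    lo, hi = hpd_interval(sym, 0.95)
    assert hi - lo == pytest.approx(1.9, abs=0.01)
    assert -1 <= lo < hi <= 1


def test_effective_sample_size_of_iid_noise():
    rng = np.random.default_rng(0)
    x = rng.normal(size=2000)
    assert effective_sample_size(x) > 1000


def test_trend_phase_signs_and_errors():
    from mitochronos.skyline import SkylineTrajectory

    times = np.linspace(0, 1000, 11)
    rising = SkylineTrajectory(
        times=times, median_Nef=np.linspace(2000, 1000, 11),
        hpd_lower=np.full(11, 500.0), hpd_upper=np.full(11, 4000.0),
        group_boundaries=[], generation_time=6.0, ess=500.0, converged=True,
    )
    assert detect_trend_phases(rising, [(0, 500), (500, 1000)]) == ["increase", "increase"]
    flat = SkylineTrajectory(
        times=times, median_Nef=np.full(11, 1000.0),
        hpd_lower=np.full(11, 500.0), hpd_upper=np.full(11, 2000.0),
        group_boundaries=[], generation_time=6.0, ess=500.0, converged=True,
    )
    assert detect_trend_phases(flat, [(0, 1000)]) == ["flat"]
    with pytest.raises(ValueError):
        detect_trend_phases(flat, [(0, 2000)])


def test_genealogy_from_dated_tree():
    from mitochronos.parsimony_tree import PhyloTree

    tree = PhyloTree.from_newick("((a:100,b:100):50,(c:120,d:120):30);",
                                 lengths="age")
    gen = genealogy_from_tree(tree)
    assert gen.n_tips == 4 and len(gen.coal_times) == 3
    assert max(gen.coal_times) == pytest.approx(150.0)
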