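import math

import numpy as np
import pytest

from mitochronos.clock_dating import (
    Calibration,
    clock_lrt,
    fit_clock,
    node_age_report,
    waiting_time,
)
from mitochronos.parsimony_tree import Node, PhyloTree


def _two_tip_tree(k=10):
    root = Node()
    a, b = Node("a"), Node("b")
    root.add(a)
    root.add(b)
    a.k = b.k = k
    return PhyloTree(root)


def _balanced_four(k_tips=20, k_internal=30):
    root, ab, cd = Node(), Node(), Node()
    root.add(ab)
    root.add(cd)
    for nm, parent in (("a", ab), ("b", ab), ("c", cd), ("d", cd)):
        leaf = parent.add(Node(nm))
        leaf.k = k_tips
    ab.k = cd.k = k_internal
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# fitting


def test_closed_form_rate_with_fixed_root():
    # k_tot/(L·t_tot): (10+10)/(1000·2·100Ky) = 1e-4 per site per Ky
    tree = _two_tip_tree()
    fit = fit_clock(tree, [Calibration(["a", "b"], 100_000.0, mode="fixed")],
                    1000.0, n_starts=1)
    assert fit.rate == pytest.approx(1.0e-4, rel=1e-6)
    assert fit.rate_se == pytest.approx(1.0e-4 / math.sqrt(20), rel=1e-3)
    assert tree.root.age_se == 0.0  # pinned by the fixed calibration


def test_symmetric_four_taxon_ages():
    tree = _balanced_four()
    fit = fit_clock(tree, [Calibration(list("abcd"), 100_000.0, age_sd=10_000.0)],
                    1000.0, n_starts=3)
    # counts 20+30 to the root vs 20 to the split: split at 0.4 of the root age
    assert tree.root.age == pytest.approx(100_000.0, rel=0.02)
    for child in tree.root.children:
        assert child.age == pytest.approx(40_000.0, rel=0.02)
    assert fit.rate == pytest.approx(5.0e-4, rel=0.02)
    # the root's only age information is the Gaussian calibration
    assert tree.root.age_se == pytest.approx(10_000.0, rel=0.05)


def test_scale_equivariance():
    c = 10.0
    t1 = _balanced_four()
    fit1 = fit_clock(t1, [Calibration(list("abcd"), 50_000.0, age_sd=5_000.0)],
                     1000.0, n_starts=1, compute_se=False)
    t2 = _balanced_four()
    fit2 = fit_clock(t2, [Calibration(list("abcd"), 50_000.0 * c, age_sd=5_000.0 * c)],
                     1000.0, n_starts=1, compute_se=False)
    assert fit2.rate == pytest.approx(fit1.rate / c, rel=1e-4)
    assert t2.root.age == pytest.approx(t1.root.age * c, rel=1e-4)


def test_fit_depends_on_counts_only():
    t1 = _balanced_four()
    t2 = _balanced_four()
    for node in t2.postorder():  # same counts, different mutation identities
        node.mutations = [(j, "A", "G") for j in range(node.k)]
    cal = [Calibration(list("abcd"), 100_000.0, age_sd=10_000.0)]
    f1 = fit_clock(t1, cal, 1000.0, n_starts=1, compute_se=False)
    f2 = fit_clock(t2, cal, 1000.0, n_starts=1, compute_se=False)
    assert f2.rate == pytest.approx(f1.rate, rel=1e-9)


def test_ancient_tip_contributes_rate_information():
    tree = _two_tip_tree(k=10)
    for leaf in tree.leaves():
        if leaf.name == "b":
            leaf.tip_age = 50_000.0
    fit = fit_clock(tree, [Calibration(["a", "b"], 100_000.0, mode="fixed")],
                    1000.0, n_starts=1)
    # durations: a: 100 Ky, b: 50 Ky -> r = 20/(1000·150) per Ky
    assert fit.rate == pytest.approx(20 / (1000.0 * 150.0), rel=1e-5)


def test_requires_a_calibration_and_handles_zero_counts():
    tree = _two_tip_tree()
    with pytest.raises(ValueError):
        fit_clock(tree, [], 1000.0)
    empty = _two_tip_tree(k=0)
    fit = fit_clock(empty, [Calibration(["a", "b"], 1000.0, mode="fixed")], 1000.0)
    assert fit.rate == 0.0 and not fit.converged


# ---------------------------------------------------------------------------
# clock test


def test_lrt_accepts_perfect_clock_and_rejects_gross_violation():
    clocklike = PhyloTree.from_newick("((a:10,b:10):5,(c:10,d:10):5);")
    stat, df, p = clock_lrt(clocklike)
    assert stat == pytest.approx(0.0, abs=1e-9) and p > 0.99 and df == 2
    broken = PhyloTree.from_newick("((a:100,b:10):5,(c:10,d:10):5);")
    stat, df, p = clock_lrt(broken)
    assert p < 0.01


def test_lrt_type_one_error_is_near_nominal():
    from mitochronos.synthetic_data import DemographicModel, simulate_genealogy

    dm = DemographicModel(epochs=[(0, math.inf, 1000.0)])
    rng = np.random.default_rng(7)
    n_rep, rejections = 120, 0
    for rep in range(n_rep):
        _, tree = simulate_genealogy(dm, 6, seed=900 + rep)
        for node in tree.postorder():
            if node.parent is not None:
                dt_ky = (node.parent.age - (node.age or 0.0)) / 1000.0
                node.k = int(rng.poisson(3.0 * dt_ky))
        _, _, p = clock_lrt(tree)
        rejections += p < 0.05
    # asymptotic 5% test; binomial noise over 120 replicates
    assert 0.005 <= rejections / n_rep <= 0.125


def test_lrt_needs_enough_leaves():
    with pytest.raises(ValueError):
        clock_lrt(PhyloTree.from_newick("(a:1,b:1);"))


# ---------------------------------------------------------------------------
# conversions and reporting


@pytest.mark.parametrize(
    "rate,units,expected",
    [
        (3.75e-5, 3790, 7.03),        # one synonymous substitution per ~7.03 Ky
        (2.11e-8, 16351.5, 2898.4),   # one mutation per ~2900 yr, mid-length genome
        (1.0, 1.0, 1.0),
    ],
)
def test_waiting_time_values(rate, units, expected):
    assert waiting_time(rate, units) == pytest.approx(expected, rel=5e-3)


def test_waiting_time_rejects_nonpositive_inputs():
    with pytest.raises(ValueError):
        waiting_time(0.0, 100)
    with pytest.raises(ValueError):
        waiting_time(1e-5, -1)


def test_node_age_report_singletons_and_cis():
    tree = _balanced_four()
    fit = fit_clock(tree, [Calibration(list("abcd"), 100_000.0, age_sd=10_000.0)],
                    1000.0, n_starts=1)
    report = node_age_report(fit, {"all": list("abcd"), "pair": ["a", "b"],
                                   "lone": ["a"]})
    by_clade = report.set_index("clade")
    assert math.isnan(by_clade.loc["lone", "T_ky"])  # singletons are n.a.
    row = by_clade.loc["pair"]
    assert row["CI_lo_ky"] == pytest.approx(row["T_ky"] - 1.96 * row["SE_ky"])
    assert row["CI_hi_ky"] == pytest.approx(row["T_ky"] + 1.96 * row["SE_ky"])
    assert bool(row["monophyletic"])


def test_non_monophyletic_clade_is_flagged_but_dated():
    tree = _balanced_four()
    fit = fit_clock(tree, [Calibration(list("abcd"), 100_000.0, age_sd=10_000.0)],
                    1000.0, n_starts=1)
    report = node_age_report(fit, {"mixed": ["a", "c"]})
    row = report.iloc[0]
    assert not row["monophyletic"] and row["T_ky"] > 0
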