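import math

import numpy as np
import pytest

from mitochronos.codon_masking import extract_coding
from mitochronos.genetic_code import translate
from mitochronos.mito_io import GeneEntry, GeneMap
from mitochronos.synthetic_data import (
    DemographicModel,
    EvolutionModel,
    default_genemap,
    make_study_like_dataset,
    simulate_genealogy,
    simulate_sequences,
)

SMALL_GENEMAP = dict(n_genes=3, codon_total=150, rrna_small=30, rrna_large=30,
                     control_length=90, minus_strand_gene=2)


def _small_genemap(reference_id="t0"):
    return default_genemap(reference_id=reference_id, **SMALL_GENEMAP)


# ---------------------------------------------------------------------------
# models


def test_demography_must_tile_time():
    with pytest.raises(ValueError):
        DemographicModel(epochs=[(0, 100.0, 50.0)])  # does not reach inf
    with pytest.raises(ValueError):
        DemographicModel(epochs=[(0, 100.0, 50.0), (200.0, math.inf, 50.0)])
    dm = DemographicModel(epochs=[(0, 100.0, 50.0), (100.0, math.inf, 20.0)])
    assert dm.ne_at(0) == 50.0 and dm.ne_at(150.0) == 20.0


def test_evolution_model_rates_are_normalized():
    evo = EvolutionModel(p_invariant=0.25, n_categories=6)
    Q = evo.rate_matrix()
    pi = np.asarray(evo.base_freqs)
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
    assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)
    cats = evo.category_rates()
    # mean over all sites (incl. the invariant class) is one
    assert cats.mean() * (1 - evo.p_invariant) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# genealogies vs coalescent theory


def test_pair_coalescent_time_matches_expectation():
    ne, g = 500.0, 6.0
    dm = DemographicModel(epochs=[(0, math.inf, ne)], generation_time=g)
    times = []
    for seed in range(2000):
        gen, _ = simulate_genealogy(dm, 2, seed=seed)
        times.append(gen.coal_times[0] / g)
    mean, se = np.mean(times), np.std(times) / math.sqrt(len(times))
    assert abs(mean - ne) < 3 * se + 1e-9


def test_total_tree_length_matches_harmonic_expectation():
    ne, g, n = 300.0, 6.0, 10
    dm = DemographicModel(epochs=[(0, math.inf, ne)], generation_time=g)
    expected = 2 * ne * sum(1.0 / k for k in range(1, n))
    lengths = []
    for seed in range(600):
        _, tree = simulate_genealogy(dm, n, seed=3000 + seed)
        total = sum((node.parent.age - node.age) / g
                    for node in tree.postorder() if node.parent is not None)
        lengths.append(total)
    mean, se = np.mean(lengths), np.std(lengths) / math.sqrt(len(lengths))
    assert abs(mean - expected) < 3 * se


def test_bottleneck_concentrates_coalescences():
    g = 6.0
    flat = DemographicModel(epochs=[(0, math.inf, 2000.0)], generation_time=g)
    squeeze = DemographicModel(
        epochs=[(0, 600.0, 2000.0), (600.0, 1200.0, 20.0), (1200.0, math.inf, 2000.0)],
        generation_time=g,
    )
    def frac_in_window(dm):
        inside = total = 0
        for seed in range(150):
            gen, _ = simulate_genealogy(dm, 12, seed=seed)
            for t in gen.coal_times:
                total += 1
                inside += 600.0 <= t < 1200.0
        return inside / total
    assert frac_in_window(squeeze) > frac_in_window(flat) + 0.2


def test_dated_tips_enter_at_their_age():
    dm = DemographicModel(epochs=[(0, math.inf, 100.0)])
    gen, tree = simulate_genealogy(dm, 4, tip_ages=[0, 0, 0, 900.0], seed=5)
    assert sorted(gen.sample_times)[-1] == pytest.approx(900.0)
    assert min(t for t in gen.coal_times) >= 0


# ---------------------------------------------------------------------------
# sequence simulation


def test_zero_rate_keeps_sequences_identical():
    dm = DemographicModel(epochs=[(0, math.inf, 200.0)])
    _, tree = simulate_genealogy(dm, 5, seed=2)
    evo = EvolutionModel(rate=0.0)
    records, truth = simulate_sequences(tree, evo, _small_genemap(), seed=3)
    assert len({r.sequence for r in records}) == 1
    assert all(n.k == 0 for n in tree.postorder() if n.parent is not None)


def test_large_kappa_suppresses_transversions():
    dm = DemographicModel(epochs=[(0, math.inf, 2000.0)])
    _, tree = simulate_genealogy(dm, 6, seed=4)
    evo = EvolutionModel(kappa=1e7, rate=2e-5, p_invariant=0.0)
    _, truth = simulate_sequences(tree, evo, _small_genemap(), seed=6)
    from mitochronos.genetic_code import is_transition

    muts = [m for n in tree.postorder() for m in n.mutations]
    assert len(muts) > 50
    transversions = [m for m in muts if not is_transition(m[1], m[2])]
    assert len(transversions) == 0


def test_branch_counts_match_poisson_expectation():
    # a two-tip tree with a known duration; neutral sites only (no coding)
    from mitochronos.parsimony_tree import Node, PhyloTree

    L, rate, dt = 2000, 1e-8, 500_000.0
    gm = GeneMap(entries=[GeneEntry("rrn", 1, L, "+", "rRNA")], reference_id="x")
    evo = EvolutionModel(rate=rate, p_invariant=0.0,
                         partition_multipliers={"RNA": 1.0})
    counts = []
    for seed in range(150):
        root = Node()
        root.age = dt
        for nm in ("a", "b"):
            leaf = root.add(Node(nm))
            leaf.age = 0.0
        tree = PhyloTree(root)
        _, _ = simulate_sequences(tree, evo, gm, seed=seed)
        counts.extend(n.k for n in tree.postorder() if n.parent is not None)
    mu = rate * L * dt  # = 10 per branch; multiple hits are a <1% correction
    mean, se = np.mean(counts), np.std(counts) / math.sqrt(len(counts))
    assert abs(mean - mu) < 3 * se + 0.15


def test_full_suppression_freezes_the_protein():
    dm = DemographicModel(epochs=[(0, math.inf, 3000.0)])
    _, tree = simulate_genealogy(dm, 6, seed=11)
    gm = _small_genemap()
    evo = EvolutionModel(rate=3e-5, p_invariant=0.0)
    recs_all, _ = simulate_sequences(tree, evo, gm, seed=12, nonsyn_suppression=1.0)
    gm.reference_id = recs_all[0].id
    coding = extract_coding(recs_all, gm)
    proteins = {translate(s) for s in coding.sequences.values()}
    assert len(proteins) == 1  # every nonsynonymous proposal was rejected

    # relaxing the knob admits protein changes (monotone response)
    _, tree2 = simulate_genealogy(dm, 6, seed=11)
    recs_none, _ = simulate_sequences(tree2, evo, gm, seed=12, nonsyn_suppression=0.0)
    gm2 = _small_genemap(reference_id=recs_none[0].id)
    coding2 = extract_coding(recs_none, gm2)
    assert len({translate(s) for s in coding2.sequences.values()}) > 1


# ---------------------------------------------------------------------------
# the study-like fixture


def test_study_fixture_is_deterministic_and_complete():
    a = make_study_like_dataset(seed=9, n_ingroup=16)
    b = make_study_like_dataset(seed=9, n_ingroup=16)
    assert [(r.id, r.sequence) for r in a.records] == [(r.id, r.sequence) for r in b.records]
    assert len(a.records) == 16 + 3
    btypes = {r.btype for r in a.records}
    assert btypes == {"swamp", "river", "outgroup"}
    ancient = next(r for r in a.records if r.id == "ancient1")
    assert ancient.tip_age == pytest.approx(6700.0)
    assert a.truth.n_distinct_sequences >= 2
    # coding geometry matches the mitogenome-scale layout
    coding = extract_coding(a.records, a.genemap)
    assert (coding.length_nt, coding.codon_count) == (11370, 3790)


def test_haplotype_collapse_agrees_with_truth_bundle():
    from mitochronos.mito_io import collapse_haplotypes

    fx = make_study_like_dataset(seed=14, n_ingroup=20)
    ref = next(r for r in fx.records if r.id == fx.reference_id)
    table = collapse_haplotypes(fx.records, ref, fx.genemap)
    assert table.n_members == len(fx.records)
    assert len(table) == fx.truth.n_distinct_sequences
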