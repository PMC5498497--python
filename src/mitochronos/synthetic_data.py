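"""Synthetic mitogenome datasets with known ground truth.

Genealogies come from the piecewise-constant coalescent (msprime), sequences
evolve along the dated tree under HKY with discretized-gamma rate
heterogeneity and an invariant class, in coding/control partitions. Coding
regions obey the vertebrate mitochondrial code: changes that would create a
stop codon are always rejected, other nonsynonymous changes are rejected
with a tunable probability (a simple stand-in for purifying selection that
makes the synonymous/nonsynonymous ratio controllable). Every generator is
a deterministic function of (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import msprime
import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .codon_masking import classify_codon_change
from .genetic_code import STOP, VERTEBRATE_MITO_CODE, complement, revcomp, translate_codon
from .mito_io import CodingIndex, GeneEntry, GeneMap, MitogenomeRecord
from .parsimony_tree import Node, PhyloTree
from .skyline import Genealogy

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# models


@dataclass
class DemographicModel:
    """Piecewise-constant female effective size through time.

    Epochs are (start_year, end_year, Ne_f) tiles of [0, ∞), most recent
    first; the last epoch must end at inf.
    """

    epochs: list[tuple[float, float, float]]
    generation_time: float = 6.0

    def __post_init__(self) -> None:
        eps = sorted(self.epochs, key=lambda e: e[0])
        if eps[0][0] != 0 or not math.isinf(eps[-1][1]):
            raise ValueError("epochs must tile [0, inf)")
        for (s0, e0, n0), (s1, e1, n1) in zip(eps, eps[1:]):
            if e0 != s1:
                raise ValueError("epochs must tile [0, inf) without gaps/overlap")
        if any(ne <= 0 for _, _, ne in eps):
            raise ValueError("Ne must be positive")
        self.epochs = eps

    def ne_at(self, years: float) -> float:
        for s, e, ne in self.epochs:
            if s <= years < e:
                return ne
        return self.epochs[-1][2]


@dataclass
class EvolutionModel:
    """HKY + discretized Γ + invariant sites, with partition multipliers.

    ``rate`` is the mean substitution rate per site per year across all
    sites (the invariant-class correction is folded in); partition
    multipliers scale it per region.
    """

    kappa: float = 20.0
    base_freqs: tuple[float, float, float, float] = (0.33, 0.26, 0.13, 0.28)
    gamma_shape: float = 0.5
    n_categories: int = 8
    p_invariant: float = 0.3
    rate: float = 2.0e-8
    partition_multipliers: dict[str, float] = field(
        default_factory=lambda: {"coding": 1.0, "RNA": 1.0, "control": 5.0}
    )

    def __post_init__(self) -> None:
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if not (0 <= self.p_invariant < 1):
            raise ValueError("p_invariant must be in [0, 1)")
        if self.gamma_shape <= 0 or self.kappa <= 0 or self.rate < 0:
            raise ValueError("kappa, gamma_shape must be positive; rate >= 0")

    def rate_matrix(self) -> np.ndarray:
        """HKY generator normalized to one expected substitution per unit
        of (rate × time)."""
        pi = np.asarray(self.base_freqs)
        Q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                ti = {i, j} in ({_IDX["A"], _IDX["G"]}, {_IDX["C"], _IDX["T"]})
                Q[i, j] = (self.kappa if ti else 1.0) * pi[j]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        return Q / scale

    def category_rates(self) -> np.ndarray:
        """Mean-one discretized gamma rates (category midpoints), rescaled by
        1/(1−p_inv) so the overall mean including invariant sites is 1."""
        k = self.n_categories
        quantiles = (np.arange(k) + 0.5) / k
        rates = gamma_dist.ppf(quantiles, a=self.gamma_shape, scale=1.0 / self.gamma_shape)
        rates = rates / rates.mean()
        return rates / (1.0 - self.p_invariant)


@dataclass
class TruthBundle:
    """Everything the estimators are later asked to recover."""

    tree: PhyloTree  # dated, with true per-branch substitution counts in .k
    branch_counts: dict[str, int]  # newick-identifiable: leafset-keyed
    demography: DemographicModel | None
    evolution: EvolutionModel
    seed: int
    n_distinct_sequences: int | None = None

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "newick_ages": self.tree.newick(lengths="age"),
            "branch_counts": self.branch_counts,
            "evolution": {
                "kappa": self.evolution.kappa,
                "base_freqs": list(self.evolution.base_freqs),
                "gamma_shape": self.evolution.gamma_shape,
                "n_categories": self.evolution.n_categories,
                "p_invariant": self.evolution.p_invariant,
                "rate": self.evolution.rate,
                "partition_multipliers": self.evolution.partition_multipliers,
            },
            "demography": (
                {
                    "epochs": [[s, (e if math.isfinite(e) else None), n]
                               for s, e, n in self.demography.epochs],
                    "generation_time": self.demography.generation_time,
                }
                if self.demography
                else None
            ),
            "n_distinct_sequences": self.n_distinct_sequences,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# genealogy simulation


def _msprime_demography(model: DemographicModel) -> msprime.Demography:
    g = model.generation_time
    dem = msprime.Demography()
    dem.add_population(name="pop", initial_size=model.epochs[0][2])
    for start, _end, ne in model.epochs[1:]:
        dem.add_population_parameters_change(
            time=start / g, initial_size=ne, population="pop"
        )
    return dem


def simulate_genealogy(
    model: DemographicModel,
    n_tips: int,
    tip_ages: list[float] | None = None,
    seed: int = 1,
) -> tuple[Genealogy, PhyloTree]:
    """Coalescent genealogy under the demographic model (haploid, mtDNA).

    ``tip_ages`` (years before present) supports ancient dated tips. Returns
    the event-time summary and the full dated tree (ages in years); leaves
    are named t0..t{n-1} in tip order.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    g = model.generation_time
    tip_ages = list(tip_ages or [0.0] * n_tips)
    if len(tip_ages) != n_tips:
        raise ValueError("need one age per tip")
    samples = [
        msprime.SampleSet(1, population="pop", time=age / g, ploidy=1)
        for age in tip_ages
    ]
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=_msprime_demography(model),
        ploidy=1,
        random_seed=(seed % (2**31 - 2)) + 1,
    )
    ttree = ts.first()
    tree = _tskit_to_phylo(ttree, ts, g)
    gen = Genealogy(
        coal_times=[n.age for n in tree.postorder() if not n.is_leaf],
        sample_times=[l.tip_age for l in tree.leaves()],
        n_tips=n_tips,
    )
    return gen, tree


def _tskit_to_phylo(ttree, ts, generation_time: float) -> PhyloTree:
    nodes: dict[int, Node] = {}

    def build(u) -> Node:
        children = ttree.children(u)
        if not children:
            node = Node(f"t{u}")
        else:
            node = Node()
            for c in children:
                node.add(build(c))
        node.age = ts.node(u).time * generation_time
        node.tip_age = node.age if not children else 0.0
        nodes[u] = node
        return node

    root = build(ttree.root)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# genome layout and root sequences


def default_genemap(
    n_genes: int = 13,
    codon_total: int = 3790,
    rrna_small: int = 600,
    rrna_large: int = 100,
    control_length: int = 900,
    minus_strand_gene: int = 12,
    reference_id: str = "sw001",
) -> GeneMap:
    """A mitogenome-like layout: two rRNAs, ``n_genes`` protein genes (one on
    the minus strand, like ND6) totalling ``codon_total`` codons plus TAA
    stops, and a terminal control region."""
    per = codon_total // n_genes
    codons = [per] * n_genes
    codons[-1] += codon_total - per * n_genes
    entries = [GeneEntry("rrnS", 1, rrna_small, "+", "rRNA")]
    pos = rrna_small + 1
    for i, c in enumerate(codons, start=1):
        length = c * 3 + 3  # CDS + complete stop codon
        strand = "-" if i == minus_strand_gene else "+"
        entries.append(GeneEntry(f"gene{i:02d}", pos, pos + length - 1, strand, "protein"))
        pos += length
    entries.append(GeneEntry("rrnL", pos, pos + rrna_large - 1, "+", "rRNA"))
    pos += rrna_large
    entries.append(GeneEntry("CR", pos, pos + control_length - 1, "+", "control"))
    gm = GeneMap(entries=entries, reference_id=reference_id)
    gm.validate()
    return gm


def random_root_sequence(genemap: GeneMap, evo: EvolutionModel, rng) -> str:
    """A root genome honouring the layout: valid ORFs (no internal stops,
    terminal TAA) on the annotated strand, background drawn from the base
    frequencies elsewhere."""
    sense = [c for c in VERTEBRATE_MITO_CODE if translate_codon(c) != STOP]
    length = max(e.end for e in genemap.entries)
    seq = list("".join(rng.choice(list(BASES), size=length, p=list(evo.base_freqs))))
    for gene in genemap.protein_entries():
        n_codons = gene.length // 3 - 1
        cds = "".join(rng.choice(sense, size=n_codons)) + "TAA"
        if gene.strand == "-":
            cds = revcomp(cds)
        seq[gene.start - 1 : gene.end] = list(cds)
    return "".join(seq)


# ---------------------------------------------------------------------------
# sequence simulation


def simulate_sequences(
    tree: PhyloTree,
    evo: EvolutionModel,
    genemap: GeneMap,
    seed: int = 1,
    nonsyn_suppression: float = 0.8,
    root_sequence: str | None = None,
) -> tuple[list[MitogenomeRecord], TruthBundle]:
    """Evolve sequences down a dated tree and record true branch counts.

    Per-site rates combine a discretized-gamma category (or the invariant
    class) with the partition multiplier of the site's region. Along each
    branch the child state is drawn from the HKY transition matrix for the
    branch duration; proposed coding changes that would create a stop are
    always reverted, other nonsynonymous codon changes are reverted with
    probability ``nonsyn_suppression``. Branch counts (observable substitutions,
    i.e. differing sites between parent and child) are stamped on the tree.
    """
    rng = np.random.default_rng(seed)
    if root_sequence is None:
        root_sequence = random_root_sequence(genemap, evo, rng)
    L = len(root_sequence)
    index = CodingIndex(root_sequence, genemap)

    # per-site rate multiplier: partition × (gamma category | invariant)
    region_mult = np.ones(L)
    for e in genemap.entries:
        key = "coding" if e.kind == "protein" else ("control" if e.kind == "control" else "RNA")
        region_mult[e.start - 1 : e.end] = evo.partition_multipliers.get(key, 1.0)
    cats = evo.category_rates()
    site_cat = rng.integers(0, evo.n_categories, size=L)
    site_rate = cats[site_cat]
    invariant = rng.random(L) < evo.p_invariant
    site_rate[invariant] = 0.0
    site_rate *= region_mult
    # terminal stop codons are conserved: hold their sites invariant so every
    # descendant keeps a readable frame
    for e in genemap.protein_entries():
        for p in range(e.start, e.end + 1):
            if p not in index.by_position:
                site_rate[p - 1] = 0.0

    Q = evo.rate_matrix()
    root = np.array([_IDX[b] for b in root_sequence], dtype=np.int8)
    seqs: dict[int, np.ndarray] = {id(tree.root): root}
    codon_positions = {
        gene: [index.cds_positions[gene][i : i + 3]
               for i in range(0, len(index.cds_positions[gene]), 3)]
        for gene in index.cds
    }
    strand_of = {e.name: e.strand for e in genemap.protein_entries()}
    site_codon: dict[int, tuple[str, int]] = {}
    for gene, cods in codon_positions.items():
        for ci, positions in enumerate(cods):
            for p in positions:
                site_codon[p - 1] = (gene, ci)

    branch_counts: dict[str, int] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_seq = seqs[id(node.parent)]
        dt = (node.parent.age or 0.0) - (node.age if node.age is not None else node.tip_age)
        if dt < 0:
            raise ValueError("tree is not time-consistent (child older than parent)")
        child = parent_seq.copy()
        for rho in np.unique(site_rate):
            if rho == 0:
                continue
            sites = np.nonzero(site_rate == rho)[0]
            P = expm(Q * (evo.rate * rho * dt))
            cum = P.cumsum(axis=1)
            u = rng.random(len(sites))
            child[sites] = (cum[parent_seq[sites]] < u[:, None]).sum(axis=1)
        # purifying selection on coding changes, judged codon-wise
        changed = np.nonzero(child != parent_seq)[0]
        affected: dict[tuple[str, int], None] = {}
        for s in changed:
            if s in site_codon:
                affected.setdefault(site_codon[s], None)
        for gene, ci in affected:
            positions = codon_positions[gene][ci]
            idx0 = [p - 1 for p in positions]
            anc = _orient(parent_seq, idx0, strand_of[gene])
            obs = _orient(child, idx0, strand_of[gene])
            verdict = classify_codon_change(anc, obs)
            if verdict == "identical":
                continue
            hits_stop = translate_codon(obs) == STOP
            if hits_stop or (
                verdict == "nonsynonymous" and rng.random() < nonsyn_suppression
            ):
                child[idx0] = parent_seq[idx0]
        node.k = int((child != parent_seq).sum())
        node.mutations = [
            (int(s), BASES[parent_seq[s]], BASES[child[s]])
            for s in np.nonzero(child != parent_seq)[0]
        ]
        seqs[id(node)] = child
    for node in tree.postorder():
        if node.parent is not None:
            key = ",".join(sorted(tree.leafset(node)))
            branch_counts[key] = node.k

    records = []
    for leaf in tree.leaves():
        seq = "".join(BASES[i] for i in seqs[id(leaf)])
        records.append(MitogenomeRecord(id=leaf.name, sequence=seq, tip_age=leaf.tip_age))
    distinct = len({r.sequence for r in records})
    truth = TruthBundle(
        tree=tree,
        branch_counts=branch_counts,
        demography=None,
        evolution=evo,
        seed=seed,
        n_distinct_sequences=distinct,
    )
    return records, truth


def _orient(seq: np.ndarray, idx0: list[int], strand: str) -> str:
    bases = "".join(BASES[seq[i]] for i in idx0)
    # cds_positions already run 3'->5' for minus-strand genes; complement only
    return bases if strand == "+" else "".join(complement(b) for b in bases)


# ---------------------------------------------------------------------------
# the study-like fixture


STUDY_DEMOGRAPHY = DemographicModel(
    epochs=[
        (0.0, 3_000.0, 50_000.0),       # rapid post-domestication expansion
        (3_000.0, 25_000.0, 5_000.0),   # decline through the LGM and Neolithic
        (25_000.0, 130_000.0, 20_000.0),
        (130_000.0, 200_000.0, 40_000.0),  # older, milder decline
        (200_000.0, math.inf, 20_000.0),
    ],
    generation_time=6.0,
)


@dataclass
class StudyFixture:
    records: list[MitogenomeRecord]
    genemap: GeneMap
    calibrations: list  # of clock_dating.Calibration
    truth: TruthBundle
    outgroup_ids: list[str]
    reference_id: str


def make_study_like_dataset(
    seed: int = 42,
    n_ingroup: int = 100,
    split_years: float = 200_000.0,
    root_years: float = 900_000.0,
    demography: DemographicModel = STUDY_DEMOGRAPHY,
    evo: EvolutionModel | None = None,
    ancient_age: float = 6_700.0,
) -> StudyFixture:
    """A full synthetic dataset shaped like the study design.

    ~100 ingroup tips drawn from two macro-lineages (populations split at
    ``split_years``), two divergent outgroup tips coalescing at 80 Ky and an
    ancient dated tip (6.7 Ky), all hanging from a root at ``root_years``
    that carries the deep (fossil-style) calibration.
    """
    from .clock_dating import Calibration

    evo = evo or EvolutionModel()
    g = demography.generation_time
    n_a = (n_ingroup + 1) // 2
    n_b = n_ingroup - n_a

    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=demography.epochs[0][2])
    dem.add_population(name="B", initial_size=demography.epochs[0][2])
    dem.add_population(name="AB", initial_size=demography.ne_at(split_years))
    for start, _end, ne in demography.epochs[1:]:
        if start < split_years:
            for pop in ("A", "B"):
                dem.add_population_parameters_change(
                    time=start / g, initial_size=ne, population=pop
                )
    dem.add_population_split(time=split_years / g, derived=["A", "B"], ancestral="AB")
    dem.sort_events()
    ts = msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(n_a, population="A", ploidy=1),
            msprime.SampleSet(n_b, population="B", ploidy=1),
        ],
        demography=dem,
        ploidy=1,
        random_seed=(seed % (2**31 - 2)) + 1,
    )
    ingroup = _tskit_to_phylo(ts.first(), ts, g)
    for i, leaf in enumerate(ingroup.leaves()):
        leaf.name = f"sw{i + 1:03d}"
    # macro-lineage labels from the two basal ingroup clades
    names_pop = {leaf.name: "lineageA" for leaf in ingroup.leaves()}
    root_children = sorted(ingroup.root.children, key=lambda c: len(ingroup.leafset(c)))
    if len(root_children) == 2:
        for leaf_name in ingroup.leafset(root_children[0]):
            names_pop[leaf_name] = "lineageB"

    # graft outgroups: ((river1, river2)@80Ky, ancient1)@120Ky, root@900Ky
    root = Node()
    root.age = root_years
    og_inner = Node()
    og_inner.age = 120_000.0
    river = Node()
    river.age = 80_000.0
    r1, r2 = Node("river1"), Node("river2")
    anc = Node("ancient1")
    anc.tip_age = ancient_age
    anc.age = ancient_age
    for leaf in (r1, r2):
        leaf.age = 0.0
        river.add(leaf)
    og_inner.add(river)
    og_inner.add(anc)
    root.add(ingroup.root)
    root.add(og_inner)
    tree = PhyloTree(root)

    records, truth = simulate_sequences(tree, evo, default_genemap(), seed=seed + 1)
    truth.demography = demography
    for rec in records:
        if rec.id.startswith("sw"):
            rec.btype = "swamp"
            rec.population = names_pop.get(rec.id, "lineageA")
            rec.region = "SEAsia"
        elif rec.id.startswith("river"):
            rec.btype = "river"
            rec.population = "river"
        else:
            rec.btype = "outgroup"
            rec.population = "ancient"
    reference_id = "sw001"
    genemap = default_genemap(reference_id=reference_id)
    calibrations = [
        Calibration(target=[r.id for r in records], age_mean=root_years,
                    age_sd=50_000.0, mode="gaussian"),
        Calibration(target=["ancient1"], age_mean=ancient_age, mode="fixed"),
    ]
    return StudyFixture(
        records=records,
        genemap=genemap,
        calibrations=calibrations,
        truth=truth,
        outgroup_ids=["river1", "river2", "ancient1"],
        reference_id=reference_id,
    )


def write_fixture(fixture: StudyFixture, out_dir) -> dict[str, str]:
    """Persist a fixture as FASTA + TSV + JSON; returns the path map."""
    import os

    from .mito_io import write_alignment, write_metadata

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, "alignment.fa"),
        "metadata": os.path.join(out_dir, "metadata.tsv"),
        "genemap": os.path.join(out_dir, "genemap.tsv"),
        "calibrations": os.path.join(out_dir, "calibrations.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_alignment(fixture.records, paths["fasta"])
    write_metadata(fixture.records, paths["metadata"])
    fixture.genemap.to_tsv(paths["genemap"])
    with open(paths["calibrations"], "w") as fh:
        fh.write("target\tage_mean\tage_sd\tmode\n")
        for cal in fixture.calibrations:
            fh.write(
                f"{','.join(cal.target)}\t{cal.age_mean}\t{cal.age_sd}\t{cal.mode}\n"
            )
    fixture.truth.to_json(paths["truth"])
    return paths
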