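import itertools

import pytest
from Bio.Data.CodonTable import unambiguous_dna_by_id

from mitochronos.codon_masking import (
    AncestralAssignment,
    CodingAlignment,
    classify_codon_change,
    extract_coding,
    infer_ancestral,
    mask_nonsynonymous,
)
from mitochronos.genetic_code import translate
from mitochronos.mito_io import GeneEntry, GeneMap, MitogenomeRecord
from mitochronos.parsimony_tree import PhyloTree


# ---------------------------------------------------------------------------
# extraction


def test_two_plus_strand_genes_concatenate_without_stops():
    # two 9-nt genes (2 codons + TAA each) -> 12 nt / 4 codons
    ref = MitogenomeRecord(id="r", sequence="ATGGCTTAA" + "CTTACATAG" + "ACGT")
    gm = GeneMap(
        entries=[
            GeneEntry("g1", 1, 9, "+", "protein"),
            GeneEntry("g2", 10, 18, "+", "protein"),
            GeneEntry("CR", 19, 22, "+", "control"),
        ],
        reference_id="r",
    )
    coding = extract_coding([ref], gm)
    assert (coding.length_nt, coding.codon_count) == (12, 4)
    assert coding.sequences["r"] == "ATGGCT" + "CTTACA"
    genes = [g for g, _, _ in coding.source_map]
    assert genes == ["g1"] * 6 + ["g2"] * 6
    assert [cp for _, _, cp in coding.source_map[:6]] == [1, 2, 3, 1, 2, 3]


def test_minus_strand_gene_is_reverse_complemented():
    from mitochronos.genetic_code import revcomp

    cds = "ATGAAATAA"  # Met Lys stop
    ref = MitogenomeRecord(id="r", sequence=revcomp(cds) + "ACGT")
    gm = GeneMap(
        entries=[
            GeneEntry("nd6", 1, 9, "-", "protein"),
            GeneEntry("CR", 10, 13, "+", "control"),
        ],
        reference_id="r",
    )
    coding = extract_coding([ref], gm)
    assert coding.sequences["r"] == "ATGAAA"
    assert "*" not in translate(coding.sequences["r"])


def test_incomplete_polyadenylation_stop_is_trimmed():
    # 7-nt gene: ATG GCT + trailing T completed by poly-A
    ref = MitogenomeRecord(id="r", sequence="ATGGCTT" + "ACGT")
    gm = GeneMap(
        entries=[
            GeneEntry("g1", 1, 7, "+", "protein"),
            GeneEntry("CR", 8, 11, "+", "control"),
        ],
        reference_id="r",
    )
    coding = extract_coding([ref], gm)
    assert coding.sequences["r"] == "ATGGCT"


def test_frame_violation_names_the_gene():
    ref = MitogenomeRecord(id="r", sequence="ATGGCTA" + "ACGT")  # 7 nt, tail 'A'
    gm = GeneMap(
        entries=[
            GeneEntry("bad", 1, 7, "+", "protein"),
            GeneEntry("CR", 8, 11, "+", "control"),
        ],
        reference_id="r",
    )
    with pytest.raises(ValueError, match="bad"):
        extract_coding([ref], gm)


# ---------------------------------------------------------------------------
# ancestral inference


def _coding(seqs):
    ids = list(seqs)
    L = len(seqs[ids[0]])
    smap = [("g", i + 1, i % 3 + 1) for i in range(L)]
    return CodingAlignment(ids=ids, sequences=dict(seqs), source_map=smap,
                           reference_id=ids[0])


def test_outgroup_consensus_ancestral():
    coding = _coding({"i1": "AAA", "i2": "AAA", "i3": "GAA", "og": "AAA"})
    anc = infer_ancestral(coding, outgroup_ids=["og"])
    assert anc.bases == "AAA" and anc.method == "outgroup"
    assert not anc.unresolved


def test_invariant_column_keeps_shared_base():
    coding = _coding({"a": "CCC", "b": "CCC", "og": "CCC"})
    assert infer_ancestral(coding, outgroup_ids=["og"]).bases == "CCC"


def test_fitch_tie_resolved_toward_outgroup():
    # ((a,b),(c,og)): column split A,G|A,G gives a root tie {A,G}; the
    # outgroup carries G so G wins
    tree = PhyloTree.from_newick("((a:1,b:1):1,(c:1,og:1):1);")
    coding = _coding({"a": "A", "b": "G", "c": "A", "og": "G"})
    anc = infer_ancestral(coding, tree=tree, outgroup_ids=["og"])
    assert anc.bases == "G" and anc.method == "fitch"


def test_outgroup_gap_at_polymorphic_column_is_unresolved():
    coding = _coding({"a": "A", "b": "G", "og": "-"})
    anc = infer_ancestral(coding, outgroup_ids=["og"])
    assert anc.unresolved == frozenset({0})


# ---------------------------------------------------------------------------
# codon-change classification against an exhaustive oracle


def _oracle_aa(codon):
    table = unambiguous_dna_by_id[2]
    return "*" if codon in table.stop_codons else table.forward_table[codon]


def test_single_hit_classification_matches_translation_oracle():
    codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
    checked = 0
    for anc in codons:
        for pos in range(3):
            for base in "ACGT":
                if base == anc[pos]:
                    continue
                obs = anc[:pos] + base + anc[pos + 1 :]
                expected = (
                    "synonymous" if _oracle_aa(anc) == _oracle_aa(obs) else "nonsynonymous"
                )
                assert classify_codon_change(anc, obs) == expected, (anc, obs)
                checked += 1
    assert checked == 64 * 9


def test_multi_hit_synonymous_requires_every_path_step_silent():
    codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
    for anc in codons[::7]:
        for obs in codons[::5]:
            verdict = classify_codon_change(anc, obs)
            if verdict == "synonymous":
                assert _oracle_aa(anc) == _oracle_aa(obs)
                for i in range(3):
                    if obs[i] != anc[i]:
                        single = anc[:i] + obs[i] + anc[i + 1 :]
                        assert _oracle_aa(single) == _oracle_aa(anc)


# ---------------------------------------------------------------------------
# masking


def test_synonymous_retained_nonsynonymous_replaced():
    # GGA>GGG is silent (kept); ATA>ACA is Met>Thr (masked)
    coding = _coding({"anc": "GGAATA", "x": "GGGACA"})
    anc = AncestralAssignment(bases="GGAATA", method="outgroup")
    masked, audit = mask_nonsynonymous(coding, anc)
    assert masked.sequences["x"] == "GGGATA"
    actions = dict(zip(audit["column"], audit["action"]))
    assert actions == {2: "retained", 4: "masked"}


def test_masking_is_idempotent_and_conservative(rng):
    ids = [f"s{i}" for i in range(6)]
    import itertools as it

    sense = [c for c in ("".join(p) for p in it.product("ACGT", repeat=3))
             if c not in ("TAA", "TAG", "AGA", "AGG")]
    anc_seq = "".join(rng.choice(sense, size=20))
    seqs = {}
    for sid in ids:
        s = list(anc_seq)
        for _ in range(6):
            j = int(rng.integers(0, len(s)))
            s[j] = str(rng.choice(list("ACGT")))
        seqs[sid] = "".join(s)
    coding = _coding(seqs)
    anc = AncestralAssignment(bases=anc_seq, method="outgroup")
    masked, audit = mask_nonsynonymous(coding, anc)
    again, audit2 = mask_nonsynonymous(masked, anc)
    assert again.sequences == masked.sequences
    assert (audit2["action"] == "masked").sum() == 0
    # only nonsynonymous-classified columns changed
    for sid in ids:
        for j, (before, after) in enumerate(zip(coding.sequences[sid], masked.sequences[sid])):
            if before != after:
                rows = audit[(audit["sequence"] == sid) & (audit["column"] == j)]
                assert (rows["action"] == "masked").all() and len(rows) == 1
    # the masked alignment translates to the ancestral protein everywhere
    anc_prot = translate(anc_seq)
    for sid in ids:
        assert translate(masked.sequences[sid]) == anc_prot


def test_unresolved_ancestral_in_a_changed_codon_is_an_error():
    coding = _coding({"a": "ATA", "b": "ACA"})
    anc = AncestralAssignment(bases="ATA", method="outgroup", unresolved=frozenset({1}))
    with pytest.raises(ValueError, match="unresolved"):
        mask_nonsynonymous(coding, anc)
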