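"""Synonymous-only coding alignments.

Builds the concatenated protein-coding alignment (13 genes in a full
mitogenome; minus-strand genes reverse-complemented into the common reading
direction, terminal stop codons dropped), infers ancestral bases, and
replaces every nonsynonymous substitution with the ancestral base so that
only synonymous variation remains — the substrate for clock-like rate
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genetic_code import complement, translate_codon
from .mito_io import CodingIndex, GeneMap, MitogenomeRecord, reference_coordinates

ACGT = frozenset("ACGT")


@dataclass
class CodingAlignment:
    """Concatenated coding sequences plus the provenance of every column."""

    ids: list[str]
    sequences: dict[str, str]
    source_map: list[tuple[str, int, int]]  # (gene, reference position, codon pos 1/2/3)
    reference_id: str

    @property
    def length_nt(self) -> int:
        return len(self.source_map)

    @property
    def codon_count(self) -> int:
        return self.length_nt // 3


@dataclass
class AncestralAssignment:
    bases: str  # one base per coding column
    method: str  # outgroup | fitch
    unresolved: frozenset = field(default_factory=frozenset)


def extract_coding(records: list[MitogenomeRecord], genemap: GeneMap) -> CodingAlignment:
    """Concatenate the protein-coding genes of every record.

    Genes are taken in genomic order; minus-strand genes are
    reverse-complemented; terminal stop codons (complete, or T/TA completed
    by polyadenylation) are trimmed via the reference. A gene that is out of
    frame after trimming is a hard error naming the gene.
    """
    by_id = {r.id: r for r in records}
    if genemap.reference_id not in by_id:
        raise ValueError(f"reference {genemap.reference_id!r} not among the records")
    reference = by_id[genemap.reference_id]
    index = CodingIndex(reference.sequence.replace("-", ""), genemap)
    coords = reference_coordinates(reference.sequence)
    col_of = {pos: col for col, (pos, sub) in enumerate(coords) if sub == 0}

    source_map: list[tuple[str, int, int]] = []
    per_gene_cols: list[tuple[str, list[int]]] = []
    for gene in sorted(genemap.protein_entries(), key=lambda e: e.start):
        positions = index.cds_positions[gene.name]
        per_gene_cols.append((gene.name, [col_of[p] for p in positions]))
        for i, pos in enumerate(positions):
            source_map.append((gene.name, pos, i % 3 + 1))

    sequences = {}
    minus = {e.name for e in genemap.protein_entries() if e.strand == "-"}
    for rec in records:
        parts = []
        for gene_name, cols in per_gene_cols:
            bases = "".join(rec.sequence[c] for c in cols)
            if gene_name in minus:
                bases = complement(bases)  # positions already run 3'->5'
            parts.append(bases)
        sequences[rec.id] = "".join(parts)
    return CodingAlignment(
        ids=[r.id for r in records],
        sequences=sequences,
        source_map=source_map,
        reference_id=reference.id,
    )


def infer_ancestral(
    coding: CodingAlignment,
    tree=None,
    outgroup_ids: list[str] | None = None,
) -> AncestralAssignment:
    """Per-column ancestral base.

    Without a tree: consensus of the outgroup sequences per column (ties
    broken by outgroup input order); a polymorphic column where no outgroup
    carries a determined base is flagged unresolved. With a rooted tree:
    Fitch state sets at the root, ties broken toward the outgroup state.
    """
    if not outgroup_ids and tree is None:
        raise ValueError("need outgroup ids or a rooted tree")
    outgroup_ids = outgroup_ids or []
    for oid in outgroup_ids:
        if oid not in coding.sequences:
            raise ValueError(f"outgroup {oid!r} not in the coding alignment")
    L = coding.length_nt
    ingroup = [coding.sequences[i] for i in coding.ids if i not in outgroup_ids]
    outgroup = [coding.sequences[i] for i in outgroup_ids]

    root_sets = None
    if tree is not None:
        from .parsimony_tree import fitch_root_sets

        root_sets = fitch_root_sets(tree, coding.sequences)

    bases = []
    unresolved = set()
    for j in range(L):
        column = [s[j] for s in ingroup] + [s[j] for s in outgroup]
        determined = sorted({b for b in column if b in ACGT})
        polymorphic = len(determined) > 1
        if not determined:
            bases.append("N")
            unresolved.add(j)
            continue
        if root_sets is not None:
            states = sorted(root_sets[j])
            out_state = next(
                (s[j] for s in outgroup if s[j] in states), None
            )
            bases.append(out_state if out_state is not None else states[0])
            continue
        out_bases = [s[j] for s in outgroup if s[j] in ACGT]
        if out_bases:
            counts = {b: out_bases.count(b) for b in set(out_bases)}
            top = max(counts.values())
            # tie toward the first-listed outgroup carrying a modal base
            bases.append(next(b for b in out_bases if counts[b] == top))
        elif polymorphic:
            bases.append(determined[0])
            unresolved.add(j)
        else:
            bases.append(determined[0])
    return AncestralAssignment(
        "".join(bases),
        "fitch" if root_sets is not None else "outgroup",
        frozenset(unresolved),
    )


def classify_codon_change(ancestral_codon: str, observed_codon: str) -> str:
    """'synonymous', 'nonsynonymous' or 'identical' for a full-codon change.

    Multi-hit codons are judged jointly: the change is nonsynonymous if the
    joint codon or any single observed difference substituted alone into the
    ancestral codon alters the amino acid.
    """
    diffs = [
        i
        for i in range(3)
        if observed_codon[i] in ACGT and observed_codon[i] != ancestral_codon[i]
    ]
    if not diffs:
        return "identical"
    aa_anc = translate_codon(ancestral_codon)
    joint = list(ancestral_codon)
    for i in diffs:
        joint[i] = observed_codon[i]
    if translate_codon("".join(joint)) != aa_anc:
        return "nonsynonymous"
    for i in diffs:
        single = list(ancestral_codon)
        single[i] = observed_codon[i]
        if translate_codon("".join(single)) != aa_anc:
            return "nonsynonymous"
    return "synonymous"


def mask_nonsynonymous(
    coding: CodingAlignment, ancestral: AncestralAssignment
) -> tuple[CodingAlignment, pd.DataFrame]:
    """Replace nonsynonymous substitutions with the ancestral base.

    Returns the masked alignment and an audit table (column, gene, codon
    position, ancestral, observed, action). Synonymous changes are retained;
    N/'-' columns are left untouched. After masking, every fully determined
    codon translates to the ancestral amino acid.
    """
    anc = ancestral.bases
    masked: dict[str, str] = {}
    audit_rows = []
    for sid in coding.ids:
        seq = list(coding.sequences[sid])
        for c0 in range(0, coding.length_nt - coding.length_nt % 3, 3):
            anc_codon = anc[c0 : c0 + 3]
            obs_codon = "".join(seq[c0 : c0 + 3])
            diffs = [
                i for i in range(3) if obs_codon[i] in ACGT and obs_codon[i] != anc_codon[i]
            ]
            if not diffs:
                continue
            if any(c0 + i in ancestral.unresolved for i in diffs):
                raise ValueError(
                    f"unresolved ancestral base in codon at column {c0} for {sid}"
                )
            verdict = classify_codon_change(anc_codon, obs_codon)
            action = "masked" if verdict == "nonsynonymous" else "retained"
            for i in diffs:
                gene, refpos, codon_pos = coding.source_map[c0 + i]
                audit_rows.append(
                    {
                        "column": c0 + i,
                        "gene": gene,
                        "ref_position": refpos,
                        "codon_position": codon_pos,
                        "ancestral": anc_codon[i],
                        "observed": obs_codon[i],
                        "sequence": sid,
                        "action": action,
                    }
                )
                if action == "masked":
                    seq[c0 + i] = anc_codon[i]
        masked[sid] = "".join(seq)
    audit = pd.DataFrame(
        audit_rows,
        columns=[
            "column", "gene", "ref_position", "codon_position",
            "ancestral", "observed", "sequence", "action",
        ],
    )
    out = CodingAlignment(
        ids=list(coding.ids),
        sequences=masked,
        source_map=list(coding.source_map),
        reference_id=coding.reference_id,
    )
    return out, audit
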