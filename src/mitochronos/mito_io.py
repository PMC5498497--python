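"""Sequence/annotation I/O, variant calling and haplotype collapsing.

Coordinates are 1-based inclusive in the reference mitogenome's numbering.
Alignment columns where the reference carries a gap (insertions relative to
the reference) are addressed as (position of the preceding reference base,
insertion_index >= 1); all other columns have insertion_index 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import (
    STOP,
    complement,
    is_transition,
    revcomp,
    translate,
    translate_codon,
)

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN-")
BTYPES = ("swamp", "river", "outgroup")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MitogenomeRecord:
    """One aligned mitogenome with sample metadata.

    ``tip_age`` is in years before present (0 for modern samples); it carries
    the age of radiocarbon-dated ancient tips used as clock calibrations.
    """

    id: str
    sequence: str
    population: str | None = None
    region: str | None = None
    btype: str = "swamp"
    tip_age: float = 0.0

    def __post_init__(self) -> None:
        if self.btype not in BTYPES:
            raise ValueError(f"btype must be one of {BTYPES}, got {self.btype!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneEntry:
    name: str
    start: int  # 1-based inclusive, reference coordinates
    end: int
    strand: str  # '+' or '-'
    kind: str  # protein | rRNA | tRNA | control

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad coordinates for {self.name}: {self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand for {self.name}: {self.strand!r}")
        if self.kind not in ("protein", "rRNA", "tRNA", "control"):
            raise ValueError(f"bad kind for {self.name}: {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneMap:
    """Gene coordinates on one reference mitogenome."""

    entries: list[GeneEntry]
    reference_id: str

    def validate(self) -> None:
        prot = sorted(self.protein_entries(), key=lambda e: e.start)
        for a, b in zip(prot, prot[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping protein genes {a.name}/{b.name}")
        control = [e for e in self.entries if e.kind == "control"]
        for c in control:
            for e in prot:
                if not (c.end < e.start or c.start > e.end):
                    raise ValueError(f"control region overlaps {e.name}")

    def protein_entries(self) -> list[GeneEntry]:
        return [e for e in self.entries if e.kind == "protein"]

    def region_of(self, position: int) -> str | None:
        """coding / control / RNA for a reference position, None if uncovered."""
        for e in self.entries:
            if e.start <= position <= e.end:
                if e.kind == "protein":
                    return "coding"
                if e.kind == "control":
                    return "control"
                return "RNA"
        return None

    @classmethod
    def from_tsv(cls, path) -> "GeneMap":
        reference_id = ""
        with open(path) as fh:
            first = fh.readline().strip()
            if first.startswith("#reference="):
                reference_id = first.split("=", 1)[1]
        df = pd.read_csv(path, sep="\t", comment="#")
        entries = [
            GeneEntry(r["name"], int(r["start"]), int(r["end"]), str(r["strand"]), r["kind"])
            for _, r in df.iterrows()
        ]
        gm = cls(entries=entries, reference_id=reference_id)
        gm.validate()
        return gm

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#reference={self.reference_id}\n")
            fh.write("name\tstart\tend\tstrand\tkind\n")
            for e in self.entries:
                fh.write(f"{e.name}\t{e.start}\t{e.end}\t{e.strand}\t{e.kind}\n")


@dataclass(frozen=True)
class Variant:
    """A difference from the reference at one reference coordinate."""

    position: int
    ref_allele: str
    alt_allele: str
    vclass: str  # transition | transversion | indel
    region: str  # coding | control | RNA
    effect: str  # synonymous | nonsynonymous | noncoding | NA
    insertion_index: int = 0

    def key(self) -> tuple:
        """Identity key used for haplotype collapsing and distinct counts."""
        return (self.position, self.insertion_index, self.alt_allele)


@dataclass
class Haplotype:
    ht_id: str
    member_ids: list[str]
    variants: list[Variant]
    haplogroup: str = "unassigned"


@dataclass
class HaplotypeTable:
    haplotypes: list[Haplotype]

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def n_members(self) -> int:
        return sum(len(h.member_ids) for h in self.haplotypes)

    def frequencies(self) -> list[float]:
        n = self.n_members
        return [len(h.member_ids) / n for h in self.haplotypes]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.haplotypes:
            rows.append(
                {
                    "ht_id": h.ht_id,
                    "n_members": len(h.member_ids),
                    "members": ",".join(h.member_ids),
                    "haplogroup": h.haplogroup,
                    "variants": ";".join(
                        f"{v.position}{'.' + str(v.insertion_index) if v.insertion_index else ''}"
                        f"{v.ref_allele}>{v.alt_allele}"
                        for v in h.variants
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class HaplogroupRule:
    """A haplogroup label with its full diagnostic motif.

    Motif entries are (reference position, derived allele) pairs; a child's
    motif must contain its parent's motif (rules form a tree).
    """

    label: str
    motif: list[tuple[int, str]]
    parent: str | None = None


# ---------------------------------------------------------------------------
# alignment I/O


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError("metadata table must have an 'id' column")
    return df.set_index("id")


def read_alignment(path, metadata: pd.DataFrame | None = None) -> list[MitogenomeRecord]:
    """Read an aligned FASTA into records, normalising the alphabet.

    Bases are upper-cased; IUPAC ambiguity codes other than ACGT become N
    (with a logged warning). A ragged alignment or an empty file is a hard
    error.
    """
    seqs = list(SeqIO.parse(str(path), "fasta"))
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(s.seq) for s in seqs}
    if len(lengths) > 1:
        bad = sorted({s.id for s in seqs if len(s.seq) != len(seqs[0].seq)})
        raise ValueError(f"ragged alignment: {', '.join(bad)} differ in length from {seqs[0].id}")
    records = []
    for s in seqs:
        raw = str(s.seq).upper()
        cleaned = "".join(b if b in VALID_BASES else "N" for b in raw)
        n_mapped = sum(1 for a, b in zip(raw, cleaned) if a != b)
        if n_mapped:
            logger.warning("%s: %d ambiguous bases mapped to N", s.id, n_mapped)
        rec = MitogenomeRecord(id=s.id, sequence=cleaned)
        if metadata is not None:
            if s.id not in metadata.index:
                raise ValueError(f"no metadata row for sequence {s.id}")
            row = metadata.loc[s.id]
            rec = replace(
                rec,
                population=row.get("population"),
                region=row.get("region"),
                btype=row.get("btype", "swamp"),
                tip_age=float(row.get("tip_age", 0.0)),
            )
        records.append(rec)
    return records


def write_alignment(records: list[MitogenomeRecord], path) -> None:
    """Write records as FASTA wrapped at 70 columns, preserving order."""
    seqrecs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(seqrecs)


def write_metadata(records: list[MitogenomeRecord], path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "population": [r.population or "" for r in records],
            "region": [r.region or "" for r in records],
            "btype": [r.btype for r in records],
            "tip_age": [r.tip_age for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference coordinates and codon context


def reference_coordinates(ref_aligned: str) -> list[tuple[int, int]]:
    """Per alignment column, the (reference position, insertion_index) pair."""
    coords = []
    pos = 0
    sub = 0
    for base in ref_aligned:
        if base == "-":
            sub += 1
        else:
            pos += 1
            sub = 0
        coords.append((pos, sub))
    return coords


class CodingIndex:
    """Codon context of every protein-coding reference position.

    Builds, from the ungapped reference and the gene map, the concatenated
    CDS of each gene (minus-strand genes reverse-complemented, terminal
    complete or polyadenylation-completed stop codons trimmed) and a lookup
    from reference position to (gene, codon index, position-in-codon,
    strand). Raises if any gene is out of frame or contains an internal stop
    after trimming.
    """

    def __init__(self, reference_ungapped: str, genemap: GeneMap):
        self.genemap = genemap
        self.cds: dict[str, str] = {}
        self.by_position: dict[int, tuple[str, int, int, str]] = {}
        # reference positions contributing to each gene's trimmed CDS, in CDS order
        self.cds_positions: dict[str, list[int]] = {}
        for gene in sorted(genemap.protein_entries(), key=lambda e: e.start):
            raw = reference_ungapped[gene.start - 1 : gene.end]
            positions = list(range(gene.start, gene.end + 1))
            if gene.strand == "-":
                raw = revcomp(raw)
                positions = positions[::-1]
            raw, positions = _trim_stop(gene.name, raw, positions)
            if len(raw) % 3 != 0:
                raise ValueError(f"gene {gene.name} out of frame after stop trimming")
            prot = translate(raw)
            if STOP in prot:
                raise ValueError(f"gene {gene.name} has an internal stop codon")
            self.cds[gene.name] = raw
            self.cds_positions[gene.name] = positions
            for i, pos in enumerate(positions):
                self.by_position[pos] = (gene.name, i // 3, i % 3, gene.strand)

    def effect_of(self, position: int, alt: str) -> str:
        """synonymous/nonsynonymous for a substitution at a coding position;
        NA at positions trimmed from the CDS (terminal stop codons)."""
        if position not in self.by_position:
            return "NA"
        gene, codon_idx, codon_pos, strand = self.by_position[position]
        codon = self.cds[gene][codon_idx * 3 : codon_idx * 3 + 3]
        base = alt if strand == "+" else complement(alt)
        mutated = codon[:codon_pos] + base + codon[codon_pos + 1 :]
        aa_ref = translate_codon(codon)
        aa_alt = translate_codon(mutated)
        if aa_alt is None:
            return "NA"
        return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def _trim_stop(name: str, cds: str, positions: list[int]) -> tuple[str, list[int]]:
    """Drop a terminal stop codon, complete or incomplete (T/TA + poly-A)."""
    overhang = len(cds) % 3
    if overhang:
        tail = cds[-overhang:]
        if tail in ("T", "TA"):
            cds, positions = cds[:-overhang], positions[:-overhang]
        else:
            raise ValueError(f"gene {name} has a {overhang}-nt overhang {tail!r}")
    if len(cds) >= 3 and translate_codon(cds[-3:]) == STOP:
        cds, positions = cds[:-3], positions[:-3]
    return cds, positions


# ---------------------------------------------------------------------------
# variant calling


def call_variants(
    record: MitogenomeRecord,
    reference: MitogenomeRecord,
    genemap: GeneMap,
    coding_index: CodingIndex | None = None,
) -> list[Variant]:
    """Differences of ``record`` from ``reference``, in reference coordinates.

    Columns where either sequence has N emit no variant; gap columns emit
    indel variants; substitutions in protein genes get a synonymous or
    nonsynonymous effect via the vertebrate mitochondrial code, honouring
    strand.
    """
    if len(record.sequence) != len(reference.sequence):
        raise ValueError("record and reference must come from the same alignment")
    if genemap.reference_id and genemap.reference_id != reference.id:
        raise ValueError(
            f"genemap is for {genemap.reference_id!r}, reference is {reference.id!r}"
        )
    if coding_index is None:
        coding_index = CodingIndex(reference.sequence.replace("-", ""), genemap)
    coords = reference_coordinates(reference.sequence)
    variants = []
    for col, (ref_b, alt_b) in enumerate(zip(reference.sequence, record.sequence)):
        if ref_b == alt_b or "N" in (ref_b, alt_b):
            continue
        pos, sub = coords[col]
        if "-" in (ref_b, alt_b):
            variants.append(
                Variant(pos, ref_b, alt_b, "indel", _region(genemap, pos), "NA", sub)
            )
            continue
        region = _region(genemap, pos)
        if region == "coding":
            effect = coding_index.effect_of(pos, alt_b)
        else:
            effect = "noncoding"
        vclass = "transition" if is_transition(ref_b, alt_b) else "transversion"
        variants.append(Variant(pos, ref_b, alt_b, vclass, region, effect, sub))
    return variants


def _region(genemap: GeneMap, position: int) -> str:
    region = genemap.region_of(position)
    if region is None:
        raise ValueError(f"position {position} not covered by the gene map")
    return region


# ---------------------------------------------------------------------------
# haplotype collapsing and haplogroup assignment


def collapse_haplotypes(
    records: list[MitogenomeRecord],
    reference: MitogenomeRecord,
    genemap: GeneMap,
    strict: bool = True,
) -> HaplotypeTable:
    """Group records that share an identical substitution-variant set.

    Indels and N columns are excluded from the identity key. In strict mode
    (default) sequences whose N positions differ stay distinct haplotypes
    (logged); with ``strict=False`` N matches anything and only substitution
    sets are compared.
    """
    if not records:
        raise ValueError("no records to collapse")
    coding_index = CodingIndex(reference.sequence.replace("-", ""), genemap)
    coords = reference_coordinates(reference.sequence)
    groups: dict[tuple, Haplotype] = {}
    order: list[tuple] = []
    for rec in records:
        variants = call_variants(rec, reference, genemap, coding_index)
        subs = frozenset(v.key() for v in variants if v.vclass != "indel")
        if strict:
            n_positions = frozenset(
                coords[i] for i, b in enumerate(rec.sequence) if b == "N"
            )
            if n_positions:
                logger.info("%s: %d N positions kept in haplotype key (strict mode)",
                            rec.id, len(n_positions))
            key = (subs, n_positions)
        else:
            key = (subs, frozenset())
        if key not in groups:
            ht = Haplotype(f"Ht{len(groups) + 1}", [], [v for v in variants if v.vclass != "indel"])
            groups[key] = ht
            order.append(key)
        groups[key].member_ids.append(rec.id)
    return HaplotypeTable([groups[k] for k in order])


def validate_rules(rules: list[HaplogroupRule]) -> dict[str, HaplogroupRule]:
    by_label = {r.label: r for r in rules}
    if len(by_label) != len(rules):
        raise ValueError("duplicate haplogroup labels")
    for r in rules:
        seen = {r.label}
        cur = r
        while cur.parent is not None:
            if cur.parent not in by_label:
                raise ValueError(f"unknown parent {cur.parent!r} for {r.label}")
            if cur.parent in seen:
                raise ValueError(f"cycle in haplogroup rules at {r.label}")
            seen.add(cur.parent)
            cur = by_label[cur.parent]
        if r.parent is not None and not set(by_label[r.parent].motif) <= set(r.motif):
            raise ValueError(f"motif of {r.label} does not extend its parent's")
    return by_label


def assign_haplogroup(variants: list[Variant], rules: list[HaplogroupRule]) -> str:
    """Deepest rule whose full motif is carried by the variant set.

    Equally deep matches on different branches give a "conflict:<labels>"
    result; no match gives "unassigned".
    """
    by_label = validate_rules(rules)

    def depth(rule: HaplogroupRule) -> int:
        d = 0
        while rule.parent is not None:
            d += 1
            rule = by_label[rule.parent]
        return d

    carried = {(v.position, v.alt_allele) for v in variants}
    matches = [r for r in rules if set(r.motif) <= carried]
    if not matches:
        return "unassigned"
    best_depth = max(depth(r) for r in matches)
    deepest = sorted(r.label for r in matches if depth(r) == best_depth)
    if len(deepest) > 1:
        return "conflict:" + "|".join(deepest)
    return deepest[0]


def read_rules(path) -> list[HaplogroupRule]:
    """Rule table: columns label, parent ('' for roots), motif 'pos:allele;...'."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    rules = []
    for _, row in df.iterrows():
        motif = []
        for item in str(row["motif"]).split(";"):
            if item:
                pos, allele = item.split(":")
                motif.append((int(pos), allele))
        rules.append(HaplogroupRule(row["label"], motif, row["parent"] or None))
    validate_rules(rules)
    return rules


# ---------------------------------------------------------------------------
# VCF export


def variants_to_vcf(
    variant_sets: dict[str, list[Variant]], reference_id: str, path
) -> None:
    """Minimal multi-record VCF of substitution variants (INFO REGION/EFFECT)."""
    seen: dict[tuple, Variant] = {}
    carriers: dict[tuple, list[str]] = {}
    for rid, variants in variant_sets.items():
        for v in variants:
            if v.vclass == "indel" or v.insertion_index:
                continue
            seen.setdefault(v.key(), v)
            carriers.setdefault(v.key(), []).append(rid)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference_id}>\n")
        fh.write('##INFO=<ID=REGION,Number=1,Type=String,Description="Genomic region">\n')
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">\n')
        fh.write('##INFO=<ID=CARRIERS,Number=1,Type=Integer,Description="Carrier count">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for key in sorted(seen):
            v = seen[key]
            info = f"REGION={v.region};EFFECT={v.effect};CARRIERS={len(carriers[key])}"
            fh.write(
                f"{reference_id}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t{info}\n"
            )
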