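"""Vertebrate mitochondrial genetic code (NCBI translation table 2).

The table is shipped as data so that effect classification (synonymous vs
nonsynonymous) is self-contained and auditable; it differs from the standard
code at four codons: ATA=Met, TGA=Trp, and AGA/AGG are stops.
"""

from __future__ import annotations

STOP = "*"

#: codon -> one-letter amino acid; STOP for termination codons
VERTEBRATE_MITO_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "M", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": STOP, "TAG": STOP,
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "W", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": STOP, "AGG": STOP,
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

MITO_STOP_CODONS = frozenset(c for c, aa in VERTEBRATE_MITO_CODE.items() if aa == STOP)

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement; N and '-' map to themselves."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon, or None if the codon contains N/'-'."""
    return VERTEBRATE_MITO_CODE.get(codon.upper())


def translate(seq: str) -> str:
    """Translate a CDS; codons with ambiguity become 'X'."""
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = translate_codon(seq[i : i + 3])
        aas.append(aa if aa is not None else "X")
    return "".join(aas)


def is_transition(a: str, b: str) -> bool:
    """True for A<->G or C<->T substitutions."""
    pair = {a.upper(), b.upper()}
    return pair <= PURINES or pair <= PYRIMIDINES
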