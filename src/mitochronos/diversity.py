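"""Summary statistics of mitogenome variation.

Haplotype diversity Hd, segregating sites S, mean pairwise difference k̄ with
its standard deviation across pairs, per-site nucleotide diversity π
(reported both raw and ×100, i.e. as a percentage), and the ratio of
distinct synonymous to nonsynonymous coding substitutions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mito_io import HaplotypeTable, MitogenomeRecord, Variant

logger = logging.getLogger(__name__)

_GAP = ord("-")
_N = ord("N")


@dataclass
class DiversitySummary:
    n_sequences: int
    n_haplotypes: int
    Hd: float
    S: int
    pi: float  # per-site
    pi_percent: float  # per-site × 100
    mean_pairwise: float
    sd_pairwise: float
    syn_nonsyn_ratio: float
    effective_length: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def _encode(records: list[MitogenomeRecord]) -> np.ndarray:
    """Alignment as an (n, L) byte matrix."""
    return np.array([np.frombuffer(r.sequence.encode(), dtype=np.uint8) for r in records])


def haplotype_diversity(table: HaplotypeTable) -> float:
    """Hd = n/(n-1) · (1 - Σ pᵢ²), the unbiased gene-diversity estimator."""
    n = table.n_members
    if n < 2:
        raise ValueError("haplotype diversity needs at least 2 sequences")
    sum_p2 = sum(p * p for p in table.frequencies())
    return n / (n - 1) * (1.0 - sum_p2)


def pairwise_stats(
    records: list[MitogenomeRecord], mask: np.ndarray | None = None
) -> tuple[float, float, float, int]:
    """(mean_pairwise, sd_pairwise, pi_percent, S) over all C(n,2) pairs.

    Differences are counted per pair over columns where both sequences have
    a determined base (pairwise deletion of gap/N). π uses the number of
    columns whose consensus (majority) state is not a gap as the effective
    length. ``mask`` is an optional boolean column filter (True = use).
    """
    if len(records) < 2:
        raise ValueError("pairwise statistics need at least 2 sequences")
    mat = _encode(records)
    if mask is not None:
        mat = mat[:, np.asarray(mask, dtype=bool)]
    n, L = mat.shape
    if L == 0:
        raise ValueError("all columns masked")
    determined = (mat != _GAP) & (mat != _N)
    # effective length: columns where the majority state is not a gap
    gap_frac = (mat == _GAP).mean(axis=0)
    effective_length = int((gap_frac <= 0.5).sum())
    if effective_length == 0:
        raise ValueError("all columns are gap-consensus")

    diffs = []
    for i in range(n):
        both = determined[i] & determined[i + 1 :]
        neq = (mat[i] != mat[i + 1 :]) & both
        diffs.extend(neq.sum(axis=1).tolist())
    diffs = np.array(diffs, dtype=float)
    mean_pw = float(diffs.mean())
    sd_pw = float(diffs.std())  # population SD across the C(n,2) pair values
    pi_percent = 100.0 * mean_pw / effective_length

    # segregating sites: columns with >=2 distinct determined bases
    S = 0
    for j in range(L):
        col = mat[determined[:, j], j]
        if col.size and np.unique(col).size > 1:
            S += 1
    return mean_pw, sd_pw, pi_percent, S


def syn_nonsyn_ratio(variant_sets: list[list[Variant]]) -> float:
    """Distinct synonymous / distinct nonsynonymous coding substitutions.

    Distinctness is by (position, alt allele) across all input variant sets.
    Returns +inf (with a warning) when no nonsynonymous variant exists.
    """
    syn, nonsyn = set(), set()
    for variants in variant_sets:
        for v in variants:
            if v.region != "coding" or v.vclass == "indel":
                continue
            if v.effect == "synonymous":
                syn.add(v.key())
            elif v.effect == "nonsynonymous":
                nonsyn.add(v.key())
    if not syn and not nonsyn:
        raise ValueError("no coding substitution variants")
    if not nonsyn:
        logger.warning("no nonsynonymous variants; syn/nonsyn ratio is infinite")
        return math.inf
    return len(syn) / len(nonsyn)


def summarize(
    records: list[MitogenomeRecord],
    table: HaplotypeTable,
    mask: np.ndarray | None = None,
) -> DiversitySummary:
    mean_pw, sd_pw, pi_percent, S = pairwise_stats(records, mask)
    try:
        ratio = syn_nonsyn_ratio([h.variants for h in table.haplotypes])
    except ValueError:
        ratio = math.nan
    mat = _encode(records)
    gap_frac = (mat == _GAP).mean(axis=0)
    effective_length = int((gap_frac <= 0.5).sum())
    return DiversitySummary(
        n_sequences=len(records),
        n_haplotypes=len(table),
        Hd=haplotype_diversity(table),
        S=S,
        pi=pi_percent / 100.0,
        pi_percent=pi_percent,
        mean_pairwise=mean_pw,
        sd_pairwise=sd_pw,
        syn_nonsyn_ratio=ratio,
        effective_length=effective_length,
    )
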