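"""Descriptive summaries: peptide length distributions, binder fractions by
length, and sequence-logo-style percent-difference motif matrices."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .binders import BINDER_CUTOFF, STRONG_CUTOFF

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")


def length_distribution(
    peptides: Iterable[str], min_len: int = 8, max_len: int = 14
) -> dict[int, int]:
    """Counts per peptide length over [min_len, max_len]; out-of-range errors."""
    counts = {length: 0 for length in range(min_len, max_len + 1)}
    for pep in peptides:
        if not min_len <= len(pep) <= max_len:
            raise ValueError(
                f"peptide {pep!r} has length {len(pep)} outside {min_len}-{max_len}"
            )
        counts[len(pep)] += 1
    return counts


def binder_fraction_by_length(
    peptide_ranks: Mapping[str, float | None],
    min_len: int = 8,
    max_len: int = 14,
    cutoff: float = BINDER_CUTOFF,
    strong_cutoff: float = STRONG_CUTOFF,
) -> pd.DataFrame:
    """Per-length (total, binders, strong) counts from best-allele %Ranks.

    ``peptide_ranks`` maps peptide -> best %Rank (None when no prediction).
    Strong binders are a subset of binders, binders of totals.
    """
    rows = {
        length: {"length": length, "total": 0, "binders": 0, "strong": 0}
        for length in range(min_len, max_len + 1)
    }
    for pep, rank in peptide_ranks.items():
        if not min_len <= len(pep) <= max_len:
            raise ValueError(f"peptide {pep!r} outside {min_len}-{max_len}")
        row = rows[len(pep)]
        row["total"] += 1
        if rank is not None and rank < cutoff:
            row["binders"] += 1
            if rank < strong_cutoff:
                row["strong"] += 1
    return pd.DataFrame([rows[k] for k in sorted(rows)]).set_index("length")


@dataclass
class MotifMatrix:
    """Percent-difference motif readout: 100 x (observed positional frequency
    minus reference background frequency), positions 1..9 by residue."""

    values: pd.DataFrame  # index: position 1..9, columns: AA_ORDER
    reference_composition: dict[str, float]


def composition_from_proteome(proteome: Sequence[tuple[str, str]]) -> dict[str, float]:
    """Per-residue background frequencies of a reference proteome."""
    counter: Counter[str] = Counter()
    for _, seq in proteome:
        counter.update(res for res in seq if res in AA_ORDER)
    total = sum(counter.values())
    if total == 0:
        raise ValueError("proteome contains no standard residues")
    return {aa: counter.get(aa, 0) / total for aa in AA_ORDER}


def motif_percent_difference(
    nine_mers: Iterable[str], reference: Mapping[str, float]
) -> MotifMatrix:
    """value(a, j) = 100 x (frequency of residue a at position j - reference
    frequency of a), over a set of 9-mers."""
    peptides = list(nine_mers)
    if not peptides:
        raise ValueError("empty peptide set")
    for pep in peptides:
        if len(pep) != 9:
            raise ValueError(f"non-9-mer peptide {pep!r} in motif set")
    ref_total = sum(reference.get(aa, 0.0) for aa in AA_ORDER)
    if abs(ref_total - 1.0) > 1e-6:
        raise ValueError(f"reference composition sums to {ref_total}, not 1")
    n = len(peptides)
    data = {}
    for j in range(9):
        counts = Counter(pep[j] for pep in peptides)
        data[j + 1] = {
            aa: 100.0 * (counts.get(aa, 0) / n - reference.get(aa, 0.0))
            for aa in AA_ORDER
        }
    values = pd.DataFrame.from_dict(data, orient="index")[list(AA_ORDER)]
    values.index.name = "position"
    return MotifMatrix(values=values, reference_composition={aa: reference.get(aa, 0.0) for aa in AA_ORDER})
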