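"""HLA binder assignment: best-ranked allele per peptide among the sample's
typed alleles, and the %Rank < 2.0 binder / < 0.5 strong-binder cutoffs.

The predictor itself is external (NetMHCpan-style rank tables are consumed,
never computed here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import BinderCall
from .matching import PeptideMatch

log = logging.getLogger(__name__)

BINDER_CUTOFF = 2.0
STRONG_CUTOFF = 0.5


@dataclass(frozen=True)
class SampleAlleles:
    sample_id: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"{self.sample_id}: empty allele list")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"{self.sample_id}: duplicate alleles")


def assign_best_allele(
    peptide: str, calls: Iterable[BinderCall], alleles: SampleAlleles
) -> tuple[str, float] | None:
    """The allele with the minimum %Rank for this peptide among the sample's
    typed alleles; ties break to the lexicographically first allele name.
    Returns None when no call exists."""
    best: tuple[str, float] | None = None
    allele_set = set(alleles.alleles)
    for call in calls:
        if call.peptide != peptide or call.allele not in allele_set:
            continue
        if best is None or call.rank_percent < best[1] or (
            call.rank_percent == best[1] and call.allele < best[0]
        ):
            if best is not None and call.rank_percent == best[1]:
                log.info(
                    "%s: %%Rank tie between %s and %s; keeping %s",
                    peptide, best[0], call.allele, min(best[0], call.allele),
                )
            best = (call.allele, call.rank_percent)
    return best


def binder_status(rank: float | None, cutoff: float = BINDER_CUTOFF,
                  strong_cutoff: float = STRONG_CUTOFF) -> str:
    if rank is None or not rank < cutoff:
        return "nonbinder"
    return "strong" if rank < strong_cutoff else "binder"


def best_rank_across_samples(
    peptide: str,
    calls_by_peptide: Mapping[str, list[BinderCall]],
    samples: Iterable[SampleAlleles],
) -> tuple[str, float] | None:
    """Best (allele, rank) for a peptide over every sample that observed it."""
    best: tuple[str, float] | None = None
    calls = calls_by_peptide.get(peptide, [])
    for sample in samples:
        got = assign_best_allele(peptide, calls, sample)
        if got is None:
            continue
        if best is None or got[1] < best[1] or (got[1] == best[1] and got[0] < best[0]):
            best = got
    return best


def index_calls(calls: Iterable[BinderCall]) -> dict[str, list[BinderCall]]:
    out: dict[str, list[BinderCall]] = {}
    for c in calls:
        out.setdefault(c.peptide, []).append(c)
    return out


def filter_binders(
    matches: Sequence[PeptideMatch],
    calls: Iterable[BinderCall],
    alleles: SampleAlleles | Sequence[SampleAlleles],
    peptide_samples: Mapping[str, Sequence[str]] | None = None,
    cutoff: float = BINDER_CUTOFF,
    strong_cutoff: float = STRONG_CUTOFF,
    drop_nonbinders: bool = False,
) -> tuple[list[PeptideMatch], dict[str, int]]:
    """Annotate matches with best allele/%Rank and binder status.

    A peptide is a binder iff its best %Rank among the typed alleles of the
    sample(s) that observed it is strictly below ``cutoff`` (strong below
    ``strong_cutoff``). When ``peptide_samples`` is given, only alleles of
    observing samples are considered; otherwise all supplied samples count.
    Returns the (optionally nonbinder-free) match list and category counts.
    """
    if isinstance(alleles, SampleAlleles):
        samples = [alleles]
    else:
        samples = list(alleles)
    by_sample = {s.sample_id: s for s in samples}
    calls_by_peptide = index_calls(calls)
    counts = {"strong": 0, "binder": 0, "nonbinder": 0}
    seen: set[str] = set()
    out: list[PeptideMatch] = []
    for m in matches:
        if peptide_samples is not None:
            relevant = [
                by_sample[sid]
                for sid in peptide_samples.get(m.peptide, [])
                if sid in by_sample
            ]
        else:
            relevant = samples
        best = best_rank_across_samples(m.peptide, calls_by_peptide, relevant)
        if best is not None:
            m.best_allele, m.best_rank = best
        m.binder_status = binder_status(m.best_rank, cutoff, strong_cutoff)
        if m.peptide not in seen:
            seen.add(m.peptide)
            counts[m.binder_status] += 1
        if m.binder_status != "nonbinder" or not drop_nonbinders:
            out.append(m)
    return out, counts
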