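"""Candidate selection for de novo peptides: length/ALC thresholds,
deduplication and reference-proteome exclusion.

HLA class I peptides are natural (non-tryptic) ligands, so proteome
exclusion is a plain substring test against every reference protein, with
optional I/L equivalence because tandem MS cannot distinguish the isobaric
leucine and isoleucine residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import PeptideObservation

_IL_TABLE = str.maketrans("I", "L")


def collapse_il(sequence: str) -> str:
    """Collapse I and L to a single symbol (L) for isobaric matching."""
    return sequence.translate(_IL_TABLE)


@dataclass(frozen=True)
class FilterConfig:
    min_len: int = 8
    max_len: int = 14
    min_alc: float = 50.0  # strict inequality: ALC must exceed this
    il_equivalence: bool = True

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len exceeds max_len")
        if not 0.0 <= self.min_alc <= 100.0:
            raise ValueError("min_alc outside 0-100")


@dataclass
class Candidate:
    """A deduplicated candidate peptide with its best ALC and observing samples."""

    peptide: str
    max_alc: float
    samples: tuple[str, ...] = field(default_factory=tuple)


def drop_reason(obs: PeptideObservation, config: FilterConfig) -> str | None:
    """Reason code for dropping an observation, or None if retained."""
    if obs.origin != "de_novo_only":
        return "not_de_novo_only"
    if len(obs.sequence) < config.min_len:
        return "too_short"
    if len(obs.sequence) > config.max_len:
        return "too_long"
    if not obs.alc > config.min_alc:
        return "low_alc"
    return None


def filter_denovo(
    observations: Iterable[PeptideObservation], config: FilterConfig | None = None
) -> list[Candidate]:
    """Apply length and ALC thresholds and deduplicate.

    Retained iff min_len <= len <= max_len, ALC strictly > min_alc, and the
    observation came from the de novo-only search. Duplicate sequences
    collapse to one candidate keeping the maximum ALC and the union of
    observing samples. Output is sorted by peptide for determinism.
    """
    config = config or FilterConfig()
    best: dict[str, Candidate] = {}
    samples: dict[str, set[str]] = {}
    for obs in observations:
        if drop_reason(obs, config) is not None:
            continue
        cand = best.get(obs.sequence)
        if cand is None:
            best[obs.sequence] = Candidate(obs.sequence, obs.alc)
            samples[obs.sequence] = {obs.sample_id}
        else:
            cand.max_alc = max(cand.max_alc, obs.alc)
            samples[obs.sequence].add(obs.sample_id)
    out = []
    for pep in sorted(best):
        cand = best[pep]
        cand.samples = tuple(sorted(samples[pep]))
        out.append(cand)
    return out


def proteome_substring_set(
    peptides: Iterable[str],
    proteome: Sequence[tuple[str, str]],
    il_equivalence: bool = True,
) -> set[str]:
    """Peptides occurring as a contiguous substring of any proteome entry."""
    if not proteome:
        raise ValueError("empty proteome")
    # one concatenated haystack with a separator that matches no residue
    blob = "#".join(seq for _, seq in proteome)
    if il_equivalence:
        blob = collapse_il(blob)
    hits = set()
    for pep in peptides:
        query = collapse_il(pep) if il_equivalence else pep
        if query in blob:
            hits.add(pep)
    return hits


def exclude_proteome(
    candidates: Iterable[Candidate] | Iterable[str],
    proteome: Sequence[tuple[str, str]],
    il_equivalence: bool = True,
) -> list:
    """Drop candidates that occur verbatim in the reference proteome."""
    cands = list(candidates)
    peptides = [c.peptide if isinstance(c, Candidate) else c for c in cands]
    hits = proteome_substring_set(peptides, proteome, il_equivalence)
    return [c for c, p in zip(cands, peptides) if p not in hits]
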