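"""Match candidate peptides against the six-frame translated transcript DB,
project matches to genomic coordinates through BED12 blocks, and classify
each match by genomic context and source-transcript class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .filtering import Candidate, collapse_il
from .io import CoverageSet, GenomeAnnotation, TranscriptRecord
from .sixframe import FrameTranslation, aa_to_nt_interval

log = logging.getLogger(__name__)

REGION_CLASSES = ("noncoding", "intronic", "novel_orf")
SOURCE_CLASSES = ("antisense", "sense_intronic", "intergenic_lncRNA")


@dataclass
class PeptideMatch:
    """A peptide located in one frame of one transcript.

    ``transcript_nt_interval`` is on the stored (transcript-strand 5'->3')
    sequence. ``genomic_intervals`` carry the coding strand: the transcript
    strand for forward frames, the opposite strand for reverse frames, so
    that extracting genome bases (reverse-complemented on '-') and
    translating always reproduces the peptide.
    """

    peptide: str
    transcript_id: str
    frame_id: int
    aa_start: int
    transcript_nt_interval: tuple[int, int]
    genomic_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    region_class: str | None = None
    source_class: str | None = None
    expressed: bool | None = None
    best_allele: str | None = None
    best_rank: float | None = None
    binder_status: str | None = None


def match_peptides(
    candidates: Iterable[Candidate] | Iterable[str],
    db: Sequence[FrameTranslation],
    il_equivalence: bool = True,
) -> list[PeptideMatch]:
    """Find every occurrence of every candidate in every stop-free frame segment.

    One match per (peptide, transcript, frame, aa_start) occurrence;
    occurrences spanning a stop are impossible by construction because the
    search runs inside stop-free segments.
    """
    peptides = sorted(
        {c.peptide if isinstance(c, Candidate) else c for c in candidates}
    )
    queries = [(p, collapse_il(p) if il_equivalence else p) for p in peptides]
    matches: list[PeptideMatch] = []
    for fr in db:
        for seg_start, segment in fr.segments:
            hay = collapse_il(segment) if il_equivalence else segment
            for peptide, query in queries:
                pos = hay.find(query)
                while pos != -1:
                    aa_start = seg_start + pos
                    matches.append(
                        PeptideMatch(
                            peptide=peptide,
                            transcript_id=fr.transcript_id,
                            frame_id=fr.frame_id,
                            aa_start=aa_start,
                            transcript_nt_interval=aa_to_nt_interval(
                                fr.frame_id, aa_start, len(peptide), fr.nt_length
                            ),
                        )
                    )
                    pos = hay.find(query, pos + 1)
    matches.sort(key=lambda m: (m.peptide, m.transcript_id, m.frame_id, m.aa_start))
    return matches


def _project_plus(
    blocks: Sequence[tuple[int, int]], start: int, end: int
) -> list[tuple[int, int]]:
    """Project a plus-orientation transcript interval through genomic blocks."""
    out = []
    offset = 0
    for block_start, size in blocks:
        lo = max(start, offset)
        hi = min(end, offset + size)
        if lo < hi:
            out.append((block_start + lo - offset, block_start + hi - offset))
        offset += size
    return out


def map_to_genome(match: PeptideMatch, transcript: TranscriptRecord) -> PeptideMatch:
    """Fill ``genomic_intervals`` by projecting the transcript nt interval
    through the BED12 block structure (splitting at block boundaries)."""
    if match.transcript_id != transcript.transcript_id:
        raise ValueError(
            f"match is on {match.transcript_id}, not {transcript.transcript_id}"
        )
    start, end = match.transcript_nt_interval
    L = transcript.length
    if not (0 <= start < end <= L):
        raise ValueError(f"nt interval ({start}, {end}) outside transcript of length {L}")
    if transcript.strand == "-":
        # stored sequence runs 3'->5' in genomic terms; mirror to genomic order
        start, end = L - end, L - start
    pieces = _project_plus(transcript.blocks, start, end)
    total = sum(e - s for s, e in pieces)
    if total != 3 * len(match.peptide):
        raise AssertionError(
            f"{match.peptide}@{transcript.transcript_id}: projected {total} nt, "
            f"expected {3 * len(match.peptide)}"
        )
    coding_strand = transcript.strand
    if match.frame_id < 0:
        coding_strand = "-" if coding_strand == "+" else "+"
    match.genomic_intervals = [
        (transcript.chrom, s, e, coding_strand) for s, e in pieces
    ]
    return match


class AnnotationIndex:
    """Interval indexes over coding-gene CDS exons, introns and spans."""

    def __init__(self, annotation: GenomeAnnotation):
        self.cds: dict[str, IntervalTree] = {}
        self.introns: dict[str, IntervalTree] = {}
        self.spans: dict[str, IntervalTree] = {}
        for gene in annotation.genes:
            cds_tree = self.cds.setdefault(gene.chrom, IntervalTree())
            for s, e in gene.cds:
                cds_tree.addi(s, e, gene)
            intron_tree = self.introns.setdefault(gene.chrom, IntervalTree())
            for s, e in gene.introns:
                intron_tree.addi(s, e, gene)
            self.spans.setdefault(gene.chrom, IntervalTree()).addi(
                gene.span[0], gene.span[1], gene
            )
        self.chroms = set(self.spans)


def classify_region(
    match: PeptideMatch, annotation: GenomeAnnotation | AnnotationIndex
) -> str:
    """Classify the peptide-coding genomic region.

    novel_orf  -- any coding base overlaps an annotated CDS exon (any strand:
                  the peptide is already proteome-excluded, so CDS overlap
                  implies a frameshift or alternate start);
    intronic   -- otherwise, any base inside a coding gene's intronic space;
    noncoding  -- everything else (including UTR-exon-only overlap).
    """
    if not match.genomic_intervals:
        raise ValueError("genomic_intervals not filled; call map_to_genome first")
    index = annotation if isinstance(annotation, AnnotationIndex) else AnnotationIndex(annotation)
    chroms = {chrom for chrom, *_ in match.genomic_intervals}
    if not chroms & index.chroms:
        log.warning(
            "%s: chromosome(s) %s not annotated; classifying noncoding",
            match.peptide,
            sorted(chroms),
        )
        match.region_class = "noncoding"
        return match.region_class
    cls = "noncoding"
    for chrom, start, end, _ in match.genomic_intervals:
        if chrom in index.cds and index.cds[chrom].overlap(start, end):
            cls = "novel_orf"
            break
        if chrom in index.introns and index.introns[chrom].overlap(start, end):
            cls = "intronic"
    match.region_class = cls
    return cls


def classify_source(
    transcript: TranscriptRecord, annotation: GenomeAnnotation | AnnotationIndex
) -> str:
    """Classify the source transcript relative to coding genes.

    Precedence: antisense (span overlaps a coding gene on the opposite
    strand) > sense_intronic (fully inside a same-strand gene's intron) >
    intergenic_lncRNA.
    """
    index = annotation if isinstance(annotation, AnnotationIndex) else AnnotationIndex(annotation)
    span_tree = index.spans.get(transcript.chrom)
    if span_tree is not None:
        hits = span_tree.overlap(transcript.tx_start, transcript.tx_end)
        for hit in hits:
            if hit.data.strand != transcript.strand:
                return "antisense"
        intron_tree = index.introns.get(transcript.chrom)
        if intron_tree is not None:
            for iv in intron_tree.overlap(transcript.tx_start, transcript.tx_end):
                if (
                    iv.data.strand == transcript.strand
                    and iv.begin <= transcript.tx_start
                    and transcript.tx_end <= iv.end
                ):
                    return "sense_intronic"
    return "intergenic_lncRNA"


def check_expression(match: PeptideMatch, coverage: CoverageSet) -> bool:
    """Expressed iff every base of every peptide-coding interval is covered."""
    if not match.genomic_intervals:
        raise ValueError("genomic_intervals not filled; call map_to_genome first")
    expressed = all(
        coverage.covers(chrom, start, end)
        for chrom, start, end, _ in match.genomic_intervals
    )
    match.expressed = expressed
    return expressed


def extract_coding_sequence(
    match: PeptideMatch, genome: dict[str, str]
) -> str:
    """Concatenate the genome bases under the match (coding-strand oriented)."""
    from .sixframe import reverse_complement

    pieces = [genome[chrom][s:e] for chrom, s, e, _ in match.genomic_intervals]
    strand = match.genomic_intervals[0][3]
    seq = "".join(pieces)
    return reverse_complement(seq) if strand == "-" else seq
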