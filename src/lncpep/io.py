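"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates held in memory are 0-based half-open (BED-native).
Any 1-based interchange is confined to formatting code in this module.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
NT_ALPHABET = frozenset("ACGTN")

_PTM_RE = re.compile(r"\(([^)]*)\)")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptRecord:
    """A spliced transcript with its BED12 block structure.

    ``sequence`` is the spliced sequence, 5'->3' on the transcript strand.
    ``blocks`` are (genomic_start, size) pairs in genomic order.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    blocks: tuple[tuple[int, int], ...]
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.transcript_id}: strand must be + or -")
        bad = set(self.sequence) - NT_ALPHABET
        if bad:
            raise FormatError(
                f"{self.transcript_id}: unsupported nucleotide codes {sorted(bad)}"
            )
        total = sum(size for _, size in self.blocks)
        if total != len(self.sequence):
            raise FormatError(
                f"{self.transcript_id}: block sizes sum to {total} but sequence "
                f"length is {len(self.sequence)}"
            )
        prev_end = None
        for start, size in self.blocks:
            if size <= 0:
                raise FormatError(f"{self.transcript_id}: non-positive block size")
            if prev_end is not None and start < prev_end:
                raise FormatError(
                    f"{self.transcript_id}: blocks overlap or are unsorted"
                )
            prev_end = start + size
        if self.blocks:
            if self.tx_start > self.blocks[0][0]:
                raise FormatError(f"{self.transcript_id}: tx_start after first block")
            if prev_end > self.tx_end:
                raise FormatError(f"{self.transcript_id}: last block beyond tx_end")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideObservation:
    """One de novo (or DB-search) peptide observation in one sample."""

    sequence: str
    alc: float
    sample_id: str
    intensity: float | None = None
    origin: str = "de_novo_only"
    modifications: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise FormatError(f"peptide {self.sequence!r}: non-amino-acid {sorted(bad)}")
        if not 0.0 <= self.alc <= 100.0:
            raise FormatError(f"peptide {self.sequence}: ALC {self.alc} outside 0-100")
        if self.origin not in ("db_search", "de_novo_only"):
            raise FormatError(f"peptide {self.sequence}: unknown origin {self.origin}")


@dataclass(frozen=True)
class BinderCall:
    """Predicted %Rank of one peptide against one HLA allele."""

    peptide: str
    allele: str
    rank_percent: float

    def __post_init__(self) -> None:
        if self.rank_percent < 0:
            raise FormatError(
                f"{self.peptide}/{self.allele}: negative %Rank {self.rank_percent}"
            )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for name, ivs in (("exon", self.exons), ("CDS", self.cds)):
            prev = None
            for s, e in ivs:
                if not (self.span[0] <= s < e <= self.span[1]):
                    raise FormatError(f"{self.gene_id}: {name} interval outside span")
                if prev is not None and s < prev:
                    raise FormatError(f"{self.gene_id}: {name} intervals overlap")
                prev = e
        # every CDS base must fall inside an exon
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise FormatError(f"{self.gene_id}: CDS interval not inside an exon")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)


@dataclass
class GenomeAnnotation:
    """Coding-gene models used for region/source classification."""

    genes: list[GeneModel] = field(default_factory=list)

    def by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out


class CoverageSet:
    """Per-sample merged read-coverage intervals, queryable for full containment."""

    def __init__(self, sample_id: str, intervals: Mapping[str, Iterable[tuple[int, int]]]):
        self.sample_id = sample_id
        self.intervals: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in intervals.items():
            self.intervals[chrom] = merge_intervals(ivs)

    def covers(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) is fully inside one merged coverage interval."""
        if start >= end:
            raise ValueError("empty interval")
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        i = bisect_right([s for s, _ in ivs], start) - 1
        if i < 0:
            return False
        s, e = ivs[i]
        return s <= start and end <= e


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if s >= e:
            raise FormatError(f"empty or inverted interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, rna_to_dna: bool = False) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercased sequence) pairs, order preserved.

    With ``rna_to_dna`` every U is normalized to T (for RNA-alphabet
    transcript databases).
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if rna_to_dna:
            seq = seq.replace("U", "T")
        if not seq:
            raise FormatError(f"empty sequence for FASTA ID {rec.id!r} in {path}")
        records.append((rec.id, seq))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED12 transcripts and gene models
# ---------------------------------------------------------------------------


def _split_bed_list(text: str, what: str, line_no: int) -> list[int]:
    try:
        return [int(x) for x in text.rstrip(",").split(",")]
    except ValueError as exc:
        raise FormatError(f"line {line_no}: bad {what} list {text!r}") from exc


def _parse_bed12_line(line: str, line_no: int):
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise FormatError(f"line {line_no}: expected 12 BED columns, got {len(cols)}")
    chrom, start, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
    strand = cols[5]
    n_blocks = int(cols[9])
    sizes = _split_bed_list(cols[10], "blockSizes", line_no)
    starts = _split_bed_list(cols[11], "blockStarts", line_no)
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise FormatError(f"line {line_no}: blockCount disagrees with block lists")
    if starts[0] != 0 or start + starts[-1] + sizes[-1] != end:
        # blockStarts must be relative to chromStart and the blocks must tile
        # out to chromEnd; anything else is a non-standard dialect we reject.
        raise FormatError(
            f"line {line_no} ({name}): blockStarts not relative to chromStart"
        )
    blocks = tuple((start + rel, size) for rel, size in zip(starts, sizes))
    thick = (int(cols[6]), int(cols[7]))
    return chrom, start, end, name, strand, blocks, thick


def gene_id_from_transcript(transcript_id: str) -> str:
    """LNCipedia-style names encode the gene before the ':' transcript index."""
    return transcript_id.split(":")[0]


def read_bed12(
    path: str | Path,
    fasta_by_id: Mapping[str, str],
    valid_chroms: Iterable[str] | None = None,
) -> list[TranscriptRecord]:
    """Load transcripts from BED12, attaching spliced sequences by ID."""
    chrom_set = set(valid_chroms) if valid_chroms is not None else None
    out: list[TranscriptRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, strand, blocks, _ = _parse_bed12_line(line, line_no)
            if chrom_set is not None and chrom not in chrom_set:
                raise FormatError(f"{name}: chromosome {chrom!r} absent from genome")
            if name not in fasta_by_id:
                raise FormatError(f"{name}: no FASTA sequence for transcript")
            seq = fasta_by_id[name]
            total = sum(size for _, size in blocks)
            if total != len(seq):
                raise FormatError(
                    f"{name}: BED blocks sum to {total} nt but FASTA has {len(seq)} nt"
                )
            out.append(
                TranscriptRecord(
                    transcript_id=name,
                    gene_id=gene_id_from_transcript(name),
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    blocks=blocks,
                    sequence=seq,
                )
            )
    return out


def write_bed12(path: str | Path, transcripts: Iterable[TranscriptRecord]) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(size) for _, size in t.blocks)
            rels = ",".join(str(start - t.tx_start) for start, _ in t.blocks)
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.tx_start),
                        str(t.tx_end),
                        t.transcript_id,
                        "0",
                        t.strand,
                        str(t.tx_start),
                        str(t.tx_start),
                        "0",
                        str(len(t.blocks)),
                        sizes,
                        rels,
                    ]
                )
                + "\n"
            )


def read_gene_bed12(path: str | Path) -> GenomeAnnotation:
    """Read coding-gene models from BED12.

    Blocks are exons; the thickStart/thickEnd pair delimits the CDS span, and
    CDS intervals are the exon pieces falling inside it (the standard BED12
    gene-model encoding).
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, strand, blocks, thick = _parse_bed12_line(
                line, line_no
            )
            exons = tuple((s, s + size) for s, size in blocks)
            ts, te = thick
            cds = tuple(
                (max(s, ts), min(e, te))
                for s, e in exons
                if max(s, ts) < min(e, te)
            )
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    span=(start, end),
                    exons=exons,
                    cds=cds,
                )
            )
    return GenomeAnnotation(genes=genes)


def write_gene_bed12(path: str | Path, annotation: GenomeAnnotation) -> None:
    with open(path, "w") as fh:
        for g in annotation.genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            rels = ",".join(str(s - g.span[0]) for s, _ in g.exons)
            thick_s = g.cds[0][0] if g.cds else g.span[0]
            thick_e = g.cds[-1][1] if g.cds else g.span[0]
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.span[0]),
                        str(g.span[1]),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(thick_s),
                        str(thick_e),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        rels,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6 coverage and generic interval output
# ---------------------------------------------------------------------------


def read_coverage_bed(path: str | Path, sample_id: str) -> CoverageSet:
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise FormatError(f"line {line_no}: expected >=3 BED columns")
            intervals.setdefault(cols[0], []).append((int(cols[1]), int(cols[2])))
    return CoverageSet(sample_id, intervals)


def write_bed6(
    path: str | Path,
    rows: Iterable[tuple[str, int, int, str, float | int, str]],
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def strip_ptm_annotations(sequence: str) -> tuple[str, tuple[str, ...]]:
    """Remove parenthesized PTM annotations, e.g. 'M(+15.99)PEP' -> ('MPEP', ('+15.99',))."""
    mods = tuple(_PTM_RE.findall(sequence))
    return _PTM_RE.sub("", sequence), mods


def read_peptide_table(path: str | Path) -> list[PeptideObservation]:
    """Read a de novo export TSV with required columns peptide, alc, sample."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require_columns(df, ["peptide", "alc", "sample"], path)
    out: list[PeptideObservation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        raw = str(row.peptide)
        seq, mods = strip_ptm_annotations(raw)
        try:
            alc = float(row.alc)
        except ValueError as exc:
            raise FormatError(f"{path} row {i}: non-numeric ALC {row.alc!r}") from exc
        intensity = None
        if "intensity" in df.columns and pd.notna(getattr(row, "intensity", None)):
            intensity = float(row.intensity)
        origin = "de_novo_only"
        if "origin" in df.columns and pd.notna(getattr(row, "origin", None)):
            origin = str(row.origin)
        try:
            obs = PeptideObservation(
                sequence=seq,
                alc=alc,
                sample_id=str(row.sample),
                intensity=intensity,
                origin=origin,
                modifications=mods,
            )
        except FormatError as exc:
            raise FormatError(f"{path} row {i}: {exc}") from exc
        out.append(obs)
    return out


def write_peptide_table(path: str | Path, observations: Iterable[PeptideObservation]) -> None:
    rows = []
    for o in observations:
        seq = o.sequence
        rows.append(
            {
                "peptide": seq,
                "alc": o.alc,
                "sample": o.sample_id,
                "intensity": "" if o.intensity is None else o.intensity,
                "origin": o.origin,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_RANK_COLUMN_ALIASES = ("rank", "%rank", "rank_percent")


def read_rank_table(path: str | Path) -> list[BinderCall]:
    """Read a %Rank table (peptide, allele, %Rank), collapsing duplicates to the minimum."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    rank_col = next((c for c in _RANK_COLUMN_ALIASES if c in df.columns), None)
    if rank_col is None or "peptide" not in df.columns or "allele" not in df.columns:
        raise FormatError(f"{path}: need columns peptide, allele and a %Rank column")
    best: dict[tuple[str, str], float] = {}
    duplicated = False
    for row in df.itertuples(index=False):
        key = (str(row.peptide), str(row.allele))
        rank = float(getattr(row, rank_col))
        if rank < 0:
            raise FormatError(f"{path}: negative %Rank for {key[0]}/{key[1]}")
        if key in best:
            duplicated = True
            best[key] = min(best[key], rank)
        else:
            best[key] = rank
    if duplicated:
        log.warning("%s: duplicate (peptide, allele) rows collapsed to minimum %%Rank", path)
    return [BinderCall(p, a, r) for (p, a), r in best.items()]


def write_rank_table(path: str | Path, calls: Iterable[BinderCall]) -> None:
    pd.DataFrame(
        [{"peptide": c.peptide, "allele": c.allele, "rank": c.rank_percent} for c in calls]
    ).to_csv(path, sep="\t", index=False)


def read_sample_alleles(path: str | Path) -> dict[str, list[str]]:
    """Read a long-format sample/allele TSV into {sample_id: [alleles]}."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require_columns(df, ["sample", "allele"], path)
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        alleles = out.setdefault(str(row.sample), [])
        if row.allele not in alleles:
            alleles.append(str(row.allele))
    return out


def write_sample_alleles(path: str | Path, alleles_by_sample: Mapping[str, Sequence[str]]) -> None:
    rows = [
        {"sample": s, "allele": a}
        for s in sorted(alleles_by_sample)
        for a in alleles_by_sample[s]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
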