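"""Synthetic fixture universe with ground truth.

Generates a toy genome with coding-gene models, lncRNA transcripts placed in
unambiguous genomic contexts, a reference proteome, de novo peptide
observations (spiked lncRNA peptides, proteome substrings, and random
decoys), per-sample read coverage, and HLA %Rank tables -- everything the
pipeline consumes, with truth labels recorded at construction time.

Context placement is deliberate so the intended classes never depend on the
classifiers under test:

* antisense lncRNAs sit wholly inside a CDS exon (peptides -> novel_orf) or
  wholly inside an intron (peptides -> intronic), on the strand opposite the
  host gene;
* sense-intronic lncRNAs sit wholly inside an intron on the host strand
  (peptides -> intronic);
* intergenic lncRNAs overlap nothing (peptides -> noncoding).

Expression truth is assigned per transcript: fully covered, uncovered, or --
for one single-block '+' transcript -- covered only up to the spiked
peptide's start (the truncated-transcript case), using the generator's own
prefix arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .filtering import collapse_il
from .io import (
    CoverageSet,
    GeneModel,
    GenomeAnnotation,
    PeptideObservation,
    TranscriptRecord,
    write_bed12,
    write_fasta,
    write_gene_bed12,
    write_peptide_table,
    write_rank_table,
    write_sample_alleles,
)
from .io import BinderCall
from .sixframe import FrameTranslation, build_translated_db, reverse_complement

AA20 = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_CHROM_LENGTHS = {"chr1": 60_000, "chr2": 40_000}
DEFAULT_ALLELES = {
    "s1": ["HLA-A*02:01", "HLA-B*07:02"],
    "s2": ["HLA-A*01:01", "HLA-C*07:01"],
}


# ---------------------------------------------------------------------------
# genome + gene models
# ---------------------------------------------------------------------------

_EXON1, _INTRON1, _EXON2, _INTRON2, _EXON3 = 1200, 2800, 3000, 2800, 1200
_GENE_SPAN = _EXON1 + _INTRON1 + _EXON2 + _INTRON2 + _EXON3
_UTR = 300  # UTR length at each CDS end
_GENE_START = 2500
_GENE_GAP = 4000


def make_genome(
    seed: int, chrom_lengths: Mapping[str, int] | None = None
) -> tuple[list[tuple[str, str]], GenomeAnnotation]:
    """Uniform-random genome with three-exon coding genes laid out on each
    chromosome; deterministic per seed."""
    chrom_lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    for name, length in chrom_lengths.items():
        if length < 10_000:
            raise ValueError(f"{name}: chromosome must be >= 10 kb, got {length}")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = []
    genes = []
    for ci, (name, length) in enumerate(sorted(chrom_lengths.items())):
        seq = bases[rng.integers(0, 4, size=length)].tobytes().decode()
        genome.append((name, seq))
        pos = _GENE_START
        gi = 0
        while pos + _GENE_SPAN + _GENE_GAP // 2 <= length:
            e1 = (pos, pos + _EXON1)
            e2 = (e1[1] + _INTRON1, e1[1] + _INTRON1 + _EXON2)
            e3 = (e2[1] + _INTRON2, e2[1] + _INTRON2 + _EXON3)
            cds = ((e1[0] + _UTR, e1[1]), e2, (e3[0], e3[1] - _UTR))
            strand = "+" if (ci + gi) % 2 == 0 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene_{name}_{gi}",
                    chrom=name,
                    strand=strand,
                    span=(pos, e3[1]),
                    exons=(e1, e2, e3),
                    cds=cds,
                )
            )
            pos = e3[1] + _GENE_GAP
            gi += 1
        if gi == 0:
            raise ValueError(f"{name}: too short to place any gene")
    return genome, GenomeAnnotation(genes=genes)


# ---------------------------------------------------------------------------
# lncRNA placement
# ---------------------------------------------------------------------------


def _spliced_sequence(
    genome_by_name: Mapping[str, str],
    chrom: str,
    strand: str,
    blocks: Sequence[tuple[int, int]],
) -> str:
    seq = "".join(genome_by_name[chrom][s : s + size] for s, size in blocks)
    return reverse_complement(seq) if strand == "-" else seq


def _make_blocks(rng: np.random.Generator, start: int, single_block: bool) -> tuple[tuple[int, int], ...]:
    if single_block:
        return ((start, int(rng.integers(330, 450))),)
    size1 = int(rng.integers(150, 210))
    gap = int(rng.integers(60, 110))
    size2 = int(rng.integers(150, 210))
    return ((start, size1), (start + size1 + gap, size2))


_MAX_LNC_SPAN = 450 + 110 + 210  # generous upper bound on any placement


@dataclass(frozen=True)
class LncMeta:
    source_class: str
    region_class: str


def make_lncRNAs(
    genome: Sequence[tuple[str, str]],
    annotation: GenomeAnnotation,
    counts: Mapping[str, int],
    seed: int,
) -> tuple[list[TranscriptRecord], dict[str, LncMeta]]:
    """Place lncRNA transcripts per source class with intended region labels.

    ``counts`` keys: antisense, sense_intronic, intergenic. Antisense
    transcripts alternate between CDS-exon hosts (novel_orf placements) and
    intron hosts (intronic placements).
    """
    rng = np.random.default_rng(seed)
    genome_by_name = dict(genome)
    genes = annotation.genes
    if not genes:
        raise ValueError("annotation has no genes; placement impossible")

    # candidate host regions
    cds_hosts = [(g, g.cds[1]) for g in genes]  # the large middle CDS exon
    intron_hosts = [(g, intron) for g in genes for intron in g.introns]
    intergenic_hosts: list[tuple[str, int, int]] = []
    for chrom, seq in genome:
        spans = sorted(g.span for g in genes if g.chrom == chrom)
        prev = 0
        for s, e in spans + [(len(seq), len(seq))]:
            if s - prev >= _MAX_LNC_SPAN + 2_000:
                intergenic_hosts.append((chrom, prev + 1_000, s - 1_000))
            prev = e
    cursors: dict[tuple, int] = {}  # host region -> next free position

    def place(host_key: tuple, lo: int, hi: int, blocks_fn) -> tuple[tuple[int, int], ...] | None:
        pos = cursors.get(host_key, lo)
        blocks = blocks_fn(pos)
        span_end = blocks[-1][0] + blocks[-1][1]
        if span_end > hi:
            return None
        cursors[host_key] = span_end + 150
        return blocks

    transcripts: list[TranscriptRecord] = []
    meta: dict[str, LncMeta] = {}

    def add(name: str, chrom: str, strand: str, blocks, source: str, region: str) -> None:
        seq = _spliced_sequence(genome_by_name, chrom, strand, blocks)
        transcripts.append(
            TranscriptRecord(
                transcript_id=f"{name}:1",
                gene_id=name,
                chrom=chrom,
                strand=strand,
                tx_start=blocks[0][0],
                tx_end=blocks[-1][0] + blocks[-1][1],
                blocks=tuple(blocks),
                sequence=seq,
            )
        )
        meta[f"{name}:1"] = LncMeta(source_class=source, region_class=region)

    for i in range(counts.get("antisense", 0)):
        over_cds = i % 2 == 0
        hosts = cds_hosts if over_cds else intron_hosts
        placed = False
        for h in range(len(hosts)):
            gene, (lo, hi) = hosts[(i + h) % len(hosts)]
            key = (gene.chrom, lo, hi)
            single = bool(rng.integers(0, 2))
            blocks = place(key, lo + 50, hi - 50, lambda p: _make_blocks(rng, p, single))
            if blocks is not None:
                strand = "-" if gene.strand == "+" else "+"
                add(
                    f"lnc-AS-{i}", gene.chrom, strand, blocks,
                    "antisense", "novel_orf" if over_cds else "intronic",
                )
                placed = True
                break
        if not placed:
            raise ValueError("antisense placement impossible; enlarge the genome")

    for i in range(counts.get("sense_intronic", 0)):
        placed = False
        for h in range(len(intron_hosts)):
            gene, (lo, hi) = intron_hosts[(i + h) % len(intron_hosts)]
            key = (gene.chrom, lo, hi)
            single = bool(rng.integers(0, 2))
            blocks = place(key, lo + 50, hi - 50, lambda p: _make_blocks(rng, p, single))
            if blocks is not None:
                add(f"lnc-SI-{i}", gene.chrom, gene.strand, blocks, "sense_intronic", "intronic")
                placed = True
                break
        if not placed:
            raise ValueError("sense-intronic placement impossible; enlarge the genome")

    for i in range(counts.get("intergenic", 0)):
        placed = False
        for h in range(len(intergenic_hosts)):
            chrom, lo, hi = intergenic_hosts[(i + h) % len(intergenic_hosts)]
            key = (chrom, lo, hi)
            # the first intergenic transcript is single-block '+' so the
            # truncated-coverage case has a trivially projectable layout
            single = True if i == 0 else bool(rng.integers(0, 2))
            strand = "+" if i == 0 else ("+" if rng.integers(0, 2) else "-")
            blocks = place(key, lo, hi, lambda p: _make_blocks(rng, p, single))
            if blocks is not None:
                add(f"lnc-IG-{i}", chrom, strand, blocks, "intergenic_lncRNA", "noncoding")
                placed = True
                break
        if not placed:
            raise ValueError("intergenic placement impossible; enlarge the genome")

    return transcripts, meta


# ---------------------------------------------------------------------------
# peptide spiking
# ---------------------------------------------------------------------------


def _count_db_occurrences(peptide: str, db: Sequence[FrameTranslation], il: bool = True) -> int:
    """Stop-aware occurrence count of a peptide across all frames (generator's
    own scan, independent of the matching module)."""
    q = collapse_il(peptide) if il else peptide
    total = 0
    for fr in db:
        hay = collapse_il(fr.aa_sequence) if il else fr.aa_sequence
        pos = hay.find(q)
        while pos != -1:
            if "*" not in hay[pos : pos + len(q)]:
                total += 1
            pos = hay.find(q, pos + 1)
    return total


@dataclass
class SpikeRecord:
    peptide: str
    transcript_id: str
    frame_id: int
    aa_start: int
    sample_id: str
    source_class: str
    region_class: str
    expressed: bool
    expression_mode: str  # full | none | truncated
    binder: bool | None = None


@dataclass
class FixtureTruth:
    """Ground-truth labels recorded while building a fixture universe."""

    spiked: dict[str, SpikeRecord] = field(default_factory=dict)
    proteome_substrings: list[str] = field(default_factory=list)
    random_decoys: list[str] = field(default_factory=list)

    def expected_final(self) -> set[str]:
        """Peptides the full pipeline should keep: spiked, binder, expressed."""
        return {
            p for p, r in self.spiked.items() if r.expressed and r.binder
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "spiked": {p: vars(r) for p, r in sorted(self.spiked.items())},
                "proteome_substrings": sorted(self.proteome_substrings),
                "random_decoys": sorted(self.random_decoys),
            },
            indent=1,
            sort_keys=True,
        )


def make_proteome(seed: int, n_entries: int = 30, min_len: int = 200, max_len: int = 400) -> list[tuple[str, str]]:
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AA20.encode(), dtype=np.uint8)
    out = []
    for i in range(n_entries):
        length = int(rng.integers(min_len, max_len + 1))
        out.append((f"prot_{i:03d}", aa[rng.integers(0, 20, size=length)].tobytes().decode()))
    return out


def spike_peptides(
    lncRNAs: Sequence[TranscriptRecord],
    lnc_meta: Mapping[str, LncMeta],
    proteome: Sequence[tuple[str, str]],
    n_spiked: int,
    n_proteome: int,
    n_decoy: int,
    seed: int,
    samples: Sequence[str] = ("s1", "s2"),
    unexpressed_fraction: float = 0.25,
) -> tuple[list[PeptideObservation], FixtureTruth, dict[str, tuple[str, int]]]:
    """Draw spiked / proteome-substring / decoy peptides with truth labels.

    Returns (observations, truth, expression_plan) where expression_plan maps
    transcript_id -> (mode, truncation_cut); mode is full/none/truncated and
    the cut is the transcript-coordinate prefix length covered for the
    truncated case (0 otherwise).
    """
    rng = np.random.default_rng(seed)
    db = build_translated_db(lncRNAs)
    frames_by_tid: dict[str, list[FrameTranslation]] = {}
    for fr in db:
        frames_by_tid.setdefault(fr.transcript_id, []).append(fr)
    proteome_blob = collapse_il("#".join(seq for _, seq in proteome))

    # expression plan per transcript: one truncated case (the single-block '+'
    # transcript placed for it), then ~unexpressed_fraction uncovered
    plan: dict[str, tuple[str, int]] = {}
    trunc_tid = next(
        (
            t.transcript_id
            for t in lncRNAs
            if len(t.blocks) == 1 and t.strand == "+"
        ),
        None,
    )
    others = [t.transcript_id for t in lncRNAs if t.transcript_id != trunc_tid]
    n_unexpressed = max(1, round(unexpressed_fraction * len(others))) if others else 0
    unexpressed = set(
        rng.choice(len(others), size=min(n_unexpressed, len(others)), replace=False)
    )
    for t in lncRNAs:
        if t.transcript_id == trunc_tid:
            plan[t.transcript_id] = ("truncated", 0)  # cut filled after spiking
        elif others.index(t.transcript_id) in unexpressed:
            plan[t.transcript_id] = ("none", 0)
        else:
            plan[t.transcript_id] = ("full", 0)

    truth = FixtureTruth()
    observations: list[PeptideObservation] = []
    chosen: set[str] = set()

    def pick_from_transcript(t: TranscriptRecord, suffix_only: bool) -> SpikeRecord | None:
        for _ in range(60):
            fr = frames_by_tid[t.transcript_id][int(rng.integers(0, 6))]
            pep_len = int(rng.integers(8, 15))
            segments = [s for s in fr.segments if len(s[1]) >= pep_len]
            if not segments:
                continue
            seg_start, segment = segments[int(rng.integers(0, len(segments)))]
            pos = int(rng.integers(0, len(segment) - pep_len + 1))
            pep = segment[pos : pos + pep_len]
            aa_start = seg_start + pos
            if suffix_only:
                # truncated case: forward frame, window in the 3' half, so the
                # uncovered genomic suffix is tx_start + nt_start onward
                if fr.frame_id < 0:
                    continue
                nt_start = (fr.frame_id - 1) + 3 * aa_start
                if nt_start < t.length * 2 // 3:
                    continue
            if pep in chosen or "X" in pep:
                continue
            if _count_db_occurrences(pep, db) != 1:
                continue
            if collapse_il(pep) in proteome_blob:
                continue
            chosen.add(pep)
            meta = lnc_meta[t.transcript_id]
            mode = plan[t.transcript_id][0]
            if mode == "truncated":
                nt_start = (fr.frame_id - 1) + 3 * aa_start
                plan[t.transcript_id] = ("truncated", nt_start)
            return SpikeRecord(
                peptide=pep,
                transcript_id=t.transcript_id,
                frame_id=fr.frame_id,
                aa_start=aa_start,
                sample_id=str(samples[int(rng.integers(0, len(samples)))]),
                source_class=meta.source_class,
                region_class=meta.region_class,
                expressed=(mode == "full"),
                expression_mode=mode,
            )
        return None

    # one spike on the truncated transcript, the rest round-robin elsewhere
    order = [t for t in lncRNAs if t.transcript_id != trunc_tid]
    if trunc_tid is not None and n_spiked > 0:
        t = next(t for t in lncRNAs if t.transcript_id == trunc_tid)
        rec = pick_from_transcript(t, suffix_only=True)
        if rec is None:
            raise ValueError(f"could not spike the truncated transcript {trunc_tid}")
        truth.spiked[rec.peptide] = rec
    i = 0
    guard = 0
    while len(truth.spiked) < n_spiked:
        guard += 1
        if guard > 50 * n_spiked:
            raise ValueError("insufficient stop-free segment space for spiking")
        t = order[i % len(order)]
        i += 1
        rec = pick_from_transcript(t, suffix_only=False)
        if rec is not None:
            truth.spiked[rec.peptide] = rec

    for rec in truth.spiked.values():
        observations.append(
            PeptideObservation(
                sequence=rec.peptide,
                alc=round(float(rng.uniform(55, 99)), 1),
                sample_id=rec.sample_id,
                intensity=round(float(rng.lognormal(14, 1)), 1),
            )
        )

    # proteome-substring peptides: removed by reference-proteome exclusion
    guard = 0
    while len(truth.proteome_substrings) < n_proteome:
        guard += 1
        if guard > 50 * max(n_proteome, 1):
            raise ValueError("could not draw proteome-substring peptides")
        _, pseq = proteome[int(rng.integers(0, len(proteome)))]
        pep_len = int(rng.integers(8, 15))
        pos = int(rng.integers(0, len(pseq) - pep_len + 1))
        pep = pseq[pos : pos + pep_len]
        if pep in chosen or _count_db_occurrences(pep, db) != 0:
            continue
        chosen.add(pep)
        truth.proteome_substrings.append(pep)
        observations.append(
            PeptideObservation(
                sequence=pep,
                alc=round(float(rng.uniform(55, 99)), 1),
                sample_id=str(samples[int(rng.integers(0, len(samples)))]),
                intensity=round(float(rng.lognormal(14, 1)), 1),
            )
        )

    # random decoys: match nothing; half carry sub-threshold ALC
    aa = np.frombuffer(AA20.encode(), dtype=np.uint8)
    guard = 0
    while len(truth.random_decoys) < n_decoy:
        guard += 1
        if guard > 50 * max(n_decoy, 1):
            raise ValueError("could not draw decoy peptides")
        pep_len = int(rng.integers(8, 15))
        pep = aa[rng.integers(0, 20, size=pep_len)].tobytes().decode()
        if (
            pep in chosen
            or _count_db_occurrences(pep, db) != 0
            or collapse_il(pep) in proteome_blob
        ):
            continue
        chosen.add(pep)
        truth.random_decoys.append(pep)
        low_alc = len(truth.random_decoys) % 2 == 0
        observations.append(
            PeptideObservation(
                sequence=pep,
                alc=round(float(rng.uniform(20, 49) if low_alc else rng.uniform(55, 95)), 1),
                sample_id=str(samples[int(rng.integers(0, len(samples)))]),
                intensity=round(float(rng.lognormal(14, 1)), 1),
            )
        )

    return observations, truth, plan


# ---------------------------------------------------------------------------
# coverage and rank tables
# ---------------------------------------------------------------------------


def make_coverage(
    lncRNAs: Sequence[TranscriptRecord],
    expression_plan: Mapping[str, tuple[str, int]],
    samples: Sequence[str] = ("s1", "s2"),
) -> dict[str, CoverageSet]:
    """Per-sample coverage: expressed transcripts fully covered (every block,
    +-10 nt padding), unexpressed ones uncovered, the truncated one covered
    only on the prefix before its spiked peptide."""
    intervals: dict[str, list[tuple[str, int, int]]] = {s: [] for s in samples}
    for t in lncRNAs:
        mode, cut = expression_plan.get(t.transcript_id, ("full", 0))
        if mode == "none":
            continue
        for sample in samples:
            if mode == "full":
                for start, size in t.blocks:
                    intervals[sample].append((t.chrom, max(0, start - 10), start + size + 10))
            else:  # truncated: single-block '+' transcript by construction
                if cut > 0:
                    intervals[sample].append((t.chrom, t.tx_start, t.tx_start + cut))
    return {
        s: CoverageSet(s, _group_by_chrom(ivs)) for s, ivs in intervals.items()
    }


def _group_by_chrom(rows: Sequence[tuple[str, int, int]]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in rows:
        out.setdefault(chrom, []).append((s, e))
    return out


def make_rank_table(
    observations: Sequence[PeptideObservation],
    alleles_by_sample: Mapping[str, Sequence[str]],
    binder_fraction: float,
    seed: int,
) -> tuple[list[BinderCall], dict[str, bool]]:
    """%Rank calls for every observed peptide against its sample's alleles.

    A designated-binder peptide gets one allele with rank in (0, 2.0) in one
    observing sample; every other (peptide, allele) rank is in (2.0, 50).
    Returns the calls and the intended binder flag per peptide.
    """
    if not 0.0 <= binder_fraction <= 1.0:
        raise ValueError("binder_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    pep_samples: dict[str, list[str]] = {}
    for obs in observations:
        pep_samples.setdefault(obs.sequence, [])
        if obs.sample_id not in pep_samples[obs.sequence]:
            pep_samples[obs.sequence].append(obs.sample_id)
    calls: list[BinderCall] = []
    intended: dict[str, bool] = {}
    for pep in sorted(pep_samples):
        is_binder = bool(rng.random() < binder_fraction)
        intended[pep] = is_binder
        binder_slot = None
        if is_binder:
            sample = pep_samples[pep][int(rng.integers(0, len(pep_samples[pep])))]
            alleles = alleles_by_sample[sample]
            binder_slot = (sample, alleles[int(rng.integers(0, len(alleles)))])
        for sample in pep_samples[pep]:
            for allele in alleles_by_sample[sample]:
                if binder_slot == (sample, allele):
                    rank = float(rng.uniform(0.05, 1.95))
                else:
                    rank = float(rng.uniform(2.05, 45.0))
                calls.append(BinderCall(pep, allele, round(rank, 3)))
    return calls, intended


# ---------------------------------------------------------------------------
# whole-universe convenience
# ---------------------------------------------------------------------------


@dataclass
class Universe:
    genome: list[tuple[str, str]]
    annotation: GenomeAnnotation
    proteome: list[tuple[str, str]]
    transcripts: list[TranscriptRecord]
    lnc_meta: dict[str, LncMeta]
    observations: list[PeptideObservation]
    coverage: dict[str, CoverageSet]
    calls: list[BinderCall]
    alleles_by_sample: dict[str, list[str]]
    truth: FixtureTruth


def make_universe(
    seed: int,
    counts: Mapping[str, int] | None = None,
    n_spiked: int = 60,
    n_proteome: int = 10,
    n_decoy: int = 20,
    binder_fraction: float = 0.7,
    chrom_lengths: Mapping[str, int] | None = None,
    alleles_by_sample: Mapping[str, Sequence[str]] | None = None,
) -> Universe:
    """Build a complete, deterministic fixture universe."""
    counts = dict(counts or {"antisense": 4, "sense_intronic": 4, "intergenic": 4})
    alleles_by_sample = {
        k: list(v) for k, v in (alleles_by_sample or DEFAULT_ALLELES).items()
    }
    samples = sorted(alleles_by_sample)
    genome, annotation = make_genome(seed, chrom_lengths)
    proteome = make_proteome(seed + 1)
    transcripts, meta = make_lncRNAs(genome, annotation, counts, seed + 2)
    observations, truth, plan = spike_peptides(
        transcripts, meta, proteome, n_spiked, n_proteome, n_decoy, seed + 3, samples
    )
    coverage = make_coverage(transcripts, plan, samples)
    calls, intended_binder = make_rank_table(
        observations, alleles_by_sample, binder_fraction, seed + 4
    )
    for pep, rec in truth.spiked.items():
        rec.binder = intended_binder[pep]
    return Universe(
        genome=genome,
        annotation=annotation,
        proteome=proteome,
        transcripts=transcripts,
        lnc_meta=meta,
        observations=observations,
        coverage=coverage,
        calls=calls,
        alleles_by_sample=alleles_by_sample,
        truth=truth,
    )


def write_universe(universe: Universe, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture file in standard formats; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_fasta": outdir / "genome.fa",
        "genes_bed": outdir / "genes.bed",
        "transcripts_fasta": outdir / "lncrna.fa",
        "transcripts_bed": outdir / "lncrna.bed",
        "proteome_fasta": outdir / "proteome.fa",
        "peptides_tsv": outdir / "peptides.tsv",
        "ranks_tsv": outdir / "ranks.tsv",
        "alleles_tsv": outdir / "alleles.tsv",
        "truth_json": outdir / "truth.json",
    }
    write_fasta(paths["genome_fasta"], universe.genome)
    write_gene_bed12(paths["genes_bed"], universe.annotation)
    write_fasta(
        paths["transcripts_fasta"],
        [(t.transcript_id, t.sequence) for t in universe.transcripts],
    )
    write_bed12(paths["transcripts_bed"], universe.transcripts)
    write_fasta(paths["proteome_fasta"], universe.proteome)
    write_peptide_table(paths["peptides_tsv"], universe.observations)
    write_rank_table(paths["ranks_tsv"], universe.calls)
    write_sample_alleles(paths["alleles_tsv"], universe.alleles_by_sample)
    paths["truth_json"].write_text(universe.truth.to_json())
    for sample, cov in sorted(universe.coverage.items()):
        p = outdir / f"coverage_{sample}.bed"
        with open(p, "w") as fh:
            for chrom in sorted(cov.intervals):
                for s, e in cov.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{sample}\t0\t+\n")
        paths[f"coverage_{sample}"] = p
    return paths
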