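"""End-to-end driver: translate -> filter -> match -> map -> binder filter ->
expression check -> region/source classification -> decoy null model ->
summaries, with per-stage counts and deterministic outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .binders import SampleAlleles, filter_binders
from .filtering import Candidate, FilterConfig, exclude_proteome, filter_denovo
from .io import (
    read_bed12,
    read_coverage_bed,
    read_fasta,
    read_gene_bed12,
    read_peptide_table,
    read_rank_table,
    read_sample_alleles,
    write_bed6,
)
from .matching import (
    AnnotationIndex,
    PeptideMatch,
    check_expression,
    classify_region,
    classify_source,
    map_to_genome,
    match_peptides,
)
from .nullmodel import (
    DecoyConfig,
    NullModelParams,
    decoy_match_count,
    empirical_pvalue,
    generate_decoy_segments,
    segment_sequences,
)
from .sixframe import build_translated_db, write_translated_fasta
from .summarize import (
    binder_fraction_by_length,
    composition_from_proteome,
    length_distribution,
    motif_percent_difference,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    transcripts_fasta: Path
    transcripts_bed: Path
    proteome_fasta: Path
    peptides_tsv: Path
    ranks_tsv: Path
    alleles_tsv: Path
    genes_bed: Path
    genome_fasta: Path | None
    coverage: dict[str, Path]
    outdir: Path
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    binder_cutoff: float = 2.0
    strong_cutoff: float = 0.5
    drop_nonbinders: bool = True
    decoy: DecoyConfig | None = None
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "binder": True,
            "expression": True,
            "classify": True,
            "decoy": True,
            "summarize": True,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        inputs = raw["inputs"]
        fc = FilterConfig(**raw.get("filter", {}))
        binder = raw.get("binder", {})
        stages = {
            "binder": True,
            "expression": True,
            "classify": True,
            "decoy": True,
            "summarize": True,
        }
        stages.update(raw.get("stages", {}))
        seed = int(raw.get("seed", 0))
        decoy = None
        if stages["decoy"]:
            decoy = DecoyConfig(seed=seed, **raw.get("decoy", {}))
        cfg = cls(
            transcripts_fasta=Path(inputs["transcripts_fasta"]),
            transcripts_bed=Path(inputs["transcripts_bed"]),
            proteome_fasta=Path(inputs["proteome_fasta"]),
            peptides_tsv=Path(inputs["peptides_tsv"]),
            ranks_tsv=Path(inputs["ranks_tsv"]),
            alleles_tsv=Path(inputs["alleles_tsv"]),
            genes_bed=Path(inputs["genes_bed"]),
            genome_fasta=Path(inputs["genome_fasta"]) if inputs.get("genome_fasta") else None,
            coverage={k: Path(v) for k, v in inputs.get("coverage", {}).items()},
            outdir=Path(raw["outdir"]),
            seed=seed,
            filter=fc,
            binder_cutoff=float(binder.get("cutoff", 2.0)),
            strong_cutoff=float(binder.get("strong_cutoff", 0.5)),
            drop_nonbinders=bool(binder.get("drop_nonbinders", True)),
            decoy=decoy,
            stages=stages,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [
            self.transcripts_fasta,
            self.transcripts_bed,
            self.proteome_fasta,
            self.peptides_tsv,
            self.ranks_tsv,
            self.alleles_tsv,
            self.genes_bed,
            *self.coverage.values(),
        ]
        if self.stages.get("decoy", True) and self.genome_fasta is not None:
            paths.append(self.genome_fasta)
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


@dataclass
class RunResult:
    matches: list[PeptideMatch]
    counts: dict[str, int]
    p_chance: float | None
    p_value: float | None
    report: dict


def _format_intervals(match: PeptideMatch) -> str:
    return ";".join(f"{c}:{s}-{e}:{st}" for c, s, e, st in match.genomic_intervals)


def run_all(config: RunConfig) -> RunResult:
    """Execute every enabled stage, writing intermediates under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise StageError(name, exc) from exc

        return wrap

    # -- load inputs
    ld = stage("load")
    transcript_fa = dict(ld(read_fasta, config.transcripts_fasta, rna_to_dna=True))
    transcripts = ld(read_bed12, config.transcripts_bed, transcript_fa)
    by_tid = {t.transcript_id: t for t in transcripts}
    proteome = ld(read_fasta, config.proteome_fasta)
    observations = ld(read_peptide_table, config.peptides_tsv)
    calls = ld(read_rank_table, config.ranks_tsv)
    alleles_by_sample = ld(read_sample_alleles, config.alleles_tsv)
    annotation = ld(read_gene_bed12, config.genes_bed)
    coverage = {
        s: ld(read_coverage_bed, p, s) for s, p in sorted(config.coverage.items())
    }
    counts["observations"] = len(observations)
    counts["transcripts"] = len(transcripts)

    # -- translate
    db = stage("translate")(build_translated_db, transcripts)
    counts["translated_entries"] = len(db)
    write_translated_fasta(outdir / "translated_db.fasta", db)

    # -- de novo filter + proteome exclusion
    flt = stage("filter")
    candidates = flt(filter_denovo, observations, config.filter)
    counts["candidates_after_filter"] = len(candidates)
    candidates = flt(
        exclude_proteome, candidates, proteome, config.filter.il_equivalence
    )
    counts["candidates_after_proteome_exclusion"] = len(candidates)
    _write_candidates(outdir / "candidates.tsv", candidates)
    peptide_samples = {c.peptide: list(c.samples) for c in candidates}

    # -- match + map
    mt = stage("match")
    matches = mt(match_peptides, candidates, db, config.filter.il_equivalence)
    for m in matches:
        mt(map_to_genome, m, by_tid[m.transcript_id])
    counts["matches"] = len(matches)
    counts["matched_peptides"] = len({m.peptide for m in matches})

    # -- binder filter
    if config.stages.get("binder", True):
        samples = [
            SampleAlleles(s, tuple(a)) for s, a in sorted(alleles_by_sample.items())
        ]
        matches, binder_counts = stage("binder")(
            filter_binders,
            matches,
            calls,
            samples,
            peptide_samples,
            config.binder_cutoff,
            config.strong_cutoff,
            config.drop_nonbinders,
        )
        counts["binder_peptides"] = binder_counts["binder"] + binder_counts["strong"]
        counts["strong_binder_peptides"] = binder_counts["strong"]
        counts["peptides_after_binder_filter"] = len({m.peptide for m in matches})

    # -- expression check
    if config.stages.get("expression", True):
        ex = stage("expression")
        kept = []
        for m in matches:
            observed_in = peptide_samples.get(m.peptide, [])
            expressed = False
            for s in observed_in:
                if s in coverage and ex(check_expression, m, coverage[s]):
                    expressed = True
                    break
            m.expressed = expressed
            if expressed:
                kept.append(m)
        matches = kept
        counts["peptides_after_expression"] = len({m.peptide for m in matches})

    # -- classification
    if config.stages.get("classify", True):
        cl = stage("classify")
        index = AnnotationIndex(annotation)
        for m in matches:
            cl(classify_region, m, index)
            m.source_class = cl(classify_source, by_tid[m.transcript_id], index)
        for name in ("noncoding", "intronic", "novel_orf"):
            counts[f"region_{name}"] = len(
                {m.peptide for m in matches if m.region_class == name}
            )
        for name in ("antisense", "sense_intronic", "intergenic_lncRNA"):
            counts[f"source_{name}"] = len(
                {m.transcript_id for m in matches if m.source_class == name}
            )

    counts["final_peptides"] = len({m.peptide for m in matches})
    _write_matches(outdir / "matches.tsv", matches)
    write_bed6(
        outdir / "peptide_regions.bed",
        [
            (c, s, e, m.peptide, 0, st)
            for m in matches
            for c, s, e, st in m.genomic_intervals
        ],
    )

    # -- decoy null model
    p_ch = p_val = None
    if config.stages.get("decoy", True):
        if config.genome_fasta is None:
            raise StageError("decoy", ValueError("genome_fasta required for decoy stage"))
        dc = stage("decoy")
        genome = dc(read_fasta, config.genome_fasta)
        decoy_cfg = config.decoy or DecoyConfig(seed=config.seed)
        segments = dc(generate_decoy_segments, genome, decoy_cfg)
        with open(outdir / "decoy_segments.bed", "w") as fh:
            for chrom, s, e in segments:
                fh.write(f"{chrom}\t{s}\t{e}\tdecoy\t0\t+\n")
        decoy_records = segment_sequences(genome, segments)
        m_decoy = dc(
            decoy_match_count,
            [c.peptide for c in candidates],
            decoy_records,
            config.filter.il_equivalence,
        )
        counts["decoy_matched_peptides"] = m_decoy
        mean_len = round(
            sum(t.length for t in transcripts) / len(transcripts)
        )
        params = NullModelParams(
            m_decoy_matches=m_decoy,
            n_decoy_transcripts=decoy_cfg.n_segments,
            segment_len_nt=decoy_cfg.segment_len_nt,
            n_real_transcripts=len(transcripts),
            mean_len_nt=mean_len,
            k_observed=counts["matched_peptides"],
        )
        p_ch, p_val = dc(empirical_pvalue, params)

    # -- summaries
    if config.stages.get("summarize", True):
        sm = stage("summarize")
        cand_peps = [c.peptide for c in candidates]
        ldist = sm(
            length_distribution, cand_peps, config.filter.min_len, config.filter.max_len
        )
        with open(outdir / "summary_lengths.tsv", "w") as fh:
            fh.write("length\tcount\n")
            for length in sorted(ldist):
                fh.write(f"{length}\t{ldist[length]}\n")
        ranks = {m.peptide: m.best_rank for m in matches}
        bf = sm(
            binder_fraction_by_length,
            ranks,
            config.filter.min_len,
            config.filter.max_len,
            config.binder_cutoff,
            config.strong_cutoff,
        )
        bf.to_csv(outdir / "summary_binders.tsv", sep="\t")
        nine = sorted({m.peptide for m in matches if len(m.peptide) == 9})
        if nine:
            ref = sm(composition_from_proteome, proteome)
            motif = sm(motif_percent_difference, nine, ref)
            motif.values.round(4).to_csv(outdir / "motif_matrix.tsv", sep="\t")

    report = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "min_len": config.filter.min_len,
            "max_len": config.filter.max_len,
            "min_alc": config.filter.min_alc,
            "il_equivalence": config.filter.il_equivalence,
            "binder_cutoff": config.binder_cutoff,
            "strong_cutoff": config.strong_cutoff,
            "decoy": None
            if config.decoy is None
            else {
                "n_segments": config.decoy.n_segments,
                "segment_len_nt": config.decoy.segment_len_nt,
                "exclude_N": config.decoy.exclude_N,
            },
        },
        "counts": counts,
        "p_chance": p_ch,
        "p_value": p_val,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    for key in sorted(counts):
        log.info("count %s = %d", key, counts[key])
    return RunResult(matches=matches, counts=counts, p_chance=p_ch, p_value=p_val, report=report)


def _write_candidates(path: Path, candidates: list[Candidate]) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tmax_alc\tsamples\n")
        for c in candidates:
            fh.write(f"{c.peptide}\t{c.max_alc}\t{','.join(c.samples)}\n")


def _write_matches(path: Path, matches: list[PeptideMatch]) -> None:
    cols = [
        "peptide",
        "transcript_id",
        "frame",
        "aa_start",
        "nt_start",
        "nt_end",
        "genomic_intervals",
        "region_class",
        "source_class",
        "expressed",
        "best_allele",
        "best_rank",
        "binder_status",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for m in matches:
            fh.write(
                "\t".join(
                    str(x) if x is not None else ""
                    for x in [
                        m.peptide,
                        m.transcript_id,
                        f"{m.frame_id:+d}",
                        m.aa_start,
                        m.transcript_nt_interval[0],
                        m.transcript_nt_interval[1],
                        _format_intervals(m),
                        m.region_class,
                        m.source_class,
                        m.expressed,
                        m.best_allele,
                        m.best_rank,
                        m.binder_status,
                    ]
                )
                + "\n"
            )
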