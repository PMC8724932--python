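import logging

import pytest
from Bio.Seq import Seq

from lncpep.io import CoverageSet, GeneModel, GenomeAnnotation, TranscriptRecord
from lncpep.matching import (
    AnnotationIndex,
    PeptideMatch,
    check_expression,
    classify_region,
    classify_source,
    extract_coding_sequence,
    map_to_genome,
    match_peptides,
)
from lncpep.sixframe import (
    aa_to_nt_interval,
    build_translated_db,
    frame_offset,
    reverse_complement,
)


def tx(tid="tx1", chrom="chr1", strand="+", blocks=((100, 30),), seq=None):
    if seq is None:
        seq = ("ACGTGGA" * 20)[: sum(s for _, s in blocks)]
    return TranscriptRecord(
        transcript_id=tid,
        gene_id=tid,
        chrom=chrom,
        strand=strand,
        tx_start=blocks[0][0],
        tx_end=blocks[-1][0] + blocks[-1][1],
        blocks=tuple(blocks),
        sequence=seq,
    )


class TestMatchPeptides:
    def test_planted_match_located_exactly(self):
        # MKWWH sits in frame +1 of this transcript at aa_start 1
        seq = "GCG" + "ATGAAATGGTGGCAT" + "TAA"
        db = build_translated_db([("t1", seq)])
        [m] = match_peptides(["MKWWH"], db)
        assert (m.transcript_id, m.frame_id, m.aa_start) == ("t1", 1, 1)
        assert m.transcript_nt_interval == (3, 18)

    def test_match_cannot_span_stop(self):
        # frame +1 translates to MK*WH: KW spans the stop
        db = build_translated_db([("t1", "ATGAAATAGTGGCAT")])
        assert match_peptides(["KW"], db) == []

    def test_peptide_in_two_transcripts_yields_two_matches(self):
        seq = "ATGAAATGGTGGCATCCC"
        db = build_translated_db([("t1", seq), ("t2", "GGG" + seq)])
        matches = match_peptides(["MKWWH"], db)
        assert {(m.transcript_id, m.frame_id) for m in matches} == {("t1", 1), ("t2", 1)}

    def test_il_equivalence_controls_isobaric_hits(self):
        # CTT = Leu; query with Ile in that position
        db = build_translated_db([("t1", "ATGCTTAAATGGCATTAA")])
        assert len(match_peptides(["MIKWH"], db, il_equivalence=True)) == 1
        assert match_peptides(["MIKWH"], db, il_equivalence=False) == []

    def test_equals_exhaustive_scan_on_universe(self, universe):
        """Segment-restricted matching must agree with a window-by-window
        scan of every frame translation (independent oracle via Biopython)."""
        db = build_translated_db(universe.transcripts)
        peptides = sorted(universe.truth.spiked)[:25]
        got = {
            (m.peptide, m.transcript_id, m.frame_id, m.aa_start)
            for m in match_peptides(peptides, db)
        }
        expected = set()
        il = str.maketrans("I", "L")
        for t in universe.transcripts:
            for frame_id in (1, 2, 3, -1, -2, -3):
                src = t.sequence if frame_id > 0 else reverse_complement(t.sequence)
                off = frame_offset(frame_id)
                usable = src[off : off + 3 * ((len(src) - off) // 3)]
                aa = str(Seq(usable).translate()).translate(il)
                for pep in peptides:
                    q = pep.translate(il)
                    for i in range(len(aa) - len(q) + 1):
                        if aa[i : i + len(q)] == q and "*" not in aa[i : i + len(q)]:
                            expected.add((pep, t.transcript_id, frame_id, i))
        assert got == expected


def _per_base_projection(transcript, nt_start, nt_end):
    """Independent per-base oracle: enumerate the genomic coordinate of every
    transcript position, then group the selected bases into runs."""
    positions = []
    for start, size in transcript.blocks:
        positions.extend(range(start, start + size))
    if transcript.strand == "-":
        positions = positions[::-1]
    wanted = sorted(positions[nt_start:nt_end])
    runs = []
    for p in wanted:
        if runs and p == runs[-1][1]:
            runs[-1][1] = p + 1
        else:
            runs.append([p, p + 1])
    return [(s, e) for s, e in runs]


class TestMapToGenome:
    def _match(self, transcript, frame_id, aa_start, aa_len, peptide="X"):
        return PeptideMatch(
            peptide="A" * aa_len,
            transcript_id=transcript.transcript_id,
            frame_id=frame_id,
            aa_start=aa_start,
            transcript_nt_interval=aa_to_nt_interval(
                frame_id, aa_start, aa_len, transcript.length
            ),
        )

    def test_single_block_plus_offset(self):
        t = tx(blocks=((100, 30),))
        m = self._match(t, 1, 1, 3)  # nt interval (3, 12)
        map_to_genome(m, t)
        assert m.genomic_intervals == [("chr1", 103, 112, "+")]

    def test_two_block_split(self):
        t = tx(blocks=((100, 10), (150, 20)))
        m = self._match(t, 1, 2, 3)  # nt interval (6, 15)
        map_to_genome(m, t)
        assert m.genomic_intervals == [
            ("chr1", 106, 110, "+"),
            ("chr1", 150, 155, "+"),
        ]

    def test_minus_strand_single_block(self):
        t = tx(strand="-", blocks=((100, 30),))
        m = self._match(t, 1, 0, 3)  # nt interval (0, 9) on stored orientation
        map_to_genome(m, t)
        assert m.genomic_intervals == [("chr1", 121, 130, "-")]

    def test_reverse_frame_flips_coding_strand(self):
        t = tx(strand="+", blocks=((100, 30),))
        m = self._match(t, -1, 0, 3)
        map_to_genome(m, t)
        assert all(strand == "-" for _, _, _, strand in m.genomic_intervals)

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize(
        "blocks", [((100, 30),), ((100, 10), (150, 20)), ((100, 7), (120, 9), (140, 14))]
    )
    def test_per_base_oracle_all_frames(self, strand, blocks):
        t = tx(strand=strand, blocks=blocks)
        for frame_id in (1, 2, 3, -1, -2, -3):
            n_aa = (t.length - frame_offset(frame_id)) // 3
            for aa_start in range(n_aa):
                m = self._match(t, frame_id, aa_start, 1)
                map_to_genome(m, t)
                s, e = m.transcript_nt_interval
                assert [
                    (gs, ge) for _, gs, ge, _ in m.genomic_intervals
                ] == _per_base_projection(t, s, e)

    def test_interval_outside_transcript_rejected(self):
        t = tx(blocks=((100, 30),))
        m = PeptideMatch("AA", t.transcript_id, 1, 0, (24, 33))
        with pytest.raises(ValueError):
            map_to_genome(m, t)

    def test_roundtrip_on_universe(self, universe, transcripts_by_id, genome_by_name):
        """Genome bases under every match translate back to the peptide."""
        from lncpep.sixframe import translate

        db = build_translated_db(universe.transcripts)
        matches = match_peptides(sorted(universe.truth.spiked), db)
        assert matches
        for m in matches:
            map_to_genome(m, transcripts_by_id[m.transcript_id])
            assert translate(extract_coding_sequence(m, genome_by_name)) == m.peptide


def _toy_annotation():
    gene = GeneModel(
        gene_id="g1",
        chrom="chr1",
        strand="+",
        span=(1000, 2000),
        exons=((1000, 1200), (1500, 2000)),
        cds=((1100, 1200), (1500, 1900)),
    )
    return GenomeAnnotation(genes=[gene])


class TestClassifyRegion:
    def _match_at(self, intervals):
        m = PeptideMatch("AAA", "t", 1, 0, (0, 9))
        m.genomic_intervals = intervals
        return m

    def test_intergenic_is_noncoding(self):
        m = self._match_at([("chr1", 5000, 5009, "+")])
        assert classify_region(m, _toy_annotation()) == "noncoding"

    def test_intron_is_intronic(self):
        m = self._match_at([("chr1", 1300, 1309, "+")])
        assert classify_region(m, _toy_annotation()) == "intronic"

    def test_cds_overlap_is_novel_orf_any_strand(self):
        m = self._match_at([("chr1", 1195, 1204, "-")])
        assert classify_region(m, _toy_annotation()) == "novel_orf"

    def test_utr_exon_only_is_noncoding(self):
        m = self._match_at([("chr1", 1010, 1019, "+")])
        assert classify_region(m, _toy_annotation()) == "noncoding"

    def test_unannotated_chromosome_warns_noncoding(self, caplog):
        m = self._match_at([("chrUn", 10, 19, "+")])
        with caplog.at_level(logging.WARNING):
            assert classify_region(m, _toy_annotation()) == "noncoding"
        assert any("chrUn" in rec.message for rec in caplog.records)

    def test_invariant_to_interval_splitting(self):
        split = self._match_at([("chr1", 1300, 1304, "+"), ("chr1", 1304, 1309, "+")])
        merged = self._match_at([("chr1", 1300, 1309, "+")])
        ann = _toy_annotation()
        assert classify_region(split, ann) == classify_region(merged, ann)

    def test_requires_mapped_intervals(self):
        with pytest.raises(ValueError):
            classify_region(PeptideMatch("AAA", "t", 1, 0, (0, 9)), _toy_annotation())


class TestClassifySource:
    def test_opposite_strand_overlap_is_antisense(self):
        t = tx(strand="-", blocks=((1150, 100),))
        assert classify_source(t, _toy_annotation()) == "antisense"

    def test_same_strand_intron_containment_is_sense_intronic(self):
        t = tx(strand="+", blocks=((1250, 100),))
        assert classify_source(t, _toy_annotation()) == "sense_intronic"

    def test_isolated_transcript_is_intergenic(self):
        t = tx(strand="+", blocks=((5000, 100),))
        assert classify_source(t, _toy_annotation()) == "intergenic_lncRNA"

    def test_universe_sources_recovered(self, universe):
        index = AnnotationIndex(universe.annotation)
        for t in universe.transcripts:
            assert classify_source(t, index) == universe.lnc_meta[t.transcript_id].source_class


class TestCheckExpression:
    def _mapped(self):
        m = PeptideMatch("AAA", "t", 1, 0, (0, 9))
        m.genomic_intervals = [("chr1", 100, 109, "+")]
        return m

    def test_full_coverage_true(self):
        cov = CoverageSet("s1", {"chr1": [(90, 120)]})
        assert check_expression(self._mapped(), cov) is True

    def test_one_missing_base_false(self):
        cov = CoverageSet("s1", {"chr1": [(100, 108)]})
        assert check_expression(self._mapped(), cov) is False

    def test_empty_coverage_false(self):
        cov = CoverageSet("s1", {})
        assert check_expression(self._mapped(), cov) is False
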