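import json

from lncpep.filtering import collapse_il
from lncpep.io import read_bed12, read_fasta
from lncpep.sixframe import build_translated_db
from lncpep.simulate import make_genome, make_lncRNAs, make_universe


def _occurrences(peptide, db):
    """Stop-aware I/L-collapsed occurrence count across all frames."""
    q = collapse_il(peptide)
    total = 0
    for fr in db:
        hay = collapse_il(fr.aa_sequence)
        pos = hay.find(q)
        while pos != -1:
            if "*" not in hay[pos : pos + len(q)]:
                total += 1
            pos = hay.find(q, pos + 1)
    return total


class TestMakeGenome:
    def test_deterministic(self):
        g1, a1 = make_genome(7)
        g2, a2 = make_genome(7)
        assert g1 == g2
        assert a1.genes == a2.genes

    def test_gene_structure_invariants(self):
        _, annotation = make_genome(7)
        for gene in annotation.genes:
            for s, e in gene.cds:
                assert any(es <= s and e <= ee for es, ee in gene.exons)
            assert gene.span[0] <= gene.exons[0][0]
            assert gene.exons[-1][1] <= gene.span[1]

    def test_genes_fit_on_chromosomes(self):
        genome, annotation = make_genome(7)
        lengths = {name: len(seq) for name, seq in genome}
        for gene in annotation.genes:
            assert gene.span[1] <= lengths[gene.chrom]


class TestMakeLncRNAs:
    def test_requested_counts_and_recoverable_classes(self, universe):
        from lncpep.matching import AnnotationIndex, classify_source

        index = AnnotationIndex(universe.annotation)
        by_source = {}
        for t in universe.transcripts:
            meta = universe.lnc_meta[t.transcript_id]
            by_source[meta.source_class] = by_source.get(meta.source_class, 0) + 1
            assert classify_source(t, index) == meta.source_class
        assert by_source == {
            "antisense": 4,
            "sense_intronic": 4,
            "intergenic_lncRNA": 4,
        }

    def test_seeded_rerun_identical(self):
        genome, annotation = make_genome(7)
        counts = {"antisense": 2, "sense_intronic": 2, "intergenic": 2}
        t1, m1 = make_lncRNAs(genome, annotation, counts, 9)
        t2, m2 = make_lncRNAs(genome, annotation, counts, 9)
        assert t1 == t2
        assert m1 == m2

    def test_block_structure_roundtrips_bed12(self, universe, universe_paths):
        fasta = dict(read_fasta(universe_paths["transcripts_fasta"]))
        again = read_bed12(universe_paths["transcripts_bed"], fasta)
        assert again == universe.transcripts
        assert any(len(t.blocks) > 1 for t in again)  # multi-exon cases present


class TestSpikedTruth:
    def test_spiked_recoverable_exactly_once(self, universe):
        db = build_translated_db(universe.transcripts)
        for peptide, rec in universe.truth.spiked.items():
            assert _occurrences(peptide, db) == 1
            fr = next(
                f
                for f in db
                if f.transcript_id == rec.transcript_id and f.frame_id == rec.frame_id
            )
            assert fr.aa_sequence[rec.aa_start : rec.aa_start + len(peptide)] == peptide

    def test_proteome_substrings_in_proteome_not_in_db(self, universe):
        db = build_translated_db(universe.transcripts)
        blob = collapse_il("#".join(seq for _, seq in universe.proteome))
        for peptide in universe.truth.proteome_substrings:
            assert collapse_il(peptide) in blob
            assert _occurrences(peptide, db) == 0

    def test_decoys_match_nothing(self, universe):
        db = build_translated_db(universe.transcripts)
        blob = collapse_il("#".join(seq for _, seq in universe.proteome))
        for peptide in universe.truth.random_decoys:
            assert _occurrences(peptide, db) == 0
            assert collapse_il(peptide) not in blob

    def test_spiked_off_proteome(self, universe):
        blob = collapse_il("#".join(seq for _, seq in universe.proteome))
        for peptide in universe.truth.spiked:
            assert collapse_il(peptide) not in blob

    def test_binder_rank_labels_consistent(self, universe):
        ranks = {}
        for c in universe.calls:
            key = c.peptide
            ranks[key] = min(ranks.get(key, 1e9), c.rank_percent)
        for peptide, rec in universe.truth.spiked.items():
            assert rec.binder == (ranks[peptide] < 2.0)

    def test_universe_deterministic(self):
        u1 = make_universe(seed=5, n_spiked=20, n_proteome=4, n_decoy=6)
        u2 = make_universe(seed=5, n_spiked=20, n_proteome=4, n_decoy=6)
        assert [o.sequence for o in u1.observations] == [o.sequence for o in u2.observations]
        assert u1.truth.to_json() == u2.truth.to_json()
        assert u1.calls == u2.calls

    def test_truth_json_well_formed(self, universe_paths):
        truth = json.loads(universe_paths["truth_json"].read_text())
        assert set(truth) == {"spiked", "proteome_substrings", "random_decoys"}
        assert len(truth["spiked"]) >= 50
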