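# Methods

## Pipeline model and assumptions

The package assumes the discovery setting of MS immunopeptidomics with de
novo sequencing: peptides are natural HLA class I ligands (8-14 residues,
no enzymatic digestion pattern), identified without a database, and scored
by an average local confidence (ALC) percentage. A peptide is considered a
potential lncRNA product when it (a) survives the confidence and length
filters, (b) does not occur anywhere in the reference proteome, and (c)
occurs in some reading frame of some transcript of a lncRNA catalog.

Key modelling choices:

* **Translation through stops.** Each transcript is translated in all six
  frames with the standard genetic code; stop codons are kept as `*` in the
  frame translation and matching is restricted to maximal stop-free
  segments, because a presented peptide cannot span a stop. The translated
  database has exactly six entries per transcript (one per frame, not one
  per segment), so database cardinality is 6 x transcript count.
* **`N`-containing codons translate to `X`**, which matches no peptide
  residue. This is conservative: ambiguous sequence can never create a
  match.
* **I/L equivalence is on by default** for both proteome exclusion and
  database matching: isoleucine and leucine are isobaric and
  indistinguishable by tandem MS, so exact-mode matching would understate
  proteome membership and overstate novelty. A flag disables it.
* **Proteome exclusion is plain substring matching** (not tryptic
  windows), matching how class I ligands are generated in vivo.
* **No ORF calling.** Peptides are accepted anywhere in a frame, not only
  downstream of an ATG; start-codon inference is out of scope.

## Coordinates

All interval arithmetic is 0-based half-open (BED-native); 1-based
conventions never leave the formatting layer. An amino-acid window
`[aa_start, aa_start + aa_len)` of frame `f` of an `L`-nt transcript maps
to the stored-orientation interval

* forward frames: `nt_start = (f - 1) + 3 aa_start`;
* reverse frames: `nt_start = L - (|f| - 1) - 3 (aa_start + aa_len)`,

always of length `3 aa_len`. Genomic projection walks the BED12 blocks
(reversed for minus-strand transcripts) and splits at block boundaries; the
strand attached to each projected interval is the *coding* strand (the
transcript strand, flipped for reverse frames), so extracting genome bases,
reverse-complementing on `-`, and translating always reproduces the
peptide. This identity is enforced as a test invariant on every fixture
match.

## Classification rules

* **Region class** of a peptide-coding region: `novel_orf` if any coding
  base overlaps an annotated CDS exon on either strand (the peptide is
  already proteome-excluded, so overlap implies a frameshift or alternate
  start); otherwise `intronic` if any base falls in a coding gene's
  intronic space; otherwise `noncoding`. Overlap with UTR exons only is
  `noncoding`, because the discrimination of interest is against coding
  exons.
* **Source class** of a transcript: `antisense` if its span overlaps a
  coding gene on the opposite strand; else `sense_intronic` if it is wholly
  contained in a same-strand intron; else `intergenic_lncRNA`. The
  precedence (antisense > sense_intronic > intergenic) resolves the rare
  multi-context cases deterministically.
* **Expression** requires *full* coverage of every base of the
  peptide-coding region in the observing sample's transcriptome intervals —
  transcript-level overlap is not enough, since a truncated transcript can
  be transcribed without the peptide-coding suffix.

The binder filter is applied before the expression check by default
(matching the narrative order match -> binder -> expression ->
classification); stage toggles make the order configurable because nothing
in the method depends on it.

## Null model

The decoy database is sampled by rejection: uniform random fixed-length
segments (default 50,000 x 2000 nt — 2000 nt being the catalog's mean
transcript length), re-drawn on overlap with an already-accepted segment or
(by default) on containing `N`. Sampling is bit-reproducible for a given
seed. The chance probability of one candidate match is

    p = m / (N_decoy x 6 x L_segment / 33)

where m is the observed decoy match count and 33 nt codes the average
11-mer. The number of candidate peptides in the real catalog is

    n = N_transcripts x (6 x L_mean / 33)

and the empirical p-value for k observed matches is the binomial upper tail
P(X >= k), X ~ Binomial(n, p).

Numerics: the tail is evaluated in log space with log-gamma binomial
coefficients (naive factorials overflow at n ~ 4e7). Above the mean the
terms are summed upward in chunks until the next term cannot move the
accumulated log-sum (threshold e^-46); at or below the mean the short lower
tail is summed and complemented. The implementation agrees with exact
rational enumeration to < 1e-12 for n <= 30, with `scipy.stats.binom.sf`
at n ~ 4e7, and with the Poisson limit within 2% at n = 1e6 — all enforced
as tests, with scipy serving only as an independent cross-check.

At LNCipedia v5.2 scale the candidate count is taken as
transcripts x (6 x 2000)/33 per transcript, giving n = 38,923,273; with
p = 3.63e-6 and k = 195 the tail evaluates to ~1.1e-5.

## Synthetic fixture universe

The generator (`lncpep.simulate`) emulates realistic pipeline inputs at desk
scale, with every label fixed at construction time:

* **Genome**: uniform random bases, two chromosomes (60 kb + 40 kb by
  default), three-exon coding genes (1200/3000/1200 nt exons, 2800 nt
  introns, 300 nt UTRs) laid out with alternating strands.
* **lncRNAs** (default 4 antisense, 4 sense-intronic, 4 intergenic; 1-2
  exons, ~330-450 nt spliced) are placed *wholly inside* one genomic
  context — a CDS exon (opposite strand), an intron (either strand), or an
  intergenic gap — so the intended region/source class of any peptide
  spiked into them is unambiguous by construction and never computed with
  the classifiers under test.
* **Peptides**: 60 spiked (drawn from stop-free segments of random frames,
  verified unique in the whole translated database under I/L collapse and
  absent from the proteome), 10 proteome substrings (verified absent from
  the database), 20 random decoys (verified absent from both; half with
  sub-threshold ALC). Spiked ALC is uniform in (55, 99); decoy low-ALC rows
  are uniform in (20, 49).
* **Expression**: ~25% of transcripts are left uncovered; one single-block
  `+`-strand transcript is the truncated-transcript case, covered only up
  to its spiked peptide's start (prefix arithmetic done by the generator
  itself). All other transcripts are fully covered in every sample.
* **Binder truth**: 70% of peptides are designated binders and receive one
  allele rank uniform in (0.05, 1.95) in one observing sample; every other
  (peptide, allele) rank is uniform in (2.05, 45).

What passing on these fixtures does **not** show: the generator models
neither MS noise beyond ALC mixing, nor real HLA motif biology, nor
misannotated catalog entries, nor alignment artifacts in real coverage
data. Fixture results demonstrate the correctness of the bookkeeping and
decision rules, not real-data sensitivity or specificity.

## Problem sizes and defaults

| parameter | default | note |
| --- | --- | --- |
| peptide length | 8-14 aa | class I ligand range |
| ALC threshold | > 50 (strict) | de novo confidence |
| binder / strong %Rank | < 2.0 / < 0.5 | strict inequalities |
| decoy segments | 50,000 x 2000 nt | scaled down (e.g. 30-500 segments of 300 nt) in fixture runs and tests |
| peptide coding length | 33 nt | average 11-mer |
| fixture universe | 100 kb genome, 12 lncRNAs, 90 observations | exhaustive oracles run in seconds |

The catalog-scale cardinality check (107,039 x 2 kb transcripts, 642,234
entries) runs the real translation path end to end in under a minute via
the vectorized codon mapper; equivalence with Biopython's translator is
asserted separately on random sequences.

## Known limitations

* The %Rank predictor is consumed, never computed; results inherit the
  quality of the supplied rank tables.
* Region classification trusts the supplied gene models; no re-alignment
  (BLAT-style) is performed, coordinates come from exact transcript
  bookkeeping.
* De novo FDR is not estimated (no decoy exists for de novo spectra); the
  decoy-genome p-value bounds chance matching of the peptide *set*, not
  per-peptide confidence.
* Duplicate (peptide, allele) rank rows collapse to the minimum rank — the
  most favorable reading — with a logged warning.
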