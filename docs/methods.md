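# Methods

This note documents the models and procedures `gsspipe` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Translated search spaces

The novelty search space is the union of a **six-frame translation** of the
genome and a **three-frame translation** of assembled transcripts.
Translation is codon-by-codon under the standard genetic code (table 1,
configurable per compartment); any codon containing N translates to `X`,
and `X` never matches a peptide residue — this prevents ambiguous genomic
sequence from absorbing peptide evidence. Frames 0–2 read the forward
strand at offsets 0–2; frames 3–5 read the reverse complement, with spans
reflected back to forward-strand coordinates, so the six-frame output of a
sequence and of its reverse complement are coordinate-mirrored equal sets
(a tested invariant).

ORFs are **stop-to-stop** segments, not ATG-anchored: peptide evidence, not
start codons, drives discovery, and start refinement is downstream of this
package's scope. `min_orf_aa` (default 10) suppresses micro-ORFs; the
shortest confidently identifiable tryptic peptide is ~7 aa, so 10 loses
nothing identifiable while keeping the database an order of magnitude
smaller. Transcripts shorter than `min_transcript_nt` (default 50 nt) are
discarded before translation; the filter is applied to assembled
transcripts, not reads. Every emitted ORF carries provenance coordinates,
and re-translating an ORF's genomic span reproduces its amino-acid sequence
(asserted in tests and re-checked at mapping time as a hard invariant).

## Digestion and matching conventions

Tryptic digestion cleaves after K or R except before P, enumerating all
peptides with ≤ `max_missed` internal uncut sites (default 2) and length in
`peptide_len_range` (default 7–45 aa, the practical detectability window).

All peptide↔database comparisons are exact substring matches **after
collapsing I→L**, because the isobaric pair is indistinguishable by MS.
The study this design follows removed predicted-proteome matches with
BLASTP; exact I/L-collapsed matching is the stricter, deterministic dialect
and is the supported semantics here. The database index concatenates the
collapsed sequences of one origin class and answers queries with a C-speed
substring scan plus a bisect over entry offsets — exact and fast at
desk scale (a 1 Mb genome's six-frame space is ~2 MB of amino acids).

Decoys are per-entry sequence reversals, one per target: deterministic,
standard, and sufficient for the q-value estimator below.

## FDR control and engine merging

Scores are comparable only within an engine, so q-values are computed per
engine: PSMs sorted by descending score, `FDR(t) = #decoys ≥ t / #targets ≥ t`
(ties share the tie group's counts), and the q-value is the running minimum
of FDR from the permissive end. The default threshold is q ≤ 0.01 at the
peptide-spectrum level (the level at which the estimator is calibrated; the
threshold is configurable). Zero-decoy input yields q = 0 everywhere with a
logged warning — identifications are then uncalibrated by construction.

After filtering, engines are merged: any spectrum assigned non-identical
I/L-collapsed peptides by different engines is discarded entirely (both
assignments), and surviving PSMs aggregate per collapsed peptide with the
union of spectra and engines. Protein inference counts a peptide as unique
iff it occurs in exactly one target entry; ≥ 2 unique peptides give a
confident identification, exactly one gives a flagged tier that mirrors
manual spectrum review (which is not automatable), and shared-only entries
are reported as ambiguous. Sequence coverage is the fraction of residues
under ≥ 1 peptide occurrence (all occurrences, overlaps once), rounded
to 0.1%.

## Staged novelty classification

GSSPs — confident peptides absent from every predicted protein and present
in ≥ 1 ORF — are mapped to nucleotide coordinates (genome ORFs:
`start + 3·offset`, mirrored within the span on the minus strand;
transcript ORFs: pushed through the exon chain, recording every junction
the peptide crosses). Classification is staged and each GSSP participates
in at most one call class:

1. **Novel genes.** ORFs whose mapped GSSPs overlap no same-strand
   protein-coding gene and carry ≥ `min_gssps` (default 2) distinct GSSPs.
   Overlap with an annotated pseudogene sets the pseudogene flag — the
   expressed-pseudogene reclassification signal.
2. **Revised gene models.** ORFs with same-strand overlap of a coding gene
   and ≥ 2 distinct GSSPs revise the maximally overlapping gene (ties break
   to the lexicographically smallest gene id). Per-peptide sub-evidence:
   wholly intronic → `intron_peptide`; straddling an exon boundary, lying
   outside the locus, or in-exon but necessarily out of frame (an in-frame
   exact match could not be a GSSP) → `exon_extension`; intronic evidence
   in ≥ 2 distinct introns additionally sets `exon_merge` (several annotated
   exons that are really one).
3. **Splice variants.** A junction peptide crosses a transcript exon–exon
   junction with ≥ `min_flank` aa (default 2) mapped on each side, and the
   implied (donor, acceptor) pair is absent from the annotation. A call
   needs one junction peptide plus ≥ 1 further unique GSSP on the same
   transcript ORF, and is novel or revised according to whether its locus
   overlaps an annotated gene.
4. **SAAVs.** Remaining GSSPs are scanned against every predicted protein
   plus the accepted novel/revised products for an equal-length window at
   I/L-collapsed Hamming distance 1–2, no indels (at most two substitutions
   per peptide). Minimum distance wins, leftmost window within a protein;
   equally good hits in different proteins are ambiguous — reported,
   flagged, not counted. Calls carry (1-based position, reference residue,
   observed residue) and are flagged low-confidence, being supported by a
   single variant peptide.

**Ordering of splice detection.** Run naively after stages 1–2, a splice
variant's supporting peptides (which also occur in genome ORFs at the same
locus) would be consumed as a novel or revised gene call, and the junction
peptide — mappable only through the transcript — could then never assemble
a splice call, contradicting the intended semantics of splice variants as
their own class. The pipeline therefore first identifies transcript ORFs
that carry a novel-junction peptide (`find_novel_junction_deferrals`) and
defers their GSSPs past stages 1–2, letting the splice stage claim the
locus whole. The staged-consumption invariant (one class per GSSP) is
preserved.

## Validation stages

**RNA-seq support.** The source procedure verified loci by visual
inspection with a ≤ 3-mismatch rule; this package makes it deterministic: a
read supports a call iff its mismatch count (NM tag, MD fallback) is ≤
`max_mismatches` (default 3) and it covers ≥ 50% of at least one of the
call's *evidence intervals* (the mapped GSSP intervals); splice calls
instead require the read's block chain to reproduce the exact junction. A
call is supported with ≥ `min_reads` (default 2) such reads in any one
sample. The per-evidence-interval denominator matters: against the whole
ORF span, no short read could ever reach 50% regardless of depth, which a
visual verification obviously did not require. Support is monotone in the
read set (tested).

**Augmented re-identification.** Accepted novel and revised products are
added to the predicted database and the PSM evidence is re-attributed
against it; novel entries re-identified with ≥ 2 unique peptides are marked
quantifiable. (The original study re-searched a separate labeled-quant raw
dataset; this package re-attributes the provided PSM tables, which
exercises the same code path — formerly orphaned GSSPs become attributable
protein evidence.)

**Differential expression.** Per-replicate condition/reference intensity
ratios (paired by replicate label, ≥ 2 pairs required) give the arithmetic
mean fold change; significance is a two-sided one-sample t-test of the log2
ratios against zero — the conventional choice for ratio data; the source
procedure's exact test is unstated, so the test is configurable. Gates are
strict inequalities: up iff FC > 1.5 and P < 0.05; down iff FC < 0.67 and
P < 0.05. No multiple-testing correction is applied by default, matching
the stated raw-P criterion; calls are invariant to global intensity
rescaling (tested). With two replicates the t-test runs at df = 1, where
P < 0.05 requires |t| > 12.7 — the criterion can only fire when replicate
channels agree tightly, which is worth knowing before trusting any n = 2
DE call.

## The synthetic-data generator

`generate_genome` builds chromosomes of GC≈0.47 background with non-
overlapping genes of 1–6 exons (intron lengths 60–300 nt at arbitrary
offsets), ~5% emitted as single-exon pseudogenes (annotated non-coding,
sequence still ORF-bearing), every coding gene's protein re-translating
exactly from its spliced CDS. `plant_novelties` then writes novelties into
intergenic space, each recorded with its locus and payload:

* novel genes and expressed pseudogenes: single-exon CDSs bracketed by
  in-frame stop codons (so the surrounding stop-to-stop ORF is exactly the
  planted protein), withheld from or pseudogene-annotated in the GFF3;
* revised models: a contiguous real CDS whose annotation carries one
  (intron), two (merge) spurious codon-aligned introns, or a mid-peptide
  3′ truncation (extension) — the annotated protein is the true protein
  minus the removed runs, so the wrong model is still internally
  consistent;
* splice variants: genuinely spliced two-exon genes with an unannotated
  junction placed ≥ 3 aa inside a tryptic peptide, emitted as anchored
  transcripts; the revised flavour annotates the first exon as a stub gene;
* SAAVs: variant-carrying *transcripts* of annotated single-exon genes
  (1–2 substitutions inside one tryptic peptide; decoys carry 3). The
  genome is untouched — reference six-frame translation cannot contain a
  strain variant; only the transcriptome assembled from the organism's own
  RNA can, and that is how such peptides enter the search space. Variant
  peptides are rejection-sampled to be proteome-unique (no foreign window
  within Hamming 2), so a planted distance-3 decoy resolves nowhere by
  construction rather than by luck;
* planted fold changes (default 8×, echoing the strongest inductions such
  analyses report) on novel products under one deficiency condition.

`simulate_evidence` digests every expressed product **fully tryptically**
(the search configuration still defaults to 2 missed cleavages; fully
cleaved evidence keeps one planted SAAV codon from surfacing in up to six
overlapping missed-cleavage peptides and spuriously crossing the
≥ 2-unique-GSSP revision threshold), samples peptides at `detect_prob`,
scores every spectrum per engine from N(μ_target, σ) with decoys from
N(μ_null, σ) (defaults 6/0/1 — cleanly separated, as FDR calibration has
its own dedicated simulation with overlapping distributions), optionally
injects cross-engine disagreement, tiles spliced reads (default 100 nt
every 30 nt, tail always covered) over every expressed transcript with a
uniform per-base mismatch process and NM computed against the genome (so
planted variants surface as genuine mismatches), and draws reporter
intensities log-normally around the planted fold changes (default log2-sd
0.05 per channel: well-behaved technical duplicates — see the df = 1 note
above — and configurable).

Synthetic proteins are concatenations of 7–13-residue segments (17-letter
alphabet excluding K, R, P and also I) terminated by K or R, so every fully
cleaved peptide lies deterministically in the 7–45 aa window and I/L
collapse is the identity on synthetic sequences; the KP-suppression rule,
missed-cleavage enumeration and I/L semantics are exercised by dedicated
unit and property tests instead. Everything is driven by
`numpy.random.default_rng(seed)` and is byte-deterministic under a fixed
seed.

**What passing on this generator does and does not show.** It shows the
pipeline's logic is correct: exact recovery of all planted classes under
complete, noiseless evidence; calibrated FDR under the two-Gaussian score
model; deterministic behaviour. It does not show performance on real MS
data — no chimeric spectra, no modification misassignment, no
retention-time or intensity structure, no homologous gene families or
repeats (random sequence makes peptide collisions negligible, which real
paralogs are not), uniform RNA-seq coverage, and no isobaric-tag ratio
compression.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; GFF3 is 1-based inclusive
  at I/O boundaries. Junctions are canonical (donor_end, acceptor_start)
  pairs in ascending genomic order, strand-independent.
* A CDS whose spliced length is not divisible by 3, or that translates with
  internal stops, is flagged untranslatable (warning), not rejected.
* Zero-variance log-ratios in DE: P = 0 when the mean log-ratio is nonzero,
  else 1 (the t statistic is degenerate there).
* Deterministic tie-breaks throughout: revised-gene target by maximal
  overlap then smallest gene id; SAAV window leftmost within a protein;
  all outputs sorted before writing; engine-merge representative peptide is
  the lexicographically smallest original spelling.
* Empty PSM input runs the whole pipeline to a clean zero-count summary.

## Problem sizes used in tests

The shared test fixture is a 200 kb, 12-gene study with one planted feature
per class; the acceptance suite and `scripts/acceptance.py` run a 1 Mb,
50-gene genome with 10 novel genes (3 over pseudogenes), 10 revised models,
5 splice variants, 10 SAAVs and 5 Hamming-3 decoys, chosen as the smallest
configuration that exercises every class with several instances each while
keeping a full run in seconds on one core. Oracle comparisons use 1,000
random 300-nt sequences (translation) and 500 random proteins (digestion);
FDR calibration pools 20 simulations of 10,000 PSMs; DE type-I error uses
1,000 simulated null proteins.

## Known limitations

* No gene-model rebuilding: calls mark evidence and proposed intervals;
  start/stop refinement and UTR inference are out of scope.
* SAAVs are amino-acid-level only; no codon-level DNA variant calling.
* No spectrum-level rescoring, PTM localization, isobaric interference
  correction, or missing-value imputation.
* Engine scores are never compared across engines; a spectrum identified by
  one engine only is kept if it passes that engine's q-value threshold.
* The exact-substring (I/L-collapsed) GSSP definition is stricter than a
  BLASTP-based removal; peptides matching a predicted protein with one
  mismatch are *not* removed and may legitimately surface as SAAVs.
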