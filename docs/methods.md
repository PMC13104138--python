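# Methods

## Scope and data model

The pipeline starts from *placements*, not reads: RNA-seq enters as per-gene
fragment counts (or fragment positions), Ribo-seq as per-position P-site
counts keyed by (chromosome, strand, position, footprint length). Trimming
and alignment are upstream concerns. Internally every interval is 0-based
half-open; GFF3 keeps its native 1-based inclusive convention on disk and
BED-like TSVs stay 0-based. All transcript-level logic runs in transcript
orientation (index 0 = the 5′ end of the mature transcript), which removes
strand special-casing from ORF scanning, Kozak scoring and frame assignment.
UTRs are always inferred from exon/CDS structure rather than trusted from
the input file: the 5′UTR is the exonic sequence strictly upstream of the
CDS, the 3′UTR strictly downstream, so |5′UTR| + |CDS| + |3′UTR| equals the
spliced length for every coding transcript. A CDS whose length is not a
multiple of 3 is flagged, not rejected.

## P-site offsets

When the input carries raw footprint 5′ ends instead of P-sites, the offset
for each footprint length L is estimated as the modal distance from 5′ ends
to annotated CDS starts, pooled over a metagene window of 5′ ends within
[−40, +10] nt of a start. Ties break toward 12 nt, and lengths with fewer
than 50 reads in the window fall back to 12 nt (the canonical plant/animal
value) and are flagged in the offset table. The mode is identifiable because
initiation pausing concentrates P-sites on start codons; data without any
start-codon enrichment would leave the mode ambiguous up to a codon, which
is why the fallback and the flag exist.

## The periodicity test

Active translation is called from reading-frame bias, not spectral
analysis: for a region with P-site frame counts (n0, n1, n2) relative to its
own start codon, the test is the one-sided binomial tail P[X ≥ n0] with
X ~ Bin(n, 1/3), gated by n ≥ 10 and f0 = n0/n ≥ 0.6, at α = 0.05. The f0
gate (0.6) carries the threshold commonly used by metagene-based callers;
the binomial test is a deliberate simplification of multitaper approaches —
fully specified, desk-scale, and with the same acceptance semantics. Its
operating characteristics under the default simulation: the null (uniform
frames, n = 60) passes at ≈ 4% without the f0 gate and < 0.1% with it;
regions with frame bias p0 = 0.75 and n ≥ 50 pass at > 99%. Frames are
always computed relative to each ORF's own AUG, so nested and overlapping
ORFs are tested independently, and codons overlapping an annotated main-ORF
CDS are excluded entirely (a uORF that dips into the CDS is judged only on
its non-overlapping codons).

## ORF discovery and acceptance

Candidates are every AUG with an in-frame stop on the transcript (span
includes the stop; minimum 3 codons). Candidates sharing a stop codon
collapse to the most-upstream AUG — the "longest ORF per stop" rule.
Classification is by AUG position: 5′UTR → 5′ORF, 3′UTR → 3′ORF,
noncoding/intergenic host → ncORF, exact CDS span → mORF; an AUG inside the
annotated CDS is "internal" and excluded from the three UTR/nc classes. An
ORF is accepted as translated when the periodicity test passes in at least
one stage (replicates pooled per stage). Per-stage ORF translation levels
are RPKM over the ORF's own span with the host library's normalization
constants. Kozak context is the [−6, +5] window around the AUG, padded with
N at transcript edges; "strong" requires A/G at −3 and G at +4, and N never
satisfies the rule.

## Quantification

Gene counts use union exon (RNA) or union CDS (Ribo) intervals over the
gene's transcripts, strand-matched, with multi-overlap semantics: a
placement inside features of k genes contributes to all k. "Total mapped"
per library is the sum of counted placements, recorded in the output
metadata. Replicates are normalized per library, then averaged; TE is
computed on the means. The pseudocount of 1 on both layers makes TE = 1
exactly for doubly-silent genes and damps ratios for weakly expressed ones
— which is why the TE classification additionally gates on expression
(≥ 50) before applying the TE > 2 / < 0.5 thresholds.

## TE classes and expression variation

A stage qualifies for classification when max(FPKM, RPKM) ≥ 50 at that
stage (the per-stage reading); a gene enters the candidate list if any stage
qualifies (the any-stage reading); both facts are recorded per gene.
"Very high" requires the gene to be high somewhere *and* a phase-mean TE
(arithmetic mean of the stage TEs within a phase) above 5 — the phase mean
is the natural reading of "TE exceeding 5 in a phase" when a phase spans
several stages. Expression variation uses the population variance
(denominator n) of log2(x+1) values across genes, per stage, over the
intersection of the two layers' median-above-1 gene filters; raw-scale
variances are emitted alongside, the log2 figures are the headline (the
log-scale is what makes the inflation estimate stable across expression
magnitudes).

## Clustering and enrichment

TE profiles of well-expressed coding genes (both layers above 1 at every
stage) are max-normalized per gene and clustered with seeded k-means
(defaults k = 18, 30 iterations, seed 19960912). Initialization is
k-means++ (scikit-learn's seeded implementation); the Lloyd iterations are
run explicitly so the per-iteration objective is available (it is checked to
be non-increasing) and determinism is guaranteed by construction. A cluster
is phase-specific when its centroid peaks inside one phase and the centroid
mean in that phase exceeds the mean elsewhere by ≥ 0.2 (a config knob; no
operational definition exists in the literature for this notion, so the
margin is explicit). Stage similarity uses UPGMA on Euclidean distances
between stage columns, exported as Newick. Enrichment is the upper-tail
hypergeometric test with BH adjustment across terms; stars (* p<0.05,
** p<0.01) are reported on the raw p as well, since adjusted and raw
significance answer different questions. Group comparisons of TE
distributions use one-way ANOVA with Tukey-HSD compact letter displays at
α = 0.05.

## Corroboration

Peptide evidence is exact substring matching of peptides (≥ 7 aa; below
that, chance matches dominate) against accepted-ORF proteins, optionally
with I/L collapsed (isobaric); reversed decoys give an empirical
chance-match rate. A peptide matching several ORFs is reported for all of
them. Isoform support requires (a) every ORF genome block inside the
isoform's exons, (b) matching strand, and (c) the ORF contiguous in the
isoform's spliced sequence (no isoform intron inside the ORF, no retained
host intron splitting it) — the operational reading of an ORF
"corresponding precisely" to an isoform.

## The synthetic-data generator

The generator emulates a ten-stage × two-replicate staged design: gene-level
log-normal mRNA abundance (ln-mean 3.0, ln-sd 1.0, per-stage jitter 0.5),
gene- and stage-specific log-normal TE (ln-sd 0.5), Poisson counts, Ribo
footprint lengths over 25–33 nt peaked at 28, P-site frames multinomial with
p = (0.75, 0.15, 0.10) on translated ORFs and uniform elsewhere, and planted
AUG-initiated ORFs (160 each in 5′UTRs, 3′UTRs and intergenic transcripts by
default; half truly translated, half present but untranslated; half with
strong Kozak context). Ribosome occupancy of planted ORFs is log-normal
(ln-mean 3.2, ln-sd 0.6, per-stage jitter 0.4) — chosen so that small
translated ORFs still accumulate enough P-sites per stage for the
periodicity test to be informative rather than trivially data-starved.
Untranslated planted ORFs receive the same occupancy with uniform positions
and frames, modelling background binding without engaged elongation; they
are the null set for the false-discovery checks.

Three constructions make the ground truth exact rather than approximate:

1. **AUG scrubbing.** Transcript sequences contain no AUG trigrams except
   planted start codons (every other occurrence is removed by a C
   substitution, which provably cannot create a stop codon or a new AUG).
   The candidate-ORF set of every transcript is therefore known in advance,
   and recovered ORFs can be matched to truth by exact span.
2. **Initiation peak.** Start codons carry 5× P-site weight, emulating
   initiation pausing; this gives the metagene the 5′-end structure offset
   calibration needs. In raw-placement mode, 5′ ends are emitted at
   P-site − 12 nt in genome space, so offset estimation and correction
   round-trip exactly.
3. **Library-scale matching.** True TE is centered at e^0.4 ≈ 1.5. The
   estimated TE inherits an overall scale from the ratio of the two
   libraries' per-million normalizations (the RNA library spans exons and
   noncoding transcripts, the Ribo library is CDS-counted), and this scale
   is independent of sequencing depth. Centering TE there makes the two
   library scales comparable, so true and estimated TE share units and the
   median estimated/true ratio sits near 1 — emulating a matched-library
   experimental design rather than correcting the estimator.

What the generator does *not* emulate: overdispersed (negative-binomial)
counts, positional coverage bias, multi-isoform abundance mixtures,
misalignment, and non-AUG initiation. Passing recovery tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to every artefact of real libraries; the
periodicity caller in particular sees cleaner frame signal than real data
would provide.

Determinism: every random draw flows from `numpy` generators seeded by
(config.seed, stream-id) tuples, so a rerun with the same config is
byte-identical across all outputs (checked via the manifest checksums).

## Problem sizes used in validation

The default validation run uses 300 coding genes plus 160 intergenic
transcripts with 480 planted ORFs, RNA depth 10 fragments/kb per abundance
unit and Ribo depth 30 P-sites/kb per TE·abundance unit (≈ 0.3 M P-sites per
library) — comfortably enough for every recovery statistic to stabilize
while keeping a full simulation-plus-analysis cycle under a minute on one
CPU. Calibration checks use 10,000 simulated null/alternative regions;
variance-inflation recovery averages 50 simulations of 2,000 genes.

## Known limitations

- The periodicity caller assumes frame bias is the signature of
  translation; it cannot distinguish a translated ORF from frame-coherent
  contamination, and it is less conservative than spectral tests on very
  short regions (mitigated by the n ≥ 10 and f0 ≥ 0.6 gates).
- ORF discovery is AUG-only: non-AUG starts and stop-codon readthrough are
  out of scope.
- Enrichment treats terms as opaque gene sets; no ontology propagation.
- `count_features` attributes multi-overlap placements fully to every gene,
  so summed gene counts can exceed the library total; this mirrors the
  multi-overlap counting convention and is intentional.
- The ≥ 50 expression gate interacts with the pseudocount: for genes near
  the gate, TE < 0.5 calls are conservative (the pseudocount pulls ratios
  toward 1).
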