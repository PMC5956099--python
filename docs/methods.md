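# Methods

## Quantities

For each somatic SNV and each dataset, the variant allele fraction is
VAF = n_var / (n_ref + n_var) over quality-filtered read counts; no
pseudocounts are added. The expressed allele balance relative to DNA is
V_R:D = VAF_tRNA / VAF_tDNA, undefined (and excluded from downstream
V_R:D analyses) when VAF_tDNA = 0 or tumor depth is below the minimum.
V_R:D is not capped above: values > 2 are meaningful and drive the
extreme-subset analyses. Purity weighting multiplies V_R:D by the
tumor-cell fraction from each available estimation method (ESTIMATE,
ABSOLUTE, LUMP, IHC, CPE); missing estimates yield missing weighted
values, and a sample is usable only when at least three of the five
estimates are present.

## Expression-status calls

SOM-E ("over-expressed", VAF_tRNA ~ 1) and SOM-L ("lost", VAF_tRNA ~ 0)
are operationalized with an explicit noise-only model: a per-read error
rate `p_err` (default 0.05) and a one-sided binomial upper tail on the
tumor-RNA counts. SOM-L is called when P(X >= n_var | n, p_err) >= alpha
(default 0.05), i.e. the observed variant reads are consistent with
sequencing noise alone; SOM-E mirrors the condition on the reference
reads. Both calls require a bi-allelic DNA signal: at least
`min_dna_minor_reads` (default 2) reads supporting each tumor-DNA allele.
Everything else is SOM. In the degenerate low-depth regime both tails can
exceed alpha; the call then goes to the side with the larger tail
probability, which keeps the two extremes mutually exclusive at every
depth. Defaults are deliberately explicit and configurable
(`p_err`, `alpha`, `min_depth` = 10, `min_dna_minor_reads`,
`max_normal_var_reads` = 1); the calibration suite verifies that balanced
variants (true VAF 0.5 in DNA and RNA, depth 50) are miscalled as an
extreme in under 1% of 10,000 replicates.

Germline screening tolerates up to `max_normal_var_reads` variant reads
in each normal dataset as noise; more evidence in either normal DNA or
RNA excludes the variant as likely germline.

## Filter cascade

Sample level: (1) at least three purity estimates; (2) hypermutator
exclusion at mutation load strictly above Q3 + 1.5·IQR, with quartiles by
linear interpolation between order statistics (the most common
convention; the rule, not any dataset-specific threshold value, is the
invariant); (3) cancer types retaining fewer than 10 samples are dropped.
Variant level, in fixed order: missing counts, tumor DNA/RNA depth < 10,
chromosome X (applied unconditionally), imprinted-region overlap
(BED input, converted to 1-based inclusive coordinates), germline
evidence, splice-annotated consequences, non-exonic consequences. The
retained set is order-independent; only the attribution of an exclusion
to its first failing rule depends on the order. Conservation
(retained + per-rule exclusions = input) is asserted on every run.

## NMD rule engine

A PTV escapes NMD when any of six rules fires; otherwise it is
NMD-elicit. All distances are computed in spliced mRNA coordinates,
strand-aware.

1. **Last-junction proximity** — escape when the PTC lies in the last
   exon or ≤ 50 nt upstream of the final exon-exon junction. This is the
   canonical boundary-rule direction from the NMD literature; a
   configuration switch (`rule1_literal`) runs the inverted reading
   ("more than 50 nt upstream") for sensitivity analyses. The canonical
   direction is the default because the screen's purpose is to remove
   transcripts *likely to escape* decay.
2. **Start-proximal reinitiation** — escape when the PTC lies within the
   first 200 *coding* nucleotides (coding offset, not mRNA offset, is the
   assumption here) and an in-frame AUG exists in the CDS strictly
   downstream of the PTC. The AUG search is confined to the annotated
   CDS; no search window beyond it is defined.
3. **Long-exon boundary** — escape when the host exon exceeds 400 nt
   (configurable; "long" is not otherwise quantified) and the PTC lies
   within 250 nt of the closest boundary of that exon.
4. **Short-lived transcript** — escape when the transcript half-life is
   below 1 h. A missing half-life leaves the flag false (assumed stable),
   logged as an assumption.
5. **Single-exon transcript** — escape; rule 1 is defined as false for
   single-exon models so each rule has a distinct trigger.
6. **NMD-insensitive gene** — escape when the gene is on the curated
   insensitive list (input table, not bundled).

When a variant record names no usable transcript, the gene's longest-CDS
model is the fallback. Half-life and insensitive-gene lists are consumed
as tables. The rule grid is tested exhaustively on hand-built transcript
fixtures covering every geometrically realizable flag combination, plus a
strand-mirror invariance property.

## TFBS gain/loss

Motifs are consumed in JASPAR text form (the categorization itself does
not depend on the motif source). Scanning converts count matrices to
log2 odds against a uniform background with a 0.01 pseudocount and scores
every window on both strands; a hit is a window whose relative score
(score − min)/(max − min) reaches 0.85 (configurable). A variant gains a
motif when a hit overlapping its position exists in the alternate window
but not the reference, loses one in the converse case; variants gaining
one motif and losing another are reported as "both" and counted in both
directions of the two-way comparison, since no precedence is defined.
Flat matrices (max = min) score 0 everywhere. Swapping the reference and
alternate windows provably swaps gain and loss.

## Associations

Non-parametric statistics throughout: Spearman rank correlation
(average-rank ties, two-sided p) and tie-corrected Kruskal-Wallis with a
chi-square p-value; all-identical data returns H = 0, p = 1 rather than
an error. Expression change is log2[(T + floor)/(N + floor)] with
floor = 0.01 abundance units, missing when neither value exceeds the
floor. Extreme subsets require V_R:D > 2 together with log2[T/N] ≥ 1 or
≤ −1. Gene ranking averages V_R:D over genes with at least
`min_mutations` (default 3, 5 for the stricter set) variants, descending,
with an alphabetical tie-break. CGC enrichment is a 2×2 chi-square
without continuity correction (configurable) of the selected genes
against the variant-bearing background. Raw p-values are always emitted
and no multiple-testing correction is applied at this layer, so users can
correct downstream. SOM-E/SOM-L variants enter correlations with their
computed V_R:D values, not imputed 0/1 surrogates. FATHMM-style
pathogenicity scores, when present on the variant table, are consumed as
annotations (categorical labels compared by two-group Kruskal-Wallis,
continuous scores by Spearman) — never computed.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
with every parameter recorded as truth:

* Each variant is clonal and heterozygous in a diploid tumor (f_D = 0.5)
  admixed with diploid normal tissue, so E[VAF_tDNA] = purity/2. Purity
  is Beta(6.5, 3.5) (mean 0.65); per-method estimates add N(0, 0.04)
  noise and are each present with probability 0.95.
* Allelic selection acts as an odds multiplier:
  mu = s·v/(s·v + 1 − v) with log s ~ N(0, 0.5²) (natural log) and a
  −0.4 shift for PTVs (mild negative selection). This form is simple,
  invertible, and makes V_R:D ≈ s near v = 0.5.
* NMD-elicit PTVs have their RNA variant share degraded by d = 0.8,
  renormalized. Mono-allelic transcription events silence the variant
  allele with probability 0.12 or the reference allele with probability
  0.05, producing the SOM-L/SOM-E extremes at roughly the relative
  frequencies seen in real tumor cohorts (SOM-L several-fold more common
  than SOM-E).
* log2 expression change beta has SD 1.0 and is coupled to log s through
  a Gaussian copula at rho = 0.3; measured expression adds N(0, 0.1²)
  log2 noise. (A Pearson copula correlation of 0.3 corresponds to a
  Spearman of ~0.29, which is what recovery tests observe.)
* Counts are binomial at Poisson depths (tumor 100x, normal DNA 60x,
  normal RNA 40x) with a per-read sequencing error of 0.005 — distinct
  from, and well inside, the caller's conservative noise model of 0.05.
  Normal samples draw variant reads at the error rate only.
* Gene models (400 genes, five autosomes plus chrX, alternating strands)
  cover archetypes that make each NMD escape rule fire by construction,
  with PTV placement windows chosen so the intended verdict is exact;
  classifier output is tested for equality with the designed truth.
  Downstream in-frame AUGs are physically planted in the genome sequence
  for the reinitiation archetype.
* TFBS gains and losses are planted by writing consensus (loss) or
  one-mismatch (gain) occurrences of two sharp 6-mer PWMs into the
  genome around selected variants; a single mismatch of a sharp 6-mer
  scores 5/6 ≈ 0.83 < 0.85, so planted truths are recovered cleanly
  (rare overlaps between planted windows keep recovery just below 100%).
* Planned-filter variants (chrX genes, imprinted genes, germline
  contamination at 30% normal VAF, low RNA depth) exercise the exclusion
  cascade; one hypermutator sample carries a 6× mutation load.

Default scale: 60 samples in five cancer types, ~33 variants per sample
(~2000–2200 variants), chosen to give every stratified analysis adequate
counts while the full generate-plus-pipeline cycle completes in seconds.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: subclonal structure and focal copy-number
alteration (segments are whole-chromosome with small noise around
diploid; the admixture model is the only purity effect), read-level
artifacts (mapping bias, strand bias, duplicates), isoform-level
expression, phasing, and sequence-consistent consequences (PTV/missense/
silent labels are assigned, not derived from the codon change). Expression
effects of allele silencing and NMD on total gene expression are not
propagated into the expression table.

## Numerical and I/O choices

Internal coordinates are 1-based inclusive (the variant-table key space);
BED is converted on ingestion. The MAF Variant_Classification mapping is
an editable module-level table; splice classes stay distinct so the
cascade can exclude them. Pileup counting (optional; TSV count tables are
the canonical input) uses the samtools-compatible read stepper with
minimum base and mapping quality 20 and duplicates excluded — standard
practice where no thresholds are otherwise specified. Result tables are
TSV with one provenance comment line; floats are written at full shortest
round-trip precision and read back with round-trip parsing, so
write-then-read is bit-exact, and no output embeds a timestamp, so equal
inputs give byte-identical outputs. Binomial tails use the exact
survival function (verified against rational-arithmetic enumeration to
1e-12 for n ≤ 25).

## Known limitations

Purity weighting multiplies V_R:D by a single per-sample fraction; DNA
and RNA aliquots may in reality differ in purity, and no derivation of
the weighting beyond direct proportionality is attempted. The status
caller ignores overdispersion (no beta-binomial) and models variants
independently, even within a gene. The hypermutator rule is
cohort-relative, so its absolute threshold depends on the input. Whether
chromosome-X exclusion should be conditioned on sex is not resolved; the
exclusion is unconditional.
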