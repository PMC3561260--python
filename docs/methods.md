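# Methods

## Binding quantification model

The screen assumes the factor binds broadly, at near-histone occupancy,
so the unit of inference is a gene window rather than a peak.  Three
windows per gene are derived strand-aware from a single-span annotation
(0-based half-open internally; GTF converted at parse time):

* **TSS window** — TSS ± `flank_bp` (default 2000 bp, total 4 kb).  An
  `upstream` geometry is available that flanks only the upstream side
  (TSS − flank … TSS), for the reading in which "2 kb upstream" is the
  whole window.  The symmetric form is the default.
* **Gene body** — the full genomic span.  Exon structure is deliberately
  ignored: diffuse binding does not respect splicing, and treating the
  body as one element keeps L well defined.  GTF exon lines are skipped.
* **TES window** — TES ± `flank_bp`, mirrored on the minus strand.

Windows are clipped to chromosome bounds; a window clipped to zero
length removes that gene from that window's ranking only (G is per
window).  Windows of one gene may overlap each other (genes < 2·flank)
and windows of different genes may overlap; each is quantified
independently and a read may count toward several windows.

**Counting.**  Reads are extended from their 5′ end to
`fragment_extension_bp` (default 200 bp, the lower end of a typical
200–400 bp sonication range; 0 disables extension) and assigned to a
window iff the extended fragment's midpoint lies in it.  The midpoint
rule assigns each read to at most one genomic point, so window edges do
not double-count; an `any_overlap` policy (≥ 1 bp overlap) is provided
for sensitivity analysis.  Both policies are implemented as
sorted-array rank queries per chromosome (midpoint: #mid ∈ [s, e);
any-overlap: #{read_start < e} − #{read_end ≤ s}) and verified against a
brute-force double loop.

**Normalization.**  RPKM = 10⁹·C/(L·N) with N the library's total mapped
reads (supplied metadata, else the ingested read count — the choice
matters when multi-mapping reads are filtered upstream).  The input
library's RPKM is subtracted from the ChIP RPKM per window; scores may
be negative.  No further GC or mappability correction is attempted.

**Calling.**  Genes are ranked per window by descending score, ties
broken by ascending gene id (deterministic and documented; with chip ≡
input every score is 0 and the "top" set is exactly this tie-break
prefix).  The top set holds ⌈fraction·G⌉ genes, fraction default 0.10.
Requiring ≥ 10 rankable genes guards the quantile against degenerate
inputs.

**Tracks.**  `export_bedgraph` writes fixed-bin (default 50 bp) coverage
of extended reads.  The bin value is the mean per-base depth over the
bin's covered bases: a single fragment spanning two bins scores 1 in
each, stacked identical fragments score their count, and Σ(value ×
covered bp) equals the summed extended read length.  Zero bins are
omitted.

## Expression screen

The design is triplicate wild-type vs knockout.  Detection calls
(present / marginal / absent) are consumed as data; the vendor
detection algorithm is out of scope, and for call-less matrices a
fallback rule calls a probe present iff its intensity exceeds a
per-sample background quantile (default 0.25).  Prefiltering keeps
probes detected in ≥ `min_detected` (default 2) samples of the genotype
whose transcripts the list is screening for: detected-in-KO for
up-in-KO candidates, detected-in-WT for down-in-KO.

Raw intensities go through across-sample quantile normalization then
log2 (`quantile_log2`) — a deliberate simplification of full microarray
preprocessing; matrices already on log2 scale use `passthrough`.  A
one-row matrix carries no rank information, so `quantile_log2`
degenerates to plain log2 there.

Per probe, a two-sided unpaired Student *t* (equal variance; Welch by
flag) compares KO with WT.  Significance is either raw *P* < 0.005
(`rawp`, the stringent mode) or BH *q* < 0.05 (`fdr`), with q-values
computed **within** each prefiltered list, since the two lists are
separate screens.  The pass flag additionally requires linear fold
change 2^|Δlog2| strictly above the cutoff (1.2 default, 1.5 optional)
and direction consistency with the list.  Probes with zero variance in
both groups have no defined *t* and are excluded with a warning rather
than given *P* = 0.

Gene collapse uses the any-probe rule: a gene is DE iff ≥ 1 probe
passes, represented by its smallest-*p* passing probe; genes with
passing probes of conflicting direction are flagged `discordant` and
kept with the representative's direction.  Passing probes absent from
the probe→gene map are reported separately as unannotated.

## Integration

Target sets are exact string intersections of the gene-level DE list
with each window's top-decile list, ordered by descending binding score
(gene-id tie-break).  The union and the genes appearing in ≥ 2 windows
are reported alongside per-window Venn counts (|DE|, |top|,
|intersection|); no single "number of targets" convention is imposed.
A per-window tally of up-in-KO vs down-in-KO target directions supports
the repression-vs-activation reading of each region.

## Comparative-Ct arithmetic

Amplification efficiency is fixed at 2 (the comparative-Ct assumption;
no Pfaffl correction): ΔCt = Ct_target − Ct_reference per sample,
ΔΔCt = ΔCt − mean(ΔCt of the calibrator genotype), fold = 2^−ΔΔCt.
Technical replicates are averaged to one ΔCt per sample before fold
reporting.  Adding a constant to both Ct values of a sample cancels in
ΔCt, and calibrator folds have geometric mean 1 by construction.

Replicate concordance mirrors a littermate-pair validation: within each
pair, technical-replicate ΔCt values of the knockout are compared with
the calibrator's by one-tailed Student *t* tests in both directions at
α = 0.05; a pair is "increased" if the increase tail is significant,
else "reduced" if the decrease tail is, else "no change" (pairs with
fewer than two technical replicates on either side are untestable and
counted as no change).  Concordance counts the pairs agreeing with the
microarray direction.  Both directions are tested because real
validation tables report conflicts; the tally does not adjudicate them.

Standard curves for qChIP-PCR fit Ct = m·log10(q) + b by least squares
on ≥ 3 dilution points (q in picograms), require m < 0, invert as
q = 10^((Ct−b)/m), flag unknowns outside the fitted Ct range as
extrapolated, and expose the implied efficiency 10^(−1/m) − 1.

## Synthetic data

The generator emulates the study conditions: non-overlapping
random-strand genes (default 1000 genes of 2–8 kb on 5 chromosomes);
uniform fragment-level background in both libraries at
`background_reads_per_kb` (default 30, fragment length 300 bp, read
length 76 bp single-end); ChIP enrichment planted by multiplying read
density by the planted fold inside chosen windows (default: 50 genes,
5% of the roster, at 5-fold in the TSS window); a log2 expression matrix
(gene baseline + group effect + N(0, noise_sd), noise_sd 0.1, 2 probes
per gene, 3 samples per group) with 30 of the enriched genes carrying a
±0.585 log2 (1.5-fold) effect, alternating direction; Bernoulli
detection calls (rate 0.95 for expressed genes, with ~60% of genes
expressed to exercise the prefilter); and Ct tables for 4 littermate
pairs in technical triplicate with Ct noise sd 0.05.  At these
conditions the per-probe power of the *t* test at *P* < 0.005 is ≈ 0.8
(noncentral *t*), i.e. ≈ 0.96 per gene with two probes, which is what
makes the end-to-end truth-recovery check meaningful rather than
trivially saturated.

A single master seed spawns independent substreams (genome, reads,
expression, qPCR, gene picks) via `numpy` SeedSequence, so components
are reproducible independently and all outputs are bit-identical given
(seed, config).

What the generator does **not** emulate: read sequences and mappability
structure (reads are intervals), CpG-methylation-driven binding
preference, probe-level PM/MM chemistry and its detection-call
statistics, intensity-dependent (heteroskedastic) microarray noise,
batch effects, and biological replicate heterogeneity beyond the
planted folds.  Passing recovery tests therefore demonstrates the
pipeline's arithmetic and ranking behaviour under its own model — not
robustness to the artefacts of real libraries.

## Numerical and design notes

* Decile size uses the ceiling rule ⌈fraction·G⌉; all tie-breaks are
  lexicographic by gene id, so every ranking is a total order and reruns
  are byte-identical.
* Fold change is reported as 2^|Δlog2| ≥ 1 with an explicit direction
  field rather than a signed ratio.
* The two prefiltered lists are allowed to differ in size; no structural
  equality between them is assumed anywhere.
* Mismatched chip/input window sets are an error naming the offending
  genes, never a silent inner join; duplicate gene ids in annotations or
  DE tables are rejected.
* Test problem sizes (1000 genes, 10 000 probes, 5 seeds) were chosen to
  keep the full suite and the acceptance script in the low minutes on a
  single core while leaving the statistical checks non-trivial.

## Known limitations

* Single-span gene models only: no isoforms, alternative TSS choice, or
  exon-level quantification; the annotation's collapsing convention is
  the user's responsibility.
* Read input is BED6 or SAM/BAM (single-end; optional minimum mapping
  quality for alignments, default off).  N for RPKM must be supplied
  explicitly when the file was pre-filtered upstream.
* The quantile+log2 normalization is a stand-in, not a replacement for
  full microarray preprocessing; detection calls are taken at face
  value.
* Gene-identifier matching in the integration step is exact; symbol
  aliasing must be resolved upstream.
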