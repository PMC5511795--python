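# Methods

`oncopanel` re-implements, as testable software, a targeted hybrid-capture
NGS platform for precision oncology: panel bookkeeping, sample and coverage
QC, germline and paired tumor–normal small-variant calling with a hotspot
rescue layer, rearrangement and copy-number detection, rule-based clinical
classification, and a five-modality reporting algorithm. The pipeline starts
at the aligned-read / pileup level: upstream read processing (trimming,
alignment, duplicate marking) is out of scope, as are the external impact
predictors, which are consumed as precomputed annotation columns.

## Panel model

Three subpanels of one capture design: a somatic subpanel (97 genes screened
for SNVs/indels/CNVs plus 17 genes with intron tiling for rearrangements), a
germline subpanel (148 hereditary-cancer genes: 72 Tier-1, of which 35
Tier-1a have management guidelines, and 76 Tier-2 genes reportable only for
syndromic patients), and a 64-gene research subpanel that is never clinically
reported. Panels load from flat TSVs; memberships merge onto one entry per
gene. The somatic and germline subpanels share 31 symbols by direct
intersection, and the registry reports that computed number rather than
forcing any other value. The lowercase isoform label `cdkn2ai3` seen in the
clinical tables is normalised to CDKN2A with an isoform note.

## Synthetic data

The generator produces the inputs the platform's validation assumes, with
known truth and full seed determinism:

* **Reference** — toy genes on one contig; an optional homology module adds
  an NGS dead zone (two segments ≥250 bp with 100% identity, where
  whole-genome mapping quality collapses to zero) and a low-stringency
  analogue differing at 1–5 positions per 250 bp.
* **Pileups** — per-site passing depth is Poisson(d); alt support is
  Binomial(depth, VAF); each remaining read miscalls at `error_rate`
  (default 1e-3, uniformly over the three non-reference bases); FFPE mode
  adds C>T/G>A deamination excess at a configurable rate. By Poisson
  thinning the marginal alt count is Poisson(d·VAF), which the test suite
  uses as an exact goodness-of-fit reference. Only this allele-count
  structure is modelled — no fragment lengths, capture-efficiency or
  base-quality recalibration — which is sufficient for the threshold
  filters, the callability accounting and the mixture experiments under
  test, but means passing tests say nothing about alignment artifacts or
  context-dependent error in real data.
* **Read pairs** — a fraction `allele_fraction` of fragments covering a
  breakpoint derive from the fused allele; junctions falling between mates
  give discordant pairs, junctions inside read 1 give split reads whose
  soft-clip coordinate equals the breakpoint exactly. Fused fragments carry
  `insert_size = 0` (undefined), which the SV caller treats as discordant.
* **Mixtures** — per site, reads are resampled from library A with
  probability `proportion_A`, else B, from each library's observed allele
  frequencies, so the expected mixed VAF is the proportion-weighted mean.
  The mixed depth is the mean of the two input depths; the mixture is
  therefore distribution-identical to A at `proportion_A = 1` in allele
  composition, not in raw depth.

## Sample QC and coverage

Sample qualification uses the fluorimetric/spectrophotometric concentration
ratio Q/N as a degradation proxy, with the decision lattice (strongest rule
first): Q/N < 0.1 → predicted failure; tumor content < 20% → enrichment
recommended; ≥100 ng and Q/N > 0.29 → accept; otherwise attempt with a
warning. The 20% purity floor is analytic: a clonal heterozygous variant at
purity p has expected VAF p/2, so the validated VAF ≥ 0.1 operating point is
first reached at p = 0.2.

Callability is the fraction of target bases with ≥k quality-passing reads
(k ∈ {10, 20, 50, 100, 500}); a gap is a maximal run of bases with fewer
than 20 passing reads, and the gap list is part of every report. Probe
redesign: regions short of 100% callability at 100× are boosted to 10×
tiling (this rule has priority — "poor" is defined at DP100, which subsumes
the DP20 variant of the definition), regions complete at 500× are relaxed
to 3×. Completeness comparisons are exact because the fractions derive from
integer counts.

## Small-variant calling

VAF is computed on quality-passing depth only (base quality ≥20, mapping
quality ≥30), since the filters are stated jointly with those cutoffs.
Germline calls require depth ≥6, alt count ≥3, VAF ≥0.1; somatic candidates
require the same depth/alt counts at VAF ≥0.025, with origin decided by
interrogating the matched normal (germline if the normal independently
passes the germline caller; somatic if the normal is covered without
germline-level support — no contamination margin is applied; undetermined
without normal coverage). Database-listed hotspots failing any threshold,
including the minimum VAF, are routed to a separate rescued output rather
than discarded. A blacklist of site- or substitution-class artifacts marks
recurrent errors as filtered. Indels are represented VCF-style,
left-aligned with the anchor base; multi-allelic sites emit one record per
allele. The platform's manual alignment-inspection step has no automated
equivalent here; calls are exported as IGV-ready VCF instead.

Dead zones get two modes: whole-genome alignment (ambiguous reads at MQ 0,
variants missed) and locus-restricted realignment, which substitutes the
counts obtained against a single-locus reference, recovering sensitivity at
the cost of specificity — every dead-zone call is therefore flagged as
needing orthogonal confirmation.

## Rearrangements

Pairs are discordant when mates map to different contigs, the insert is
undefined, or |insert| > mean + k·sd (k = 4 by default; the anomaly
multiplier is not fixed by the platform description, so it is configurable).
Clusters of ≥3 discordant/split fragments (matching the "mutated allele
count ≥3" ethos of the point-mutation caller) within a window of
mean + 3·sd seed events. The breakpoint is the modal split-read clip
coordinate when split evidence exists (ties: highest support, then
leftmost), giving single-base resolution; otherwise the cluster edge.
Inferred allele fraction = supporting fragments / fragments spanning the
A-side breakpoint.

## Copy number

Depth ratios are computed per gene region against a pool of ≥3 samples
captured with the same protocol: per-sample total-depth normalisation, then
log2 of sample over pool median; pool-median-zero regions are uncallable.
Allelic imbalance is the mean |VAF − 0.5| of region het SNPs and marks
calls corroborated above 0.1. Defaults: gain at log2 ≥ +0.4, loss at
≤ −0.8. Both thresholds sit ≈0.2 inside the single-copy-change expectations
(log2(3/2) ≈ +0.585, log2(1/2) = −1.0): placing the gain cut at the
single-copy expectation itself would leave a copy-3 region straddling its
own threshold (the log2-ratio standard error is ≈0.06 at 500×), so the
detection margin is mirrored from the loss side. With a paired normal, a
tumor call over a neutral normal is somatic and a shared call is germline.
No purity/ploidy deconvolution or multi-region segmentation is attempted —
targets are sparse panel exons and calls are per gene region.

## Classification rules

Somatic: eligible variants have frequency <0.05 in all four population
databases (dbSNP, 1000 Genomes, ESP, ExAC; absent = 0, comparisons strict)
and are in COSMIC/ICGC or protein-impacting. Eligible variants matched in
the drug-association KB become actionable, with the most specific match
winning (exact variant → variant-class pattern → gene level), drug
directions preserved (including resistance), and one of six evidence
levels. Eligible without a match → somatic VUS; ineligible → not reported.

Germline: pathogenic = solid-evidence HGMD DM below 0.05; likely pathogenic
= non-DM, protein-drastic (nonsense/start-loss/splice/frameshift), in a
germline-LoF cancer-risk gene, below 0.01; VUS = anything else below 0.01
(`other`), controversial DM below 0.05 (`DM_controversial`), or a
likely-pathogenic profile with frequency in [0.01, 0.05) (`freq_band`).
The solid-vs-controversial judgement is an expert-curated input flag, never
inferred. A known gap in the rule lattice: a non-DM, non-drastic variant
with frequency in [0.01, 0.05) falls in no category and is not reported.

Tumor-only mode removes calls at frequency ≥0.05 in any database and flags
retained, non-subclonal (VAF ≥ 0.3 by default; "non-subclonal" is otherwise
unquantified) known hereditary-cancer variants for a germline-testing
warning.

The bundled clinical case tables encode the platform's published series
(39 tumors, 36 germline samples) with the curation flags the expert review
produced; re-running the engines over them reproduces every printed
category, the 35/39 actionability yield and the 15/36 Tier-1
DM-Controversial prevalence.

## Reporting

Five request situations (aim × samples × consent) map onto five pipeline
configurations; all other combinations are rejected. Modalities 2–4 run a
parallel germline search over the somatic-subpanel genes (the narrow
reading of "variants with potential therapeutic relevance"; the full
germline subpanel enters only in modality 4) and re-inject drug-relevant
germline findings into the therapeutic section so paired subtraction can
never hide them. Hereditary findings are disclosed explicitly only under
consent; otherwise they surface as warnings "as present in the tumor".
Every report embeds the QC decision, callability and the gap list. The
estimated-percent-of-tumor-affected column of the published case table has
no stated convention and is deliberately not implemented.

## Validation harness and problem sizes

Confusion metrics match calls to truth on (chrom, pos, ref, alt), count
rescued calls as detections, and stratify by truth VAF (≥0.05, ≥0.10,
>0.20; left-closed). Frequency concordance uses Pearson R with an OLS fit;
the bundled external-quality-assessment table keeps both columns on the
percent scale as printed (R is scale-invariant).

The end-to-end caller benchmark (`calling_performance_simulation`, also run
by `scripts/acceptance.py`) simulates 2,000 variant sites with true allele
fractions on the 0.10–0.50 grid plus 10,000 negative sites at mean depth
950× and per-base error 1e-3, runs the paired somatic caller with rescue
disabled and an empty blacklist, and reports sensitivity and specificity.
These sizes give binomial standard errors below 0.2 percentage points on
both rates while keeping the whole suite and the acceptance script in the
low seconds. The mixture experiment mixes two libraries with private het
variants at 10/50/90% and checks detection at the resulting expected VAFs.

## Known limitations

* The noise model is site-independent; recurrent, context-dependent
  artifacts exist in the blacklist contract only.
* The SV caller does no assembly and classifies events by strand
  orientation only.
* CNV calls assume high purity; subclonal copy changes shrink the log2
  ratio toward 0 and will be missed at the default thresholds.
* The drug KB and population/disease databases are mock tables with the
  documented schema, not live database content.
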