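# Methods

This note documents the models behind each `isoscan` stage, the defaults
that matter, what the synthetic generator does and does not emulate, and
the numerical and design choices made where more than one reasonable
option existed.

## Normalization and shared substrate

Expression is quantified as TPM in the long-read sense — read counts per
1,000,000 mapped full-length reads per feature — so no length correction
is applied (each full-length read is one molecule observation). The
working scale is `log(TPM/10 + 1)` with the natural logarithm; the `/10`
damps the shot noise of shallow single-cell libraries before the log.
All-zero cells keep all-zero columns and are flagged rather than dropped,
so downstream stages can refuse them explicitly.

Cell QC discards cells with fewer than 500 detected genes (count ≥ 1) or
a mitochondrial count fraction strictly above 60%; isoforms are kept only
when at least 3 individuals each contribute at least 3 expressing cells.
"Detected/expressed" means count ≥ 1 throughout; no TPM floor is applied.
Highly variable genes are ranked per technology batch by binned
standardized dispersion (variance of log expression z-scored within bins
of mean expression, 20 bins) and the per-batch top lists are unioned,
with ties broken by gene id for determinism.

Differential expression uses the two-sided Wilcoxon rank-sum test on TPM
(rank tests are invariant to the monotone log transform). Fold change is
`(mean TPM A + 1)/(mean TPM B + 1)`; the 1-TPM pseudocount on both means
is symmetric and avoids division by zero. Significance requires BH
adjusted p < 0.05 and fold change ≥ 2 or ≤ 0.5.

## UTR deviation

UTR lengths per isoform are derived from annotation as the exonic bases
outside the CDS on the appropriate side of the transcript in its strand
orientation; non-coding isoforms have undefined UTRs and are excluded
from both sums of the expressed UTR length. Expression weights are TPM,
which removes library-depth confounding; consequently EUL and GUD are
invariant to global scaling of a cell's library.

The shortened/lengthened classifier fits `GUD ~ cell_type` per gene over
target (cancer) and reference (normal) cells with at least 10
defined-GUD cells per side. The technology batch enters as a random
intercept when there are ≥ 3 batch levels and as a fixed covariate
otherwise — a random intercept cannot be estimated stably from two
levels, and with two technologies a fixed term is the honest model. A
gene is called shortened only when all three criteria hold: negative
cell-type estimate, p < 0.05, and mean GUD difference ≤ −10 bp
(lengthened symmetrically with ≥ +10 bp). The magnitude rule is applied
as a signed ±10 bp threshold; the sign convention is negative =
shortening. Singular or failed fits are reported unchanged with a
diagnostic flag rather than silently dropped.

## Local splicing events and PSI

Events are enumerated from exon coordinates per gene, deterministically
and independent of transcript input order:

- **SE** — an internal exon with both flanking introns versus a
  transcript whose single intron spans the exon; inclusion = the
  exon-containing isoforms.
- **RI** — an exon spanning exactly two adjacent exons of another
  isoform plus the intron between; inclusion = the intron-retaining
  isoforms.
- **A5/A3** — two introns sharing one splice site, with the variable-side
  exons overlapping (the overlap requirement keeps alternative terminal
  exons from being double-reported); the donor side varies for A5 and
  the acceptor side for A3, strand-aware. Inclusion = isoforms using the
  shorter intron (more exonic sequence).
- **AF/AL** — non-overlapping alternative first (last) exons splicing to
  a shared exon; strand decides first versus last. Inclusion = the form
  whose alternative exon is genomically left (an arbitrary but
  deterministic convention; ΔPSI interpretation just follows the
  inclusion definition).
- **MX** — two non-overlapping internal exons with identical flanking
  splice sites that never co-occur in one isoform; inclusion = the
  genomically left exon.

PSI of an event in a cell is TPM(inclusion)/TPM(all participating
isoforms), undefined when the participating TPM is below 1 (isoform-TPM
events in the SUPPA sense, not junction-read PSI). Swapping inclusion and
exclusion sets maps PSI to 1 − PSI exactly.

Differential splicing uses a two-sided rank-sum test on per-cell PSI
with at least 10 defined cells per group, gated at raw p < 0.05 and
|ΔPSI| ≥ 0.1. The gate deliberately uses the raw p (a BH column is
reported additionally, not used for the gate). The per-patient mode
compares each patient's target cells against the pooled reference cells
and reports the union with per-patient flags.

Splicing-factor coupling is summarized as Pearson correlation between
event PSI and SF log expression over cells with defined PSI, followed by
average-linkage hierarchical clustering (Euclidean metric on the
correlation profiles) cut at k = 2, and a per-cluster 2×2 Fisher exact
test of retained-intron membership. Event-set overlap between two
contrasts counts events with |ΔPSI| > 0.05 in both and the same sign
(opposite sign in rescue mode, for knockdown-reversion designs) and
reports the upper-tail hypergeometric p on (universe, set A, set B,
overlap).

## Differential transcript and CDS usage

The two-stage procedure treats the gene as the screening unit and the
transcript (or CCDS group) as the confirmation unit. Per gene, per-cell
unit proportions (unit count / gene total, over gene-expressing cells,
at least 10 per group) are compared between groups by rank-sum per unit;
the gene screen p combines the unit p-values by Šidák
(`1 − (1 − min p)^k`), which is conservative under the negative
dependence induced by proportions summing to one. BH across genes gives
the screen-stage overall FDR; within screened genes (OFDR < 0.05) unit
p-values are Holm-adjusted. A unit is significant when its gene screens,
its confirmed p is < 0.05, and the pooled-count proportion difference
exceeds 10%. This stage-wise screen/confirm structure replaces a
Dirichlet-multinomial fit + stage-wise correction stack with a
distribution-free equivalent honoring the same OFDR semantics; the
estimator is swappable behind `usage_test`.

CDS grouping collapses transcripts sharing a CCDS id — or, when no id is
annotated, an identical CDS genomic interval set — so UTR-only switches
cannot register as differential CDS usage (a gene whose transcripts all
share one CDS has a single unit and is skipped). CDS-change annotation
compares the dominant up- and down-regulated units (largest
|Δproportion| in each direction, the natural exemplar rule): CDS length
difference (> 20 bp flags a coding change), exon differences counted as
the symmetric difference of exon interval sets, and domain loss judged
by overlap of a domain's genomic footprint (mapped from CDS-relative
coordinates through the CDS walk) with CDS regions absent from the other
isoform.

## Allele-specific expression

The caller tests, per (site, cell), whether the mutant read count
exceeds what sequencing error explains: with
`ε = C_other/(C_wt + C_mut + C_other)` as the error estimate, the
one-sided p is `P(X ≥ C_mut)` for `X ~ Binomial(n, ε)` with
n = all reads at the site. BH correction runs across all tested
(site, cell) pairs in a run; confirmation additionally requires
`C_wt + C_mut ≥ 3` in cancer cells or `≥ 10` in normal cells, whose
higher bar encodes the prior that normal cells should not carry somatic
mutations.

Two choices deserve note. First, ε defaults to per-site pooling across
cells with a floor of 10⁻³: a per-cell ε degenerates to zero whenever
`C_other = 0` (the common case at 10–20× coverage), which would make any
single mutant read "significant"; pooling stabilizes the null and the
floor bounds it away from zero even at error-free sites. Per-cell mode
is retained for fidelity. Second, misreads of the wild-type base land on
the specific mutant base only ~1/3 of the time while ε is estimated from
all non-wt/non-mut reads, so ε over-estimates the mutant-specific error
rate and the test errs conservative — the null-calibration check asserts
that conservative direction.

Allelic matrices Ewt/Emut/Etot are normalized per cell by the cell's
total mapped reads from the expression matrix, on the same
log(CPM/10+1) scale as expression. Correlation-shift analysis restricts
each site to cells with any allelic coverage (≥ 15 by default), computes
Pearson r between each allelic vector and each highly-variable gene, and
clusters HVGs on the `r_mut − r_wt` profiles (average linkage, k
clusters); zero-variance allelic vectors give NA and are excluded from
clustering.

## Signatures

Module scores are mean log expression of the set minus mean expression
of bin-matched controls: genes are cut into 25 equal-frequency bins of
average expression and, for each set gene, up to 100 control genes are
sampled (seeded) from its bin excluding the set itself — without the
exclusion a coherently shifted set would cancel against its own bin
mates. A fully degenerate bin (all members in the set) falls back to the
full bin, which correctly drives the whole-transcriptome score to zero.
The iCMS score of a subtype is the up-marker score minus the down-marker
score; a patient is assigned the subtype with the higher mean score over
its cancer cells, with margins at or below a configurable tie threshold
(default 0: exact ties only) left unassigned, because no principled
margin is derivable a priori. Subtype-consistent calls label a feature
Up (Down) in a subtype only when both comparisons — against the other
subtype and against normal epithelium — pass the mode's threshold in the
same direction (fold change ≥ 2 with p < 0.05 for transcripts;
ΔPSI ≥ 0.1 with p < 0.05, upward only, for splicing events); reciprocal
fold changes make "Up in both subtypes" impossible.

## Synthetic data generator

The generator emulates the data shape the statistics consume: multi-exon
genes (six-exon template) whose isoforms differ by one structural
variant each (exon skip, intron retention, alternative donor/acceptor,
alternative first/last exon, mutually exclusive exon, or 3′-UTR length);
negative-binomial counts (variance μ(1 + φμ), shared dispersion
φ = 0.3) around group-wise expected isoform proportions, log-normal
library sizes (median 10⁴ reads), two technology batches with mild
gene-level multiplicative effects (log-sd 0.1), and patients assigned
round-robin. Default group sizes are 200 normal + 200 cancer cells and
roughly half the genes are multi-isoform.

Planted effects are encoded in expectation so truth is closed-form: an
APA shift Δ uses an isoform pair whose 3′-UTRs differ by 2|Δ| and moves
the short-isoform proportion from 0.25 to 0.75; a ΔPSI effect moves the
inclusion proportion from 0.5 − Δ/2 to 0.5 + Δ/2; isoform switches take
the configured proportion vectors verbatim. Splicing-factor coupling
introduces a per-cell latent factor moving both the SF's expected
expression and the coupled event's inclusion proportion — the only place
per-cell proportion variation enters; elsewhere proportions are fixed
per gene, keeping truth arithmetic exact. Allelic counts draw per-cell
coverage as Poisson (mean 10) with a 30% dropout of uncovered
site-cells; reads are misread with probability `error_rate` (default
0.02), split 1/3 to the mutant base and 2/3 to the two remaining bases,
so the error model's "other" channel is informative about the mutant
channel in the ratio the caller assumes; carrier cells (default 80% of
cancer cells per site) emit mutant reads at the configured allele
fraction (default 0.5).

What the generator does **not** emulate: read-level artifacts
(truncation, mismapping, strand bias), gene-length or GC effects,
transcript-assembly and quantification error, correlated gene programs,
cell-type substructure beyond the two groups, doublets, or ambient
contamination. Passing tests therefore demonstrate that the statistics
recover what they claim under their own noise model at realistic sizes —
not that upstream quantification artifacts cannot bias them on real
data.

## Problem sizes and numerics

Test and acceptance runs use 40–200 cells per group and 4–100 genes per
fixture, chosen so each check completes in seconds while leaving the
relevant asymptotics (rank tests at n ≥ 40, BH across ≥ 50 features)
intact. Rank-sum tests fall back to p = 1 for constant features rather
than erroring. Ties in every ranking (HVG, clustering input order,
event ids) break on identifiers, and all simulation randomness flows
from a single integer seed through independent child streams, so every
artifact is byte-reproducible.

## Known limitations

- The two-stage usage test controls screen-stage OFDR with a
  conservative Šidák combination; it is less powerful than a
  Dirichlet-multinomial likelihood machinery for genes with many
  low-count units.
- The UTR classifier assumes GUD is approximately homoscedastic between
  cell types; strongly expression-dependent EUL noise is not modeled.
- Event extraction operates on annotated isoform structures only; events
  supported by reads but absent from the annotation are invisible.
- The per-site pooled ε assumes the error rate is homogeneous across
  cells at a site; cell-specific error processes would require the
  per-cell mode plus deeper coverage.
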