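# Methods

This note describes the models and procedures implemented in `splicequant`,
the choices behind their parameters, and what the synthetic benchmarks do
and do not demonstrate.

## Event model

An alternative-splicing event (ASE) is a binary choice between an
*included* and an *excluded* isoform at one locus. Seven forms are
annotated from a transcriptome GTF: skipped exon (SE), mutually exclusive
exons (MXE), alternative 5′/3′ splice site (A5SS/A3SS), alternative
first/last exon (AFE/ALE) and intron retention (IR). Enumeration works per
gene on the transcript structures:

- **IR** — an intron of one transcript fully contained in an exon of
  another transcript of the same gene (optionally every annotated intron
  with `--all-introns`);
- **SE** — a transcript carries two tandem junctions around a middle exon
  while another transcript carries the direct skip junction;
- **MXE** — two non-overlapping middle exons share both outer junction
  boundaries and never co-occur in one annotated transcript;
- **A5SS/A3SS** — two junctions share one boundary, differ at the other,
  and the exons at the differing boundary overlap (without the overlap
  requirement every MXE would also emit two spurious alt-splice-site
  events); donor/acceptor polarity follows the transcript strand;
- **AFE/ALE** — non-overlapping terminal exons splice into (out of) the
  same exon group through distinct first (last) junctions.

Polarity: for IR/SE/A5SS/A3SS the isoform with the larger alternatively
spliced region is Included; for MXE/AFE/ALE the isoform with the shorter
first intron in transcript orientation is Included; exact ties break to the
lexicographically smaller junction coordinates and are logged.

**Exon groups** are the connected components of the exon-overlap graph of
one gene (half-open intervals; abutting exons do not overlap). Exons that
fully span an intron of a sibling transcript (intron-retaining exons) are
excluded from the graph: including them would fuse the two groups flanking
every annotated retained intron, and the SpliceOver metric is defined
precisely by those two flanking groups.

All internal coordinates are 0-based half-open; GTF input/output is 1-based
inclusive; BED exports are 0-based half-open.

## Quantification

PSI = Included / (Included + Excluded). Junction-backed isoform abundances
are raw junction-read counts (no length normalization needed); isoforms
spanning two tandem junctions (SE inclusion, MXE isoforms) use the mean of
the two counts. For IR, the included isoform is measured by **IntronDepth**:
the 30% trimmed mean of per-base depth across the intron, with the trim
split symmetrically (floor of 15% of bases removed from each tail; if the
trim empties the list the median is used). Spliced (excluded) abundance for
IR offers three estimators of increasing robustness:

- **SpliceExact** — count of the junction exactly spanning the intron;
- **SpliceMax** — max of the donor-sharing and acceptor-sharing sums;
- **SpliceOver** (default) — max of the junction sums arising from the two
  flanking exon groups. Donor membership in a group is
  `span.start < donor <= span.end` (a donor coordinate equals its exon's
  end); acceptor membership is `span.start <= acceptor < span.end`. A
  junction only counts toward a group sum if it also crosses the intron of
  interest, so junctions internal to a flanking group are not treated as
  spliced abundance.

SpliceOver exists because the spliced major isoform may share *neither*
splice site with the intron of interest; in that case SpliceMax
under-counts the spliced isoform and over-estimates the IR-ratio
(IR-ratio = IntronDepth / (IntronDepth + spliced abundance), the IR
special case of PSI). The multi-isoform benchmark measures exactly this
configuration.

Junction counts and IntronDepth are treated as commensurate depth units:
a junction is crossed by `read_length - 1` of the read start positions that
produce one unit of coverage depth, so both approximate transcript depth at
the locus to within a factor `(r-1)/r`.

Read filters: unmapped, secondary, supplementary, QC-fail and
duplicate-flagged alignments are dropped; MAPQ is not filtered by default.
Deletions count as covered, insertions and skips do not. Overlapping mate
bases count twice (no overlap clipping). One BAM is processed in a single
deterministic pass; parallelism is offered only across samples.

## Coverage store

Per-sample coverage is kept in a BGZF-compressed, self-indexed `.cov` file
holding up to three strata (unstranded, plus, minus; unstranded libraries
store one). The stream is ordinary concatenated gzip members: a fixed-size
header block (stored-deflate, so it can be patched in place with the index
location after the body is written), run-length records `(depth int32,
run uint32)` per stratum and chromosome, a JSON index of genomic-position →
virtual-offset anchors every 16,384 bases (configurable), and the standard
BGZF EOF block. Queries binary-search the anchors and decompress only the
overlapping blocks; binned means aggregate exact per-base depths. Depth is
capped at 2³¹−1 (overflow raises, never wraps). The format is this
package's own; no binary compatibility with other tools' coverage formats
is claimed.

## Differential analysis

Events are pre-filtered: an event is tested when Inc+Exc ≥ 20 in at least
half the samples of *each* contrast group (both thresholds configurable,
plus an optional PSI-range filter). Two matrices (events × samples) of
included and excluded counts are the only input; tandem means may be
fractional and are rounded half-even before count models.

**Stage 1 (isoform-wise GLM).** Library size factors are median-of-ratios
on the Inc+Exc totals (total-count fallback when zeros dominate). Each of
the included and excluded matrices is fit per event with a log-link
negative-binomial GLM, no intercept, batch and treatment main effects and
an offset of log size factors; the treatment contrast is reported as log2
fold change with a Wald p. This stage tells whether a splicing change is
driven by the included isoform, the excluded isoform, or both.

**Interaction GLM.** The two matrices are concatenated column-wise, each
sample appearing once as Included and once as Excluded with an ASE
indicator. The per-event model uses per-sample intercepts plus one ASE
coefficient per treatment level; the sample intercepts absorb library size,
gene expression and any batch structure exactly, so the remaining
information is the within-sample Included:Excluded ratio and the test is
invariant to expression-only changes by construction. NB dispersion is
estimated per event by method of moments from a Poisson fit and shrunk in
log space toward a log-linear mean–dispersion trend. The
likelihood-ratio statistic for "the ASE coefficient differs between the two
contrast levels" (1 df) is referred to a quasi-likelihood F distribution:
the per-event Pearson lack-of-fit dispersion is moderated with a
moment-estimated prior df (matching the variance of log s² to
trigamma identities), and F = LR/s²_posterior with df (1, resid + prior).
The plain chi-square LRT is also available (`test="lrt"`) but is
anticonservative at 3v3.

**Beta-binomial two-group test.** `m = Included` successes out of
`Y = Included + Excluded` trials, `m ~ BetaBinomial(Y, p_group, φ)` with
φ the overdispersion on (0,1) (φ→0 is binomial). φ is estimated per event
by a df-corrected moment match of the binomial Pearson statistic at the
fitted group proportions — at few replicates this is far less biased than
per-event maximum likelihood — and shrunk linearly toward the all-event
mean with weight `n_eff/(n_eff+n0)`, where `n_eff` counts informative
samples and `n0 = 10`: dispersion information grows with replicates, not
depth, so shrinkage is deliberately strong at typical replicate numbers.
Group proportions are profiled at the shrunk φ and the likelihood ratio for
`p_A = p_B` is referred to chi-square after a genomic-control scale
correction (median LR over the chi²₁ median, floored at 1). The scale
correction assumes a mostly-null event panel, as in transcriptome-wide
analyses; under heavy contamination (a large differential fraction) it
costs some power but not validity. Two-group contrasts only; no batch term.

FDR is Benjamini–Hochberg over the non-missing p-values; missing values
propagate. Events are called differential at q < 0.05 and |ΔPSI| > 0.05,
ordered by q, then |ΔPSI| descending, then event id. ΔPSI is the difference
of group mean PSIs (undefined PSIs excluded; an event needs ≥ 2 defined
samples per group to be tested).

Calibration was verified on 2000-event null simulations (3v3, beta
precision 30, N ~ 50+Poisson(20)) across 12 seeds: rejection at p<0.05 in
0.044–0.062 (GLM) and 0.041–0.068 (beta-binomial) with KS distance from
uniform ≤ 0.03.

## Coverage plots and the T-score

For one event and sample, raw per-base coverage over the event region ± a
100-base flank is divided by a single normalization factor estimating
transcript depth at the locus: SpliceOver + IntronDepth for IR, included +
excluded junction counts otherwise (the non-IR factor is an extension
justified by the same transcript-depth argument). With this factor,
constitutive regions sit near 1 and the mean normalized intron coverage
equals the IR-ratio. Samples with factor < 1 are flagged ineligible rather
than plotted. Group traces are pointwise means with ±1 SD ribbons
(the band definition is this package's choice).

Differential splicing between two groups is visualized by a per-base
two-tailed pooled-variance Student's t-test on the normalized coverages
(Student's rather than Welch's, following the named test); p-values are
floored at 1e-300 and −log10 p capped at 300. Degenerate bases (both group
variances ~0) give p = 1 when the means agree and the floor otherwise,
using a relative tolerance of 1e-12 since float means of identical values
differ at machine precision. The **event T-score** is the mean of −log10 p
across the alternatively spliced region excluding five boundary bases at
each end; regions of ≤ 10 bases are used whole (logged). Eligibility: IR
and SE events are scored (intron / skipped exon); MXE, AFE and ALE are not
(their alternative regions are mutually exclusive, so coverage differences
are not interpretable as one signed signal); A5SS/A3SS are scored on the
inter-splice-site region unless an annotated intron of an interfering
transcript lies inside it.

## Synthetic data

The generator produces deterministic toy genomes and reads; everything is
a pure function of (scenario, seed).

- **Named scenarios**: a seven-transcript multi-isoform IR locus (retained
  intron; exact splice; donor-, acceptor-sharing variants; two
  alternative-flank transcripts sharing neither splice site), a two-isoform
  IR locus, a cassette exon, an A5SS pair with an interfering third
  transcript, and an MXE pair.
- **Read simulation**: reads per transcript are
  `round(abundance × (L − r + 1)/r)` with uniform start positions, giving
  interior per-base depth ≈ abundance and junction counts ≈ abundance ×
  (r−1)/r, so coverage- and junction-based estimators agree by design.
  Spliced reads receive correct N CIGAR operations; output is a sorted,
  indexed BAM plus a ground-truth PSI table. No sequencing-error, GC- or
  positional-bias model is included — so passing benchmarks demonstrate
  correctness of the estimators under ideal sampling, not robustness to
  the coverage biases of real libraries (which the single per-event
  normalization factor explicitly does not correct).
- **IR panel** (read level): independent two-isoform IR genes; group mean
  PSIs from U(0.05, 0.35); 10% of events shifted by U(0.1, 0.3) in group B;
  per-sample PSIs Beta-distributed with precision 100 (replicate PSI sd
  ≈ 0.03–0.04 at low PSI, in line with the high replicate concordance
  reported for intron retention); isoform depths 50× split by the drawn
  PSI. The high-PSI panel is the exact reflection (same draws, ψ → 1−ψ),
  so the low-vs-high comparison is paired and isolates the representational
  asymmetry of coverage plots: excluded isoforms appear only as missing
  coverage, so at PSI near 1 the differential signal competes with the
  coverage noise of the dominant included isoform.
- **Count-level simulation**: per event, group mean PSIs uniform on
  (0.05, 0.95), a labelled 10% differential fraction with |ΔPSI| ≥ 0.1;
  per sample, PSI ~ Beta(mean, precision 30), N ~ 50 + Poisson(20),
  Included ~ Binomial(N, PSI). The truth table records both the population
  group means and the realized means of the drawn per-sample PSIs; recovery
  is measured against the realized means, the quantity a finite-sample
  group-mean estimator targets.

## Benchmark problem sizes

The self-checks regenerate all inputs from a seed: the multi-isoform locus
with three replicates at ~30–60× per isoform; the anchoring check with
three replicates at 60×; T-score panels of 300 events (30 differential)
per direction; 2000-event null and 10%-differential count panels at 3v3;
200 random coverage tracks for format fidelity; 40 random toy genes for the
enumeration oracle. These sizes keep each check within a couple of minutes
on one CPU while making the summary statistics stable across seeds (AUROC
estimator sd ~0.02 at 30 positives).

## Known limitations

- The single per-event normalization factor cannot correct GC or 5′/3′
  coverage bias, and batch effects enter only the count models, not the
  coverage normalization.
- The T-score is uninformative for MXE/AFE/ALE and weak at PSI near 1
  (by design of coverage representation, as the mirrored panel shows).
- The genomic-control scale in the beta-binomial test assumes a mostly-null
  panel; analyses of small, strongly differential event sets should prefer
  the interaction GLM.
- The interaction-GLM statistic is only approximately invariant to scaling
  a single sample's counts (deeper samples carry more weight); ΔPSI is
  exactly invariant.
- Junctions in overlapping genes on the same strand are resolved per gene;
  overlapping genes do not merge exon groups.
- Paired-end mate overlap is not clipped; junctions present in both mates
  count twice.
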