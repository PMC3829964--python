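# Methods

## The data model

`antarray` analyzes single-color (one channel per array)
background-subtracted fluorescence intensities. The unit of analysis is
the *contig* (an assembled transcript fragment); each contig is
represented on the array by several 60-mer probes whose multiplicity
encodes the platform design: 2 probes for contigs with an annotated
ORF, 4 (2 per reading direction) for unknown-ORF contigs, and always 5
for odorant-receptor contigs. Arrays come in two hybridization batches
("datasets"): dataset 1 contrasts queens, males and workers; dataset 2
contrasts large and tiny workers. Each group contributes 4 arrays; the
dataset-1 worker group is 3 biological replicates plus 1 technical
replicate of pooled RNA.

The synthetic generator draws intensities from a log-normal model,

    log2 I(p, s) = b(c) + o(p) + delta(c, g(s)) + eps(c, s),

with per-contig baselines `b` (normal, mean/sd configurable globally
and per contig class), fixed per-probe offsets `o`, group-specific
spiked log2 fold-changes `delta`, and replicate noise `eps` at the
(contig, array) level — i.e. biological variation shared by a contig's
probes within one array. Technical replicates re-draw a noise term of
sd `technical_noise_factor x replicate_noise_sd` (default factor 0.5)
around the *pooled mean* of their group's biological noise, matching
how a technical replicate of pooled RNA behaves. Linear intensities are
`2^log2`, floor-clipped at `clip_floor` (default 0, representing
background-subtraction floors). Everything is deterministic given
(config, seed); sub-streams for baselines, offsets, and noise are
spawned from a single seed sequence.

### What the generator emulates, and what it does not

It reproduces the replicate structure, probe multiplicities, two-batch
design, absolute-intensity scale (baselines around 2^8–2^10), and known
spiked effects. It does not model dye chemistry, spatial artifacts,
probe sequence effects (GC content, cross-hybridization), or
heavy-tailed/outlier noise. Passing recovery tests therefore
demonstrates that the statistical machinery does what it claims under a
clean log-normal world — not that the thresholds are optimal for any
particular real dataset.

## Normalization and aggregation

Quantile normalization uses the mean-of-order-statistics construction:
every column receives the vector of row-wise means of the per-column
order statistics; ties within a column get the mean of the normalized
values over their tied ranks. Datasets are normalized separately and
never mixed. Note that the "identical multiset in every column"
property is exact only for tie-free columns: the tie rule necessarily
replaces tied positions by their average. Probe pooling is the
unweighted mean over a contig's probes per array, including both
orientations of unknown-ORF contigs; the default log transform is
log2(value + 1), so floor-clipped zeros map to 0. The log base is a
configuration choice; the ±0.5 grey band of the candidate screen (see
below) is calibrated for log2.

## Differential expression cascade

Group means and the fold gate operate on the linear scale; hypothesis
tests operate on log2 values, consistent with the log-normal noise
model. Per contig:

- *expressed* ⇔ the largest linear group mean is ≥ `min_mean_intensity`
  (default 100) — a contig high in only one caste is kept;
- three-group comparisons use a one-way fixed-effects ANOVA, two-group
  comparisons a pooled-variance two-tailed Student *t*-test (not Welch);
  technical replicates count as ordinary fourth observations;
- BH step-up adjustment spans all expressed contigs of the comparison;
- *relevant* ⇔ expressed ∧ adjusted p ≤ alpha ∧ largest pairwise ratio
  of linear group means ≥ `min_fold` (default 2);
- contigs passing the adjusted ANOVA receive a Student–Newman–Keuls
  step-down grouping: ordered means, stretches of length r = k..2
  compared against q(alpha, r, df_error)·sqrt(MSE/n_h) with n_h the
  harmonic mean of the stretch's group sizes; a stretch declared
  homogeneous is never subdivided. SNK is computed only for
  BH-significant contigs, mirroring standard post-hoc practice.

Degenerate inputs are resolved explicitly: all observations identical →
F = 0, p = 1; zero within-group variance with distinct means → p = 0
(flagged by ±inf statistics); nonpositive MSE aborts the SNK.

The heatmap export masks (emits as missing) every cell of a contig that
is not expressed above cutoff or not relevant in its comparison.

## The expression-factor screen

Within the focal group (the macroglomerulus-bearing phenotype), each OR
gene's LTI is its mean log2 value over *biological* replicates;
technical replicates are excluded by definition. The expression factor

    EF = (LTI_cand − LTI_mean) / SD

standardizes a gene against the whole OR-related gene set. `SD` is the
*sample* standard deviation (n−1) of the LTI vector — reading the
looser phrase "standard deviation of the mean" as a standard error
would inflate EFs by ~sqrt(n_genes) and is incompatible with reported
candidate EFs in the 2–3.5 range. By construction the EF vector has
mean 0 and sample SD 1 over the gene set, and is invariant to affine
rescalings of the LTIs.

A candidate satisfies EF ≥ `ef_min` (default 2) *and* log_fold =
LTI_focal − LTI_reference ≥ `band_halfwidth` (default 0.5, the grey
band of biologically irrelevant differences; 0.5 log2 ≈ 1.4-fold). The
band gate is one-sided for candidacy — candidates must be enriched in
the focal phenotype — while the symmetric band is still reported for
plotting. Output is ranked by EF, ties broken by log_fold then gene id.
Percentile ranks within a reference gene class count strictly smaller
LTIs, with ties counting one half.

## GO presence/absence comparison

A contig is present on an array when its aggregated linear intensity is
≥ the presence threshold (default 100, reusing the expression cutoff),
and present in a group when called on ≥ 50% of the group's arrays
(majority rule). Each term is tested independently with Pearson's
chi-square (no continuity correction, no multiple-testing correction
across terms) on the 2 × k table of annotated vs non-annotated present
contigs per group; expected counts below 5 are flagged, and groups with
no present contigs make the term's test skipped-and-flagged.

**A calibration caveat discovered during validation:** when group
presence is a per-contig Bernoulli thinning with probability q, the
annotated-proportion estimator has only (1−q) times the variance the
contingency-table asymptotics assume, so the per-term test is
*conservative* under the pipeline null (measured mean chi-square ≈ 0.34
at q ≈ 0.69, matching the analytic factor). On the chi-square's own
sampling model — independent multinomial samples of present contigs per
group — the test is calibrated, and the suite verifies both facts.
Practically this means "no term differs" conclusions are safe, while
per-term power is lower than nominal.

## Scenario conditions (fixed study parameters)

- **Worker screen** — 200 OR genes (baseline N(8, 0.5) log2) embedded
  among 1000 background contigs (N(9, 1.5)); one candidate pinned at
  baseline 8.8 and spiked log2(2.1) in large workers; 4 + 4 arrays,
  replicate sd 0.25, probe offset sd 0.25. The pinned baseline makes
  the candidate's expected EF ≈ 3.4. The background embedding matters:
  quantile normalization on an OR-only array would fold the spikes'
  extreme order statistics back onto whichever genes rank top in the
  comparison group.
- **Male screen** — same design; three candidates pinned at baseline
  8.3 and spiked log2(5.5), log2(11), log2(22.7) in males vs queens.
- **DE spike recovery** — 50 contigs, one spiked at log2FC 2.0 in a
  4 + 4 subcaste design. The 2.0 figure is a power choice: BH across
  mostly-null contigs pushes the effective per-contig threshold to
  ~alpha/m, where the df = 6 t-test needs a ≥4-fold change for ≥99%
  per-seed recovery.
- **Nulls** — DE: the three-caste design (3 biological + 1 technical
  worker replicate), 500 contigs, no spikes. GO: a subcaste design with
  all baselines pinned at the presence cutoff (log2 100) so presence
  calls are driven by independent per-array noise — an exchangeable
  null that exercises genuinely random 2 × k tables.

Problem sizes in the test suite (100 seeds for recovery rates, 50 for
nulls, 1000 random vectors for the BH oracle, 200 instances for the
SNK oracle) are the package's chosen trade-off between statistical
resolution of the rates being estimated and a test suite that runs in a
couple of minutes.

## Numerical choices

- BH is implemented directly from the step-up definition
  (min_{j≥i} m·p_(j)/j, capped at 1) so it agrees *exactly* with a
  brute-force evaluation; statsmodels' `fdr_bh` agrees to 1e-12 and
  serves as an independent cross-check.
- SNK critical points come from `scipy.stats.studentized_range`; the
  test suite re-derives accept/reject decisions from an independent
  double numerical integration of the studentized-range CDF.
- Chi-square statistics delegate to `scipy.stats.chi2_contingency`
  with a brute-force Σ(O−E)²/E oracle in the tests; degenerate tables
  (an all-zero row) short-circuit to chi2 = 0, p = 1, flagged.
- Ratios with a zero denominator (floor-clipped group means) are
  reported as infinite rather than erroring, and pass the fold gate.

## Known limitations

- No empirical-Bayes variance moderation (limma-style); at n = 4 the
  plain t-test/ANOVA cascade has limited power, which the EF screen
  deliberately sidesteps for the OR set.
- The GO comparison treats contigs as independent observations;
  array-count-based alternatives would need a different variance model.
- Presence calling by absolute intensity is a proxy for platform
  detection flags, which the pipeline does not model.
- The grey band and EF thresholds assume log2; other bases require
  rescaling `band_halfwidth`.
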