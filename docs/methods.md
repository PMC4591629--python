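# Methods

`cisspread` quantifies how far transcriptional silencing spreads in *cis*
from the integration site of an inducible silencer — the scenario of an
XIST transgene recruited to an autosome, where one homolog carries the
transgene and silencing of that homolog is read out as allelic imbalance
at heterozygous sites. This note records the model, the estimators, the
numerical choices, and what the synthetic data do and do not capture.

## The allelic silencing estimator

At a heterozygous site with alleles a and b, the allelic ratio in a
condition is `a / (a + b)`. The workflow applied per region of interest
(a gene for RNA-seq, a genomic window for ChIP-seq):

1. **Zero filter.** Sites with zero allelic reads in either condition are
   excluded up front (a ratio is an error there, never silently 0).
2. **Biallelic filter.** Only sites with a control ratio in **[0.3, 0.7]**
   are retained. The interval is read as closed: 0.30 and 0.70 pass. It is
   symmetric, so the filter is independent of which allele is labelled a.
3. **Phasing.** The allele with *fewer reads in the induced condition* is
   designated the cis (silenced) allele. The phase of variants relative to
   the transgene is generally unknown, so the method infers it from the
   direction of change. Exact ties designate allele a deterministically
   and set a flag; a tied site has ratio 0.5 and does not move the pooled
   estimate in expectation.
4. **ChIP depth filter** (ChIP mode only). Sites whose total reads differ
   by more than 2-fold from the region's per-condition mean are excluded.
   This is a *single pass against the original mean* — the mean is not
   recomputed and the filter not reapplied; with depths {10,10,10,100} the
   mean is 32.5 and every site fails, which is the fixed semantics.
5. **Aggregation with one outlier pass.** The region ratio is the
   read-weighted pool (sum of designated-allele reads over sum of allelic
   reads) per condition. Sites whose condition-specific ratio deviates
   from the pooled ratio by strictly more than **0.15** in either
   condition are removed once, and the pooled ratio recomputed once. The
   deviation is checked in both conditions, the conservative reading of a
   procedure that does not pin the condition down; the per-condition
   alternative and a mean-of-ratios pool are config options since both
   points are genuinely open.
6. **Read gate.** A region needs at least **4** (RNA) or **5** (ChIP)
   allelic reads *in both conditions*, counted over retained sites.
7. **Percent allelic silencing** = `(r_ctrl − r_exp) / r_ctrl × 100`,
   where r is the pooled frequency of the designated silenced allele.
   Negative values (allelic gain) are reported, not clipped.

### Known bias of the phasing rule

Designating the per-site minimum of the induced counts selects the
downward noise fluctuation when there is no true silencing. Under the
null at per-site depth d the pooled induced ratio is biased low by about
`0.4 / sqrt(d)` (≈ 0.056 at d = 50), inflating percent silencing by
roughly 11 points at depth 50 and ~2.5 points at depth 1000. This is a
property of the method itself, not of this implementation; it vanishes as
depth grows. The parameter-recovery check therefore compares the mean
estimate across genes at depth 1000 against the closed form
`100·(0.5 − (1−s)/(2−s))/0.5`, and the null-control check at the default
depth of 50 verifies that despite the bias fewer than 5 % of genes exceed
|30 %| apparent silencing — the threshold used for calling a gene
allelically silenced.

## Gene-level statistics

- **Total-reduction band.** A gene "silences" if its total expression
  drops by 30–60 % (inclusive). With one of two alleles fully silenced
  the ceiling is 50 %; the band deliberately excludes larger drops, which
  are more plausibly trans effects. Genes above 60 % are reported
  separately, never folded into the band. Expression is gated at mean
  FPKM ≥ 5 across conditions (condition-specific gating available).
- **Proportion test.** A 2×2 chi-square (uncorrected) of band membership ×
  near-integration (default within 30 Mb) vs rest of genome. Expected
  cells < 1 raise a small-sample flag; a degenerate margin returns the
  null outcome rather than an exception.
- **Distance decay.** The published analyses this emulates name a
  chi-square permutation test without specifying its construction; ours
  is declared, not inferred: genes are ranked
  by |distance| and split into 5 equal-count bins; the statistic is the
  chi-square of silenced/not counts across bins; the null permutes gene
  labels; the empirical p is `(1 + #{perm ≥ obs}) / (1 + n_perm)` (never
  0). Bin count, statistic and permutation unit are exposed. Because the
  scientific claim is directional, a one-sided Cochran–Armitage-style
  decreasing-trend statistic is available (`method="trend"`). Calibration:
  type-I error 0.035–0.054 at α = 0.05 across seeds (1,000 null
  simulations, 1,000 permutations each — slightly conservative from the
  discreteness of the statistic), power ≈ 1.0 on the default gradient.
- **Correlations** are scipy Spearman/Pearson with pairwise-complete
  missing handling; constant inputs flag rather than raise. Per-gene
  p-value families can be Holm-adjusted — a stricter default than
  reporting unadjusted per-gene values.

## Chromatin windows

Coverage is summed into non-overlapping windows (2 kb and 1 Mb are the
conventional sizes; the partial terminal window is kept and its true
width used for densities). No normalization formula is standard
here; we use counts-per-million per condition before differencing
(input subtraction optional). Note that CPM couples the arms: a genuine
gain on the integration arm necessarily shows as a compensating deficit
elsewhere in CPM units — visible in the arm summaries of the synthetic
data, and worth remembering when reading the q-arm row. Arm summaries
use a paired t-test across windows in scope, with windows assigned to
arms by midpoint; zero-variance differences are handled explicitly
(delta ≡ 0 ⇒ t = 0, p = 1, flagged). Gene metaprofiles rescale each body
to 40 mean-signal bins with 10 kb flanks in 10 fixed-width bins,
oriented 5′→3′ (minus-strand genes flipped); flank bases beyond the
chromosome are NaN-padded out of the mean, and genes shorter than one
base per body bin are skipped and counted.

## Contact matrices

40 kb binned symmetric matrices are summed into 1 Mb bins (25×25 blocks,
partial last megabase allowed); the anchored profile is the row of the
1 Mb bin containing the integration position. Bins are 0-based half-open,
so position 1,000,000 belongs to bin 1. Total mass is conserved exactly.
The diagonal (intra-anchor) entry is reported but flagged, since
self-contacts dominate any anchored profile. Normalization (ICE/KR) is
out of scope — the intended inputs are already-normalized published
matrices.

## The synthetic data

The generator emulates the *structure* of the real datasets this
pipeline targets, with truth recorded for recovery tests:

- **Silencing field.** `s(d) = silencing_max · 2^(−d/halflife)`, zeroed
  inside "resistant" domains to emulate discontinuous spread. No
  quantitative decay length exists for the real phenomenon (silencing was
  observed out to ~50 Mb but concentrated near the site); the default
  half-life of 5 Mb is explicitly arbitrary, and the functional form is a
  config option in spirit — monotone exponential is simply the least
  structured choice.
- **Counts.** Per-site depth is gamma-Poisson (mean 50, shape 10 —
  variance ≈ 6× the mean, typical RNA-seq overdispersion). Control allele
  split is Binomial(d, ½); induced cis-allele output is scaled by (1−s),
  so the induced total depth scales by (2−s)/2 and the cis allele
  frequency is `(1−s)/(2−s)`. Phase is drawn per variant, stored only in
  the truth.
- **Genes.** 200 genes over 50 Mb, one per equal slot (hence disjoint and
  sorted by construction), Poisson(6) variants each (min 1), integration
  at 5 Mb on the p arm, centromere at 25 Mb.
- **Chromatin.** The repressive baseline is a smooth log-normal profile;
  the induced level is `baseline × (1 + gain·w)` with a proximity weight
  halving every 20 Mb on the integration arm and zero on the other arm,
  times log-normal noise. `noise_sd = 0.15` was calibrated once by
  simulation so the rank correlation between baseline and gain on the
  integration arm lands in the regime reported for the real data
  (ρ ≈ 0.87 at 500 windows). The active mark is promoter-boosted and lost
  in proportion to local silencing, more strongly at promoters.
- **Contacts.** Expected counts `hic_depth · (1+|i−j|)^(−α)` (α = 1),
  Poisson-sampled symmetrically; noise can be disabled for exact
  closed-form checks.
- **Expression.** Control FPKM is log-normal; induced FPKM is
  `(2−s)/2` of control with 10 % log-normal noise.

What the generator does *not* capture: mappability and reference bias at
variant sites, correlated errors between conditions, genotyping error,
copy-number and karyotype abnormalities, domain-scale correlation of
contacts beyond the distance law, and any feedback between chromatin
state and expression. Passing tests therefore demonstrate correctness of
the estimators and calibration of the tests under the declared generative
model — not robustness to those real-data pathologies.

## Determinism and problem sizes

All randomness flows from a single integer seed through fixed, named
sub-streams per product, so any artifact is reproducible independently of
generation order; identical parameters give byte-identical outputs. The
shipped checks use: 1,000 random regions for oracle equivalence, 40 genes
× 5 silencing levels for recovery, 3 × 200 genes for the null control,
1,000 null simulations × 1,000 permutations for test calibration and 60
gradient simulations for power, 500-window tracks, and a 1,250-bin
contact matrix — sizes chosen so the complete suite runs in about a
minute on one core while keeping Monte-Carlo error well inside each
check's margin.
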