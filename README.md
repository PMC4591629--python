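# cisspread

Allele-specific quantification of *cis*-silencing spread from an
inducible XIST transgene integration site.

When the long non-coding RNA XIST is expressed from a single-copy
transgene, it silences the chromosome it is transcribed from — but only
that homolog, and with an efficiency that falls off with distance from
the integration site and can skip resistant domains. Because only one
homolog is silenced, the cleanest readout is **allelic imbalance**: at a
heterozygous site, the transgene-linked (cis) allele loses reads in the
induced condition while the trans allele is untouched. `cisspread`
implements that readout and its companion analyses for people studying
XIST biology, chromosome-scale silencing, or any inducible cis-acting
repressor:

- **allelic workflow** — site-level allelic ratios, biallelic filtering
  (control ratio in [0.3, 0.7]), phasing by the lower induced count,
  read-weighted per-gene pooling with a single 0.15 outlier-removal pass,
  a 2-fold ChIP depth filter, 4/5-read gates, and
  `percent allelic silencing = (r_ctrl − r_exp)/r_ctrl × 100`;
- **silencing statistics** — the 30–60 % total-reduction band, a 2×2
  chi-square of near-integration enrichment, a chi-square permutation
  test for decay of silencing with distance, correlation helpers;
- **chromatin windows** — fixed-window quantification (CPM), per-arm
  paired-t change summaries, strand-aware gene metaprofiles with 10 kb
  flanks, and the correlation of repressive-mark gain with pre-existing
  levels;
- **Hi-C anchoring** — 40 kb → 1 Mb block-sum rebinning and the contact
  profile anchored at the bin containing the transgene;
- **a synthetic-data generator** with known ground truth (exponential
  distance decay of the silenced fraction, optional resistant domains,
  overdispersed counts), so every estimator has parameter-recovery tests.

If one allele carries true silenced fraction *s*, the induced cis-allele
frequency is `(1−s)/(2−s)` and the expected percent allelic silencing is
`100·(0.5 − (1−s)/(2−s))/0.5` — the closed form the recovery tests check
against. See `docs/methods.md` for the full model, numerical choices,
and known limitations (including the finite-depth bias of the
minimum-read phasing rule).

## Worked example

```python
import cisspread as cs
from cisspread.pipeline import regions_from_genes

params = cs.SimParams(seed=1)          # 50 Mb, 200 genes, integration at 5 Mb
genes, variants = cs.generate_genes(params)
truth = cs.make_ground_truth(params, genes, variants)
counts = cs.simulate_allelic_counts(genes, truth, params)

regions = regions_from_genes(genes, params.integration_pos)
summaries, audit = cs.summarize_regions(counts, regions, mode="rna")
near = summaries[summaries["distance_to_integration"].abs() < 2e6]
print(near[["region_id", "n_sites_retained", "percent_allelic_silencing"]].head())

calls = summaries[summaries["passed_min_reads"]]
res = cs.distance_decay_permutation_test(
    (calls["percent_allelic_silencing"] > 30).to_numpy(),
    calls["distance_to_integration"].to_numpy(),
    n_bins=5, n_perm=10_000, seed=1)
print(f"decay p = {res.p_value:.4f}, silenced per bin = {res.bin_silenced}")
```

prints

```
   region_id  n_sites_retained  percent_allelic_silencing
12     g0012                10                  41.568389
13     g0013                 5                  47.246296
14     g0014                 8                  63.136863
15     g0015                 5                  53.600888
16     g0016                 4                  43.657463
```

— genes within 2 Mb of the integration site lose roughly 40–65 % of
their cis-allele expression (their true silenced fractions are 0.6–0.8;
the estimate maps through the ratio definition) — and

```
decay p = 0.0001, silenced per bin = [34.  1.  1.  0.  0.]
```

— of the genes called silenced (allelic change > 30 %), almost all sit
in the nearest distance quintile, and no permutation of gene labels
reproduces so steep a gradient.

The same analyses run from the shell: `cisspread simulate`, `allelic`,
`stats`, `chip`, `hic`, and `pipeline` (see `cisspread --help`). The
numbered drivers in `analysis/` (01_simulate → 05_hic_anchor) run the
whole study narrative on the default synthetic chromosome and write
their tables under `results/`.

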