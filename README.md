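# allelochoice

Simulation and analysis toolkit for studying **clonal allelic choice** at the
immunoglobulin kappa variable (Vκ) locus in F1 hybrid (B6 × Cast) pre-B cells.

In a hybrid cell every Vκ segment exists in two parental copies that can be told
apart by strain SNPs. Before rearrangement, each segment's two alleles are
activated (made accessible and non-coding transcribed) independently and
stochastically, so an individual clone carries a mosaic of silent, monoallelic
and biallelic segments. This package provides:

- a **generative model** of per-allele activation (independent Bernoulli choices
  with allele-specific probabilities) together with closed-form predictions,
  maximum-likelihood parameter estimation and goodness-of-fit testing
  (`activation_model`);
- **synthetic data generators** for loci, clones, allele-resolved read counts
  with negative-binomial noise, SNP panels, read pairs, clone pools and
  rearrangement repertoires (`synthetic_data`);
- **allele assignment** of read pairs via SNP base calls and strand-aware
  feature windows, with conservation-checked tallies (`allelic_assignment`);
- a replicate-consistent **monoallelic caller** (exact binomial test,
  Benjamini–Hochberg FDR, fold-change filter, depth gating)
  (`monoallelic_calling`);
- **clonal profile analysis**: allelic-ratio matrices, PCA, hierarchical
  clustering with Newick export, replicate-stability checks,
  accessibility/transcription concordance and heatmaps (`clonal_profiles`);
- **repertoire analysis**: normalisation, rearrangement allelic ratios,
  ncRNA–repertoire coupling correlation, skew summaries and induction kinetics
  (`repertoire`);
- text-based **file formats, a YAML-configured pipeline with a hashed
  manifest, and a CLI** (`io`, `cli`).

See [docs/methods.md](docs/methods.md) for the statistical methods.

## Quick start (CLI)

```bash
# simulate a study-scale dataset (96 segments, 60 functional, 4 clones + pool)
allelochoice simulate --preset study --seed 1 --outdir sim/

# assign simulated read pairs to parental alleles
allelochoice assign --reads sim/reads.tsv --locus sim/locus.bed \
    --snps sim/snps.tsv --out sim/assigned.tsv

# call monoallelic features from two replicates
allelochoice call --replicates rep1.tsv --replicates rep2.tsv --out calls.tsv

# analytic model predictions
allelochoice model predict --p-b6 0.43 --p-cast 0.25

# or run the whole pipeline from a YAML config
allelochoice run --config config.yaml --outdir run/
```

## Worked example (Python)

```python
from allelochoice import (
    ActivationModelParams, CountNoiseParams, make_locus, simulate_clone,
    simulate_counts, call_with_replicates, split_by_sample,
    categories_from_calls, estimate_params, goodness_of_fit,
    expected_active_fraction,
)

params = ActivationModelParams(p_b6=0.43, p_cast=0.25, n_potential=60, n_total=96)
expected_active_fraction(params)   # 0.3578125  -> ~35.8% of segments active

locus = make_locus(96, 60, seed=42)
clone = simulate_clone(locus, params, seed=43, clone_id="cloneA")
counts = simulate_counts(clone, CountNoiseParams(), seed=44)

calls = call_with_replicates(split_by_sample(counts))
calls["category"].value_counts()
# insufficient    63   (silent segments: too little depth to test)
# mono_b6         19
# mono_cast       10
# biallelic        4

cats = categories_from_calls(calls, n_potential=60)
# CategoryCounts(silent=27, mono_b6=19, mono_cast=10, biallelic=4)

est = estimate_params(cats, n_potential=60)
(est.params.p_b6, est.params.p_cast)        # (0.3833, 0.2333)

gof = goodness_of_fit(cats, est.params, n_fitted=2)
(gof.statistic, gof.p_value)                # (0.736, 0.391) -> model fits
```

## Repository layout

```
src/allelochoice/     library modules
tests/                pytest suite (unit, property-based and acceptance tests)
scripts/acceptance.py headline-number reproduction script
docs/methods.md       statistical methods note
```
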