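# Methods

This note documents the statistical model, algorithms and numerical choices
implemented in `allelochoice`.

## 1. Activation model

Setting: a locus of `n_total` Vκ segments of which `n_potential` are
functional ("potential"). In an F1 hybrid clone each potential segment carries
a B6 and a Cast allele. The model assumes each allele is activated
independently with allele-specific probabilities `p_b6` and `p_cast`,
identically across segments and clones. Non-potential segments are always
silent on both alleles.

Per potential segment the category probabilities are

| category   | probability                 |
|------------|-----------------------------|
| silent     | (1 − p_b6)(1 − p_cast)      |
| mono_b6    | p_b6 (1 − p_cast)           |
| mono_cast  | (1 − p_b6) p_cast           |
| biallelic  | p_b6 · p_cast               |

and the expected fraction of *all* segments active in a clone is

```
E[active] = (1 − (1 − p_b6)(1 − p_cast)) · n_potential / n_total
```

At the study parameters (p_b6 = 0.43, p_cast = 0.25, 60/96 functional) this is
0.3578125, i.e. ≈ 35.8% of segments active per clone, inside the observed
30–40% band. `scripts/acceptance.py` reports this number (as a percentage) and
aborts unless a ≥10⁶-clone Monte-Carlo simulation of the same Bernoulli
process agrees to within 0.5 percentage points.

### Estimation

With `n_potential` known, the MLE is closed-form:
`p̂_b6 = (mono_b6 + biallelic) / n_potential` (and symmetrically for Cast),
because per-allele activations are independent Bernoulli observations.

With `n_potential` unknown, the estimator profiles an integer grid
`k ∈ [mono_b6 + mono_cast + biallelic, n_total]`: for each k it forms plug-in
estimates `p̂(k)` and evaluates the multinomial log-likelihood of the observed
four-category tally with `silent = k − observed actives` (non-potential
segments are indistinguishable from silent ones, but k is identifiable
because the biallelic/monoallelic split constrains the product p_b6·p_cast
while the margins constrain the sums). The reported `n_potential` maximises
this profile likelihood.

### Goodness of fit

`goodness_of_fit` compares an observed category tally to model-expected
counts. For large samples it uses Pearson's chi-square with
`df = 3 − n_fitted`. When any expected cell count is < 5 it falls back to an
exact multinomial test (total probability of all compositions with
probability ≤ the observed one, enumerated vectorised with `gammaln` log-pmfs
for totals ≤ 200) or a Monte-Carlo version of the same test above that size.
Calibration is verified in the test suite by a Kolmogorov–Smirnov test for
uniformity of p-values under the model.

## 2. Synthetic data generation

- **Locus**: segments of 400–600 bp placed on one chromosome with
  inter-segment gaps > 21 kb so that assignment windows (500 bp upstream /
  10 kb downstream, strand-aware) never overlap for any strand combination;
  `n_potential` functional segments are chosen uniformly at random.
- **Clone**: independent per-allele Bernoulli draws over potential segments.
- **Counts**: per replicate, allele-resolved counts are Gamma–Poisson
  (negative-binomial) with mean `mu_active` (default 100) for active alleles
  and `mu_leak` (default 1% of that) for silent ones, dispersion 0.1
  (`r = 1/dispersion`). An optional per-segment multiplicative bias scales the
  Cast mean to mimic fixed genetic (sequence-driven) allele preferences.
- **SNPs and reads**: SNPs are scattered across each segment's assignment
  window; simulated read pairs are placed uniformly inside the window with
  parental bases at covered SNP positions.
- **Pools**: sums of independent clone draws; a pool of one clone is
  bit-identical to the corresponding single-clone simulation.
- **Repertoire**: rearrangement events are multinomial over active alleles
  with weights `coupling · (allele-masked ncRNA share) + (1 − coupling) ·
  uniform`; induction kinetics are modelled by giving the early allele a
  `1 − time_fraction/2` share of events.

All generators take `numpy.random.SeedSequence`-compatible seeds and spawn
child streams, so every artefact is reproducible bit-for-bit.

## 3. Allele assignment

A read pair is assigned to a feature only if it is fully contained in the
feature's strand-matched window. Base calls at covered SNP positions tag it
B6, Cast, `unassigned` (no informative SNP) or `conflict` (discordant SNPs);
only cleanly tagged pairs contribute to counts. The tallies satisfy the
conservation identity `assigned + unassigned + ambiguous + conflict = reads`.

## 4. Monoallelic calling

Per feature with depth ≥ 20 reads, a two-sided exact binomial test of
B6 vs Cast counts against 0.5 (tail doubled including the point mass, capped
at 1; identical to `scipy.stats.binomtest` under the symmetric null, verified
against rational-arithmetic enumeration to 1e-12 for all totals ≤ 30).
P-values are Benjamini–Hochberg adjusted across the tested family; a
monoallelic call additionally requires a ≥ 2-fold count difference. With
replicates, a feature is called monoallelic only if **every** replicate
independently passes significance and fold; pooled counts are reported.
Empirical type-I error under a balanced null is ≤ the nominal 5% FDR
(verified in the acceptance suite).

## 5. Clonal profiles

Allelic-ratio matrices (b6/(b6+cast), depth ≥ 10 for visualisation) feed PCA
(column-centred SVD, component signs fixed by making the largest-magnitude
loading positive) and average-linkage hierarchical clustering on Euclidean
distances, exported as Newick.

**Missing-data policy.** The default `na_policy="complete"` keeps only
features observed in every sample. For clonal-stability analyses with few
samples this discards most clone-discriminating features — a segment active
in all 8 samples of a 4-clone × 2-replicate design has probability ≈ 0.11, so
complete-case retains mostly uninformative shared features. The
`na_policy="mean"` option imputes a feature's missing ratios with its observed
mean, which is neutral after centring and preserves discriminating features;
it is the recommended (and tested) policy for replicate-stability and
clade-purity analyses. With it, PCA nearest-neighbour replicate identity and
4-clade purity hold in ≥ 95% of seeded runs (observed 100/100).

## 6. Repertoire coupling

The ncRNA–rearrangement correlation is the Pearson r between ncRNA allelic
ratios and rearrangement allelic ratios over segments meeting depth in both
assays (≥ 3 shared points required). Under a generative coupling of 0.9 with
realistic per-segment genetic bias, r exceeds 0.5 (around the reported
r ≈ 0.6) and the mean r increases monotonically with the generative coupling.
`skew_fraction` reports the fraction of segments with pooled ratios beyond a
0.8/0.2 skew threshold; unbiased many-clone pools show essentially none.

## 7. Numerical and engineering choices

- Exact binomial p-values use `scipy.stats.binom.cdf` tail doubling rather
  than summing pmfs, avoiding O(n) accumulation error at high depth.
- BH adjustment delegates to `statsmodels.stats.multitest.multipletests`.
- The exact multinomial GoF enumerates composition grids vectorised in numpy;
  log-pmfs use `scipy.special.gammaln`.
- The pipeline writes a `manifest.json` with SHA-256 hashes of every output;
  reruns with the same config are bit-identical (including the heatmap PNG).
- All file formats are plain TSV/BED/JSON with validating readers that report
  file and line on error; pipeline stages abort with a stage-tagged
  `PipelineError` on corrupt inputs.

## 8. Problem sizes and limitations

The implementation targets study-scale data: ~100 segments, ≤ a few hundred
clones per pool, ~10⁵–10⁶ reads or rearrangement events, and count depths of
order 10²–10³ per feature. Known simplifications: activation probabilities
are shared across segments (per-segment bias enters only through count
means), alleles and segments are independent (no chromosomal domain
structure), replicates share the clone state exactly, and read simulation
ignores sequencing error in SNP base calls.
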