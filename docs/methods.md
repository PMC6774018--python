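# Methods

`coreacc` analyses community functional-gene tables from shotgun
metagenomes of a blocked two-factor field experiment (nitrogen addition N as
the whole-plot factor, water addition W as the subplot factor, b blocks,
one sample per block × N × W cell). This note documents the models, the
numerical choices, and what the synthetic-data studies do and do not show.

## Presence calls and the core/accessory partition

A gene family g is *present* in sample s when

    counts[g, s] / total[s] >= threshold   and   counts[g, s] > 0,

with `total[s]` the full per-sample annotation total and a default
threshold of 5 × 10⁻⁷ — about one confident hit at the >2 × 10⁶
annotations per sample typical of deep soil shotgun data. The comparison is
inclusive, so the one-read-at-depth boundary counts as present. The filter
is applied per sample (a gene can be present in one sample and
filtered-absent in another) because richness is a per-sample quantity; a
`global` scope is available that keeps a gene everywhere once it clears the
threshold somewhere. The same operation with threshold 1/892 serves 16S OTU
tables rarefied to an 892-fragment minimum.

*Core* genes are present in every sample of the set, *accessory* genes in
at least one but not all, *absent* genes in none (post-filter). Component
relative abundances are always computed against the unfiltered per-sample
total, so sub-threshold tail mass stays in the denominator; with the
defaults the core carries ≈99.8% of annotation mass and the accessory
component ≈0.2% while dominating richness variation. The partition is
computed after filtering; the order is exposed through the threshold
argument (threshold 0 partitions the raw table).

## Diversity

* Richness: column sums of the presence matrix.
* Abundance β-diversity: Bray-Curtis, d(i,j) = 1 − 2Σ min(pᵢ,pⱼ)/(Σpᵢ+Σpⱼ),
  on relative abundances over full totals, optionally restricted to a gene
  subset (e.g. the core set). Core profiles are *not* renormalized within
  the subset by default — at ≈99.8% core mass the difference is in the
  fourth decimal, but the choice is explicit (`renormalize=True` rescales).
* Presence β-diversity: Bray-Curtis on 0/1 vectors, identically the
  Sørensen dissimilarity 1 − 2a/(2a+b+c). A sample with no presences in
  the requested subset gets dissimilarity 1 to every other sample and a
  logged flag rather than NaN.
* PCoA: classical scaling of −½·centered(D²). Negative eigenvalues (usual
  for Bray-Curtis) are dropped from both coordinates and the
  explained-fraction denominator, with their magnitude logged; the Lingoes
  constant correction is available (`correction='lingoes'`). Explained
  fractions are non-increasing by construction.
* Average genome size (AGS): the cell-abundance-weighted mean genome length
  Σₜ pₜₛ·gₜ. Weighting is by taxon (cell) relative abundance — the scale at
  which the synthetic ground truth is defined — not by base-pair share;
  read-level genome-size estimation is out of scope.

## Raup-Crick null model and SES

For each treatment group the model asks whether members are more similar in
gene content than random assembly predicts. Randomized assemblages conserve
each sample's observed richness exactly and draw genes without replacement
from the rows of the supplied matrix, with inclusion probability
proportional to occupancy (default) or uniform. Draws use exponential sort
keys (Efraimidis–Spirakis), which vectorizes over randomizations and
samples. Similarity is 1 − Sørensen by default; an abundance variant
reassigns each sample's positive counts to its randomized gene set and
scores 1 − Bray-Curtis.

SES = (observed mean within-group similarity − null mean)/null SD; the
p-value is the two-sided rank statistic 2·min(r₊+1, r₋+1)/(n+1), which can
never reach zero. Per-sample SES values (a sample's mean similarity to its
group mates, standardized the same way) feed the between-treatment
split-plot ANOVA; per-pair SES values are returned for inspection but are
not used inferentially because pairs sharing a sample are not independent.

Two properties of the estimator worth knowing, both demonstrated by the
package's own simulations:

1. **Occupancy weighting carries a negative SES bias.** The weights are
   occupancies estimated from the same 16 samples being tested; their
   sampling noise (a gene at true rate q is seen in Binomial(16, q)
   samples) makes null assemblages share high-occupancy genes more often
   than the data-generating process does, biasing SES negative even for
   exchangeable-gene data. The uniform null is exactly the conditional
   randomization when genes are exchangeable, and it is what the
   calibration study uses. Occupancy weighting remains the default for
   data analysis because field data have genuinely heterogeneous gene
   prevalence, but its SES values should be read as conservative for
   filtering (shifted toward divergence).
2. **The observed pool truncates the regional pool.** The null draws from
   genes observed at least once; when a material fraction of the latent
   pool goes undetected, null similarity exceeds observed similarity by
   roughly the detected-pool fraction. Calibration statements therefore
   use conditions where the observed pool covers the latent pool.

## Inferential statistics

**Split-plot ANOVA.** Exact balanced-design decomposition for b blocks ×
2 × 2 with one observation per cell. Degrees of freedom: Block b−1, N 1,
Block×N b−1, W 1, N×W 1, Residual 2(b−1). Error strata: Block and N are
tested against Block×N (the whole-plot error — the convention implied by
tables that report both Block and Block×N terms); W and N×W against the
subplot residual. p-values come from the F distribution, matching standard
practice for univariate index tables. Zero-variance strata produce NaN
(0/0) or +inf (positive SS over zero error) with a degeneracy flag rather
than an exception. Incomplete or unbalanced designs are rejected — there
is no Type-III fallback.

**PERMANOVA.** One factor at a time: SS_total = Σ_{i<j} d²ᵢⱼ/n,
SS_within summed per group, pseudo-F = (SS_between/(a−1))/(SS_within/(n−a)),
p by label permutation (999 default), optionally restricted within blocks
(`strata`). The two-factor design is analysed per factor; a joint
multi-factor partition is out of scope.

**Mantel.** Pearson correlation of upper-triangle vectors, null by
simultaneous row/column permutation of the second matrix, one-tailed
(`greater`) by default since the analyses here test positive association.

## Pooled-effect arithmetic

For a balanced 2 × 2 mean table (control, W, N, NW; equal replication) the
marginal factor effect pools the two +factor means against the two −factor
means (unweighted — identical to the marginal means under balance) and
reports percent change, absolute difference and fold change, with
fold = 1 + percent/100 exactly. Rounding for display is decimal half-up
with a 9-decimal guard digit so binary float residue cannot flip a printed
digit. The bundled field-trial table carries 13 soil/plant/microbial
indices from a 5-year grassland N × W experiment; its "soil available N"
row is the one index whose reported percent change is inconsistent with
its own printed means, so it is excluded from the reproduction checks.

## Synthetic community generator

The generator plants the mechanisms the analysis is meant to recover, at
the magnitudes of the grassland study it emulates:

* 4 blocks × {±N} × {±W} = 16 samples; 4,647 core genes carrying 99.83% of
  annotation mass (lognormal across genes, σ = 0.7); an 8,000-gene
  accessory pool at 0.17% collective mass (lognormal σ = 0.5); 4 × 10⁶
  annotations per sample drawn multinomially (column sums are exact).
* **N mechanism**: an AOB-like guild with a 2.6 Mb genome carrying only
  core genes (1,500 of them) is amplified 11.2-fold in +N samples. Its
  baseline community fraction and the background mean genome size are
  solved in closed form from the target AGS contrast
  5.93 → 5.81 × 10⁶ bases, giving f₀ ≈ 0.0037 → f₁ ≈ 0.0396.
* **W mechanism**: one treatment-shared random accessory subset is zeroed
  in every +W sample. Shared loss is what raises within-group similarity
  above the null (SES > 0, ecological filtering); independent per-sample
  loss would not. `w_filter_strength` is the target fractional drop in
  *total observed* gene richness (default 0.061): at ~4.6k core + ~1.3k
  accessory genes a 6.1% total-richness drop corresponds to removing about
  a quarter of the accessory repertoire.
* **Detection-aware calibration.** Real accessory genes sit at the
  detection threshold (0.17% of 4 × 10⁶ annotations spread over ~1.5k
  genes ≈ 2–3 expected counts each, against a ≥2-count filter), so
  observed accessory richness is substantially below latent richness. The
  generator solves the latent per-gene occupancy p₀ and the W-removal
  subset size against a Poisson detection model (Gauss–Hermite integration
  over the unit-mean lognormal block/sample jitter, σ_block = 0.10,
  σ_noise = 0.15) so that the *observed* statistics hit the targets:
  mean observed accessory count 1,317 across all samples and the 6.1%
  observed richness drop. Core genes are parameterized so their minimum
  expected coverage stays far above the filter; the planted core is
  recovered exactly in every run of the calibration study.
* All randomness flows from one seed through named `SeedSequence` child
  streams (core weights, occupancy, W subset, block, noise, counts, taxa,
  covariates), so any component can be reproduced independently and reruns
  are byte-identical.

Covariates are linear treatment responses (N raises SOM, available N and
ammonia-oxidation potential and lowers pH; W raises moisture and
respiration) with Gaussian noise at 5% of baseline; with zero noise the
pooled-effect arithmetic recovers the configured shifts exactly.

What the generator does **not** emulate: taxon-specific gene linkage (gene
mass mixes only a background community and the AOB guild), horizontal gene
transfer, compositional count correlation beyond the multinomial,
relic-DNA, read-level sequencing error, or any calibrated coupling between
functional and taxonomic β-diversity — the Mantel correlation between the
two is whatever the shared block/noise structure induces (reported, not
calibrated). Passing recovery tests therefore shows the analysis machinery
is correct and well-calibrated under these mechanisms, not that real soils
satisfy them.

## Simulation-study problem sizes

Repeated-simulation studies (null-model type-I calibration over 200
neutral runs; power over 200 planted-filtering runs) use a reduced
configuration: 300 core genes, a 450-gene accessory pool targeting 150
observed accessory genes per sample, 5 × 10⁵ annotations per sample, 999
randomizations, uniform weighting. Occupancy per accessory gene is ~1/3 of
samples so the observed pool covers the latent pool (see the truncation
caveat above) and per-gene detection is near-saturated, making genes
exchangeable — the regime in which the type-I error of the SES test is a
well-posed quantity. Single-run recovery checks (core partition, mass
split, richness drop, AGS) run at the full default conditions, averaged
over 20 seeds.

## Known limitations

* The null model conditions on observed richness and occupancy but not on
  both margins jointly; fixed-fixed swap algorithms are out of scope.
* PERMANOVA is single-factor (with optional block strata); no interaction
  partition.
* AGS ignores genome-size weighting of read sampling (a larger genome
  yields proportionally more reads); with the cell-level ground truth used
  here the two conventions differ only through a constant factor absorbed
  by calibration.
* The pooled-effect module reproduces arithmetic on printed means; it
  cannot reproduce the original per-plot P values, which require raw data.
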