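# Methods

## Data model

An OTU table is an integer matrix of read ("copy") counts, OTUs × samples.
Counts are stored exactly; relative abundances are derived on demand and
never stored, so every filter operates on copies. An OTU is *detected* in
a sample iff its count is ≥ 1. A replicate design maps each sample to the
specimen (individual) it subsamples; operations that reason about
triplicates require exactly three replicates per specimen and fail loudly
otherwise — a sample missing from the design is an error, never a silent
exclusion.

## Filtering semantics

The seven methods differ in scope and in the strictness of their
comparisons, which follow each criterion's wording exactly rather than
being harmonised:

- **Dataset scope** (`dataset_relative`, `dataset_max_copies`): the
  criterion is evaluated on counts pooled over all samples and removal
  deletes the OTU row everywhere, including samples where it was absent
  anyway. `dataset_relative` removes an OTU when pooled/grand < fraction
  (strict `<`, so an OTU sitting exactly at the threshold is kept);
  the implied copy threshold is fraction × grand total and therefore
  scales with study size. `dataset_max_copies` keeps an OTU iff its
  maximum per-sample count strictly exceeds the threshold (">10 copies").
- **Sample scope** (`sample_singleton`, `sample_min_copies`): cells are
  zeroed independently per sample ("<10 copies" zeroes counts 1–9); rows
  that become all-zero are dropped. Zeroing cells rather than deleting
  rows keeps the dataset-scope semantics genuinely distinct. A "≤ 10"
  reading is expressible as `min_copies=11`.
- **Triplicate scope** (`triplicate_max_copies`,
  `triplicate_intersection`): decided independently per specimen across
  its three replicates. The max-copies criterion is non-strict ("≥10"),
  and a passing OTU keeps all three replicate counts, zeros included.

All methods satisfy per-sample read conservation (pre = post + removed)
and are idempotent; both properties are enforced by the test suite on
randomised tables.

## Reliability and CV

For each specimen, the unit set is the union of OTUs detected in at
least one of its three replicates; each unit is classified by the number
of replicates in which it is detected (3/2/1) and the classes are
reported as percentages of the unit set. Aggregates are means with
standard errors (sample sd / √n) across specimens; reads-removed
percentages aggregate across samples instead. A specimen whose union is
empty contributes nothing and is flagged. Because the intersection
filter leaves, within each specimen, only OTUs detected in all three
replicates, reliability after it is exactly 100/0/0 on any input with
complete triplicates — a structural identity, not a tuning outcome.

The CV of a (specimen, OTU) unit is sd/mean over the three replicate
counts, with absences counted as zeros. The sample standard deviation
(ddof = 1) is the default, giving √3 for a single-replicate detection
such as (10, 0, 0); the population form (ddof = 0, giving √2) is exposed
because aggregate CVs near 1.4 for sporadic OTUs are consistent with it.

Units are stratified two ways. For CV, copy-count bins (>1000,
100–1000, 10–100, 1–10) are assigned by the unit's mean copies, except
that units detected in at most two replicates with every count below 10
form a separate *sporadic* bin; binning by mean copies is the resolution
chosen for counts that differ between replicates. For detection
reliability, relative-abundance bins (>1%, 0.1–1%, 0.01–0.1%, <0.01%)
are assigned by the unit's mean within-sample relative abundance. All
bins are lower-edge inclusive and upper-edge exclusive (a value exactly
at 1% falls in the >1% bin); empty bins are omitted rather than reported
as zero.

## Diversity

Alpha metrics are computed on raw counts without rarefaction: observed
richness; Chao1 in the bias-corrected form S_obs + f₁(f₁−1)/(2(f₂+1)),
defined even without doubletons (the classic f₁²/(2f₂) form is available
behind a flag); Shannon entropy in natural-log units (base
configurable); inverse Simpson 1/Σpᵢ². After any filter that removes all
sub-2-copy cells, f₁ = 0 in every sample and Chao1 collapses to observed
richness exactly.

Bray–Curtis dissimilarity is Σᵢ|xᵢⱼ−xᵢₖ| / Σᵢ(xᵢⱼ+xᵢₖ), by default on
raw counts with a `relative=True` option. PCoA double-centers −½D²,
eigendecomposes, and scales eigenvectors by the square roots of the
positive eigenvalues; negative eigenvalues (Bray–Curtis is non-metric)
are reported unmodified so distortion can be assessed — no Cailliez or
Lingoes correction.

PERMANOVA partitions squared dissimilarities: SS_total = (1/n)Σ_{i<j}d²,
SS_within summed per group with 1/n_g scaling, R² = SS_between/SS_total,
pseudo-F = (SS_between/(a−1))/(SS_within/(n−a)). The p-value permutes
group labels without restriction, seeded, with the +1 correction
p = (1+#{F* ≥ F})/(1+B); ties are counted with a 1e-12 slack so that
exactly-equal permuted statistics (including infinite F in perfectly
separated designs) register as exceedances. Passing
`n_permutations="exact"` enumerates all distinct relabellings and
reports the unconditional fraction with F* ≥ F. The type-I error of the
sampled test is verified by simulation in the test suite.

In the method-comparison grid, Bray–Curtis is computed on relative
abundances (`relative_beta=True`). Sequencing depth spans a three-fold
range in this design, and on raw counts two replicates of identical
composition at 30k and 60k reads already differ by BC ≈ 0.33, so
raw-count beta-diversity would measure depth, not composition, and bury
the individual signal the grid is meant to expose. The standalone
`bray_curtis` keeps raw counts as its default.

## Statistical comparisons

Per-sample alpha-diversity vectors for each filter are compared against
the unfiltered baseline with a two-sided t-test (Welch by default;
pooled variance optional) followed by the Mann–Whitney U test
(tie-corrected normal approximation). Both p-values are reported; the
two-level significance markers (* p<0.05, ** p<0.001) follow the t-test.
The comparison is unpaired by default to match the named tests, although
the samples are identical across filters; a `paired=True` mode (paired t
and Wilcoxon signed-rank) is provided for the matched design.

## Synthetic data

The generator emulates a triplicate human-stool amplicon study well
enough that every pipeline stage, and the qualitative ordering of the
filtering methods, is exercised with known ground truth:

1. **Core community.** 300 OTUs receive lognormal(0, σ=2.3) abundances,
   phylum labels allocated by largest remainder to a fixed mixture
   (Firmicutes 72.6%, Bacteroidetes 18.6%, Verrucomicrobia 5.2%,
   Actinobacteria 2.7%, Proteobacteria 0.6%, other 0.3%), and
   within-phylum masses rescaled so each phylum's total share equals its
   mixture weight.
2. **Individuals.** Each of 12 specimens draws its true profile from a
   Dirichlet centred on the core profile with concentration
   `individuality` × core (default 600) — strong between-individual
   divergence with shared dominant taxa.
3. **Replicates.** Depth is hierarchical: a specimen-level mean ~
   N(40572, √(10883² − 2000²)) and per-replicate depths ~ N(specimen
   mean, 2000), clamped to [24776, 74720]. Replicates of one specimen
   are prepped and pooled together, so most of the depth spread lies
   between specimens; with fully independent depths, the raw-copy CV of
   every abundant OTU would equal the depth CV (~0.27) as a single
   common-mode term and the CV-vs-abundance gradient would be
   unidentifiable. Before multinomial sampling, the specimen profile is
   perturbed by iid lognormal noise (sd 0.05 per OTU, renormalised),
   modelling subsampling/pipetting/PCR variability between aliquots;
   pure multinomial resampling would make abundant OTUs implausibly
   exact across replicates and copy-number-based triplicate filters
   artificially perfect.
4. **Spurious OTUs.** Each replicate receives Poisson(rate 40)
   distinct artifact OTUs drawn from a pool of 3000, so recurrence of
   the same artifact across a triplicate is rare. Copy numbers are
   geometric with mean 1.5, except a 2% high-copy component (10 +
   geometric, chimera/contamination-like); that component is why a small
   fraction of replicate-unique OTUs survives even the ≥10-copies-in-a-
   triplicate filter, as replicate studies observe.
5. Identical seed ⇒ bit-identical output; the spurious OTU ids injected
   into each sample and the true specimen profiles are returned as
   ground truth.

Defaults were calibrated once against the descriptive structure of a
12-individual triplicate study — ~190–230 detected OTUs per sample,
~75% of reads in OTUs above 1% relative abundance, 40–47% of
union-detected OTUs appearing in a single replicate, Firmicutes ≈ 72.6%,
and a specimen-level PERMANOVA R² ≈ 0.97 that survives every filtering
method — and frozen.

What the generator does *not* model: sequence-level error (reads,
chimeras as sequences), primer and extraction bias, compositional
correlations between taxa, overdispersed (non-Poisson) artifact counts,
or batch effects between specimens. Passing tests therefore demonstrate
correctness of the statistics and the robustness of the method ordering
under a plausible artifact model, not agreement with any particular
sequencing run's headline numbers.

## Numerical conventions and degenerate inputs

- Percentages per specimen sum to 100 exactly (integer-ratio floats);
  aggregate SEs use ddof=1 and are 0 for n=1.
- CV is undefined (error) for an OTU absent from all three replicates;
  Shannon/inverse Simpson require a positive sample total; Bray–Curtis
  rejects a pair of all-zero samples; PERMANOVA requires at least two
  groups and a residual degree of freedom.
- Mean-reads-per-sample displays truncate toward zero; full precision is
  retained internally.
- File parsing rejects, with the offending row/column named: duplicated
  sample or OTU ids, ragged rows, non-integer or negative counts, and
  malformed `.shared` headers. Parse→serialise round trips are lossless
  for both supported table formats.

## Problem sizes in the test suite

The default synthetic configuration (36 samples, ~2,000 table rows) runs
each pipeline stage in well under a second, so the ordering checks use
20 independent seeds and the PERMANOVA type-I calibration uses 500 null
simulations of 12 exchangeable samples at 199 permutations each; the
whole suite completes in under a minute on one core.
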