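# Methods

## Data model and identification rules

The atomic observation is the peptide-spectrum match (PSM): one tandem
mass spectrum assigned to a peptide at a percent ¹³C atom enrichment on a
0–100% grid in 1% steps, the resolution at which isotope-aware database
searches score candidate enrichments. A PSM is **labeled** when its
enrichment is at or above a threshold τ, by default 2% inclusive — the
smallest grid value clearly above the 1.109% natural ¹³C abundance.
Both the threshold and the natural-abundance constant are recorded in
output metadata and configurable.

Protein identifications follow the two-peptide rule: a protein is
reported only with at least one peptide unique to it plus at least one
additional peptide (unique or shared). PSMs whose entire candidate
protein group fails the rule are flagged *orphaned*: they are excluded
from protein-level outputs but retained in sample-level spectral metrics,
which are defined over all PSMs of a sample rather than only those in
identified proteins. A PSM inherits the taxonomy of its identified
protein group; if the group is taxonomically mixed, the PSM's taxonomy
is set to missing, it is excluded from taxon-level tests, and the
conflict is counted in the sample metadata.

**Balanced spectral counting.** Each PSM carries one unit of count. A
unique-peptide PSM gives its unit to its one protein; a shared-peptide
PSM splits it over the identified candidates proportionally to each
candidate's unique-peptide PSM count, or equally if all candidates have
none. The name denotes exactly this allocation; conservation holds by
construction (protein totals plus the unassigned bucket equal the PSM
count), and relative abundances are balanced counts over the sample's
assigned total. PSM-level weights stay 1 regardless of the split, so
sample-level metrics are per-spectrum proportions.

## Labeling metrics

For enrichments *eᵢ* with weights *wᵢ* and threshold τ:

- label frequency (%) = 100 · Σ{wᵢ : eᵢ ≥ τ} / Σ wᵢ
- average enrichment (%) = Σ{wᵢeᵢ : eᵢ ≥ τ} / Σ{wᵢ : eᵢ ≥ τ},
  undefined (returned as an explicit missing value, never zero) when no
  PSM is labeled.

Both are computed for any subset: a sample, a taxon within a sample, or a
COG category within a taxon. Replicate aggregation reports the arithmetic
mean and the sample (n−1) standard deviation.

The labeled-enrichment histogram uses half-open 3%-wide bins [4,7), …,
[97,100). Its denominator is the *total* labeled weight, so mass in
[2,4) — barely-labeled spectra — counts toward the denominator but falls
in no bin, and bin proportions sum to ≤ 1. The bin convention is written
into every output header. Enrichment exactly 100 likewise falls outside
the half-open last bin; in practice the search grid's 100% draws are
clipped into [97,100) only if they arrive below 100.

## Permutation test

The null hypothesis for a group is exchangeability: that its PSMs are a
random subset of their background pool — the whole sample for taxon
tests, the taxon's own PSMs for COG-within-taxon tests, so the COG null
states that ¹³C enrichment within a taxon is independent of functional
category. For each group the engine draws `n_perm` (default 1,000) random
subsets of the pool, uniformly without replacement, stopping each draw
when the cumulative weight first reaches the group's observed weight;
with unit weights this is exact size matching. Both metrics are computed
on every draw, so the frequency and enrichment nulls share subsets and a
single seed reproduces both bit for bit.

Significance is two-sided at α = 0.05 by the empirical inner-95% rule:
the observed value is called *high* (*low*) when it is at or beyond the
97.5th (2.5th) percentile of the null, percentiles by linear
interpolation, comparisons inclusive so that values as extreme as the
critical values reject. Z-scores, (observed − null mean)/null SD, are
reported for visualization and ranking, not as the test. Draws on which
average enrichment is undefined (no labeled PSM selected) are excluded
from that null's moments and percentiles and their count is reported.
Empirical two-sided p-values with the +1 correction are included, and a
Benjamini–Hochberg helper is available but off by default — the primary
report makes per-group calls without multiplicity correction.

Groups lighter than `min_weight` (default 13 PSM-equivalents) are
skipped: labeled spectra are reliably observable only for groups beyond
roughly a dozen protein identifications, and empirical percentiles of
very light groups are dominated by discreteness. A group spanning the
entire pool has no null and raises a degenerate-null error.

Seeds for each (sample, grouping, group) batch derive from the master
seed by SHA-256 hashing of the context, so adding or removing one group
never shifts another group's draws, and all results are reproducible from
the master seed alone.

**Calibration.** Because the null values are discrete (counts over a
fixed subset size) and comparisons are inclusive, the realized type-I
error of the rule sits slightly above the nominal 5% — seeded
exchangeable-label experiments (pool 3,000, group 300, labeling
probability 0.25, 1,000 permutations, 250 replicates) put it near 5–7%.
Power against a taxon with 3× elevated labeling probability at group
weight 500 in a pool of 2,000 is essentially 100%. The Monte-Carlo null
mean agrees with exhaustive subset enumeration on small pools to within
Monte-Carlo error; enumeration is used only as a test oracle, never in
the analysis path.

Weighted nulls ("equivalent balanced spectral counts") are supported via
the cumulative-weight stopping rule; the default is unit weights
("equivalent numbers of spectra"), and the two coincide for unit-weight
data.

## Cohort statistics

Time-point contrasts use Student's two-sample t-test with pooled
variance, two-tailed by default; with triplicate label frequencies this
is the test whose p-value rounds to 0.01 for the bundled 15 h vs 32 h
comparison (Welch's unequal-variance form does not, which is why pooled
is the default). Replicate agreement of protein relative-abundance
profiles uses Lin's concordance correlation coefficient in its original
population-moment form, ρc = 2·cov(x,y)/(var x + var y + (x̄ − ȳ)²),
computed over the union of protein identifiers with absent proteins at
zero; |ρc| ≤ |Pearson r| always, with equality only at matched means and
variances. Community growth is summarized as fold change and percent
increase between successive direct cell counts; the Pearson correlation
between labeling change and count change is provided as a generic
operation, with the pairing left to the caller.

## Synthetic data

The generator emulates isotope-aware search output for a mixed
bacterioplankton community. Each PSM draws a taxon from the configured
community proportions, a protein uniformly within the taxon, a labeled
flag Bernoulli(p_label), and an enrichment:

- unlabeled: natural abundance 1.109% plus ±0.5% uniform jitter,
  truncated below the threshold. Any sub-threshold distribution is
  observationally equivalent for the metrics; this one stays near the
  physically meaningful constant.
- labeled: a mixture of normals (weight, mode, SD per component), clipped
  to [τ, 100] and snapped to the 1% grid.

Peptides are random 10-mers, unique by construction: three unique
peptides per protein plus one peptide shared with a neighboring protein
of the same taxon, used with the configured shared-peptide fraction
(default 0.2). COG letters are assigned per protein from a per-taxon
distribution and held fixed across samples, so labeling is independent of
COG by construction (the COG-test null is true unless a configuration
says otherwise). Protein identifiers are deterministic, giving
cross-sample concordance something real to measure.

The default experiment is triplicates at 15 h and 32 h from one location
(MB1a–c, MB2a–c) plus one sample per time point from a second (OR1,
OR2), 20,000 PSMs per sample. The early community's labeled-enrichment
mixture is (0.62 @ 3% SD 1.5, 0.38 @ 35% SD 8): the large barely-labeled
component is required for average enrichments near 15% to coexist with a
histogram mode at 35%, since a pure 35% mode would put average enrichment
near 35%. The 32-h and second-location samples switch to (0.33 @ 3%,
0.28 @ 17% SD 3, 0.39 @ 60% SD 10) — bimodal with average enrichment
near 28% — and scale per-taxon labeling probabilities by 1.95 (32 h),
3.8 and 4.26 (second location, 15 h and 32 h). The nine-taxon community
and its per-taxon labeling probabilities give pooled label frequencies
near 2.5% (15 h), 4.8% (32 h), and 9–11% (second location). Ground truth
(per-sample per-taxon p_label, mixture, realized counts) is written
beside every dataset.

What the generator does not emulate: FDR-driven PSM filtering artifacts,
enrichment-estimation error correlated with peptide length or intensity,
protein-abundance skew (proteins are uniform within a taxon), taxonomic
misannotation, or chimeric spectra. Passing tests therefore demonstrate
the statistics behave as designed under the stated model, not that real
search output satisfies that model.

## Numerical and design choices

- Empirical percentiles: NumPy's linear-interpolation definition, stated
  in output headers.
- Undefined metrics are explicit signals (exceptions or missing values),
  never silently zero.
- Zero-variance t-tests: t = 0, p = 1 at equal means; infinite t, p = 0
  otherwise.
- All TSV output uses `%.10g` floats and a header comment with version,
  resolved-configuration hash, and master seed; identical inputs and seed
  reproduce files byte for byte.
- Problem sizes in the calibration suite (pools of 2,000–3,000, groups of
  300–500, 100–250 replicates) were chosen to represent one sample's
  taxa while keeping the full suite runnable in minutes on a single CPU.
- The pipeline tests COG categories within the two heaviest orders per
  sample by default (`n_cog_taxa`), mirroring the practice of examining
  dominant taxa.

## Known limitations

- The two-peptide rule is applied per sample from the PSM evidence
  actually observed, not from a global protein database; proteins shared
  across samples can be identified in one sample and not another.
- Balanced-count allocation uses unique-peptide PSM counts as weights;
  other allocation schemes (e.g. iterative redistribution) exist and give
  slightly different shared-peptide splits.
- The inner-95% call inherits the granularity of 1,000 permutations;
  p-values below ~0.002 are not resolvable, and `n_perm` below 2/α
  triggers a warning because the critical values degenerate.
- Taxon tests treat taxa as fixed labels; no phylogenetic shrinkage or
  hierarchy across order/genus levels is attempted.
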