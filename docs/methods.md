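# Methods

## Scoring model

The package treats a metabolic reconstruction as a fixed annotation
resource: a set of strain-level metabolic models, each a binary vector
over a shared reaction universe, with reactions optionally annotated to
subsystems and exchange reactions optionally grouped into
compound-exchange (CE) families. The scoring pipeline is linear algebra
over three matrices built from the inputs:

- **X** (taxon × sample): ASV/OTU counts are collapsed to the chosen
  rank, divided by the per-sample total over all collapsed features, and
  restricted to taxa matching a reconstruction strain. Because
  normalization precedes the restriction, a column of X sums to the
  matched fraction of the community (≤ 1) — this is deliberate: the
  score of a reaction then reflects how much of the *observed* community
  can run it, and a poorly covered sample is visibly down-weighted
  rather than silently inflated. `renormalize_after_match=True` restores
  column sums of 1 for users who prefer coverage-independent scores.
- **R** (reaction × taxon): the fraction of the taxon's strains carrying
  the reaction (`ratio`), or an any-strain indicator (`full`). The
  `full` mode exists as an explicit contrast: it dominates `ratio`
  elementwise and reproduces the all-or-nothing weighting used by
  mgPipe.
- **S** (subsystem × reaction): `global` rows put weight 1/|members| on
  each member reaction (rows sum to 1, so Y is a convex combination of
  member activities and never exceeds the best member). `contextualized`
  renormalizes per sample over members with W > 0 — again the mgPipe
  contrast — which rescales partially-present subsystems upward; a
  subsystem with no present member scores 0 in that sample.

W = R·X and Y = S·W are exact matrix products; both land in [0, 1] by
construction (X columns ≤ 1, R ≤ 1, S rows sum to ≤ 1). Reactions with
neither a subsystem nor a CE assignment contribute to W only and are
reported in a log line; a reaction carrying both contributes to both
subsystem rows.

## Matching and ambiguity

Strain lineages and sample taxa are compared after a light
normalization: case-folding, `g__`/`s__`-style prefix stripping, and
collapsing underscores/whitespace — the differences that separate
Silva-style lineage strings from reconstruction strain naming. The
species-level key is the binomial ("genus epithet"), never the bare
epithet, since epithets recur across genera. How reconstruction strain
names should be tokenized is genuinely underdetermined (subspecies,
"sp." suffixes, strain codes); the normalization here is a documented
package choice, and the bundle TSV schema keeps it inspectable.

"Unambiguous assignment" is operationalized as: the lineage has a
non-empty name at the chosen rank and that name contains none of the
markers `uncultured`, `metagenome`, `sp.`, `unidentified` (configurable)
— common 16S practice. Features failing this are dropped with reason
"ambiguous assignation"; no prevalence filtering or rarefaction is
applied. Zero-total samples are an error, not a silent drop.

## Statistics

Group comparison uses the two-sided Mann–Whitney U test. Exact p-values
are computed when both groups have ≤ 8 samples and the pooled data is
tie-free; otherwise the normal approximation with tie and continuity
corrections is used (the exact distribution is cheap precisely where the
approximation is worst). Rows constant across all samples —
including all-zero rows — get p = 1 by convention and are retained, so
the Benjamini–Hochberg denominator m is reproducible from the input
bundle alone. BH is applied separately to the reaction table and the
subsystem table, matching how results are reported per level. The sign
convention is ΔΨ = mean(group A) − mean(group B) with A the first label
given. Note that with 3 vs 3 samples the smallest attainable exact
two-sided p is 0.1, so no 3v3 comparison can pass α = 0.05; the
miniature example is therefore analysed at α = 0.1.

## Exploration

PCA treats samples as observations. Coordinates are mean-centered but
not variance-scaled by default: scores share the [0, 1] scale and
scaling would inflate near-constant reactions. Components follow a
deterministic sign convention (largest-magnitude loading positive).
Group separation is summarized by the mean silhouette coefficient on the
first two components (matching 2-D plots; configurable), Euclidean
distance, with singleton-group samples contributing 0. Heatmap ordering
uses average-linkage agglomerative clustering with Euclidean distances
on rows and columns independently; scipy's deterministic tie-breaking
(lowest original index) makes leaf orders reproducible. Group ellipses
are 1-SD covariance ellipses in PC1/PC2; the module emits parameters,
rendering is left to the caller.

## Synthetic data

`make_toy_example` freezes a miniature dataset whose hard constraints
are the method's worked properties: sample m1 abundances (0.7, 0.3, 0),
one reaction carried by exactly half of one taxon's strains (R entry
0.5), and a first subsystem of exactly three reactions (S row of 1/3s).
All other counts and presence entries are free choices frozen in the
fixture; the test group shifts mass to the third taxon so the second
subsystem carries a designed effect.

`make_synthetic` draws bundles and counts reproducibly from a single
seed. Strain reaction sets are Bernoulli at the given density (with
every reaction guaranteed ≥ 1 strain, since zero-strain reactions are
rejected at load); counts are Dirichlet-multinomial — compositional and
overdispersed, the minimal realistic model for 16S counts — with a
per-taxon log2 fold-change applied to designated taxa in the second
group. Defaults (30 taxa × 3 strains, 150 reactions, 15 subsystems + 2
CE families, 24 samples, density 0.25, concentration 30, depth 50 000)
emulate a desk-scale two-arm 16S study. What the generator does *not*
emulate: phylogenetic correlation between taxa, realistic bundle
structure (real reconstructions have heavy-tailed subsystem sizes and
correlated strain repertoires), sequencing noise beyond multinomial
sampling, or real CE catalogues. Passing tests therefore demonstrate
algorithmic correctness and calibration under the stated count model,
not performance on any real cohort.

Simulation sizes used by the test suite (10 datasets × ~30 reaction rows
for the null calibration check; 20 random fixtures for the product
oracles) were chosen to keep the whole suite in the seconds range while
leaving ≥ 200 null rows for a binomial check of the type-I rate.

## Numerical choices and edge cases

- Contextualized presence is the exact test W > 0 (W is built from
  exact ratios of small integers and relative frequencies); a
  configurable epsilon exists for robustness with user-supplied W.
- All matrices are dense pandas DataFrames with lexicographically
  sorted labels fixed at load; determinism everywhere is preferred over
  sparse storage at the scales involved (AGORA2-sized bundles are a few
  thousand × tens of thousands, still comfortably dense).
- TSV outputs use fixed 6-decimal formatting so reruns are
  byte-identical.
- Errors are loud and typed: missing files, parse failures, and schema
  violations are distinct classes and distinct CLI exit codes (2/3/4).

## Known limitations

- Functional inference is presence-based: scores quantify the genomic
  *capacity* of the community, not flux or expression; no
  constraint-based simulation is performed.
- Matching quality is bounded by 16S taxonomic resolution; strain-level
  heterogeneity within a species enters only through the ratio weights.
- The two-group Wilcoxon design excludes paired tests, >2-group omnibus
  tests, and covariate adjustment.
- Real reconstruction content (AGORA/AGREDA/AGORA2) is user-supplied in
  the bundle TSV schema; the package ships none of it.
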