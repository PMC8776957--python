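# Methods

This note documents the models implemented in `forestplots`, the
defaults of the synthetic survey generator, the numerical choices
made where the design was genuinely open, and what the test suite
does and does not demonstrate.

## Survey design and the synthetic generator

The sampling frame is a balanced nested design: islands × forest
types × plots × subplots.  Defaults are 3 islands ("Pico",
"SaoMiguel", "Terceira"), 3 forest types (natural forest NF, exotic
woodland EW, production forest PF), 10 plots of 100 m² per
island × type cell, and 4 subplots of 25 m² per plot — 90 plots and
360 subplots.  The generator (`forestplots.datagen`) emulates the
statistical structure such a survey exhibits, not any particular
measured dataset:

- **Species pool** (default 108 taxa).  The first entries are the
  per-type dominants: one exotic conifer for PF, one exotic broadleaf
  for EW, three endemic broadleaf trees for NF; each has affinity 1.0
  for its home type.  Remaining taxa draw a home type (NF 0.5, EW 0.3,
  PF 0.2 — natural forest hosts the largest share of the flora), a
  status (endemic 0.3 / native 0.3 / exotic 0.4) and a growth form,
  with home affinities U(0.5, 1) and off-home affinities U(0.02, 0.25)
  scaled by a per-type "openness" (NF 1.2, EW 0.7, PF 0.3) that makes
  NF stands the richest and PF stands the poorest.
- **Cover.**  Per subplot and taxon, occupancy is Bernoulli with
  probability ∝ baseline × affinity^type_effect × island-modifier^
  island_effect, and cover conditional on presence is log-normal
  (σ = 0.6 on the log scale) around a mean set by the taxon's
  geometric rank-abundance position within its home type (ratios
  NF 0.85, EW 0.60, PF 0.20: PF is near-monocultural, NF the most
  even).  Cover is continuous percent cover in [0, 100]; field
  protocols often use ordinal cover scales, but no specific scale is
  assumed here.  With `type_effect = island_effect = 0` every subplot
  draws from identical distributions, so group labels are exchangeable
  — this null mode underlies the permutation-test calibration.
- **Trees.**  Plot stem counts are Poisson with type-specific density
  means (NF 3300, EW 4400, PF 2100 ha⁻¹, giving ≈ 2900 stems over 90
  plots).  Taxa are drawn with probability ∝ (affinity × rank scale)²
  among woody taxa — canopy composition is more concentrated than
  understory cover, which drives planted stands toward monoculture.
  DBH is log-normal truncated at the 2.5 cm measurement threshold
  (medians ≈ 7 / 10 / 18 cm for NF / EW / PF); heights are normal
  (means 4.8 / 8.8 / 22 m — montane natural forest is short, planted
  conifer stands tallest).  NF trees are frequently multi-stemmed
  (Poisson extra branches, mean 0.8); branch diameters split a drawn
  total so that Σd² is preserved.
- **Litter and soil.**  Litter dry mass and carbon concentration vary
  by forest type (conifer litter accumulates: PF 900 g m⁻² at
  400 g C kg⁻¹ vs NF 400 g m⁻² at 360 g C kg⁻¹).  Soil bulk density
  and organic matter vary by island (young basaltic soils: Pico BD
  ≈ 500 kg m⁻³ vs ≈ 1000 kg m⁻³ elsewhere), reflecting the empirical
  pattern that soil carbon stocks differ mainly between islands while
  litter stocks differ mainly between forest types.  Soil sampling
  depth is U(0.05, 0.10) m, the depth window over which stocks are
  scaled.
- **Determinism.**  One root seed feeds five named sub-streams (pool,
  cover, trees, litter, soil) via `SeedSequence` spawn keys, so equal
  configurations are bit-identical and adding a component never shifts
  another's draws.

## Diversity

Shannon diversity uses the natural logarithm (nats); evenness is
Pielou's J = H/ln S, defined as 0 when S = 1 so the value always
exists.  The additive partition computes αₖ as the unweighted mean
richness of the pooled abundances of each level-k group (the balanced
design makes weighting immaterial; a size-weighted variant is
available), γ as the pooled total, and βₖ as successive differences —
the identity γ = α₁ + Σβ then holds exactly by construction, and each
β ≥ 0 because pooling can only add species.  The hierarchy is
configurable (default plot < island × type cell < forest type) because
the appropriate lowest level (subplot vs plot) depends on the survey.

## Community analysis

All community statistics operate on plot-level composition, obtained
by summing the four subplot cover vectors of each plot.

- **Hellinger distance** is the Euclidean distance between
  square-root relative-abundance rows (bounded by √2).  UPGMA is the
  size-weighted Lance–Williams update of average linkage, with ties
  broken on the smallest cluster-id pair so the schedule is
  deterministic.  Cophenetic correlation is Pearson's r between the
  original distances and the heights of each pair's lowest common
  merge; it is returned as NaN when either vector has zero variance.
- **Cluster count** is chosen by cutting the dendrogram at
  k = 2…k_max and maximising the mean silhouette width (ties go to
  the smaller k); the Mantel r between the distance vector and the
  binary same/different-cluster vector is reported as a diagnostic
  only, since no principled rule combines the two indices.
- **NMDS** minimises Kruskal stress-1 by alternating isotonic
  regression of configuration distances on the rank order of the
  input dissimilarities with a Guttman-transform update.  Starts: one
  classical-scaling (principal-coordinate) configuration plus 19
  random starts (1-D embeddings in particular are riddled with local
  minima); convergence when the stress change drops below 1e-6; ties
  in the monotone regression receive the primary (averaging)
  treatment.
- **PERMANOVA** Gower-centres the squared-distance matrix and assigns
  each factor the increment in explained trace over the preceding
  factors (sequential sums of squares, factor order forest type then
  island by default, mirroring the reporting convention).  p-values
  use free permutation of unit labels and the add-one estimator
  p = (1 + #{F* ≥ F})/(1 + n_perm), so p ≥ 1/(n_perm + 1) always.
- **IndVal** is the single-group Dufrêne–Legendre form: specificity
  A = group mean abundance over the sum of group means, fidelity
  B = within-group occupancy, IndVal = 100·A·B, statistic = each
  taxon's maximum-group IndVal, significance by label permutation.
  No multiple-testing correction is applied by default (per-species
  α = 0.05, characteristic threshold 70%); a Holm option would be a
  one-line addition but is deliberately not the default.

## Structure and carbon

A tree enters the statistics when its largest branch diameter reaches
2.5 cm; once retained, all branches count toward basal area.  This is
one reading of the "DBH above 2.5 cm" rule for multi-stemmed trees;
the alternative (per-branch filtering) would drop small side branches
of retained trees.  Basal area is reported both per plot (m²) and per
hectare, since published tables are not always explicit about the
scaling.

The allometric engine evaluates a closed set of forms (power law in
D, power law in D²H, log-linear in ln D and ln H, linear in per-tree
basal area, general linear over declared predictors) resolved per
taxon with a mandatory generic fallback; fallback use is flagged per
tree.  For multi-branch trees fed to a single-diameter form, D is the
quadratic-mean equivalent diameter √(Σdᵢ²), which preserves total
basal area.  The packaged registry contains synthetic literature-style
coefficients for the simulated dominants (marked as such in the file);
real analyses must supply their own registry.

Carbon conversion: BGB = root:shoot × AGB with the ratio shipped as
configuration (0.25 default; IPCC 2006 Guidelines Vol. 4 Table 4.4
tabulate values by climate zone), and carbon fraction 0.48
(broadleaf) / 0.51 (conifer) applied to AGB + BGB.  Source
descriptions of whether the fraction applies to total biomass or AGB
alone are sometimes contradictory; the total-biomass reading is the
default and `fraction_applies_to="agb"` exposes the alternative for
sensitivity runs.  Litter: g m⁻² × g C kg⁻¹ × 10⁻⁵ → Mg C ha⁻¹.
Soil: OM (g kg⁻¹) × 10⁻³ × 0.58 × bulk density (kg m⁻³) × measured
depth (m) × 10 → Mg C ha⁻¹, using the per-site depth rather than a
fixed profile.

## Group statistics

The two-way ANOVA uses Type-II sums of squares (equal to the
classical decomposition on balanced designs, and free of
interaction-ordering assumptions when user-supplied data are not
balanced), delegated to statsmodels.  Tukey HSD runs on the nine
island × type cells treated as nine groups for table rendering — the
comparison family behind published letter annotations — with
main-effect comparisons available separately.  Letter displays use
insert-and-absorb: starting from one set holding all groups, every
significant pair splits the sets containing both members, and subset
sets are absorbed; this guarantees that two groups share a letter iff
their comparison is non-significant (minimality of the letter count
is not guaranteed).  Normality and homoscedasticity diagnostics never
gate the computation.

## Problem sizes and runtime choices

The test suite and the acceptance script size their simulations to
the statistics they check: partition additivity uses 50 small surveys
(1–3 plots per cell); permutation calibration uses 500 null surveys
of 12 plots × 199 permutations in the tests (200 in the script);
structure-recovery checks use full 90-plot surveys over 20 seeds with
minimal permutation counts where only variance shares are needed.
These sizes give stable Monte-Carlo error for the asserted bounds.

## Limitations

The generator reproduces the *direction and rough magnitude* of the
contrasts a real gradient survey shows (diversity ordering NF > EW >
PF, forest type dominating compositional variance, carbon-pool
orderings), not any measured values: passing tests demonstrate the
correctness and calibration of the statistical machinery, and the
internal consistency of the pipeline, but say nothing about any
particular forest.  There are no spatial coordinates, no climate
simulation, no between-plot autocorrelation, and plots are treated as
independent replicates (no nested random effects).  Published cell
means from real surveys cannot be reproduced without the raw plot
data.
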