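# Methods

This note documents the statistical models implemented in `desertniche`,
the assumptions behind them, the synthetic-study generator used to validate
them, and the numerical design choices that were genuinely open.

## Study design assumed by the data model

A capture record is one animal in one trap at one check: (year, season,
plot, day 1–4, morning/afternoon check, station row/column, species,
individual PIT-tag ID). A *session* is the (year, season, plot) block of
four consecutive trapping days; the two daily checks are collapsed into
session-level presence because the abundance estimator is defined at
session granularity. Seasons are ordered spring < summer < autumn within a
year; there is no winter trapping. Station indices are 0-based internally
(7 rows × 8 columns by default); parsers accept 1-based labels via a flag.

## Minimum number known alive (MNKA)

`mnka(history, t) = a + b`: *a* = individuals caught at session *t*, *b* =
individuals caught at an earlier and a later session but not at *t*.
Properties that the test suite asserts:

- MNKA ≥ the number actually caught (b ≥ 0), and adding any capture event
  never decreases any session's MNKA.
- With perfect detection and survival 1 in the simulator, MNKA equals the
  true abundance in every session.
- Under constant true N and constant capture probability, mean MNKA is
  highest at interior sessions and lowest at the first and last sessions,
  where no bracketing information exists. MNKA is therefore treated
  throughout as a negatively biased lower bound, not as truth.

MNKA is computed per species per plot; community totals are sums. Density
defaults to a 1-ha effective trapped area (the nominal grid area) but is
configurable, since a 7×8 grid at 15 m spacing strictly spans
90 m × 105 m = 0.945 ha. The log10(n+1) transform is available as an
explicit, never implicit, preprocessing step.

## Niche metrics

Breadth is implemented with the product form Σ N_ij·lg N_ij inside the
normalised Shannon–Wiener index. (A quotient form Σ N_ij/lg N_ij sometimes
seen in print cannot be correct: it violates the index's own [0, 1] range
and the Shannon–Wiener construction it is named for.) Because the index
equals H/log r, the log base cancels; base 10 is used and a test asserts
base-invariance. Overlap is 1 minus half the L1 distance between plot-use
proportion vectors; it is symmetric and invariant to rescaling of either
vector.

N_ij is the per-plot MNKA for the (year, season). Per-year index values are
summarised across the five study years as mean ± se (sd/√n); a species
absent in a season yields NaN and is excluded from summaries with a logged
count. Summaries across years (rather than plots) are the only grouping
that yields a per-season standard error in this design.

## Habitat factor table

Three 100 m² shrub quadrats and three 1 m² herb quadrats per plot per
season are averaged per plot; soil moisture/hardness keep their four 5-cm
depth layers as separate columns; monthly meteorology joins through the
trapping month of each season (April/July/October). Shrub canopy radius is
recorded in cm and converted to metres inside the coverage formula — the
only unit reading that yields coverage as a sane ground fraction
(SR = 50 cm, Den = 4/100 m² → C = 3.14·0.25·4/100 = 3.14%). The constant
3.14 is used verbatim rather than π so results match the printed formula
bit-for-bit. Diversity indices use the standard forms these names denote:
Shannon H = −Σ p ln p, Gini–Simpson D = 1 − Σ p², Pielou E = H/ln S
(undefined when S = 1). Two Shannon indices appear among the factors; the
rodent one is labelled H.R and the shrub one H.S to keep the 31 column
names unique (7 biotic + 24 abiotic). Missing cells are flagged, never
imputed. Total coverage above 100% (overlapping canopies) is allowed with a
warning.

## Factor screening

For each species, a seeded random-forest regression of the species'
log10(MNKA+1) plot-level use on the factor table, with the species' own
population column excluded from its predictor set (it would be the response
itself). Niche breadth proper is defined across plots and has only one
value per (species, season, year), far too few rows to screen 31 factors;
the plot-level use values carry the same occupancy signal at the grain at
which the factors vary, which is why they serve as the screening response.

The high/very-high thresholds come from *shadow* factors: row-permuted
copies of every real factor appended to the design, which by construction
carry no signal. "Mean" is the mean and "MAX" the maximum of the shadow
importances; a real factor above Mean has high contribution, above MAX very
high. Each factor gets nine independently permuted shadow copies: with a
single copy, real and shadow columns are exchangeable under a null
response, so the top importance would land on a real factor half the time;
nine copies put ≈90% of that null probability on the shadow side, making
the MAX threshold usable. Importance is model-agnostic permutation
importance (reproducible, not biased toward high-cardinality or correlated
features the way impurity importance is). Screening is a filter, not a
predictor: no hyperparameter tuning is done.

Pooling for the ordination takes the union of per-species very-high sets
(falling back to a species' high set when its very-high set is empty), then
removes multicollinearity by iterative VIF filtering: VIF_j = 1/(1 − R²_j)
from the regression of factor j on the others with intercept; while any
VIF ≥ 10 the single worst factor is dropped, ties broken toward the later
column so removal is deterministic. A perfectly collinear column reports
VIF = +inf rather than raising.

## Redundancy analysis

The response block is the per-(plot, season, year) species MNKA matrix,
Hellinger-transformed (row-wise square root of proportions; rows where no
species was caught are undefined and are dropped with a logged notice
before the transform). Factors are z-scored. RDA centres the response
columns, regresses them on the factors with intercept, and
eigendecomposes the fitted and residual blocks via SVD; canonical plus
residual eigenvalues reconstruct the total variance to 1e-8, which is
asserted on every run. R² is the canonical share of total variance;
adjusted R² uses Ezekiel's formula. `proportion_explained_per_axis` is
relative to total variance; `cumulative_first_two` is the first two
canonical eigenvalues' share of the *constrained* variance. Biplot scores
use correlation (type-2) scaling of factors with the constrained site
scores.

The global permutation test permutes response rows without restriction (no
blocking) and uses pseudo-F = (SS_can/m)/(SS_res/(n−m−1)) with the add-one
p-value rule, so p is never 0 and bottoms out at 1/(n_perm+1); 999
permutations by default, seed mandatory.

Forward selection uses a double stopping rule with a global gate:

1. selection starts only if the full model's global permutation test is
   significant at α — without this gate, picking the best of many
   candidates and then testing only that one inflates the type-I error far
   above α;
2. at each step the candidate with the largest adjusted-R² gain is admitted
   if its *conditional* permutation test (a partial RDA of the candidate
   with the already-selected factors partialled out of both response and
   candidate) has p ≤ α;
3. the loop stops once the selected model's adjusted R² reaches the full
   model's adjusted R² — beyond that ceiling further gains are
   indistinguishable from overfitting.

A stricter variant vetoes the best candidate whenever the *candidate
model's* adjusted R² exceeds the full model's. That variant was evaluated
and rejected: when few factors are truly informative, the one-factor
model's adjusted R² exceeds the full model's with probability ≈ ½
regardless of effect size (the comparison reduces to whether the noise
factors' chance R² exceeds 9/(n−2)), so the rule refuses a genuinely strong
factor about half the time. The ceiling-as-continuation-check above
preserves the rule's intent (never exceed what the full model can justify)
without that pathology.

## Synthetic-study generator

The generator emulates the full design: 24 plots, 7×8 trap grid, 4-day
sessions, 3 seasons × 5 years (80,640 cage-days). Per species and year,
plot occupancy is a symmetric Dirichlet draw; its concentration α is an
interpretable evenness dial (the analytic breadth of the draw is stored as
truth). Session abundances are multinomial allocations of a fixed
per-season total. Individuals carry persistent IDs, are plot-faithful (no
dispersal), survive between sessions with configurable probability
(separately across the winter gap, so hibernators can be modelled with 0),
and are recruited to hold the plot's latent abundance at its target.
Detection is an independent Bernoulli per trap check. An optional trailing
buffer session extends the record one season past the study to exercise the
bracketing term at the final real session.

Default parameters (chosen once as ecologically plausible for a desert
rodent assemblage of this kind): per-season totals 140/90/60/40 for the
four species (ZW/SZ/MZ/WZ codes), Dirichlet α of 10/4/0.8/4 so the
qualitative breadth ordering matches a community with one spatial
specialist (MZ) and one generalist (ZW); per-check capture probability
0.25 (per-session detection ≈ 0.9); inter-session survival 0.7.

Environment tables are generated from per-plot latent "knobs" (shrub/grass
height, grass density and biomass, soil moisture/hardness by layer): a
linked knob is baseline + scale·(Σ coefficient × z-scored species density +
Gaussian noise of sd `noise_sd`), an unlinked knob is pure noise; quadrat
replicates add proportional jitter (zero when `noise_sd` is 0, so a linked
continuous factor is then an exact affine function of density). Default
linkage ties shrub height to WZ and the 5–10 cm soil moisture to SZ.

What the generator does *not* emulate: within-grid movement and
trap-position effects, behavioural responses to capture (trap-happy/shy),
inter-plot dispersal, density dependence, and any nonlinear
factor–density relationships. Passing recovery tests therefore show the
estimators are correct under these idealisations, not that field data meet
them.

## Sizes, tolerances and degenerate inputs

- Exact-algebra checks (breadth ≡ entropy/log r) at 1e-12; linear-algebra
  oracle agreement and variance conservation at 1e-8.
- Permutation-test calibration uses 1,000 null trials of 199 permutations
  at n = 20; forward-selection recovery uses 100 seeded runs at n = 60 with
  10 candidate factors. Pipeline tests run a reduced design (8 plots, 2
  years, 99 permutations, 40 trees) — the statistics are grain-invariant,
  so the smaller design exercises the identical code paths.
- Degenerate inputs: all-zero use vectors give NaN with a warning (breadth,
  overlap); all-zero community rows are a hard error in the Hellinger
  transform and are filtered upstream by the pipeline; single-species
  communities give Pielou NaN; perfectly collinear factors give infinite
  VIF; a rank-deficient RDA design raises and points to `vif_filter`.
- All floating output is written at 6 significant digits; internal
  computation is double precision throughout.

## Known limitations

- MNKA has no variance estimator here; the package deliberately reports the
  point count only (no Jolly–Seber or closed-population likelihoods, no
  spatially explicit capture-recapture).
- The screening response (plot-level use) is a design choice; a different
  aggregation of occupancy could rank factors differently.
- The RDA row granularity is (plot, season, year); coarser granularities
  (e.g. per season only) change eigenvalue shares and are not comparable
  across choices.
- The Mean/MAX screening thresholds are heuristic; the shadow-ensemble size
  (9 per factor) controls the null familywise rate near 10% but is not an
  exact test.
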