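# Methods

## The unusualness statistic

A song is a vector of categorical states, one per feature of the coding
scheme. Its unusualness within region *r*, for a song of society *s*, is

U = Σ_f ln p_{r,−s}(f, x_f),

the log-likelihood of the song under the per-feature state proportions of
the region's songs with society *s* held out entirely (leave-one-society-out,
LOSO). The statistic assumes features are scored independently — it is a
naive-Bayes-style typicality score, not a joint model of feature
co-occurrence — and it conditions on region, so it measures deviation from
*regional* convention, not global rarity. Because every song contributes
exactly F log terms (F = 37 for a complete song under the default scheme),
scores are comparable across songs.

Two readings of the scoring rule are circulated for this family of
statistics: the sum of log state probabilities (a genuine log-likelihood)
and the log of the summed probabilities. The package implements the
log-likelihood as the default: a log-of-sum is bounded by ln F, does not
scale with the number of features, and is not a likelihood. The literal
log-of-sum variant is retained behind `convention="log_of_sum"` for
sensitivity analysis only.

**Zero counts.** A state never observed in the LOSO pool has empirical
probability 0, which would send U to −∞. The default floor is
1/(support_n + 1), where support_n is the number of out-of-society songs in
the region: it keeps scores finite, shrinks to 0 as regional support grows,
and never exceeds the smallest observable nonzero frequency's order of
magnitude. The floor rule is an argument (`floor_rule`) everywhere it is
used, since whether the original analyses floored, smoothed, or simply never
hit a zero count is not documentable; results for well-sampled regions are
insensitive to the choice.

**Log base** is natural. Only orderings and linear rescalings of U matter
downstream (all regression variables are standardized).

**Societal traits** are scored by the same LOSO construction, except each
society has at most one state per trait, so the pool is the region's other
societies with a non-missing state for that trait, and the score is the
*mean* of the log-probabilities over the society's non-missing traits.
Averaging rather than summing is deliberate: trait coverage varies by
society, and a sum would conflate having many recorded traits with being
unusual. Societies with no scorable trait, and regions with one society,
get an explicit missing score rather than a silent drop.

**Degenerate inputs.** A society whose region has no out-of-society songs
cannot be scored (raised as `SupportError` in the single-context API;
skipped with a log entry in the corpus-level loop). Scoring a song against
frequencies that did not exclude its society is a programming error and
raises (`ContaminationError`).

## Filtering and data model

Songs are kept only if every scheme feature is coded (whole-song deletion).
Per-feature deletion would retain more data but make scores incomparable
across songs (different numbers of log terms); it is not implemented.
Missing-value sentinels in source CSVs default to blank and "NA",
configurable. The feature scheme is data, not code: a JSON file listing
each feature's permitted integer codes and optional 13-point display
positions. The packaged default mirrors the 37 coding lines of the
Cantometric scheme by name but its per-line state inventories are schematic
(the file is labelled synthetic); real analyses should load the scheme
shipped with their data release. The default trait→theme map (which
Ethnographic Atlas variables count as kinship vs economic) is likewise an
editable approximation shipped as YAML.

## Predictors

* **Contact** — the number of other sampled societies within a fixed
  great-circle radius (haversine, IUGG mean Earth radius 6371.0088 km),
  boundary inclusive, counted globally across the sample (a flag restricts
  to within-region counting). The default radius is 500 km, selectable by
  ELPD comparison of bivariate models at 250/500/1000 km; radii whose ELPD
  difference from the best is below 4 are reported as equivalent.
* **Cultural isolation** — patristic distance from the society's language
  tip to the nearest tip mapped to a *different* sampled society; societies
  sharing a tip get 0; unmapped societies get a logged missing value (no
  imputation).
* **Style** — for each song, the arithmetic mean unusualness of the
  society's other songs (missing for singleton societies). The LOSO
  construction of U makes this a legitimate predictor rather than a
  statistical artefact.
* All model variables are z-scored (sample sd, n−1) over complete-case
  rows; rows with any missing covariate are flagged and excluded, with the
  deletion count logged.

## Regression models

Gaussian linear models on standardized variables:

* **Model 1**: unusualness ~ neighbours + phylo_nn + kinship_u +
  economic_u, plus a society random intercept u_j ~ N(0, τ²).
* **Model 2**: the same fixed effects plus society_mean_loo, no random
  intercept.
* An intercept-only model serves as the predictive baseline, and bivariate
  neighbour-count models drive radius selection.

The aggregate (kinship+economic) trait score is available as an optional
covariate but excluded from the default models, since the two theme scores
already carry its information.

Priors are weakly informative — N(0, 2.5²) on intercept and slopes,
half-Student-t(3, 0, 2.5) on σ and τ — appropriate for standardized data
and overridable in `ModelSpec`. Posteriors are simulated by a blocked Gibbs
sampler: the half-t priors are represented as inverse-gamma scale mixtures,
making every full conditional conjugate (Gaussian for coefficients and
group intercepts, inverse-gamma for variances and their mixing parameters).
The default run is 4 chains × 4000 iterations with the first 2000 discarded
as warmup; for this conjugate sampler on standardized designs that is far
more than needed for stable summaries, and tests use shorter chains.
Convergence is monitored by R-hat and bulk ESS (arviz); any R-hat above
1.05 flags the fit non-converged (the fit is returned, flagged, never
silently accepted). A rank-deficient fixed-effects design raises
immediately rather than relying on the prior to regularize it.

Interval summaries are equal-tailed credible intervals at 89% mass by
default (HPD by flag). R² is partitioned per posterior draw as

marginal = var(Xβ) / (var(Xβ) + τ² + σ²),
conditional = (var(Xβ) + τ²) / (var(Xβ) + τ² + σ²),

with var(Xβ) the sample variance of the fixed-effect predictor over the
fitted rows, summarized by the posterior mean; without a group effect the
two coincide. Predictive comparison uses PSIS-LOO ELPD with pointwise
values, pairwise differences and difference SEs; an exact refit-every-row
LOO is provided as an oracle for small instances, and k-fold CV (seeded
shuffle, k refits, held-out log predictive density; unseen groups predicted
with the random intercept marginalized out) checks that conclusions do not
hinge on a data subset. Standard k-fold refits the model k times.

## Synthetic data

The generator is the package's test bed and defines what the tests can and
cannot show. Per region r and feature f a baseline distribution is drawn
from Dirichlet(α_r·1); per society a style deviation from Dirichlet(α_s·1);
the society's song distribution is the mixture (1−λ)·baseline + λ·deviation.
λ ∈ [0, 1] ("style strength") is the single dial for within-society
consistency; α_s (default 0.3) controls how spiky idiosyncratic styles are;
α_r (default 1.0) gives flat-ish regional baselines. Defaults: 4 regions ×
10 societies × 4–12 songs, 10 features × 5 states — big enough for stable
scores, small enough for fast tests. Traits reuse the same mixture with one
draw per society-trait. Geography places each region's societies in a
Gaussian cluster (default 300 km spread; km→degrees via the local latitude
cosine, adequate below ~1000 km) around well-separated centres. The tree is
a pure-birth (Yule) tree over one language tip per society, rescaled to unit
depth. A separate regression generator produces standardized covariates
with known slopes, group sd and residual sd for recovery and calibration
tests. Dirichlet mixtures were chosen over logit-normal styles because
expected state frequencies are available in closed form, which makes oracle
tests exact. All randomness descends from one seed through named
SeedSequence spawns.

What the generator does **not** emulate: real Cantometric feature semantics
and their correlated, ordinal structure; genre composition within
repertoires; realistic geography or region boundaries; phylogenetic signal
in musical style (tree and styles are independent); coder error. Passing
tests therefore demonstrate the statistic's arithmetic, its invariances and
the inferential machinery's calibration — not that any substantive claim
holds for real corpora.

## Problem sizes used in checks

The structural checks run on ≤50-song instances where brute-force oracles
are exact. The statistical checks use: slope recovery at n = 500; interval
calibration over 200 null replicates at n = 100 with shortened chains; R²
recovery at n = 2000 over 250 groups with planted variance ratio 1:1:2
(250 groups keeps the realized group variance within a few percent of its
target, so the planted ratio is actually identifiable); ELPD comparison at
n = 300 with a unit slope. The end-to-end check and the acceptance script
use a 5-region × 12-society world with 3–18 songs per society, 37 features
and λ = 0.7 — uneven sampling and strong-but-not-total styles, the regime
the analysis is designed for.

## Known limitations

* Feature independence: U ignores co-occurrence structure; a song unusual
  only in its *combination* of individually common states scores as typical.
* Region definitions are taken as given; scores are only as meaningful as
  the regional partition.
* The probability floor, though principled, is a modelling choice with no
  empirical counterpart; rankings deep in a poorly sampled region's tail
  depend on it.
* The Gibbs sampler covers Gaussian likelihoods with a single random
  intercept — the model family used here — not generalized or multi-level
  extensions.
* k-fold and exact LOO are Monte-Carlo estimates; agreement between them is
  to simulation error, not bitwise.
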