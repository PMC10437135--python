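# songtypicality

How unusual is a song within the musical traditions of its region?

`songtypicality` implements a leave-one-society-out (LOSO) typicality
statistic for cross-cultural song codings — tables in which each song is
rated on a few dozen categorical features of musical performance (vocal
organisation, tempo, nasality, …), each song belongs to a society, and
each society to a geographic region. It is written for comparative
musicologists and cultural-evolution researchers who want to find the
outliers in such corpora and ask *why* they are outliers: unusual social
organisation, isolation from neighbouring groups, or a society-wide
musical style.

## The statistic

For a song from society *s* in region *r*, coded in state
*x<sub>f</sub>* on each feature *f = 1…F*, its **unusualness** is the
regional log-likelihood

&nbsp;&nbsp;&nbsp;&nbsp;*U* = Σ<sub>f</sub> ln *p*<sub>r,−s</sub>(*f*, *x<sub>f</sub>*),

where *p*<sub>r,−s</sub>(*f*, ·) are the per-feature state proportions
among the region's songs **excluding every song of society *s***.
Smaller (more negative) *U* is more unusual; *U* ≤ 0 always, and *U* = 0
only when every state the song uses is universal among out-of-society
songs. Holding the focal society out means a society cannot look typical
merely because its own repertoire dominates the regional sample, and it
licenses using the mean unusualness of a society's *other* songs as a
genuine predictor of a song's own unusualness. States unobserved in the
LOSO pool are floored at 1/(*n*+1) (with *n* the pool size) so scores
stay finite.

The same construction scores categorical societal traits (kinship and
economic variables), averaged over a society's non-missing traits.

Downstream, the package builds per-song covariates — number of societies
within a great-circle radius (default 500 km), patristic distance to the
nearest sampled language on a phylogeny, trait unusualness, and the
society-mean-LOO "style" term — and fits Bayesian Gaussian regressions
(blocked Gibbs sampler; Normal(0, 2.5²) priors on standardized slopes,
half-Student-t(3, 0, 2.5) on scales), with an optional society random
intercept. It reports 89% credible intervals, marginal/conditional R²
(fixed-effects share vs fixed-plus-society share of model variance),
PSIS-LOO ELPD model comparison, radius selection, and 10-fold
cross-validation.

A fully seeded synthetic-data module generates all inputs (codings,
societies with clustered coordinates, traits, a Yule language tree) from
a Dirichlet-mixture model with a single society-style dial, so every
stage is testable with known ground truth.

## Worked example

```python
from songtypicality import SimConfig, simulate_world, all_song_unusualness, \
    society_trait_unusualness
from songtypicality.predictors import assemble_predictors
from songtypicality.inference import ModelSpec, fit_model, MODEL1_EFFECTS, MODEL2_EFFECTS
from songtypicality.report import top_percent_summary, society_rankings

world = simulate_world(SimConfig(seed=7, style_strength=0.7, society_concentration=0.2))
scores = all_song_unusualness(world["codings"], world["scheme"])
print(scores.head(3).to_string(index=False))
```
```
   unit_id society_id region_id  unusualness  n_items_scored
song_00001     R1_S01        R1   -14.670502              10
song_00002     R1_S01        R1   -17.984842              10
song_00003     R1_S01        R1   -17.081301              10
```

Each row is one song's LOSO regional log-likelihood over its 10 features
(here, the synthetic scheme). The most unusual 3% of songs concentrate
in few societies, and societies can be ranked by mean score:

```python
top = top_percent_summary(scores, 0.03)
print(f"top 3%: {top.n_songs} songs from {top.n_societies} societies")
print(society_rankings(scores, min_songs=5).head(3)[
    ["society_id", "n_songs", "mean_unusualness"]].to_string(index=False))
```
```
top 3%: 10 songs from 6 societies
society_id  n_songs  mean_unusualness
    R3_S03        8        -19.326166
    R1_S07       11        -18.655984
    R2_S06        5        -18.340527
```

Fitting the two regression models — trait/isolation covariates with a
society random intercept (model 1), then the same covariates plus the
society-mean-LOO style term in place of the intercept (model 2):

```python
kin = society_trait_unusualness(world["traits"], world["societies"], "kinship")
eco = society_trait_unusualness(world["traits"], world["societies"], "economic")
table = assemble_predictors(scores, kin, eco, world["societies"], world["tree"],
                            radius_km=500.0)
m1 = fit_model(table, ModelSpec(fixed_effects=tuple(MODEL1_EFFECTS),
                                group="society_id", seed=1))
m2 = fit_model(table, ModelSpec(fixed_effects=tuple(MODEL2_EFFECTS),
                                group=None, seed=2))
print(f"model 1: marginal R2 = {m1.marginal_r2:.3f}, conditional R2 = {m1.conditional_r2:.3f}")
print(f"model 2: marginal R2 = {m2.marginal_r2:.3f}")
```
```
model 1: marginal R2 = 0.047, conditional R2 = 0.359
model 2: marginal R2 = 0.219
```

The covariates alone explain ~5% of the variance, but knowing which
society a song comes from raises the explained share to ~36% — and the
style covariate recovers most of that gap as a fixed effect. That is the
signature of society-level musical style in this simulation (its
strength is set by `style_strength`).

The same pipeline runs from the shell: `songtypicality simulate | score |
predictors | fit | report` (see `songtypicality --help`). For real data,
point `score` at a codings CSV and the release's own feature-scheme JSON;
the packaged default scheme is a schematic stand-in.

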