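# Methods

## Scoring free-text identifications

Answers are resolved against a static taxonomy snapshot (one row per species:
binomen, genus, family, synonyms, common names, MIVS flag, regions). Matching
is case- and whitespace-insensitive and proceeds species-first: binomina,
listed synonyms and common names resolve to a species; otherwise bare genus
and family names resolve to those ranks. There is deliberately no fuzzy or
edit-distance matching — challenge participants chose from a drop-down, so
misspellings are not an expected failure mode — and no live taxonomic-backbone
reconciliation; the synonym list in the snapshot is the only source of
nomenclatural equivalence.

The ordinal score keys on the entered rank: an answer above species level can
never score 3, even for a monotypic genus, and a correct bare genus or family
scores 2 or 1 respectively. For the binary MIVS score, a genus- or
family-level answer takes the status of that higher taxon — MIVS iff it
contains at least one MIVS species in the snapshot — and skips count as
incorrect, consistent with the ordinal scale's pooling of "incorrect or
skipped".

The taxa-repeat covariate counts, per response, how many earlier photos of
the same species that participant saw; it is 0-based (the 10th photo of a
species carries the value 9) and enters the model linearly.

## The graded response model

Scores follow a cumulative-logit two-parameter model; see the README for the
equations. Design choices that were genuinely open:

- **Discrimination link.** The discrimination intercept is on the log scale,
  α = exp(δ0 + d_photo + d_species). A log link keeps α positive without
  truncation and makes the reference first-photo prediction (≈16% species
  level for a North American colubrid) come out right, which an identity link
  grossly violates.
- **Sign convention.** Higher η means higher scores; family coefficients are
  negative when a family is harder than the Boidae reference.
- **Thresholds** are enforced ordered via a first-value + log-gaps transform,
  not by rejection.
- **Identification.** The participant-ability sd is fixed at 1 in every draw,
  setting the latent scale. With many species per family and region the
  remaining location trade-off between thresholds, fixed effects and species
  deviations is well identified; with few (≲5 species per family) it mixes
  slowly and family contrasts inherit wide intervals.
- **Priors** (overridable): Normal(0, 2.5) on β and on the thresholds,
  Normal(0, 1) on δ0, half-Normal(0, 1) on the group-level sds, and an
  LKJ(2)-type weakly-regularizing prior on the two difficulty–discrimination
  correlations.

## Sampling

The posterior is sampled with an in-package adaptive HMC: non-centred group
effects, analytic gradients (verified against finite differences in the test
suite), jittered trajectory lengths (uniform 1..max_leapfrog leapfrog steps),
dual-averaging step-size adaptation targeting 0.8 acceptance, and a diagonal
mass matrix re-estimated at 50% and 90% of warmup. Divergent transitions
(|ΔH| > 1000 after warmup) and acceptance rates are recorded in the posterior
metadata. Library defaults are 4 chains × 1000 post-warmup draws; the test
suite and examples use 1–2 chains × a few hundred draws, which at the problem
sizes below give split-Rhat < 1.1 on all monitored parameters while keeping a
fit under two minutes. The slowest-mixing direction is the joint location of
thresholds, fixed effects and species deviations; longer trajectories
(max_leapfrog 64) are what controls it.

Rank-normalized split-chain Rhat and bulk/tail ESS come from arviz, as does
PSIS-LOO (standard tail fraction min(0.2 S, 3 √S); observations with Pareto
k > 0.7 are flagged in the comparison table). An exact leave-one-out oracle
(n refits) in the test suite checks the PSIS approximation independently.

## Model comparison and prediction

Six candidate fixed-effect structures are compared, all containing photo
region + family + taxa repeat; candidates add photo quality, the home-region
effect, both, or the home-region × region interaction (with and without
quality). Comparison is by LOOIC (−2 elpd_loo), lower better.

The prediction target for Bayesian R² and MAE is the expected score — the
mean of the category values 0–3 under the per-draw category probabilities —
which is the natural reading of accuracy "in score units" for an ordinal
outcome. Bayesian R² per draw is var(fitted expected scores) over itself plus
the mean conditional score variance. "Without group-level effects" means all
group deviations set to 0, the new-cluster convention; units unseen in
training likewise predict at 0 deviation.

## Synthetic challenge generator

The generator forward-simulates the exact generative process the GRM assumes.
Defaults are the full-scale study conditions: 250 participants, 100 species ×
10 photos in 9 families and 6 global regions plus 100 single-photo
distractors, participant home regions drawn at the observed mix (50% North
America, 22% Europe, 10% Africa, 10% Asia, 4% each South America and
Australasia), about 400 photos answered per participant, and all effect sizes
at the reference posterior medians (participant ability sd 1.00, photo
difficulty/discrimination sds 0.65/0.21 with correlation 0.70, species sds
0.62/0.31 with correlation 0.34, home-region effect 3.14, taxa-repeat 0.08).
Presentation order is a uniform random permutation per participant — the real
challenge's order was only "haphazard" — with an optional high-quality-first
schedule mirroring the platform default. Photo quality is assigned per photo
but has no generative effect by default, matching the top model. All
randomness flows from a single root seed; identical seeds give byte-identical
tables.

The synthetic taxonomy is schematic: every family gets at least two genera
and every genus at least two species so that genus- and family-level wrong
answers are always realizable when converting scores back to answer strings.
The real challenge included singleton families (Cylindrophiidae and other
obscure lineages with one or two species), which the default allocation
deliberately avoids; analyses of such families on real data will show wider
uncertainty than anything the synthetic tests exercise. The generator also
does not emulate response times, participant recruitment or drop-out, answer
misspellings, or source-misidentified photos — so passing recovery tests
demonstrates correctness of the model and sampler under the model's own
assumptions, not robustness to real-data pathologies.

Skips are not modelled separately from wrong answers (the ordinal scale pools
them); `attach_answer_strings` exposes a skip probability only to exercise
the scoring pipeline.

## Problem sizes used in the tests

Parameter recovery runs three replicate challenges of 150 participants × 300
photos (100 species × 3), ~80 photos answered per participant, fitted with
2 chains × 500 post-warmup draws; across replicates at least 90% of the 20
generating fixed effects must fall inside their 95% credible intervals. The
exact-LOO cross-check uses 20 participants × 30 photos without group effects
(600 refits). The closed-form category-frequency check uses 50 000 simulated
responses. These sizes were chosen as the smallest at which the checks are
sharp; the library itself has no scale limits beyond memory.

## Known limitations

- The reference-median prediction for the *10th* photo of a North American
  colubrid evaluates to ≈30–32%, noticeably below the ≈38% the original
  full-data analysis reports for that cell; plugging point medians into the
  nonlinear link is not the same as averaging the link over the posterior,
  and the package does not attempt to reconcile the two. No test asserts that
  value.
- Threshold and discrimination intercepts are weakly identified when the
  reference family has few species; their marginal Rhat converges more slowly
  than the fixed-effect contrasts.
- Quintile confidence intervals are normal approximations of the
  across-participant mean; a bootstrap is not currently wired in.
- Modal-answer ties in the consensus table count as majority-incorrect (a
  conservative convention, applied uniformly).
- The per-genus confusion table reports the share identified as non-MIVS
  against both the all-responses and the non-skip denominator, since either
  reading is defensible.
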