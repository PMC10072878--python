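# Methods

## Effect estimation

Growth of the focal species in a well is its fluorescence reading minus
the same well's t = 0 reading; negative post-baseline values are retained
(not truncated). The analysis timepoint defaults to 24 h, by which focal
monocultures have saturated, and is configurable
(`FilterConfig.analysis_timepoint_h`).

The effect of a community on its focal is

    effect = ln( median(coculture growth) / median(monoculture growth) )

in natural log. Natural log (rather than log10) is the deliberate
reading of the convention that a 5× autofluorescence filter "allows
effects of at least about −1.5": ln(1/5) = −1.609, while
log10(1/5) = −0.699 would not match.

Uncertainty is a bootstrap standard deviation: both well groups are
resampled with replacement independently, B = 100 times, and the SD of
the B log-ratios is reported. Pairing across chips is not preserved
(nothing in the assay links a specific coculture well to a specific
monoculture well). Each community draws its resamples from a substream
seeded by (run seed, CRC32 of the community label), so results do not
depend on iteration order. Effects with SD > |effect| are classified
neutral; neutrality is a reporting category only — neutral singles still
contribute their point estimates to model predictions.

### Filtering and censoring

* Communities with fewer than `min_replicates` (default 3) wells are
  dropped, after dosage pooling (below), with a logged reason.
* An affecting species is used with a focal only if the focal's
  monoculture median is ≥ `autofluorescence_factor` (default 5, boundary
  inclusive) times that species' autofluorescence.
* Coculture medians at or below the detection floor give censored
  estimates clamped at ln(floor/mono): signal below autofluorescence is
  unidentifiable. For multi-species communities the floor is the *sum*
  of the members' autofluorescences, since unlabeled signals add in the
  focal's channel; when no autofluorescence table is supplied the floor
  is machine epsilon (censoring effectively off). Censored-ness
  propagates as a flag onto any prediction built from a censored effect.

## Composition arithmetic and pooling

Droplets are treated as equal-volume (the device produces uniform 1 nl
droplets); unequal volumes are unsupported. Mixing two cultures at a
volume ratio dilutes each by its volume fraction, and a species' starting
OD in a k-droplet well is the mean of its per-droplet concentrations.
Wells whose droplet multisets differ only in dosage (AAB, ABB,
AB + blank) are pooled under one community key, each well weighted
equally, because different initial fractions were found not to change the
measured effect; pooling is the collapse performed by `community_key` and
replicate counts are summed across variants. OD values are carried as
dimensionless OD600 throughout — no conversion to cells/ml is attempted.

## Combination models

* additive — sum of the lower-order effects;
* mean — arithmetic mean;
* weighted mean — mean weighted by each affecting species' maximum OD600
  (carrying capacity from its growth curve); only defined on the singles
  basis, since a max-OD weight for a *pair* is not meaningful;
* strongest — the element with the largest absolute value. An exact tie
  between opposite signs returns the negative member (deterministic, and
  consistent with the dominance of negative effects in such screens) and
  is flagged.

Trio predictions on the pairs basis apply the same rule to the three
measured pair effects; "additive" is then the plain sum of the three
pair effects even though that counts each species twice — the natural
reading of an additive accumulation of measured joint effects, and the
construction under which additive predictions are expected to degrade
for larger communities.

## Evaluation

Accuracy is nRMSE: RMSE between predicted and observed joint effects
divided by the IQR of the observed effects *of the evaluated subset* —
stratum-specific when stratifying. Quantiles everywhere use linear
interpolation (numpy's default, type 7).

The bootstrap resamples individual wells with replacement within every
community (monoculture groups included), per focal; medians, single/pair/
trio effects and model predictions are all recomputed inside each
replicate; per-focal resamples are pooled into one full dataset per
replicate and one nRMSE per model is computed from it. One global
resample is shared across models per replicate (models are deterministic
functions of the resampled effects, so this gives a paired comparison).
Summaries are the median and IQR of nRMSE over B replicates (default
1000). Replicates in which a stratum degenerates (fewer than two finite
communities, or zero observed IQR) are dropped from that stratum's
summary and counted in `n_missing`. With resampling disabled the
procedure reduces exactly to plain nRMSE on the point estimates.

Sign strata (neg-neg / neg-pos / pos-pos) are assigned from the
point-estimate signs of the members' single effects on the full
(unresampled) data; zero counts as positive, and neutral-classified
singles are *not* excluded — stratification is by sign, not by
classification. Signed prediction errors are predicted − observed on the
log scale, so for negative joint effects a negative error means the
model overestimated the magnitude.

## Synthetic data generator

The generator emulates the screen's statistical structure, not its
physics:

* **Single effects** come from a two-sided exponential mixture: negative
  with probability 1 − `frac_positive`, magnitudes exponential on each
  side. Both scales are solved in closed form from the target median,
  IQR and positive fraction (defaults −0.15, 0.94, 0.33), so the
  empirical summaries converge to the targets as n grows. The closed
  form covers the screen-like regime (negative median, positive fraction
  between 0.25 and 0.5); the one-sided limits fit the median only.
* **Joint effects** are `truth_rule` applied to the member singles plus
  Normal(0, `joint_noise_sd`) noise (default SD 0.15); every noise draw
  is recorded in the truth object.
* **Replicate counts** follow a lognormal (σ = 1), rounded and truncated
  to `replicate_range` (default [1, 285]); the location parameter is
  solved numerically so the truncated, discretized mean equals
  `replicate_mean` (default 19). A lognormal is chosen for the right
  skew typical of random droplet pooling; the true law of the screen is
  unknown beyond its range and mean. Focal monocultures are the
  denominator of every effect and are heavily replicated on a real chip,
  so their count is fixed (`mono_replicates`, default 50) rather than
  drawn.
* **Signals**: monoculture growth is lognormal with median
  `mono_signal_mean` (1000 a.u.) and shape set from `measurement_cv`
  (default 0.1) — median-parameterized so noise-free and noisy runs
  share medians and the zero-noise round trip is exact. Coculture growth
  is the monoculture median × exp(true effect) × the same multiplicative
  noise (fluorescence noise is scale-dependent). Readings are baseline
  offset (uniform 5–15% of the monoculture signal, removed exactly by
  t = 0 subtraction) + summed autofluorescence of the affecting species
  present + growth; timepoints after 24 h saturate (×1.05 then flat).
  Per-species autofluorescence is exponential with scale
  `autofluorescence_scale` (default 20 a.u., i.e. ~1–10% of signal, so
  the 5× filter occasionally rejects a species, as in a real screen).
* Droplet pooling is simulated at the community level via replicate
  counts; `dosage_variants=True` instead emits literal AAB/ABB/AB+blank
  droplet compositions that must pool back to the same communities.

What passing tests on this generator do **not** show about real data:
there is no growth dynamics (effects are imposed, not emergent), no
focal-by-affecting structure beyond independent draws, no chip or batch
effects, no fluorescence–biomass nonlinearity, and measurement noise is
homoscedastic on the log scale. Recovery of the generating rule here
demonstrates the estimator and evaluator are correct and well-powered at
screen-like replicate counts — not that any particular rule governs real
communities.

## Problem sizes used in validation

The bundled end-to-end checks run one focal with 30 affecting species and
all 435 pairs at bootstrap B = 200 (three generating rules × three
seeds), and the noise-free round trip uses two focals × 8 affecting
species; both complete in seconds while leaving every code path
(filtering, bootstrap, stratification) exercised.

## Traits

Carbon profiles are normalized to the best carbon source (max = 1);
antibiotic profiles to drug-free growth, unclamped — values above 1
(better growth with drug) are kept and flagged. Distances are plain
Euclidean on the normalized vectors (scipy), patristic distances are
summed branch lengths on a user-supplied newick tree (dendropy; tree
building is out of scope), and trait–effect association uses Spearman
rank correlation with mid-ranked ties (scipy), chosen as the standard
assumption-light statistic for monotone association.

## Known limitations

* The weighted-mean model silently falls back to being skipped when
  max-OD values are missing or non-finite for any member.
* Bootstrap SE and nRMSE bootstraps clamp non-positive resampled medians
  rather than dropping those replicates; with heavy-tailed noise and very
  small groups this slightly shrinks the estimated spread.
* The CLI `evaluate` stage re-reads the well table rather than reusing
  `estimate` outputs; on very large tables that is wasteful but keeps
  stages independent.
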