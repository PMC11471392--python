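# Methods

This note documents the models and procedures implemented in `ecometrics`,
the parameters that matter, the numerical conventions, and the known
limitations — the information a user needs to judge what a fitted model
and a passing test suite do and do not establish.

## The ecometric model

The unit of analysis is a **community**: the set of species whose
geographic ranges overlap one sampling point of a regular projected grid.
Each community is summarised by the arithmetic mean x̄ and the sample
standard deviation σ (n − 1 denominator) of a bounded functional trait —
here the relative blade length (RBL) of the lower carnassial, the fraction
of the first lower molar occupied by the slicing trigonid blade. Only
species with trait values count; communities with fewer than three
trait-bearing species are dropped (`min_richness = 3`). The sample-SD
choice treats the community as a sample from a regional trait pool; the
estimator is a one-line switch if population SD is preferred.

The (x̄, σ) plane is discretised into `n_bins × n_bins` equal-width bins
(default 25 × 25 = 625) spanning the observed `[min, max]` on each axis.
Bins are half-open with the last bin closed, so a value on an interior
edge belongs to the higher bin and the axis maximum stays in the top bin.
This makes the assignment a deterministic partition: every community lies
in exactly one bin, and bin counts sum to the community count.

For each non-empty bin, the observed environment of its member communities
— mean annual temperature (MAT, °C) or annual precipitation modelled as
ln(AP/mm) — is smoothed with a Gaussian kernel, and the **peak of the
likelihood surface** is the bin's maximum-likelihood environment estimate.
Precipitation is log-transformed because ecologically meaningful variation
at low rainfall would otherwise be swamped by variation at high rainfall;
all precipitation outputs are back-transformed to mm by exponentiation.

A community's estimated environment is its bin's peak. Model fit is the
squared Pearson correlation R² between estimated and observed environments
(constant estimate vectors define R² = 0; the regression form
1 − SSres/SStot is also computed and reported as a diagnostic — it can
differ because the bin-peak estimator is not a least-squares fit).
Anomalies are estimate − observation in natural units: positive means the
model calls the location wetter or warmer than observed.

### Numerical conventions for the kernel peak

* Bandwidth: Silverman's rule per bin,
  `h = 0.9·min(sd, IQR/1.34)·n^(−1/5)`, floored at 1% of the full
  environmental range so single-community and zero-spread bins still have
  a defined surface. A fixed numeric bandwidth can be passed instead.
* Evaluation: 512 equally spaced points spanning `[min − 3h, max + 3h]`.
* Peak extraction: every grid point whose sampled density is within 10⁻³
  of the maximum is refined by a dense local evaluation (201 points over
  the surrounding two grid steps), and the refined maximum wins. The
  refinement matters because a coarse grid's density error is quadratic in
  the grid step and can rank two nearly equal modes in the wrong order.
* Ties: modes whose refined densities agree within 10⁻⁵ relative are
  treated as equally likely and resolve to the **smallest** environmental
  value. This makes symmetric bimodal bins deterministic.
* Degenerate bins (all members share one value) return that value exactly.

### Prediction outside the calibrated space

Fossil summaries can land outside the modern trait ranges or in empty
bins. Out-of-range summaries are clamped to the nearest edge bin; empty
bins borrow the estimate of the nearest non-empty bin (Euclidean distance
in bin-index units, ties to the lower indices). Both situations are
flagged on the prediction so downstream tables can mark extrapolated
reconstructions. The rationale for clamping rather than refusing is that a
reconstruction pipeline must produce (flagged) estimates for every site.

## Validation battery

* **Shuffle null** — permute the estimate vector against the observations
  and recompute R², 100 times. Destroys all structure; its distribution is
  the ~χ²₁/n of squared correlation between independent vectors.
* **Bin-randomization null** — assign every community to a uniform random
  bin, refit all bin peaks from the reassigned memberships, re-estimate,
  recompute R², 100 times. This null *retains* the estimator's structural
  overfitting: each community's own observation still contributes to its
  (random) bin's peak, so with few communities per bin the null R² is well
  above zero. Empirical exceedance is reported in the bias-avoiding form
  `(1 + #{null ≥ observed}) / (1 + reps)`.
* **Down-sampling sensitivity** — for each sample size in a ladder
  (100…9100 step 1000 at full scale; the test suite uses
  {100, 600, 1100, 1600} × 5 repeats to fit a desktop budget), draw that
  many communities without replacement, split 80/20, fit on the training
  set (the training set defines its own bin edges) and score R² on the
  held-out set through the clamp/borrow prediction rules.

### A structural caveat on null comparisons

Because a training community's own observation enters its bin's peak, the
in-sample R² of an association-free dataset is not zero: it scales like
`k·B/n` (B = occupied bins, k ≈ 0.6 empirically), which exceeds the
shuffle-null band (~3.84/n) whenever more than a handful of bins are
occupied, at any sample size. The shuffle null is therefore a test of
*association*, not of *overfitting*; the bin-randomization null, which is
centred above the association-free level, is the appropriate yardstick for
the latter. Held-out R² from the sensitivity analysis is the only estimate
free of this term. The published-scale application (tens of thousands of
communities, hundreds per bin) makes the overfitting term negligible
relative to the reported fits, but it dominates at toy scale.

## Paleoclimate hindcasting

Fossil assemblages (≥ 3 species with trait values, traits in [0, 1]) are
summarised with the identical (x̄, σ) estimator and passed through the two
fitted modern models; precipitation is back-transformed to mm. Each site
is paired with the **nearest** modern community within two grid spacings
(configurable), and the reconstruction table reports predicted and modern
climate, their differences (predicted − modern), and the displacement of
the community through ecometric space (modern − fossil, per axis).
Extinct species enter through explicit trait values in the fossil input;
no imputation is performed.

## The synthetic world

The generator provides study systems with the statistical structure the
analysis assumes, not realistic biogeography:

* **Climate** — MAT: a linear south–north gradient over (−15, 30) °C plus
  a Gaussian-filtered random field (correlation length 5 cells, SD 3 °C).
  log-AP: a west–east gradient over (4.7, 7.9) ln mm (~110–2700 mm) plus a
  smoothed field of SD 0.35, exponentiated, so AP > 0 everywhere. Noise
  amplitude 0 yields exact linear gradients (used by degenerate-case
  tests).
* **Species pool** (default 60 species) — each species gets a climatic
  niche centre at the (jittered) climate of a random cell, and an
  elliptical hard envelope with a cutoff at 2 breadth units; breadths are
  12.5% of each climate axis range, calibrated once so the default world's
  median community richness sits at the configured target of 12 (between
  the continental means reported for real carnivoran communities).
* **Trait–niche coupling** — species trait ~ Normal(μ, s) with
  μ = 0.88 − 0.25·c_mean·wetness and
  s = 0.04 + 0.15·c_sd·(hotness + wetness)/2, clipped to the observed
  carnivoran range [0.41, 1.0]. Both couplings live in [0, 1]. Communities
  then *inherit* the target pattern emergently — trait SD rising with
  temperature and precipitation, lowest means only in wet cells — which is
  exactly what the ecometric model must detect; nothing couples
  communities to climate directly.
* **Ranges** — presence = inside-envelope × Bernoulli(occupancy = 0.85)
  per cell, producing range holes that exercise the richness filter.
* **Fossil assemblages** — drawn from the species whose envelopes contain
  a designated paleoclimate; species whose envelope also contains the
  site's modern climate are conditioned on their observed modern presence,
  so an assemblage drawn under the modern climate is a subsample of the
  modern community. Bernoulli membership is topped up deterministically
  (nearest niche first) to the three-species minimum.
* **Determinism** — one master seed; every stage draws from an independent
  substream (`SeedSequence(entropy=seed, spawn_key=(stage, …))`), so any
  stage reproduces in isolation and whole pipelines are byte-identical
  under a fixed config.

What the generator does **not** emulate: polygon range topology,
dispersal limitation, phylogenetic autocorrelation of traits, shared
climatic history, observation error in trait measurements, or the real
data's sample sizes. Passing tests on synthetic worlds therefore
demonstrate that the estimators recover a known trait–climate coupling of
the assumed form — not that any particular real-world fit is correct.

## Problem sizes used by the test suite

The default synthetic study system is a 60 × 50 grid (~2,900 communities
after filtering) — large enough that the fitted R² dwarfs both nulls under
strong coupling. The negative-control analysis uses twenty 30 × 25 worlds
with couplings set to zero; the sensitivity ladder uses sizes
{100, 600, 1100, 1600} with 5 repeats. These sizes are the package's
standing defaults for its own verification and are reported alongside
every quantity the acceptance script writes.

## Known limitations

* MAT and AP are fitted independently; the model carries no covariance
  between them, and a joint reconstruction may be climatically
  inconsistent at extreme summaries.
* Equal-width binning over observed ranges makes bin edges
  dataset-dependent; models fitted on different community sets are not
  bin-compatible (use the serialised model file to apply a fixed model).
* Significance from the randomization nulls ignores spatial
  autocorrelation among communities (neighbouring communities share most
  species); spatial block cross-validation would be the stricter test.
* The in-sample R² of small datasets contains the structural overfitting
  term described above; prefer held-out R² when comparing models at small
  n.
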