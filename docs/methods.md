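# Methods

This note documents the models, defaults and numerical choices behind
`fetalcwas`, and what the synthetic tests do and do not establish about
real data.

## Synthetic cohorts

The generator emulates the statistical skeleton of a small fetal
resting-state cohort: by default 59 scans, 100 ROIs, 110 volumes at TR 3 s
(~5.5 min of data), and questionnaire scores for four instruments.

**Time series.** Each subject's ROI × volume matrix is drawn from a
zero-mean multivariate normal whose correlation matrix has block structure:
`within_module_r` (default 0.4) inside each of `n_modules` (default 14)
equal-size contiguous blocks — remainder ROIs join the last block — and
`between_module_r` (default 0.05) elsewhere. The defaults give a clear but
not caricatured modular architecture: at 110 volumes the per-edge sampling
noise (SD ≈ 1/√110 ≈ 0.10) is a substantial fraction of the within/between
contrast, as in real short scans. If edge edits make the matrix indefinite
it is repaired by eigenvalue clipping at 1e-8 with the diagonal rescaled to
1 — deterministic and standard.

**Behavior scores.** Scores are truncated normals on the instrument bounds
(SSAI/STAI 20–80, PSS 0–40, EPDS 0–30) with cohort means/SDs 26.66 (6.72),
28.09 (6.62), 9.27 (5.13) and 3.24 (2.84). The underlying normal is
*moment-matched* so that the truncated distribution itself has the stated
mean and SD; naive truncation of N(mean, SD) at a floor one SD below the
mean would inflate the mean by ~2 points. The SSAI case sits essentially on
the boundary of what a truncated normal can realise (SD ≈ mean − floor), so
the solver lands on the nearest attainable moments (within 0.05 of the
targets).

**Planted effects.** A brain–behavior effect sets the population
correlation of each edge in a chosen set to
`base_r + slope × (score − mean score)`, clipped to ±0.9, before sampling —
the generating slope is therefore the direct target of recovery tests
rather than an additive-signal proxy. Recovery fixtures use a slope of
0.02 r-units per score unit (scores spanning ~25 units ⇒ edge-r range
~0.5), calibrated once in a pilot so that recovery at n = 59 is expected
to succeed when the machinery is correct and to fail under bugs; the
per-pair power at this slope is what the planted-pair tests exercise, not
an empirical effect size.

**Motion.** Frame-to-frame translation/rotation deltas are small
(|N(0, 0.08 mm)|, |N(0, 0.1°)|, clipped safely below threshold) with
independent Bernoulli spikes (default probability 0.05) that exceed 1 mm or
1.5°.

**What the generator does not emulate:** autocorrelated hemodynamics,
scanner drift and physiological noise, spatially varying SNR, fetal head
pose, repeated scans of the same subject, or non-Gaussian score
distributions. Passing tests show the *estimators* behave correctly
(calibration, recovery, invariances) under the assumed data model, not
that the scientific findings would replicate on real fetal data.

## Motion QC

Censoring removes any volume whose frame-to-frame translation exceeds
1 mm *or* rotation exceeds 1.5°, plus the immediately preceding frame
(both frames of a motion transition are corrupted). The rotation rule is
deliberately read as "greater than 1.5°": censoring *low* rotation would
be incoherent, and the threshold is configurable. The MAD rule removes
volumes where strictly more than 10% of ROI signals deviate from their own
time-series median by more than `mad_k` × MAD; the deviation multiplier is
not standardized, so it is a parameter with default 3.0. Constant series
(MAD = 0) never deviate. Inclusion requires retained volumes × TR ≥ 4
minutes (80 volumes at TR 3 s). Censoring is idempotent and can only
shrink the keep mask.

Nuisance regression is per-ROI OLS on retained volumes only and requires
an intercept in the regressor span. Optional band-pass filtering
(Butterworth order 2, 0.009–0.08 Hz) runs on the full grid with censored
volumes linearly interpolated and re-masked afterwards; whether filtering
should precede or follow censoring is genuinely open, so the filter is off
by default and isolated behind a flag — downstream tests are
structure-level and insensitive to this choice.

## Connectomes

Pearson correlation over retained volumes (≥ 3 required; constant series
are an error naming the ROIs), Fisher z = atanh(r) with |r| clipped at
1 − 1e-7 so perfect correlations stay finite (|z| ≤ 8.06) without
materially affecting statistics. The canonical edge order is the row-major
upper triangle keyed by ROI label order; every module shares it, and
vectorization round-trips exactly.

## MDMR

Distances between connectivity profiles are Manhattan (L1) — well behaved
in high dimension and the package's default throughout. Gower centering
`G = −½ C (D∘D) C` converts squared distances to an inner-product matrix;
with hat matrix `H` from the design (intercept + m covariates),

- omnibus: `pseudo-F = [tr(HG)/m]/[(tr(G) − tr(HG))/(n−m−1)]`,
  `pseudo-R² = tr(HG)/tr(G)` (using tr(HGH) = tr(HG) by idempotence);
- per factor: numerator `tr(HG) − tr(H_red G)` on 1 df against the same
  full-model residual.

Permutation inference uses raw subject relabeling for the omnibus test and
Freedman–Lane for factors: the permuted Gower matrix is
`(P E_r + H_r) G (P E_r + H_r)ᵀ` with `E_r = I − H_red`, i.e. reduced-model
residuals are permuted while fitted nuisance effects stay in place. The
p-value is the add-one estimator `(1 + #{F_perm ≥ F_obs})/(B + 1)`, so
p ≥ 1/(B+1) and p = 0 is impossible. The default permutation count is
100,000 (the conventional choice for final inference at these cohort
sizes); tests and the pipeline default use smaller counts since the
add-one estimator is unbiased at any B.

Correctness anchors: with Euclidean distances on a univariate response,
pseudo-F/R² equal classical OLS F/R² to ~1e-13; `vegan::adonis2` agrees on
multivariate fixtures; null p-values are uniform (KS test); rejection at
α = 0.05 over 500 null synthetic cohorts lies in the binomial 95% band.

Scans are treated as exchangeable units (repeated scans of one subject are
not modeled); covariate screening (`screen_covariates`) retains candidates
whose marginal omnibus p falls below a keep-threshold (default 0.10) — a
pragmatic stand-in for "keep covariates that explain profile variability",
since no standard exact rule exists.

## Community detection

Modules come from modularity maximization on the group-mean z matrix with
a resolution parameter γ, using Leiden optimization on a two-layer signed
decomposition: positive weights contribute at full strength, negative
weights penalize co-assignment scaled by their share of total weight
(`v⁻/(v⁺+v⁻)` — the asymmetric convention, under which positive structure
dominates). Defaults: γ = 1.5 (biased toward smaller modules, so a
100-ROI network can plausibly decompose into ~14 communities),
100 seeded restarts combined by consensus: co-assignment frequencies are
thresholded at 0.5 and re-clustered until all runs agree (with a singleton
fall-back if nothing agrees, and a hard iteration cap of 20). γ = 0 is the
degenerate single-module limit and is returned directly. The consensus is
deterministic in the master seed. The planted 14-block cohort is recovered
with ARI = 1, and module counts are non-decreasing in γ on the planted
fixture.

## Enrichment

Edges are screened by the Pearson correlation of Fisher-z connectivity
with the behavior score; two-tailed p from the t reference on n − 2 df;
"strong" means p < .05 with *no* multiple-testing correction at the edge
level — the enrichment stage, not the screen, carries inference. Edges
map to the K(K+1)/2 unordered module pairs (within-module pairs included).
Per pair, the 1-df Pearson χ² (no continuity correction — the statistic is
referred to a permutation null, not its asymptotic distribution) compares
in-pair vs out-pair significance counts; enrichment is one-sided
(over-representation only), so the working statistic is χ² when observed >
expected and 0 otherwise. The permutation null shuffles the behavior score
and re-runs the *entire* screen-and-count pipeline per permutation
(per-pair comparison, add-one estimator); pairs at or below expectation
are never called enriched. Calibration: ~5% of pairs called at α = 0.05
under the null; a planted one-pair effect attains the minimum p in > 90%
of replicates at n = 59.

## Reporting and determinism

Summary percentages are always recomputed from counts (one decimal);
top-k edge tables rank by |r| with deterministic label-order tie-breaks.
All randomness descends from a single master seed via seed sequences
(per-subject, per-stage streams), so identical configs give byte-identical
outputs; the manifest records versions, parameters and stage timings.

## Problem sizes in the test suite

Calibration suites run at deliberately modest scale — 30 ROIs (435
edges), 40–59 subjects, 110 volumes, 199 permutations, 50–500
replicates — chosen so the whole suite completes in about a minute while
keeping Monte-Carlo error small relative to the tested tolerances (95%
binomial bands, ARI = 1, p-value uniformity at KS α = 0.01). The
module-recovery fixture uses the full 100-ROI, 14-module geometry at 2000
volumes, where the planted partition is information-theoretically easy and
exact recovery is the correct expectation.

## Known limitations

- No voxel-level preprocessing: the pipeline starts at ROI time series.
- No analytic MDMR p-values (permutation only, by design).
- Repeated scans are treated as independent; a mixed-model or
  restricted-permutation treatment is out of scope.
- The enrichment χ² treats edges as exchangeable units; spatial
  autocorrelation of edges sharing an ROI is ignored (as is conventional).
- Community detection on noisy group matrices is resolution-dependent;
  module counts are an empirical outcome, not a contract.
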