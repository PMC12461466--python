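# Methods

This note documents the models, statistics, numerical conventions and
design decisions behind `clusterdose`, in the spirit of a statistical
software methods appendix. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
external data.

## Quantities

**fICSD.** For one particle class c (type + specific energy in MeV/u), the
frequency ionization cluster-size distribution f(ν) counts nanoscopic
ionization clusters of size ν per micrometre of track per source particle.
Frequencies are stored already normalized; a raw-count constructor divides
by (number of source particles × mean chord length of the sensitive
cylinder). The chord length uses the Cauchy formula 4V/S = 2rL/(r+L) for a
cylinder (default r = 30.4 nm, L = 161 nm, a chromatin-fibre-sized
volume). For a parallel beam the mean path can differ from the isotropic
Cauchy chord; since the normalization convention of raw counts is a user
contract rather than a measured quantity, the isotropic form was chosen and
documented, and users with beam-specific normalizations can pre-normalize.
Entries at ν = 0 carry no cluster information and are dropped.

**C_k.** The ionization parameter family used throughout: C_k = Σ_{ν≥k}
f(ν), clusters of k or more ionizations per μm. k_max defaults to 10.
Tail sums are accumulated left-to-right over the ν-sorted support; the
summation order is part of the contract so that independent
implementations agree bit-for-bit (no pairwise/compensated reordering).

**Voxel averaging and cluster dose.** In a voxel j traversed by classes c
with summed track lengths t_j^c, the voxel-averaged I_p is the
track-length-weighted mean Σ t_j^c I_p^c / Σ t_j^c; fluence is total track
length over voxel volume; cluster dose is g_j = φ_j I_p^{φ_j} / ρ0 with
ρ0 = 1 pg/μm³ (liquid water) by default, so g is in pg⁻¹ (clusters per
picogram, numerically clusters per μm³ of water). Energies missing from
the C_k table clamp to the nearest boundary energy when out of range and
snap to the nearest grid point when in range; the nearest-neighbour metric
is logarithmic by default (particle data tables are typically log-spaced)
with a linear option, ties resolving to the lower energy. Records are
accepted pre-segmented per class; no segmentation rule is imposed.

## The LQ model and its fitting

Survival is modelled as ln S = −α g − β g² with no intercept (S(0) = 1
exactly); α is in pg, β in pg². The fit minimizes Σ w_i (ln S_i + α g_i +
β g_i²)² with weights w_i = 1/S_i (reciprocal survival; a 1/S² convention
is available). The model is linear in (α, β), so the weighted normal
equations are solved in closed form — no iterative optimizer, no local
minima. Negative fitted β is allowed and reported; clipping would bias the
dispersion comparison across k. At least 3 points with distinct g are
required.

**Parameter covariance.** The 1/S weights are heuristic precision weights,
not true inverse variances: under the multiplicative (lognormal) noise
model the ln-S residuals are homoscedastic, while 1/S weighting
concentrates leverage on the few lowest-survival points. The classical
scaled normal-equations covariance (XᵀWX)⁻¹·χ²/(n−p) then underestimates
parameter uncertainty several-fold (2·SE intervals covered the truth in
only ~35% of simulation replicates at n = 60, σ_lnS = 0.1). The default is
therefore the HC3 leverage-corrected sandwich estimator, which restored
~95% empirical coverage in the same simulation; the classical form remains
available via `covariance="scaled"`. χ² reported with a fit uses the same
weights as the fit, keeping the Δχ² comparison internally consistent.

**Δχ².** For points grouped by particle, Δχ² = χ²_combined − Σ_g χ²_group.
The per-group model nests the combined one, so Δχ² ≥ 0 up to round-off
(asserted at 1e−9). Small Δχ² means a single (α, β) pair describes every
radiation quality — the defining property of a preferred I_p.

**Confidence bands.** Bands are built by drawing 1000 (α, β) pairs from a
bivariate normal with the fit covariance, evaluating the survival curves on
a grid, and taking mean ± 1 SD pointwise. Because exp is convex the sample
mean can sit slightly above the central curve, so the envelope is widened
pointwise (elementwise min/max with the central curve) to guarantee it
contains the fitted curve; with zero covariance it collapses to the curve
exactly. Sampling is seeded and bit-reproducible.

## Dispersion methods

All standard deviations in this module use the population (1/N) divisor,
matching the definition of the per-window SD, and all standard errors are
population SD / √N_units.

**Method 1 — moving window.** Points are sorted ascending in cluster dose
(ties broken lexicographically by dataset/particle/energy/survival so
window contents are deterministic). The window holds n = max(3,
round-half-up(1% of N)) points and slides one point at a time, giving
N − n + 1 windows; σ_T is the mean per-window population SD of survival
(survival scale, not ln S) and SE_T its population SD over √N_windows. A
"centered" label variant exists for plotting; window contents are
identical, as a symmetric window around each interior point enumerates the
same window set. Per-window sums are accumulated left-to-right so the
brute-force oracle comparison in the tests is bit-exact. The variable
variant windows each point i by {j : |g_j − g_i| ≤ 0.05 g_i}; windows with
fewer than 2 points are skipped and counted, and the statistic is an error
if every window is skipped (sparse axis). The variable window is only
meaningful when the cluster-dose axis is densely populated.

**Method 2 — LQ residuals.** r_i = |S_i − Ŝ_i| / Ŝ_i on the survival
scale (the fit itself is in ln S); r_T is the mean and SE_T the population
SD over √N.

**Method 3 — BIC with bootstrap SE.** BIC = LLH + p·ln N with p = 2 for LQ
and 1 for the purely linear model. Residuals are taken in ln S from the
weighted fit and σ is their population SD. The default (`gaussian`)
convention evaluates the proper Gaussian −2 log-likelihood N ln 2π +
2N ln σ + SSR/σ². A literal legacy surrogate, LLH = −N ln σ + SSR/σ², is
preserved behind `convention="paper"` for traceability only: with σ
estimated from the residuals, SSR/σ² ≈ N, the −N ln σ term dominates, and
the surrogate *decreases* as the fit worsens — it is not a valid
−2 log-likelihood and is documented (and tested) as unusable for
selection. The SE of the BIC comes from 100 seeded subsamples of
floor(0.8 N) points drawn without replacement (with-replacement is a
config option); the statistic is the mean subsample BIC.

**Selection.** For each method the preferred k is the argmin of the
statistic over the evaluated k range (ties to the smaller k). Every k
whose statistic lies within one standard error of the minimum is reported
as statistically indistinguishable. No multiplicity correction is applied:
selection is a descriptive minimum with an SE, not a hypothesis test.

## Synthetic data generator

The generator stands in for an external fICSD database and published
survival measurements, with ground truth built in.

*What it emulates.* Several particle classes whose C_k profiles differ in
shape across k, and survival that is an exact LQ function of cluster dose
at one designated threshold k* with multiplicative lognormal noise.

*Construction.* Class q has a geometric fICSD f(ν) = A_q(1−p_q)p_q^{ν−1}
truncated at ν_max = 30, so C_k = A_q p_q^{k−1}(1 − p_q^{ν_max−k+1}) in
closed form — a testable generator with one shape knob p_q playing the
role of radiation quality. For k ≠ k*, C_k/C_{k*} = p_q^{k−k*} varies
across classes with distinct p_q, so survival plotted against the wrong
cluster dose provably cannot collapse onto a single curve: noiseless
dispersion is zero only at k*. Real track-structure fICSDs are not
geometric, but no method under test depends on the family.

*Default study conditions.* Five classes (proton-like to argon-like) with
p ∈ {0.35, 0.45, 0.55, 0.65, 0.75} and amplitude 20/μm; 8 fluences per
class; noise SD 0.08 on ln S. The aerobic-like preset sets k* = 5,
α = 0.3 pg, β = 0.02 pg²; the hypoxic-like preset sets k* = 7,
α = 0.12 pg, β = 0.01 pg² (radioresistance: larger clusters required per
lethal event, shallower initial slope). Fluence grids are chosen so that
every class shares the same 8 log-spaced cluster-dose values at k*,
spanning survival from ≈0.9 down to 1e−3 — sampling both the α-dominated
shoulder and the β-dominated tail, and realizing the central comparison
(same cluster dose, different particle) exactly. Survival is not clamped
at 1, preserving the lognormal error structure at low dose.

*What it does not emulate.* Physically realistic energy/LET dependence of
the fICSDs, secondary-fragment spectra, depth-dose geometry, experimental
dosimetry uncertainty, or oxygen-enhancement physics beyond the preset
differences. Passing recovery tests therefore demonstrate the correctness
and sensitivity of the statistical machinery, not the radiobiological
validity of any particular C_k on real beams.

## Problem sizes and determinism

Simulation-based checks use sizes chosen to give stable rates at desk
scale: 200 scenario draws per preset for selection-rate tests (the
acceptance script reports rates over 100 draws), 500 replicates for LQ
recovery in the tests (200 in the script), 100 bootstrap subsamples per
BIC evaluation, and 10 candidate k per scenario. A full scenario
evaluation (10 k × {4 statistics + 100-subsample bootstrap}) takes ~0.2 s.

Every stochastic stage draws from `numpy.random.default_rng` seeded
through a named sub-seed derived from the master seed (SHA-256 of the
stage name folded into a `SeedSequence`, kept below 2³¹), so adding or
removing a method does not perturb the streams of others, and a rerun of
the evaluate pipeline with identical config and seed is byte-identical.

## Known limitations

- The geometric fICSD family makes wrong-k misalignment monotone and
  strong; real databases may separate candidate k far more weakly, and
  selection rates on real data will be correspondingly lower.
- The 1/S weighting convention is itself a modelling choice; the package
  treats it as the fitting contract and compensates on the inference side
  (HC3), but alternative weightings change the absolute χ² scale.
- The variable cluster-dose window is undefined on sparse axes and is
  reported as such rather than silently padded.
- Voxel averaging accepts pre-segmented track records; it does not
  re-segment tracks by local energy loss.
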