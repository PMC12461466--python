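# clusterdose

Nanodosimetric cluster-dose survival analysis for ion-beam radiobiology.

In ion radiotherapy, the biological effect of a beam depends not only on the
absorbed dose but on how densely ionizations cluster at the nanometre scale
(the scale of short DNA segments). The ionization-detail formalism condenses
this track structure into an **ionization parameter** I_p. The family used
here is

> C_k — the number of ionization clusters of k or more ionizations per
> micrometre of track, the tail sum C_k = Σ_{ν≥k} f(ν) of the frequency
> ionization cluster-size distribution f(ν) of one particle class
> (type + energy).

Multiplying the fluence φ of charged particles in a voxel by the
track-length-averaged I_p over the particle mix, divided by the density ρ0
of the reference medium (water, 1 pg/μm³), gives the **cluster dose**

> g = φ · I_p^φ / ρ0   [pg⁻¹],

a macroscopic, fluence-proportional quantity directly analogous to absorbed
dose and therefore optimizable in treatment planning. If a cluster-size
threshold k exists for which *the same cluster dose gives the same cell
survival regardless of particle type, energy, or fluence*, treatment plans
can be optimized on cluster dose alone, without RBE weighting. This package
implements the statistical machinery to find that **preferred I_p**:

1. **Moving window** — sort survival points by cluster dose, slide a window
   of n = max(3, 1% of N) points, average the per-window population SD of
   survival (σ_T ± SE). Model-free. A variable window (neighbours within
   ±5% of the cluster dose) is also provided.
2. **LQ residuals** — fit the linear-quadratic model
   ln S = −α g − β g² by weighted least squares (weights 1/S) and average
   the relative residuals |S−Ŝ|/Ŝ (r_T ± SE).
3. **Bootstrap BIC** — Bayesian information criterion of the weighted LQ
   fit, with its standard error from 100 random 80% subsamples.

For each method the preferred k is the argmin of the statistic over
k = 1..10, with all k within one standard error reported as
indistinguishable. A nested-model check, Δχ² = χ²(one combined LQ fit) −
Σ χ²(per-particle fits), quantifies how well a *single* curve describes all
radiation qualities; it is minimized at the preferred k.

Because real fICSD databases and survival measurements are external, the
package ships a first-class synthetic generator: particle classes with
geometric cluster-size distributions (closed-form C_k) and survival that is
exactly LQ in the cluster dose at a designated k* plus lognormal noise.
Classes have distinct distribution shapes, so the wrong k provably cannot
collapse survival onto one curve — making preferred-I_p selection testable
by parameter recovery.

## Worked example

```sh
clusterdose generate --preset aerobic_like --seed 42 --out demo/
clusterdose evaluate --survival demo/survival.csv --ck demo/ck.csv \
    --variable-window-pct 5 --seed 42 --out demo/report.json
```

prints

```
dataset: aerobic_like  (n = 40 points)
  delta-chi2 minimized at k = 5
  bic                      preferred k = 5  (within 1 SE: 5)
  lq_residuals             preferred k = 5  (within 1 SE: 5)
  moving_window            preferred k = 5  (within 1 SE: 5)
  moving_window_variable   preferred k = 5  (within 1 SE: 5)
  combined LQ at k = 5: alpha = 0.288 /pg (SE 0.012), beta = 0.02107 /pg^2 (SE 0.00096)
```

The aerobic-like preset embeds k* = 5, α = 0.3 pg, β = 0.02 pg² and 8%
lognormal noise across five particle classes (proton-like to argon-like).
All four statistics independently recover k = 5, and the combined LQ fit at
that k recovers the generating α and β within their standard errors — the
"same cluster dose, same survival" property holds only at the true
threshold. The hypoxic-like preset (radioresistant: k* = 7, α = 0.12 pg)
behaves the same way with k = 7.

The library surface mirrors the pipeline: `clusterdose.icsd` (fICSDs, C_k
tables, chord-length normalization), `clusterdose.voxel` (energy clamping,
fluence, voxel-averaged I_p, cluster dose), `clusterdose.survival`
(measurement records, dose→fluence conversion, cluster-dose mapping),
`clusterdose.lq` (weighted LQ fits, Δχ², confidence bands),
`clusterdose.association` (the three dispersion methods and selection),
`clusterdose.synthetic` (scenarios and presets), and
`clusterdose.pipeline`/`clusterdose.cli` (orchestration). See
`docs/methods.md` for the statistical details and design choices.

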