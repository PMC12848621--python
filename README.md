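# mmpolar

Mueller-matrix polarimetry analysis of thin tissue sections, built for
tracking microstructural change — amyloid-plaque deposition in ageing mouse
brain being the motivating case — through the higher-order statistics of
polarimetric parameter maps.

A transmission Mueller polarimeter cycles a polarization-state generator and
analyzer through six states (H, V, ±45°, right/left circular) and records
36 intensity images per sample.  Every element of the per-pixel 4×4 Mueller
matrix **M** — which maps input to output Stokes vectors,
`S_out = M·S_in` — is a signed four-term sum of those images
(`m11 = HH+HV+VH+VV`, …, `m44 = RR−RL−LR+LL`; first letter the generator
state, second the analyzer).  After normalization by m11, the
Lu–Chipman polar decomposition `M = M_Δ·M_R·M_D` yields per-pixel maps of

* diattenuation `D = |(m12,m13,m14)|/m11`,
* polarizance `P = |(m21,m31,m41)|/m11`,
* retardance `R = arccos((tr m_R + 1)/2 − 1)` (radians),
* depolarization power `Δ = 1 − |tr m_Δ|/3`.

The statistical layer computes population central moments of each map over
a tissue mask — mean μ, std σ, skewness `Σ(x−μ)³/(Nσ³)`, non-excess
kurtosis `Σ(x−μ)⁴/(Nσ⁴)` — aggregates them by age group, and fits trends
against age (linear for μ and σ, `α·e^{βx} + c` for skewness and
kurtosis).  The physics behind the analysis: small (Rayleigh-like)
scatterers depolarize circular light faster than linear (`m22 ≈ m33 > m44`),
while wavelength-scale (Mie-like) scatterers such as amyloid plaques
preserve helicity (`m44 ≳ m22`), so a growing plaque burden drags the m44
and Δ distributions asymmetric — rising skewness, falling kurtosis — while
their means barely move.

Because measured brain data of this kind is not public, the package ships a
first-class synthetic phantom generator (`mmpolar.phantom`): an effective
per-pixel Mueller model of a tissue ellipse with age-increasing Mie-like
plaque disks, exact exportable ground truth for every stage, and a seeded
36-state measurement simulator with configurable SNR.  See
`docs/methods.md` for the full model.

## Worked example

Simulate the default 21-sample cohort (7 ages × 3 replicates) at 96×96 px
and run the full chain:

```python
import mmpolar as mp
from mmpolar.pipeline import RunConfig, run_pipeline

cfg = RunConfig(phantom=mp.PhantomSpec(shape=(96, 96)), seed=1,
                parameters=("m22", "m44", "Delta"))
res = run_pipeline(cfg)
print(res.table_text())
```

which prints, per analyzed parameter, the age-group moment table:

```
Delta
                  75       100       125       150       175       200       225
      Mean     0.147     0.147     0.149     0.149     0.149     0.150     0.150
       Std     0.015     0.017     0.019     0.019     0.020     0.021     0.021
      Skew     0.362     0.658     0.955     0.820     0.864     0.911     0.896
      Kurt     5.618     5.723     5.917     5.626     5.488     5.126     5.030
```

Reading it: the depolarization *mean* is flat near 0.15 across ages — the
average optical character of the tissue hardly changes — but the *skewness*
roughly triples from 75 to 225 days as rare strongly-depolarizing plaque
pixels stretch the upper tail, and the *kurtosis* drifts down as growing
heterogeneity broadens the distribution.  `res.trends` carries the fitted
trend per moment; for this run the fitted trend signs are positive for
Delta and m44 skewness, negative for Delta kurtosis, and the m22 mean/std
drift is below 1 % — the signature the phantom injects.  The same numbers
land in `moments.csv`, `trends.csv` and `moment_table.csv` when `out_dir`
is set.

The same chain is scriptable from a shell:

```sh
mmpolar simulate --out data --seed 1 --size 96
mmpolar pipeline --manifest data/manifest.csv --out run --params m22,m44,Delta
```

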