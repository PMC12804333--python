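# survmctp

Multiple contrast test procedures (MCTPs) for right-censored k-sample
survival data that remain powerful when the proportional-hazards assumption
fails — in particular under late effects and *crossing* hazards, where the
classical log-rank test loses most of its power.

## Who this is for

Biostatisticians analysing multi-arm time-to-event studies who need
*simultaneous local decisions* — not just "some arms differ" but *which*
pairs differ, with family-wise error rate (FWER) control — and who cannot
rely on proportional hazards.

## The statistics

Data are `(X_ji, δ_ji)` for subject `i` of group `j = 1..k`, with
`X_ji = min(T_ji, C_ji)` and `δ_ji = I(X_ji = T_ji)`. Hypotheses are pairwise
equalities of cumulative hazards, `H0^{j1,j2}: A_j1 ≡ A_j2`, over a
Dunnett-type (many-to-one) or Tukey-type (all-pairs) family of q contrasts.
The building block is the weighted log-rank statistic

    T_{j1,j2}(w) = √(n/(n_j1 n_j2)) ∫ w(F̂(t−)) · Y_j1 Y_j2/(Y_j1+Y_j2) · d(Â_j2 − Â_j1)

with `Y_j` the at-risk process, `Â_j` the Nelson–Aalen estimator, and `F̂`
the pooled Kaplan–Meier CDF. The weight steers power: `w ≡ 1` is the
log-rank, `w(t) = t^r (1−t)^g` the Fleming–Harrington family, and
`w(t) = 1 − 2t` the crossing weight. The default multi-directional set is
`{1, 1 − 2t}`.

Four procedures share this core:

| method | local statistic | calibration |
|---|---|---|
| adjusted log-rank | `T(w)²/Σ̂ ~ χ²₁` | Bonferroni `α/q` |
| adjusted mdir | quadratic form `Z = T' Σ̂⁻ T` over m weights | pairwise permutation + Bonferroni |
| MultiWeightedLR | max of studentized `|T(w^(r))|` | equicoordinate Gaussian quantile of the joint m·q correlation |
| multiCASANOVA | pooled Wald form `C = T̃' Ĉov⁻ T̃` | wild bootstrap (Rademacher / centered-Poisson multipliers) of `C_max` |

The last two exploit the joint dependence between contrasts instead of a
Bonferroni split, and hold their power under non-proportional hazards.

## Worked example

Simulate a 4-group crossing-hazards trial (Weibull shapes 1.5–4.5 at scale
5, n=60 per group, 20% uniform censoring) and test all pairs:

```python
from survmctp import SurvivalMCTP, sample_scenario, scenario

data = sample_scenario(scenario("cross", n=60, censoring=0.2), rng=12)
model = SurvivalMCTP.from_dataframe(data.to_frame())
print(model.fit(method="multicasanova", contrasts="tukey", seed=7).summary())
```

```
Multiple contrast test: multiCASANOVA (rademacher)
contrasts: tukey (q = 6), alpha = 0.05
critical value: 6.132
n_boot: 1000
multiplier: rademacher
seed: 7
--------------------------------------------------------
contrast             statistic     p-value  reject
1 vs 2                    4.12      0.2158      no
1 vs 3                   17.78    0.000999     yes
1 vs 4                    22.3    0.000999     yes
2 vs 3                   5.986     0.05694      no
2 vs 4                   14.72    0.000999     yes
3 vs 4                   6.493     0.03696     yes
--------------------------------------------------------
global null rejected: yes
```

Each row is one pairwise comparison: `statistic` is the Wald form
`C_{j1,j2}` combining the log-rank and crossing weights, compared against
the shared wild-bootstrap critical value 6.13; `p-value` is the bootstrap
tail fraction. Four pairs differ significantly. The same data through
`method="adjusted-logrank"` rejects *nothing* (all local p ≥ 0.16): the
hazards cross, so each plain log-rank statistic integrates early and late
differences with opposite signs and cancels — exactly the regime these
procedures are built for.

The same model runs from the shell:

```sh
survmctp simulate --scenario cross --n 60 --censoring 0.2 --seed 12 --out trial.csv
survmctp test --input trial.csv --method multicasanova --contrasts tukey --seed 7
```

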