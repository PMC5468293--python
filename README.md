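# gaitsig

Velocity-dependent gait-signature analysis for mouse and human walking data.

Spatial and temporal gait parameters — stride length, swing and stance
duration, cadence, swing speed — change lawfully with walking velocity.
Comparing raw or averaged parameters between conditions is therefore only
valid when the velocity distributions match, which they rarely do after an
experimental intervention.  `gaitsig` instead models each parameter as a
curve over stride velocity within a restricted *walking range* and asks
whether an intervention moved the animal **along** its curve (a change in
speed only) or **off** the curve (a shift in gait signature).  It is aimed
at labs running runway/walkway gait assays in rodent disease models and at
translational work comparing those assays with human instrumented-walkway
data.

## The model

For each gait parameter `Y` and stride velocity `v` (cm/s), three candidate
families are fit by least squares over the walking range (default
`3 ≤ v ≤ 16` cm/s in mice):

```
linear      Y = β0 + β1 v
one-phase   Y = Y0 + (Plateau − Y0)(1 − e^(−K v))
two-phase   Y = Y0 + SpanFast(1 − e^(−KFast v)) + SpanSlow(1 − e^(−KSlow v))
```

The simplest adequate family is chosen by the extra sum-of-squares F-test

```
F = ((SS1 − SS2)/(DF1 − DF2)) / (SS2/DF2)
```

(simpler model 1 vs more complex model 2; the complex model is preferred
only at p ≤ 0.05).  Two datasets A and B are then tested for a shared
curve by comparing one pooled fit against separate fits:

```
F = ((SScomb − (SSA+SSB)) / (DFcomb − (DFA+DFB))) / ((SSA+SSB)/(DFA+DFB))
```

p < α means the datasets are best described by two separate curves — the
gait signature has shifted.  Residual diagnostics (Wald–Wolfowitz runs
test, D'Agostino–Pearson omnibus K² normality) accompany every fit, and
conventional speed-independent analyses (normality-gated t / rank tests,
ANOVA + Holm–Šídák, Kruskal–Wallis + Dunn, exact noncentral-t power) are
included for contrast.

## Worked example

```python
from gaitsig import (GeneratorConfig, generate_cohort, add_offset,
                     select_model, compare_two, classify_shift, LINEAR)
from gaitsig.synthetic_data import split_random_halves

cohort = generate_cohort(GeneratorConfig(seed=1))        # 400 strides
sel = select_model(cohort, "stride_length_mm")
print(sel.preferred.family, [round(s.p, 4) for s in sel.steps])

base, other = split_random_halves(cohort, seed=2)
shifted = add_offset(other, "stride_length_mm", 5.0)     # +5 mm per stride
res = compare_two(base, shifted, "stride_length_mm", LINEAR)
print(f"F = {res.F:.2f}, p = {res.p:.3g}, shared = {res.shared}")
print(classify_shift(res).label,
      res.shift_summary["intercept"]["difference"])
```

prints

```
one_phase [0.0, 0.9491]
F = 100.80, p = 4.11e-36, shared = False
intercept-shift 4.521296699511048
```

The stride-length curve of the baseline cohort is best captured by the
one-phase family (the linear fit is rejected at p < 1e-4, the two-phase
refinement is unnecessary at p = 0.95).  After 5 mm is added to every
stride of one random half, the shared-curve test strongly rejects a single
curve (F = 100.8 on 2 and 396 df), and the shift is classified as an
intercept shift whose estimated magnitude (4.5 mm, 95% CI covering 5 mm)
matches the injected offset.

A command-line interface mirrors the library
(`gaitsig simulate|derive|filter|fit|compare|plot`); see `gaitsig --help`.

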