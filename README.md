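# petasym

Reference-tissue kinetic modelling and hemispheric-asymmetry statistics for
dynamic TSPO PET.

Many brain PET studies with the TSPO radioligand [11C](R)PK11195 average left
and right regions of interest, implicitly assuming the two hemispheres bind
the tracer identically. `petasym` implements the quantification chain needed
to test that assumption: simplified reference tissue model (SRTM) fitting of
regional time-activity curves against a cerebellar grey-matter pseudoreference,
derivation of the distribution volume ratio (DVR) and tracer delivery ratio
(R1) per bilateral region, and a battery of laterality statistics — asymmetry
index, signed relative difference, paired Cohen's d, exact Wilcoxon and
Mann-Whitney tests with Holm-Šídák correction, volume-vs-binding asymmetry
correlation, and a random-intercept linear mixed-effects model of hemisphere,
age, sex, handedness and scanning centre.

It is aimed at PET methodologists and neuroimaging statisticians who need a
tested, reproducible implementation of this analysis. Because clinical TSPO
datasets are rarely shareable, the package ships a first-class synthetic-data
module that generates two-centre cohorts (default: 50 + 26 subjects on the two
centres' printed 18- and 17-frame schedules) with known ground-truth
asymmetry, so every stage is testable without any download.

## The model

SRTM expresses a target-tissue TAC through the reference-tissue TAC:

    C_T(t) = R1 · C_R(t) + (k2 − R1·k2a) · ∫₀ᵗ C_R(s) · e^(−k2a·(t−s)) ds

with `k2a = k2 / (1 + BP_ND)` and `DVR = BP_ND + 1`. Fitting uses the
basis-function method (256 log-spaced `k2a` values on [0.005, 1] /min with
golden-section refinement); an independent multi-start nonlinear
least-squares fitter serves as a cross-check in the tests. Model values are
frame averages computed by segment-analytic convolution of the piecewise
linear reference curve — no discretisation grid is involved.

Laterality metrics follow the convention *positive = right > left*:

    AI       = (right − left) / (right + left)
    rel.diff = 100 · (right − left) / mean(left, right)  =  200 · AI
    Cohen's d = mean(right − left) / SD(right − left)

## Worked example

```sh
petasym run-all --out demo --seed 1
petasym report --report demo/report.json
```

prints

```
  brain_gmwm: rel diff +1.63% d=1.03 p_adj=5.16e-11
     frontal: rel diff +2.04% d=1.59 p_adj=5.14e-13
 grey_matter: rel diff +1.98% d=1.39 p_adj=7.97e-13
   occipital: rel diff +0.64% d=0.45 p_adj=0.000317
    parietal: rel diff +1.56% d=0.97 p_adj=4.16e-10
     putamen: rel diff +3.46% d=2.05 p_adj=3.54e-13
    temporal: rel diff +2.78% d=1.56 p_adj=4.33e-13
    thalamus: rel diff +2.95% d=2.29 p_adj=2.94e-13
LME hemisphere (right vs left): 0.0169 [0.0119, 0.0218] p=2.49e-11
```

Reading: in this simulated 76-subject cohort the right grey matter DVR exceeds
the left by 1.98% on average (paired effect size d = 1.39); every region's
Holm-Šídák-adjusted Wilcoxon p-value is far below 0.001 except the weakly
lateralised occipital cortex; and the mixed model attributes a +0.0169 DVR
difference to hemisphere after adjusting for age, sex, handedness (9 subjects
with unknown handedness excluded) and centre. Per-seed cohort values scatter
around the generator's injected truth (+1.87% grey-matter asymmetry, d
calibrated near 1.1).

The same pipeline runs from CSV TAC tables (`petasym fit`, `petasym analyze`;
see `petasym --help`), and the `roi` module extracts regional TACs and volumes
from already-aligned 4D images, label volumes and grey-matter probability maps
(NIfTI-1).

Python API sketch:

```python
from petasym import CohortConfig, RunConfig, run_full_analysis
report = run_full_analysis(RunConfig(cohort=CohortConfig(), seed=1))
```

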