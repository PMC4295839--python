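# promkin

Inference of quantitative promoter regulation models from reporter-gene
time series, built around the FliA/FlgM module of the *E. coli* motility
network.

## The problem

Kinetic microplate experiments with fluorescent transcriptional fusions
yield, per well, paired absorbance `A(t)` (OD 600 nm) and fluorescence
`I(t)` (GFP) readings. From these one wants to know whether a target
promoter's activity can be explained quantitatively by its regulators —
and what information is required to do so. Two complications dominate:

* **mRNA is not protein.** Promoter activities are poor proxies for
  regulator protein concentrations; the protein is a low-pass-filtered,
  half-life-dependent transform of the activity.
* **Specific regulation is not the whole story.** The activity of the
  gene-expression machinery (growth physiology) modulates every promoter;
  a constitutive promoter (phage λ pRM) reads it out.

`promkin` implements the full analysis chain: promoter activity
estimation, protein reconstruction, mechanistic model fitting, monotone
sign-pattern inference, and in-silico studies of when each correction
matters. Because no machine-readable dataset is deposited for the original
experiments, a first-class synthetic-data generator reproduces the
statistical structure of the study: five growth conditions (ΔrpoS-M9,
ΔcpxR-M9, ΔcsgD-M9, ΔcsgD-LB, WT-LB), ~150 readings over 7–16 h,
5–8 replicates, pulse-shaped activities with condition-dependent timing
and a >10-fold amplitude spread, logistic growth, slow reporter
degradation, autofluorescence and measurement noise.

## The model

With background-corrected signals and cubic smoothing splines, the
derived quantities are

    mu(t) = d ln A / dt                      growth rate
    r(t)  = I(t) / A(t)                      reporter concentration  [RFU]
    f(t)  = (dI/dt)/A + gamma_r * I/A        promoter activity  [RFU/min]

with `gamma_r = 0.0006 /min` (GFPmut2 half-life 19 h). A regulator protein
with half-life `t_half` (degradation constant `gamma_p = ln2/t_half`)
follows

    dp/dt = f(t) - (gamma_p + mu(t)) * p(t),
    p(0)  = (mu_T + gamma_r)/(mu_T + gamma_p') * r(T)     (preculture steady state)

where `gamma_p'` is the stationary-phase degradation constant. The
regulation of a FliA-dependent promoter combines FliA–FlgM titration
(quasi-equilibrium with dissociation constant `K`), Hill activation by
free FliA, and the constitutive read-out `f_const`:

    pA_free = ½ (−(K + pM − pA) + sqrt((K + pM − pA)² + 4 K pA))
    f = f_const * ( k0 + k1 * pA_free^n / (theta^n + pA_free^n) )

Parameters `c = (k0, k1, n, theta, K)` are estimated by multistart
minimization of the band-weighted absolute misfit

    Q(c) = sum_s sum_t |f̄ˢ(t) − f(x̄ˢ(t), c)| / (2 εˢ(t))

over a data-driven box, where `εˢ` is the ±2·SEM replicate band.
Monotone sign-pattern analysis independently tests which regulator roles
(+1 activator / −1 repressor / 0 absent) the time series admit, and which
are *minimal* (no role can be dropped).

## Worked example

```python
from promkin import synthetic_data as sd, fitting as ft

scenario = sd.default_scenario(seed=0)          # truth: k1=6, n=2, theta=300, K=150
data, truth = sd.make_fit_dataset(scenario, regressors="proteins",
                                  noise_rel=0.05, seed=1)
fit = ft.fit_regulation(data, model="eq2_eq3", n_starts=10, seed=0)
print(f"Q = {fit.Q:.1f}")
print(f"k0={fit.params.k0:.3f} k1={fit.params.k1:.2f} n={fit.params.n:.2f} "
      f"theta={fit.params.theta:.0f} K={fit.params.K:.0f}")
```

prints

```
Q = 146.5
k0=0.150 k1=6.10 n=1.95 theta=307 K=156
```

i.e. the parameters of the generating regulation function — basal rate
0.15, maximal rate 6, Hill exponent 2, threshold 300, titration constant
150 — are recovered within a few percent from noisy five-condition data.
Across repeated experiments `K` is the most weakly constrained direction
(most FliA is free in the excited regime), so its recovery is judged
through the misfit rather than as a point estimate.

The command line wraps the same stages:

```
promkin simulate --seed 1 --out sim/
promkin preprocess --plate sim/plate.csv --out prof/
promkin reconstruct --profiles prof/ --grid 7:240:27 --out rec/
promkin fit --profiles prof/ --regressors proteins --out fit.json
promkin signpatterns --profiles prof/ --grid 7:240:5 --out map.csv
promkin run-all --seed 1 --starts 8 --out report.json
promkin simstudy halflife --cells 5 --out heatmap.csv
```

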