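# pulsepd

Population pharmacodynamic modeling of pulsatile endogenous hormones.

Hormones such as growth hormone (GH), prolactin or luteinizing hormone are
secreted in discrete bursts whose timing and height vary within and
between people.  Summary statistics (AUC, C_max) discard the time course,
and estimating the location of ~15 pulses inside a nonlinear mixed-effects
(NLME) model is numerically fragile.  `pulsepd` implements the pragmatic
two-step alternative for scientists quantifying drug effects on pulsatile
secretion:

1. **Deconvolution** - each densely sampled 24 h profile is decomposed
   into Gaussian secretion events convolved with first-order elimination:

       C(t) = ∫ S(τ) E(t−τ) dτ + C(0) E(t),
       S(t) = Σₙ exp(ln Aₙ − ((t − Tₙ)/w)²/2)

   by fully automated insertion / weighted re-fit / pruning of pulses,
   yielding each individual's pulse times, amplitudes, secretion width,
   basal secretion and half-life.

2. **Population model** - the pulse times are fixed inputs to a turnover
   model with pulsatile input,

       dC/dt = k_in + S(t)·(1 + Effect(t)) − k_out·C,   k_in = Baseline·k_out

   estimated by NLME (Laplace approximation with interaction): log-normal
   inter-individual variability on baseline, initial concentration,
   elimination, width and amplitude; a per-pulse (between-occasion) effect
   κₙ on amplitude, `Aₙ = θ_A·exp(η + κₙ)`; a power covariate model on
   total body water %; proportional residual error.

A drug given as a bolus modulates secretion through a Hill (E_max)
function of the amount remaining in the body,
`Effect(t) = E_max·A(t)^γ / (EA50^γ + A(t)^γ)`, which supports simulation
of agonists (E_max > 0) and antagonists (−1 ≤ E_max < 0), clinical-trial
simulation with full variability, and re-estimation of the drug-effect
parameters from the simulated trial.

The clinical data the method was developed on are not public; the package
ships a seeded fixture generator that emulates them (24 h of duplicate
samples every 10 min, ~15 pulses/day, assay CV noise, LLOQ censoring),
plus the reference population parameter table as packaged data.

See `docs/methods.md` for the model, the estimation algorithms, their
numerical choices and known limitations (notably: basal secretion is only
weakly identifiable from heavily overlapping pulse trains).

## Worked example

Generate three synthetic normal-weight subjects and deconvolve them:

```python
from pulsepd.io_cli import (FixtureSpec, generate_fixture,
                            series_from_fixture, REFERENCE_GROUPS)
from pulsepd.deconvolution import autodeconvolve, constant_cv

spec = FixtureSpec(groups={"normal": (REFERENCE_GROUPS["normal"], 3)}, seed=42)
raw, truths = generate_fixture(spec)
for s in series_from_fixture(raw, constant_cv(0.05), lloq=0.03):
    r = autodeconvolve(s)
    t = truths[s.subject_id]
    print(f"{s.subject_id}: {r.pulse_frequency} pulses (true {t.n_pulses}), "
          f"half-life {r.half_life:.3f} h (true {t.half_life:.3f}), "
          f"width {r.secretion_sd:.2f} h (true {t.secretion_width:.2f})")
```

prints

```
normal-01: 15 pulses (true 15), half-life 0.213 h (true 0.265), width 0.44 h (true 0.43)
normal-02: 15 pulses (true 15), half-life 0.168 h (true 0.143), width 0.53 h (true 0.54)
normal-03: 16 pulses (true 16), half-life 0.374 h (true 0.353), width 0.42 h (true 0.42)
```

i.e. the pulse count is recovered exactly here, and half-life and shared
width to within the uncertainty expected from a single noisy profile.
Each result also carries the per-pulse times/amplitudes, basal secretion,
the initial concentration and fit statistics; `summarize_groups` produces
the group mean (sd) table with two-group t tests against a reference
group.

The same workflow is available from the shell:

```
pulsepd generate-fixture --seed 42 --n-subjects 3 --out raw.csv
pulsepd deconvolve --input raw.csv --pulses-out pulses.csv --summary-out summary.csv
pulsepd simulate-typical --emax 10 --ea50 2 --gamma 5 --dose 10 --out typical.csv
pulsepd simulate-trial --seed 1 --out trial.csv
pulsepd reestimate --seed 1 --out report.csv
```

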