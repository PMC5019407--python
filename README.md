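# fearcircuit

Trial-based simulation of amygdala–mPFC neural circuit models of fear
conditioning and extinction, for computational neuroscientists studying how
**uncertainty** during learning shapes the persistence of fear memory — in
particular the **partial reinforcement extinction effect (PREE)**: fear
acquired when a conditioned stimulus (CS, e.g. a tone) is only
probabilistically paired with an aversive unconditioned stimulus (US, e.g. a
foot shock) is markedly more resistant to extinction than fear acquired
under full CS–US pairing.

## The models

**Basic circuit.** Three rate units driven by the CS through plastic weights:
a *fear* unit `F` (readout of behavioral freezing), a *persistent* unit `P`
(prediction of US intensity) and an *extinction* unit `E` (prediction of
safety) that inhibits the fear unit:

```
F(t) = [w_F CS(t) − w_F,E E(t)]₊        P(t) = w_P CS(t)        E(t) = w_E CS(t)
```

Weights update once per trial under rectified prediction-error
(Rescorla–Wagner-style) rules, with `[x]₊ = max(x, 0)` the learning signal:

```
Δw_F = α_F CS [US − F]₊
Δw_P = α_P CS [US − P]₊
Δw_E = α_E CS [F·(P − US − E)]₊
```

Under partial reinforcement the extinction unit already acquires safety
weight during conditioning (on the unreinforced trials), so at extinction
onset its learning signal `F·(P − US − E)` is weak and fear is suppressed
slowly and incompletely — the PREE, graded by the waiting-time entropy of
the US.

**Extended circuit.** The same logic mapped onto amygdala subnuclei and the
ventromedial prefrontal cortex: the lateral amygdala (LA) as `P`, the
central amygdala (CEA) as `F`, and two extinction units — the vmPFC (`E1`)
and the intercalated cells (ITC, `E2`), with vmPFC → ITC excitation and
ITC → CEA inhibition.  The ITC weight has two-timescale plasticity modelling
early- vs late-phase LTP: a fast learning-signal-driven term plus slow
relaxation toward a capacity `w_E2∞` that grows with vmPFC activity:

```
Δw_E2  = α_E2 CS [F·(P − US − E2)]₊ − β_E2 (w_E2 − w_E2∞)
Δw_E2∞ = α_E2∞ CS E1 − β_E2∞ (w_E2∞ − w_E2)
```

The relaxation terms run on every trial, including stimulus-free resting
trials — this is the consolidation mechanism.  It reproduces the
optogenetic dissociation: silencing the vmPFC during extinction leaves
within-session extinction intact but blocks consolidation (large
spontaneous recovery later), while silencing it during retrieval has little
effect.  The package also implements the "shock procedure": re-conditioning
an extinction-resistant memory with a *stronger* US paradoxically unlocks
complete re-extinction.

A companion statistical observer (sequential Bayesian logistic regression)
estimates the US probability trial by trial and quantifies *surprise*
(−log predictive probability), which correlates with the circuit's learning
signals.

## Worked example

Sweep the reinforcement probability `p = P(US|CS)` and tabulate the PREE:

```
$ fearcircuit pree --p-grid 0.3:1.0:0.1 -o pree.csv
  p  entropy_bits       tau  residual_F  sE_onset
0.3      2.937636 20.849234    0.604306  0.197173
0.4      2.427376 20.507271    0.590603  0.218786
0.5      2.000000 20.270039    0.538038  0.257874
0.6      1.618251 19.621842    0.449972  0.334000
0.7      1.258987 18.625572    0.341983  0.434015
0.8      0.902410 16.913576    0.220148  0.571953
0.9      0.521106 14.148156    0.105563  0.773846
1.0      0.000000 11.339517    0.040703  1.000000
```

Reading the table: as `p` falls, the Shannon entropy of the waiting time to
the next US (`entropy_bits`, the uncertainty of the schedule) rises; the
fitted extinction time constant `tau` (trials, from `F₁·exp(−t/τ)+F₀`)
lengthens; the residual fear at the end of a 50-trial extinction phase
(`residual_F`, in units of the US intensity) grows from ≈0.04 (full
reinforcement extinguishes almost completely) to ≈0.60; and the safety
learning signal on the first extinction trial (`sE_onset`) — the drive
available to the extinction unit — shrinks.  Uncertain conditioning leaves
little to be surprised about when the US stops, and the fear sticks.

The same sweep is available in the library as
`fearcircuit.metrics.pree_curves([...])`, and the perturbation experiments
as scenario presets, e.g.:

```python
from fearcircuit import io
result = io.run_scenario("fig3_sil_ext")       # vmPFC silenced in extinction
ret = [r for r in result.records if r.phase == "retrieval"][0]
print(ret.F)                                   # 0.1638 (vs 0.0654 in fig3_control)
```

Retrieval-phase fear across the five vmPFC conditions (defaults): control
0.0654, activation-during-extinction 0.0, activation-during-retrieval
0.0455, silencing-during-extinction 0.1638, silencing-during-retrieval
0.0855.  The shock procedure (`fearcircuit.extended_model.run_shock_experiment`)
gives final CEA activity 0.030 after re-extinction with a 3× US versus
0.310 with a same-intensity US.

Other CLI entry points: `fearcircuit schedule`, `run-basic`, `run-extended`,
`surprise`, `scenario`, `sweep` (see `--help` on each).

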