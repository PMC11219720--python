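# shockbia

Segmental multifrequency bioimpedance (BIA) and hemodynamic analysis of
hemorrhage–resuscitation experiments, with a mechanistic two-compartment
fluid-kinetics simulator that stands in for access-restricted animal
data.

## The problem

In hypovolemic shock, the choice of resuscitation fluid decides where
the infused water ends up: balanced crystalloid stays extracellular, 5%
dextrose water becomes free water after glucose metabolism and enters
cells (1/3 extracellular : 2/3 intracellular), and 20% albumin expands
plasma oncotically — unless it leaks through a shock-damaged
endothelium, where it draws intracellular water outward instead.
Segmental multifrequency BIA can watch this happen non-invasively:
low-frequency current (5 kHz) cannot cross cell membranes and sees only
extracellular water, while high-frequency current (1 MHz) sees total
body water, so

* rising |Z| means water loss, falling |Z| means water gain;
* the trajectory of **x** = standardized |Z(5 kHz)| against
  **y** = standardized |Z(5 kHz)| / |Z(1 MHz)| (which houses
  (Z_in + Z_ex)/Z_in) is a straight line while intracellular impedance
  Z_in is constant, and bends when intracellular water changes;
* the time at which the 1 MHz curve regains its baseline marks
  restoration of pre-hemorrhage total body water — and is a candidate
  marker for when further fluid stops helping (ΔSV < 10% = no fluid
  responsiveness).

This package implements that full analysis chain — per-series z-scoring,
Gaussian-MLE group medians with interquartile bands and B-spline
interpolation, trajectory curvature classification by
total-least-squares residual share, 1 MHz recovery detection, and
five-timepoint endpoint statistics (Jarque–Bera, pointwise independent
t-tests, percent changes, the ΔSV rule) — together with a simulator of
the underlying experiment: a 180-min protocol of 1 L controlled
hemorrhage followed by 2 L of group-specific fluid, for three groups of
five swine.  See `docs/methods.md` for the model and every default.

## Worked example

```python
from shockbia.simulator import generate_dataset
from shockbia.io import RunConfig, analyze_group

cfg = RunConfig()
for group in cfg.groups:
    impedance, vitals, truth = generate_dataset(5, group, seed=42)
    res = analyze_group(impedance, vitals, cfg)
    c, r = res["curvature"], res["flags"]["restored"]
    print(f"{group:22s} curvature {c['score']:.5f} ({c['label']:6s}) "
          f"recovery {res['recovery_min']:5.1f} min  "
          f"restored MAP={r['map']} SV={r['sv']}")
```

prints

```
crystalloid            curvature 0.00042 (linear) recovery 100.2 min  restored MAP=False SV=False
crystalloid_dextrose   curvature 0.00603 (curved) recovery 108.7 min  restored MAP=False SV=False
crystalloid_albumin    curvature 0.00322 (curved) recovery  78.1 min  restored MAP=True SV=True
```

Reading this: the crystalloid-only group's trajectory is linear
(intracellular water untouched), while metabolized dextrose water and
leaked albumin both move intracellular water and bend their groups'
trajectories (score above the 0.0015 threshold).  Every group's 1 MHz
impedance regains its baseline during the resuscitation period, i.e.
total body water is replaced before the end of the experiment.  Only
the crystalloid + 20% albumin combination returns MAP and stroke volume
to their starting level (start-vs-end difference non-significant at
α = 0.05): crystalloid restores volume but dilutes plasma protein, so
pressure stays depressed.

The same story as a sequence of narrative steps lives under
`analysis/` (`01_simulate_cohort.py` … `05_hemodynamic_endpoints.py`),
each printing what it found and writing its tables to `results/`.
A CLI wraps the pipeline: `shockbia run --seed 0 --out results/`
(also `simulate`, `analyze`, `endpoints`, `report`).

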