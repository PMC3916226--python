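# nfkbsim

Simulation and scenario analysis of how overexpressed Hsp72 (the inducible
70 kDa heat shock protein) attenuates TNFα-induced NF-κB activation in
microglia.

In resting cells the transcription factor NF-κB is held in the cytoplasm by
its inhibitor IκBα.  TNFα activates the IκB kinase complex (IKK), which
phosphorylates IκBα on Ser32, triggering its ubiquitination and proteasomal
degradation; freed NF-κB enters the nucleus and induces — among hundreds of
targets — its own inhibitor IκBα and the IKK-attenuating protein A20, two
negative feedback loops that shape a sharp activation transient.
Constitutive Hsp72 overexpression damps this response, but the interaction
site(s) are debated.  `nfkbsim` provides the computational half of that
investigation for microglial BV2 cells: an ODE model of the pathway, a
catalog of candidate regulation scenarios expressed as multiplicative
parameter perturbations, a plausibility classifier against the key
experimental observations, parameter-uncertainty ensembles, and a synthetic
assay generator with the matching statistical battery (one-way ANOVA,
Newman–Keuls post-hoc, one-sample t, ΔΔCt fold changes).

## The model

Concentrations in µM, time in minutes.  The IKK module cycles three forms

```
d[IKKa]/dt = ka·TNF·[IKKn] − (ki + kiA20·[A20])·[IKKa]
d[IKKn]/dt = −ka·TNF·[IKKn] + kp·[IKKi]
d[IKKi]/dt = (ki + kiA20·[A20])·[IKKa] − kp·[IKKi]
```

with TNF ∈ {0, 1} and no basal IKK activity.  Downstream, IκBα binds NF-κB
(a1/d1a), active IKK phosphorylates complexed IκBα (kc2a, free IκBα at the
slower kc1a), and the tagged protein passes through E3-ligase engagement
(kua1), poly-ubiquitination (kuc1) and proteasomal degradation (kupd),
releasing NF-κB.  Tagged intermediates are also degraded constitutively
(kdpi), and the IκBα:NF-κB complex can enter the nucleus (i2a) — two
structural refinements over the classical core model.  Nuclear NF-κB drives
Hill-2 transcription of IκBα and A20 mRNA (c1a, c1, half-saturation Ka);
translation rates are c2a and c2.  IκBα translation rate c2a is the target
of one candidate Hsp72 mechanism.  Total NF-κB and total IKK are conserved;
the only free initial conditions are the two pools [IkBaNFkB(0)] and
[IKKn(0)].

Every simulation follows the experimental protocol: equilibrate without
stimulus (the resting cell), then stimulate from that equilibrium at t = 0
for 150 min.  Hsp72 hypotheses are applied as multiplicative factors on
rates/pools *before* equilibration.  A scenario is **plausible** when it
reduces resting total IκBα, reduces peak IKK activity, reduces peak nuclear
NF-κB, and leaves resting NF-κB activity within ±15% of control — the four
key experimental observations.

## Worked example

```python
from nfkbsim import (build_catalog, nominal_parameters, nominal_pools,
                     observable, peak, simulate_scenario_run, evaluate_scenario)

params, pools = nominal_parameters(), nominal_pools()
catalog = build_catalog()

control = simulate_scenario_run(params, pools)               # nominal model
hsp72 = simulate_scenario_run(params, pools, catalog["Fig6A_combined"])

amp_c, t_c = peak(observable(control, "nuclear_nfkb"))
amp_h, t_h = peak(observable(hsp72, "nuclear_nfkb"))
print(f"control peak : {amp_c:.4f} µM at {t_c:.0f} min")
print(f"combined peak: {amp_h:.4f} µM at {t_h:.0f} min "
      f"({100 * amp_h / amp_c:.1f}% of control)")

verdict = evaluate_scenario(catalog["Fig6A_combined"], control, hsp72)
print("plausible:", verdict.plausible)
```

prints

```
control peak : 0.0430 µM at 18 min
combined peak: 0.0114 µM at 23 min (26.6% of control)
plausible: True
```

i.e. the combined hypothesis — p65 pool at 70%, A20-dependent IKK
inactivation ×10, IκBα phosphorylation ÷6 — attenuates the nuclear NF-κB
peak to about a quarter of control while preserving resting activity,
whereas single-mechanism scenarios fail at least one plausibility criterion
(try `"FigS4A_IKKn_8th"` or `"FigS4C_pool70_kc2a10th"`).

The same analyses are scriptable from the shell:

```
nfkbsim scenario list
nfkbsim scenario classify --name Fig6A_combined
nfkbsim ensemble --scenario Fig6A_combined --n 100 --fraction 0.2 --seed 1 --out out/
nfkbsim pipeline --out pipeline_out/
```

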