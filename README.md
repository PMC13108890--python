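# ehtsim

Desk-scale in-silico assessment of ventricular-tachycardia (VT)
inducibility in infarcted myocardium, before and after
engineered-heart-tissue (EHT) remuscularization.

Remuscularizing an infarct scar with a patch of stem-cell-derived
cardiomyocytes restores contractile mass but introduces a slow-conducting
(≈12 cm/s), long-action-potential tissue layer over the scar — an
arrhythmogenic substrate in its own right. `ehtsim` is a research package
for exploring that trade-off with programmed electrical stimulation on
synthetic infarct geometries: 2D sheets (and thin 3D slabs) carrying a
non-conducting scar core, a slow remodeled border zone, an optional
epicardial graft layer at an immature (C10 = 10% of healthy coupling) or
matured (C90 = 90%) state, and an optional Purkinje-like conduction
system coupled through junctions.

It is aimed at computational electrophysiologists who want a small,
fully scriptable, deterministic substitute for organ-scale inducibility
pipelines: every mechanism — scar-as-insulator excision, border-zone slow
conduction, graft bridging, conduction-system bypass — is reproduced at
centimeter scale in minutes on one CPU.

## Model in brief

Propagation follows the monodomain reaction–diffusion equation
∂u/∂t = ∇·(**D**∇u) + f(u,h) with P1 finite elements, lumped mass and
operator splitting. The orthotropic tensor **D** = D_T I + (D_L−D_T)ffᵀ
uses region longitudinal diffusion D_L = 0.0013 (healthy), 0.000882
(border zone), 0.013 (conduction system) cm²/ms and transverse ratios
0.25 / 0.345; the graft is isotropic at a configurable fraction of
healthy. Membrane kinetics are a two-variable excitable surrogate
(Mitchell–Schaeffer class) calibrated per region so that emergent
quantities match measured porcine / hiPSC values: prepaced APD90 of
196–218 ms (healthy, by wall layer), 384 ms (border zone, with fast-Na
excitability at 38%), 310 ms (conduction system), 405 ms (graft), and
planar strand conduction velocities of 74.2 cm/s (healthy) and ≈12 cm/s
(immature graft). Inducibility is probed with 4 S1 stimuli at 600 ms
plus one extrastimulus at 250–295 ms, and scored as
IS = Σc/(3N), c ∈ {0,1,3} for {no reentry, non-sustained VT, sustained VT},
with non-captured trials excluded.

See `docs/methods.md` for the full model description, numerical choices
and limitations.

## Worked example

Run the shipped graft-bridge comparison — a transmural scar strip
splitting a 72×44 mm sheet, bridged by two graft patches — from the
shell:

```sh
ehtsim run-campaign src/ehtsim/data/scenarios/bridge-l1-c10.yaml --outdir out_c10
```

```
{
 "scenario": "bridge-l1-c10",
 "n_included": 1,
 "IS": 1.0,
 "provenance": {"config_hash": "…", "version": "0.1.0", "seed": 0}
}
```

IS = 1.0: the single programmed-stimulation trial ends in sustained VT —
the premature wave crawls through the immature graft bridge (≈170 ms per
crossing), re-emerges into recovered myocardium and circulates through
the two bridges indefinitely. The same scenario without the graft
(`bridge-mi.yaml`) or with matured C90 conductivity
(`bridge-l1-c90.yaml`) prints IS = 0.0 (no reentry): the scar halves are
electrically separate, respectively the faster crossing re-emerges into
refractory tissue. `ehtsim report` regenerates the whole comparison
table.

The same from Python:

```python
from ehtsim.workflow import shipped_scenario, run_scenario
report = run_scenario(shipped_scenario("bridge-l1-c10"))
print(report.score, report.table.label.tolist())   # 1.0 ['sVT']
```

Lower-level building blocks (`build_sheet`, `label_infarct`,
`excise_scar`, `attach_eht`, `couple_tree`, `run`, `cv_map`, …) are all
importable directly; `ehtsim calibrate` regenerates the default kinetics
calibration from scratch.

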