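# Methods

`ehtsim` assesses ventricular-tachycardia (VT) inducibility in synthetic
infarcted tissue before and after engineered-heart-tissue (EHT)
remuscularization, at desk scale. This note documents the model, its
assumptions, the parameters that matter, and what the synthetic substrate
does and does not capture.

## Tissue model

Electrical propagation follows the monodomain reaction–diffusion
equation,

∂u/∂t = ∇·(**D** ∇u) + f(u, h),

on simplicial meshes (triangulated 2D sheets by default; thin
tetrahedral slabs are available for layer-labeling studies). `u` is a
normalized transmembrane variable (0 ≈ −85 mV at rest, 1 ≈ +25 mV at
peak); **D** is an orthotropic diffusion tensor built per element from
the fiber direction **f** as D = D_T I + (D_L − D_T) **f f**ᵀ with
D_T = ρ·D_L. Region defaults (longitudinal diffusion in cm²/ms,
transverse ratio ρ):

| region | D_L (cm²/ms) | ρ | rationale |
|---|---|---|---|
| healthy (HZ) | 0.0013 | 0.25 | calibrated to a healthy porcine epicardial CV of 74.2 cm/s |
| border zone (BZ) | 0.000882 | 0.345 | post-infarct remodeling; reduced anisotropy |
| conduction system (CS) | 0.013 | 1 (1D cable) | fast Purkinje-like conduction (≈200 cm/s class) |
| graft (EHT) | fraction × HZ | 1 (isotropic) | immature C10 = 10%, matured C90 = 90% of HZ |

Scar (SZ) is an insulator: elements made purely of scar nodes are
excised, scar nodes shared with surviving elements are conservatively
retagged (most frequent non-scar label, border zone preferred on ties,
so slow-conducting isthmuses survive), and the excision surface
automatically receives the natural zero-flux boundary of the
finite-element formulation.

Geometry is internal millimetres and milliseconds; diffusion inputs are
specified in cm²/ms (the literature convention) and converted in exactly
one constant (`CM2_TO_MM2`), and velocities report in cm/s
(1 mm/ms = 100 cm/s). This conversion is deliberately centralized and
unit-tested — it is the highest-risk constant in the package.

## Surrogate membrane kinetics

A single two-variable excitable family (Mitchell–Schaeffer class)
replaces the biophysically detailed porcine, Purkinje and hiPSC-CM ionic
models. Written in the rest-shifted variable v = (u − u_rest)/(1 − u_rest):

du/dt = (1 − u_rest)[ s·h·v²(1−v)/τ_in − v/τ_out ],
dh/dt = (1−h)/τ_open below the gate (v < 0.13), −h/τ_close above it.

Design constraints that fixed the free constants:

- **τ_out = 30·τ_in.** The foot of the excitation threshold sits at
  v* ≈ τ_in/(s·τ_out) = 1/(30·s). With the border zone's s = 0.38 this
  keeps v* ≈ 0.09 below the gate (0.13), so 38%-excitability tissue
  still conducts (at ≈30 cm/s) while the rest state stays locally
  stable. Smaller ratios made the border zone block outright; larger
  ones destabilized rest at the fast upstroke rates the healthy CV
  demands. CV calibration therefore varies τ_in with τ_out tied to it.
- **Per-region calibration, not per-current fitting.** Only emergent
  quantities are pinned: τ_in is bisected until a 1D strand
  (20 mm, 0.1 mm spacing, probes at 5/15 mm) conducts at 74.2 cm/s at
  healthy diffusion; τ_close is bisected until the prepaced (600 ms
  cycle) APD90 hits the region target — 218/207/196 ms for
  endo/mid/epicardial healthy layers, 384 ms border zone, 310 ms
  conduction system, 405 ms graft. The graft gets its own (slower)
  upstroke rate, calibrated to 12 cm/s at 10% of healthy diffusion,
  consistent with immature hiPSC-CM tissue. Calibrations are
  deterministic bisections (APD tolerance 1 ms, CV tolerance 2%); the
  result ships as `ehtsim/data/default_calibration.json` and
  `ehtsim calibrate` regenerates it from scratch.
- **Bounded APD calibration bracket.** Past τ_close ≈ 0.75 of the
  pacing cycle the paced cell falls into 2:1-like alternans and the
  steady APD is no longer monotone in τ_close; the bisection bracket
  stops short of that regime and treats an alternans-collapsed APD as
  "too long".
- **Functional remodeling mapping.** The border zone's reduced fast-Na
  conductance (38% of normal) maps onto the excitability multiplier
  s = 0.38; its K1-mediated APD prolongation maps onto the 384 ms APD
  target. Both are the remodeling's functional consequences rather than
  channel-level parameters, which the surrogate does not resolve.
- **Elevated conduction-system diastolic potential.** The CS rests
  +3 mV above working myocardium. Writing the kinetics in the
  rest-shifted variable makes that offset an exact, locally stable fixed
  point; a biased-leak implementation instead self-excited, because at
  the calibrated upstroke rates the regenerative current's basin
  boundary sits only ≈3–4 mV above rest.
- **Graft automaticity (off by default).** A constant diastolic drift
  gated on near-complete gate recovery (h above a firing threshold
  derived from the requested intrinsic cycle length) gives slow
  spontaneous firing that saturates around 0.8–1.2 s cycle lengths and
  is overdrive-suppressed at the 600 ms pacing cycle. The mapping is
  order-of-magnitude by design; the tested contract is slow intrinsic
  rhythm plus suppression in paced, coupled tissue.

APD90 is measured between the upward and downward crossings of the
10%-of-amplitude level relative to the pre-stimulus baseline, with
linear interpolation between samples. Activation is the upward crossing
of u = 0.5 (≈ −30 mV) with positive slope — a convention the source data
never states, recorded here as an explicit assumption.

## Numerics

Godunov splitting per time step: explicit reaction (forward Euler on u,
exact exponential update on the gate) followed by an implicit
lumped-mass P1 finite-element diffusion solve, pre-factorized (sparse
LU) once per mesh. The step is fixed at dt = 0.05 ms (0.1 ms for the
long scenario campaigns), inside the conventional [0.01, 0.1] ms band;
reproducibility was preferred over adaptive stepping. Potentials are
sampled every 1 ms; activation events are recorded at full dt resolution
with linear interpolation. Halving dt changes the calibrated strand CV
by under 1%. Runs are bitwise deterministic for a fixed mesh and
configuration. Simulations terminate early once every stimulus has been
delivered and the tissue is provably quiescent (all nodes within 0.02 of
rest), which cannot alter any activation-based classification.

Stimulus convention: current density (µA/cm²) divided by membrane
capacitance (1 µF/cm²) gives mV/ms, normalized by the 110 mV span; the
standard pulse (80 µA/cm², 1 ms) is strongly suprathreshold, and
capture-threshold behavior, not absolute amplitude, is the tested
contract.

Discretization bias: at the 0.5 mm spacing used for sheet campaigns the
planar CV runs ≈7% below its 0.1 mm-strand calibration (63.9 at 1.0 mm,
68.9 at 0.5 mm, 71.9 at 0.25 mm vs 74.7 cm/s converged). Quantitative CV
targets are therefore always measured on 0.1 mm strands; sheet scenarios
are interpreted qualitatively (outcome classes), where a uniformly
slightly-slow medium does not change the mechanism.

## Conduction system and junctions

A seeded recursive bifurcation generator (depth-limited binary tree,
segment length decaying geometrically, angle jitter from a seeded RNG)
stands in for anatomical fractal-tree algorithms. The tree is a 1D cable
(mean element length 528 µm, cross-section weight 0.3 mm²) carrying the
fast CS diffusion, which tapers sigmoidally to the ventricular value
over the last 2 mm of each terminal branch — the taper exists to soften
source–sink mismatch at the junctions. Each endpoint couples resistively
to every viable myocardial node within 0.5 mm (anatomical reference
density ≈14.5 connections per endpoint); the total junction conductance
per endpoint (default 0.3 mm³/ms, split evenly across connections) was
chosen so the anterograde junction delay is ≈1 ms, the order observed in
the anatomical models, with retrograde conduction essentially
delay-free. Weakening the coupling lengthens the delay monotonically to
conduction block, reproducing junctional source–sink failure.

## Stimulation protocol and scoring

The inducibility protocol delivers four S1 stimuli at 600 ms from a
pacing site (all viable nodes within 1 mm of a seed), then one
extrastimulus S2 at 250/265/280/295 ms, and observes 2.5 s. Initial
states come from single-cell prepacing per region; the surrogate has no
slow ionic memory (convergence within ~5 beats, verified), so the
tissue-level S1 train suffices to reach the tissue steady state.

Outcome classification works from the activation-event set alone:

- **capture**: a fresh activation outside a guard radius (2× the site
  radius) within 50 ms of S2; otherwise NC (excluded from scoring);
- **reentry**: the direct S2 wavefront reaches everything within one
  tissue traversal, estimated as the 99th percentile of first post-S2
  activation times; a node re-activates if it fires at least twice after
  S2 with activity beyond that horizon, and reentry is called when ≥1%
  of post-S2-activated nodes re-activate (robust to boundary echo);
- **sustainment**: sVT if any activity persists to 2 s after S2, nsVT if
  reentry extinguished earlier, NR otherwise.

The inducibility score is IS = Σc/(3N), c ∈ {0, 1, 3} for
{NR, nsVT, sVT}, over the N included trials; evaluated in exact rational
arithmetic before conversion to float.

Pacing sites are placed algorithmically at equal angles on a ring just
outside the border zone (the anatomical segment-based site selection has
no analog on a slab).

## Synthetic substrate: what it emulates, what it does not

The generator reproduces the *statistical* features the mechanisms need:
a non-conducting scar core with a slow, long-APD border zone;
transmural/apicobasal harmonic layer coordinates thresholded 40:35:25
and (from the apex) 17:35:48; rotating fibers; an epicardial graft layer
resistively coupled to the host over its footprint (complete
engraftment), centered on the infarct (L1) or shifted by half a
footprint (L2); an endocardial conduction-system tree. It does not
reproduce ventricular anatomy, image-derived scar shapes, the He–Purkinje
hierarchy, bath loading, or mechanical deformation. Desk-scale sheets
are far smaller than a ventricle, so reentrant circuits must be
engineered geometrically (below); passing scenario regressions
demonstrates the *mechanisms*, not per-animal inducibility statistics,
which are out of reach at this scale by design.

## Shipped scenarios

Wavelength arithmetic drives the scenario geometry. With a border-zone
APD of 384 ms, any circuit through border zone needs a period ≳390 ms —
longer than any path a desk-scale sheet affords — so reentry here rides
on the two slow-conducting structures that create long delays in little
space: the immature graft (≈12 cm/s: 20 mm of freestanding graft buys
≈170 ms) and functional APD shortening at short cycle lengths.

1. **healthy-control** — uniform sheet; every S2 yields NR.
2. **infarct-reentry** (baseline-infarct analog) — a large elliptical
   transmural scar with a border-zone rim on a 100×70 mm sheet; the
   premature wave blocks in the still-refractory rim, breaks, and
   circulates around the obstacle (perimeter ≳130 mm, loop period
   ≳200 ms, sustainable thanks to restitution).
3. **cs-flip pair** (CS-contrast analog) — the isthmus substrate with
   (`cs-enables`) and without (`isthmus-reentry`) the conduction-system
   tree. The fast bypass is open during the 600 ms drive but refractory
   at every extrastimulus coupling ≤ 295 ms (CS APD 310 ms), so the S1
   and S2 activation sequences differ; together with the CS acting as a
   recovered return limb during slow reentry, the tree upgrades the
   non-sustained channel reentry to sustained VT. The *suppressing*
   direction — a CS configuration that lowers the outcome class — did
   not reproduce in this surrogate despite an extensive search (junction
   weights spanning the conducting range, spanning/dense/channel-confined
   trees, every S2 offset, bridge and isthmus substrates): because the
   working-myocardium excitation threshold must sit low for the
   38%-excitability border zone to conduct, any junction whose CS-side
   plateau outlasts the local refractory period re-excites its
   surroundings (the capacitive effect), and the CS is monotonically
   pro-arrhythmic here. The corresponding regression is shipped and
   deliberately failing, as an honest record of the surrogate's limit.
4. **bridge L1/L2 × C10/C90** (graft-placement and maturation analog) —
   a fully transmural scar strip splits the sheet; two immature graft
   patches bridge it. The S2 wave crawls through the freestanding graft
   (≈170 ms per crossing), re-emerges into recovered myocardium, and a
   sustained figure-of-eight through the two bridges results (sVT).
   Without the graft the two halves are electrically separate (NR); at
   C90 the crossing is ≈3× faster, the wave re-emerges into refractory
   tissue, and reentry is abolished (NR) — electrical maturation as an
   antiarrhythmic intervention.

Each shipped scenario pins its expected outcome class as a regression.

## Known limitations

- The surrogate has no ionic concentrations, no calcium handling, no
  afterdepolarization mechanisms; only APD/CV phenomenology.
- Automaticity cycle-length mapping saturates near ~1 s.
- The intrinsic CS cycle, drug effects and post-infarct CS remodeling
  are out of scope.
- 2D bilayer grafts share host coordinates (zero geometric offset); the
  interlayer link conductance stands in for the 0.5–0.6 mm embedding.
- Inducibility scores from desk-scale scenario sets are not comparable
  to whole-heart per-subject scores; only formula exactness and
  mechanism reproduction are claimed.
- The conduction system never *reduces* inducibility in this surrogate
  (see the scenario section): junctional protection requires ionic
  detail (sodium inactivation, transitional-cell source–sink asymmetry)
  that a two-variable model does not carry.
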