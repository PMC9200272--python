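# Methods

`calyxnano` couples two computational engines: quantitative analysis of the
nanoscale organization of synaptic proteins from 3D single-molecule
localization (STORM) data, and a particle-based Monte Carlo model of quantal
glutamatergic transmission at a calyx of Held-type synapse. This note
documents the models, the parameters that matter, the numerical choices, and
the limits of what the synthetic-data tests demonstrate.

## Localization analysis

**Input model.** A synapse is a disc-shaped cloud of localizations
(x, y, z in nm) for one protein channel. Real data carry anisotropic
localization error (σ ≈ 10–15 nm laterally, 40–50 nm axially); the analysis
never rescales z — all distances are plain 3D Euclidean distances, matching
the convention of the field's cluster analyses. A `z_weight` flag exists for
sensitivity analyses only.

**Background removal.** Nearest-neighbor distances (NND) are computed for
all localizations; points closer than mean(NND) + 2·sd(NND) are linked
(single linkage) and the largest connected component is the synaptic
cluster. Equal-size ties are resolved toward the component whose centroid is
nearest the origin, making the step deterministic.

**Borders and volumes.** The synaptic-cluster border is the 3D alpha shape
at α = 150 nm: the union of Delaunay tetrahedra with circumradius ≤ α.
Volume is the summed tetrahedral volume; the border is the set of faces
belonging to exactly one kept tetrahedron. Nanocluster volumes use the same
α with a convex-hull fallback for small member sets (8–20 points) whose
alpha complex is empty or fragmented.

**Local density and nanocluster detection.** Each localization's local
density is the count of neighbors within 2.5× the median NND, excluding the
point itself (so the homogeneous-null mean matches the Poisson expectation
ρ·(4/3)πr³). The detection threshold is mean(LD0) + 4·sd(LD0), where LD0
pools the local densities of 20 uniform resamplings of the same number of
points inside the cluster's own alpha shape, evaluated at the observed
counting radius. Supra-threshold points are split top-down: candidate peaks
are local maxima of the density field; the closest peak pair is repeatedly
merged (the weaker peak dropped; ties keep the lower index) until all peaks
are ≥ 80 nm apart; members join the nearest surviving peak; groups with
fewer than 8 members are discarded. The reported peak is the
local-density-weighted centroid of the members. The randomization count (20)
and all thresholds are arguments, not constants.

**Trans-synaptic alignment.** Each synapse is rotated into its *en face*
frame by principal axes (disc plane = two largest-variance axes); clouds
with an in-plane/normal variance ratio below 1.2 are flagged as having no
well-defined plane. The cross-channel enrichment profile is the target
channel's areal density in 20-nm annuli (0–200 nm) around each reference
nanocluster peak, with annulus areas clipped to the synapse footprint
(convex hull) so edge bins are not biased low, normalized by the synapse's
own mean target density (1 = no enrichment). Empty annuli are reported as
missing and excluded from averaging. Rescaling a profile so the 140-nm bin
reads 0.5 is available only as an export step for simulator placement
profiles.

## Quantal simulator

**Geometry.** The cleft is the 28-nm gap between two coaxial discs of
radius 250 nm (a 0.5-µm lateral extent read as the cylinder diameter — the
source wording is ambiguous and the value is configurable). The PSD disc
(radius 140 nm, matching the outer receptor subregion boundary) carries 100
receptors, each a flat disc of radius 10 nm; discs may overlap. A glial
sheath stands 40 nm beyond the synaptic edge; each molecule contact with it
is absorbed with probability p = min(1, ρ_T·π·r_T²) — the area-coverage
approximation of a uniform transporter density ρ_T = 5000/µm² with capture
radius r_T = 5 nm, giving p ≈ 0.39. Pre- and postsynaptic membranes reflect.

**Release.** A vesicle holds 8000 glutamate molecules (P12 value) and
empties at a constant rate over τ = 73/γ µs, where γ is the fusion-pore
conductance in nS; at the measured γ = 0.375 nS, τ ≈ 0.2 ms. Integer
per-step counts come from accumulated-remainder rounding and sum exactly to
the vesicle content; exponential emptying is available behind a flag.
Release sites are uniform over the synaptic-cluster disc for spontaneous
events (mEPSC) and over the 60-nm nanocluster disc for evoked events
(EPSC).

**Diffusion and hits.** Free molecules take Gaussian steps with per-axis
variance 2·D·dt (D = 0.4 µm²/ms, dt = 0.5 µs; rms step ≈ 20 nm/axis). A
*hit* is a step whose path crosses the postsynaptic plane inside a receptor
disc; the crossing point is linearly interpolated, the molecule is
reflected, and overlapping discs each register the crossing (reflection does
not consume the molecule, so receptors do not compete). With multiple plane
contacts in one step (the rms step is comparable to the cleft height), only
the first crossing position is used; this discretization error is at the
scale of the lateral step (≈14 nm) and is shared by all conditions.

**Binding calibration.** Under a homogeneous concentration C, the expected
number of crossings through a disc of area A per step is C·A·σ/√(2π)
(σ = per-axis step s.d.). Each hit therefore represents a fixed
concentration increment C_hit = 1/(N_A·A·σ/√(2π)), and a binding transition
with rate constant k_on contributes k_on·n_hits·C_hit·dt to the per-step
transition load — so the expected binding rate reproduces k_on·C exactly,
with no free parameter. The crossing-rate formula is itself verified
against brute-force segment–disc counting in the test suite.

**Receptor gating.** Each receptor runs a nine-state Markov chain
(C0–C1–C2–O with an open-adjacent desensitized state and a liganded
desensitized branch D1–D4; two binding steps plus one on the desensitized
branch). Per step, the total outgoing load Q = Σ λ_j·dt gives a jump
probability 1 − e^(−Q); at most one transition fires per receptor per step,
chosen proportionally to the λ_j (competing risks). A guard rejects any
concentration-independent rate with rate·dt > 0.1. The single cycle
(C1–C2–D2–D1) satisfies microscopic reversibility by construction — the
D2→D1 unbinding rate is derived from the other cycle rates — and a
cycle-basis check validates arbitrary user-supplied tables. Uniform scaling
of all rates (the KO fit uses 0.6) preserves reversibility exactly.

**Rate tables.** Rates are configuration data. The defaults describe a
fast-gating class (GluA4-like, 45 pS) and a slow-gating class (GluA1-like,
31 pS). Binding k_on = 3/(mM·ms) (within the published AMPAR range); the
gating rates were calibrated, within microscopic reversibility, against the
constraints the model is asked to reproduce: ≈65% fast-receptor share of
the peak current at a 29:21 fast:slow ratio, a ≈50% amplitude cost of
scaling all rates by 0.6 under the redistributed placement, monotonically
decreasing decay across the developmental ratios, and an mEPSC with ≈0.2 ms
10–90% rise and sub-millisecond decay. Any alternative table can be loaded
from YAML.

**Current.** I(t) = Σ_type g_type·n_open,type(t)·(V_m − V_rev) with
g = 45/31 pS, V_m = −60 mV, V_rev = 0 — ten open fast receptors give
−27 pA.

**Receptor placement.** Receptors are apportioned to three concentric
subregions (0–60, 60–100, 100–140 nm) with counts proportional to annulus
area × relative density, realized exactly by largest-remainder rounding,
and placed uniformly within each annulus. The control profile (3, 1, 1)
yields 40 receptors inside 60 nm — a threefold areal density contrast; a
KO-like redistribution uses a flattened profile (default 1.5, 1, 1 —
illustrative, as the measured redistribution is condition-specific).
Slow/fast labels (0.45/0.55 at P12) are assigned by a seeded permutation
independent of position, so changing the ratio under a common seed relabels
the minimum number of receptors.

**Averaging and metrics.** Averaged responses use independently seeded runs
(default 160, matching the standard averaging depth; cheaper defaults are
used in tests) with release sites redrawn per run. One global seed fans out
to per-run child seeds; the receptor-state sampler consumes a fixed number
of RNG draws per receptor-step, so two conditions simulated with the same
seed share identical diffusion streams — common random numbers, which is
what makes small between-condition contrasts resolvable. Metrics are
computed on the mean trace: amplitude is the absolute peak; the 10–90% rise
time is interpolated on the rising phase (model-free — more robust than a
fitted rise on stochastic traces); the decay is an amplitude-weighted
double-exponential fit from the peak down to 1% of the peak, with time
constants bounded by twice the fitted span and a flagged 1/e fallback. The
1%-floor truncation exists because rare re-openings from desensitized
states leave a sub-percent tail that otherwise drags the slow time constant
to arbitrarily large values.

**Deterministic (well-mixed) route.** For questions about the kinetic
scheme itself, the package integrates the rate equations against the
volume-averaged free-glutamate transient of seeded runs and mixes per-type
open probabilities by receptor counts. This noise-free route is used to
assert the strict decay ordering across all five developmental ratios: the
adjacent 11:9 and 29:21 ratios differ by ~2% in expected decay, below the
sampling noise of any practical stochastic run count, so the stochastic
sweep is only required to reproduce the ordering across the well-separated
ratios.

## Synthetic data: what it does and does not establish

The generators plant disc-shaped clusters with known nanocluster positions,
enrichment factors, background fractions and noise, plus paired channels
with controlled cross-channel alignment (aligned / laterally offset /
independent). Passing tests therefore establish that the detection and
profiling recover *planted* structure under realistic noise — they do not
establish performance on real STORM artifacts that are deliberately out of
scope: fluorophore blinking (multiple localizations per molecule beyond
what the ≥8-member filter absorbs), drift residuals, PSF-shape effects, or
z-dependent detection efficiency.

## Numerical and design choices

* Null randomizations: 20 per cluster; the threshold stabilizes to well
  below the 4-SD band width at this depth.
* Alpha-complex inclusion tests use the Delaunay triangulation's simplex
  lookup; uniform sampling inside the complex is per-tetrahedron by volume.
* The false-positive rate of detection on homogeneous clusters is bounded
  by the Gaussian-tail expectation of the 4-SD threshold and verified
  empirically (≤10% of seeds yield any nanocluster).
* Receptor discs may overlap (the source geometry is silent on exclusion);
  a flag enables non-overlapping placement by rejection.
* The simulation records every step (0.5 µs) in memory and decimates to
  10 µs on export.
* Problem sizes in the shipped analyses (8 synapses/group, 48–96 runs per
  condition) were chosen so the full pipeline runs on a laptop-class single
  core in minutes while keeping the reported contrasts several standard
  errors wide; the paper-depth 160-run averaging is one argument away.

## Known limitations

* The cleft is laterally closed at the glial wall; there is no open
  extrasynaptic space beyond it, so late rebinding from escaped glutamate
  is absent.
* Transporters are a probabilistic absorbing wall, not explicit kinetic
  binding sites; uptake saturation cannot occur.
* The nine-state rate tables are calibrated defaults, not fitted to any
  recorded traces shipped with the package; conclusions about absolute
  amplitudes are weaker than conclusions about contrasts between conditions
  sharing a table.
* mEPSC and EPSC differ only in release-site dispersion; multivesicular
  release, trains and short-term plasticity are out of scope.
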