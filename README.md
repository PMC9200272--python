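# calyxnano

Tools for asking how the *nanoscale arrangement* of synaptic proteins sets
the strength and speed of synaptic transmission, built around the calyx of
Held — the giant auditory brainstem synapse where AMPA-type glutamate
receptors (AMPARs), their PSD-95 scaffold, and the presynaptic release
machinery (RIM1) are organized into aligned nanoclusters. The package is
aimed at people analyzing 3D single-molecule localization (STORM) data of
synaptic proteins and at modelers linking that organization to quantal
currents.

Two engines share one code base:

1. **Localization analysis** — from a table of 3D localizations (nm):
   background removal by a nearest-neighbor-distance (NND) cutoff
   (mean + 2 SD, single linkage, keep the primary subcluster); synaptic
   cluster border and volume from the 3D alpha shape at α = 150 nm; a
   per-point local density (neighbors within 2.5× the median NND);
   nanoclusters as points above mean(LD₀) + 4·sd(LD₀) of a uniform
   randomized null, split at density peaks ≥ 80 nm apart with ≥ 8 members;
   and trans-synaptic alignment as the normalized density of a target
   channel vs distance from reference nanocluster peaks in the en face
   plane.

2. **Quantal simulator** — a Monte Carlo model of one vesicle's glutamate
   (8000 molecules, emptied over τ = 73/γ µs) diffusing in a 28-nm cleft
   (D = 0.4 µm²/ms, 0.5-µs steps), taken up at a surrounding glial wall
   (5000 transporters/µm²), and gating 100 fast (45 pS) and slow (31 pS)
   AMPARs, each a nine-state Markov chain obeying microscopic
   reversibility. The current is I(t) = Σ g·n_open(t)·(V_m − V_rev); mean
   traces are quantified by peak amplitude, 10–90% rise time and an
   amplitude-weighted double-exponential decay time.

A synthetic-data module generates localization clusters with planted
nanoclusters, paired channels with controlled alignment, and receptor
placements, so every stage is testable without microscope data.

## Worked example

Detect nanoclusters in a synthetic two-channel synapse and simulate the
quantal response of the control vs a redistributed receptor placement:

```python
from calyxnano.synth import SyntheticClusterSpec, generate_synaptic_cluster, generate_receptor_map
from calyxnano.clusters import make_synaptic_cluster, detect_nanoclusters, cluster_report
from calyxnano.sim import SimConfig, average_traces
from calyxnano.sim.metrics import metrics_of

spec = SyntheticClusterSpec(n_localizations=2000,
                            nanocluster_centers=((-75.0, 0.0), (75.0, 0.0)),
                            enrichment_factor=5.0, seed=42)
cluster = make_synaptic_cluster(generate_synaptic_cluster(spec))
ncs = detect_nanoclusters(cluster, seed=1)
rep = cluster_report(cluster, ncs)
print(rep.n_nanoclusters, round(rep.fraction_locs_in_nc, 2))

rm = generate_receptor_map(relative_densities=(3.0, 1.0, 1.0),
                           slow_fast_ratio=(0.45, 0.55), seed=0)
trace, _ = average_traces(SimConfig(receptor_map=rm), n_runs=64, seed=1)
m = metrics_of(trace)
print(f"{m.peak_amplitude_pA:.1f} pA, rise {m.rise_10_90_us:.0f} us, decay {m.decay_tau_us:.0f} us")
```

prints

```
2 0.27
19.7 pA, rise 154 us, decay 983 us
```

— the two planted nanoclusters are recovered, with 27% of localizations
inside them, and the control placement (threefold receptor density inside
60 nm) produces a ~20-pA mEPSC with a ~0.15-ms rise and ~1-ms decay.

The `analysis/` directory holds the narrative drivers
(`01_synthesize_localizations.py` … `05_cohort_summary.py`): synthetic
cohort generation, nanocluster detection, enrichment profiling, the
simulation experiments (P16 fast/slow decomposition, the developmental
fast:slow sweep, the KO redistribution and rate-scaling comparison), and
the descriptive cohort summary. Each writes its tables under `results/`.
A `calyxnano` CLI exposes the same stages
(`synthesize`, `analyze-clusters`, `alignment-profile`, `simulate-quantal`,
`run-all`).

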