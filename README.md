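# scramblekit

Tools for quantifying phospholipid scramblase activity from two directions
at once:

1. **Flip-flop counting in coarse-grained membrane simulations.** Given a
   bilayer trajectory (GRO + XTC, or a plain-text internal format), the
   package computes each lipid's orientation angle — the bisector of the two
   head-to-tail-end vectors measured against the bilayer normal — smooths it
   over 50 ns windows resampled every 25 ns, and counts *scrambling events*:
   crossings of the whole 55°–125° buffer region, meaning one complete
   leaflet inversion. Events are aggregated into events/µs across
   replicates and characterized further: per-residue contact fractions and
   dwell times within 5 Å of the translocating phosphate bead, and the
   phosphate's height above the membrane midplane through the crossing.

2. **Kinetics of the fluorescence scramblase assay.** Reconstituted
   vesicles carrying a trace NBD-labelled phospholipid are interrogated
   with a topological probe: dithionite (chemically quenches outer-leaflet
   reporter) or fatty-acid-free BSA (extracts outer-leaflet reporter, which
   then fluoresces at ~40 % of its in-membrane intensity). The package
   models each vesicle as two exchanging lipid pools,

   ```
   dO/dt = −k_probe·O + k_scr·(I − O)        (k_scr > 0 only in
   dI/dt =           − k_scr·(I − O)          scramblase-active vesicles)
   ```

   with fluorescence F = I + O + qf·(1 − I − O), solved in closed form as a
   sum of exponentials. It predicts plateaus (protein-free dithionite: 50 %
   loss; fully scrambling: 100 %; BSA: 30 % / 60 %), simulates traces, fits
   mono-/bi-exponential decays (fast phase = probe reaction, t½ ≈ 12 s;
   slow phase = scrambling), and inverts the plateau algebra to estimate
   the fraction of scramblase-active vesicles.

A synthetic-data module generates angle series and bead-level trajectories
with an exact ground-truth flip log (Poisson-distributed inversions,
logistic transits, aborted buffer excursions, angular noise) and assay
traces with known rate constants, so every stage of both pipelines is
testable without external simulation data.

Intended users: membrane biophysicists analyzing Martini-style bilayer
simulations for lipid scrambling, and experimentalists fitting
dithionite/BSA assay traces.

## Worked example

`examples/detect_flip_events.py` generates a 100-lipid, 10 µs synthetic
bilayer (1 flip/lipid/µs, 15° angular noise, 30 % aborted excursions) and
runs the full detector:

```
ground-truth events: 1032
detected events:     1032 (516 up->down, 516 down->up)
trajectory rate:     103.2 events/µs over 10 µs
per-lipid rate:      1.03 flips/lipid/µs (generator set 1.0)
```

Every generated inversion was recovered, no spurious events were counted
(aborted buffer excursions are correctly ignored), and the per-lipid rate
matches the generating rate. `examples/fit_assay_trace.py` shows the assay
arm — fitting a noisy simulated dithionite trace recovers the probe phase
(t½ ≈ 12 s), the slow scrambling phase (t½ ≈ 400 s) and the active-vesicle
fraction (0.70 recovered from a 0.70 ground truth); the other examples
cover plateau prediction and event anatomy.

A thin CLI wraps the same functions: `scramblekit traj-gen`,
`scramblekit flip detect|rate|contacts|ztrace`,
`scramblekit assay simulate|fit|compare`, and `scramblekit run --config
cfg.yaml` for reproducible config-driven chains.

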