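"""Characterize one flip event: residue contacts and the phosphate z-trace.

Builds a small bead trajectory with one scripted inversion and two static
labelled protein beads (one beside the translocation path, one far away),
then reports which residues the translocating phosphate contacted within
5 Å, their dwell times, and the head-bead height relative to the membrane
midplane through the crossing.
"""

import numpy as np

from scramblekit import synthetic
from scramblekit.flip import contact_profile, phosphate_z_trace
from scramblekit.types import FlipEvent, SynthTrajParams

params = SynthTrajParams(n_lipids=8, duration=600.0, flip_rate=0.0,
                         angle_noise_sd=0.0, leaflet_split=0.5, seed=0)
traj, topo, log = synthetic.generate_bead_trajectory(
    params,
    scripted_flips=[(0, 200.0)],  # lipid 0 inverts between 200 and 300 ns
    decoys=[
        ("TYR32", (4.0, 7.0, 40.0)),    # 3 Å from the crossing point
        ("THR123", (4.0, 34.0, 40.0)),  # 30 Å away
    ],
)
ev = log.events[0]
event = FlipEvent(ev.lipid_id, ev.start_ns, ev.end_ns, ev.direction)

profile = contact_profile(traj, topo, [event], cutoff=5.0, margin_ns=10.0)
print("per-residue contact fractions over the event window (5 Å cutoff):")
print(profile.fractions.to_string(index=False))

times, z = phosphate_z_trace(traj, topo, event, margin_ns=20.0)
mid = np.argmin(np.abs(z))
print(f"\nphosphate z-offset: {z[0]:+.1f} Å at {times[0]:.0f} ns  ->  "
      f"{z[-1]:+.1f} Å at {times[-1]:.0f} ns")
print(f"midplane crossing near t = {times[mid]:.0f} ns "
      f"(event window {ev.start_ns:.0f}-{ev.end_ns:.0f} ns, {ev.direction})")
print(
    "\nResidues lining the translocation path show contact fractions near 1"
    "\nwith dwell times spanning the transit; distant residues show 0. The"
    "\nz-trace changes sign exactly once as the head group crosses the"
    "\nbilayer midplane."
)
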