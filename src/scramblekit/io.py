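"""Readers and writers for trajectories, event tables, rates and traces.

Two trajectory representations are supported: a plain-text internal format
(JSON header + tab-separated bead coordinates, inspectable with any text
tool) and standard GRO + XTC pairs through MDAnalysis.  All column headers
carry unit suffixes; trajectory times are ns, assay times are s.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, TopologyError
from .types import (
    FlipEvent,
    FluorescenceTrace,
    GroundTruthLog,
    LipidTopology,
    RateResult,
    Trajectory,
    events_to_frame,
)

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_gro_xtc",
    "load_gro_xtc",
    "topology_from_beads",
    "write_events",
    "read_events",
    "write_truth",
    "write_rates",
    "write_trace",
    "read_trace",
]

_MAGIC = "#scramblekit-traj"


# ---------------------------------------------------------------- internal

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Plain-text trajectory: one JSON header line, then TSV coordinates."""
    path = Path(path)
    header = {
        "version": 1,
        "box_A": traj.box.tolist(),
        "times_ns": traj.times.tolist(),
        "beads": traj.beads.to_dict(orient="records"),
    }
    with path.open("w") as fh:
        fh.write(f"{_MAGIC} {json.dumps(header)}\n")
        fh.write("frame\tbead_id\tx_A\ty_A\tz_A\n")
        n_frames, n_beads, _ = traj.coords.shape
        flat = traj.coords.reshape(n_frames * n_beads, 3)
        frames = np.repeat(np.arange(n_frames), n_beads)
        beads = np.tile(np.arange(n_beads), n_frames)
        df = pd.DataFrame(
            {
                "frame": frames,
                "bead_id": beads,
                "x_A": flat[:, 0],
                "y_A": flat[:, 1],
                "z_A": flat[:, 2],
            }
        )
        df.to_csv(fh, sep="\t", index=False, header=False, float_format="%.4f")


def read_trajectory(path: str | Path) -> tuple[Trajectory, LipidTopology]:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith(_MAGIC):
            raise InputError(f"{path} is not a scramblekit trajectory file")
        header = json.loads(first[len(_MAGIC) :])
        df = pd.read_csv(
            fh,
            sep="\t",
            names=["frame", "bead_id", "x_A", "y_A", "z_A"],
            skiprows=1,
        )
    beads = pd.DataFrame(header["beads"])
    times = np.asarray(header["times_ns"], dtype=float)
    n_frames, n_beads = times.size, len(beads)
    if len(df) != n_frames * n_beads:
        raise InputError(
            f"{path}: expected {n_frames * n_beads} coordinate rows, got {len(df)}"
        )
    coords = (
        df.sort_values(["frame", "bead_id"])[["x_A", "y_A", "z_A"]]
        .to_numpy()
        .reshape(n_frames, n_beads, 3)
    )
    traj = Trajectory(
        times=times,
        coords=coords,
        box=np.asarray(header["box_A"], dtype=float),
        beads=beads,
    )
    return traj, topology_from_beads(beads)


def topology_from_beads(beads: pd.DataFrame) -> LipidTopology:
    """Build a LipidTopology from a bead table (head + exactly two tail ends)."""
    head: dict[int, int] = {}
    tails: dict[int, list[int]] = {}
    protein: dict[int, str] = {}
    for row in beads.itertuples():
        if row.kind == "protein":
            protein[int(row.bead_id)] = str(row.residue)
        elif row.role == "head":
            if int(row.lipid_id) in head:
                raise TopologyError(f"lipid {row.lipid_id} has two head beads")
            head[int(row.lipid_id)] = int(row.bead_id)
        elif row.role == "tail_end":
            tails.setdefault(int(row.lipid_id), []).append(int(row.bead_id))
    for lid in head:
        if len(tails.get(lid, [])) != 2:
            raise TopologyError(
                f"lipid {lid} must have exactly two tail-end beads, "
                f"found {len(tails.get(lid, []))}"
            )
    return LipidTopology(
        head_index=head,
        tail_end_indices={lid: (t[0], t[1]) for lid, t in tails.items()},
        protein_residues=protein,
    )


# ---------------------------------------------------------------- GRO/XTC

def write_gro_xtc(traj: Trajectory, gro_path: str | Path, xtc_path: str | Path) -> None:
    """Export to a GRO coordinate file (first frame) plus an XTC trajectory.

    MDAnalysis native units apply on disk (Å positions handled internally,
    ps times); scramblekit's ns timestamps are converted on the way out.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n_atoms = len(traj.beads)
    resindex = np.zeros(n_atoms, dtype=int)
    resnames, resids, names = [], [], []
    res_seen: dict[tuple, int] = {}
    for row in traj.beads.itertuples():
        if row.kind == "lipid":
            key = ("DOPC", int(row.lipid_id))
            rname, rid, aname = "DOPC", int(row.lipid_id) + 1, str(row.residue)
        else:
            m = re.match(r"([A-Za-z]+)(\d+)$", str(row.residue))
            rname = m.group(1)[:4].upper() if m else str(row.residue)[:4].upper()
            rid = int(m.group(2)) if m else 9000 + len(res_seen)
            key = (rname, rid)
            aname = "BB"
        if key not in res_seen:
            res_seen[key] = len(res_seen)
            resnames.append(rname)
            resids.append(rid)
        resindex[int(row.bead_id)] = res_seen[key]
        names.append(aname)
    u = mda.Universe.empty(
        n_atoms,
        n_residues=len(resnames),
        atom_resindex=resindex,
        trajectory=False,
    )
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    dims = np.tile(np.array([*traj.box, 90.0, 90.0, 90.0]), (traj.n_frames, 1))
    dt_ps = (
        float(traj.times[1] - traj.times[0]) * 1000.0 if traj.n_frames > 1 else 1.0
    )
    u.load_new(
        traj.coords.astype(np.float32),
        format=MemoryReader,
        dimensions=dims,
        dt=dt_ps,
    )
    with mda.Writer(str(gro_path), n_atoms) as w:
        w.write(u.atoms)
    with mda.Writer(str(xtc_path), n_atoms) as w:
        for _ in u.trajectory:
            w.write(u.atoms)


def load_gro_xtc(
    gro_path: str | Path,
    xtc_path: str | Path | None = None,
    head_name: str = "PO4",
    tail_end_names: Sequence[str] = ("C4A", "C4B"),
    lipid_resnames: Sequence[str] = ("DOPC",),
) -> tuple[Trajectory, LipidTopology]:
    """Read a GRO (+ optional XTC) pair into the internal representation.

    Lipids are residues whose resname is in ``lipid_resnames``; the head is
    the bead named ``head_name``, tail ends the two beads named in
    ``tail_end_names``.  All other beads are treated as protein, labelled
    RESNAME+resid.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(gro_path), str(xtc_path)) if xtc_path else mda.Universe(
        str(gro_path)
    )
    rows = []
    head: dict[int, int] = {}
    tails: dict[int, list[int]] = {}
    protein: dict[int, str] = {}
    lipid_counter: dict[int, int] = {}
    for atom in u.atoms:
        idx = int(atom.index)
        if atom.resname in lipid_resnames:
            lid = lipid_counter.setdefault(int(atom.resindex), len(lipid_counter))
            if atom.name == head_name:
                role = "head"
                head[lid] = idx
            elif atom.name in tail_end_names:
                role = "tail_end"
                tails.setdefault(lid, []).append(idx)
            else:
                role = "tail_mid"
            rows.append((idx, "lipid", lid, role, atom.name))
        else:
            label = f"{atom.resname}{atom.resid}"
            protein[idx] = label
            rows.append((idx, "protein", -1, "protein", label))
    missing = [lid for lid in lipid_counter.values() if lid not in head]
    missing += [
        lid for lid in lipid_counter.values() if len(tails.get(lid, [])) != 2
    ]
    if missing:
        raise TopologyError(
            f"lipid(s) {sorted(set(missing))} lack a {head_name} head or two "
            f"{'/'.join(tail_end_names)} tail-end beads"
        )
    n_frames = len(u.trajectory)
    coords = np.empty((n_frames, len(u.atoms), 3))
    times = np.empty(n_frames)
    box = None
    for i, ts in enumerate(u.trajectory):
        coords[i] = ts.positions
        times[i] = ts.time / 1000.0  # ps -> ns
        if box is None:
            box = ts.dimensions[:3].astype(float).copy()
    if n_frames > 1 and times[1] <= times[0]:
        times = np.arange(n_frames, dtype=float)  # reader had no time metadata
    beads = pd.DataFrame(
        rows, columns=["bead_id", "kind", "lipid_id", "role", "residue"]
    )
    traj = Trajectory(times=times, coords=coords, box=box, beads=beads)
    topo = LipidTopology(
        head_index=head,
        tail_end_indices={lid: (t[0], t[1]) for lid, t in tails.items()},
        protein_residues=protein,
    )
    return traj, topo


# ---------------------------------------------------------------- tables

def write_events(events: Sequence[FlipEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events(path: str | Path) -> list[FlipEvent]:
    df = pd.read_csv(path)
    required = {"lipid_id", "start_ns", "end_ns", "direction"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: event CSV needs columns {sorted(required)}")
    return [
        FlipEvent(
            lipid_id=int(r.lipid_id),
            start_ns=float(r.start_ns),
            end_ns=float(r.end_ns),
            direction=str(r.direction),
        )
        for r in df.itertuples()
    ]


def write_truth(log: GroundTruthLog, path: str | Path) -> None:
    log.to_frame().to_csv(path, index=False)


def write_rates(result: RateResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def write_trace(trace: FluorescenceTrace, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# probe_addition_time_s={trace.probe_addition_time_s}\n")
        pd.DataFrame(
            {"time_s": trace.times_s, "intensity": trace.intensity}
        ).to_csv(fh, index=False)


def read_trace(path: str | Path) -> FluorescenceTrace:
    path = Path(path)
    t_add = 0.0
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        if line.startswith("#"):
            m = re.search(r"probe_addition_time_s=([-\d.eE+]+)", line)
            if m:
                t_add = float(m.group(1))
        else:
            fh.seek(pos)
        df = pd.read_csv(fh)
    if not {"time_s", "intensity"}.issubset(df.columns):
        raise InputError(f"{path}: trace CSV needs columns time_s, intensity")
    return FluorescenceTrace(
        times_s=df["time_s"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        probe_addition_time_s=t_add,
    )
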