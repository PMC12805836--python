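"""Synthetic trajectories and assay traces with exact ground truth.

The generator emulates the statistical structure of a Martini-style DOPC
bilayer interrogated for scrambling: each lipid has an orientation angle
(tail bisector against the bilayer normal) that rests near 0° (lower
leaflet, tails up) or 180° (upper leaflet, tails down) with frame-to-frame
angular jitter, and occasionally undergoes an excursion through the
55°-125° buffer region.  Completed excursions are leaflet inversions
(flip-flops); a configurable fraction abort inside the buffer and return.
Completed events form a Poisson process per lipid at ``flip_rate``
(excursions are scheduled at rate flip_rate/(1-backslide_prob) and thinned
by abortion); overlapping excursions are queued so one lipid is never in
two transits at once.  Everything the generator injects is returned in a
:class:`GroundTruthLog`, making detector sensitivity and false-positive
rates measurable exactly.

A bead-level generator realizes the same angle program geometrically
(one phosphate head bead, two tails of two beads each) so the full
pipeline — trajectory in, events out — can be exercised, including
optional static "decoy" protein beads for contact-profile tests.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .types import (
    AbortedExcursion,
    AngleSeries,
    AssayParams,
    FluorescenceTrace,
    GroundTruthEvent,
    GroundTruthLog,
    LipidTopology,
    SynthTrajParams,
    Trajectory,
)

__all__ = [
    "generate_angle_series",
    "generate_bead_trajectory",
    "generate_assay_trace",
]

# geometry of the synthetic coarse-grained lipid (Å)
_TAIL_LENGTH = 16.0
_TAIL_SPLAY_DEG = 25.0
_LEAFLET_HALF_THICKNESS = 18.0
_GRID_SPACING = 8.0
_BOX_Z = 80.0

_BUFFER_LO, _BUFFER_HI = 55.0, 125.0  # aborted excursions peak inside this band


def _logistic_ramp(n: int) -> np.ndarray:
    """Monotone 0->1 ramp on n samples, exactly 0 and 1 at the ends."""
    x = np.linspace(-4.0, 4.0, n)
    s = 1.0 / (1.0 + np.exp(-x))
    return (s - s[0]) / (s[-1] - s[0])


class _Excursion:
    __slots__ = ("start", "end", "completed", "peak")

    def __init__(self, start: float, end: float, completed: bool, peak: float = 0.0):
        self.start, self.end, self.completed, self.peak = start, end, completed, peak


def _schedule_lipid(
    rng: np.random.Generator, params: SynthTrajParams
) -> list[_Excursion]:
    """Queueing construction: excursion attempts arrive as a Poisson process
    (rate flip_rate/(1-backslide_prob) per µs); an attempt landing inside a
    running transit is delayed to its end; attempts that cannot finish
    before the trajectory ends are dropped."""
    if params.flip_rate == 0.0:
        return []
    rate_ns = params.flip_rate / (1.0 - params.backslide_prob) / 1000.0  # per ns
    d = params.flip_duration
    out: list[_Excursion] = []
    t = 0.0  # arrival clock
    busy_until = 0.0
    while True:
        t += rng.exponential(1.0 / rate_ns)
        if t >= params.duration:
            break
        start = max(t, busy_until)
        end = start + d
        if end > params.duration:
            break
        completed = rng.random() >= params.backslide_prob
        peak = rng.uniform(_BUFFER_LO, _BUFFER_HI) if not completed else 0.0
        out.append(_Excursion(start, end, completed, peak))
        busy_until = end
    return out


def _scripted_schedule(
    lipid_id: int,
    scripted: Sequence[tuple[int, float]],
    params: SynthTrajParams,
) -> list[_Excursion]:
    exc = []
    for lid, start in sorted(scripted, key=lambda p: p[1]):
        if lid != lipid_id:
            continue
        end = start + params.flip_duration
        if start < 0 or end > params.duration:
            raise ParameterError(
                f"scripted flip at {start} ns does not fit inside the trajectory"
            )
        if exc and start < exc[-1].end:
            raise ParameterError("scripted flips of one lipid overlap")
        exc.append(_Excursion(start, end, completed=True))
    return exc


def generate_angle_series(
    params: SynthTrajParams,
    scripted_flips: Sequence[tuple[int, float]] | None = None,
) -> tuple[AngleSeries, GroundTruthLog]:
    """Per-lipid orientation-angle series plus the exact event log.

    ``scripted_flips`` replaces the random schedule with explicit
    (lipid_id, start_ns) completed inversions, for deterministic fixtures.

    Returns angles in [0°, 180°] sampled every ``frame_interval`` ns;
    resting lipids sit at 0° or 180° (per starting leaflet) with Gaussian
    jitter of sd ``angle_noise_sd`` folded back into range; completed
    inversions follow a logistic ramp over ``flip_duration``; aborted
    excursions rise to a uniform peak inside the buffer band and return.
    """
    rng = np.random.default_rng(params.seed)
    n_frames = int(round(params.duration / params.frame_interval)) + 1
    times = np.arange(n_frames) * params.frame_interval
    dt = params.frame_interval

    # starting leaflets: first round(split*n) lipids up, deterministically
    n_up = int(round(params.leaflet_split * params.n_lipids))
    start_upper = np.zeros(params.n_lipids, dtype=bool)
    start_upper[:n_up] = True

    base = np.empty((params.n_lipids, n_frames))
    log = GroundTruthLog()
    for lipid in range(params.n_lipids):
        if scripted_flips is not None:
            schedule = _scripted_schedule(lipid, scripted_flips, params)
        else:
            schedule = _schedule_lipid(rng, params)
        upper = bool(start_upper[lipid])
        rest = 180.0 if upper else 0.0
        row = np.full(n_frames, rest)
        for exc in schedule:
            i0 = int(round(exc.start / dt))
            i1 = int(round(exc.end / dt))
            i1 = min(i1, n_frames - 1)
            n = i1 - i0 + 1
            if n < 2:
                continue
            if exc.completed:
                target = 0.0 if upper else 180.0
                row[i0 : i1 + 1] = rest + (target - rest) * _logistic_ramp(n)
                row[i1 + 1 :] = target
                log.events.append(
                    GroundTruthEvent(
                        lipid_id=lipid,
                        start_ns=times[i0],
                        end_ns=times[i1],
                        direction="up->down" if upper else "down->up",
                    )
                )
                upper = not upper
                rest = target
            else:
                bump = np.sin(np.pi * np.linspace(0.0, 1.0, n)) ** 2
                row[i0 : i1 + 1] = rest + (exc.peak - rest) * bump
                log.aborted.append(
                    AbortedExcursion(
                        lipid_id=lipid, start_ns=times[i0], end_ns=times[i1]
                    )
                )
        base[lipid] = row

    if params.angle_noise_sd > 0:
        noisy = base + rng.normal(0.0, params.angle_noise_sd, size=base.shape)
        noisy = np.abs(noisy)  # reflect at 0
        noisy = np.where(noisy > 180.0, 360.0 - noisy, noisy)  # reflect at 180
        np.clip(noisy, 0.0, 180.0, out=noisy)
    else:
        noisy = base
    series = AngleSeries(
        times=times,
        angles=noisy,
        valid=np.ones_like(noisy, dtype=bool),
        lipid_ids=np.arange(params.n_lipids),
    )
    return series, log


def _u_from_angles(theta_deg: np.ndarray, phi: np.ndarray):
    """Unit bisector u(theta, phi) and the in-plane perpendicular w = du/dtheta."""
    th = np.radians(theta_deg)
    ct, st = np.cos(th), np.sin(th)
    cp, sp = np.cos(phi), np.sin(phi)
    u = np.stack([st * cp, st * sp, ct], axis=-1)
    w = np.stack([ct * cp, ct * sp, -st], axis=-1)
    return u, w


def generate_bead_trajectory(
    params: SynthTrajParams,
    scripted_flips: Sequence[tuple[int, float]] | None = None,
    decoys: Sequence[tuple[str, tuple[float, float, float]]] | None = None,
) -> tuple[Trajectory, LipidTopology, GroundTruthLog]:
    """Bead-level trajectory realizing the same angle program geometrically.

    Each lipid gets five beads (PO4 head; two tails of a mid and an end
    bead) placed so the head->tail-end bisector reproduces the generated
    orientation angle exactly, while the head bead's z tracks the
    (noise-free) inversion program across the membrane midplane.
    ``decoys`` adds static labelled protein beads, e.g.
    ``[("TYR32", (40., 40., 40.))]``, for contact analyses.
    """
    series, log = generate_angle_series(params, scripted_flips)
    rng = np.random.default_rng(params.seed + 1)  # independent of the angle noise
    n, n_frames = params.n_lipids, series.times.size

    # reconstruct the noise-free leaflet program to drive head z
    n_up = int(round(params.leaflet_split * n))
    sign = np.where(np.arange(n) < n_up, 1.0, -1.0)  # +1 = upper leaflet
    zprog = np.tile(sign[:, None] * _LEAFLET_HALF_THICKNESS, (1, n_frames))
    dt = params.frame_interval
    for e in log.events:
        i0, i1 = int(round(e.start_ns / dt)), int(round(e.end_ns / dt))
        a, b = zprog[e.lipid_id, i0], -zprog[e.lipid_id, i0]
        zprog[e.lipid_id, i0 : i1 + 1] = a + (b - a) * _logistic_ramp(i1 - i0 + 1)
        zprog[e.lipid_id, i1 + 1 :] = b
    for a_exc in log.aborted:
        i0, i1 = int(round(a_exc.start_ns / dt)), int(round(a_exc.end_ns / dt))
        bump = np.sin(np.pi * np.linspace(0.0, 1.0, i1 - i0 + 1)) ** 2
        zprog[a_exc.lipid_id, i0 : i1 + 1] *= 1.0 - bump

    nx = int(math.ceil(math.sqrt(n)))
    box_xy = max(40.0, nx * _GRID_SPACING)
    box = np.array([box_xy, box_xy, _BOX_Z])
    gx, gy = np.meshgrid(np.arange(nx), np.arange(nx))
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1)[:n] * _GRID_SPACING + 4.0

    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)  # static azimuth per lipid
    u, w = _u_from_angles(series.angles, phi[:, None])  # (n, T, 3)
    alpha = math.radians(_TAIL_SPLAY_DEG)
    dir1 = math.cos(alpha) * u + math.sin(alpha) * w
    dir2 = math.cos(alpha) * u - math.sin(alpha) * w

    head = np.empty((n, n_frames, 3))
    head[:, :, 0] = grid[:, 0][:, None]
    head[:, :, 1] = grid[:, 1][:, None]
    head[:, :, 2] = _BOX_Z / 2.0 + zprog
    head[:, :, 2] += rng.normal(0.0, 1.0, size=(n, n_frames))  # thermal z jitter

    beads_per_lipid = 5  # PO4, C1A, C4A, C1B, C4B
    n_protein = len(decoys) if decoys else 0
    coords = np.empty((n_frames, n * beads_per_lipid + n_protein, 3))
    rows = []
    for lipid in range(n):
        b0 = lipid * beads_per_lipid
        coords[:, b0] = head[lipid]
        coords[:, b0 + 1] = head[lipid] + 0.5 * _TAIL_LENGTH * dir1[lipid]
        coords[:, b0 + 2] = head[lipid] + _TAIL_LENGTH * dir1[lipid]
        coords[:, b0 + 3] = head[lipid] + 0.5 * _TAIL_LENGTH * dir2[lipid]
        coords[:, b0 + 4] = head[lipid] + _TAIL_LENGTH * dir2[lipid]
        for j, (name, role) in enumerate(
            [
                ("PO4", "head"),
                ("C1A", "tail_mid"),
                ("C4A", "tail_end"),
                ("C1B", "tail_mid"),
                ("C4B", "tail_end"),
            ]
        ):
            rows.append((b0 + j, "lipid", lipid, role, name))
    if decoys:
        for k, (label, pos) in enumerate(decoys):
            idx = n * beads_per_lipid + k
            coords[:, idx] = np.asarray(pos, dtype=float)
            rows.append((idx, "protein", -1, "protein", label))
    beads = pd.DataFrame(
        rows, columns=["bead_id", "kind", "lipid_id", "role", "residue"]
    )
    traj = Trajectory(times=series.times.copy(), coords=coords, box=box, beads=beads)
    topo = LipidTopology(
        head_index={l: l * beads_per_lipid for l in range(n)},
        tail_end_indices={
            l: (l * beads_per_lipid + 2, l * beads_per_lipid + 4) for l in range(n)
        },
        protein_residues={
            int(r.bead_id): str(r.residue)
            for r in beads.itertuples()
            if r.kind == "protein"
        },
    )
    return traj, topo, log


def generate_assay_trace(
    params: AssayParams,
    times_s: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    probe_addition_time_s: float = 0.0,
    baseline: float = 1.0,
) -> FluorescenceTrace:
    """Forward-simulate a fluorescence trace from the two-pool model.

    Samples before ``probe_addition_time_s`` sit at ``baseline``; afterwards
    the closed-form solution (scaled by baseline) applies.  ``noise_sd`` is
    the i.i.d. Gaussian noise sd as a fraction of the baseline.
    """
    from .assay import solve_population

    t = np.asarray(times_s, dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ParameterError("times must be strictly increasing")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    sol = solve_population(params)
    post = t >= probe_addition_time_s
    intensity = np.full(t.shape, float(baseline))
    intensity[post] = baseline * sol(t[post] - probe_addition_time_s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd * baseline, size=t.shape)
    return FluorescenceTrace(
        times_s=t,
        intensity=intensity,
        probe_addition_time_s=probe_addition_time_s,
        normalized=(baseline == 1.0 and probe_addition_time_s == 0.0),
    )
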