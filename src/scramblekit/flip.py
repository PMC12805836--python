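"""Lipid flip-flop detection and event anatomy for bilayer trajectories.

The orientation of each lipid is summarized by one vector: the bisector of
the two head-to-tail-end vectors, measured as an angle against the bilayer
normal (+z).  Resting lipids sit near 0° (head in the lower leaflet) or
180° (upper leaflet).  A flip-flop is counted when the 50 ns-smoothed,
25 ns-resampled angle crosses the whole 55°-125° buffer region: a
three-zone state machine commits a lipid to the below-55° or above-125°
zone on every non-buffer sample and emits one event per committed-zone
change.  Excursions that enter the buffer and return are not events.

Event anatomy: per-residue contact fractions and dwell times of protein
beads around the translocating phosphate (5 Å cutoff), and the
phosphate-bead height above the membrane midplane through the crossing.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, RangeError, TopologyError
from .types import (
    AngleSeries,
    ContactProfile,
    DetectorConfig,
    FlipEvent,
    LipidTopology,
    RateResult,
    Trajectory,
    ZONE_LOWER_LEAFLET,
    ZONE_UPPER_LEAFLET,
    as_direction,
)

__all__ = [
    "compute_orientation_angles",
    "smooth_and_resample",
    "detect_flip_events",
    "scrambling_rate",
    "contact_profile",
    "phosphate_z_trace",
]

logger = logging.getLogger(__name__)

_DEGENERATE_NORM = 1e-6


def _minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def compute_orientation_angles(
    traj: Trajectory, topo: LipidTopology
) -> AngleSeries:
    """Per-lipid, per-frame orientation angle against the bilayer normal.

    For each lipid the two head->tail-end vectors are taken under the
    minimum-image convention, normalized, and summed; the bisector's angle
    to +z (degrees in [0, 180]) is reported.  Samples whose normalized sum
    is shorter than 1e-6 (tails exactly antiparallel) are flagged invalid
    rather than given a fabricated angle.
    """
    lipid_ids = topo.lipid_ids
    n_beads = traj.coords.shape[1]
    for lid in lipid_ids:
        refs = (topo.head_index[lid], *topo.tail_end_indices[lid])
        if any(not 0 <= i < n_beads for i in refs):
            raise TopologyError(
                f"lipid {lid} references bead(s) {refs} absent from the trajectory "
                f"({n_beads} beads)"
            )
    heads = np.array([topo.head_index[l] for l in lipid_ids])
    t1 = np.array([topo.tail_end_indices[l][0] for l in lipid_ids])
    t2 = np.array([topo.tail_end_indices[l][1] for l in lipid_ids])

    box = traj.box
    v1 = _minimum_image(traj.coords[:, t1] - traj.coords[:, heads], box)
    v2 = _minimum_image(traj.coords[:, t2] - traj.coords[:, heads], box)
    n1 = np.linalg.norm(v1, axis=-1, keepdims=True)
    n2 = np.linalg.norm(v2, axis=-1, keepdims=True)
    bad_len = (n1[..., 0] < _DEGENERATE_NORM) | (n2[..., 0] < _DEGENERATE_NORM)
    if np.any(bad_len):
        logger.warning(
            "%d samples with zero-length head->tail vectors marked invalid",
            int(bad_len.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        u = v1 / n1 + v2 / n2
    norm_u = np.linalg.norm(u, axis=-1)
    degenerate = norm_u < _DEGENERATE_NORM
    if np.any(degenerate & ~bad_len):
        logger.warning(
            "%d samples with antiparallel tails (undefined bisector) marked invalid",
            int((degenerate & ~bad_len).sum()),
        )
    valid = ~(degenerate | bad_len)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.clip(u[..., 2] / norm_u, -1.0, 1.0)
    angles = np.degrees(np.arccos(np.where(valid, cos_t, 0.0)))
    angles[~valid] = np.nan
    return AngleSeries(
        times=traj.times.copy(),
        angles=angles.T,  # (lipids, frames)
        valid=valid.T,
        lipid_ids=np.asarray(lipid_ids),
    )


def smooth_and_resample(series: AngleSeries, cfg: DetectorConfig) -> AngleSeries:
    """Centered moving average over ``smooth_window``, decimated to one
    sample per ``resample_stride``.

    The window is truncated at the series edges; invalid samples are
    excluded from each window mean (a window with no valid samples yields
    an invalid output sample).  Output times are the window centers.
    """
    dt = series.dt
    k = int(round(cfg.smooth_window / dt))
    if k < 2:
        raise ConfigError(
            f"smooth_window {cfg.smooth_window} ns spans {k} sample(s); need >= 2"
        )
    stride = max(1, int(round(cfg.resample_stride / dt)))
    half_lo = (k - 1) // 2
    half_hi = k // 2
    T = series.times.size
    vals = np.where(series.valid, series.angles, 0.0)
    cnts = series.valid.astype(float)
    csum = np.concatenate(
        [np.zeros((series.n_lipids, 1)), np.cumsum(vals, axis=1)], axis=1
    )
    ccnt = np.concatenate(
        [np.zeros((series.n_lipids, 1)), np.cumsum(cnts, axis=1)], axis=1
    )
    idx = np.arange(0, T, stride)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, T)
    wsum = csum[:, hi] - csum[:, lo]
    wcnt = ccnt[:, hi] - ccnt[:, lo]
    valid = wcnt > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(valid, wsum / np.maximum(wcnt, 1.0), np.nan)
    return AngleSeries(
        times=series.times[idx],
        angles=mean,
        valid=valid,
        lipid_ids=series.lipid_ids.copy(),
    )


def detect_flip_events(
    series: AngleSeries, cfg: DetectorConfig = DetectorConfig()
) -> list[FlipEvent]:
    """Buffer-zone state machine over an already smoothed/resampled series.

    Zones: A below ``lower_threshold`` (head in lower leaflet), B above
    ``upper_threshold`` (upper leaflet), buffer in between.  The committed
    zone updates only on valid, non-buffer samples; an event is emitted
    whenever it changes, carrying start = time of the last sample seen in
    the origin zone and end = time of the first sample in the destination
    zone.  A lipid's initial committed zone is deferred to its first
    non-buffer sample; a lipid that never leaves the buffer yields no
    events (logged).
    """
    events: list[FlipEvent] = []
    zone_code = np.where(
        series.angles < cfg.lower_threshold,
        0,
        np.where(series.angles > cfg.upper_threshold, 2, 1),
    )
    never_committed = []
    for li, lid in enumerate(series.lipid_ids):
        committed = -1
        last_committed_t = 0.0
        for si in range(series.times.size):
            if not series.valid[li, si]:
                continue
            z = zone_code[li, si]
            if z == 1:
                continue
            t = float(series.times[si])
            if committed == -1:
                committed = z
            elif z != committed:
                start_zone = (
                    ZONE_LOWER_LEAFLET if committed == 0 else ZONE_UPPER_LEAFLET
                )
                end_zone = ZONE_LOWER_LEAFLET if z == 0 else ZONE_UPPER_LEAFLET
                events.append(
                    FlipEvent(
                        lipid_id=int(lid),
                        start_ns=last_committed_t,
                        end_ns=t,
                        direction=as_direction(start_zone, end_zone),
                    )
                )
                committed = z
            last_committed_t = t
        if committed == -1:
            never_committed.append(int(lid))
    if never_committed:
        logger.warning(
            "%d lipid(s) never left the buffer zone (no committed leaflet): %s",
            len(never_committed),
            never_committed[:10],
        )
    return events


def scrambling_rate(
    event_sets: Sequence[Sequence[FlipEvent]],
    durations: Sequence[float],
    time_unit: str = "us",
) -> RateResult:
    """Events per µs, per replicate and averaged across replicates.

    ``durations`` are replicate lengths in ``time_unit`` ('us' or 'ns');
    rates are always reported per µs.  With equal-length replicates the
    mean of per-replicate rates equals total events / total time.
    """
    if len(event_sets) == 0:
        raise InputError("need at least one replicate")
    if len(event_sets) != len(durations):
        raise InputError("one duration per replicate required")
    scale = {"us": 1.0, "ns": 1e-3}.get(time_unit)
    if scale is None:
        raise InputError("time_unit must be 'us' or 'ns'")
    dur_us = np.asarray(durations, dtype=float) * scale
    if np.any(dur_us <= 0):
        raise InputError("durations must be > 0")
    counts = np.array([len(ev) for ev in event_sets], dtype=float)
    rates = counts / dur_us
    return RateResult(
        per_replicate=tuple(float(r) for r in rates),
        mean=float(rates.mean()),
        sd=float(rates.std(ddof=1)) if rates.size > 1 else 0.0,
        total_events=int(counts.sum()),
        total_time_us=float(dur_us.sum()),
    )


def _window_frames(traj: Trajectory, t0: float, t1: float) -> np.ndarray:
    sel = (traj.times >= t0) & (traj.times <= t1)
    return np.flatnonzero(sel)


def contact_profile(
    traj: Trajectory,
    topo: LipidTopology,
    events: Sequence[FlipEvent],
    cutoff: float = 5.0,
    margin_ns: float = 10.0,
) -> ContactProfile:
    """Residue contact statistics around translocating phosphates.

    For each event, over the window (start - margin, end + margin) at full
    frame resolution, a residue is "contacted" if any of its beads comes
    within ``cutoff`` Å (minimum image) of the event lipid's head bead in
    at least one frame.  Reports the per-residue fraction of events
    contacted and the distribution of contiguous-contact dwell times (ns).
    """
    if not topo.protein_residues:
        raise InputError("trajectory has no labelled protein beads")
    if not events:
        raise InputError("no events to profile")
    residues = sorted(set(topo.protein_residues.values()))
    res_beads = {
        r: np.array(
            [b for b, lab in topo.protein_residues.items() if lab == r]
        )
        for r in residues
    }
    dt = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 1.0
    contacted_events = {r: 0 for r in residues}
    dwells: dict[str, list[float]] = defaultdict(list)
    for ev in events:
        frames = _window_frames(traj, ev.start_ns - margin_ns, ev.end_ns + margin_ns)
        if frames.size == 0:
            continue
        head = traj.coords[frames, topo.head_index[ev.lipid_id]]  # (F, 3)
        for r in residues:
            pos = traj.coords[np.ix_(frames, res_beads[r])]  # (F, nb, 3)
            d = _minimum_image(pos - head[:, None, :], traj.box)
            within = (np.linalg.norm(d, axis=-1) <= cutoff).any(axis=1)  # (F,)
            if within.any():
                contacted_events[r] += 1
                # contiguous runs of contact
                padded = np.concatenate([[False], within, [False]])
                starts = np.flatnonzero(~padded[:-1] & padded[1:])
                ends = np.flatnonzero(padded[:-1] & ~padded[1:])
                dwells[r].extend(((ends - starts) * dt).tolist())
    n_ev = len(events)
    table = pd.DataFrame(
        {
            "residue": residues,
            "fraction": [contacted_events[r] / n_ev for r in residues],
            "n_events": [contacted_events[r] for r in residues],
            "mean_dwell_ns": [
                float(np.mean(dwells[r])) if dwells[r] else 0.0 for r in residues
            ],
        }
    )
    return ContactProfile(
        fractions=table,
        dwell_times_ns={r: np.asarray(v) for r, v in dwells.items()},
        cutoff_A=cutoff,
        n_events=n_ev,
    )


def phosphate_z_trace(
    traj: Trajectory,
    topo: LipidTopology,
    event: FlipEvent,
    margin_ns: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Head-bead height above the membrane midplane through an event.

    The midplane is the per-frame mean z of all head beads; positive
    offsets are the upper leaflet.  Returns (times_ns, z_offset_A) over
    the event window extended by ``margin_ns`` on both sides.
    """
    t0, t1 = event.start_ns - margin_ns, event.end_ns + margin_ns
    if t1 < traj.times[0] or t0 > traj.times[-1]:
        raise RangeError(
            f"event window [{t0}, {t1}] ns lies outside the trajectory "
            f"[{traj.times[0]}, {traj.times[-1]}] ns"
        )
    frames = _window_frames(traj, t0, t1)
    if frames.size == 0:
        raise RangeError("event window contains no trajectory frames")
    head_idx = np.array([topo.head_index[l] for l in topo.lipid_ids])
    center = traj.coords[np.ix_(frames, head_idx)][:, :, 2].mean(axis=1)
    z = traj.coords[frames, topo.head_index[event.lipid_id], 2] - center
    return traj.times[frames].copy(), z
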