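"""Shared fixtures and oracles for the scramblekit test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from scramblekit.types import AngleSeries, DetectorConfig


@pytest.fixture
def detector_cfg() -> DetectorConfig:
    return DetectorConfig()


def make_series(angles, dt: float = 25.0, valid=None) -> AngleSeries:
    """Wrap raw per-lipid angle rows into an AngleSeries (times in ns)."""
    a = np.atleast_2d(np.asarray(angles, dtype=float))
    v = np.ones_like(a, dtype=bool) if valid is None else np.atleast_2d(valid)
    return AngleSeries(
        times=np.arange(a.shape[1]) * dt,
        angles=a,
        valid=v,
        lipid_ids=np.arange(a.shape[0]),
    )


def oracle_event_count(angles, lower: float = 55.0, upper: float = 125.0) -> int:
    """Independent flip counter: collapse the committed-zone sequence.

    Drop buffer samples, collapse consecutive duplicates of the remaining
    below/above labels, and count adjacent differing pairs.  This is the
    whole buffer-zone rule stated a different way, used as the oracle for
    the state-machine detector.
    """
    zones = [0 if a < lower else (2 if a > upper else 1) for a in angles]
    committed = [z for z in zones if z != 1]
    collapsed = [k for k, _ in itertools.groupby(committed)]
    return max(len(collapsed) - 1, 0)


def match_events(truth_events, detected, tol_ns: float = 150.0):
    """Greedy one-to-one matching of detected events to ground truth.

    Events match if lipid and direction agree and their midpoints differ by
    at most ``tol_ns`` (smoothing/resampling shifts timings by up to about
    the window width).  Returns (true_positives, false_positives,
    false_negatives).
    """
    by_lipid: dict[int, list] = {}
    for i, e in enumerate(detected):
        by_lipid.setdefault(e.lipid_id, []).append((i, e))
    used: set[int] = set()
    tp = 0
    for te in truth_events:
        mid_t = (te.start_ns + te.end_ns) / 2
        for i, de in by_lipid.get(te.lipid_id, []):
            if i in used or de.direction != te.direction:
                continue
            if abs((de.start_ns + de.end_ns) / 2 - mid_t) <= tol_ns:
                used.add(i)
                tp += 1
                break
    return tp, len(detected) - tp, len(truth_events) - tp
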