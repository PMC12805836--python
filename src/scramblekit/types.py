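"""Core data containers shared across the analysis modules.

Unit conventions
----------------
Trajectory domain: times in **ns**, coordinates and distances in **Å**,
rates in events/µs.  Assay domain: times in **s**, rate constants in s⁻¹,
fluorescence dimensionless (normalized to 1 at probe addition).  Column
headers of everything written to disk carry an explicit unit suffix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

Direction = Literal["up->down", "down->up"]

#: Angle (deg, against +z) below which a lipid's tail bisector points up,
#: i.e. the head group sits in the *lower* leaflet.
ZONE_LOWER_LEAFLET = "A"
#: Angle above the upper threshold: tails point down, head in *upper* leaflet.
ZONE_UPPER_LEAFLET = "B"


@dataclass(frozen=True)
class SynthTrajParams:
    """Parameters of the synthetic flip-flop trajectory generator.

    ``flip_rate`` is the rate of *completed* inversions per lipid per µs;
    aborted excursions are generated on top of it so that completed-event
    counts stay Poisson with mean ``n_lipids * flip_rate * duration``.
    """

    n_lipids: int = 100
    duration: float = 10_000.0  # ns
    frame_interval: float = 1.0  # ns
    flip_rate: float = 1.0  # completed flips per lipid per µs
    flip_duration: float = 100.0  # ns, nominal transit time of an inversion
    angle_noise_sd: float = 15.0  # deg, frame-to-frame jitter
    backslide_prob: float = 0.3  # probability an excursion aborts in the buffer
    leaflet_split: float = 0.5  # fraction of lipids starting in the upper leaflet
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids < 1:
            raise ParameterError("n_lipids must be >= 1")
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0")
        if not 0.0 <= self.backslide_prob < 1.0:
            raise ParameterError("backslide_prob must be in [0, 1)")
        if self.angle_noise_sd < 0:
            raise ParameterError("angle_noise_sd must be >= 0")
        if self.flip_rate < 0:
            raise ParameterError("flip_rate must be >= 0")
        if self.flip_duration <= 0:
            raise ParameterError("flip_duration must be > 0")
        if not 0.0 <= self.leaflet_split <= 1.0:
            raise ParameterError("leaflet_split must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruthEvent:
    lipid_id: int
    start_ns: float
    end_ns: float
    direction: Direction


@dataclass(frozen=True)
class AbortedExcursion:
    lipid_id: int
    start_ns: float
    end_ns: float


@dataclass
class GroundTruthLog:
    """Exact record of what the generator put into a synthetic trajectory."""

    events: list[GroundTruthEvent] = field(default_factory=list)
    aborted: list[AbortedExcursion] = field(default_factory=list)

    def for_lipid(self, lipid_id: int) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.lipid_id == lipid_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.lipid_id, e.start_ns, e.end_ns, e.direction) for e in self.events],
            columns=["lipid_id", "start_ns", "end_ns", "direction"],
        )


@dataclass
class AngleSeries:
    """Per-lipid orientation angle (deg, against +z) over time.

    ``angles`` has one row per lipid; ``valid`` masks samples whose bisector
    was numerically defined.  Times are uniform and strictly increasing.
    """

    times: np.ndarray  # (T,), ns
    angles: np.ndarray  # (L, T), degrees in [0, 180]
    valid: np.ndarray  # (L, T), bool
    lipid_ids: np.ndarray  # (L,)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        self.valid = np.atleast_2d(np.asarray(self.valid, dtype=bool))
        self.lipid_ids = np.asarray(self.lipid_ids)
        if self.angles.shape != self.valid.shape:
            raise ParameterError("angles and valid must have identical shape")
        if self.angles.shape[1] != self.times.size:
            raise ParameterError("angles must have one column per time sample")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")

    @property
    def n_lipids(self) -> int:
        return self.angles.shape[0]

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ParameterError("sampling interval undefined for <2 samples")
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class DetectorConfig:
    """Buffer-zone flip detector settings (angles in deg, times in ns)."""

    lower_threshold: float = 55.0
    upper_threshold: float = 125.0
    smooth_window: float = 50.0
    resample_stride: float = 25.0

    def __post_init__(self) -> None:
        from .errors import ConfigError

        if not 0.0 < self.lower_threshold < self.upper_threshold < 180.0:
            raise ConfigError(
                "thresholds must satisfy 0 < lower_threshold < upper_threshold < 180"
            )
        if not self.smooth_window >= self.resample_stride > 0:
            raise ConfigError(
                "windows must satisfy smooth_window >= resample_stride > 0"
            )


@dataclass(frozen=True)
class FlipEvent:
    """One detected (or ground-truth) leaflet inversion.

    ``start_ns`` is the last sample in the origin zone, ``end_ns`` the first
    sample in the destination zone.
    """

    lipid_id: int
    start_ns: float
    end_ns: float
    direction: Direction

    def __post_init__(self) -> None:
        if not self.start_ns < self.end_ns:
            raise ParameterError("event start must precede its end")


@dataclass(frozen=True)
class RateResult:
    """Scrambling rate aggregated across replicates (events/µs)."""

    per_replicate: tuple[float, ...]
    mean: float
    sd: float
    total_events: int
    total_time_us: float

    def to_dict(self) -> dict:
        return {
            "per_replicate_events_per_us": list(self.per_replicate),
            "mean_events_per_us": self.mean,
            "sd_events_per_us": self.sd,
            "total_events": self.total_events,
            "total_time_us": self.total_time_us,
        }


@dataclass
class ContactProfile:
    """Per-residue lipid contact statistics over a set of flip events."""

    fractions: pd.DataFrame  # columns: residue, fraction, n_events, mean_dwell_ns
    dwell_times_ns: dict[str, np.ndarray]
    cutoff_A: float
    n_events: int


@dataclass
class Trajectory:
    """Minimal bead trajectory: frames x beads x xyz with an orthorhombic box.

    ``beads`` is a table with one row per bead: bead_id, kind
    ('lipid'|'protein'), lipid_id (-1 for protein), role
    ('head'|'tail_mid'|'tail_end'|'protein'), residue label.
    """

    times: np.ndarray  # (F,), ns
    coords: np.ndarray  # (F, B, 3), Å
    box: np.ndarray  # (3,), Å, orthorhombic
    beads: pd.DataFrame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ParameterError("coords must have shape (frames, beads, 3)")
        if self.coords.shape[0] != self.times.size:
            raise ParameterError("one coordinate frame per time sample required")
        if self.coords.shape[1] != len(self.beads):
            raise ParameterError("bead table must describe every bead")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class LipidTopology:
    """Maps each lipid to its phosphate head bead and two tail-end beads."""

    head_index: dict[int, int]  # lipid_id -> bead index
    tail_end_indices: dict[int, tuple[int, int]]
    protein_residues: dict[int, str] = field(default_factory=dict)  # bead idx -> label

    def __post_init__(self) -> None:
        from .errors import TopologyError

        used: set[int] = set()
        for lid, h in self.head_index.items():
            tails = self.tail_end_indices.get(lid)
            if tails is None or len(tails) != 2:
                raise TopologyError(
                    f"lipid {lid} must have exactly two tail-end beads"
                )
            trio = {h, *tails}
            if len(trio) != 3 or used & trio:
                raise TopologyError(f"bead indices of lipid {lid} are not unique")
            used |= trio

    @property
    def lipid_ids(self) -> list[int]:
        return sorted(self.head_index)


@dataclass(frozen=True)
class AssayParams:
    """Two-pool kinetic model of the fluorescence scramblase assay.

    The reporter lipid is split between an outer pool O (exposed to the
    probe) and an inner pool I.  The probe acts on O at ``k_probe``;
    scrambling exchanges I and O at ``k_scramble`` in the
    ``fraction_active`` share of vesicles.  Probe-acted lipid fluoresces at
    ``quantum_factor`` relative to membrane lipid (0 for the dithionite
    chemical quench, ~0.4 for BSA back-extraction).
    """

    probe: Literal["dithionite", "bsa"]
    k_probe: float  # s^-1
    k_scramble: float = 0.0  # s^-1
    fraction_active: float = 0.0
    outer_fraction0: float = 0.5
    quantum_factor: float | None = None

    def __post_init__(self) -> None:
        if self.probe not in ("dithionite", "bsa"):
            raise ParameterError("probe must be 'dithionite' or 'bsa'")
        qf = self.quantum_factor
        if qf is None:
            qf = 0.0 if self.probe == "dithionite" else 0.4
            object.__setattr__(self, "quantum_factor", qf)
        if self.k_probe < 0 or self.k_scramble < 0:
            raise ParameterError("rate constants must be >= 0")
        for name in ("fraction_active", "outer_fraction0", "quantum_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.probe == "dithionite" and self.quantum_factor != 0.0:
            raise ParameterError("dithionite fully quenches: quantum_factor must be 0")


@dataclass
class FluorescenceTrace:
    """Fluorescence time course with the probe-addition time marked.

    ``pre_addition`` flags samples recorded before the probe went in.
    After :func:`scramblekit.fitting.normalize_trace` the time axis is
    re-zeroed to probe addition and the pre-addition mean is 1.
    """

    times_s: np.ndarray
    intensity: np.ndarray
    probe_addition_time_s: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times_s.shape != self.intensity.shape:
            raise ParameterError("times and intensity must have the same length")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ParameterError("times must be strictly increasing")

    @property
    def pre_addition(self) -> np.ndarray:
        return self.times_s < self.probe_addition_time_s

    def post_segment(self) -> tuple[np.ndarray, np.ndarray]:
        m = ~self.pre_addition
        return self.times_s[m] - self.probe_addition_time_s, self.intensity[m]


@dataclass(frozen=True)
class ModelSolution:
    """Closed-form population fluorescence F(t) = plateau + Σ Aᵢ e^(−λᵢ t).

    Exponential terms are sorted by decreasing rate constant; amplitudes of
    coincident rates are merged.  F(0) = plateau + ΣAᵢ = 1.
    """

    plateau: float
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]  # s^-1, λ >= 0, descending

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.plateau)
        for a, lam in zip(self.amplitudes, self.rates):
            out = out + a * np.exp(-lam * t)
        return out


@dataclass
class FitResult:
    """Result of a mono- or bi-exponential decay fit.

    ``half_times_s`` are ln2/k per component, ordered fast then slow.
    """

    model: Literal["mono", "bi"]
    plateau: float
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]  # s^-1, descending (fast first)
    half_times_s: tuple[float, ...]
    residual_rms: float
    converged: bool
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "plateau": self.plateau,
            "amplitudes": list(self.amplitudes),
            "rates_per_s": list(self.rates),
            "half_times_s": list(self.half_times_s),
            "residual_rms": self.residual_rms,
            "converged": self.converged,
            "message": self.message,
        }


def as_direction(start_zone: str, end_zone: str) -> Direction:
    """Map committed-zone transition to a leaflet direction label.

    Zone A (angle < lower threshold) has the tail bisector pointing up, so
    the head group sits in the lower leaflet; zone B is the upper leaflet.
    """
    if (start_zone, end_zone) == (ZONE_UPPER_LEAFLET, ZONE_LOWER_LEAFLET):
        return "up->down"
    if (start_zone, end_zone) == (ZONE_LOWER_LEAFLET, ZONE_UPPER_LEAFLET):
        return "down->up"
    raise ParameterError(f"not a flip transition: {start_zone}->{end_zone}")


def events_to_frame(events: Sequence[FlipEvent | GroundTruthEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.lipid_id, e.start_ns, e.end_ns, e.direction) for e in events],
        columns=["lipid_id", "start_ns", "end_ns", "direction"],
    )
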