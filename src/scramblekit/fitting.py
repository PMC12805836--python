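"""Normalization and exponential fitting of scramblase assay traces.

Protein-free liposome traces are fit with a mono-exponential
F(t) = plateau + A e^(-k t); scramblase-containing samples with a
double exponential F(t) = plateau + A1 e^(-k1 t) + A2 e^(-k2 t), whose
fast phase reflects the probe reaction (dithionite reduction, t1/2 ~ 12 s)
and whose slow phase reflects scrambling.  The fitted eigen-rates can be
mapped back to microscopic (k_probe, k_scramble) through the two-pool
model in :mod:`scramblekit.assay`, whose solution is exactly such a sum
of exponentials.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.optimize import least_squares

from .errors import InputError
from .types import FitResult, FluorescenceTrace

__all__ = [
    "normalize_trace",
    "fit_decay",
    "classify_scrambling",
    "scramble_rate_from_fit",
]

LN2 = math.log(2.0)


def normalize_trace(
    raw: FluorescenceTrace, probe_addition_time_s: float | None = None
) -> FluorescenceTrace:
    """Normalize to the mean pre-addition fluorescence and re-zero time.

    Divides the whole trace by the mean of samples recorded before probe
    addition, shifts the time axis so the probe goes in at t = 0, and keeps
    the pre-addition segment (flagged through ``pre_addition``).
    Idempotent on already-normalized traces.
    """
    t_add = (
        raw.probe_addition_time_s
        if probe_addition_time_s is None
        else probe_addition_time_s
    )
    pre = raw.times_s < t_add
    n_pre = int(pre.sum())
    if n_pre == 0:
        raise InputError("no samples before probe addition: cannot normalize")
    if n_pre < 5:
        warnings.warn(
            f"only {n_pre} pre-addition samples; baseline estimate is noisy",
            stacklevel=2,
        )
    baseline = float(raw.intensity[pre].mean())
    if baseline <= 0:
        raise InputError("non-positive pre-addition baseline")
    return FluorescenceTrace(
        times_s=raw.times_s - t_add,
        intensity=raw.intensity / baseline,
        probe_addition_time_s=0.0,
        normalized=True,
    )


def _exp_model(t: np.ndarray, plateau: float, amps, rates) -> np.ndarray:
    out = np.full(t.shape, plateau)
    for a, k in zip(amps, rates):
        out = out + a * np.exp(-k * t)
    return out


def _loglinear_rate(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS of log(y) on t for y > 0; returns (amplitude, rate)."""
    m = y > 0
    if m.sum() < 2:
        return max(float(np.nanmax(y, initial=0.0)), 1e-6), 1e-3
    slope, inter = np.polyfit(t[m], np.log(y[m]), 1)
    return float(np.exp(inter)), float(max(-slope, 1e-9))


def _initial_guess(t: np.ndarray, f: np.ndarray, n_exp: int):
    """Deterministic start: tail log-linear fit for the slow phase, then a
    log-linear fit of the early residual for the fast phase."""
    plateau0 = float(np.clip(f[max(-max(t.size // 10, 3), -t.size):].mean(), 0.0, 1.0))
    resid = f - plateau0
    tail = slice(t.size // 2, None)
    a_slow, k_slow = _loglinear_rate(t[tail], resid[tail])
    if n_exp == 1:
        return plateau0, [max(min(a_slow, 1.0), 1e-6)], [k_slow]
    early = resid - a_slow * np.exp(-k_slow * t)
    head = slice(0, max(t.size // 4, 4))
    a_fast, k_fast = _loglinear_rate(t[head], early[head])
    if k_fast <= k_slow:
        k_fast = 10.0 * k_slow  # degenerate init; let the optimizer separate them
        a_fast = max(1.0 - plateau0 - a_slow, 1e-6)
    return (
        plateau0,
        [max(min(a_fast, 1.0), 1e-6), max(min(a_slow, 1.0), 1e-6)],
        [k_fast, k_slow],
    )


def fit_decay(trace: FluorescenceTrace, model: str = "bi") -> FitResult:
    """Nonlinear least-squares fit of a mono- or bi-exponential decay.

    Expects a normalized trace; only the post-addition segment is fit.
    Ordinary least squares, bounded parameters (plateau in [0, 1], rates
    and amplitudes positive).  Components are reported fast-first; half
    times are ln2/k.  Non-convergence is returned as a flagged result,
    never raised.
    """
    if model not in ("mono", "bi"):
        raise InputError("model must be 'mono' or 'bi'")
    if not trace.normalized:
        warnings.warn("fitting a trace that was not normalized", stacklevel=2)
    t, f = trace.post_segment()
    n_exp = 1 if model == "mono" else 2
    if t.size < 2 * n_exp + 2:
        return FitResult(
            model=model, plateau=float("nan"), amplitudes=(), rates=(),
            half_times_s=(), residual_rms=float("nan"),
            converged=False, message="too few post-addition samples",
        )
    plateau0, amps0, rates0 = _initial_guess(t, f, n_exp)
    x0 = np.array([plateau0, *amps0, *rates0])
    lo = np.array([0.0] + [0.0] * n_exp + [1e-12] * n_exp)
    hi = np.array([1.0] + [1.5] * n_exp + [np.inf] * n_exp)
    x0 = np.clip(x0, lo + 1e-12, np.where(np.isinf(hi), x0, hi - 1e-12))

    def resid(x):
        return _exp_model(t, x[0], x[1 : 1 + n_exp], x[1 + n_exp :]) - f

    try:
        res = least_squares(
            resid, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14,
            gtol=1e-14, max_nfev=20_000,
        )
        ok = bool(res.success)
        msg = res.message
        x = res.x
    except Exception as exc:  # pragma: no cover - defensive
        return FitResult(
            model=model, plateau=float("nan"), amplitudes=(), rates=(),
            half_times_s=(), residual_rms=float("nan"),
            converged=False, message=str(exc),
        )
    order = np.argsort(-x[1 + n_exp :])  # fast (large k) first
    amps = tuple(float(x[1 + i]) for i in order)
    rates = tuple(float(x[1 + n_exp + i]) for i in order)
    rms = float(np.sqrt(np.mean(resid(x) ** 2)))
    slowest = rates[-1] if rates else 0.0
    if ok and slowest > 0 and t[-1] < 5.0 * LN2 / slowest:
        warnings.warn(
            "trace shorter than 5 half-times of the slow phase; "
            "plateau and slow rate may be poorly constrained",
            stacklevel=2,
        )
    return FitResult(
        model=model,
        plateau=float(x[0]),
        amplitudes=amps,
        rates=rates,
        half_times_s=tuple(LN2 / k if k > 0 else float("inf") for k in rates),
        residual_rms=rms,
        converged=ok,
        message=msg,
    )


def scramble_rate_from_fit(fit: FitResult) -> tuple[float, float]:
    """Map fitted biexponential eigen-rates back to (k_probe, k_scramble).

    The two-pool model's eigenvalues satisfy fast + slow = k_probe +
    2 k_scramble and fast * slow = k_probe * k_scramble, so
    k_probe = (s - sqrt(s^2 - ...)) inversion reduces to a quadratic:
    k_probe + k_scramble = (fast + slow) - (k_probe k_scramble)/k_probe...
    Solved directly: k_probe and k_scramble are the roots of
    z^2 - b z + c = 0 with c = fast*slow and b chosen so the pair maps back
    onto (fast, slow); the admissible branch has k_probe >= k_scramble.
    """
    if fit.model != "bi" or len(fit.rates) != 2:
        raise InputError("need a converged biexponential fit")
    fast, slow = fit.rates
    c = fast * slow  # = k_probe * k_scramble
    s = fast + slow  # = k_probe + 2 k_scramble
    # k_scramble solves 2 z^2 - s z + ... : substitute k_probe = s - 2 z
    # => (s - 2 z) z = c  =>  2 z^2 - s z + c = 0
    disc = s * s - 8.0 * c
    if disc < 0:
        raise InputError("fitted rates are not realizable by the two-pool model")
    z = (s - math.sqrt(disc)) / 4.0  # smaller root -> k_scramble <= k_probe
    return s - 2.0 * z, z


def classify_scrambling(
    fit: FitResult,
    protein_free_reference: FitResult,
    margin: float = 0.05,
    probe: str = "dithionite",
    quantum_factor: float | None = None,
    outer_fraction0: float = 0.5,
) -> dict:
    """Compare a sample fit with a protein-free reference fit.

    Verdict is "scrambling-positive" iff the sample's plateau loss exceeds
    the reference loss by more than ``margin`` (fraction units, default 5
    percentage points).  Also reports the slow-phase half time and the
    fraction of scramblase-active vesicles implied by the plateau algebra
    (when the observed loss is in the attainable range).
    """
    from .assay import fraction_active_from_plateau

    if not (fit.converged and protein_free_reference.converged):
        raise InputError("both fits must have converged")
    loss = 1.0 - fit.plateau
    loss_ref = 1.0 - protein_free_reference.plateau
    diff = loss - loss_ref
    try:
        fa = fraction_active_from_plateau(
            loss, probe, quantum_factor, outer_fraction0
        )
    except Exception:
        fa = float("nan")
    return {
        "verdict": "scrambling-positive" if diff > margin else "scrambling-negative",
        "plateau_loss": loss,
        "reference_loss": loss_ref,
        "loss_difference": diff,
        "slow_half_time_s": fit.half_times_s[-1] if fit.half_times_s else float("nan"),
        "fraction_active": fa,
        "margin": margin,
    }
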