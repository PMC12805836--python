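"""Two-pool kinetic model of the fluorescence scramblase assay.

A vesicle carries reporter lipid split between an outer-leaflet pool O
(initially ``outer_fraction0``) and an inner pool I.  The topological probe
acts only on the outer pool, at first-order rate ``k_probe``: dithionite
chemically quenches the fluorophore (acted lipid is dark), while
fatty-acid-free BSA extracts the lipid into a complex that still fluoresces
at ``quantum_factor`` (~0.4) of its in-membrane intensity.  In vesicles that
carry a functional scramblase the two leaflets exchange lipid symmetrically
at ``k_scramble``, feeding the protected inner pool to the probe:

    dO/dt = -k_probe * O + k_scramble * (I - O)
    dI/dt =             - k_scramble * (I - O)

Fluorescence is F = I + O + quantum_factor * (1 - I - O).  The population
signal mixes scramblase-active and protein-free vesicle classes with weight
``fraction_active``.  The linear system is solved in closed form (2x2
eigen-decomposition), so F(t) is exactly a sum of at most three
exponentials plus a plateau; no numerical integration is involved.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ParameterError, RangeError
from .types import AssayParams, FluorescenceTrace, ModelSolution

__all__ = [
    "solve_class",
    "solve_population",
    "solve_trace",
    "plateau",
    "fraction_active_from_plateau",
    "eigenrates",
]

_MERGE_TOL = 1e-12


def eigenrates(k_probe: float, k_scramble: float) -> tuple[float, float]:
    """Decay eigenvalues (fast, slow) of the coupled two-pool system.

    Roots of mu^2 - (k_probe + 2 k_scramble) mu + k_probe k_scramble = 0.
    Both are real and non-negative; as k_scramble -> 0 the fast eigenvalue
    tends to k_probe and the slow one to zero.
    """
    if k_probe < 0 or k_scramble < 0:
        raise ParameterError("rate constants must be >= 0")
    s = k_probe + 2.0 * k_scramble
    disc = math.sqrt(k_probe * k_probe + 4.0 * k_scramble * k_scramble)
    fast = 0.5 * (s + disc)
    # stable form for the small root: product / large root
    slow = (k_probe * k_scramble / fast) if fast > 0 else 0.0
    return fast, slow


def _membrane_pool_solution(
    k_probe: float, k_scramble: float, o0: float, i0: float
) -> tuple[float, list[tuple[float, float]]]:
    """Closed-form M(t) = I(t) + O(t) as (constant, [(amplitude, rate), ...])."""
    if k_scramble == 0.0:
        # decoupled: O decays alone, I is protected
        if k_probe == 0.0:
            return o0 + i0, []
        return i0, [(o0, k_probe)]
    fast, slow = eigenrates(k_probe, k_scramble)
    if fast - slow < _MERGE_TOL:
        # only possible when both rates are ~0
        return o0 + i0, []
    # eigenvectors of [[-(kp+ks), ks], [ks, -ks]] for eigenvalue -mu satisfy
    # O-component = (ks - mu)/ks * I-component; expand (O0, I0) on that basis.
    kp, ks = k_probe, k_scramble
    # solve c_fast, c_slow for I(t) = c_f e^{-fast t} + c_s e^{-slow t}
    # with I' = -ks(I - O) => O = I - I'/(-... ) use direct linear solve:
    # I(0)=i0 ; O(0)=o0 with O_mu = I_mu * (ks - mu)/ks
    a_f = (ks - fast) / ks
    a_s = (ks - slow) / ks
    # [ [1, 1], [a_f, a_s] ] @ [c_f, c_s] = [i0, o0]
    det = a_s - a_f
    c_f = (a_s * i0 - o0) / det
    c_s = (o0 - a_f * i0) / det
    terms = [
        ((1.0 + a_f) * c_f, fast),
        ((1.0 + a_s) * c_s, slow),
    ]
    const = 0.0
    # a zero eigenvalue contributes a constant, not a decay
    decays = []
    for amp, lam in terms:
        if lam < _MERGE_TOL:
            const += amp
        else:
            decays.append((amp, lam))
    return const, decays


def solve_class(params: AssayParams, active: bool) -> ModelSolution:
    """Exact F(t) for a single vesicle class (scramblase-active or not)."""
    ks = params.k_scramble if active else 0.0
    o0 = params.outer_fraction0
    i0 = 1.0 - o0
    qf = params.quantum_factor
    const, decays = _membrane_pool_solution(params.k_probe, ks, o0, i0)
    # F = M + qf (1 - M) = qf + (1 - qf) M
    plateau_val = qf + (1.0 - qf) * const
    amps = [(1.0 - qf) * a for a, _ in decays]
    rates = [lam for _, lam in decays]
    return _canonical(plateau_val, amps, rates)


def _canonical(
    plateau_val: float, amps: list[float], rates: list[float]
) -> ModelSolution:
    merged: dict[float, float] = {}
    for a, lam in zip(amps, rates):
        key = next((k for k in merged if abs(k - lam) < _MERGE_TOL), lam)
        merged[key] = merged.get(key, 0.0) + a
    pairs = sorted(merged.items(), key=lambda p: -p[0])
    pairs = [(lam, a) for lam, a in pairs if abs(a) > _MERGE_TOL]
    return ModelSolution(
        plateau=plateau_val,
        amplitudes=tuple(a for _, a in pairs),
        rates=tuple(lam for lam, _ in pairs),
    )


def solve_population(params: AssayParams) -> ModelSolution:
    """Population-level F(t): mixture of active and inactive vesicle classes."""
    fa = params.fraction_active
    act = solve_class(params, active=True)
    inact = solve_class(params, active=False)
    plateau_val = fa * act.plateau + (1.0 - fa) * inact.plateau
    amps = [fa * a for a in act.amplitudes] + [
        (1.0 - fa) * a for a in inact.amplitudes
    ]
    rates = list(act.rates) + list(inact.rates)
    return _canonical(plateau_val, amps, rates)


def solve_trace(params: AssayParams, times_s: np.ndarray) -> FluorescenceTrace:
    """Evaluate the closed-form population model on a time grid (s).

    Times are measured from probe addition and must be non-negative.
    """
    t = np.asarray(times_s, dtype=float)
    if np.any(t < 0):
        raise RangeError("solve_trace times are measured from probe addition; got t < 0")
    sol = solve_population(params)
    return FluorescenceTrace(
        times_s=t, intensity=sol(t), probe_addition_time_s=0.0, normalized=True
    )


def plateau(params: AssayParams) -> float:
    """Asymptotic normalized fluorescence F(t -> inf).

    Dithionite: only the inner pool of inactive vesicles survives,
    plateau = (1 - fraction_active) * (1 - outer_fraction0).  BSA: acted
    lipid keeps ``quantum_factor`` of its fluorescence, plateau =
    1 - (1 - qf) * (fraction_active + (1 - fraction_active) * outer_fraction0).

    This is end-state algebra: it assumes k_probe > 0 and, for the active
    class, k_scramble > 0 (any nonzero scrambling eventually exposes the
    whole inner pool).  With k_probe > 0 and k_scramble = 0 the dynamic
    solution instead plateaus at the protein-free value regardless of
    fraction_active.
    """
    fa = params.fraction_active if params.k_scramble > 0.0 else 0.0
    if params.k_probe == 0.0:
        return 1.0
    qf = params.quantum_factor
    of0 = params.outer_fraction0
    return 1.0 - (1.0 - qf) * (fa * 1.0 + (1.0 - fa) * of0)


def fraction_active_from_plateau(
    observed_loss: float,
    probe: str,
    quantum_factor: float | None = None,
    outer_fraction0: float = 0.5,
) -> float:
    """Invert the plateau algebra: fluorescence loss -> fraction of active vesicles.

    ``observed_loss`` is 1 - plateau (e.g. 0.73 for a 73% drop).  Inputs
    outside the attainable interval raise :class:`RangeError` naming that
    interval rather than being clamped.
    """
    if probe not in ("dithionite", "bsa"):
        raise ParameterError("probe must be 'dithionite' or 'bsa'")
    if quantum_factor is None:
        quantum_factor = 0.0 if probe == "dithionite" else 0.4
    qf, of0 = quantum_factor, outer_fraction0
    floor = (1.0 - qf) * of0  # protein-free loss
    ceil = 1.0 - qf  # fully active loss
    if not floor <= observed_loss <= ceil:
        raise RangeError(
            f"observed loss {observed_loss:.4f} outside attainable interval "
            f"[{floor:.4f}, {ceil:.4f}] for probe={probe}, "
            f"quantum_factor={qf}, outer_fraction0={of0}"
        )
    if ceil == floor:
        raise RangeError("plateau does not depend on fraction_active (degenerate)")
    return (observed_loss - floor) / (ceil - floor)
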