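"""Quadratic-phase rotation targets and the propagator quality factor.

A SORDOR target is a uniform rotation by a flip angle ``beta`` about an axis
in the transverse plane whose phase varies quadratically with offset:

    alpha(wz) = Q * tp / (2 * Omega) * wz**2 + alpha0,
    UT(wz)    = exp(-i * beta * (cos(alpha) Ix + sin(alpha) Iy)).

``Q = 0`` recovers the constant-axis broadband universal-rotation (BURBOP)
target.  Pulse performance is scored by the normalised real overlap

    Phi = Re tr(UT^dag Ueff) / 2,

averaged over an offset x B1 ensemble; Phi = 1 iff the pulse realises the
target exactly (including the global sign, which is deliberate: the members
of a 90/180 pair must share sign conventions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._su2 import matrix_to_su2, su2_re_overlap, su2_to_matrix
from .propagation import EnsembleGrid, PulseShape, propagate_grid

__all__ = [
    "TargetSpec",
    "target_phase",
    "target_propagator",
    "target_su2_grid",
    "point_fidelity",
    "ensemble_quality",
]


@dataclass
class TargetSpec:
    """Design target for one member of a quadratic-phase pulse pair.

    Parameters
    ----------
    beta : float
        Effective flip angle in radians, in (0, 2*pi].
    q : float
        Dimensionless phase-dispersion scaling factor, |q| < 1.
    bandwidth : float
        Full optimised bandwidth Omega in rad/s; offsets span
        [-Omega/2, +Omega/2].
    tp : float
        Nominal pulse length in seconds (enters the phase coefficient).
    alpha0 : float
        Constant phase offset in radians (arbitrary gauge), default 0.
    """

    beta: float
    q: float
    bandwidth: float
    tp: float
    alpha0: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.beta <= 2.0 * np.pi):
            raise ValueError("beta must be in (0, 2*pi]")
        if abs(self.q) >= 1.0:
            raise ValueError("|q| must be < 1")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.tp <= 0:
            raise ValueError("tp must be > 0")

    @property
    def phase_coefficient(self) -> float:
        """Quadratic coefficient Q*tp/(2*Omega), in rad per (rad/s)^2."""
        return self.q * self.tp / (2.0 * self.bandwidth)


def target_phase(spec: TargetSpec, offset) -> np.ndarray | float:
    """Target axis phase alpha(wz) in radians at the given offset(s) (rad/s)."""
    offset = np.asarray(offset, dtype=float)
    out = spec.phase_coefficient * offset**2 + spec.alpha0
    return out if out.ndim else float(out)


def target_su2_grid(spec: TargetSpec, offsets):
    """Target propagators at each offset, as ``(a, b)`` component arrays."""
    alpha = spec.phase_coefficient * np.asarray(offsets, dtype=float) ** 2 + spec.alpha0
    half = 0.5 * spec.beta
    a = np.full_like(alpha, np.cos(half), dtype=complex)
    b = -np.sin(half) * (np.sin(alpha) + 1j * np.cos(alpha))
    return a, b


def target_propagator(spec: TargetSpec, offset: float) -> np.ndarray:
    """``exp(-i beta (cos(alpha) Ix + sin(alpha) Iy))`` as a 2x2 matrix."""
    a, b = target_su2_grid(spec, [offset])
    return su2_to_matrix(a[0], b[0])


def point_fidelity(u_eff: np.ndarray, u_target: np.ndarray,
                   modulus: bool = False) -> float:
    """Normalised propagator overlap ``Re tr(UT^dag Ueff)/2`` in [-1, 1].

    With ``modulus=True`` the global-phase-insensitive ``|tr|/2`` variant is
    returned instead (not the default: pair phase-matching needs the sign).
    """
    ae, be = matrix_to_su2(u_eff)
    at, bt = matrix_to_su2(u_target)
    if modulus:
        return float(abs(np.conj(at) * ae + np.conj(bt) * be))
    return float(su2_re_overlap(at, bt, ae, be))


def ensemble_quality(pulse: PulseShape, spec: TargetSpec, grid: EnsembleGrid) -> float:
    """Weighted average of the point overlap over the offset x B1 ensemble."""
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    wz, b1, w = grid.flat()
    a, b = propagate_grid(pulse, wz, b1)
    at, bt = target_su2_grid(spec, wz)
    return float(np.sum(w * su2_re_overlap(at, bt, a, b)))
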