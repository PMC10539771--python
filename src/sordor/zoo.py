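"""Reference pulse families: hard pulses, frequency-swept chirps, the
constant-axis (Q = 0) universal-rotation baseline, and the amplitude/length
scaled self-refocusing 180.

The scaled 180 implements the swept-pulse echo condition: if the 90 imparts
a quadratic phase ``alpha90(w) = C*w^2`` to transverse magnetisation, a
refocusing rotation with axis phase ``alpha180(w) = (C/2)*w^2`` reflects it
to ``2*alpha180 - alpha90 = const`` — an offset-independent phase, i.e. a
spectrum that needs no phase correction.  By the quadratic-coefficient rule
``C = Q*tp/(2*Omega)``, halving ``tp`` at the pair's Q and Omega halves C
exactly; doubling the rf amplitude restores enough control authority to
reach the 180 rotation in the halved duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grape import OptimisationProblem, optimise, smooth_random_phases
from .propagation import DEFAULT_SLICE_DURATION, EnsembleGrid, PulseShape
from .targets import TargetSpec

__all__ = [
    "ChirpSpec",
    "hard_pulse",
    "chirp_pulse",
    "burbop_spec",
    "scaled_refocusing_180",
]


@dataclass
class ChirpSpec:
    """Frequency-swept (chirped) pulse parameters.

    ``sweep_width`` is the full instantaneous-frequency excursion in rad/s;
    ``smoothing`` the fractional edge length of the sine-squared amplitude
    ramps; ``law`` either "linear" or "constant-adiabaticity" (sweep rate
    proportional to the squared instantaneous amplitude, keeping the
    adiabaticity factor time-invariant through the smoothed edges).  The
    defaults — CA law with strong (40 %) edge smoothing — give the
    WURST-like envelope that makes a short chirp a good broadband inverter;
    a plain linear sweep of the same length shows pronounced inversion
    ripple near the band edges.
    """

    sweep_width: float
    tp: float
    peak_amplitude_hz: float
    smoothing: float = 0.4
    law: str = "constant-adiabaticity"

    def __post_init__(self):
        if self.sweep_width <= 0:
            raise ValueError("sweep_width must be > 0")
        if not (0.0 <= self.smoothing < 0.5):
            raise ValueError("smoothing fraction must be in [0, 0.5)")
        if self.law not in ("linear", "constant-adiabaticity"):
            raise ValueError(f"unknown sweep law {self.law!r}")


def hard_pulse(beta: float, amplitude_hz: float, phase: float = 0.0) -> PulseShape:
    """Single-slice rectangular pulse of flip angle ``beta`` (radians)."""
    if amplitude_hz <= 0:
        raise ValueError("amplitude must be > 0")
    duration = beta / (2.0 * np.pi * amplitude_hz)
    return PulseShape(duration, np.array([amplitude_hz]), np.array([phase]),
                      label=f"hard{np.degrees(beta):.0f}")


def chirp_pulse(spec: ChirpSpec,
                slice_duration: float = DEFAULT_SLICE_DURATION) -> PulseShape:
    """Frequency-swept pulse with sine-squared edge smoothing.

    The rf phase is the cumulative integral of the instantaneous frequency,
    which sweeps from ``-sweep_width/2`` to ``+sweep_width/2``; under the
    constant-adiabaticity law the sweep rate is rescaled by the squared
    envelope (and renormalised to the same total excursion), so the sweep
    slows where the rf field is weak.
    """
    n = max(int(round(spec.tp / slice_duration)), 2)
    t = (np.arange(n) + 0.5) * slice_duration
    env = np.ones(n)
    edge = spec.smoothing * spec.tp
    if edge > 0:
        rising = t < edge
        falling = t > spec.tp - edge
        env[rising] = np.sin(0.5 * np.pi * t[rising] / edge) ** 2
        env[falling] = np.sin(0.5 * np.pi * (spec.tp - t[falling]) / edge) ** 2
    if spec.law == "constant-adiabaticity":
        rate = env**2
    else:
        rate = np.ones(n)
    rate = rate / (rate.sum() * slice_duration) * spec.sweep_width  # rad/s^2 profile
    # instantaneous frequency at slice centres, centred sweep
    freq = np.cumsum(rate) * slice_duration - 0.5 * rate * slice_duration
    freq = freq - 0.5 * spec.sweep_width
    phase = np.cumsum(freq) * slice_duration - 0.5 * freq * slice_duration
    return PulseShape(slice_duration, spec.peak_amplitude_hz * env, phase,
                      label=f"chirp-{spec.law}")


def burbop_spec(beta: float, bandwidth: float, tp: float,
                alpha0: float = 0.0) -> TargetSpec:
    """Constant-axis universal-rotation target: the Q = 0 special case."""
    return TargetSpec(beta=beta, q=0.0, bandwidth=bandwidth, tp=tp, alpha0=alpha0)


def scaled_refocusing_180(spec: TargetSpec, base_amplitude_hz: float,
                          slice_duration: float = DEFAULT_SLICE_DURATION,
                          n_offsets: int = 101,
                          b1_range: float = 0.0, n_b1: int = 5,
                          max_iterations: int = 2000,
                          seed: int = 17) -> tuple[PulseShape, TargetSpec]:
    """Self-refocusing 180 matched to a pair's quadratic phase.

    Optimises a fresh 180-degree pulse at twice the base rf amplitude and
    half the pair's duration, keeping Q and Omega — so its quadratic
    coefficient is exactly half the pair's, the echo condition above.  (A
    naive time-compression of the existing 180 would quarter, not halve,
    the coefficient and fails the condition.)
    """
    target = TargetSpec(beta=np.pi, q=spec.q, bandwidth=spec.bandwidth,
                        tp=spec.tp / 2.0, alpha0=spec.alpha0)
    n = int(round(target.tp / slice_duration))
    pulse = PulseShape(slice_duration, np.full(n, 2.0 * base_amplitude_hz),
                       smooth_random_phases(n, seed), label="sordor180-scaled")
    grid = EnsembleGrid.uniform_band(target.bandwidth, n_offsets,
                                     b1_range=b1_range, n_b1=n_b1)
    res = optimise(OptimisationProblem(pulse, target, grid,
                                       max_iterations=max_iterations))
    return res.pulse, target
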