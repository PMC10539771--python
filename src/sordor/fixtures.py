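"""Deterministic fixture generators for tests, examples, and benchmarks."""

from __future__ import annotations

import numpy as np

from .grape import smooth_random_phases
from .morph import MorphNode, MorphRunRecord
from .propagation import DEFAULT_SLICE_DURATION, PulseShape
from .seqsim import SpinSystem

__all__ = ["fixture_generator", "random_shape", "toy_19f_system",
           "planted_morph_record", "ppm_range_to_hz", "larmor_hz"]

#: gyromagnetic ratio of 19F relative to 1H
GAMMA_19F_OVER_1H = 0.9407728


def larmor_hz(spectrometer_1h_mhz: float, nucleus: str = "19F") -> float:
    """Observe frequency in Hz for a spectrometer named by its 1H frequency."""
    if nucleus == "1H":
        ratio = 1.0
    elif nucleus == "19F":
        ratio = GAMMA_19F_OVER_1H
    else:
        raise ValueError(f"unknown nucleus {nucleus!r}")
    return spectrometer_1h_mhz * 1e6 * ratio


def ppm_range_to_hz(ppm_low: float, ppm_high: float,
                    spectrometer_1h_mhz: float, nucleus: str = "19F") -> float:
    """Width in Hz of a chemical-shift range at a given field.

    E.g. the -63 to -216 ppm fluorine window at a 400 MHz (1H) magnet spans
    about 58 kHz.
    """
    return abs(ppm_high - ppm_low) * 1e-6 * larmor_hz(spectrometer_1h_mhz, nucleus)


def random_shape(seed: int, n_slices: int = 64, amplitude_hz: float = 1e4,
                 slice_duration: float = DEFAULT_SLICE_DURATION) -> PulseShape:
    """Constant-amplitude pulse with a seeded smooth random phase."""
    return PulseShape(slice_duration, np.full(n_slices, amplitude_hz),
                      smooth_random_phases(n_slices, seed),
                      label=f"random-{seed}")


def toy_19f_system(seed: int = 0, spectrometer_1h_mhz: float = 400.0,
                   carrier_ppm: float = -140.0, j_max_hz: float = 100.0,
                   t2_s: float | None = None) -> SpinSystem:
    """Three fluorine spins spread over the -63 to -216 ppm window.

    Shifts are drawn inside the window, converted to Hz offsets from the
    carrier; couplings up to ``j_max_hz`` emulate the large J values common
    in fluorinated compounds.
    """
    rng = np.random.default_rng(seed)
    nu0 = larmor_hz(spectrometer_1h_mhz)
    ppm = rng.uniform(-216.0, -63.0, size=3)
    offsets = (ppm - carrier_ppm) * 1e-6 * nu0
    j = np.zeros((3, 3))
    pairs = [(0, 1), (0, 2), (1, 2)]
    vals = rng.uniform(5.0, j_max_hz, size=3)
    for (i, k), v in zip(pairs, vals):
        j[i, k] = j[k, i] = v
    t2 = None if t2_s is None else [t2_s] * 3
    return SpinSystem(offsets_hz=offsets, j_hz=j, t2_s=t2)


def planted_morph_record(seed: int = 0, n_q: int = 4, n_tp: int = 5) -> tuple:
    """Morph record with a known best (Q, tp) node for both flip angles.

    Returns ``(record, (q_best, tp_best))``; the planted node has the
    highest min(Phi90, Phi180) by construction.
    """
    rng = np.random.default_rng(seed)
    qs = np.round(np.linspace(0.7, 0.85, n_q), 3)
    tps = np.round(np.linspace(450e-6, 750e-6, n_tp), 9)
    best = (qs[rng.integers(n_q)], tps[rng.integers(n_tp)])
    record = MorphRunRecord()
    for q in qs:
        for tp in tps:
            for beta in (np.pi / 2, np.pi):
                base = 0.999 if (q, tp) == best else rng.uniform(0.90, 0.995)
                pulse = random_shape(int(1000 * q + 1e6 * tp), n_slices=8)
                record.add(MorphNode(beta=beta, q=float(q), bandwidth=2 * np.pi * 4e4,
                                     tp=float(tp), quality=float(base),
                                     pulse=pulse, warm_start=None))
    return record, best


def fixture_generator(kind: str, seed: int = 0, **kwargs):
    """Dispatching front-end: random-shape | toy-19F-system | planted-morph-record."""
    if kind == "random-shape":
        return random_shape(seed, **kwargs)
    if kind == "toy-19F-system":
        return toy_19f_system(seed, **kwargs)
    if kind == "planted-morph-record":
        return planted_morph_record(seed, **kwargs)
    raise ValueError(f"unknown fixture kind {kind!r}")
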