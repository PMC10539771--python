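"""Morphic-GRAPE staging: warm-started parameter ramps and pair selection.

Good quadratic-phase 90-degree pulses are hard to reach by cold-started
gradient ascent; the morphing strategy instead ramps a design parameter
(bandwidth, duration, Q, B1 range) in small increments, re-optimising at
each node from the previous node's solution.  Every node is recorded with
its warm-start provenance so a run is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grape import OptimisationProblem, optimise, smooth_random_phases
from .propagation import DEFAULT_SLICE_DURATION, EnsembleGrid, PulseShape
from .targets import TargetSpec, ensemble_quality

__all__ = [
    "MorphStage",
    "MorphNode",
    "MorphRunRecord",
    "SordorPair",
    "ramp_bandwidth",
    "expand_duration",
    "select_best_pair",
    "b1_robustify",
    "design_pair",
    "duration_quality_sweep",
    "matched_duration",
]


@dataclass
class MorphStage:
    """One staged parameter ramp: which knob moves and through which values."""

    varied_parameter: str  # bandwidth | duration | q | b1_range
    value_sequence: Sequence[float]
    max_iterations: int = 300

    def __post_init__(self):
        if self.varied_parameter not in ("bandwidth", "duration", "q", "b1_range"):
            raise ValueError(f"unknown varied_parameter {self.varied_parameter!r}")
        seq = np.asarray(self.value_sequence, dtype=float)
        d = np.diff(seq)
        if seq.size and not (np.all(d >= 0) or np.all(d <= 0)):
            raise ValueError("value_sequence must be monotone")


@dataclass
class MorphNode:
    """One optimisation node of a morph run."""

    beta: float
    q: float
    bandwidth: float
    tp: float
    quality: float
    pulse: PulseShape
    warm_start: str | None  # key of the node that seeded this one, or None
    iterations: int = 0

    @property
    def key(self) -> str:
        return node_key(self.beta, self.q, self.tp, self.bandwidth)


def node_key(beta: float, q: float, tp: float, bandwidth: float) -> str:
    return (f"beta={np.degrees(beta):.1f}|q={q:.4f}"
            f"|tp={tp * 1e6:.1f}us|bw={bandwidth / (2 * np.pi) / 1e3:.3f}kHz")


@dataclass
class MorphRunRecord:
    """Grid of optimised nodes plus warm-start provenance."""

    nodes: list = field(default_factory=list)
    alpha0: float = 0.0

    def add(self, node: MorphNode) -> None:
        self.nodes.append(node)

    def __len__(self) -> int:
        return len(self.nodes)

    def to_frame(self) -> pd.DataFrame:
        """Tabular (beta, Q, tp, Omega, Phi) view of the run."""
        rows = [dict(beta_deg=np.degrees(n.beta), q=n.q,
                     tp_us=n.tp * 1e6,
                     bandwidth_khz=n.bandwidth / (2.0 * np.pi) / 1e3,
                     quality=n.quality, iterations=n.iterations,
                     warm_start=n.warm_start) for n in self.nodes]
        return pd.DataFrame(rows)

    def best_node(self, beta: float) -> MorphNode:
        cand = [n for n in self.nodes if np.isclose(n.beta, beta)]
        if not cand:
            raise ValueError(f"record has no nodes with beta={beta}")
        return max(cand, key=lambda n: n.quality)

    def save_summary(self, path) -> None:
        payload = dict(alpha0=self.alpha0,
                       nodes=[{k: v for k, v in asdict(n).items() if k != "pulse"}
                              for n in self.nodes])
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


@dataclass
class SordorPair:
    """A phase-matched 90/180 pulse pair sharing one quadratic target phase."""

    pulse90: PulseShape
    pulse180: PulseShape
    q: float
    bandwidth: float
    tp: float
    alpha0: float = 0.0
    quality90: float = np.nan
    quality180: float = np.nan

    def spec(self, beta: float) -> TargetSpec:
        return TargetSpec(beta=beta, q=self.q, bandwidth=self.bandwidth,
                          tp=self.tp, alpha0=self.alpha0)

    @property
    def paired_quality(self) -> float:
        return min(self.quality90, self.quality180)


def _grid_for(bandwidth: float, n_offsets: int, b1_range: float, n_b1: int) -> EnsembleGrid:
    return EnsembleGrid.uniform_band(bandwidth, n_offsets,
                                     b1_range=b1_range, n_b1=n_b1)


def _optimise_node(pulse, spec, grid, max_iterations):
    try:
        return optimise(OptimisationProblem(pulse, spec, grid,
                                            max_iterations=max_iterations))
    except FloatingPointError:
        return None


def ramp_bandwidth(seed_pulses: Mapping[float, PulseShape],
                   omega_from: float, omega_to: float, step: float,
                   q_list: Sequence[float], tp: float,
                   alpha0: float = 0.0,
                   n_offsets: int = 101,
                   max_iterations: int = 300,
                   record: MorphRunRecord | None = None) -> MorphRunRecord:
    """Warm-started bandwidth ramp for every Q and every seeded flip angle.

    ``seed_pulses`` maps flip angle beta -> starting shape; each Q chains
    its own sequence of re-optimisations across the bandwidth values
    ``omega_from, omega_from + step, ..., omega_to`` (rad/s, inclusive).
    Failed nodes are recorded with the previous pulse and its quality.
    """
    if omega_to < omega_from:
        raise ValueError("omega_to must be >= omega_from")
    if step <= 0:
        raise ValueError("step must be > 0")
    omegas = np.arange(omega_from, omega_to + 0.5 * step, step)
    omegas[-1] = min(omegas[-1], omega_to)
    record = MorphRunRecord(alpha0=alpha0) if record is None else record
    for q in q_list:
        for beta, seed_pulse in seed_pulses.items():
            pulse = seed_pulse
            prev_key = None
            for om in omegas:
                spec = TargetSpec(beta=beta, q=q, bandwidth=om, tp=tp, alpha0=alpha0)
                grid = _grid_for(om, n_offsets, 0.0, 1)
                res = _optimise_node(pulse, spec, grid, max_iterations)
                if res is None:
                    quality = ensemble_quality(pulse, spec, grid)
                    node = MorphNode(beta, q, om, tp, quality, pulse,
                                     prev_key, iterations=0)
                else:
                    pulse = res.pulse
                    node = MorphNode(beta, q, om, tp, res.quality, pulse,
                                     prev_key, iterations=res.iterations)
                record.add(node)
                prev_key = node.key
    return record


def _extend_pulse(pulse: PulseShape, tp_new: float) -> PulseShape:
    """Lengthen a pulse by appending edge-value slices up to ``tp_new``."""
    n_new = int(round(tp_new / pulse.slice_duration))
    if n_new < pulse.n_slices:
        raise ValueError("target duration shorter than current pulse")
    extra = n_new - pulse.n_slices
    if extra == 0:
        return pulse
    amps = np.concatenate([pulse.amplitudes,
                           np.full(extra, pulse.amplitudes[-1])])
    phases = np.concatenate([pulse.phases, np.full(extra, pulse.phases[-1])])
    return PulseShape(pulse.slice_duration, amps, phases, label=pulse.label)


def expand_duration(record: MorphRunRecord,
                    tp_from: float, tp_to: float, step: float,
                    q_list: Sequence[float], bandwidth: float,
                    beta_list: Sequence[float] = (np.pi / 2, np.pi),
                    n_offsets: int = 101,
                    max_iterations: int = 300) -> MorphRunRecord:
    """Warm-started duration expansion at fixed bandwidth.

    For each Q the chain starts from the recorded node at ``tp_from`` and
    lengthens the pulse by appending slices (edge-value initialisation),
    re-optimising at each duration.  New nodes are appended to the record.
    """
    if tp_to < tp_from:
        raise ValueError("tp_to must be >= tp_from")
    tps = np.arange(tp_from, tp_to + 0.5 * max(step, 1e-12), step) if step > 0 \
        else np.array([tp_from])
    by_key = {n.key: n for n in record.nodes}
    for q in q_list:
        for beta in beta_list:
            start_key = node_key(beta, q, tp_from, bandwidth)
            if start_key not in by_key:
                raise ValueError(f"record has no starting node {start_key}")
            pulse = by_key[start_key].pulse
            prev_key = start_key
            for tp in tps[1:] if tps.size > 1 else []:
                pulse = _extend_pulse(pulse, tp)
                spec = TargetSpec(beta=beta, q=q, bandwidth=bandwidth,
                                  tp=pulse.duration, alpha0=record.alpha0)
                grid = _grid_for(bandwidth, n_offsets, 0.0, 1)
                res = _optimise_node(pulse, spec, grid, max_iterations)
                if res is not None:
                    pulse = res.pulse
                    node = MorphNode(beta, q, bandwidth, pulse.duration,
                                     res.quality, pulse, prev_key,
                                     iterations=res.iterations)
                else:
                    node = MorphNode(beta, q, bandwidth, pulse.duration,
                                     ensemble_quality(pulse, spec, grid),
                                     pulse, prev_key, iterations=0)
                record.add(node)
                prev_key = node.key
    return record


def select_best_pair(record: MorphRunRecord,
                     beta90: float = np.pi / 2,
                     beta180: float = np.pi) -> SordorPair:
    """Best phase-matched pair: maximise min(Phi90, Phi180) over (Q, tp, Omega).

    Both members of every candidate pair are scored against the identical
    quadratic phase alpha(wz) (same Q, tp, Omega, alpha0 by construction).
    """
    if not record.nodes:
        raise ValueError("empty morph record")
    by_params: dict[tuple, dict[float, MorphNode]] = {}
    for n in record.nodes:
        params = (round(n.q, 10), round(n.tp, 12), round(n.bandwidth, 6))
        slot = by_params.setdefault(params, {})
        # keep the best node per (params, beta)
        if n.beta not in slot or n.quality > slot[n.beta].quality:
            slot[n.beta] = n
    best = None
    for params, slot in by_params.items():
        if beta90 not in slot or beta180 not in slot:
            continue
        paired = min(slot[beta90].quality, slot[beta180].quality)
        if best is None or paired > best[0]:
            best = (paired, slot[beta90], slot[beta180])
    if best is None:
        raise ValueError("record contains no (Q, tp, Omega) node with both flip angles")
    _, n90, n180 = best
    return SordorPair(pulse90=n90.pulse, pulse180=n180.pulse, q=n90.q,
                      bandwidth=n90.bandwidth, tp=n90.tp, alpha0=record.alpha0,
                      quality90=n90.quality, quality180=n180.quality)


def b1_robustify(pair: SordorPair, b1_range: float = 0.05, n_b1: int = 5,
                 n_offsets: int = 101, max_iterations: int = 3000) -> SordorPair:
    """Re-optimise both pulses against a Gaussian-weighted B1 ensemble.

    ``b1_range`` is the fractional +/- rf-amplitude miscalibration; 0 keeps
    the nominal grid (a no-op up to re-optimisation noise).  The returned
    pair carries the ensemble qualities.
    """
    grid = _grid_for(pair.bandwidth, n_offsets, b1_range, n_b1)
    out = {}
    for beta, pulse in ((np.pi / 2, pair.pulse90), (np.pi, pair.pulse180)):
        spec = pair.spec(beta)
        res = optimise(OptimisationProblem(pulse, spec, grid,
                                           max_iterations=max_iterations))
        out[beta] = res
    return SordorPair(pulse90=out[np.pi / 2].pulse, pulse180=out[np.pi].pulse,
                      q=pair.q, bandwidth=pair.bandwidth, tp=pair.tp,
                      alpha0=pair.alpha0,
                      quality90=out[np.pi / 2].quality,
                      quality180=out[np.pi].quality)


def design_pair(nu1_hz: float = 1e4,
                bandwidth_hz: float = 5e4,
                tp: float = 720e-6,
                q: float = 0.80,
                alpha0: float = 0.0,
                slice_duration: float = DEFAULT_SLICE_DURATION,
                ramp_start_hz: float = 1e4,
                ramp_step_hz: float = 5e3,
                b1_range: float = 0.05,
                n_b1: int = 5,
                n_offsets: int = 101,
                ramp_iterations: int = 400,
                final_iterations: int = 3000,
                seed: int = 0) -> SordorPair:
    """End-to-end design of a phase-matched 90/180 pair at fixed duration.

    Bootstraps from seeded smooth-random phases at an easy (narrow)
    bandwidth, ramps the bandwidth up with warm starts, then robustifies
    against the Gaussian B1 ensemble.  All frequencies in Hz at this
    user-facing level.
    """
    n = int(round(tp / slice_duration))
    seeds = {np.pi / 2: PulseShape(slice_duration, np.full(n, nu1_hz),
                                   smooth_random_phases(n, seed + 1)),
             np.pi: PulseShape(slice_duration, np.full(n, nu1_hz),
                               smooth_random_phases(n, seed + 2))}
    record = ramp_bandwidth(seeds, 2 * np.pi * ramp_start_hz,
                            2 * np.pi * bandwidth_hz, 2 * np.pi * ramp_step_hz,
                            q_list=[q], tp=tp, alpha0=alpha0,
                            n_offsets=n_offsets, max_iterations=ramp_iterations)
    # the pair at the final bandwidth node
    final_nodes = {b: [n_ for n_ in record.nodes
                       if np.isclose(n_.beta, b)
                       and np.isclose(n_.bandwidth, 2 * np.pi * bandwidth_hz)][-1]
                   for b in (np.pi / 2, np.pi)}
    pair = SordorPair(pulse90=final_nodes[np.pi / 2].pulse,
                      pulse180=final_nodes[np.pi].pulse,
                      q=q, bandwidth=2 * np.pi * bandwidth_hz, tp=tp,
                      alpha0=alpha0,
                      quality90=final_nodes[np.pi / 2].quality,
                      quality180=final_nodes[np.pi].quality)
    return b1_robustify(pair, b1_range=b1_range, n_b1=n_b1,
                        n_offsets=n_offsets, max_iterations=final_iterations)


# ---------------------------------------------------------------------------
# duration/quality sweeps (energy comparison between pulse families)


def duration_quality_sweep(beta: float, q: float, bandwidth: float,
                           durations: Sequence[float],
                           nu1_hz: float = 1e4,
                           slice_duration: float = DEFAULT_SLICE_DURATION,
                           n_offsets: int = 51,
                           max_iterations: int = 300,
                           seed: int = 0) -> pd.DataFrame:
    """Best quality versus pulse duration at fixed rf amplitude.

    Warm-starts along increasing duration (edge-value extension), the same
    protocol for any Q; with Q = 0 this produces the constant-axis
    universal-rotation (BURBOP) baseline curve.  At constant amplitude the
    pulse energy is proportional to the duration, so duration ratios at
    matched quality are rf-energy ratios.
    """
    durations = np.sort(np.asarray(durations, dtype=float))
    grid = EnsembleGrid.uniform_band(bandwidth, n_offsets)
    n0 = int(round(durations[0] / slice_duration))
    pulse = PulseShape(slice_duration, np.full(n0, nu1_hz),
                       smooth_random_phases(n0, seed))
    rows = []
    for tp in durations:
        pulse = _extend_pulse(pulse, tp)
        spec = TargetSpec(beta=beta, q=q, bandwidth=bandwidth, tp=pulse.duration)
        res = optimise(OptimisationProblem(pulse, spec, grid,
                                           max_iterations=max_iterations))
        pulse = res.pulse
        rows.append(dict(tp_us=pulse.duration * 1e6, quality=res.quality,
                         log10_infidelity=np.log10(max(1.0 - res.quality, 1e-16))))
    return pd.DataFrame(rows)


def matched_duration(sweep: pd.DataFrame, quality_star: float) -> float:
    """Duration (us) at which a sweep reaches a quality threshold.

    Linear interpolation of log10(1 - Phi) against duration, the scale on
    which quality-vs-duration curves are roughly linear.
    """
    y = sweep["log10_infidelity"].to_numpy()
    x = sweep["tp_us"].to_numpy()
    target = np.log10(max(1.0 - quality_star, 1e-16))
    if y.min() > target:
        raise ValueError("sweep never reaches the requested quality")
    # first crossing from above
    for i in range(1, len(y)):
        if y[i] <= target:
            lo, hi = i - 1, i
            if y[hi] == y[lo]:
                return float(x[hi])
            frac = (target - y[lo]) / (y[hi] - y[lo])
            return float(x[lo] + frac * (x[hi] - x[lo]))
    raise ValueError("sweep never reaches the requested quality")
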