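"""Morphic staging: ramps, duration expansion, pair selection, B1 hardening."""

import numpy as np
import pytest

from sordor.fixtures import planted_morph_record, random_shape
from sordor.grape import OptimisationProblem, optimise
from sordor.morph import (MorphStage, b1_robustify, expand_duration,
                          matched_duration, ramp_bandwidth, select_best_pair)
from sordor.propagation import EnsembleGrid
from sordor.targets import TargetSpec, ensemble_quality

TWO_PI = 2 * np.pi


def _seed_pulses(n=100, tp=100e-6, nu1=1e4):
    return {np.pi / 2: random_shape(21, n_slices=n, amplitude_hz=nu1,
                                    slice_duration=tp / n),
            np.pi: random_shape(22, n_slices=n, amplitude_hz=nu1,
                                slice_duration=tp / n)}


class TestMorphStage:
    def test_rejects_non_monotone_sequence(self):
        with pytest.raises(ValueError):
            MorphStage("bandwidth", [1.0, 3.0, 2.0])
        with pytest.raises(ValueError):
            MorphStage("frequency", [1.0, 2.0])


class TestRampBandwidth:
    def test_one_step_ramp_is_plain_optimisation(self):
        seeds = _seed_pulses()
        om = TWO_PI * 1e4
        record = ramp_bandwidth(seeds, om, om, TWO_PI * 5e3, q_list=[0.5],
                                tp=100e-6, n_offsets=21, max_iterations=150)
        assert len(record) == 2  # one node per flip angle
        spec = TargetSpec(np.pi / 2, 0.5, om, 100e-6)
        grid = EnsembleGrid.uniform_band(om, 21)
        direct = optimise(OptimisationProblem(seeds[np.pi / 2], spec, grid,
                                              max_iterations=150))
        node = [n for n in record.nodes if np.isclose(n.beta, np.pi / 2)][0]
        assert node.quality == pytest.approx(direct.quality, abs=1e-12)

    def test_node_bookkeeping_and_warm_start_chain(self):
        seeds = _seed_pulses()
        record = ramp_bandwidth(seeds, TWO_PI * 5e3, TWO_PI * 1.5e4,
                                TWO_PI * 5e3, q_list=[0.4, 0.6], tp=100e-6,
                                n_offsets=15, max_iterations=60)
        # |Q| x bandwidth steps nodes per flip angle
        assert len(record) == 2 * 3 * 2
        df = record.to_frame()
        for (_, _), group in df.groupby(["q", "beta_deg"]):
            starts = group.sort_values("bandwidth_khz").warm_start.tolist()
            assert starts[0] is None  # chain roots at the seed pulse
            assert all(s is not None for s in starts[1:])

    def test_warm_ramp_beats_cold_start_on_hard_instance(self):
        """Morphing to a wide band outperforms a cold start with the same
        total iteration budget (the motivation for the staging)."""
        seeds = _seed_pulses(n=120, tp=120e-6)
        target_om = TWO_PI * 3e4
        record = ramp_bandwidth({np.pi / 2: seeds[np.pi / 2]}, TWO_PI * 1e4,
                                target_om, TWO_PI * 1e4, q_list=[0.7],
                                tp=120e-6, n_offsets=31, max_iterations=100)
        warm = record.nodes[-1].quality
        spec = TargetSpec(np.pi / 2, 0.7, target_om, 120e-6)
        grid = EnsembleGrid.uniform_band(target_om, 31)
        cold = optimise(OptimisationProblem(seeds[np.pi / 2], spec, grid,
                                            max_iterations=300)).quality
        assert warm >= cold - 1e-6


class TestExpandDuration:
    def test_zero_length_expansion_is_identity(self):
        seeds = _seed_pulses()
        om = TWO_PI * 1e4
        record = ramp_bandwidth(seeds, om, om, TWO_PI * 5e3, q_list=[0.5],
                                tp=100e-6, n_offsets=15, max_iterations=60)
        n_before = len(record)
        expand_duration(record, 100e-6, 100e-6, 20e-6, q_list=[0.5],
                        bandwidth=om, n_offsets=15, max_iterations=60)
        assert len(record) == n_before

    def test_quality_nondecreasing_with_duration(self):
        """Longer pulses at fixed band reach equal or better quality."""
        seeds = _seed_pulses(n=60, tp=60e-6)
        om = TWO_PI * 2e4
        record = ramp_bandwidth(seeds, om, om, TWO_PI * 5e3, q_list=[0.6],
                                tp=60e-6, n_offsets=21, max_iterations=150)
        expand_duration(record, 60e-6, 120e-6, 20e-6, q_list=[0.6],
                        bandwidth=om, n_offsets=21, max_iterations=150)
        df = record.to_frame()
        for _, group in df.groupby("beta_deg"):
            q = group.sort_values("tp_us").quality.to_numpy()
            assert np.all(np.diff(q) > -5e-3)

    def test_expanded_shapes_remain_valid(self):
        seeds = _seed_pulses(n=40, tp=40e-6)
        om = TWO_PI * 1e4
        record = ramp_bandwidth(seeds, om, om, TWO_PI * 5e3, q_list=[0.5],
                                tp=40e-6, n_offsets=11, max_iterations=30)
        expand_duration(record, 40e-6, 80e-6, 20e-6, q_list=[0.5],
                        bandwidth=om, n_offsets=11, max_iterations=30)
        for node in record.nodes:
            assert node.pulse.n_slices == round(node.tp / node.pulse.slice_duration)
            assert np.all(node.pulse.amplitudes >= 0)


class TestSelectBestPair:
    def test_single_node_record(self):
        record, _ = planted_morph_record(seed=1, n_q=1, n_tp=1)
        pair = select_best_pair(record)
        assert pair.paired_quality == min(n.quality for n in record.nodes)

    def test_planted_maximum_is_found(self):
        record, (q_best, tp_best) = planted_morph_record(seed=4)
        pair = select_best_pair(record)
        assert pair.q == pytest.approx(q_best)
        assert pair.tp == pytest.approx(tp_best)

    def test_empty_record_rejected(self):
        from sordor.morph import MorphRunRecord
        with pytest.raises(ValueError):
            select_best_pair(MorphRunRecord())


@pytest.fixture(scope="module")
def nominal_pair():
    om = TWO_PI * 1e4
    seeds = _seed_pulses(n=80, tp=80e-6)
    record = ramp_bandwidth(seeds, om, om, TWO_PI * 5e3, q_list=[0.6],
                            tp=80e-6, n_offsets=21, max_iterations=250)
    return select_best_pair(record)


class TestB1Robustify:

    def test_ensemble_quality_improves(self, nominal_pair):
        grid = EnsembleGrid.uniform_band(nominal_pair.bandwidth, 21,
                                         b1_range=0.05, n_b1=5)
        before = min(
            ensemble_quality(nominal_pair.pulse90, nominal_pair.spec(np.pi / 2), grid),
            ensemble_quality(nominal_pair.pulse180, nominal_pair.spec(np.pi), grid))
        hard = b1_robustify(nominal_pair, b1_range=0.05, n_offsets=21,
                            max_iterations=400)
        assert hard.paired_quality >= before - 1e-9

    def test_nominal_quality_loss_is_bounded(self, nominal_pair):
        hard = b1_robustify(nominal_pair, b1_range=0.05, n_offsets=21,
                            max_iterations=400)
        grid = EnsembleGrid.uniform_band(nominal_pair.bandwidth, 21)
        nominal_after = ensemble_quality(hard.pulse90,
                                         nominal_pair.spec(np.pi / 2), grid)
        assert nominal_after >= nominal_pair.quality90 - 5e-3

    def test_zero_range_is_noop_up_to_reoptimisation(self, nominal_pair):
        same = b1_robustify(nominal_pair, b1_range=0.0, n_offsets=21,
                            max_iterations=100)
        assert same.paired_quality >= nominal_pair.paired_quality - 1e-6


class TestMorphRecordSerialisation:
    def test_summary_json_round_trip(self, tmp_path):
        import json
        record, _ = planted_morph_record(seed=2, n_q=2, n_tp=2)
        path = tmp_path / "record.json"
        record.save_summary(path)
        payload = json.loads(path.read_text())
        assert len(payload["nodes"]) == len(record)
        assert "pulse" not in payload["nodes"][0]
        frame = record.to_frame()
        assert {"q", "tp_us", "bandwidth_khz", "quality"} <= set(frame.columns)


class TestMatchedDuration:
    def test_interpolates_on_log_infidelity(self):
        import pandas as pd
        sweep = pd.DataFrame(dict(tp_us=[100.0, 200.0, 300.0],
                                  quality=[0.9, 0.99, 0.999],
                                  log10_infidelity=[-1.0, -2.0, -3.0]))
        assert matched_duration(sweep, 0.99) == pytest.approx(200.0)
        # halfway on the log scale
        assert matched_duration(sweep, 1 - 10**-1.5) == pytest.approx(150.0)
        with pytest.raises(ValueError):
            matched_duration(sweep, 0.99999)
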