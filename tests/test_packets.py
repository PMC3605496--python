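"""Packet detection, wave linking, and equilibrium statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synfire import DetectionParams, detect_packets, equilibrium_statistics, link_waves
from synfire.config import make_fixture
from synfire.engine import SpikeData
from synfire.packets import Packet


class TestDetectPackets:
    def test_empty_input(self):
        assert detect_packets(np.array([]), DetectionParams()) == []

    def test_planted_packet_on_sparse_background(self):
        """A 100-neuron pool with 80 spikes in [50, 51] ms and 2 background
        spikes elsewhere yields exactly one packet with the stated size and
        median location."""
        rng = np.random.default_rng(3)
        packet = np.sort(rng.uniform(50.0, 51.0, size=80))
        times = np.sort(np.concatenate([[10.0, 400.0], packet]))
        det = DetectionParams(n_theta=40)
        pk = detect_packets(times, det, pool=7)
        assert len(pk) == 1
        q = pk[0]
        assert q.pool == 7
        assert 50.0 <= q.time <= 51.0
        assert q.size >= 80
        # median tie-break: lower middle element of the sublist
        assert q.time == q.spike_times[(q.spike_times.size - 1) // 2]

    def test_constant_subthreshold_rate_yields_nothing(self):
        times = np.arange(0.0, 500.0, 0.2)  # 15 per window of 3 ms
        det = DetectionParams(n_theta=20)
        assert detect_packets(times, det) == []

    def test_minimum_run_length_excludes_marginal_blips(self):
        # 7 spikes in a tight cluster: each window holds 7 > n_theta=5 but the
        # suprathreshold run is shorter than min_run
        times = np.sort(np.random.default_rng(1).uniform(10.0, 10.2, 5))
        det = DetectionParams(n_theta=4, min_run=6)
        assert detect_packets(times, det) == []

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(0.0, 500.0))
    def test_translation_invariance(self, shift):
        rng = np.random.default_rng(11)
        base = np.sort(
            np.concatenate([rng.uniform(20.0, 21.0, 50), rng.uniform(0.0, 100.0, 8)])
        )
        det = DetectionParams(n_theta=25)
        a = detect_packets(base, det)
        b = detect_packets(base + shift, det)
        assert len(a) == len(b) == 1
        assert b[0].time - a[0].time == pytest.approx(shift, abs=1e-9)
        assert a[0].size == b[0].size

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            detect_packets(np.array([2.0, 1.0]), DetectionParams())


class TestLinkWaves:
    @staticmethod
    def _packets(times_by_pool):
        return {
            mu: [Packet(pool=mu, time=t, size=50) for t in ts]
            for mu, ts in times_by_pool.items()
        }

    def test_uniform_gaps_form_single_wave(self):
        pk = self._packets({mu: [100.0 + 2.5 * mu] for mu in range(10)})
        ws = link_waves(pk, DetectionParams())
        assert ws.n_waves == 1
        assert len(ws.waves[0]) == 10

    def test_large_gap_breaks_chain(self):
        times = {mu: [100.0 + 2.5 * mu] for mu in range(5)}
        times.update({mu: [100.0 + 2.5 * 4 + 7.0 + 2.5 * (mu - 5)] for mu in range(5, 10)})
        ws = link_waves(self._packets(times), DetectionParams())
        assert ws.n_waves == 2
        assert sorted(len(w) for w in ws.waves) == [5, 5]

    def test_lapping_links_to_earlier_candidate(self):
        pk = self._packets({0: [100.0], 1: [102.0, 104.0]})
        ws = link_waves(pk, DetectionParams(), n_pools=2)
        first = ws.waves[0]
        assert [q.time for q in first] == [100.0, 102.0]

    def test_each_packet_in_at_most_one_wave(self):
        rng = np.random.default_rng(5)
        pk = self._packets(
            {mu: sorted(rng.uniform(0, 400, rng.integers(0, 4))) for mu in range(20)}
        )
        ws = link_waves(pk, DetectionParams())
        seen = set()
        for w in ws.waves:
            for q in w:
                key = (q.pool, q.time)
                assert key not in seen
                seen.add(key)

    def test_ring_wraps_across_last_pool(self):
        pk = self._packets({0: [100.0, 112.0], 1: [103.0], 2: [106.0], 3: [109.0]})
        ws = link_waves(pk, DetectionParams(), n_pools=4, ring=True)
        assert max(len(w) for w in ws.waves) == 5  # wrapped 3 -> 0


class TestEquilibriumStatistics:
    @staticmethod
    def _spikes(times, n_neurons=100, duration=3000.0):
        times = np.asarray(times, dtype=float)
        return SpikeData(
            neuron_ids=np.zeros(times.size, dtype=np.int64),
            times=np.sort(times), n_neurons=n_neurons, duration=duration, dt=0.1,
        )

    def test_no_waves_gives_zero_statistics(self):
        from synfire.packets import WaveSet

        stats = equilibrium_statistics(
            self._spikes([]), WaveSet(waves=[], n_pools=10)
        )
        assert stats.mean_h == 0.0 and stats.max_h == 0
        assert stats.t_start == 1000.0
        assert stats.mean_nu == 0.0

    def test_single_uninterrupted_wave_counts_one(self):
        packets = [
            Packet(pool=k % 10, time=50.0 + 3.0 * k, size=10,
                   spike_times=np.array([50.0 + 3.0 * k]),
                   spike_ids=np.array([k % 7]))
            for k in range(990)
        ]
        from synfire.packets import WaveSet

        ws = WaveSet(waves=[packets], n_pools=10)
        stats = equilibrium_statistics(
            self._spikes([q.time for q in packets]), ws
        )
        assert stats.max_h == 1
        assert stats.mean_h == pytest.approx(1.0, abs=0.05)

    def test_duration_floor(self):
        from synfire.packets import WaveSet

        with pytest.raises(ValueError):
            equilibrium_statistics(
                self._spikes([], duration=1500.0), WaveSet(waves=[], n_pools=5)
            )

    def test_packet_spikes_counted_once_across_overlapping_pools(self):
        """The same physical spike appearing in two pools' packets adds to
        nu_W only once."""
        from synfire.packets import WaveSet

        t = np.array([1500.0, 1500.1, 1500.2])
        ids = np.array([1, 2, 3])
        p1 = Packet(pool=0, time=1500.1, size=3, spike_times=t, spike_ids=ids)
        p2 = Packet(pool=1, time=1500.1, size=3, spike_times=t, spike_ids=ids)
        ws = WaveSet(waves=[[p1], [p2]], n_pools=2)
        spikes = self._spikes(t, n_neurons=10, duration=3000.0)
        stats = equilibrium_statistics(spikes, ws, transient_floor=1000.0)
        # nu_W integrates 3 unique spikes, not 6
        window_s = (3000.0 - stats.t_start) / 1000.0
        assert stats.mean_nu_W == pytest.approx(3 / 10 / window_s)


class TestPlantedFixtureRecovery:
    def test_recall_and_precision_are_perfect(self):
        """On planted packets (>= 0.8 n_E spikes) over <= 5 Hz background,
        detection finds every planted packet and nothing else."""
        for seed in (0, 1, 2):
            fx = make_fixture(
                "raster_with_packets",
                {"n_pools": 12, "n_E": 100, "duration": 2000.0,
                 "background_Hz": 5.0, "packet_frac": 0.8},
                seed=seed,
            )
            det = DetectionParams.for_pool_size(fx["n_E"])
            hits, detected = 0, 0
            for mu, times in fx["rasters"].items():
                pk = detect_packets(times, det, pool=mu)
                detected += len(pk)
                hits += any(
                    abs(q.time - fx["planted_times"][mu]) <= det.T_w for q in pk
                )
            assert hits == len(fx["rasters"])  # recall 1.0
            assert detected == len(fx["rasters"])  # precision 1.0
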