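"""Spike-packet extraction, wave linking, and equilibrium statistics.

Packet detection operates on the merged spike train of one pool. Around every
spike time ``t_k`` a window ``[t_k, t_k + T_w)`` (T_w = 3 ms) defines a sublist
``S_k``; sublists with more than ``n_theta`` spikes are *suprathreshold*
(``n_theta ~= 0.4 n_E`` in the low-background regime this detector targets).
Maximal consecutive runs of at least 6 suprathreshold sublists each yield one
packet: among the run's sublists with maximal count, the middle one (index
``floor(m/2)``, 0-based) is the packet; its time is the median of its spike
times (lower-middle element for even sizes).

Waves are chains of packets on consecutive pools whose inter-packet interval
lies in the link window (0.5 to 6 ms). From the extracted waves the module
computes the time-resolved wave count h(t), the population rate nu(t) and the
packet-spike rate nu_W(t), plus their equilibrium means after the initial
transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectionParams",
    "Packet",
    "WaveSet",
    "detect_packets",
    "link_waves",
    "equilibrium_statistics",
    "EquilibriumStats",
]


@dataclass(frozen=True)
class DetectionParams:
    """Packet-detection constants (times in ms, counts in spikes)."""

    T_w: float = 3.0
    n_theta: int = 40
    min_run: int = 6
    link_window: tuple[float, float] = (0.5, 6.0)
    rate_bin: float = 20.0

    def __post_init__(self):
        if self.T_w <= 0:
            raise ValueError("T_w must be positive")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.n_theta < 1:
            raise ValueError("n_theta must be >= 1")

    @classmethod
    def for_pool_size(cls, n_E: int, **kw) -> "DetectionParams":
        """Default count threshold n_theta = round(0.4 * n_E)."""
        return cls(n_theta=int(round(0.4 * n_E)), **kw)


@dataclass
class Packet:
    pool: int
    time: float  # median spike time, ms
    size: int  # spike count of the packet sublist
    spike_times: np.ndarray = field(repr=False, default=None)
    spike_ids: np.ndarray | None = field(repr=False, default=None)
    wave_id: int = -1


def detect_packets(
    pool_spike_times: np.ndarray,
    params: DetectionParams,
    pool: int = 0,
    spike_ids: np.ndarray | None = None,
) -> list[Packet]:
    """Extract spike packets from the sorted merged spike train of one pool.

    ``spike_ids``, when given (aligned with the times), lets downstream rate
    accounting identify each packet-member spike uniquely even when pools
    overlap.
    """
    t = np.asarray(pool_spike_times, dtype=float)
    if t.size == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    # |S_k| = number of spikes in [t_k, t_k + T_w)
    counts = np.searchsorted(t, t + params.T_w, side="left") - np.arange(t.size)
    supra = counts > params.n_theta

    packets: list[Packet] = []
    k = 0
    n = t.size
    while k < n:
        if not supra[k]:
            k += 1
            continue
        end = k
        while end < n and supra[end]:
            end += 1
        run = np.arange(k, end)  # maximal run of suprathreshold sublists
        if run.size >= params.min_run:
            run_counts = counts[run]
            maxc = run_counts.max()
            best = run[run_counts == maxc]
            j = int(best[best.size // 2])  # middle maximal sublist
            spikes = t[j : j + counts[j]]
            median = spikes[(spikes.size - 1) // 2]  # lower-middle for even n
            ids = spike_ids[j : j + counts[j]] if spike_ids is not None else None
            packets.append(
                Packet(pool=pool, time=float(median), size=int(counts[j]),
                       spike_times=spikes, spike_ids=ids)
            )
        k = end
    return packets


@dataclass
class WaveSet:
    """Linked waves; ``waves[i]`` is an ordered list of packets."""

    waves: list[list[Packet]]
    n_pools: int

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    def all_packets(self):
        for w in self.waves:
            yield from w


def link_waves(
    packets_by_pool: dict[int, list[Packet]] | list[list[Packet]],
    params: DetectionParams,
    n_pools: int | None = None,
    ring: bool = False,
) -> WaveSet:
    """Greedy chaining of consecutive-pool packets.

    Two packets on consecutive pools are linked if the interval between them
    lies in the link window; when several successor packets qualify (wave
    lapping) the earliest is chosen. Each packet joins at most one wave.
    Waves are seeded from unconsumed packets in global time order.
    """
    if isinstance(packets_by_pool, dict):
        pools = packets_by_pool
        n_pools = n_pools if n_pools is not None else (max(pools) + 1 if pools else 0)
    else:
        pools = {i: pk for i, pk in enumerate(packets_by_pool)}
        n_pools = n_pools if n_pools is not None else len(packets_by_pool)
    for mu, pk in pools.items():
        pk.sort(key=lambda q: q.time)

    lo, hi = params.link_window
    seeds = sorted(
        ((q.time, mu, i) for mu, pk in pools.items() for i, q in enumerate(pk))
    )
    consumed: set[tuple[int, int]] = set()
    waves: list[list[Packet]] = []
    for _, mu, i in seeds:
        if (mu, i) in consumed:
            continue
        wave = [pools[mu][i]]
        consumed.add((mu, i))
        cur_mu, cur_t = mu, pools[mu][i].time
        while True:
            nxt = cur_mu + 1
            if ring:
                nxt %= n_pools
            elif nxt >= n_pools:
                break
            cand = None
            for j, q in enumerate(pools.get(nxt, [])):
                if (nxt, j) in consumed:
                    continue
                gap = q.time - cur_t
                if lo <= gap <= hi:
                    cand = (nxt, j)
                    break  # packets sorted by time: first hit is earliest
                if gap > hi:
                    break
            if cand is None:
                break
            consumed.add(cand)
            q = pools[cand[0]][cand[1]]
            wave.append(q)
            cur_mu, cur_t = cand[0], q.time
        waves.append(wave)
    for wid, w in enumerate(waves):
        for q in w:
            q.wave_id = wid
    return WaveSet(waves=waves, n_pools=n_pools)


def extract_pool_packets(
    spikes,
    pools_E: np.ndarray,
    params: DetectionParams,
) -> dict[int, list[Packet]]:
    """Per-pool packet extraction for a SpikeData-like object.

    ``pools_E`` is the (n_pools, n_E) membership table; each pool's merged
    spike train is assembled from its members (a neuron belonging to several
    pools contributes its train to each of them).
    """
    order = np.argsort(spikes.neuron_ids, kind="stable")
    ids_s = spikes.neuron_ids[order]
    ts_s = spikes.times[order]
    n_ids = int(pools_E.max()) + 1 if pools_E.size else 0
    starts = np.searchsorted(ids_s, np.arange(n_ids + 1))
    per_pool: dict[int, list[Packet]] = {}
    for mu in range(pools_E.shape[0]):
        t_parts, i_parts = [], []
        for j in pools_E[mu]:
            lo, hi = starts[j], starts[j + 1]
            t_parts.append(ts_s[lo:hi])
            i_parts.append(ids_s[lo:hi])
        t = np.concatenate(t_parts) if t_parts else np.empty(0)
        i = np.concatenate(i_parts) if i_parts else np.empty(0, dtype=np.int64)
        o = np.argsort(t, kind="stable")
        per_pool[mu] = detect_packets(t[o], params, pool=mu, spike_ids=i[o])
    return per_pool


@dataclass
class EquilibriumStats:
    mean_nu: float  # Hz, all spikes
    mean_nu_W: float  # Hz, packet-member spikes
    mean_h: float
    max_h: int
    t_start: float  # ms
    h_t: np.ndarray = field(repr=False, default=None)  # per-dt wave count
    nu_W_t: np.ndarray = field(repr=False, default=None)  # per rate_bin, Hz
    nu_t: np.ndarray = field(repr=False, default=None)  # per rate_bin, Hz


def equilibrium_statistics(
    spikes,
    waves: WaveSet,
    total_duration: float | None = None,
    params: DetectionParams = DetectionParams(),
    transient_floor: float = 1000.0,
) -> EquilibriumStats:
    """Wave-count and rate statistics after the initial transient.

    ``spikes`` is a SpikeData-like object (``times``, ``neuron_ids``,
    ``n_neurons``, ``duration``, ``dt``). A wave is counted alive from its
    first packet time to its last packet time plus one link interval (the
    wave's mean inter-packet gap; 3 ms for single-packet waves). The analysis
    window starts at t_start = max(transient_floor, t_mean), where t_mean is
    when h(t) first exceeds its mean over [transient_floor, duration].
    """
    duration = float(total_duration or spikes.duration)
    if duration < 2000.0:
        raise ValueError("need at least 2000 ms for equilibrium statistics")
    dt = spikes.dt
    nbins = int(round(duration / dt))
    h_t = np.zeros(nbins)
    for w in waves.waves:
        t0 = w[0].time
        if len(w) > 1:
            t1 = w[-1].time + (w[-1].time - w[0].time) / (len(w) - 1)
        else:
            t1 = w[0].time + 3.0
        i0 = min(nbins, max(0, int(t0 / dt)))
        i1 = min(nbins, max(0, int(np.ceil(t1 / dt))))
        h_t[i0:i1] += 1

    floor_idx = int(transient_floor / dt)
    if waves.n_waves == 0:
        t_start = transient_floor
    else:
        h_mean_ref = h_t[floor_idx:].mean()
        above = np.nonzero(h_t >= h_mean_ref)[0]  # >= so a flat h(t) qualifies
        t_mean = above[0] * dt if above.size else duration
        t_start = max(transient_floor, float(t_mean))

    window_ms = duration - t_start
    window_s = window_ms / 1000.0
    i_start = int(t_start / dt)

    sel = spikes.times >= t_start
    mean_nu = sel.sum() / spikes.n_neurons / window_s if window_s > 0 else 0.0

    # packet-member spikes, deduplicated across overlapping pools: a spike is
    # identified by (neuron id, grid time) where ids are available
    pk_t, pk_key = [], []
    for q in waves.all_packets():
        if q.spike_times is None:
            continue
        pk_t.append(q.spike_times)
        if q.spike_ids is not None:
            steps = np.round(q.spike_times / dt).astype(np.int64)
            pk_key.append(q.spike_ids.astype(np.int64) * (nbins + 1) + steps)
        else:
            pk_key.append(np.round(q.spike_times / dt).astype(np.int64))
    if pk_t:
        _, first = np.unique(np.concatenate(pk_key), return_index=True)
        pk_all = np.concatenate(pk_t)[first]
    else:
        pk_all = np.empty(0)
    mean_nu_W = (
        (pk_all >= t_start).sum() / spikes.n_neurons / window_s
        if window_s > 0
        else 0.0
    )

    if waves.n_waves == 0:
        mean_h, max_h = 0.0, 0
    else:
        mean_h = float(h_t[i_start:].mean()) if i_start < nbins else 0.0
        max_h = int(h_t[i_start:].max()) if i_start < nbins else 0

    nbig = int(np.ceil(duration / params.rate_bin))
    edges = np.arange(nbig + 1) * params.rate_bin
    per_bin_s = params.rate_bin / 1000.0
    nu_t = np.histogram(spikes.times, bins=edges)[0] / spikes.n_neurons / per_bin_s
    nu_W_t = np.histogram(pk_all, bins=edges)[0] / spikes.n_neurons / per_bin_s

    return EquilibriumStats(
        mean_nu=float(mean_nu), mean_nu_W=float(mean_nu_W),
        mean_h=mean_h, max_h=max_h, t_start=float(t_start),
        h_t=h_t, nu_W_t=nu_W_t, nu_t=nu_t,
    )
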