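"""Construction of synfire-chain embeddings and non-embedded control chains.

The embedding places ``p`` excitatory pools of size ``n_E`` (and paired
inhibitory "shadow" pools of size ``n_I = gamma * n_E``) into populations of
``N_E`` excitatory and ``N_I = gamma * N_E`` inhibitory neurons. Pool
membership is balanced: every neuron appears in ``floor(p*n_E/N_E)`` or
``ceil(p*n_E/N_E)`` pools and the members of any single pool are distinct.
All excitatory synapses are pool-to-pool links: E-pool mu projects all-to-all
onto E-pool mu+1 and I-pool mu+1, with the pools ordered into a single ring,
so the embedding is at combinatorial capacity

    C_E = p n_E^2 / N_E = alpha n_E^2,

where alpha = p/N_E is the embedding level. Inhibitory neurons connect to
random targets such that every neuron's inhibitory in-degree equals
``round(gamma' * excitatory in-degree)``.

Excitatory transmission delays are the sum of an inter-link component
tau_A ~ U[0.5, 4.5) ms drawn once per pool-to-pool link and an intra-link
component tau_B ~ U[0, 0.5) ms drawn per synapse; inhibitory synapses draw
both components independently per synapse. Delays are rounded half-up to the
dt grid with a one-step minimum.

``build_control_chain`` builds the open, non-overlapping feedforward chain
used to characterize packet propagation under external Poisson background.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from ._rng import stream_rng

__all__ = [
    "EmbeddingConfig",
    "DelayModel",
    "NetworkSpec",
    "DerivedCounts",
    "derive_counts",
    "build_embedding",
    "build_control_chain",
]

DT_DEFAULT = 0.1  # ms; simulation grid, shared by delays and spike times


@dataclass(frozen=True)
class EmbeddingConfig:
    """Geometry of one embedding realization."""

    C_E: int
    n_E: int
    gamma: float = 0.25
    gamma_prime: float = 0.25
    N_E: int | None = None  # defaults to 10*C_E (10% connection probability)
    seed: int = 0

    @property
    def N_E_effective(self) -> int:
        return int(self.N_E if self.N_E is not None else 10 * self.C_E)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class DelayModel:
    """Two-component transmission-delay distribution (ms)."""

    tau_A_range: tuple[float, float] = (0.5, 4.5)  # per-link, spread 4.0 ms
    tau_B_range: tuple[float, float] = (0.0, 0.5)  # per-synapse, spread 0.5 ms

    def draw_tau_A(self, rng: np.random.Generator, size=None):
        return rng.uniform(*self.tau_A_range, size=size)

    def draw_tau_B(self, rng: np.random.Generator, size=None):
        return rng.uniform(*self.tau_B_range, size=size)


def round_delay_to_steps(delay_ms, dt: float = DT_DEFAULT) -> np.ndarray:
    """Half-up rounding to the dt grid with a one-step minimum."""
    steps = np.floor(np.asarray(delay_ms) / dt + 0.5).astype(np.int64)
    return np.maximum(steps, 1)


class DerivedCounts(NamedTuple):
    p: int
    alpha: float
    N_I: int
    n_I: int
    C_I: int


def derive_counts(config: EmbeddingConfig) -> DerivedCounts:
    """Pool count, embedding level and inhibitory bookkeeping for a config.

    p is the nearest integer to N_E*C_E/n_E^2 (combinatorial capacity) and
    alpha = C_E/n_E^2 pools per excitatory neuron. gamma*n_E and gamma*N_E
    must be integral (within rounding tolerance).
    """
    if config.n_E < 1:
        raise ValueError("n_E must be >= 1")
    if config.C_E < config.n_E:
        raise ValueError("C_E must be >= n_E")
    N_E = config.N_E_effective
    p = int(round(N_E * config.C_E / config.n_E**2))
    if p < 1:
        raise ValueError("derived pool count p < 1")
    alpha = config.C_E / config.n_E**2
    n_I_f = config.gamma * config.n_E
    N_I_f = config.gamma * N_E
    if abs(n_I_f - round(n_I_f)) > 1e-9 or abs(N_I_f - round(N_I_f)) > 1e-9:
        raise ValueError(
            f"gamma={config.gamma} does not give integral pool/population "
            f"sizes for n_E={config.n_E}, N_E={N_E}"
        )
    C_I = int(round(config.gamma_prime * config.C_E))
    return DerivedCounts(p, alpha, int(round(N_I_f)), int(round(n_I_f)), C_I)


@dataclass
class NetworkSpec:
    """One network realization: pools, synapses (CSR by presynaptic id), delays.

    Neuron ids: excitatory 0..N_E-1, inhibitory N_E..N_E+N_I-1. A synapse's
    sign is that of its presynaptic neuron.
    """

    N_E: int
    N_I: int
    pools_E: np.ndarray  # (p, n_E) int
    pools_I: np.ndarray | None  # (p, n_I) int or None
    indptr: np.ndarray  # (N+1,) CSR row pointer over presynaptic id
    targets: np.ndarray  # (n_syn,) postsynaptic ids
    delay_steps: np.ndarray  # (n_syn,) int, on the dt grid
    dt: float = DT_DEFAULT
    ring: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.N_E + self.N_I

    @property
    def n_pools(self) -> int:
        return self.pools_E.shape[0]

    @property
    def n_E(self) -> int:
        return self.pools_E.shape[1]

    @property
    def n_synapses(self) -> int:
        return int(self.targets.size)

    def outputs_of(self, neuron_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(targets, delay_steps) of one presynaptic neuron, O(out-degree)."""
        lo, hi = self.indptr[neuron_id], self.indptr[neuron_id + 1]
        return self.targets[lo:hi], self.delay_steps[lo:hi]

    def exc_in_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_neurons, dtype=np.int64)
        exc_hi = self.indptr[self.N_E]
        np.add.at(deg, self.targets[: int(exc_hi)], 1)
        return deg

    def inh_in_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_neurons, dtype=np.int64)
        exc_hi = self.indptr[self.N_E]
        np.add.at(deg, self.targets[int(exc_hi):], 1)
        return deg

    def pool_count_per_neuron(self) -> np.ndarray:
        cnt = np.zeros(self.n_neurons, dtype=np.int64)
        np.add.at(cnt, self.pools_E.ravel(), 1)
        if self.pools_I is not None and self.pools_I.size:
            np.add.at(cnt, self.pools_I.ravel(), 1)
        return cnt

    # -- serialization: named arrays + JSON metadata in one .npz container --

    def save(self, path) -> None:
        meta = dict(self.meta)
        meta.update(
            N_E=self.N_E, N_I=self.N_I, dt=self.dt, ring=self.ring,
            has_pools_I=self.pools_I is not None,
        )
        arrays = dict(
            pools_E=self.pools_E,
            indptr=self.indptr,
            targets=self.targets,
            delay_steps=self.delay_steps,
            meta_json=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )
        if self.pools_I is not None:
            arrays["pools_I"] = self.pools_I
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "NetworkSpec":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            pools_I = z["pools_I"] if meta.pop("has_pools_I") else None
            return cls(
                N_E=int(meta.pop("N_E")),
                N_I=int(meta.pop("N_I")),
                pools_E=z["pools_E"],
                pools_I=pools_I,
                indptr=z["indptr"],
                targets=z["targets"],
                delay_steps=z["delay_steps"],
                dt=float(meta.pop("dt")),
                ring=bool(meta.pop("ring")),
                meta=meta,
            )


def _balanced_pool_assignment(
    n_population: int, p: int, pool_size: int, rng: np.random.Generator, id_offset: int = 0
) -> np.ndarray:
    """Assign neurons to pools so that per-neuron pool counts differ by <= 1
    and members within each pool are distinct.

    Sampling without replacement from a replicated id multiset, followed by a
    swap-repair pass for within-pool duplicates.
    """
    total = p * pool_size
    base, extra = divmod(total, n_population)
    counts = np.full(n_population, base, dtype=np.int64)
    if extra:
        counts[rng.choice(n_population, size=extra, replace=False)] += 1
    multiset = np.repeat(np.arange(n_population, dtype=np.int64), counts)
    rng.shuffle(multiset)
    pools = multiset.reshape(p, pool_size)

    # repair within-pool duplicates by swapping with entries of other pools
    for _ in range(1000):
        dup_rows = []
        for mu in range(p):
            row = pools[mu]
            if np.unique(row).size != pool_size:
                dup_rows.append(mu)
        if not dup_rows:
            break
        for mu in dup_rows:
            row = pools[mu]
            seen: set[int] = set()
            for j in range(pool_size):
                v = int(row[j])
                if v in seen:
                    # swap with a random slot elsewhere that keeps both rows valid
                    for _attempt in range(200):
                        mu2 = int(rng.integers(p))
                        if mu2 == mu:
                            continue
                        j2 = int(rng.integers(pool_size))
                        w = int(pools[mu2, j2])
                        if w not in seen and w not in set(row) and v not in set(pools[mu2]):
                            pools[mu, j], pools[mu2, j2] = w, v
                            break
                    seen.add(int(pools[mu, j]))
                else:
                    seen.add(v)
    else:
        raise RuntimeError("pool assignment repair did not converge")
    return pools + id_offset


def _csr_from_coo(pre, post, delay_steps, n_neurons):
    order = np.argsort(pre, kind="stable")
    pre = np.asarray(pre)[order]
    post = np.asarray(post)[order]
    delay_steps = np.asarray(delay_steps)[order]
    indptr = np.zeros(n_neurons + 1, dtype=np.int64)
    np.add.at(indptr, pre + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, post.astype(np.int64), delay_steps.astype(np.int64)


def build_embedding(
    config: EmbeddingConfig,
    delays: DelayModel = DelayModel(),
    seed: int | None = None,
    dt: float = DT_DEFAULT,
) -> NetworkSpec:
    """One realization of the ring embedding at combinatorial capacity."""
    counts = derive_counts(config)
    N_E = config.N_E_effective
    if config.n_E > N_E:
        raise ValueError("n_E may not exceed N_E")
    seed = config.seed if seed is None else seed
    rng = stream_rng(seed, "embedding")

    p, n_I, N_I = counts.p, counts.n_I, counts.N_I
    pools_E = _balanced_pool_assignment(N_E, p, config.n_E, rng)
    pools_I = _balanced_pool_assignment(N_I, p, n_I, rng, id_offset=N_E)

    n_E = config.n_E
    fan_out = n_E + n_I
    n_exc_syn = p * n_E * fan_out
    pre = np.empty(n_exc_syn, dtype=np.int64)
    post = np.empty(n_exc_syn, dtype=np.int64)
    delay = np.empty(n_exc_syn, dtype=np.float64)
    tau_A = delays.draw_tau_A(rng, size=p)
    k = 0
    for mu in range(p):
        nxt = (mu + 1) % p
        tgt = np.concatenate([pools_E[nxt], pools_I[nxt]])
        blk = n_E * fan_out
        pre[k : k + blk] = np.repeat(pools_E[mu], fan_out)
        post[k : k + blk] = np.tile(tgt, n_E)
        delay[k : k + blk] = tau_A[mu] + delays.draw_tau_B(rng, size=blk)
        k += blk

    # inhibitory synapses: per-target in-degree = round(gamma' * exc in-degree)
    exc_in = np.zeros(N_E + N_I, dtype=np.int64)
    np.add.at(exc_in, post, 1)
    inh_in = np.round(config.gamma_prime * exc_in).astype(np.int64)
    total_inh = int(inh_in.sum())
    pre_i = np.empty(total_inh, dtype=np.int64)
    post_i = np.empty(total_inh, dtype=np.int64)
    k = 0
    for tgt_id in range(N_E + N_I):
        m = int(inh_in[tgt_id])
        if m == 0:
            continue
        srcs = rng.choice(N_I, size=m, replace=False) + N_E
        pre_i[k : k + m] = srcs
        post_i[k : k + m] = tgt_id
        k += m
    delay_i = delays.draw_tau_A(rng, size=total_inh) + delays.draw_tau_B(
        rng, size=total_inh
    )

    pre_all = np.concatenate([pre, pre_i])
    post_all = np.concatenate([post, post_i])
    steps_all = round_delay_to_steps(np.concatenate([delay, delay_i]), dt)
    indptr, targets, delay_steps = _csr_from_coo(
        pre_all, post_all, steps_all, N_E + N_I
    )
    meta = {
        "kind": "embedding",
        "config": dataclasses.asdict(config),
        "config_hash": config.content_hash(),
        "seed": seed,
        "p": p,
        "alpha": counts.alpha,
    }
    return NetworkSpec(
        N_E=N_E, N_I=N_I, pools_E=pools_E, pools_I=pools_I,
        indptr=indptr, targets=targets, delay_steps=delay_steps,
        dt=dt, ring=True, meta=meta,
    )


def build_control_chain(
    n_E: int,
    n_pools: int = 100,
    delays: DelayModel = DelayModel(),
    seed: int = 0,
    dt: float = DT_DEFAULT,
) -> NetworkSpec:
    """Open feedforward chain of disjoint pools (no inhibitory population).

    Used to measure packet-propagation statistics under external Poisson
    background. Link delays follow the embedding's distribution: one tau_A per
    link plus per-synapse tau_B jitter.
    """
    if n_pools < 2:
        raise ValueError("need at least two pools")
    rng = stream_rng(seed, "control-chain")
    N = n_pools * n_E
    pools_E = np.arange(N, dtype=np.int64).reshape(n_pools, n_E)
    n_syn = (n_pools - 1) * n_E * n_E
    pre = np.empty(n_syn, dtype=np.int64)
    post = np.empty(n_syn, dtype=np.int64)
    delay = np.empty(n_syn, dtype=np.float64)
    tau_A = delays.draw_tau_A(rng, size=n_pools - 1)
    blk = n_E * n_E
    for mu in range(n_pools - 1):
        k = mu * blk
        pre[k : k + blk] = np.repeat(pools_E[mu], n_E)
        post[k : k + blk] = np.tile(pools_E[mu + 1], n_E)
        delay[k : k + blk] = tau_A[mu] + delays.draw_tau_B(rng, size=blk)
    indptr, targets, delay_steps = _csr_from_coo(
        pre, post, round_delay_to_steps(delay, dt), N
    )
    meta = {"kind": "control_chain", "n_pools": n_pools, "seed": seed}
    return NetworkSpec(
        N_E=N, N_I=0, pools_E=pools_E, pools_I=None,
        indptr=indptr, targets=targets, delay_steps=delay_steps,
        dt=dt, ring=False, meta=meta,
    )
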