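"""Time-stepped network simulation and packet-propagation characterization.

The integrator advances all neurons on a fixed dt grid (0.1 ms by default).
Presynaptic spikes are delivered through a circular calendar whose depth is
the maximum synaptic delay in steps; per step each neuron receives integer
counts of excitatory and inhibitory events (calendar deliveries plus optional
external Poisson background), applied as instantaneous jumps after the leak
decay (excitatory before inhibitory, threshold test last).

Wave-initiating stimuli are packets of ``n_E`` input spikes, normally
distributed in time (sigma = 0.1 ms) around the stimulus time, delivered to
every neuron of the target E-pool (and its shadow I-pool, when present) with
an independent intra-link delay per spike and target.

``characterize_propagation`` runs the control-chain protocol: 100 ms of
background-only warm-up, a stimulus packet into the third pool, and detection
of the resulting wave. From repeated trials it estimates the survival
probability P_S over the chain, the participation probability p_f (mean packet
size / n_E over surviving trials), and the mean pool-to-pool propagation time
T (time between the packets ten pools apart at the end of the chain, /10).
Trials of one cell are simulated as a single vectorized batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._rng import stream_rng, stream_seed
from .network import DelayModel, NetworkSpec, build_control_chain
from .neurons import NeuronParams
from . import packets as _packets

__all__ = [
    "StimulusProtocol",
    "SpikeData",
    "PropagationTable",
    "run_network",
    "characterize_propagation",
    "build_propagation_table",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Ongoing wave-initiation stimuli (times in ms)."""

    target_pool: int = 0
    period: float = 40.0
    start: float = 200.0
    packet_size: int | None = None  # None -> n_E of the target pool
    packet_sigma: float = 0.1
    transient_ramp: tuple[float, float] | None = None  # initial (lam_E, lam_I) kHz

    def stimulus_times(self, duration: float) -> np.ndarray:
        if self.period <= 0:
            raise ValueError("stimulus period must be positive")
        if self.start >= duration:
            return np.array([])
        return np.arange(self.start, duration, self.period)


@dataclass
class SpikeData:
    """Spike records of one run: (neuron id, time ms), ascending in time."""

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: float
    dt: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.times.size)

    def spikes_of(self, neuron_subset) -> np.ndarray:
        mask = np.isin(self.neuron_ids, neuron_subset)
        return self.times[mask]

    def save(self, path) -> None:
        """Two-column whitespace text (neuron_id time_ms) + JSON sidecar."""
        with open(path, "w") as fh:
            for nid, t in zip(self.neuron_ids, self.times):
                fh.write(f"{int(nid)} {t:.4f}\n")
        sidecar = dict(self.meta)
        sidecar.update(
            n_neurons=self.n_neurons, duration=self.duration, dt=self.dt
        )
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(sidecar, fh, indent=1, default=str)

    @classmethod
    def load(cls, path) -> "SpikeData":
        rows = [line.split() for line in open(path) if line.strip()]
        data = np.asarray(rows, dtype=float) if rows else np.empty((0, 2))
        with open(str(path) + ".meta.json") as fh:
            meta = json.load(fh)
        return cls(
            neuron_ids=data[:, 0].astype(np.int64),
            times=data[:, 1],
            n_neurons=int(meta.pop("n_neurons")),
            duration=float(meta.pop("duration")),
            dt=float(meta.pop("dt")),
            meta=meta,
        )


def _stim_schedule(
    spec: NetworkSpec,
    protocol: StimulusProtocol,
    delays: DelayModel,
    duration: float,
    dt: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """All stimulus deliveries of one trial as (sorted step, target) arrays."""
    times = protocol.stimulus_times(duration)
    if times.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    pool = protocol.target_pool
    tgt = spec.pools_E[pool]
    if spec.pools_I is not None:
        tgt = np.concatenate([tgt, spec.pools_I[pool]])
    n_spikes = protocol.packet_size or spec.n_E
    steps_all, tgts_all = [], []
    for t0 in times:
        spike_t = rng.normal(t0, protocol.packet_sigma, size=n_spikes)
        # one delivery per (input spike, target neuron), independent tau_B
        tb = delays.draw_tau_B(rng, size=(n_spikes, tgt.size))
        t_arr = spike_t[:, None] + tb
        steps = np.floor(t_arr / dt + 0.5).astype(np.int64).ravel()
        steps_all.append(steps)
        tgts_all.append(np.tile(tgt, n_spikes))
    steps = np.concatenate(steps_all)
    tgts = np.concatenate(tgts_all)
    order = np.argsort(steps, kind="stable")
    return steps[order], tgts[order]


class _AliasPoisson:
    """Vectorized Poisson sampler for one fixed mean (Walker alias method).

    Cheaper than ``Generator.poisson`` for the per-step background draws,
    where the mean is constant across neurons and steps.
    """

    def __init__(self, mean: float, tail: float = 1e-14):
        from scipy import stats

        nmax = max(4, int(stats.poisson.isf(tail, mean)) + 2)
        pmf = stats.poisson.pmf(np.arange(nmax), mean)
        pmf = pmf / pmf.sum()
        m = pmf.size
        prob = pmf * m
        alias = np.zeros(m, dtype=np.int64)
        small = [i for i in range(m) if prob[i] < 1.0]
        large = [i for i in range(m) if prob[i] >= 1.0]
        prob = prob.copy()
        while small and large:
            s, g = small.pop(), large.pop()
            alias[s] = g
            prob[g] = prob[g] - (1.0 - prob[s])
            (small if prob[g] < 1.0 else large).append(g)
        self._prob = prob
        self._alias = alias
        self._m = m

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        u = rng.random(size) * self._m
        j = u.astype(np.int64)
        frac = u - j
        return np.where(frac < self._prob[j], j, self._alias[j])


def _simulate_batch(
    spec: NetworkSpec,
    params: NeuronParams,
    bg_lam_E: float,
    bg_lam_I: float,
    schedules: list[tuple[np.ndarray, np.ndarray]],
    n_steps: int,
    dt: float,
    rng: np.random.Generator,
    ramp: tuple[float, float] | None = None,
    ramp_steps: np.ndarray | None = None,
    early_stop=None,
    check_every: int = 500,
):
    """Core integrator; trials share the network but have independent noise.

    Returns per-trial (neuron_ids, spike_steps) arrays. ``early_stop``, if
    given, is called every ``check_every`` steps with
    ``(trial_original_index, segment_ids, segment_steps)`` per still-active
    trial and must return True to retire the trial; retired trials stop
    consuming random numbers and compute.
    """
    n_trials = len(schedules)
    N = spec.n_neurons
    depth = int(spec.delay_steps.max()) + 1 if spec.n_synapses else 2

    V = np.full((n_trials, N), params.V_P)
    refrac = np.zeros((n_trials, N), dtype=np.int32)
    exc_buf = np.zeros((depth, n_trials, N), dtype=np.int16)
    has_inh = spec.N_I > 0
    inh_buf = np.zeros((depth, n_trials, N), dtype=np.int16) if has_inh else None

    ref_steps = int(round(params.tau_ref / dt))
    decay = np.exp(-dt / params.tau_P)
    cond = params.model_kind == "conductance"
    if cond:
        # lookup tables: (1-g)^n for integer event counts
        max_n = 4096
        fac_E = (1.0 - params.g_E) ** np.arange(max_n)
        fac_I = (1.0 - params.g_I) ** np.arange(max_n)

    sampler_E = _AliasPoisson(bg_lam_E * dt) if bg_lam_E > 0 else None
    sampler_I = _AliasPoisson(bg_lam_I * dt) if bg_lam_I > 0 else None

    cursors = [0] * n_trials
    out_ids: list[list[np.ndarray]] = [[] for _ in range(n_trials)]
    out_steps: list[list[np.ndarray]] = [[] for _ in range(n_trials)]
    seg_mark = [0] * n_trials  # chunk index where the current segment starts
    orig = np.arange(n_trials)  # active-row -> original trial index

    indptr, targets, dsteps = spec.indptr, spec.targets, spec.delay_steps
    N_E = spec.N_E

    for t in range(n_steps):
        n_act = orig.size
        if n_act == 0:
            break
        slot = t % depth
        exc = exc_buf[slot].astype(np.int64)
        inh = inh_buf[slot].astype(np.int64) if has_inh else np.zeros_like(exc)
        exc_buf[slot] = 0
        if has_inh:
            inh_buf[slot] = 0

        lam_scale = 1.0
        if ramp is not None:
            k = int(np.searchsorted(ramp_steps, t, side="right"))
            lam_scale = max(0.0, 1.0 - k / 4.0)
        if sampler_E is not None:
            exc += sampler_E.draw(rng, (n_act, N))
        if sampler_I is not None:
            inh += sampler_I.draw(rng, (n_act, N))
        if ramp is not None and lam_scale > 0:
            exc += rng.poisson(ramp[0] * lam_scale * dt, size=(n_act, N))
            inh += rng.poisson(ramp[1] * lam_scale * dt, size=(n_act, N))

        # scheduled stimulus deliveries
        for row in range(n_act):
            steps_s, tgts_s = schedules[orig[row]]
            c0 = cursors[orig[row]]
            if c0 < steps_s.size and steps_s[c0] <= t:
                c1 = int(np.searchsorted(steps_s, t, side="right"))
                np.add.at(exc, (row, tgts_s[c0:c1]), 1)
                cursors[orig[row]] = c1

        np.subtract(refrac, 1, out=refrac, where=refrac > 0)
        active = refrac == 0

        Vn = params.V_P + (V - params.V_P) * decay
        if cond:
            np.clip(exc, 0, 4095, out=exc)
            np.clip(inh, 0, 4095, out=inh)
            Vn = params.V_E + (Vn - params.V_E) * fac_E[exc]
            Vn = params.V_I + (Vn - params.V_I) * fac_I[inh]
        else:
            Vn = Vn + exc * params.a_E + inh * params.a_I
        V = np.where(active, Vn, params.V_R)

        spiked = active & (V >= params.V_Theta)
        if spiked.any():
            V[spiked] = params.V_R
            refrac[spiked] = ref_steps + 1
            trial_idx, nid = np.nonzero(spiked)
            for row in np.unique(trial_idx):
                ids = nid[trial_idx == row]
                tr = orig[row]
                out_ids[tr].append(ids)
                out_steps[tr].append(np.full(ids.size, t + 1, dtype=np.int64))
                # deliver to calendar, excitatory and inhibitory senders apart
                for buf, sub in (
                    (exc_buf, ids[ids < N_E]),
                    (inh_buf, ids[ids >= N_E]),
                ):
                    if buf is None or sub.size == 0:
                        continue
                    tg = np.concatenate(
                        [targets[indptr[j] : indptr[j + 1]] for j in sub]
                    )
                    dl = np.concatenate(
                        [dsteps[indptr[j] : indptr[j + 1]] for j in sub]
                    )
                    if tg.size:
                        np.add.at(buf, ((t + dl) % depth, row, tg), 1)

        if early_stop is not None and (t + 1) % check_every == 0:
            keep = np.ones(orig.size, dtype=bool)
            for row in range(orig.size):
                tr = orig[row]
                mark = seg_mark[tr]
                seg_i = out_ids[tr][mark:]
                seg_s = out_steps[tr][mark:]
                ids = np.concatenate(seg_i) if seg_i else np.empty(0, np.int64)
                st = np.concatenate(seg_s) if seg_s else np.empty(0, np.int64)
                if early_stop(tr, ids, st, t):
                    keep[row] = False
                seg_mark[tr] = len(out_ids[tr])
            if not keep.all():
                orig = orig[keep]
                V = V[keep]
                refrac = refrac[keep]
                exc_buf = np.ascontiguousarray(exc_buf[:, keep])
                if has_inh:
                    inh_buf = np.ascontiguousarray(inh_buf[:, keep])

    results = []
    for tr in range(n_trials):
        if out_ids[tr]:
            ids = np.concatenate(out_ids[tr])
            steps = np.concatenate(out_steps[tr])
        else:
            ids = np.empty(0, dtype=np.int64)
            steps = np.empty(0, dtype=np.int64)
        results.append((ids, steps))
    return results


def run_network(
    spec: NetworkSpec,
    params: NeuronParams,
    protocol: StimulusProtocol | None = None,
    background: tuple[float, float] | None = None,
    duration: float = 1000.0,
    dt: float | None = None,
    seed: int = 0,
    delays: DelayModel = DelayModel(),
) -> SpikeData:
    """Simulate one NetworkSpec realization; reproducible given ``seed``.

    ``background`` is an optional (lambda_E, lambda_I) pair of external Poisson
    rates in kHz applied uniformly to every neuron; the embedded network runs
    without it (waves alone drive the activity).
    """
    dt = spec.dt if dt is None else dt
    n_steps_f = duration / dt
    if abs(n_steps_f - round(n_steps_f)) > 1e-9:
        raise ValueError("duration must be a multiple of dt")
    n_steps = int(round(n_steps_f))
    rng = stream_rng(seed, "run_network")

    if protocol is not None:
        schedule = _stim_schedule(spec, protocol, delays, duration, dt, rng)
        ramp = protocol.transient_ramp
        ramp_steps = (
            np.round(protocol.stimulus_times(duration)[:4] / dt).astype(int)
            if ramp is not None
            else None
        )
    else:
        schedule = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        ramp, ramp_steps = None, None

    bg_E, bg_I = background if background is not None else (0.0, 0.0)
    ((ids, steps),) = _simulate_batch(
        spec, params, bg_E, bg_I, [schedule], n_steps, dt, rng,
        ramp=ramp, ramp_steps=ramp_steps,
    )
    meta = {
        "seed": seed,
        "network": spec.meta.get("kind", "unknown"),
        "params_hash": params.content_hash(),
    }
    return SpikeData(
        neuron_ids=ids, times=steps * dt, n_neurons=spec.n_neurons,
        duration=duration, dt=dt, meta=meta,
    )


@dataclass
class PropagationResult:
    P_S: float
    p_f: float  # NaN if no trial survived
    T: float  # NaN if no trial survived
    n_trials: int


def characterize_propagation(
    n_E: int,
    lambda_E: float,
    gamma_prime: float = 0.25,
    params: NeuronParams = NeuronParams(),
    trials: int = 100,
    delays: DelayModel = DelayModel(),
    seed: int = 0,
    n_pools: int = 100,
    dt: float = 0.1,
    warmup: float = 100.0,
    stim_pool: int = 2,
    detection: "_packets.DetectionParams | None" = None,
    early_stop: bool = True,
) -> PropagationResult:
    """Control-chain propagation statistics at one (n_E, lambda_E) cell.

    P_S is the fraction of trials in which a spike packet is detected in the
    last pool; p_f the mean packet size over surviving trials divided by n_E;
    T the mean pool-to-pool time, estimated from the packets ten pools apart
    at the end of the chain.

    With ``early_stop`` (default), a trial is retired once its wave either
    produced a suprathreshold window in the last pool or left no
    suprathreshold window anywhere for a whole 50 ms segment (a dead wave
    cannot re-form, and a retired survivor receives no further chain input),
    which changes no detection outcome but saves most of the simulated time.
    """
    if trials < 1:
        raise ValueError("need at least one trial")
    if n_pools < stim_pool + 12:
        raise ValueError("chain too short for propagation timing estimate")
    chain = build_control_chain(n_E, n_pools, delays, seed=stream_seed(seed, "chain"), dt=dt)
    lam_I = gamma_prime * lambda_E
    protocol = StimulusProtocol(
        target_pool=stim_pool, period=1e9, start=warmup, packet_sigma=0.1
    )
    duration = warmup + (n_pools - stim_pool) * 6.0 + 20.0
    n_steps = int(round(duration / dt))
    rng = stream_rng(seed, "characterize")
    schedules = [
        _stim_schedule(chain, protocol, delays, duration, dt, rng)
        for _ in range(trials)
    ]
    det = detection or _packets.DetectionParams.for_pool_size(n_E)

    check_every = int(round(50.0 / dt))
    stim_step = int(round(warmup / dt))
    last = n_pools - 1

    def _max_window(times: np.ndarray) -> int:
        if times.size == 0:
            return 0
        c = np.searchsorted(times, times + det.T_w, side="left") - np.arange(times.size)
        return int(c.max())

    def _stop(tr, ids, steps, t):
        if t < stim_step + check_every:
            return False
        times = steps * dt
        pools = ids // n_E
        sel = pools == last
        if sel.any() and _max_window(np.sort(times[sel])) > det.n_theta:
            return True  # packet reached the last pool; nothing left upstream
        for mu in np.unique(pools):
            if _max_window(np.sort(times[pools == mu])) > det.n_theta:
                return False  # wavefront still alive somewhere
        return True  # no suprathreshold window for a whole segment: wave dead

    results = _simulate_batch(
        chain, params, lambda_E, lam_I, schedules, n_steps, dt, rng,
        early_stop=_stop if early_stop else None, check_every=check_every,
    )

    survived = 0
    sizes: list[float] = []
    T_vals: list[float] = []
    last, tenth_from_last = n_pools - 1, n_pools - 11
    for ids, steps in results:
        times = steps * dt
        pool_of = ids // n_E
        per_pool = {}
        for mu in range(stim_pool, n_pools):
            sel = pool_of == mu
            pk = _packets.detect_packets(np.sort(times[sel]), det, pool=mu)
            pk = [q for q in pk if q.time >= warmup]
            per_pool[mu] = pk
        if not per_pool[last]:
            continue
        survived += 1
        sizes.extend(q.size for pk in per_pool.values() for q in pk)
        t_last = per_pool[last][0].time
        if per_pool[tenth_from_last]:
            T_vals.append((t_last - per_pool[tenth_from_last][0].time) / 10.0)
    P_S = survived / trials
    p_f = float(np.mean(sizes) / n_E) if survived else float("nan")
    T = float(np.mean(T_vals)) if T_vals else float("nan")
    return PropagationResult(P_S=P_S, p_f=p_f, T=T, n_trials=trials)


@dataclass
class PropagationTable:
    """Grids of P_S, p_f, T over (n_E, lambda_E) from control-chain trials.

    ``P_S`` in [0,1]; ``p_f`` and ``T`` are NaN where no trial survived.
    """

    n_E_grid: np.ndarray
    lambda_E_grid: np.ndarray  # kHz
    P_S: np.ndarray  # (n_nE, n_lam)
    p_f: np.ndarray
    T: np.ndarray
    trials: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.n_E_grid = np.asarray(self.n_E_grid)
        self.lambda_E_grid = np.asarray(self.lambda_E_grid, dtype=float)
        for name in ("P_S", "p_f", "T"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.P_S.shape != (self.n_E_grid.size, self.lambda_E_grid.size):
            raise ValueError("P_S shape does not match grids")
        measured = self.P_S[~np.isnan(self.P_S)]  # NaN marks unmeasured cells
        if np.any((measured < 0) | (measured > 1)):
            raise ValueError("P_S outside [0,1]")

    def row(self, n_E) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = int(np.nonzero(self.n_E_grid == n_E)[0][0])
        return self.P_S[i], self.p_f[i], self.T[i]

    @classmethod
    def merge(cls, tables: "list[PropagationTable]") -> "PropagationTable":
        """Union of tables over (n_E, lambda_E); unmeasured cells are NaN.

        Lets each pool size be characterized on its own background-rate
        bracket (the survival cliff moves with n_E) and still be queried as
        one table.
        """
        n_E_grid = np.unique(np.concatenate([t.n_E_grid for t in tables]))
        lam_grid = np.unique(np.concatenate([t.lambda_E_grid for t in tables]))
        shape = (n_E_grid.size, lam_grid.size)
        P_S = np.full(shape, np.nan)
        p_f = np.full(shape, np.nan)
        T = np.full(shape, np.nan)
        for t in tables:
            ii = np.searchsorted(n_E_grid, t.n_E_grid)
            jj = np.searchsorted(lam_grid, t.lambda_E_grid)
            P_S[np.ix_(ii, jj)] = t.P_S
            p_f[np.ix_(ii, jj)] = t.p_f
            T[np.ix_(ii, jj)] = t.T
        trials = min(t.trials for t in tables)
        meta = {}
        for t in tables:
            meta.update(t.meta)
        return cls(n_E_grid.astype(int), lam_grid, P_S, p_f, T, trials, meta)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for k in sorted(self.meta):
                fh.write(f"# {k}={self.meta[k]}\n")
            fh.write(f"# trials={self.trials}\n")
            fh.write("n_E\tlambda_E_kHz\tP_S\tp_f\tT_ms\n")
            for i, ne in enumerate(self.n_E_grid):
                for j, lam in enumerate(self.lambda_E_grid):
                    fh.write(
                        f"{int(ne)}\t{lam:.10g}\t{self.P_S[i, j]:.10g}"
                        f"\t{self.p_f[i, j]:.10g}\t{self.T[i, j]:.10g}\n"
                    )

    @classmethod
    def from_tsv(cls, path) -> "PropagationTable":
        meta, rows = {}, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val.strip()
                elif line and not line.startswith("n_E"):
                    rows.append([float(x) for x in line.split("\t")])
        arr = np.asarray(rows)
        n_E_grid = np.unique(arr[:, 0]).astype(int)
        lam_grid = np.unique(arr[:, 1])
        shape = (n_E_grid.size, lam_grid.size)
        P_S = arr[:, 2].reshape(shape)
        p_f = arr[:, 3].reshape(shape)
        T = arr[:, 4].reshape(shape)
        trials = int(meta.pop("trials", "0"))
        return cls(n_E_grid, lam_grid, P_S, p_f, T, trials, meta)


def build_propagation_table(
    n_E_grid,
    lambda_E_grid,
    gamma_prime: float = 0.25,
    params: NeuronParams = NeuronParams(),
    trials: int = 20,
    delays: DelayModel = DelayModel(),
    seed: int = 0,
    n_pools: int = 100,
    dt: float = 0.1,
) -> PropagationTable:
    """Cell-wise ``characterize_propagation`` over (n_E, lambda_E) grids.

    The reference grids are n_E in {20,24,...,220} and lambda_E in
    {1,...,300} kHz with 100 trials per cell; desk-scale work uses coarser
    configurable grids.
    """
    n_E_grid = np.asarray(n_E_grid)
    lambda_E_grid = np.asarray(lambda_E_grid, dtype=float)
    if np.any(np.diff(n_E_grid) <= 0) or np.any(np.diff(lambda_E_grid) <= 0):
        raise ValueError("grids must be strictly ascending")
    shape = (n_E_grid.size, lambda_E_grid.size)
    P_S = np.zeros(shape)
    p_f = np.full(shape, np.nan)
    T = np.full(shape, np.nan)
    for i, ne in enumerate(n_E_grid):
        for j, lam in enumerate(lambda_E_grid):
            res = characterize_propagation(
                int(ne), float(lam), gamma_prime, params, trials, delays,
                seed=stream_seed(seed, "cell", int(ne), float(lam)),
                n_pools=n_pools, dt=dt,
            )
            P_S[i, j], p_f[i, j], T[i, j] = res.P_S, res.p_f, res.T
    meta = {
        "gamma_prime": gamma_prime,
        "params_hash": params.content_hash(),
        "seed": seed,
        "n_pools": n_pools,
    }
    return PropagationTable(n_E_grid, lambda_E_grid, P_S, p_f, T, trials, meta)
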