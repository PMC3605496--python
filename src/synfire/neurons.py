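"""Single-neuron membrane dynamics and the stochastic-rate table f_S.

Two synapse models are supported. In the *conductance* model each presynaptic
spike produces an instantaneous, voltage-dependent jump

    V <- V + g_X (V_X - V),   X in {E, I},

so the membrane potential is confined to [V_I, V_E] and repeated jumps contract
the distance to the reversal potential geometrically. In the *current* model the
jump is a fixed amplitude a_X. Between inputs the potential decays exponentially
toward the resting potential V_P with time constant tau_P. A spike is emitted
when V reaches the threshold V_Theta; the potential is then clamped at the reset
value V_R for an absolute refractory period tau_ref during which inputs are
discarded.

The grid-based integrator used throughout the package applies, per time step of
width dt: leak decay, then all excitatory jumps, then all inhibitory jumps, then
the threshold test (spike times live on the dt grid). Same-type delta jumps
commute, and the E-before-I ordering of simultaneous events is a fixed
convention of this package.

``estimate_fS`` measures the stochastic spiking rate nu_S = f_S(lambda_E,
lambda_I) of a neuron bombarded by independent Poisson input streams, tabulated
on a grid of excitatory background rates with a fixed inhibitory/excitatory
ratio gamma'. The reference protocol is 100 runs of 5000 ms with the first
1000 ms discarded; smaller desk-scale protocols are configurable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
from dataclasses import dataclass, field

import numpy as np

from ._rng import stream_rng

__all__ = [
    "NeuronParams",
    "NeuronState",
    "RateTable",
    "step_membrane",
    "integrate_counts",
    "simulate_single_neuron",
    "estimate_fS",
]


@dataclass(frozen=True)
class NeuronParams:
    """Neuron and synapse parameters (potentials in mV, times in ms).

    Defaults are the reference parameter set of the embedding model:
    conductance-based synapses with dimensionless jumps g_E = 0.005 and
    g_I = 0.11 on a leaky integrate-and-fire neuron.
    """

    model_kind: str = "conductance"  # "conductance" | "current"
    V_E: float = 0.0
    V_I: float = -80.0
    V_P: float = -70.0
    V_R: float = -70.0
    V_Theta: float = -55.0
    tau_P: float = 20.0
    tau_ref: float = 2.0
    g_E: float = 0.005
    g_I: float = 0.11
    a_E: float = 0.0
    a_I: float = 0.0

    def __post_init__(self) -> None:
        if self.model_kind not in ("conductance", "current"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.tau_P <= 0:
            raise ValueError("tau_P must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if self.model_kind == "conductance":
            if not (self.V_I <= self.V_R <= self.V_Theta < self.V_E):
                raise ValueError("require V_I <= V_R <= V_Theta < V_E")
            if self.g_E < 0 or self.g_I < 0:
                raise ValueError("conductance jumps must be non-negative")
        else:
            if not (self.V_R <= self.V_Theta):
                raise ValueError("require V_R <= V_Theta")
            if self.a_I > 0:
                raise ValueError("inhibitory amplitude a_I must be <= 0")

    def replace(self, **kw) -> "NeuronParams":
        return dataclasses.replace(self, **kw)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class NeuronState:
    """Membrane potential (mV) and remaining refractory time (ms)."""

    V: float
    refractory_remaining: float = 0.0
    spiked: bool = False


def _apply_jumps(V, params: NeuronParams, n_exc, n_inh):
    """Excitatory then inhibitory delta jumps (vectorized over V/counts)."""
    if params.model_kind == "conductance":
        V = params.V_E + (V - params.V_E) * (1.0 - params.g_E) ** n_exc
        V = params.V_I + (V - params.V_I) * (1.0 - params.g_I) ** n_inh
    else:
        V = V + n_exc * params.a_E + n_inh * params.a_I
    return V


def step_membrane(
    state: NeuronState,
    params: NeuronParams,
    n_exc: int,
    n_inh: int,
    dt: float,
) -> NeuronState:
    """Advance one neuron by one grid step of width ``dt``.

    Leak decay toward V_P over dt, then ``n_exc`` excitatory jumps, then
    ``n_inh`` inhibitory jumps, then the threshold test. During refractoriness
    the potential stays at V_R and all inputs are discarded.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_exc < 0 or n_inh < 0:
        raise ValueError("input counts must be non-negative")

    if state.refractory_remaining > 0:
        remaining = max(0.0, state.refractory_remaining - dt)
        return NeuronState(V=params.V_R, refractory_remaining=remaining, spiked=False)

    V = params.V_P + (state.V - params.V_P) * np.exp(-dt / params.tau_P)
    V = _apply_jumps(V, params, n_exc, n_inh)
    if V >= params.V_Theta:
        return NeuronState(
            V=params.V_R, refractory_remaining=params.tau_ref, spiked=True
        )
    return NeuronState(V=float(V), refractory_remaining=0.0, spiked=False)


def integrate_counts(
    params: NeuronParams,
    exc_counts: np.ndarray,
    inh_counts: np.ndarray,
    dt: float,
    V0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the grid integrator over a whole count sequence for one neuron.

    Returns ``(V_trace, spike_steps)`` where ``V_trace[k]`` is the potential at
    the end of step ``k`` and ``spike_steps`` the indices of threshold
    crossings. Used for convergence checks against event-based integration.
    """
    exc_counts = np.asarray(exc_counts)
    inh_counts = np.asarray(inh_counts)
    state = NeuronState(V=params.V_P if V0 is None else V0)
    trace = np.empty(len(exc_counts))
    spikes = []
    for k in range(len(exc_counts)):
        state = step_membrane(state, params, int(exc_counts[k]), int(inh_counts[k]), dt)
        if state.spiked:
            spikes.append(k)
        trace[k] = state.V
    return trace, np.array(spikes, dtype=int)


def _poisson_batch_counts(
    params: NeuronParams,
    lam_E: np.ndarray,
    lam_I: np.ndarray,
    n_steps: int,
    dt: float,
    rng: np.random.Generator,
    record_from_step: int = 0,
):
    """Vectorized Poisson-bombardment simulation of a batch of neurons.

    ``lam_E``/``lam_I`` give per-neuron input rates in kHz (events/ms). Returns
    the spike count of every neuron over ``[record_from_step, n_steps)``.
    """
    lam_E = np.atleast_1d(np.asarray(lam_E, dtype=float))
    lam_I = np.atleast_1d(np.asarray(lam_I, dtype=float))
    n = lam_E.size
    V = np.full(n, params.V_P)
    refrac = np.zeros(n, dtype=np.int64)
    ref_steps = int(round(params.tau_ref / dt))
    decay = np.exp(-dt / params.tau_P)
    counts = np.zeros(n, dtype=np.int64)
    mean_E = lam_E * dt
    mean_I = lam_I * dt

    cond = params.model_kind == "conductance"
    if cond:
        log1m_gE = np.log1p(-params.g_E) if params.g_E < 1 else -np.inf
        log1m_gI = np.log1p(-params.g_I) if params.g_I < 1 else -np.inf

    for t in range(n_steps):
        np.subtract(refrac, 1, out=refrac, where=refrac > 0)
        active = refrac == 0
        ne = rng.poisson(mean_E)
        ni = rng.poisson(mean_I)
        Vn = params.V_P + (V - params.V_P) * decay
        if cond:
            Vn = params.V_E + (Vn - params.V_E) * np.exp(ne * log1m_gE)
            Vn = params.V_I + (Vn - params.V_I) * np.exp(ni * log1m_gI)
        else:
            Vn = Vn + ne * params.a_E + ni * params.a_I
        V = np.where(active, Vn, params.V_R)
        spiked = active & (V >= params.V_Theta)
        V[spiked] = params.V_R
        refrac[spiked] = ref_steps + 1
        if t >= record_from_step:
            counts += spiked
    return counts


def simulate_single_neuron(
    params: NeuronParams,
    lambda_E: float,
    lambda_I: float,
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Spike times (ms, on the dt grid) of one neuron under Poisson bombardment.

    Input counts per step are Poisson with means ``lambda_E*dt`` and
    ``lambda_I*dt`` (rates in kHz). Deterministic given ``seed``.
    """
    if lambda_E < 0 or lambda_I < 0:
        raise ValueError("input rates must be non-negative")
    if duration <= dt:
        raise ValueError("duration must exceed dt")
    rng = stream_rng(seed, "single-neuron")
    n_steps = int(round(duration / dt))
    state = NeuronState(V=params.V_P)
    mean_E, mean_I = lambda_E * dt, lambda_I * dt
    out = []
    for t in range(n_steps):
        ne = int(rng.poisson(mean_E)) if mean_E > 0 else 0
        ni = int(rng.poisson(mean_I)) if mean_I > 0 else 0
        state = step_membrane(state, params, ne, ni, dt)
        if state.spiked:
            out.append((t + 1) * dt)
    return np.array(out)


@dataclass
class RateTable:
    """Tabulated stochastic spiking rate nu_S = f_S(lambda_E, gamma' lambda_E).

    ``lambda_E_grid`` is in kHz (events/ms), ``rate_Hz`` in spikes/s. Queries
    between grid points use linear interpolation; queries outside the grid
    range are an error.
    """

    lambda_E_grid: np.ndarray
    rate_Hz: np.ndarray
    gamma_prime: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lambda_E_grid = np.asarray(self.lambda_E_grid, dtype=float)
        self.rate_Hz = np.asarray(self.rate_Hz, dtype=float)
        if self.lambda_E_grid.size == 0:
            raise ValueError("empty rate-table grid")
        if np.any(np.diff(self.lambda_E_grid) <= 0):
            raise ValueError("lambda_E grid must be strictly ascending")
        if np.any(self.rate_Hz < 0):
            raise ValueError("rates must be non-negative")

    def __call__(self, lambda_E):
        lam = np.asarray(lambda_E, dtype=float)
        lo, hi = self.lambda_E_grid[0], self.lambda_E_grid[-1]
        if np.any(lam < lo - 1e-12) or np.any(lam > hi + 1e-12):
            raise ValueError(
                f"lambda_E query outside table range [{lo}, {hi}] kHz"
            )
        return np.interp(lam, self.lambda_E_grid, self.rate_Hz)

    def derivative(self, lambda_E: float) -> float:
        """d(rate)/d(lambda_E) in Hz/kHz: slope of the interpolant's segment
        (central difference over one grid interval at interior nodes)."""
        g = self.lambda_E_grid
        i = int(np.clip(np.searchsorted(g, lambda_E) - 1, 0, g.size - 2))
        lo = max(i - 0, 0)
        if np.isclose(lambda_E, g[i], atol=1e-12) and 0 < i < g.size - 1:
            return float((self.rate_Hz[i + 1] - self.rate_Hz[i - 1]) / (g[i + 1] - g[i - 1]))
        return float((self.rate_Hz[lo + 1] - self.rate_Hz[lo]) / (g[lo + 1] - g[lo]))

    def to_tsv(self, path) -> None:
        header_meta = dict(self.meta)
        header_meta["gamma_prime"] = self.gamma_prime
        with open(path, "w") as fh:
            for k in sorted(header_meta):
                fh.write(f"# {k}={header_meta[k]}\n")
            fh.write("lambda_E_kHz\trate_Hz\n")
            for lam, r in zip(self.lambda_E_grid, self.rate_Hz):
                fh.write(f"{lam:.10g}\t{r:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "RateTable":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val.strip()
                elif line and not line.startswith("lambda"):
                    rows.append([float(x) for x in line.split("\t")])
        arr = np.asarray(rows)
        gamma_prime = float(meta.pop("gamma_prime", "nan"))
        return cls(arr[:, 0], arr[:, 1], gamma_prime, meta)


def estimate_fS(
    params: NeuronParams,
    lambda_E_grid,
    gamma_prime: float = 0.25,
    n_runs: int = 100,
    run_duration: float = 5000.0,
    discard: float = 1000.0,
    dt: float = 0.1,
    seed: int = 0,
) -> RateTable:
    """Tabulate f_S over a grid of excitatory background rates.

    Per grid point, the mean rate over ``[discard, run_duration]`` averaged
    across ``n_runs`` independent runs, with ``lambda_I = gamma' * lambda_E``.
    All (grid point, run) pairs are simulated as one vectorized batch.
    """
    grid = np.asarray(lambda_E_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda_E grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("lambda_E grid must be strictly ascending")
    if not 0 <= discard < run_duration:
        raise ValueError("require 0 <= discard < run_duration")

    rng = stream_rng(seed, "fS")
    lam_E = np.repeat(grid, n_runs)
    lam_I = gamma_prime * lam_E
    n_steps = int(round(run_duration / dt))
    rec_from = int(round(discard / dt))
    counts = _poisson_batch_counts(params, lam_E, lam_I, n_steps, dt, rng, rec_from)
    window_s = (run_duration - discard) / 1000.0
    rates = counts.reshape(grid.size, n_runs).mean(axis=1) / window_s
    meta = {
        "params_hash": params.content_hash(),
        "seed": seed,
        "n_runs": n_runs,
        "run_duration_ms": run_duration,
        "discard_ms": discard,
        "dt_ms": dt,
    }
    return RateTable(grid, rates, gamma_prime, meta)
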