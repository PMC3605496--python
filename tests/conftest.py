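"""Shared fixtures.

The simulation-backed fixtures are session-scoped because control-chain
characterization is the expensive step; several tests (threshold-rate
monotonicity, capacity ordering, mean-field cross-validation) read different
aspects of the same tables.
"""

from __future__ import annotations

import numpy as np
import pytest

from synfire import (
    DetectionParams,
    EmbeddingConfig,
    NeuronParams,
    PropagationTable,
    StimulusProtocol,
    build_embedding,
    build_propagation_table,
    equilibrium_statistics,
    estimate_fS,
    extract_pool_packets,
    link_waves,
    run_network,
)

GI_VALUES = (0.10, 0.11, 0.12)

# desk-scale control-chain protocol: 50 pools (the per-pool failure rate is
# length-invariant), reduced trial counts
N_POOLS = 50
LAM_GRID_80 = (8.0, 12.0, 16.0, 20.0, 24.0)
LAM_GRID_112 = (28.0, 36.0, 44.0, 52.0, 60.0)


@pytest.fixture(scope="session")
def table1_params() -> NeuronParams:
    return NeuronParams()


@pytest.fixture(scope="session")
def prop_tables_by_gI() -> dict[float, PropagationTable]:
    """Control-chain survival tables for two pool sizes at three inhibition
    levels, each pool size characterized around its own survival cliff."""
    out = {}
    for gI in GI_VALUES:
        params = NeuronParams(g_I=gI)
        t80 = build_propagation_table(
            [80], LAM_GRID_80, params=params, trials=8, seed=101, n_pools=N_POOLS
        )
        t112 = build_propagation_table(
            [112], LAM_GRID_112, params=params, trials=6, seed=102, n_pools=N_POOLS
        )
        out[gI] = PropagationTable.merge([t80, t112])
    return out


@pytest.fixture(scope="session")
def fs_tables_by_gI() -> dict:
    """Simulated stochastic-rate tables f_S for the three inhibition levels."""
    grid = np.array([2.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
    return {
        gI: estimate_fS(
            NeuronParams(g_I=gI), grid, gamma_prime=0.25,
            n_runs=24, run_duration=2500.0, discard=500.0, seed=77,
        )
        for gI in GI_VALUES
    }


@pytest.fixture(scope="session")
def meanfield_inputs():
    """Rate table and n_E=80 propagation row for the scaled-down
    mean-field-versus-simulation comparison (g_I = 0.11)."""
    params = NeuronParams()
    rate = estimate_fS(
        params, np.array([2.0, 6.0, 10.0, 14.0, 18.0, 22.0, 26.0]),
        gamma_prime=0.25, n_runs=30, run_duration=3000.0, discard=500.0, seed=55,
    )
    prop = build_propagation_table(
        [80], [10.0, 13.0, 15.0, 16.0, 17.0, 18.0, 20.0],
        params=params, trials=16, seed=56, n_pools=N_POOLS,
    )
    return rate, prop


@pytest.fixture(scope="session")
def embedding_equilibrium():
    """Driven equilibrium of the scaled-down embedding (C_E=500, N_E=5000,
    n_E=80): spikes, waves and equilibrium statistics over 5 s."""
    cfg = EmbeddingConfig(C_E=500, n_E=80, N_E=5000)
    spec = build_embedding(cfg, seed=11)
    data = run_network(
        spec, NeuronParams(), StimulusProtocol(), duration=5000.0, seed=13
    )
    det = DetectionParams.for_pool_size(spec.n_E)
    per_pool = extract_pool_packets(data, spec.pools_E, det)
    waves = link_waves(per_pool, det, n_pools=spec.n_pools, ring=True)
    stats = equilibrium_statistics(data, waves, params=det)
    return {"spec": spec, "spikes": data, "waves": waves, "stats": stats}
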