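"""Independent reference implementations used only to check the package.

These deliberately share no code with ``synfire``: the event-driven
integrator advances the membrane analytically between input events (no time
grid), and the moment estimators are brute-force ensemble averages.
"""

from __future__ import annotations

import math

import numpy as np


def event_driven_lif(
    params,
    exc_times: np.ndarray,
    inh_times: np.ndarray,
    duration: float,
    sample_times: np.ndarray | None = None,
):
    """Exact event-by-event integration of the delta-synapse LIF neuron.

    Returns (spike_times, sampled_V). Threshold crossings can only occur at
    input events (between events V decays toward V_P < V_Theta). During the
    refractory period V is clamped at V_R and events are discarded.
    """
    events = np.concatenate(
        [
            np.column_stack([exc_times, np.ones_like(exc_times)]),
            np.column_stack([inh_times, -np.ones_like(inh_times)]),
        ]
    )
    events = events[np.argsort(events[:, 0], kind="stable")]
    events = events[events[:, 0] < duration]

    samples = np.asarray(sample_times) if sample_times is not None else np.empty(0)
    sampled_V = np.empty(samples.size)
    si = 0

    V = params.V_P
    t = 0.0
    ref_until = -math.inf
    spikes = []

    def decay(V, dt_):
        return params.V_P + (V - params.V_P) * math.exp(-dt_ / params.tau_P)

    for et, kind in events:
        # emit samples before this event
        while si < samples.size and samples[si] <= et:
            ts = samples[si]
            if ts < ref_until:
                sampled_V[si] = params.V_R
            else:
                t0 = max(t, ref_until)
                base = params.V_R if ref_until > t else V
                sampled_V[si] = decay(base, ts - t0) if ts >= t0 else V
            si += 1
        if et < ref_until:
            continue  # event discarded during refractoriness
        if ref_until > t:
            V = params.V_R
            t = ref_until
        V = decay(V, et - t)
        t = et
        if params.model_kind == "conductance":
            if kind > 0:
                V = V + params.g_E * (params.V_E - V)
            else:
                V = V + params.g_I * (params.V_I - V)
        else:
            V = V + (params.a_E if kind > 0 else params.a_I)
        if V >= params.V_Theta:
            spikes.append(et)
            V = params.V_R
            ref_until = et + params.tau_ref
    while si < samples.size:
        ts = samples[si]
        if ts < ref_until:
            sampled_V[si] = params.V_R
        else:
            t0 = max(t, ref_until)
            base = params.V_R if ref_until > t else V
            sampled_V[si] = decay(base, ts - t0) if ts >= t0 else V
        si += 1
    return np.asarray(spikes), sampled_V


def poisson_event_times(rate_kHz: float, duration: float, rng) -> np.ndarray:
    n = rng.poisson(rate_kHz * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def event_driven_rate(
    params, lam_E: float, lam_I: float, duration: float, discard: float, rng
) -> float:
    """Mean rate (Hz) of the event-driven neuron under Poisson bombardment."""
    exc = poisson_event_times(lam_E, duration, rng)
    inh = poisson_event_times(lam_I, duration, rng)
    spikes, _ = event_driven_lif(params, exc, inh, duration)
    n = np.count_nonzero(spikes >= discard)
    return n / ((duration - discard) / 1000.0)
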