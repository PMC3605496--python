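"""Diffusion-approximation analysis: Siegert rate and the conductance-vs-
current model comparison.

In the diffusion approximation the free membrane potential (threshold
removed) is Gaussian with mean mu, standard deviation sigma and an effective
time constant tau. For current-based synapses tau = tau_P,

    mu = V_P + tau_P (lambda_E a_E + lambda_I a_I),
    sigma^2 = (tau_P/2)(lambda_E a_E^2 + lambda_I a_I^2),

while conductance-based synapses shorten the membrane time constant with
background rate (the high-conductance state),

    1/tau = 1/tau_P + lambda_E g_E + lambda_I g_I,
    mu = tau (V_P/tau_P + lambda_E g_E V_E + lambda_I g_I V_I),
    sigma^2 = (tau/2)(lambda_E g_E^2 (V_E-mu)^2 + lambda_I g_I^2 (V_I-mu)^2),

the effective-time-constant form of the standard conductance-synapse moment
expressions. The stochastic firing rate then follows the Siegert
first-passage formula

    f_S = [tau_ref + tau * Int_{(V_R-mu)/sqrt(2)sigma}^{(V_Theta-mu)/sqrt(2)sigma}
           sqrt(pi) e^{z^2} (1 + erf z) dz]^{-1},

which depends on the synapse model only through (mu, sigma, tau). The
quadrature uses erfcx for moderate arguments and switches to a log-space
asymptotic tail for large upper limits, where e^{z^2} would overflow.

``sweep_comparison`` reproduces the simplified capacity analysis: at a fixed
population rate nu (default 5 Hz) and for each connectivity C_E the
background rate is lambda_E = C_E nu, the stochastic rate is
nu_S = f_S(lambda_E, gamma' lambda_E), and the minimum pool size comes from
the Gaussian criterion n_E,min a_eff = V_Theta - (mu - 1.645 sigma) (95 % of
the distribution shifted above threshold). The sweep over connectivity is
truncated at C_E,max, the first point where (a) the stochastic-rate fixed
point loses stability, (b) nu_S exceeds nu/2, or (c) the capacity
alpha_max = C_E/n_E,min^2 stops increasing. This analysis assumes zero
intra-link delay spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special

from .neurons import NeuronParams

__all__ = [
    "GaussianMoments",
    "siegert_rate",
    "moments_conductance",
    "moments_current",
    "n_E_min_gaussian",
    "fit_current_to_conductance",
    "sweep_comparison",
    "ComparisonSweep",
    "Z_95",
]

Z_95 = 1.645  # one-sided 95% normal quantile used in the pool-size criterion


@dataclass(frozen=True)
class GaussianMoments:
    """Free membrane-potential distribution: mean (mV), sd (mV), tau (ms)."""

    mu: float
    sigma: float
    tau: float


def moments_conductance(
    lambda_E: float, lambda_I: float, params: NeuronParams
) -> GaussianMoments:
    """Gaussian moments for conductance synapses (rates in kHz)."""
    if lambda_E < 0 or lambda_I < 0:
        raise ValueError("rates must be non-negative")
    inv_tau = 1.0 / params.tau_P + lambda_E * params.g_E + lambda_I * params.g_I
    tau = 1.0 / inv_tau
    mu = tau * (
        params.V_P / params.tau_P
        + lambda_E * params.g_E * params.V_E
        + lambda_I * params.g_I * params.V_I
    )
    var = (tau / 2.0) * (
        lambda_E * params.g_E**2 * (params.V_E - mu) ** 2
        + lambda_I * params.g_I**2 * (params.V_I - mu) ** 2
    )
    return GaussianMoments(mu=mu, sigma=math.sqrt(var), tau=tau)


def moments_current(
    lambda_E: float, lambda_I: float, params: NeuronParams
) -> GaussianMoments:
    """Gaussian moments for current synapses: tau = tau_P (rates in kHz)."""
    if lambda_E < 0 or lambda_I < 0:
        raise ValueError("rates must be non-negative")
    tau = params.tau_P
    mu = params.V_P + tau * (lambda_E * params.a_E + lambda_I * params.a_I)
    var = (tau / 2.0) * (lambda_E * params.a_E**2 + lambda_I * params.a_I**2)
    return GaussianMoments(mu=mu, sigma=math.sqrt(var), tau=tau)


_Z_SPLIT = 5.0  # above this, e^{z^2} terms go through log-space asymptotics
# (1 + erf z differs from 2 by a relative erfc(5)/2 ~ 8e-13 beyond the split,
# and capping the quadrature range keeps its dynamic range tractable)


def _log_E(x: float) -> float:
    """log of e^{x^2} dawsn(x) = log Int_0^x e^{t^2} dt for x > 0."""
    return x * x + math.log(special.dawsn(x))


_Z_DEEP = -30.0  # below this, erfcx(-z) ~ -1/(sqrt(pi) z): integrate analytically


def _quad_moderate(a: float, b: float) -> float:
    """Quadrature of sqrt(pi) erfcx(-z) over a moderate range, with the far
    subthreshold stretch handled by the two-term asymptotic antiderivative
    -ln|z| + 1/(4 z^2)."""
    val = 0.0
    if a < _Z_DEEP:
        c = min(b, _Z_DEEP)
        val += (-math.log(-c) + 0.25 / c**2) - (-math.log(-a) + 0.25 / a**2)
        a = c
    if b > a:
        q, _ = integrate.quad(
            lambda z: math.sqrt(math.pi) * special.erfcx(-z), a, b,
            epsabs=1e-12, limit=200,
        )
        val += q
    return val


def _siegert_integral(a: float, b: float) -> tuple[float, float]:
    """The Siegert integral as (value, log_value); value may overflow to inf.

    Integrand sqrt(pi) e^{z^2}(1+erf z) = sqrt(pi) erfcx(-z).
    """
    if b <= _Z_SPLIT:
        val = _quad_moderate(a, b)
        return val, (math.log(val) if val > 0 else -math.inf)
    lo = max(a, _Z_SPLIT)
    head = 0.0
    if a < _Z_SPLIT:
        head = _quad_moderate(a, _Z_SPLIT)
    # tail: 1 + erf z ~= 2, so Int ~ 2 sqrt(pi) (E(b) - E(lo)), E(x)=e^{x^2}dawsn(x)
    log_tail = (
        math.log(2.0 * math.sqrt(math.pi))
        + _log_E(b)
        + math.log1p(-math.exp(min(0.0, _log_E(lo) - _log_E(b))))
    )
    if log_tail < 700.0:
        val = head + math.exp(log_tail)
        return val, math.log(val)
    return math.inf, log_tail


def siegert_rate(moments: GaussianMoments, params: NeuronParams) -> float:
    """First-passage (Siegert) firing rate in Hz for Gaussian moments."""
    if moments.sigma <= 0:
        raise ValueError("sigma must be positive")
    a = (params.V_R - moments.mu) / (math.sqrt(2.0) * moments.sigma)
    b = (params.V_Theta - moments.mu) / (math.sqrt(2.0) * moments.sigma)
    val, log_val = _siegert_integral(a, b)
    if not math.isfinite(val):
        # tau_ref is negligible against an astronomically long passage time
        log_rate = math.log(1000.0) - log_val - math.log(moments.tau)
        return math.exp(log_rate) if log_rate > -700.0 else 0.0
    denom = params.tau_ref + moments.tau * val
    if not math.isfinite(denom) or denom <= 0:
        raise ArithmeticError("non-finite Siegert denominator")
    return 1000.0 / denom


def effective_jump_E(params: NeuronParams) -> float:
    """Excitatory unit jump for the pool-size criterion.

    Current model: a_E. Conductance model: g_E (V_E - V_avg) with
    V_avg = (V_R + V_Theta)/2 (the response varies little over [V_R, V_Theta]).
    """
    if params.model_kind == "current":
        return params.a_E
    V_avg = 0.5 * (params.V_R + params.V_Theta)
    return params.g_E * (params.V_E - V_avg)


def n_E_min_gaussian(
    moments: GaussianMoments, params: NeuronParams, a_eff: float | None = None
) -> int:
    """Minimum pool size shifting 95 % of the potential above threshold:
    ceil((V_Theta - mu + 1.645 sigma) / a_eff)."""
    a = effective_jump_E(params) if a_eff is None else a_eff
    if a <= 0:
        raise ValueError("effective excitatory jump must be positive")
    need = params.V_Theta - (moments.mu - Z_95 * moments.sigma)
    return max(0, math.ceil(need / a - 1e-12))


def fit_current_to_conductance(
    cond_params: NeuronParams,
    C_E_fit: float,
    nu: float,
    V_P_choice: float | None = None,
    gamma_prime: float = 0.25,
) -> NeuronParams:
    """Current-based model matched to a conductance model's (mu, sigma, tau).

    The match is evaluated at lambda_E = C_E_fit * nu (nu in Hz), with
    tau_P set to the conductance model's effective tau and (a_E, a_I) solved
    from the two moment constraints given the resting potential V_P
    (default: V_P = mu, which makes the mean input current vanish,
    a_E lambda_E + a_I lambda_I = 0).
    """
    lam_E = C_E_fit * nu / 1000.0
    lam_I = gamma_prime * lam_E
    if lam_E <= 0 or lam_I <= 0:
        raise ValueError("fit requires positive input rates")
    m = moments_conductance(lam_E, lam_I, cond_params)
    V_P = m.mu if V_P_choice is None else float(V_P_choice)
    S = (m.mu - V_P) / m.tau  # = a_E lam_E + a_I lam_I
    Q = 2.0 * m.sigma**2 / m.tau  # = a_E^2 lam_E + a_I^2 lam_I
    # eliminate a_I: quadratic in a_E
    A = lam_E + lam_E**2 / lam_I
    B = -2.0 * S * lam_E / lam_I
    C = S**2 / lam_I - Q
    disc = B * B - 4.0 * A * C
    if disc < 0:
        raise ValueError("infeasible fit: no real (a_E, a_I) for this V_P")
    for a_E in ((-B + math.sqrt(disc)) / (2 * A), (-B - math.sqrt(disc)) / (2 * A)):
        a_I = (S - lam_E * a_E) / lam_I
        if a_E > 0 and a_I <= 0:
            return NeuronParams(
                model_kind="current",
                V_E=cond_params.V_E, V_I=cond_params.V_I,
                V_P=V_P, V_R=cond_params.V_R, V_Theta=cond_params.V_Theta,
                tau_P=m.tau, tau_ref=cond_params.tau_ref,
                a_E=a_E, a_I=a_I,
            )
    raise ValueError("infeasible fit: no sign-consistent (a_E, a_I)")


@dataclass
class SweepSeries:
    """Performance of one model over connectivity, truncated at C_E_max."""

    varied_value: float
    C_E: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    nu_S: np.ndarray  # Hz
    n_E_min: np.ndarray
    alpha_max: np.ndarray
    C_E_max: float
    terminating_condition: str  # "instability" | "nu_S_bound" | "alpha_plateau" | "grid_end"


@dataclass
class ComparisonSweep:
    family: str
    varied_name: str
    nu: float  # Hz
    series: list[SweepSeries] = field(default_factory=list)


def _fs_hat(params: NeuronParams, lam_E: float, gamma_prime: float) -> float:
    moments = (
        moments_conductance if params.model_kind == "conductance" else moments_current
    )(lam_E, gamma_prime * lam_E, params)
    return siegert_rate(moments, params)


def _sweep_one_model(
    params: NeuronParams,
    C_E_grid: np.ndarray,
    nu: float,
    gamma_prime: float,
    varied_value: float,
) -> SweepSeries:
    nu_kHz = nu / 1000.0
    rows = {k: [] for k in ("C_E", "mu", "sigma", "nu_S", "n_E_min", "alpha_max")}
    term = "grid_end"
    mom_fn = (
        moments_conductance if params.model_kind == "conductance" else moments_current
    )
    dlam = float(np.min(np.diff(C_E_grid))) * nu_kHz if C_E_grid.size > 1 else 1e-3
    prev_alpha = -np.inf
    for C_E in C_E_grid:
        lam = C_E * nu_kHz
        m = mom_fn(lam, gamma_prime * lam, params)
        nu_S = siegert_rate(m, params)
        # naive fixed-point stability: |C_E dfs/dlambda| < 1, one-interval step
        lo = max(lam - dlam, 1e-9)
        slope = (_fs_hat(params, lam + dlam, gamma_prime) - _fs_hat(params, lo, gamma_prime)) / (
            (lam + dlam - lo) * 1000.0
        )
        if abs(C_E * slope) >= 1.0:
            term = "instability"
            break
        if nu_S >= 0.5 * nu:
            term = "nu_S_bound"
            break
        nmin = n_E_min_gaussian(m, params)
        alpha = C_E / nmin**2 if nmin > 0 else np.inf
        if alpha <= prev_alpha:
            term = "alpha_plateau"
            break
        prev_alpha = alpha
        rows["C_E"].append(C_E)
        rows["mu"].append(m.mu)
        rows["sigma"].append(m.sigma)
        rows["nu_S"].append(nu_S)
        rows["n_E_min"].append(nmin)
        rows["alpha_max"].append(alpha)
    arrays = {k: np.asarray(v) for k, v in rows.items()}
    C_E_max = float(arrays["C_E"][-1]) if arrays["C_E"].size else float("nan")
    return SweepSeries(
        varied_value=varied_value,
        C_E=arrays["C_E"], mu=arrays["mu"], sigma=arrays["sigma"],
        nu_S=arrays["nu_S"], n_E_min=arrays["n_E_min"],
        alpha_max=arrays["alpha_max"],
        C_E_max=C_E_max, terminating_condition=term,
    )


# reference sweep grids of the comparison figure
G_I_SWEEP = (0.02, 0.05, 0.07, 0.08, 0.085, 0.09, 0.095, 0.10)
A_I_SWEEP = (0.25, 0.5, 0.75, 0.875, 1.0, 1.125, 1.25, 1.3125, 1.375, 1.4375, 1.5)
V_P_SWEEP = tuple(np.linspace(-88.4, -56.6, 21))


def sweep_comparison(
    family: str,
    varied_grid=None,
    C_E_grid=None,
    nu: float = 5.0,
    base_params: NeuronParams = NeuronParams(),
    gamma_prime: float = 0.25,
    fitted_g_I: float = 0.095,
) -> ComparisonSweep:
    """Capacity sweep for one model family.

    Families: ``conductance`` (vary g_I), ``current`` (conventional: vary a_I
    with a_E matched to g_E), ``fitted_vp`` (current model fitted to one
    conductance model, vary V_P), ``fitted_gi`` (current model fitted with
    V_P = mu to each conductance model as g_I varies).
    """
    if C_E_grid is None:
        C_E_grid = np.arange(250, 20001, 250, dtype=float)
    C_E_grid = np.asarray(C_E_grid, dtype=float)

    defaults = {
        "conductance": ("g_I", G_I_SWEEP),
        "current": ("a_I", A_I_SWEEP),
        "fitted_vp": ("V_P", V_P_SWEEP),
        "fitted_gi": ("g_I", G_I_SWEEP),
    }
    if family not in defaults:
        raise ValueError(f"unknown family {family!r}")
    varied_name, grid_default = defaults[family]
    varied = tuple(varied_grid) if varied_grid is not None else grid_default

    sweep = ComparisonSweep(family=family, varied_name=varied_name, nu=nu)
    a_E_matched = effective_jump_E(base_params.replace(model_kind="conductance"))

    for v in varied:
        if family == "conductance":
            model = base_params.replace(model_kind="conductance", g_I=float(v))
        elif family == "current":
            model = base_params.replace(
                model_kind="current", a_E=a_E_matched, a_I=-abs(float(v)),
                g_E=0.0, g_I=0.0,
            )
        elif family == "fitted_vp":
            cond = base_params.replace(model_kind="conductance", g_I=fitted_g_I)
            cond_series = _sweep_one_model(cond, C_E_grid, nu, gamma_prime, fitted_g_I)
            model = fit_current_to_conductance(
                cond, cond_series.C_E_max, nu, V_P_choice=float(v),
                gamma_prime=gamma_prime,
            )
        else:  # fitted_gi
            cond = base_params.replace(model_kind="conductance", g_I=float(v))
            cond_series = _sweep_one_model(cond, C_E_grid, nu, gamma_prime, float(v))
            model = fit_current_to_conductance(
                cond, cond_series.C_E_max, nu, V_P_choice=None,
                gamma_prime=gamma_prime,
            )
        sweep.series.append(
            _sweep_one_model(model, C_E_grid, nu, gamma_prime, float(v))
        )
    return sweep
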