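"""Mean-field self-consistency, wave-regulation equilibrium, and capacity.

The asynchronous background input to every neuron arrives at rates
lambda_E ~= C_E * nu and lambda_I = gamma' * lambda_E (in kHz), where the
population rate nu = nu_W + nu_S splits into wave spiking and stochastic
spiking. With the measured single-neuron rate table f_S and the control-chain
propagation tables (P_S, p_f, T), the stationary state for h waves solves

    lambda_E = C_E [ (h/N_E) n_E p_f(lambda_E) / T(lambda_E) + f_S(lambda_E) ]

(all terms in kHz; f_S tables store Hz and are converted). The smallest root
is the physical low-rate state; its stability is judged by the naive
balanced-random-network criterion |C_E d f_S/d lambda_E| < 1.

Wave regulation: survival over L pools P_S defines the threshold rate
lambda_E,max (P_S = 0.5) and its inverse, the minimum pool size n_E,min.
Assuming exponentially distributed wave lifetimes, the driven system
equilibrates where the stimulation rate balances wave death:

    T_S = T L / log(1/P_S),      h_eq = T_S / T_stim,

which combined with the rate balance yields the equilibrium condition

    L n_E p_f / (T_stim log(1/P_S) N_E) = lambda_E/C_E - f_S(lambda_E).

Embedding capacity at a conditioning activity level (firing rate nu_eq, or
waves per neuron h_eq/N_E) is alpha_max(C_E) = C_E / n_E,min^2, truncated by
the rate-stability limit C_E,max1 = 1/(d f_S/d lambda_E) and by the
wave-dominance limit C_E,max2 = lambda_E,max / (2 f_S(lambda_E,max))
(at least half of all spikes must belong to waves).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import optimize

from .engine import PropagationTable
from .neurons import RateTable

__all__ = [
    "MeanFieldSolution",
    "NoSolutionError",
    "DegenerateSurvivalError",
    "PropagationRow",
    "solve_selfconsistent",
    "lambda_E_max",
    "n_E_min",
    "equilibrium_waves",
    "equilibrium_state",
    "capacity_curve",
    "CapacityCurve",
]

P_S_CLIP = 1e-6  # guard for log(1/P_S)


class NoSolutionError(RuntimeError):
    """Raised when the self-consistency residual has no sign change."""

    def __init__(self, msg, residual_lo=None, residual_hi=None):
        super().__init__(msg)
        self.residual_lo = residual_lo
        self.residual_hi = residual_hi


class DegenerateSurvivalError(ValueError):
    """P_S is exactly 0 or 1: wave lifetime zero or infinite."""


class Crossing(NamedTuple):
    value: float
    out_of_range: bool


@dataclass
class MeanFieldSolution:
    """Self-consistent stationary state (rates in the units noted)."""

    lambda_E: float  # kHz
    lambda_I: float  # kHz
    nu: float  # Hz
    nu_W: float  # Hz
    nu_S: float  # Hz
    h_over_NE: float
    stable: bool
    residual: float  # kHz, at the returned root
    inputs: dict = field(default_factory=dict)

    @property
    def h(self) -> float | None:
        N_E = self.inputs.get("N_E")
        return None if N_E is None else self.h_over_NE * N_E

    def background_correction(self) -> float:
        """The neglected fraction n_E/(C_E (1 + nu_S/nu_W)) of the
        excitatory background rate (the approximation lambda_E ~= C_E nu)."""
        n_E, C_E = self.inputs["n_E"], self.inputs["C_E"]
        if self.nu_W <= 0:
            return 0.0
        return n_E / (C_E * (1.0 + self.nu_S / self.nu_W))


class PropagationRow:
    """One pool size's P_S, p_f, T as interpolable functions of lambda_E."""

    def __init__(self, table: PropagationTable, n_E: int):
        if n_E not in table.n_E_grid:
            raise ValueError(f"n_E={n_E} not in propagation table")
        self.n_E = int(n_E)
        P_S_raw, p_f_raw, T_raw = table.row(n_E)
        meas = ~np.isnan(P_S_raw)  # NaN P_S cells are unmeasured
        self.lam = table.lambda_E_grid[meas]
        self._P_S = P_S_raw[meas]
        self._p_f = p_f_raw[meas]
        self._T = T_raw[meas]
        ok = ~np.isnan(self._p_f) & ~np.isnan(self._T)
        self._lam_ok = self.lam[ok]
        self._p_f_ok = self._p_f[ok]
        self._T_ok = self._T[ok]

    @property
    def defined_range(self) -> tuple[float, float]:
        if self._lam_ok.size == 0:
            raise ValueError("p_f/T defined nowhere on this row")
        return float(self._lam_ok[0]), float(self._lam_ok[-1])

    def P_S(self, lam):
        return np.interp(lam, self.lam, self._P_S)

    def p_f(self, lam):
        lo, hi = self.defined_range
        if np.any(np.asarray(lam) < lo) or np.any(np.asarray(lam) > hi):
            raise ValueError("lambda_E outside the defined p_f range")
        return np.interp(lam, self._lam_ok, self._p_f_ok)

    def T(self, lam):
        lo, hi = self.defined_range
        if np.any(np.asarray(lam) < lo) or np.any(np.asarray(lam) > hi):
            raise ValueError("lambda_E outside the defined T range")
        return np.interp(lam, self._lam_ok, self._T_ok)


def _crossing_half(lam: np.ndarray, P_S: np.ndarray) -> Crossing:
    """First downward crossing of P_S through 0.5, linearly interpolated."""
    above = P_S > 0.5
    if not above.any():
        return Crossing(float(lam[0]), True)
    if above.all():
        return Crossing(float(lam[-1]), True)
    # walk from the first above-point to the first subsequent below-point
    i = int(np.nonzero(above)[0][0])
    while i + 1 < lam.size and P_S[i + 1] > 0.5:
        i += 1
    if i + 1 >= lam.size:
        return Crossing(float(lam[-1]), True)
    p0, p1 = P_S[i], P_S[i + 1]
    frac = (p0 - 0.5) / (p0 - p1)
    return Crossing(float(lam[i] + frac * (lam[i + 1] - lam[i])), False)


def lambda_E_max(n_E: int, table: PropagationTable) -> Crossing:
    """Threshold background rate: P_S(lambda_E,max; n_E) = 0.5 (kHz)."""
    row = PropagationRow(table, n_E)
    return _crossing_half(row.lam, row._P_S)


def n_E_min(lambda_E: float, table: PropagationTable) -> Crossing:
    """Minimum pool size for propagation at a given background rate.

    Inverse of lambda_E,max on the n_E axis, linearly interpolated between
    pool sizes of the table.
    """
    lam_max, flags = [], []
    for ne in table.n_E_grid:
        c = lambda_E_max(int(ne), table)
        lam_max.append(c.value)
        flags.append(c.out_of_range)
    lam_max = np.asarray(lam_max)
    n_grid = np.asarray(table.n_E_grid, dtype=float)
    usable = ~np.asarray(flags)
    if usable.sum() < 2:
        return Crossing(float(n_grid[0]), True)
    lam_u, n_u = lam_max[usable], n_grid[usable]
    order = np.argsort(lam_u)
    lam_u, n_u = lam_u[order], n_u[order]
    if lambda_E < lam_u[0]:
        return Crossing(float(n_u[0]), True)
    if lambda_E > lam_u[-1]:
        return Crossing(float(n_u[-1]), True)
    return Crossing(float(np.interp(lambda_E, lam_u, n_u)), False)


def _rate_kHz(rate_table: RateTable, lam):
    return rate_table(lam) / 1000.0


def solve_selfconsistent(
    C_E: float,
    n_E: int,
    h_over_NE: float,
    tables: tuple[RateTable, PropagationTable | PropagationRow],
    lambda_tol: float = 1e-3,
    n_scan: int = 2000,
) -> MeanFieldSolution:
    """Smallest root of the background self-consistency equation.

    The residual lambda_E - C_E[(h/N_E) n_E p_f/T + f_S] is scanned on a fine
    grid over the joint table support; the first sign change is refined by
    bisection to ``lambda_tol`` (kHz). A stability flag from the naive
    balanced-network criterion is attached.
    """
    if h_over_NE < 0:
        raise ValueError("h_over_NE must be >= 0")
    rate_table, prop = tables
    row = prop if isinstance(prop, PropagationRow) else PropagationRow(prop, n_E)

    def residual(lam: float) -> float:
        wave = h_over_NE * n_E * row.p_f(lam) / row.T(lam) if h_over_NE > 0 else 0.0
        return lam - C_E * (wave + float(_rate_kHz(rate_table, lam)))

    if h_over_NE > 0:
        lo = max(row.defined_range[0], rate_table.lambda_E_grid[0])
        hi = min(row.defined_range[1], rate_table.lambda_E_grid[-1])
    else:
        lo = rate_table.lambda_E_grid[0]
        hi = rate_table.lambda_E_grid[-1]
    if hi <= lo:
        raise NoSolutionError("tables have no common lambda_E support")

    grid = np.linspace(lo, hi, n_scan)
    res = np.array([residual(x) for x in grid])
    root = None
    if abs(res[0]) < lambda_tol:
        root = float(grid[0])
    else:
        sign_change = np.nonzero(np.diff(np.sign(res)) != 0)[0]
        if sign_change.size == 0:
            raise NoSolutionError(
                "no sign change of the self-consistency residual in "
                f"[{lo:.3g}, {hi:.3g}] kHz",
                residual_lo=float(res[0]),
                residual_hi=float(res[-1]),
            )
        i = int(sign_change[0])
        # locate to lambda_tol, then polish: the residual at the root should
        # vanish to rounding, not merely to the bracketing tolerance
        root = float(
            optimize.brentq(
                residual, grid[i], grid[i + 1], xtol=min(lambda_tol, 1e-10)
            )
        )

    nu_S = float(rate_table(root))
    nu_W = (
        1000.0 * h_over_NE * n_E * float(row.p_f(root)) / float(row.T(root))
        if h_over_NE > 0 and root > row.defined_range[0] - 1e-12
        else 0.0
    )
    gamma_prime = rate_table.gamma_prime
    slope = rate_table.derivative(root) / 1000.0  # kHz per kHz
    stable = abs(C_E * slope) < 1.0
    return MeanFieldSolution(
        lambda_E=root,
        lambda_I=gamma_prime * root,
        nu=nu_W + nu_S,
        nu_W=nu_W,
        nu_S=nu_S,
        h_over_NE=h_over_NE,
        stable=stable,
        residual=float(residual(root)),
        inputs={"C_E": C_E, "n_E": n_E},
    )


class WaveEquilibrium(NamedTuple):
    T_S: float  # expected wave lifetime, ms
    h_eq: float  # equilibrium wave count
    P_S_at_eq: float


def equilibrium_waves(
    lambda_E: float,
    row: PropagationRow,
    T_stim: float = 40.0,
    L: int = 98,
) -> WaveEquilibrium:
    """Exponential-lifetime relations T_S = T L / log(1/P_S), h_eq = T_S/T_stim."""
    P_S = float(row.P_S(lambda_E))
    if P_S <= 0.0 or P_S >= 1.0:
        raise DegenerateSurvivalError(
            f"P_S={P_S} at lambda_E={lambda_E}: lifetime zero or infinite"
        )
    P_c = float(np.clip(P_S, P_S_CLIP, 1 - P_S_CLIP))
    T = float(row.T(lambda_E))
    T_S = T * L / np.log(1.0 / P_c)
    return WaveEquilibrium(T_S=T_S, h_eq=T_S / T_stim, P_S_at_eq=P_S)


def survival_for_waves(h_eq: float, T_hat: float, T_stim: float = 40.0, L: int = 98) -> float:
    """Approximate inversion P_S ~= exp(-L T_hat / (h_eq T_stim))."""
    return float(np.exp(-L * T_hat / (h_eq * T_stim)))


@dataclass
class EquilibriumPrediction:
    exact: MeanFieldSolution
    approx: MeanFieldSolution
    h_eq: float  # from the exact solution
    h_eq_approx: float
    lambda_E_max: float


def equilibrium_state(
    C_E: float,
    n_E: int,
    tables: tuple[RateTable, PropagationTable],
    T_stim: float = 40.0,
    L: int = 98,
    N_E: float | None = None,
) -> EquilibriumPrediction:
    """Equilibrium of the stimulus-driven system.

    Solves the wave-death/stimulation balance for lambda_E by bisection on
    the table (P_S clipped away from {0,1}), and also reports the cheap
    approximation that evaluates everything at lambda_E = lambda_E,max.
    """
    rate_table, prop = tables
    row = PropagationRow(prop, n_E)
    N_E = float(N_E if N_E is not None else 10 * C_E)

    def F(lam: float) -> float:
        P = float(np.clip(row.P_S(lam), P_S_CLIP, 1 - P_S_CLIP))
        left = L * n_E * float(row.p_f(lam)) / (T_stim * np.log(1.0 / P) * N_E)
        return left - (lam / C_E - float(_rate_kHz(rate_table, lam)))

    lo = max(row.defined_range[0], rate_table.lambda_E_grid[0])
    hi = min(row.defined_range[1], rate_table.lambda_E_grid[-1])
    grid = np.linspace(lo, hi, 400)
    vals = np.array([F(x) for x in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise NoSolutionError(
            "wave-equilibrium condition has no root on the table",
            residual_lo=float(vals[0]), residual_hi=float(vals[-1]),
        )
    i = int(sign_change[0])
    lam_star = float(optimize.brentq(F, grid[i], grid[i + 1], xtol=1e-4))

    def _solution_at(lam: float) -> MeanFieldSolution:
        nu_S = float(rate_table(lam))
        nu = 1000.0 * lam / C_E
        return MeanFieldSolution(
            lambda_E=lam,
            lambda_I=rate_table.gamma_prime * lam,
            nu=nu,
            nu_W=nu - nu_S,
            nu_S=nu_S,
            h_over_NE=float("nan"),
            stable=abs(C_E * rate_table.derivative(lam) / 1000.0) < 1.0,
            residual=0.0,
            inputs={"C_E": C_E, "n_E": n_E, "N_E": N_E, "T_stim": T_stim, "L": L},
        )

    exact = _solution_at(lam_star)
    weq = equilibrium_waves(lam_star, row, T_stim, L)
    exact.h_over_NE = weq.h_eq / N_E

    lmax = lambda_E_max(n_E, prop)
    approx = _solution_at(lmax.value)
    h_eq_approx = float(row.T(lmax.value)) * L / (T_stim * np.log(2.0))
    approx.h_over_NE = h_eq_approx / N_E
    return EquilibriumPrediction(
        exact=exact, approx=approx,
        h_eq=weq.h_eq, h_eq_approx=h_eq_approx,
        lambda_E_max=lmax.value,
    )


@dataclass
class CapacityCurve:
    """Embedding capacity versus connectivity at fixed activity level."""

    conditioning: str  # "nu_eq" | "h_over_NE"
    value: float
    C_E: np.ndarray
    alpha_max: np.ndarray
    n_E_min: np.ndarray
    C_E_max1: np.ndarray
    C_E_max2: np.ndarray
    valid: np.ndarray  # conditioning inside table support and C_E below limits

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# conditioning={self.conditioning}\n# value={self.value}\n")
            fh.write("C_E\talpha_max\tn_E_min\tC_E_max1\tC_E_max2\tvalid\n")
            for i in range(self.C_E.size):
                fh.write(
                    f"{self.C_E[i]:.10g}\t{self.alpha_max[i]:.10g}"
                    f"\t{self.n_E_min[i]:.10g}\t{self.C_E_max1[i]:.10g}"
                    f"\t{self.C_E_max2[i]:.10g}\t{int(self.valid[i])}\n"
                )


def capacity_curve(
    conditioning: str,
    value: float,
    C_E_grid,
    tables: tuple[RateTable, PropagationTable],
    T_stim: float = 40.0,
    L: int = 98,
    N_E_over_C_E: float = 10.0,
) -> CapacityCurve:
    """alpha_max(C_E) with both connectivity limits.

    ``conditioning="nu_eq"`` fixes the equilibrium firing rate (value in Hz):
    lambda_E = C_E * nu_eq and n_E,min follows from the propagation table.
    ``conditioning="h_over_NE"`` fixes the waves-per-neuron level; the
    lifetime relation is inverted numerically on the table for each pool size
    and the resulting (C_E, alpha) points are reported parametrically on the
    pool-size grid (interpolated onto ``C_E_grid`` where possible).
    """
    rate_table, prop = tables
    C_E_grid = np.asarray(C_E_grid, dtype=float)

    if conditioning == "nu_eq":
        nu_kHz = value / 1000.0
        lam = C_E_grid * nu_kHz
        nmin = np.empty_like(lam)
        valid = np.ones(lam.size, dtype=bool)
        for i, x in enumerate(lam):
            c = n_E_min(float(x), prop)
            nmin[i] = c.value
            valid[i] &= not c.out_of_range
        alpha = C_E_grid / nmin**2
        fs_kHz = np.array([float(_rate_kHz(rate_table, x)) for x in lam])
        slopes = np.array([rate_table.derivative(float(x)) / 1000.0 for x in lam])
        with np.errstate(divide="ignore"):
            cmax1 = np.where(slopes > 0, 1.0 / slopes, np.inf)
            cmax2 = np.where(fs_kHz > 0, lam / (2.0 * fs_kHz), np.inf)
        valid &= C_E_grid <= np.minimum(cmax1, cmax2)
        return CapacityCurve(
            conditioning, value, C_E_grid, alpha, nmin, cmax1, cmax2, valid
        )

    if conditioning == "h_over_NE":
        pts_C, pts_alpha, pts_n = [], [], []
        for ne in prop.n_E_grid:
            row = PropagationRow(prop, int(ne))

            def G(lam: float) -> float:
                P = float(np.clip(row.P_S(lam), P_S_CLIP, 1 - P_S_CLIP))
                h_eq = float(row.T(lam)) * L / (T_stim * np.log(1.0 / P))
                nu_kHz = value * ne * float(row.p_f(lam)) / float(row.T(lam)) + float(
                    _rate_kHz(rate_table, lam)
                )
                C_E = lam / nu_kHz if nu_kHz > 0 else np.inf
                return h_eq - value * N_E_over_C_E * C_E

            lo, hi = row.defined_range
            lo = max(lo, rate_table.lambda_E_grid[0])
            hi = min(hi, rate_table.lambda_E_grid[-1])
            grid = np.linspace(lo, hi, 200)
            vals = np.array([G(x) for x in grid])
            sc = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
            if sc.size == 0:
                continue
            i = int(sc[0])
            lam_star = float(optimize.brentq(G, grid[i], grid[i + 1], xtol=1e-4))
            nu_kHz = value * ne * float(row.p_f(lam_star)) / float(
                row.T(lam_star)
            ) + float(_rate_kHz(rate_table, lam_star))
            C_E = lam_star / nu_kHz
            pts_C.append(C_E)
            pts_alpha.append(C_E / ne**2)
            pts_n.append(float(ne))
        pts_C = np.asarray(pts_C)
        order = np.argsort(pts_C)
        pts_C, pts_alpha, pts_n = (
            pts_C[order],
            np.asarray(pts_alpha)[order],
            np.asarray(pts_n)[order],
        )
        valid = (C_E_grid >= pts_C.min()) & (C_E_grid <= pts_C.max()) if pts_C.size else np.zeros(C_E_grid.size, bool)
        alpha = np.interp(C_E_grid, pts_C, pts_alpha) if pts_C.size else np.full(C_E_grid.size, np.nan)
        nmin = np.interp(C_E_grid, pts_C, pts_n) if pts_C.size else np.full(C_E_grid.size, np.nan)
        # the two connectivity limits are tied to the nu_eq conditioning and
        # are not reported for the wave-count conditioning
        cmax1 = np.full(C_E_grid.size, np.nan)
        cmax2 = np.full(C_E_grid.size, np.nan)
        return CapacityCurve(
            conditioning, value, C_E_grid, alpha, nmin, cmax1, cmax2, valid
        )

    raise ValueError(f"unknown conditioning {conditioning!r}")
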