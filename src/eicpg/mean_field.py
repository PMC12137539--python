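r"""Quasi-stationary mean-field theory of the two-population rate network.

Averaging over connectivity realizations, the input to a neuron is a
Gaussian process with mean and variance

    mu    = A * [phi]
    Delta = g_tot**2 * [phi^2] + v_in * u**2

where ``A = m_E N_E + m_I N_I`` is the anatomical imbalance,
``g_tot**2 = v_E N_E + v_I N_I`` the summed weight variance, and ``u`` the
external drive.  Under quasi-stationarity (the drive ``U(t) = 1 + sin(wt)``
varies slowly against tau), the activation is Gaussian with the same
moments, closing the system through

    [phi]   = int Dz phi(mu + sqrt(Delta) z)
    [phi^2] = int Dz phi^2(mu + sqrt(Delta) z)

Output feedback is omitted from the theory.  The stationary solution loses
stability when the variance gain ``g_tot**2 * int Dz phi'(...)**2`` reaches
one; scanned over the drive cycle (evaluated at the cycle-RMS drive, see
``DRIVE_RMS``) this criterion places the boundary between g_tot = 2.25
(stable for all A in [-15, 15]) and 2.5 (unstable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy.optimize import root

from .errors import SolverFailureError
from .params import _imbalance_coeff
from .transfer import RectTanh, TransferFunction, get_transfer

__all__ = [
    "MFTState", "StabilityReport", "DRIVE_RMS",
    "gaussian_moments", "gaussian_deriv_sq_moment", "solve_stationary",
    "stability_margin", "stability_scan", "mft_curves", "lyapunov_proxy",
]

#: root-mean-square of the drive U(t) = 1 + sin(w t) over one cycle
DRIVE_RMS = math.sqrt(1.5)

_GL_NODES, _GL_WEIGHTS = leggauss(96)
_GH_NODES, _GH_WEIGHTS = hermgauss(201)
_Z_CUT = 8.5  # standard-normal mass beyond this is < 1e-17


def _rect_tanh_integrals(mu: float, delta: float) -> tuple[float, float, float]:
    """([phi], [phi^2], [phi'^2]) for the rectified tanh under N(mu, delta).

    The rectification kink is handled exactly by truncating the domain at
    z0 = -mu/sqrt(Delta) and integrating the smooth tanh factors with
    Gauss-Legendre; plain Gauss-Hermite would converge only algebraically
    across the kink.
    """
    if delta <= 0:
        r = max(0.0, math.tanh(mu))
        d = 1.0 / math.cosh(mu) ** 2 if mu > 0 else 0.0
        return r, r * r, d * d
    s = math.sqrt(delta)
    lo = max(-mu / s, -_Z_CUT)
    hi = _Z_CUT
    if lo >= hi:
        return 0.0, 0.0, 0.0
    z = 0.5 * (hi - lo) * _GL_NODES + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * _GL_WEIGHTS * np.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
    x = mu + s * z
    t = np.tanh(x)
    sech2 = 1.0 / np.cosh(np.minimum(x, 350.0)) ** 2
    return float(w @ t), float(w @ (t * t)), float(w @ (sech2 * sech2))


def _smooth_integrals(
    mu: float, delta: float, transfer: TransferFunction
) -> tuple[float, float, float]:
    """Gauss-Hermite moments for transfer functions without a kink."""
    if delta <= 0:
        r = float(transfer(mu))
        d = float(transfer.deriv(mu))
        return r, r * r, d * d
    x = mu + math.sqrt(2.0 * delta) * _GH_NODES
    w = _GH_WEIGHTS / math.sqrt(math.pi)
    f = transfer(x)
    d = transfer.deriv(x)
    return float(w @ f), float(w @ (f * f)), float(w @ (d * d))


def _integrals(mu, delta, transfer):
    if isinstance(transfer, RectTanh):
        return _rect_tanh_integrals(mu, delta)
    return _smooth_integrals(mu, delta, transfer)


def gaussian_moments(
    mu: float, delta: float, transfer: TransferFunction | str = "rect_tanh"
) -> tuple[float, float]:
    """Population rate moments ([phi], [phi^2]) under a Gaussian input."""
    transfer = get_transfer(transfer)
    pm, p2, _ = _integrals(mu, delta, transfer)
    return pm, p2


def gaussian_deriv_sq_moment(
    mu: float, delta: float, transfer: TransferFunction | str = "rect_tanh"
) -> float:
    """E[phi'(mu + sqrt(Delta) z)^2], the slope factor of the variance gain."""
    transfer = get_transfer(transfer)
    return _integrals(mu, delta, transfer)[2]


@dataclass(frozen=True)
class MFTState:
    """Self-consistent quasi-stationary solution at drive value ``u``."""

    mu: float
    delta: float
    phi_mean: float
    phi_sq_mean: float
    u: float
    residual: float = 0.0


def solve_stationary(
    A: float,
    g_tot: float,
    v_in: float = 1.0 / 3.0,
    u: float = 1.0,
    transfer: TransferFunction | str = "rect_tanh",
    damping: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 20000,
) -> MFTState:
    """Solve the four self-consistency equations at one drive value.

    Damped fixed-point iteration on (mu, Delta); if the residual stays
    above 1e-10, a 2-D root solve takes over.  Raises
    :class:`SolverFailureError` (carrying the last residual) when neither
    converges.
    """
    transfer = get_transfer(transfer)
    ext = v_in * u * u
    mu, delta = 0.5 * A, 0.25 * g_tot**2 + ext + 1e-6
    res = math.inf
    for _ in range(max_iter):
        pm, p2, _ = _integrals(mu, delta, transfer)
        mu_new = A * pm
        delta_new = g_tot**2 * p2 + ext
        res = max(abs(mu_new - mu), abs(delta_new - delta))
        if res < tol:
            mu, delta = mu_new, delta_new
            break
        mu += damping * (mu_new - mu)
        delta += damping * (delta_new - delta)

    if res >= 1e-10:
        def residuals(v):
            m, d = v[0], max(v[1], 0.0)
            pm_, p2_, _ = _integrals(m, d, transfer)
            return [A * pm_ - m, g_tot**2 * p2_ + ext - d]

        sol = root(residuals, [mu, delta], method="hybr", tol=1e-13)
        mu, delta = sol.x[0], max(sol.x[1], 0.0)
        res = float(np.max(np.abs(residuals([mu, delta]))))
        if res >= 1e-10:
            raise SolverFailureError(
                f"mean-field solver failed at A={A}, g_tot={g_tot}, u={u}",
                residual=res,
            )

    pm, p2, _ = _integrals(mu, delta, transfer)
    return MFTState(mu=mu, delta=delta, phi_mean=pm, phi_sq_mean=p2, u=u,
                    residual=res)


@dataclass(frozen=True)
class StabilityReport:
    """Variance-gain stability assessment of one or more solutions."""

    variance_gain: float
    stable: bool
    max_stable_g_tot: float | None = None
    table: "pd.DataFrame | None" = None


def stability_margin(
    state: MFTState,
    g_tot: float,
    transfer: TransferFunction | str = "rect_tanh",
) -> StabilityReport:
    """Variance gain g_tot^2 * E[phi'^2] at a converged stationary state.

    The stationary solution is linearly stable against fluctuation growth
    iff the gain is below one.
    """
    gain = g_tot**2 * gaussian_deriv_sq_moment(state.mu, state.delta, transfer)
    return StabilityReport(variance_gain=gain, stable=bool(gain < 1.0))


def stability_scan(
    g_grid,
    A_values=range(-15, 16),
    v_in: float = 1.0 / 3.0,
    u: float = DRIVE_RMS,
    transfer: TransferFunction | str = "rect_tanh",
) -> StabilityReport:
    """Scan (g_tot, A) and report the largest g_tot stable for every A.

    Stability is judged at the cycle-RMS drive ``u`` (default
    sqrt(<U^2>) = sqrt(1.5) for U = 1 + sin), the effective drive power
    the slowly varying input delivers over one stride.
    """
    rows = []
    for g in g_grid:
        worst = 0.0
        for A in A_values:
            st = solve_stationary(A, g, v_in=v_in, u=u, transfer=transfer)
            gain = stability_margin(st, g, transfer).variance_gain
            worst = max(worst, gain)
            rows.append({"g_tot": g, "A": A, "u": u, "gain": gain,
                         "stable": gain < 1.0})
    table = pd.DataFrame(rows)
    by_g = table.groupby("g_tot")["stable"].all()
    stable_gs = by_g[by_g].index
    max_stable = float(stable_gs.max()) if len(stable_gs) else None
    worst_overall = float(table["gain"].max())
    return StabilityReport(
        variance_gain=worst_overall,
        stable=bool(table["stable"].all()),
        max_stable_g_tot=max_stable,
        table=table,
    )


def _drive_grid(n_u: int = 32) -> np.ndarray:
    """Midpoint grid of U = 1 + sin over one cycle (avoids the exact zero)."""
    theta = 2.0 * math.pi * (np.arange(n_u) + 0.5) / n_u
    return 1.0 + np.sin(theta)


def mft_curves(
    A_grid,
    g_tot: float,
    *,
    n_exc: int = 375,
    n_inh: int = 375,
    p_exc: float = 0.1,
    p_inh: float = 0.1,
    v_in: float = 1.0 / 3.0,
    n_u: int = 32,
    transfer: TransferFunction | str = "rect_tanh",
) -> pd.DataFrame:
    """Cycle-averaged mean-field predictions across an imbalance grid.

    For each A, the quasi-stationary state is solved on a midpoint grid of
    the drive over one cycle and the moments are time-averaged.  The mean
    recurrent input is additionally split into its excitatory part
    ``m_E N_E [phi]`` and inhibitory part ``m_I N_I [phi]`` using the
    by-strength parameterization at the given population sizes and
    connection probabilities.
    """
    from .params import solve_params_for_imbalance, weight_moments

    us = _drive_grid(n_u)
    rows = []
    for A in A_grid:
        states = [solve_stationary(A, g_tot, v_in=v_in, u=u, transfer=transfer)
                  for u in us]
        mu = float(np.mean([s.mu for s in states]))
        delta = float(np.mean([s.delta for s in states]))
        pm = float(np.mean([s.phi_mean for s in states]))
        p2 = float(np.mean([s.phi_sq_mean for s in states]))
        st_rms = solve_stationary(A, g_tot, v_in=v_in, u=DRIVE_RMS,
                                  transfer=transfer)
        gain = stability_margin(st_rms, g_tot, transfer).variance_gain
        try:
            pars = solve_params_for_imbalance(
                A, "by_g", g_tot=g_tot, n_exc=n_exc, n_inh=n_inh,
                p_exc=p_exc, p_inh=p_inh)
            mom = weight_moments(pars)
            e_cur = mom.m_exc * n_exc * pm
            i_cur = mom.m_inh * n_inh * pm
        except Exception:
            e_cur = i_cur = math.nan
        rows.append({"A": A, "g_tot": g_tot, "mu": mu, "delta": delta,
                     "phi_mean": pm, "phi_sq_mean": p2,
                     "e_current": e_cur, "i_current": i_cur,
                     "gain": gain, "stable": gain < 1.0})
    return pd.DataFrame(rows)


def lyapunov_proxy(
    A: float,
    g_tot: float,
    *,
    n_tot: int = 750,
    p: float = 0.1,
    seed: int = 0,
    duration: float = 2.0,
    perturbation: float = 1e-8,
    v_in: float = 1.0 / 3.0,
    omega: float = 2.0 * math.pi / 0.72,
) -> float:
    """Simulation-based stability fallback: twin-trajectory divergence rate.

    Runs two copies of an untrained network from initial conditions
    differing by ``perturbation`` and returns the mean exponential growth
    rate (1/s) of their distance over the second half of the run.
    Positive values indicate chaotic / unstable dynamics, negative values
    a stable driven response.  Raises NumericalDivergenceError if the
    activations blow up outright.
    """
    from .network import build_connectivity, seed_streams, step
    from .params import solve_params_for_imbalance

    ne = n_tot // 2
    pars = solve_params_for_imbalance(
        A, "by_g", g_tot=g_tot, n_exc=ne, n_inh=n_tot - ne,
        p_exc=p, p_inh=p, seed=seed, v_in=v_in)
    conn = build_connectivity(pars)
    transfer = get_transfer(pars.transfer)
    rng = seed_streams(pars.seed)["init"]
    x_a = rng.standard_normal(n_tot)
    x_b = x_a + perturbation * rng.standard_normal(n_tot)
    n_steps = int(duration / pars.dt)
    y0 = np.zeros(pars.n_outputs)
    t_half = n_steps // 2
    log_d = []
    for t in range(n_steps):
        u = 1.0 + math.sin(omega * t * pars.dt)
        x_a = step(x_a, conn, u, y0, transfer)
        x_b = step(x_b, conn, u, y0, transfer)
        if t >= t_half:
            d = float(np.linalg.norm(x_a - x_b))
            log_d.append(math.log(max(d, 1e-300)))
    times = np.arange(len(log_d)) * pars.dt
    slope = np.polyfit(times, log_d, 1)[0]
    return float(slope)
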