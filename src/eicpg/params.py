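r"""Anatomical network parameters and the excitation-inhibition imbalance algebra.

A network consists of an excitatory population (size ``n_exc``, connection
probability ``p_exc``, strength ``g_exc``) and an inhibitory one
(``n_inh``, ``p_inh``, ``g_inh``).  Nonzero recurrent weights are half-normal
magnitudes: positive for excitatory source neurons, negative for inhibitory
ones (Dale's law).  The pre-truncation Gaussian variance ``V0`` is chosen so
that the *full* weight set (zeros included) has variance ``v = g^2 / N``
independently of the connection probability::

    V0 = v / (p * (1 - 2*p/pi))

which makes the full-set mean of one population::

    m = sqrt(2/pi) * sqrt(p * v / (1 - 2*p/pi))

The **anatomical imbalance** is the mean summed recurrent weight onto a
neuron, ``A = m_E * N_E + m_I * N_I`` (m_I < 0): positive A means
excitation-dominated, negative A inhibition-dominated.  The **total
connection strength** is ``g_tot = sqrt(v_E N_E + v_I N_I) =
sqrt(g_E^2 + g_I^2)``.  ``solve_params_for_imbalance`` inverts this algebra:
given a target A and one of the totals held fixed, it returns per-population
parameters realizing it by varying N, p, or g globally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from scipy.optimize import brentq

from .errors import InfeasibleImbalanceError, InvalidParameterError

__all__ = [
    "NetworkParams",
    "WeightMoments",
    "truncated_gaussian_variance",
    "half_normal_mean",
    "weight_moments",
    "imbalance_of",
    "solve_params_for_imbalance",
]

_2_OVER_PI = 2.0 / math.pi


@dataclass(frozen=True)
class NetworkParams:
    """All anatomical and integration parameters of one network instance.

    Parameters
    ----------
    n_exc, n_inh
        Neuron counts of the excitatory / inhibitory population.
    p_exc, p_inh
        Connection probabilities in (0, 1].
    g_exc, g_inh
        Nonnegative connection-strength scalars; the full-set weight
        variance of each population is ``g**2 / N``.
    tau
        Neuronal time constant in seconds.
    dt
        Euler integration step in seconds.
    v_in
        Variance of the Gaussian input weights.
    n_outputs
        Readout dimensionality (number of muscles / channels).
    seed
        Master seed for this network instance; expands into independent
        streams for connectivity, initial states, and sequence shuffling.
    """

    n_exc: int
    n_inh: int
    p_exc: float
    p_inh: float
    g_exc: float
    g_inh: float
    tau: float = 0.01
    dt: float = 0.005
    v_in: float = 1.0 / 3.0
    n_outputs: int = 17
    seed: int = 0
    transfer: str = field(default="rect_tanh")

    def __post_init__(self):
        if self.n_exc < 1 or self.n_inh < 1:
            raise InvalidParameterError("population sizes must be positive integers")
        for name in ("p_exc", "p_inh"):
            p = getattr(self, name)
            if not (0.0 < p <= 1.0):
                raise InvalidParameterError(f"{name}={p} must lie in (0, 1]")
        if self.g_exc < 0 or self.g_inh < 0:
            raise InvalidParameterError("connection strengths must be nonnegative")
        if self.tau <= 0 or self.dt <= 0:
            raise InvalidParameterError("tau and dt must be positive")
        if self.v_in < 0:
            raise InvalidParameterError("v_in must be nonnegative")

    # -- derived totals -------------------------------------------------
    @property
    def n_tot(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def p_tot(self) -> float:
        return (self.n_exc * self.p_exc + self.n_inh * self.p_inh) / self.n_tot

    @property
    def v_exc(self) -> float:
        """Full-set variance of excitatory weights, g_E^2 / N_E."""
        return self.g_exc**2 / self.n_exc

    @property
    def v_inh(self) -> float:
        return self.g_inh**2 / self.n_inh

    @property
    def g_tot(self) -> float:
        return math.sqrt(self.g_exc**2 + self.g_inh**2)

    def with_seed(self, seed: int) -> "NetworkParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class WeightMoments:
    """First two moments of the full (zeros included) weight sets.

    ``m_exc >= 0`` and ``m_inh <= 0`` are the full-set means;
    ``v0_exc``/``v0_inh`` are the variances of the pre-truncation
    Gaussians; ``imbalance = m_exc*n_exc + m_inh*n_inh``.
    """

    m_exc: float
    m_inh: float
    v0_exc: float
    v0_inh: float
    imbalance: float


def truncated_gaussian_variance(v: float, p: float) -> float:
    """Pre-truncation Gaussian variance V0 producing full-set variance ``v``.

    A weight is, with probability ``p``, the magnitude |Z| of
    Z ~ N(0, V0) and otherwise zero.  Choosing
    ``V0 = v / (p * (1 - 2p/pi))`` makes the variance of the full weight
    set equal to ``v`` for every connection probability, with full-set
    mean ``sqrt(2/pi) * sqrt(p*v / (1 - 2p/pi))``.
    """
    if v <= 0:
        raise InvalidParameterError(f"target variance v={v} must be positive")
    if not (0.0 < p <= 1.0):
        raise InvalidParameterError(f"connection probability p={p} must lie in (0, 1]")
    return v / (p * (1.0 - _2_OVER_PI * p))


def half_normal_mean(v: float, p: float) -> float:
    """Full-set mean of the sparse half-normal weight construction."""
    v0 = truncated_gaussian_variance(v, p)
    return p * math.sqrt(_2_OVER_PI * v0)


def weight_moments(params: NetworkParams) -> WeightMoments:
    """Full-set weight moments and the anatomical imbalance of ``params``."""
    m_e = half_normal_mean(params.v_exc, params.p_exc)
    m_i = -half_normal_mean(params.v_inh, params.p_inh)
    return WeightMoments(
        m_exc=m_e,
        m_inh=m_i,
        v0_exc=truncated_gaussian_variance(params.v_exc, params.p_exc),
        v0_inh=truncated_gaussian_variance(params.v_inh, params.p_inh),
        imbalance=m_e * params.n_exc + m_i * params.n_inh,
    )


def _imbalance_coeff(p: float, n: float) -> float:
    """Coefficient a such that one population contributes a*g to A."""
    return math.sqrt(_2_OVER_PI) * math.sqrt(p * n / (1.0 - _2_OVER_PI * p))


def imbalance_of(params: NetworkParams) -> float:
    r"""Anatomical imbalance A = m_E N_E + m_I N_I.

    In terms of the anatomical parameters::

        A = sqrt(2/pi) * ( g_E * sqrt(p_E N_E / (1 - 2 p_E / pi))
                         - g_I * sqrt(p_I N_I / (1 - 2 p_I / pi)) )
    """
    return (
        _imbalance_coeff(params.p_exc, params.n_exc) * params.g_exc
        - _imbalance_coeff(params.p_inh, params.n_inh) * params.g_inh
    )


def _solve_by_g(
    A: float, g_tot: float, n_exc: int, n_inh: int, p_exc: float, p_inh: float
) -> tuple[float, float]:
    """Solve a*g_E - b*g_I = A with g_E^2 + g_I^2 = g_tot^2, g >= 0."""
    a = _imbalance_coeff(p_exc, n_exc)
    b = _imbalance_coeff(p_inh, n_inh)
    # Substitute g_I = (a g_E - A)/b into the circle constraint.
    qa = 1.0 + (a / b) ** 2
    qb = -2.0 * a * A / b**2
    qc = (A / b) ** 2 - g_tot**2
    disc = qb**2 - 4.0 * qa * qc
    if disc < 0:
        raise InfeasibleImbalanceError(
            f"imbalance A={A} unreachable at g_tot={g_tot} (no real solution)"
        )
    g_e = (-qb + math.sqrt(disc)) / (2.0 * qa)
    g_i = (a * g_e - A) / b
    if g_e < 0 or g_i < 0:
        raise InfeasibleImbalanceError(
            f"imbalance A={A} at g_tot={g_tot} requires a negative strength"
        )
    return g_e, g_i


def solve_params_for_imbalance(
    A: float,
    mode: str,
    *,
    g_tot: float | None = None,
    n_tot: int | None = None,
    p_tot: float | None = None,
    n_exc: int | None = None,
    n_inh: int | None = None,
    p_exc: float | None = None,
    p_inh: float | None = None,
    g_exc: float | None = None,
    g_inh: float | None = None,
    **extra,
) -> NetworkParams:
    """Find per-population parameters realizing imbalance ``A``.

    ``mode`` selects which anatomical quantity is varied globally while
    its total is held fixed:

    - ``"by_g"``: vary (g_E, g_I) at fixed ``g_tot`` (closed form, exact);
      requires n_exc, n_inh, p_exc, p_inh.
    - ``"by_N"``: vary the E/I split of ``n_tot`` at fixed shared p and g
      (``p_exc``/``g_exc`` taken as the common values); the returned split
      is rounded to integers, so the achieved imbalance (via
      :func:`imbalance_of`) can differ from the target by the rounding
      residual.
    - ``"by_p"``: vary (p_E, p_I) at fixed ``p_tot`` (numeric root,
      |residual| < 1e-9); requires n_exc, n_inh and the common g.

    Remaining ``NetworkParams`` fields (tau, dt, v_in, n_outputs, seed,
    transfer) pass through ``extra``.
    """
    if mode == "by_g":
        if g_tot is None or None in (n_exc, n_inh, p_exc, p_inh):
            raise InvalidParameterError("by_g requires g_tot, n_exc, n_inh, p_exc, p_inh")
        g_e, g_i = _solve_by_g(A, g_tot, n_exc, n_inh, p_exc, p_inh)
        return NetworkParams(
            n_exc=n_exc, n_inh=n_inh, p_exc=p_exc, p_inh=p_inh,
            g_exc=g_e, g_inh=g_i, **extra,
        )

    if mode == "by_N":
        if n_tot is None or p_exc is None or g_exc is None:
            raise InvalidParameterError("by_N requires n_tot and common p_exc, g_exc")
        p = p_exc
        g = g_exc
        k = math.sqrt(_2_OVER_PI) * g * math.sqrt(p / (1.0 - _2_OVER_PI * p))
        d = A / k  # sqrt(N_E) - sqrt(N_I)
        # representable only while both sqrt(N_E) and sqrt(N_I) stay
        # nonnegative, i.e. d^2 <= n_tot (the one-population extreme)
        if d * d > n_tot:
            raise InfeasibleImbalanceError(
                f"imbalance A={A} unreachable with n_tot={n_tot} at p={p}, g={g}"
            )
        x = (d + math.sqrt(2.0 * n_tot - d * d)) / 2.0  # sqrt(N_E)
        ne = int(round(x * x))
        ne = min(max(ne, 1), n_tot - 1)
        return NetworkParams(
            n_exc=ne, n_inh=n_tot - ne, p_exc=p, p_inh=p,
            g_exc=g, g_inh=g, **extra,
        )

    if mode == "by_p":
        if p_tot is None or None in (n_exc, n_inh) or g_exc is None:
            raise InvalidParameterError("by_p requires p_tot, n_exc, n_inh and common g_exc")
        g = g_exc
        ntot = n_exc + n_inh
        eps = 1e-9

        def p_i_of(p_e: float) -> float:
            return (p_tot * ntot - n_exc * p_e) / n_inh

        def f(p_e: float) -> float:
            pars = NetworkParams(
                n_exc=n_exc, n_inh=n_inh, p_exc=p_e, p_inh=p_i_of(p_e),
                g_exc=g, g_inh=g,
            )
            return imbalance_of(pars) - A

        # p_E range keeping both probabilities inside (0, 1]
        lo = max(eps, (p_tot * ntot - n_inh) / n_exc + eps)
        hi = min(1.0, (p_tot * ntot - eps * n_inh) / n_exc)
        if lo >= hi or f(lo) * f(hi) > 0:
            raise InfeasibleImbalanceError(
                f"imbalance A={A} unreachable at p_tot={p_tot} with the given populations"
            )
        p_e = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
        return NetworkParams(
            n_exc=n_exc, n_inh=n_inh, p_exc=p_e, p_inh=p_i_of(p_e),
            g_exc=g, g_inh=g, **extra,
        )

    raise InvalidParameterError(f"unknown mode {mode!r}; use by_g, by_N or by_p")
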