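r"""Dale's-law reservoir construction and rate dynamics.

The recurrent matrix ``j_rec`` follows the column convention: column ``j``
holds the outgoing weights of neuron ``j``; the first ``n_exc`` columns
belong to excitatory neurons (entries >= 0), the rest to inhibitory ones
(entries <= 0).  Each entry is nonzero with probability ``p`` (Bernoulli
mask, diagonal included) and, when nonzero, is a half-normal magnitude
scaled so the full-set variance equals ``g**2 / N`` for any ``p``.

Dynamics (Euler-forward, step ``dt``)::

    tau * dx/dt = -x + j_rec @ phi(x) + j_fb @ y + j_in * u
    y = w_out @ phi(x)

with ``u(t)`` a scalar drive from the rhythm-generation layer and ``y``
fed back (the network's own output unless an external series is given).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NumericalDivergenceError
from .params import NetworkParams, weight_moments
from .transfer import TransferFunction, get_transfer

__all__ = ["Connectivity", "SimulationResult", "seed_streams",
           "build_connectivity", "step", "run_network"]

#: activations beyond this magnitude abort the run as divergent
DIVERGENCE_LIMIT = 1e6


def seed_streams(master_seed: int, n_streams: int = 3):
    """Expand one master seed into named independent RNG streams.

    Returns generators for ("connectivity", "init", "sequence"); the
    ``init`` stream is consumed sequentially across training iterations.
    """
    children = np.random.SeedSequence(master_seed).spawn(n_streams)
    return {name: np.random.default_rng(ss)
            for name, ss in zip(("connectivity", "init", "sequence"), children)}


@dataclass
class Connectivity:
    """Realized weight matrices of one network instance.

    ``j_rec``: (n_tot, n_tot) recurrent weights (Dale sign pattern by
    column); ``j_in``: (n_tot,) Gaussian input weights; ``j_fb``:
    (n_tot, n_outputs) uniform [-1, 1] feedback weights; ``w_out``:
    (n_outputs, n_tot) readout, zero until trained.
    """

    j_rec: np.ndarray
    j_in: np.ndarray
    j_fb: np.ndarray
    w_out: np.ndarray
    params: NetworkParams = field(repr=False)


def build_connectivity(params: NetworkParams, seed: int | None = None) -> Connectivity:
    """Draw all weight matrices for ``params`` (deterministic given seed).

    ``seed`` overrides ``params.seed``.  The excitatory block is
    ``mask * |N(0, V0_E)|``; the inhibitory block the negative analogue.
    """
    master = params.seed if seed is None else seed
    rng = seed_streams(master)["connectivity"]
    ne, ni, ntot = params.n_exc, params.n_inh, params.n_exc + params.n_inh
    mom = weight_moments(params)

    j_rec = np.zeros((ntot, ntot))
    mask_e = rng.random((ntot, ne)) < params.p_exc
    j_rec[:, :ne] = mask_e * np.abs(rng.normal(0.0, np.sqrt(mom.v0_exc), (ntot, ne)))
    mask_i = rng.random((ntot, ni)) < params.p_inh
    j_rec[:, ne:] = -(mask_i * np.abs(rng.normal(0.0, np.sqrt(mom.v0_inh), (ntot, ni))))

    j_in = rng.normal(0.0, np.sqrt(params.v_in), ntot)
    j_fb = rng.uniform(-1.0, 1.0, (ntot, params.n_outputs))
    w_out = np.zeros((params.n_outputs, ntot))
    return Connectivity(j_rec=j_rec, j_in=j_in, j_fb=j_fb, w_out=w_out, params=params)


def step(
    x: np.ndarray,
    conn: Connectivity,
    u: float,
    y_fb: np.ndarray,
    transfer: TransferFunction,
    rates: np.ndarray | None = None,
) -> np.ndarray:
    """One Euler-forward step; returns the new activation vector.

    ``rates`` may pass phi(x) if already computed.  Raises
    :class:`NumericalDivergenceError` when activations leave the finite
    range (unstable coupling regimes must fail loudly).
    """
    p = conn.params
    r = transfer(x) if rates is None else rates
    drive = conn.j_rec @ r + conn.j_fb @ y_fb + conn.j_in * u
    x_new = x + (p.dt / p.tau) * (-x + drive)
    if not np.all(np.isfinite(x_new)) or np.max(np.abs(x_new)) > DIVERGENCE_LIMIT:
        raise NumericalDivergenceError(
            "activations diverged; the coupling regime is unstable"
        )
    return x_new


@dataclass
class SimulationResult:
    """Trajectories of one network run: rates, activations, outputs."""

    rates: np.ndarray       # (n_tot, T)
    activations: np.ndarray  # (n_tot, T)
    outputs: np.ndarray     # (n_outputs, T)


def run_network(
    conn: Connectivity,
    input_series: np.ndarray,
    feedback: "str | np.ndarray" = "self",
    x0: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    transfer: TransferFunction | str | None = None,
    record_activations: bool = True,
) -> SimulationResult:
    """Integrate the network over ``input_series`` (sampled at ``dt``).

    ``feedback="self"`` feeds the network its own readout ``w_out @ r``;
    an array of shape (n_outputs, T) supplies an external feedback series
    (e.g. the target during open-loop probing).  The initial activation is
    drawn from the standard normal using ``rng`` (or the instance's "init"
    stream) unless ``x0`` is given.
    """
    p = conn.params
    transfer = get_transfer(transfer or p.transfer)
    ntot, T = p.n_exc + p.n_inh, len(input_series)
    if x0 is None:
        rng = rng or seed_streams(p.seed)["init"]
        x0 = rng.standard_normal(ntot)
    external_fb = None if isinstance(feedback, str) else np.asarray(feedback)

    x = np.array(x0, dtype=float)
    rates = np.empty((ntot, T))
    acts = np.empty((ntot, T)) if record_activations else None
    outputs = np.empty((p.n_outputs, T))
    for t in range(T):
        r = transfer(x)
        y = conn.w_out @ r
        rates[:, t] = r
        outputs[:, t] = y
        if acts is not None:
            acts[:, t] = x
        y_fb = y if external_fb is None else external_fb[:, t]
        x = step(x, conn, float(input_series[t]), y_fb, transfer, rates=r)
    return SimulationResult(
        rates=rates,
        activations=acts if acts is not None else np.empty((ntot, 0)),
        outputs=outputs,
    )
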