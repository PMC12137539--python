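"""FORCE-style readout training with recursive least squares.

Only the linear readout ``w_out`` is trained; the recurrent, input, and
feedback weights stay fixed.  During training the network runs closed-loop
on its own output while RLS nudges ``w_out`` toward the target every
``update_interval`` steps.  With the inverse-correlation estimate
initialized as ``P = I / alpha`` and no forgetting, RLS converges to the
ridge-regression solution with penalty ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TrainingDivergenceError
from .network import Connectivity, SimulationResult, seed_streams, step
from .targets import AssembledSignal
from .transfer import get_transfer

__all__ = ["RLSState", "rls_update", "train_network", "test_network"]

DEFAULT_ALPHA = 1.0
DEFAULT_UPDATE_INTERVAL = 2


@dataclass
class RLSState:
    """Recursive-least-squares bookkeeping for the readout update.

    ``P`` is the running inverse of the (regularized) rate-correlation
    matrix; it stays symmetric positive definite throughout training.
    """

    P: np.ndarray
    alpha: float = DEFAULT_ALPHA
    update_interval: int = DEFAULT_UPDATE_INTERVAL

    @classmethod
    def init(cls, n: int, alpha: float = DEFAULT_ALPHA,
             update_interval: int = DEFAULT_UPDATE_INTERVAL) -> "RLSState":
        return cls(P=np.eye(n) / alpha, alpha=alpha,
                   update_interval=update_interval)


def rls_update(rls: RLSState, w: np.ndarray, r: np.ndarray,
               y_target: np.ndarray) -> np.ndarray:
    """One RLS step; mutates ``rls.P`` and ``w`` in place, returns the error.

    k = P r / (1 + r' P r);  e = W r - y*;  W <- W - e k';  P <- P - k (P r)'.
    The returned error is the pre-update output error ``e``.
    """
    pr = rls.P @ r
    k = pr / (1.0 + r @ pr)
    e = w @ r - y_target
    w -= np.outer(e, k)
    rls.P -= np.outer(k, pr)
    if not np.all(np.isfinite(w)):
        raise TrainingDivergenceError("readout weights became non-finite")
    return e


def train_network(
    conn: Connectivity,
    train_signal: AssembledSignal,
    n_iterations: int = 5,
    alpha: float = DEFAULT_ALPHA,
    update_interval: int = DEFAULT_UPDATE_INTERVAL,
    rng: np.random.Generator | None = None,
) -> list[float]:
    """Train ``conn.w_out`` on a training signal; returns per-iteration RMSE.

    Each iteration reinitializes the activations from the standard normal
    (and the fed-back output from the new state) while ``w_out`` and ``P``
    carry over, then runs the full signal closed-loop with RLS updates
    every ``update_interval`` steps.  The iteration RMSE is computed from
    the post-update outputs against the target.
    """
    p = conn.params
    transfer = get_transfer(p.transfer)
    rng = rng or seed_streams(p.seed)["init"]
    n_tot = p.n_exc + p.n_inh
    rls = RLSState.init(n_tot, alpha=alpha, update_interval=update_interval)
    targets = train_signal.signal
    u_series = train_signal.input_wave
    T = targets.shape[1]

    errors = []
    for it in range(n_iterations):
        x = rng.standard_normal(n_tot)
        sq_sum, count = 0.0, 0
        for t in range(T):
            r = transfer(x)
            if t % update_interval == 0:
                try:
                    rls_update(rls, conn.w_out, r, targets[:, t])
                except TrainingDivergenceError as err:
                    err.iteration = it
                    raise
            y = conn.w_out @ r
            sq_sum += float(np.sum((y - targets[:, t]) ** 2))
            count += y.size
            x = step(x, conn, float(u_series[t]), y, transfer, rates=r)
        errors.append(np.sqrt(sq_sum / count))
    return errors


def test_network(conn: Connectivity, test_signal: AssembledSignal,
                 rng: np.random.Generator | None = None) -> SimulationResult:
    """Run a frozen-readout test episode with own-output feedback.

    Returns the full trajectories; the first stride of the test signal
    covers the network's initialization transient and is excluded from
    evaluation downstream.
    """
    from .network import run_network

    p = conn.params
    rng = rng or seed_streams(p.seed)["init"]
    return run_network(conn, test_signal.input_wave, feedback="self", rng=rng)
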