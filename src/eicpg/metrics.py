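"""Outcome measures for trained pattern-formation networks.

* stride success: per muscle and per stride, the output is a success when
  its RMSE against the target is at or below 0.05; performance is the
  percentage of successful muscle-stride cells (first stride excluded as
  the initialization transient).
* effective dimensionality: number of principal components needed for 99%
  of the firing-rate variance (time samples as observations, neurons as
  variables, mean-centred).
* coactivation index (CAI): time-averaged overlap of two max-normalized
  activation traces, 1 for identical and 0 for strictly alternating
  signals; reported as the mean over all unordered muscle pairs.
* between-task variance: variance across the per-activity mean cycles
  after time-normalizing every stride to 0-100%.
* firing-rate statistics: across-neuron mean and variance (time-averaged)
  of both activations and rates, plus the skewness of the pooled rate
  distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import skew
from sklearn.decomposition import PCA

from .errors import InvalidParameterError

__all__ = [
    "EvaluationReport", "stride_success", "effective_dimensionality",
    "coactivation_index", "coactivation_matrix_mean", "between_task_variance",
    "firing_rate_stats", "evaluate_run",
]

SUCCESS_RMSE_THRESHOLD = 0.05
VARIANCE_THRESHOLD = 0.99
CYCLE_GRID_POINTS = 101


def _evaluated_strides(bounds, exclude_first: bool):
    return bounds[1:] if exclude_first else list(bounds)


def stride_success(
    outputs: np.ndarray,
    targets: np.ndarray,
    bounds,
    threshold: float = SUCCESS_RMSE_THRESHOLD,
    exclude_first: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-muscle, per-stride success classification.

    Returns ``(success, rmse)`` of shape (n_channels, n_evaluated_strides);
    the first stride is skipped by default (initialization transient).
    """
    outputs = np.asarray(outputs)
    targets = np.asarray(targets)
    if outputs.shape != targets.shape:
        raise InvalidParameterError(
            f"outputs {outputs.shape} and targets {targets.shape} misaligned")
    ev = _evaluated_strides(bounds, exclude_first)
    rmse = np.empty((outputs.shape[0], len(ev)))
    for k, (a, b) in enumerate(ev):
        diff = outputs[:, a:b] - targets[:, a:b]
        rmse[:, k] = np.sqrt(np.mean(diff**2, axis=1))
    return rmse <= threshold, rmse


def performance_pct(success_matrix: np.ndarray) -> float:
    """Percentage of successful muscle-stride cells."""
    return 100.0 * float(np.mean(success_matrix))


def effective_dimensionality(
    data: np.ndarray, variance_threshold: float = VARIANCE_THRESHOLD
) -> int:
    """Smallest number of PCs whose cumulative explained variance reaches
    the threshold.  ``data`` is (variables, samples); constant data has
    dimensionality 0 by convention.
    """
    data = np.asarray(data, dtype=float)
    if data.size == 0 or data.ndim != 2 or data.shape[1] < 2:
        raise InvalidParameterError("need a 2-D matrix with at least 2 samples")
    X = data.T - data.T.mean(axis=0)  # samples x variables, centred
    if not np.any(np.abs(X) > 1e-14):
        return 0
    n_comp = min(X.shape)
    ratios = PCA(n_components=n_comp, svd_solver="full").fit(X).explained_variance_ratio_
    cum = np.cumsum(ratios)
    return int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)


def coactivation_index(y1: np.ndarray, y2: np.ndarray) -> float:
    """Time-averaged coactivation of two nonnegative activation traces.

    Each trace is normalized to its own maximum over the window; the
    instantaneous index is 2*min/(sum of magnitudes), averaged over time
    points where at least one trace is active.  Returns NaN (with a
    warning) when either trace is identically zero.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    m1, m2 = np.max(np.abs(y1)), np.max(np.abs(y2))
    if m1 == 0.0 or m2 == 0.0:
        warnings.warn("coactivation undefined for an all-zero signal")
        return float("nan")
    a, b = np.abs(y1) / m1, np.abs(y2) / m2
    denom = a + b
    active = denom > 0
    if not np.any(active):
        return float("nan")
    cai_t = 2.0 * np.minimum(a[active], b[active]) / denom[active]
    return float(np.mean(cai_t))


def coactivation_matrix_mean(outputs: np.ndarray) -> float:
    """Mean CAI over all unordered channel pairs (NaN pairs skipped)."""
    n = outputs.shape[0]
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                vals.append(coactivation_index(outputs[i], outputs[j]))
    vals = np.asarray(vals)
    return float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")


def _resample_cycle(block: np.ndarray, n_points: int = CYCLE_GRID_POINTS) -> np.ndarray:
    """Time-normalize one stride (channels x samples) onto a 0-100% grid."""
    n = block.shape[1]
    src = np.linspace(0.0, 1.0, n)
    dst = np.linspace(0.0, 1.0, n_points)
    return np.stack([np.interp(dst, src, block[c]) for c in range(block.shape[0])])


def between_task_variance(
    outputs: np.ndarray,
    bounds,
    activity_labels,
    exclude_first: bool = True,
) -> float:
    """Variance across the per-task mean cycles of the output.

    Every evaluated stride is resampled to a common 0-100% grid, cycles
    are averaged within each task, and the population variance (divisor n)
    across the task means is averaged over channels and cycle points.
    """
    ev = _evaluated_strides(list(zip(bounds, activity_labels)), exclude_first)
    by_task: dict[str, list[np.ndarray]] = {}
    for (a, b), act in ev:
        by_task.setdefault(act, []).append(_resample_cycle(outputs[:, a:b]))
    if not by_task:
        raise InvalidParameterError("no strides to evaluate")
    task_means = np.stack([np.mean(cycles, axis=0) for cycles in by_task.values()])
    return float(np.mean(np.var(task_means, axis=0)))


@dataclass(frozen=True)
class RateStats:
    """Population statistics of a rate / activation trajectory."""

    rate_mean: float
    rate_network_variance: float
    rate_skewness: float
    input_mean: float
    input_network_variance: float


def firing_rate_stats(
    rate_matrix: np.ndarray,
    input_matrix: np.ndarray | None = None,
    pooled_skew: bool = True,
) -> RateStats:
    """Across-neuron mean/variance (time-averaged) and rate skewness.

    Skewness defaults to the pooled (neurons x time) rate distribution,
    matching how firing-rate histograms are usually presented; set
    ``pooled_skew=False`` to use per-neuron time averages instead.
    Constant rates yield skewness 0 by convention.
    """
    r = np.asarray(rate_matrix, dtype=float)
    rate_mean = float(np.mean(np.mean(r, axis=0)))
    rate_var = float(np.mean(np.var(r, axis=0)))
    pool = r.ravel() if pooled_skew else r.mean(axis=1)
    rate_skew = 0.0 if np.ptp(pool) == 0 else float(skew(pool))
    if input_matrix is not None and input_matrix.size:
        x = np.asarray(input_matrix, dtype=float)
        in_mean = float(np.mean(np.mean(x, axis=0)))
        in_var = float(np.mean(np.var(x, axis=0)))
    else:
        in_mean = in_var = float("nan")
    return RateStats(rate_mean=rate_mean, rate_network_variance=rate_var,
                     rate_skewness=rate_skew, input_mean=in_mean,
                     input_network_variance=in_var)


@dataclass(frozen=True)
class EvaluationReport:
    """All outcome parameters of one trained network on one test episode."""

    success_matrix: np.ndarray
    rmse_matrix: np.ndarray
    performance_pct: float
    n_npc: int
    n_output_pc: int
    cai_mean: float
    between_task_var: float
    rate_stats: RateStats

    def scalar_row(self) -> dict:
        """Flatten to one row of scalar metrics (for result tables)."""
        return {
            "performance_pct": self.performance_pct,
            "n_npc": self.n_npc,
            "n_output_pc": self.n_output_pc,
            "cai_mean": self.cai_mean,
            "between_task_var": self.between_task_var,
            "rate_mean": self.rate_stats.rate_mean,
            "rate_network_variance": self.rate_stats.rate_network_variance,
            "rate_skewness": self.rate_stats.rate_skewness,
            "input_mean": self.rate_stats.input_mean,
            "input_network_variance": self.rate_stats.input_network_variance,
        }


def evaluate_run(
    outputs: np.ndarray,
    rates: np.ndarray,
    activations: np.ndarray,
    test_signal,
    threshold: float = SUCCESS_RMSE_THRESHOLD,
) -> EvaluationReport:
    """Compute the full outcome report for one test episode."""
    bounds = test_signal.stride_bounds
    success, rmse = stride_success(outputs, test_signal.signal, bounds,
                                   threshold=threshold)
    # evaluation window: everything from the second stride on
    start = bounds[1][0] if len(bounds) > 1 else 0
    return EvaluationReport(
        success_matrix=success,
        rmse_matrix=rmse,
        performance_pct=performance_pct(success),
        n_npc=effective_dimensionality(rates[:, start:]),
        n_output_pc=effective_dimensionality(test_signal.signal[:, start:]),
        cai_mean=coactivation_matrix_mean(outputs[:, start:]),
        between_task_var=between_task_variance(outputs, bounds,
                                               test_signal.activities),
        rate_stats=firing_rate_stats(rates[:, start:],
                                     activations[:, start:] if activations.size else None),
    )
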