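"""Experiment orchestration: imbalance sweeps, mean-field comparison, and
speed generalization.

A sweep crosses an imbalance grid with one varied anatomical quantity
(neuron split, connection probabilities, or connection strengths) at fixed
totals, trains ``n_instances`` independently seeded networks per cell, and
aggregates the outcome metrics.  Seeds expand deterministically from the
master seed via a counter scheme, so result tables are exactly
reproducible from (config, seed), and the same test-sequence seeds are
shared across parameter settings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mean_field, metrics
from .errors import EICPGError, InfeasibleImbalanceError
from .network import build_connectivity, run_network, seed_streams
from .params import NetworkParams, imbalance_of, solve_params_for_imbalance
from .targets import (ACTIVITY_PERIODS, assemble_signal, primitive_patterns,
                      synthetic_muscle_targets)
from .training import test_network, train_network

log = logging.getLogger("eicpg")

__all__ = ["ExperimentConfig", "run_sweep", "run_generalization",
           "run_mft_comparison", "cell_seed"]


@dataclass
class ExperimentConfig:
    """Resolved settings of one sweep.

    Defaults give a desk-scale profile; the full study grid uses
    ``a_grid=range(-15, 16)``, ``n_instances=20`` and the complete lists of
    totals (n_tot in {300..2000}, p_tot in 0.05..0.5, g_tot in
    {0.5..2.25 step 0.25} plus sqrt(2*1.5^2)).
    """

    sweep_mode: str = "by_g"
    a_grid: list = field(default_factory=lambda: [-10, -5, 0, 5, 10])
    g_tot: float = float(np.sqrt(2 * 1.5**2))
    n_tot: int = 750
    p_tot: float = 0.1
    n_exc: int = 375
    n_inh: int = 375
    p_exc: float = 0.1
    p_inh: float = 0.1
    g_common: float = 1.5
    n_instances: int = 5
    n_channels: int = 17
    seed: int = 0
    target_seed: int = 0
    n_iterations: int = 5
    transfer: str = "rect_tanh"
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def cell_seed(master: int, cell_index: int, instance: int) -> int:
    """Deterministic per-(cell, instance) seed below 2**31."""
    ss = np.random.SeedSequence([master, cell_index, instance])
    return int(ss.generate_state(1)[0] % (2**31))


def _params_for_cell(cfg: ExperimentConfig, A: float) -> NetworkParams:
    common = dict(n_outputs=cfg.n_channels, transfer=cfg.transfer)
    if cfg.sweep_mode == "by_g":
        return solve_params_for_imbalance(
            A, "by_g", g_tot=cfg.g_tot, n_exc=cfg.n_exc, n_inh=cfg.n_inh,
            p_exc=cfg.p_exc, p_inh=cfg.p_inh, **common)
    if cfg.sweep_mode == "by_N":
        return solve_params_for_imbalance(
            A, "by_N", n_tot=cfg.n_tot, p_exc=cfg.p_exc, g_exc=cfg.g_common,
            **common)
    if cfg.sweep_mode == "by_p":
        return solve_params_for_imbalance(
            A, "by_p", p_tot=cfg.p_tot, n_exc=cfg.n_exc, n_inh=cfg.n_inh,
            g_exc=cfg.g_common, **common)
    raise EICPGError(f"unknown sweep mode {cfg.sweep_mode!r}")


def _train_and_evaluate(params: NetworkParams, patterns, instance_seed: int,
                        n_iterations: int) -> dict:
    """Build, train, test and score one network instance."""
    params = params.with_seed(instance_seed)
    conn = build_connectivity(params)
    streams = seed_streams(instance_seed)
    train_sig = assemble_signal(patterns, "train")
    # test sequences are shuffled by the instance's own sequence stream
    shuffle_seed = int(streams["sequence"].integers(2**31))
    test_sig = assemble_signal(patterns, "test", seed=shuffle_seed)
    train_errors = train_network(conn, train_sig, n_iterations=n_iterations,
                                 rng=streams["init"])
    sim = test_network(conn, test_sig, rng=streams["init"])
    report = metrics.evaluate_run(sim.outputs, sim.rates, sim.activations,
                                  test_sig)
    row = report.scalar_row()
    row["final_train_rmse"] = train_errors[-1]
    return row


def run_sweep(cfg: ExperimentConfig, resume_dir: str | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the imbalance sweep; returns (per-instance, aggregate) tables.

    Failures in single cells are logged and marked, never abort the sweep;
    with ``resume_dir`` (or ``cfg.out_dir``), finished cells found on disk
    are reused instead of recomputed.
    """
    out_dir = Path(resume_dir or cfg.out_dir) if (resume_dir or cfg.out_dir) else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    patterns = synthetic_muscle_targets(n_channels=cfg.n_channels,
                                        seed=cfg.target_seed)
    rows = []
    for ci, A in enumerate(cfg.a_grid):
        cache = out_dir / f"cell_{cfg.sweep_mode}_A{A}.csv" if out_dir else None
        if cache is not None and cache.exists():
            rows.append(pd.read_csv(cache))
            log.info("cell A=%s loaded from %s", A, cache)
            continue
        try:
            params = _params_for_cell(cfg, A)
        except InfeasibleImbalanceError as err:
            log.warning("cell A=%s infeasible: %s", A, err)
            continue
        cell_rows = []
        for inst in range(cfg.n_instances):
            seed = cell_seed(cfg.seed, ci, inst)
            try:
                row = _train_and_evaluate(params, patterns, seed,
                                          cfg.n_iterations)
                row.update(A_target=A, A_achieved=imbalance_of(params),
                           instance=inst, seed=seed, mode=cfg.sweep_mode,
                           g_exc=params.g_exc, g_inh=params.g_inh,
                           n_exc=params.n_exc, n_inh=params.n_inh,
                           p_exc=params.p_exc, p_inh=params.p_inh,
                           failed=False)
            except EICPGError as err:
                log.warning("cell A=%s instance %d failed: %s", A, inst, err)
                row = dict(A_target=A, instance=inst, seed=seed,
                           mode=cfg.sweep_mode, failed=True)
            cell_rows.append(row)
        cell_df = pd.DataFrame(cell_rows)
        if cache is not None:
            cell_df.to_csv(cache, index=False)
        rows.append(cell_df)

    per_instance = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    ok = per_instance[~per_instance.get("failed", pd.Series(dtype=bool))]
    numeric = ok.select_dtypes("number").drop(columns=["instance", "seed"],
                                              errors="ignore")
    agg = numeric.groupby(ok["A_target"]).agg(["mean", "std"]) if len(ok) else pd.DataFrame()
    if out_dir:
        per_instance.to_csv(out_dir / "sweep_instances.csv", index=False)
        agg.to_csv(out_dir / "sweep_aggregate.csv")
    return per_instance, agg


TRAIN_SPEEDS = (0.6, 1.2, 1.6)
TEST_SPEEDS = tuple(np.round(np.arange(0.3, 2.01, 0.1), 10))


def run_generalization(cfg: ExperimentConfig,
                       test_speeds=TEST_SPEEDS) -> pd.DataFrame:
    """Motor-primitive speed generalization.

    Networks are trained on the primitive patterns of three speeds and
    tested on each speed of the 0.3-2.0 m/s grid separately; the returned
    table carries per-speed success percentages and a trained/untrained
    flag.
    """
    train_patterns = {f"{s:.1f}m/s": primitive_patterns(s) for s in TRAIN_SPEEDS}
    rows = []
    for ci, A in enumerate(cfg.a_grid):
        try:
            params = _params_for_cell(cfg, A)
        except InfeasibleImbalanceError as err:
            log.warning("generalization A=%s infeasible: %s", A, err)
            continue
        params = replace(params, n_outputs=5)  # five primitive channels
        for inst in range(cfg.n_instances):
            seed = cell_seed(cfg.seed, 10_000 + ci, inst)
            p_inst = params.with_seed(seed)
            conn = build_connectivity(p_inst)
            streams = seed_streams(seed)
            train_sig = assemble_signal(train_patterns, "train")
            train_network(conn, train_sig, n_iterations=cfg.n_iterations,
                          rng=streams["init"])
            for speed in test_speeds:
                pat = primitive_patterns(float(speed))
                test_sig = assemble_signal({pat.activity: pat}, "test", seed=0)
                sim = test_network(conn, test_sig, rng=streams["init"])
                success, _ = metrics.stride_success(sim.outputs, test_sig.signal,
                                                    test_sig.stride_bounds)
                rows.append({"A": A, "instance": inst, "speed": float(speed),
                             "trained": float(speed) in TRAIN_SPEEDS,
                             "performance_pct": metrics.performance_pct(success)})
    return pd.DataFrame(rows)


def run_mft_comparison(
    cfg: ExperimentConfig,
    duration: float = 1.08 + 3 * ACTIVITY_PERIODS["run"],
    discard: float = 1.08,
    omega: float = 2 * np.pi / ACTIVITY_PERIODS["run"],
) -> pd.DataFrame:
    """Mean-field predictions vs. simulated statistics of untrained networks.

    Untrained networks (zero readout, so feedback contributes nothing) are
    driven by U(t) = 1 + sin(w t); their time-averaged population mean
    input and mean rate over the post-transient window are compared with
    the cycle-averaged quasi-stationary theory.  The default window keeps
    an integer number of drive cycles (1.5 discarded, 3 kept), so the
    time average of the periodically modulated signal is unbiased.
    """
    rows = []
    for ci, A in enumerate(cfg.a_grid):
        theory = mean_field.mft_curves(
            [A], cfg.g_tot, n_exc=cfg.n_exc, n_inh=cfg.n_inh,
            p_exc=cfg.p_exc, p_inh=cfg.p_inh).iloc[0]
        params = _params_for_cell(cfg, A)
        sim_mu, sim_rate = [], []
        for inst in range(cfg.n_instances):
            seed = cell_seed(cfg.seed, 20_000 + ci, inst)
            conn = build_connectivity(params.with_seed(seed))
            t = np.arange(int(duration / params.dt)) * params.dt
            u = 1.0 + np.sin(omega * t)
            sim = run_network(conn, u, rng=seed_streams(seed)["init"])
            keep = t >= discard
            sim_mu.append(float(np.mean(sim.activations[:, keep])))
            sim_rate.append(float(np.mean(sim.rates[:, keep])))
        rows.append({
            "A": A, "g_tot": cfg.g_tot,
            "mft_mu": theory["mu"], "mft_phi_mean": theory["phi_mean"],
            "e_current": theory["e_current"], "i_current": theory["i_current"],
            "sim_mu_mean": float(np.mean(sim_mu)),
            "sim_mu_std": float(np.std(sim_mu)),
            "sim_rate_mean": float(np.mean(sim_rate)),
            "sim_rate_std": float(np.std(sim_rate)),
            "n_instances": cfg.n_instances,
        })
    return pd.DataFrame(rows)
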