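"""Periodic multi-channel locomotor target signals.

Three ingredients:

* :func:`primitive_patterns` — five bell-shaped motor primitives per gait
  cycle, peaking at evenly spaced cycle fractions; stride frequency follows
  a monotone speed map.  Used for the speed-generalization experiment.
* :func:`synthetic_muscle_targets` — a 17-channel stand-in for
  musculoskeletal-model muscle activations: each channel is a nonnegative
  mixture of the primitive bumps with activity-specific amplitude scaling,
  timing shifts, and stride periods, clipped to [0, 1].  The three
  activities (slow walk, fast walk, run) are mutually distinguishable and
  the channel set is low-dimensional by construction.
* :func:`assemble_signal` — splices single-stride patterns into training
  (15 strides, activities in blocks of five) or test (21 strides, randomly
  interleaved) sequences: one-sample gaps filled by linear interpolation,
  20 Hz second-order zero-phase Butterworth low-pass, 50 samples trimmed
  from both ends.  The paired drive wave U(t) = 1 + sin(w t) switches
  frequency at stride boundaries, restarting each stride at U = 1 rising.

Everything is sampled at 200 Hz, the integration time base.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import InvalidParameterError

__all__ = [
    "StridePattern", "AssembledSignal", "ACTIVITY_PERIODS",
    "primitive_patterns", "synthetic_muscle_targets", "assemble_signal",
    "save_patterns", "load_external_targets",
]

SAMPLE_RATE = 200.0

#: stride periods (s) per locomotor activity; running taken as 720 ms
ACTIVITY_PERIODS = {"slow_walk": 1.30, "fast_walk": 1.00, "run": 0.72}

#: cycle fractions where the five motor-primitive bumps peak
PRIMITIVE_CENTERS = (0.1, 0.3, 0.5, 0.7, 0.9)
PRIMITIVE_WIDTH = 0.08     # bump sigma, fraction of the cycle
PRIMITIVE_AMPLITUDE = 0.8

#: linear speed (m/s) -> stride frequency (Hz) map for the primitives
SPEED_FREQ_INTERCEPT = 0.6
SPEED_FREQ_SLOPE = 0.25


@dataclass
class StridePattern:
    """One gait cycle of a multi-channel target.

    ``channels`` is (n_channels, n_samples) with values in [0, 1] spanning
    exactly one stride of duration ``period`` seconds.
    """

    activity: str
    period: float
    channels: np.ndarray
    sample_rate: float = SAMPLE_RATE

    @property
    def omega(self) -> float:
        """Angular stride frequency, 2*pi / period."""
        return 2.0 * np.pi / self.period

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]


@dataclass
class AssembledSignal:
    """A stride sequence spliced into one continuous target + drive pair."""

    signal: np.ndarray                      # (n_channels, T)
    input_wave: np.ndarray                  # (T,)
    stride_bounds: list = field(default_factory=list)  # [(start, stop)]
    activities: list = field(default_factory=list)
    sample_rate: float = SAMPLE_RATE

    @property
    def n_strides(self) -> int:
        return len(self.stride_bounds)


def _circular_bumps(n_samples: int, centers, width: float) -> np.ndarray:
    """Periodic Gaussian bumps over one cycle; rows are primitives."""
    frac = np.arange(n_samples) / n_samples
    out = np.empty((len(centers), n_samples))
    for i, c in enumerate(centers):
        d = np.abs(frac - c)
        d = np.minimum(d, 1.0 - d)  # wrap-around distance keeps strides periodic
        out[i] = np.exp(-0.5 * (d / width) ** 2)
    return out


def primitive_patterns(
    speed: float,
    n_primitives: int = 5,
    sample_rate: float = SAMPLE_RATE,
) -> StridePattern:
    """Five bell-shaped motor primitives for one stride at a gait speed.

    The stride frequency is linear in speed (0.6 + 0.25 * speed Hz);
    supported speeds span 0.3-2.0 m/s, the tested generalization range.
    """
    if not (0.3 <= speed <= 2.0):
        raise InvalidParameterError(f"speed {speed} m/s outside supported range [0.3, 2.0]")
    period = 1.0 / (SPEED_FREQ_INTERCEPT + SPEED_FREQ_SLOPE * speed)
    n_samples = int(round(period * sample_rate))
    centers = np.linspace(0.1, 0.9, n_primitives)
    channels = PRIMITIVE_AMPLITUDE * _circular_bumps(n_samples, centers, PRIMITIVE_WIDTH)
    return StridePattern(activity=f"{speed:.1f}m/s", period=period,
                         channels=channels, sample_rate=sample_rate)


def synthetic_muscle_targets(
    n_channels: int = 17,
    activities: dict | None = None,
    seed: int = 0,
    sample_rate: float = SAMPLE_RATE,
) -> dict[str, StridePattern]:
    """Seeded 17-channel locomotor-like targets for three activities.

    Each channel mixes 4-5 of the primitive bumps with nonnegative weights
    shared across activities; activities differ by a global amplitude
    scale, a timing shift of the bump centers, and their stride period.
    Sharing the channel mixing keeps the concatenated set low-rank
    (99% of variance within a handful of components, as in real muscle
    activations), while the shifts and scales keep the activities
    mutually distinguishable.
    """
    activities = dict(activities or ACTIVITY_PERIODS)
    rng = np.random.default_rng(seed)

    n_prim = len(PRIMITIVE_CENTERS)
    mixing = np.zeros((n_channels, n_prim))
    for ch in range(n_channels):
        k = rng.integers(4, n_prim + 1)
        active = rng.choice(n_prim, size=k, replace=False)
        mixing[ch, active] = rng.uniform(0.2, 1.0, size=k)

    amp_scale = {"slow_walk": 0.75, "fast_walk": 0.90, "run": 1.0}
    center_shift = {"slow_walk": 0.0, "fast_walk": 0.04, "run": -0.05}
    # per-channel peak targets keep amplitudes well inside [0, 1]
    peak = rng.uniform(0.45, 0.95, size=n_channels)

    patterns = {}
    for i, (act, period) in enumerate(activities.items()):
        n_samples = int(round(period * sample_rate))
        shift = center_shift.get(act, 0.02 * (i - 1))
        centers = (np.asarray(PRIMITIVE_CENTERS) + shift) % 1.0
        basis = _circular_bumps(n_samples, centers, PRIMITIVE_WIDTH)
        raw = mixing @ basis
        raw /= np.maximum(raw.max(axis=1, keepdims=True), 1e-12)
        scale = amp_scale.get(act, 0.85)
        channels = np.clip(scale * peak[:, None] * raw, 0.0, 1.0)
        patterns[act] = StridePattern(activity=act, period=period,
                                      channels=channels, sample_rate=sample_rate)
    return patterns


def _lowpass(signal: np.ndarray, sample_rate: float, cutoff: float = 20.0) -> np.ndarray:
    sos = butter(2, cutoff, btype="low", fs=sample_rate, output="sos")
    return sosfiltfilt(sos, signal, axis=-1)


TRIM_SAMPLES = 50


def assemble_signal(
    patterns: dict[str, StridePattern],
    mode: str,
    seed: int = 0,
    n_train_repeats: int = 5,
    n_test_strides: int = 21,
) -> AssembledSignal:
    """Splice stride patterns into a continuous training or test signal.

    ``mode="train"``: each activity repeated ``n_train_repeats`` times in
    blocks (order as given, 15 strides for three activities).
    ``mode="test"``: ``n_test_strides`` strides with the activities evenly
    represented and the order shuffled by ``seed``.

    Consecutive strides are joined across a one-sample gap filled by
    linear interpolation; the target is low-pass filtered (20 Hz,
    2nd-order bidirectional Butterworth) and the first and last
    ``TRIM_SAMPLES`` samples of both target and drive are cut.  The drive
    U = 1 + sin(w t) uses each stride's own frequency with the phase reset
    at stride onsets.
    """
    acts = list(patterns)
    if mode == "train":
        order = [a for a in acts for _ in range(n_train_repeats)]
    elif mode == "test":
        reps, rem = divmod(n_test_strides, len(acts))
        order = acts * reps + acts[:rem]
        rng = np.random.default_rng(seed)
        order = [order[i] for i in rng.permutation(len(order))]
    else:
        raise InvalidParameterError(f"mode must be 'train' or 'test', got {mode!r}")

    n_ch = next(iter(patterns.values())).channels.shape[0]
    sr = next(iter(patterns.values())).sample_rate
    sig_blocks, u_blocks, bounds, labels = [], [], [], []
    pos = 0
    for k, act in enumerate(order):
        pat = patterns[act]
        block = pat.channels
        t = np.arange(pat.n_samples) / sr
        u = 1.0 + np.sin(pat.omega * t)
        if k > 0:
            prev_sig = sig_blocks[-1][:, -1]
            prev_u = u_blocks[-1][-1]
            # one-sample gap filled by the midpoint of its neighbours
            sig_blocks.append(0.5 * (prev_sig + block[:, 0])[:, None])
            u_blocks.append(np.array([0.5 * (prev_u + u[0])]))
            pos += 1
        bounds.append((pos, pos + pat.n_samples))
        labels.append(act)
        sig_blocks.append(block)
        u_blocks.append(u)
        pos += pat.n_samples

    signal = np.concatenate(sig_blocks, axis=1)
    wave = np.concatenate(u_blocks)
    signal = _lowpass(signal, sr)

    signal = signal[:, TRIM_SAMPLES:-TRIM_SAMPLES]
    wave = wave[TRIM_SAMPLES:-TRIM_SAMPLES]
    T = signal.shape[1]
    trimmed_bounds = [
        (max(a - TRIM_SAMPLES, 0), min(b - TRIM_SAMPLES, T)) for a, b in bounds
    ]
    return AssembledSignal(signal=signal, input_wave=wave,
                           stride_bounds=trimmed_bounds, activities=labels,
                           sample_rate=sr)


# ---------------------------------------------------------------------------
# serialization

def save_patterns(patterns: dict[str, StridePattern], path: str | Path) -> None:
    """Write stride patterns to HDF5 (one group per activity) or CSV+JSON.

    CSV mode (path ending in .csv) writes one file per activity next to a
    ``<stem>_meta.json`` sidecar carrying periods and sample rates.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            for act, pat in patterns.items():
                g = f.create_group(act)
                g.create_dataset("channels", data=pat.channels)
                g.attrs["period"] = pat.period
                g.attrs["sample_rate"] = pat.sample_rate
                g.attrs["activity"] = pat.activity
    elif path.suffix == ".csv":
        meta = {}
        for act, pat in patterns.items():
            fp = path.with_name(f"{path.stem}_{act}.csv")
            header = ",".join(f"ch{i}" for i in range(pat.channels.shape[0]))
            np.savetxt(fp, pat.channels.T, delimiter=",", header=header, comments="")
            meta[act] = {"period": pat.period, "sample_rate": pat.sample_rate,
                         "file": fp.name}
        path.with_name(f"{path.stem}_meta.json").write_text(json.dumps(meta, indent=1))
    else:
        raise InvalidParameterError(f"unsupported pattern format: {path.suffix}")


def load_external_targets(path: str | Path) -> dict[str, StridePattern]:
    """Load stride patterns from an HDF5 or CSV+JSON file set.

    Values outside [0, 1] trigger a validation warning and are clipped.
    Intended for externally deposited muscle-activation targets; the
    synthetic generator writes the same layout.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"target file not found: {path}")
    patterns: dict[str, StridePattern] = {}
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            for act in f:
                g = f[act]
                patterns[act] = StridePattern(
                    activity=str(g.attrs.get("activity", act)),
                    period=float(g.attrs["period"]),
                    channels=np.asarray(g["channels"]),
                    sample_rate=float(g.attrs.get("sample_rate", SAMPLE_RATE)),
                )
    elif path.suffix == ".json":
        meta = json.loads(path.read_text())
        for act, info in meta.items():
            data = np.loadtxt(path.with_name(info["file"]), delimiter=",", skiprows=1)
            patterns[act] = StridePattern(
                activity=act, period=float(info["period"]),
                channels=np.atleast_2d(data).T,
                sample_rate=float(info.get("sample_rate", SAMPLE_RATE)),
            )
    else:
        raise InvalidParameterError(
            f"unsupported target format {path.suffix}; use .h5/.hdf5 or the _meta.json"
        )
    for act, pat in patterns.items():
        if pat.channels.min() < 0.0 or pat.channels.max() > 1.0:
            warnings.warn(f"pattern {act!r} has values outside [0, 1]; clipping")
            pat.channels = np.clip(pat.channels, 0.0, 1.0)
    return patterns
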