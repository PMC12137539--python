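"""Neuronal transfer functions.

Every transfer function maps activations to firing rates in [0, 1) and
exposes its derivative, which the mean-field stability analysis needs.
The default is the rectified hyperbolic tangent: zero rate for
non-positive input, saturating below one for large positive input.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TransferFunction", "RectTanh", "Sigmoid", "get_transfer"]


class TransferFunction:
    """Base class: a map R -> [0, 1) with a pointwise derivative."""

    name: str = "abstract"

    def __call__(self, x):
        raise NotImplementedError

    def deriv(self, x):
        raise NotImplementedError


class RectTanh(TransferFunction):
    """phi(x) = tanh(x) for x > 0, else 0.

    Biological constraints baked in: nonnegative rates, silence for
    inhibitory net input, saturation for strong drive.  The derivative
    is sech^2(x) on the active branch and 0 on the silent branch
    (the value at exactly x = 0 is taken from the silent branch).
    """

    name = "rect_tanh"

    def __call__(self, x):
        return np.maximum(np.tanh(x), 0.0)

    def deriv(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, 1.0 / np.cosh(np.minimum(np.abs(x), 350.0)) ** 2, 0.0)


class Sigmoid(TransferFunction):
    """Logistic transfer, phi(x) = 1 / (1 + exp(-x)); range (0, 1)."""

    name = "sigmoid"

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return 0.5 * (1.0 + np.tanh(0.5 * x))

    def deriv(self, x):
        s = self(x)
        return s * (1.0 - s)


_REGISTRY = {cls.name: cls for cls in (RectTanh, Sigmoid)}


def get_transfer(name_or_fn: "str | TransferFunction") -> TransferFunction:
    """Resolve a transfer function by name ("rect_tanh", "sigmoid") or pass through."""
    if isinstance(name_or_fn, TransferFunction):
        return name_or_fn
    try:
        return _REGISTRY[name_or_fn]()
    except KeyError:
        raise KeyError(
            f"unknown transfer function {name_or_fn!r}; "
            f"available: {sorted(_REGISTRY)}"
        ) from None
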