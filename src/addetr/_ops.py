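"""Dispatch helpers that work on both numpy arrays and autodiff Tensors.

The box-regression losses are written once against this shim; at
evaluation time they run on plain arrays, at training time on
:class:`addetr.nn.Tensor` so gradients flow to the predicted boxes.
"""

from __future__ import annotations

import numpy as np

from .nn.tensor import Tensor
from .nn import tensor as _t


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _any_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def maximum(a, b):
    if _any_tensor(a, b):
        return _t.maximum(a, b)
    return np.maximum(a, b)


def minimum(a, b):
    if _any_tensor(a, b):
        return _t.minimum(a, b)
    return np.minimum(a, b)


def exp(x):
    return x.exp() if is_tensor(x) else np.exp(x)


def log(x):
    return x.log() if is_tensor(x) else np.log(x)


def sqrt(x):
    return x.sqrt() if is_tensor(x) else np.sqrt(x)


def abs_(x):
    return x.abs() if is_tensor(x) else np.abs(x)


def arctan(x):
    return x.arctan() if is_tensor(x) else np.arctan(x)


def arcsin(x):
    return x.arcsin() if is_tensor(x) else np.arcsin(np.clip(x, -1.0, 1.0))


def sin(x):
    return x.sin() if is_tensor(x) else np.sin(x)


def cos(x):
    return x.cos() if is_tensor(x) else np.cos(x)


def clip(x, lo, hi):
    return minimum(maximum(x, lo), hi)


def detach(x):
    return x.detach() if is_tensor(x) else x


def mean(x):
    return x.mean() if is_tensor(x) else np.mean(x)


def sum_(x):
    return x.sum() if is_tensor(x) else np.sum(x)


def asdata(x) -> np.ndarray:
    return x.data if is_tensor(x) else np.asarray(x)
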