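"""Parameter transforms between unconstrained and model scales.

The hierarchy places normal priors on unconstrained parameters; the
model-scale (constrained) parameters are obtained with the standard
normal CDF for unit-interval parameters (learning rate, bias, decay, WM
propensity, non-decision time), an affine probit for WM capacity
``C = 2 + 3 * Phi(x)``, and ``exp`` for the positive race parameters
(k, A, eta).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, ndtr, ndtri

__all__ = [
    "PARAM_NAMES",
    "phi_approx",
    "constrain",
    "unconstrain",
    "transform_params",
]

#: Canonical parameter order used throughout the fitting module.
PARAM_NAMES = ("alpha", "bias", "phi", "rho", "C", "k", "A", "eta", "tau")

_PROBIT = ("alpha", "bias", "phi", "rho", "tau")
_LOG = ("k", "A", "eta")


def phi_approx(x):
    """Fast logistic approximation of the standard normal CDF.

    ``Phi_approx(x) = logistic(0.07056 x^3 + 1.5976 x)``; max absolute
    error below 1.5e-3 on [-5, 5].  The exact CDF (``scipy.special.ndtr``)
    is used in the transforms themselves; this approximation is provided
    for parity with samplers that rely on it.
    """
    x = np.asarray(x, dtype=float)
    out = expit(0.07056 * x**3 + 1.5976 * x)
    return float(out) if out.ndim == 0 else out


def constrain(x: np.ndarray) -> dict:
    """Map an unconstrained 9-vector (PARAM_NAMES order) to model scale."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(PARAM_NAMES),):
        raise ValueError(f"expected shape ({len(PARAM_NAMES)},), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite unconstrained parameters")
    out = {}
    for name, xi in zip(PARAM_NAMES, x):
        if name in _PROBIT:
            out[name] = float(ndtr(xi))
        elif name == "C":
            out[name] = float(2.0 + 3.0 * ndtr(xi))
        else:
            out[name] = float(np.exp(xi))
    return out


def unconstrain(params: dict) -> np.ndarray:
    """Inverse of :func:`constrain`; defined on the open domain."""
    x = np.empty(len(PARAM_NAMES))
    for i, name in enumerate(PARAM_NAMES):
        v = float(params[name])
        if name in _PROBIT:
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")
            x[i] = ndtri(v)
        elif name == "C":
            if not 2.0 < v < 5.0:
                raise ValueError(f"C={v} outside (2, 5)")
            x[i] = ndtri((v - 2.0) / 3.0)
        else:
            if v <= 0.0:
                raise ValueError(f"{name}={v} must be positive")
            x[i] = np.log(v)
    return x


def transform_params(unconstrained: np.ndarray) -> dict:
    """Alias for :func:`constrain` (the spec-level operation name)."""
    return constrain(unconstrained)
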