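"""Compiled numerical kernels for likelihood evaluation.

The hierarchical fit evaluates the model's pointwise log-likelihood many
thousands of times, so the forward replay of the learning model and the
LBA log-density are implemented here with numba.  The pure-Python modules
(`agent`, `lba`) define the reference semantics; tests assert the two
paths agree to near machine precision.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["subject_pointwise_loglik", "lba_log_defective_density"]

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)
_LOG_FLOOR = math.log(1e-300)
_LOG2 = math.log(2.0)


@njit(cache=True, inline="always")
def _npdf(x):
    return math.exp(-0.5 * x * x) * _INV_SQRT_2PI


@njit(cache=True, inline="always")
def _ncdf(x):
    # erfc keeps the tiny tail mass that erf saturates away
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True)
def _fpt_pdf(t, v, A, b, s):
    ts = t * s
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    f = (-v * _ncdf(z1) + s * _npdf(z1) + v * _ncdf(z2) - s * _npdf(z2)) / A
    return f if f > 0.0 else 0.0


@njit(cache=True)
def _fpt_cdf(t, v, A, b, s):
    ts = t * s
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    F = (
        1.0
        + (b - A - t * v) / A * _ncdf(z1)
        - (b - t * v) / A * _ncdf(z2)
        + ts / A * (_npdf(z1) - _npdf(z2))
    )
    if F < 0.0:
        return 0.0
    if F > 1.0:
        return 1.0
    return F


@njit(cache=True)
def lba_log_defective_density(rt, choice0, v0, v1, v2, A, b, s, tau):
    """Floored log defective density; ``choice0`` is 0-based."""
    td = rt - tau
    if td <= 0.0:
        return _LOG_FLOOR
    pnorm = 1.0 - _ncdf(-v0 / s) * _ncdf(-v1 / s) * _ncdf(-v2 / s)
    if pnorm <= 0.0:
        return _LOG_FLOOR
    if choice0 == 0:
        d = _fpt_pdf(td, v0, A, b, s) * (1.0 - _fpt_cdf(td, v1, A, b, s)) * (
            1.0 - _fpt_cdf(td, v2, A, b, s)
        )
    elif choice0 == 1:
        d = _fpt_pdf(td, v1, A, b, s) * (1.0 - _fpt_cdf(td, v0, A, b, s)) * (
            1.0 - _fpt_cdf(td, v2, A, b, s)
        )
    else:
        d = _fpt_pdf(td, v2, A, b, s) * (1.0 - _fpt_cdf(td, v0, A, b, s)) * (
            1.0 - _fpt_cdf(td, v1, A, b, s)
        )
    d = d / pnorm
    if d <= 0.0 or not math.isfinite(d):
        return _LOG_FLOOR
    ll = math.log(d)
    return ll if ll > _LOG_FLOOR else _LOG_FLOOR


@njit(cache=True)
def _softmax3_row(q0, q1, q2, beta):
    m = max(q0, max(q1, q2))
    e0 = math.exp(beta * (q0 - m))
    e1 = math.exp(beta * (q1 - m))
    e2 = math.exp(beta * (q2 - m))
    z = e0 + e1 + e2
    return e0 / z, e1 / z, e2 / z


@njit(cache=True)
def subject_pointwise_loglik(
    block_start,  # int8[n_trials]: 1 where a new block begins
    stim,  # int64[n_trials]: stimulus index local to the block (0-based)
    set_size,  # int64[n_trials]
    action,  # int64[n_trials]: 0-based chosen action
    reward,  # float64[n_trials]: 0/1
    rt,  # float64[n_trials]: seconds
    slope_z,  # float64[n_trials]: standardized neural slope (0 when absent)
    alpha,
    bias,
    phi,
    rho,
    capacity,
    k,
    A,
    eta,
    tau,
    beta_slope,
    beta_rl,
    beta_wm,
    s,
    eps_h,
    eta_min,
):
    """Forward replay of the RLWM agent with LBA trial log-densities.

    Mirrors agent.policy / agent.prior_entropy / lba.trial_loglik /
    agent.update_state trial by trial; returns one log-density per trial.
    """
    n = block_start.shape[0]
    out = np.empty(n)
    b = A + k
    q_rl = np.empty((5, 3))
    q_wm = np.empty((5, 3))
    n_s = 0
    w = 0.0
    pi = np.empty((5, 3))
    for t in range(n):
        if block_start[t] == 1:
            n_s = int(set_size[t])
            for i in range(n_s):
                for j in range(3):
                    q_rl[i, j] = 1.0 / 3.0
                    q_wm[i, j] = 1.0 / 3.0
            cn = capacity / n_s
            w = rho * (cn if cn < 1.0 else 1.0)

        # policies for all stimuli in the block and their average
        mu0 = 0.0
        mu1 = 0.0
        mu2 = 0.0
        for i in range(n_s):
            r0, r1, r2 = _softmax3_row(q_rl[i, 0], q_rl[i, 1], q_rl[i, 2], beta_rl)
            m0, m1, m2 = _softmax3_row(q_wm[i, 0], q_wm[i, 1], q_wm[i, 2], beta_wm)
            pi[i, 0] = w * m0 + (1.0 - w) * r0
            pi[i, 1] = w * m1 + (1.0 - w) * r1
            pi[i, 2] = w * m2 + (1.0 - w) * r2
            mu0 += pi[i, 0]
            mu1 += pi[i, 1]
            mu2 += pi[i, 2]
        mu0 /= n_s
        mu1 /= n_s
        mu2 /= n_s
        h = 0.0
        if mu0 > 0.0:
            h -= mu0 * math.log(mu0)
        if mu1 > 0.0:
            h -= mu1 * math.log(mu1)
        if mu2 > 0.0:
            h -= mu2 * math.log(mu2)
        h /= _LOG2
        if h < eps_h:
            h = eps_h

        eta_t = eta + beta_slope * slope_z[t]
        if eta_t < eta_min:
            eta_t = eta_min
        si = stim[t]
        v0 = eta_t * pi[si, 0] / h
        v1 = eta_t * pi[si, 1] / h
        v2 = eta_t * pi[si, 2] / h

        out[t] = lba_log_defective_density(rt[t], action[t], v0, v1, v2, A, b, s, tau)

        # learning update of the chosen entry, then WM decay of all entries
        a = action[t]
        r = reward[t]
        pe = r - q_rl[si, a]
        arl = alpha if pe >= 0.0 else (1.0 - bias) * alpha
        q_rl[si, a] = q_rl[si, a] + arl * pe
        pe_wm = r - q_wm[si, a]
        awm = 1.0 if pe_wm >= 0.0 else (1.0 - bias)
        q_wm[si, a] = q_wm[si, a] + awm * pe_wm
        for i in range(n_s):
            for j in range(3):
                q_wm[i, j] = q_wm[i, j] + phi * (1.0 / 3.0 - q_wm[i, j])
    return out
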