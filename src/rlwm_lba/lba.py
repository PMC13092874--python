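"""Linear ballistic accumulator (LBA) for 3-alternative choice and RT.

Each response alternative has an independent accumulator that starts at a
uniform random point in ``[0, A]`` and rises linearly with a slope drawn
from ``Normal(v_a, s)``; the first accumulator to reach the threshold
``b = A + k`` determines the choice, and the response time is the passage
time plus the non-decision time ``tau``.

Drift rates are constructed from the RLWM policy: the mixed policy
probability of each action is divided by the block-level prior-policy
entropy and scaled by ``eta`` (optionally trial-varying), so confident,
low-uncertainty policies accumulate quickly.

Conventions: the drift standard deviation ``s`` is fixed (default 1.0)
for identifiability; trials on which every sampled slope is non-positive
are resampled, and the density is renormalized by the probability that at
least one slope is positive so that simulator and likelihood agree.  The
7 s response deadline is not treated as censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.stats import norm

from .agent import EPS_H

__all__ = [
    "LBAParams",
    "DriftVector",
    "drift_rates",
    "lba_defective_density",
    "trial_loglik",
    "simulate_race",
    "simulate_races",
    "positive_drift_prob",
    "LOG_FLOOR",
]

#: Floor applied to log-densities so the likelihood stays finite.
LOG_FLOOR = float(np.log(1e-300))


@dataclass(frozen=True)
class LBAParams:
    """Race parameters.

    ``start_range`` (A) is the width of the uniform start-point
    distribution, ``rel_threshold`` (k) the distance from A to the
    threshold ``b = A + k``, ``drift_sd`` (s) the between-trial drift
    variability (fixed by convention), ``ndt`` (tau) the non-decision
    time in seconds, and ``eta`` the drift scaling.
    """

    start_range: float
    rel_threshold: float
    ndt: float
    eta: float
    drift_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.start_range <= 0 or self.rel_threshold <= 0 or self.drift_sd <= 0:
            raise ValueError("A, k and s must be strictly positive")
        if not 0.0 < self.ndt < 1.0:
            raise ValueError("non-decision time must lie in (0, 1) s")
        if self.eta <= 0:
            raise ValueError("eta must be strictly positive")

    @property
    def threshold(self) -> float:
        return self.start_range + self.rel_threshold


@dataclass
class DriftVector:
    """Per-trial mean drifts ``v_a = eta_t * pi_a / H_prior``."""

    v: np.ndarray
    source_policy: Optional[np.ndarray] = None
    h_prior: Optional[float] = None
    eta_t: Optional[float] = None


def drift_rates(pi: np.ndarray, h_prior: float, eta_t: float) -> DriftVector:
    """Map a policy and its prior entropy to mean drift rates."""
    pi = np.asarray(pi, dtype=float)
    if not np.all(np.isfinite(pi)) or not np.isfinite(h_prior) or not np.isfinite(eta_t):
        raise ValueError("non-finite drift inputs")
    if h_prior < EPS_H:
        raise ValueError(f"h_prior below entropy floor {EPS_H}")
    if eta_t <= 0:
        raise ValueError("eta_t must be positive")
    v = eta_t * pi / h_prior
    return DriftVector(v=v, source_policy=pi, h_prior=float(h_prior), eta_t=float(eta_t))


def _fpt_pdf(t, v, A, b, s):
    """First-passage density of one accumulator (unconditional on winning)."""
    ts = t * s
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    f = (-v * norm.cdf(z1) + s * norm.pdf(z1) + v * norm.cdf(z2) - s * norm.pdf(z2)) / A
    return np.maximum(f, 0.0)


def _fpt_cdf(t, v, A, b, s):
    """First-passage distribution of one accumulator."""
    ts = t * s
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    F = (
        1.0
        + (b - A - t * v) / A * norm.cdf(z1)
        - (b - t * v) / A * norm.cdf(z2)
        + ts / A * (norm.pdf(z1) - norm.pdf(z2))
    )
    return np.clip(F, 0.0, 1.0)


def positive_drift_prob(v: np.ndarray, s: float) -> float:
    """P(at least one sampled slope is positive) -- the renormalizer."""
    return float(1.0 - np.prod(norm.cdf(-np.asarray(v, dtype=float) / s)))


def lba_defective_density(
    t: Union[float, np.ndarray],
    choice: int,
    drifts: DriftVector,
    params: LBAParams,
) -> Union[float, np.ndarray]:
    """Defective density of (choice, RT): winner density times losers' survival.

    Conditioned on at least one positive sampled slope (the simulator's
    resampling contract).  Returns 0 for ``t <= tau``.  Integrating over t
    and summing over choices yields 1.
    """
    if choice not in (1, 2, 3):
        raise ValueError("choice must be 1, 2 or 3")
    t = np.asarray(t, dtype=float)
    A, b, s, tau = params.start_range, params.threshold, params.drift_sd, params.ndt
    v = np.asarray(drifts.v, dtype=float)
    td = t - tau
    valid = td > 0
    tdv = np.where(valid, td, 1.0)  # dummy where invalid
    dens = _fpt_pdf(tdv, v[choice - 1], A, b, s)
    for j in range(3):
        if j != choice - 1:
            dens = dens * (1.0 - _fpt_cdf(tdv, v[j], A, b, s))
    dens = dens / positive_drift_prob(v, s)
    out = np.where(valid, dens, 0.0)
    return float(out) if out.ndim == 0 else out


def trial_loglik(
    rt: float,
    choice: int,
    drifts: DriftVector,
    params: LBAParams,
) -> float:
    """Log defective density, floored at log(1e-300) so it is always finite."""
    if rt is None or not np.isfinite(rt):
        raise ValueError("rt is missing or non-finite")
    d = lba_defective_density(rt, choice, drifts, params)
    if d <= 0 or not np.isfinite(d):
        return LOG_FLOOR
    return max(float(np.log(d)), LOG_FLOOR)


def simulate_races(
    n: int,
    drifts: DriftVector,
    params: LBAParams,
    rng: Union[int, np.random.Generator],
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized race simulation: ``n`` independent (choice, rt) draws.

    Start points are Uniform(0, A), slopes Normal(v_a, s); trials on
    which all three slopes are non-positive are redrawn.  Choices are
    1-based.
    """
    v = np.asarray(drifts.v, dtype=float)
    if not np.any(v > 0):
        raise ValueError("at least one mean drift must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    A, b, s, tau = params.start_range, params.threshold, params.drift_sd, params.ndt

    choices = np.empty(n, dtype=np.int64)
    rts = np.empty(n, dtype=float)
    pending = np.arange(n)
    while pending.size:
        m = pending.size
        slopes = rng.normal(v, s, size=(m, 3))
        starts = rng.uniform(0.0, A, size=(m, 3))
        ok = (slopes > 0).any(axis=1)
        idx = pending[ok]
        t = np.where(slopes[ok] > 0, (b - starts[ok]) / slopes[ok], np.inf)
        w = np.argmin(t, axis=1)
        choices[idx] = w + 1
        rts[idx] = tau + t[np.arange(idx.size), w]
        pending = pending[~ok]
    return choices, rts


def simulate_race(
    drifts: DriftVector,
    params: LBAParams,
    rng_seed: Union[int, np.random.Generator],
) -> tuple[int, float]:
    """Single race draw; see :func:`simulate_races`."""
    c, t = simulate_races(1, drifts, params, rng_seed)
    return int(c[0]), float(t[0])
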