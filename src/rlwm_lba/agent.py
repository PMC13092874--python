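"""Hybrid reinforcement-learning / working-memory (RLWM) value model.

Two modules learn the expected reward of each stimulus-action pair under
deterministic 0/1 feedback:

* an RL module updating ``Q_RL`` with the delta rule at learning rate
  ``alpha_rl``, reduced by a ``bias`` factor after negative prediction
  errors (neglect of negative feedback);
* a WM module updating ``Q_WM`` with learning rate 1 (perfect one-shot
  storage), subject to the same bias, and decaying every trial toward its
  initial value 1/3 at rate ``phi``.

Each module emits a softmax policy; they are mixed with weight
``W_WM = rho * min(1, C / n_s)`` where ``C`` is WM capacity and ``n_s``
the block's set size.  The Shannon entropy of the block-average mixed
policy, taken before the current stimulus is encoded, quantifies the
remaining uncertainty about the block's stimulus-response mappings and
later scales accumulator drift rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import softmax, xlogy

__all__ = [
    "EPS_H",
    "AgentParams",
    "AgentState",
    "PolicyBundle",
    "init_state",
    "rl_update",
    "wm_update",
    "wm_decay",
    "mixing_weight",
    "policy",
    "prior_entropy",
    "update_state",
]

#: Floor on the prior-policy entropy (bits); keeps drift rates finite when
#: the average policy degenerates.  With finite softmax sensitivity this is
#: essentially never binding.
EPS_H = 1e-6

N_ACTIONS = 3


@dataclass(frozen=True)
class AgentParams:
    """RLWM parameters.

    ``beta_rl`` / ``beta_wm`` are fixed softmax sensitivities (choice
    stochasticity is carried by the accumulator race, not the softmax);
    ``alpha_wm`` is identically 1 by construction of the WM module.
    """

    alpha_rl: float
    bias: float
    phi: float
    rho: float
    capacity: float
    beta_rl: float = 10.0
    beta_wm: float = 10.0

    alpha_wm: float = field(default=1.0, init=False)

    def __post_init__(self) -> None:
        for name in ("alpha_rl", "bias", "phi", "rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 2.0 <= self.capacity <= 5.0:
            raise ValueError(f"capacity must lie in [2, 5], got {self.capacity}")


@dataclass
class AgentState:
    """Per-block value state: Q matrices (stimuli x 3) and mixing weight."""

    q_rl: np.ndarray
    q_wm: np.ndarray
    w_wm: float
    n_actions: int = N_ACTIONS


@dataclass
class PolicyBundle:
    """Policies for one stimulus plus the block-level uncertainty measure."""

    p_rl: np.ndarray
    p_wm: np.ndarray
    pi: np.ndarray
    mu_pi: np.ndarray
    h_prior: float


def init_state(n_stimuli: int, params: AgentParams, set_size: Optional[int] = None) -> AgentState:
    """Fresh block state: both Q matrices at the uniform value 1/3."""
    if set_size is None:
        set_size = n_stimuli
    q0 = np.full((n_stimuli, N_ACTIONS), 1.0 / N_ACTIONS)
    return AgentState(
        q_rl=q0.copy(),
        q_wm=q0.copy(),
        w_wm=mixing_weight(params.rho, params.capacity, set_size),
    )


def _effective_alpha(alpha: float, bias: float, prediction_error: float) -> float:
    return alpha if prediction_error >= 0 else (1.0 - bias) * alpha


def rl_update(q: float, reward: int, params: AgentParams) -> float:
    """Delta-rule update of a Q_RL entry with negative-feedback bias."""
    pe = reward - q
    return q + _effective_alpha(params.alpha_rl, params.bias, pe) * pe


def wm_update(q: float, reward: int, params: AgentParams) -> float:
    """One-shot WM update (learning rate 1) with negative-feedback bias."""
    pe = reward - q
    return q + _effective_alpha(params.alpha_wm, params.bias, pe) * pe


def wm_decay(state: AgentState, params: AgentParams) -> AgentState:
    """Decay all Q_WM entries toward 1/3 at rate phi (in place)."""
    q0 = 1.0 / state.n_actions
    state.q_wm += params.phi * (q0 - state.q_wm)
    return state


def mixing_weight(rho: float, capacity: float, set_size: int) -> float:
    """WM share of the policy: ``rho * min(1, C / n_s)``."""
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    return rho * min(1.0, capacity / set_size)


def _module_policies(state: AgentState, params: AgentParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Softmax policies of both modules and their mixture, all stimuli."""
    p_rl = softmax(params.beta_rl * state.q_rl, axis=1)
    p_wm = softmax(params.beta_wm * state.q_wm, axis=1)
    pi = state.w_wm * p_wm + (1.0 - state.w_wm) * p_rl
    return p_rl, p_wm, pi


def prior_entropy(state: AgentState, params: AgentParams) -> float:
    """Shannon entropy (bits) of the block-average policy, floored at EPS_H.

    The average is taken over the block's stimuli using the current
    (pre-trial) state, i.e. before the current stimulus is encoded.
    """
    _, _, pi = _module_policies(state, params)
    mu = pi.mean(axis=0)
    h = float(-np.sum(xlogy(mu, mu)) / np.log(2.0))
    return max(h, EPS_H)


def policy(state: AgentState, stimulus: int, params: AgentParams) -> PolicyBundle:
    """Mixed action policy for one stimulus plus block-average entropy."""
    n = state.q_rl.shape[0]
    if not 0 <= stimulus < n:
        raise KeyError(f"unknown stimulus index {stimulus} (state has {n})")
    p_rl, p_wm, pi = _module_policies(state, params)
    mu = pi.mean(axis=0)
    h = float(-np.sum(xlogy(mu, mu)) / np.log(2.0))
    return PolicyBundle(
        p_rl=p_rl[stimulus],
        p_wm=p_wm[stimulus],
        pi=pi[stimulus],
        mu_pi=mu,
        h_prior=max(h, EPS_H),
    )


def update_state(
    state: AgentState, stimulus: int, action: int, reward: int, params: AgentParams
) -> AgentState:
    """Post-feedback update: delta updates, then WM decay of all entries.

    ``action`` is 1-based (task convention).  Decay is applied once per
    trial to every stimulus-action entry, after the update of the current
    trial's entry.
    """
    a = action - 1
    state.q_rl[stimulus, a] = rl_update(state.q_rl[stimulus, a], reward, params)
    state.q_wm[stimulus, a] = wm_update(state.q_wm[stimulus, a], reward, params)
    return wm_decay(state, params)
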