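"""Synthetic-data generator for behavior and epoched EEG.

The generator is the study's stand-in population: subject parameters are
drawn from a normal hierarchy on the unconstrained scale (mirroring the
fitted model), behavior is simulated by running the task with an
RLWM-LBA responder (policy -> entropy -> drift rates -> race), and
epoched EEG is synthesized so that the statistical structure the
analyses assume is actually present:

* a centro-parietal ramp (CPP), peaking at CPz, that rises toward the
  response with a buildup rate increasing in the trial's drift rate and
  therefore a response-locked peak amplitude increasing in drift;
* a fronto-central negativity around 300 ms after stimulus onset whose
  amplitude scales with the chosen option's Q_RL value and with delay;
* a parietal positivity around 540 ms scaling with set size;
* temporally autocorrelated AR(1) noise on every channel.

Stimulus- and response-locked epochs are cut from the same continuous
per-trial signal.  EEG is generated only for the analysis set (correct,
non-first presentations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import agent as ag
from . import lba as lb
from . import task as tk
from ._seeding import derive_seed
from .transforms import PARAM_NAMES, constrain

__all__ = [
    "GeneratorConfig",
    "EEGConfig",
    "EpochSet",
    "BIOSEMI64_LABELS",
    "channel_positions",
    "sample_subject_params",
    "simulate_behavior",
    "simulate_eeg",
    "LBAResponder",
]

#: 64-channel 10/20-style label set (BioSemi cap ordering).
BIOSEMI64_LABELS = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8",
    "FC6", "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6",
    "CP4", "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

_ROW_Y = {
    "Fp": 4.0, "AF": 3.0, "F": 2.0, "FT": 1.0, "FC": 1.0, "C": 0.0, "T": 0.0,
    "TP": -1.0, "CP": -1.0, "P": -2.0, "PO": -3.0, "O": -4.0, "I": -5.0,
}


def channel_positions(labels: Sequence[str]) -> np.ndarray:
    """Idealized 2-D scalp-plane coordinates (x: left-, right+; y: posterior-).

    Sufficient for Gaussian spatial weighting and neighborhood checks; not
    a biophysical head model.
    """
    pos = np.empty((len(labels), 2))
    for i, lab in enumerate(labels):
        head = lab.rstrip("z0123456789")
        tail = lab[len(head):]
        y = _ROW_Y[head]
        if tail == "z" or tail == "":
            x = 0.0
        else:
            n = int(tail)
            lateral = (n + 1) // 2
            x = -float(lateral) if n % 2 == 1 else float(lateral)
        pos[i] = (x, y)
    return pos


@dataclass(frozen=True)
class EEGConfig:
    """Shape and effect sizes of the synthetic EEG.

    Amplitudes are in microvolts (per z-unit of the driving covariate);
    CPP rates are in microvolts per millisecond.  Noise is AR(1) with the
    given lag-one coefficient and stationary standard deviation.
    """

    channels: Sequence[str] = BIOSEMI64_LABELS
    sampling_rate: float = 512.0
    epoch_start_ms: float = -700.0
    epoch_samples: int = 716
    cpp_base_rate: float = 0.07  # uV/ms at average drift
    cpp_gain: float = 0.05  # uV/ms per z(drift)
    cpp_min_rate: float = 0.005
    cpp_max_buildup_ms: float = 600.0
    cpp_fall_ms: float = 200.0
    q_effect: float = 2.5  # uV per z(Q_RL), sign applied negatively at 300 ms
    delay_effect: float = 1.5  # uV per z(delay), negative component
    setsize_effect: float = 2.5  # uV per z(set size), positive at 540 ms
    stim_component_ms: tuple = (300.0, 540.0)
    stim_component_sd_ms: tuple = (50.0, 60.0)
    ar_coef: float = 0.95
    noise_sd: float = 8.0
    spatial_sigma: float = 1.0
    cpp_center: str = "CPz"
    frontal_center: str = "FCz"
    parietal_center: str = "POz"

    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        return self.epoch_start_ms + step * np.arange(self.epoch_samples)


#: Default group-level distribution of subject parameters on the
#: unconstrained scale: a population with slow RL learning (~0.07),
#: moderate neglect of negative feedback, WM decay ~0.3, high WM use
#: (~0.84) with capacity ~3.9, threshold geometry A~0.8, k~0.5, drift
#: scaling eta~2.7 and non-decision time ~0.3 s.
DEFAULT_GROUP_MEANS = {
    "alpha": -1.5, "bias": -0.5, "phi": -0.5, "rho": 1.0, "C": 0.3,
    "k": -0.7, "A": -0.25, "eta": 1.0, "tau": -0.5,
}
DEFAULT_GROUP_SDS = {
    "alpha": 0.5, "bias": 0.5, "phi": 0.4, "rho": 0.5, "C": 0.6,
    "k": 0.3, "A": 0.3, "eta": 0.3, "tau": 0.3,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort."""

    n_subjects: int = 20
    group_means: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_MEANS))
    group_sds: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SDS))
    beta_slope_true: float = 0.0
    design: tk.DesignSpec = field(default_factory=tk.DesignSpec)
    eeg: EEGConfig = field(default_factory=EEGConfig)
    drift_sd: float = 1.0
    eta_min: float = 0.01
    seed: int = 0


@dataclass
class EpochSet:
    """Epoched EEG: trials x channels x samples, with its time base."""

    data: np.ndarray
    times: np.ndarray
    channels: list
    sampling_rate: float
    lock: str
    trial_index: np.ndarray

    def __post_init__(self) -> None:
        if self.lock not in ("stimulus", "response"):
            raise ValueError("lock must be 'stimulus' or 'response'")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis mismatch")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis mismatch")


def sample_subject_params(config: GeneratorConfig, rng_seed: int) -> pd.DataFrame:
    """Draw per-subject parameters from the generator's normal hierarchy.

    Returns a frame indexed by subject with both unconstrained columns
    (``x_<name>``) and model-scale columns, mapped through the same
    transforms the fitting module uses.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for subj in range(config.n_subjects):
        x = np.array(
            [
                rng.normal(config.group_means[n], _checked_sd(config.group_sds[n], n))
                for n in PARAM_NAMES
            ]
        )
        con = constrain(x)
        row = {"subject": subj}
        row.update({f"x_{n}": xi for n, xi in zip(PARAM_NAMES, x)})
        row.update(con)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


def _checked_sd(sd: float, name: str) -> float:
    if sd < 0:
        raise ValueError(f"group sd for {name} must be non-negative")
    return sd


class LBAResponder:
    """Task responder that chooses via the RLWM policy and an LBA race."""

    def __init__(
        self,
        agent_params: ag.AgentParams,
        lba_params: lb.LBAParams,
        set_size: int,
        rng: np.random.Generator,
        beta_slope: float = 0.0,
        eta_min: float = 0.01,
        stimulus_order: Optional[Sequence[str]] = None,
    ):
        self.agent_params = agent_params
        self.lba_params = lba_params
        self.rng = rng
        self.beta_slope = beta_slope
        self.eta_min = eta_min
        self.state = ag.init_state(set_size, agent_params, set_size)
        self._index = {s: i for i, s in enumerate(stimulus_order or [])}
        self.last_latents: dict = {}

    def _stim_index(self, stimulus) -> int:
        if stimulus not in self._index:
            self._index[stimulus] = len(self._index)
        return self._index[stimulus]

    def __call__(self, stimulus):
        si = self._stim_index(stimulus)
        bundle = ag.policy(self.state, si, self.agent_params)
        slope_z = float(self.rng.standard_normal())
        eta_t = max(self.lba_params.eta + self.beta_slope * slope_z, self.eta_min)
        drifts = lb.drift_rates(bundle.pi, bundle.h_prior, eta_t)
        choice, rt = lb.simulate_race(drifts, self.lba_params, self.rng)
        # the task's 7 s response window; the likelihood ignores this
        # censoring (it affects <1% of trials at default parameters)
        rt = min(rt, 7.0)
        self.last_latents = {
            "pi_chosen": float(bundle.pi[choice - 1]),
            "h_prior": bundle.h_prior,
            "eta_t": eta_t,
            "cpp_slope_z": slope_z,
            "drift_chosen": float(drifts.v[choice - 1]),
            "q_rl_chosen": float(self.state.q_rl[si, choice - 1]),
            "q_wm_chosen": float(self.state.q_wm[si, choice - 1]),
            "w_wm": self.state.w_wm,
        }
        return choice, rt

    def observe(self, stimulus, action, reward):
        si = self._stim_index(stimulus)
        ag.update_state(self.state, si, int(action), int(reward), self.agent_params)


LATENT_COLUMNS = (
    "pi_chosen", "h_prior", "eta_t", "cpp_slope_z", "drift_chosen",
    "q_rl_chosen", "q_wm_chosen", "w_wm",
)


def simulate_behavior(
    config: GeneratorConfig,
    params: Optional[pd.DataFrame] = None,
    rng_seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate the full cohort's behavior through task + agent + race.

    Returns one row per trial with the task columns (including delay and
    the EEG inclusion flag) plus latent columns recording the generating
    policy, entropy, drift, Q values and the trial's standardized neural
    slope (``cpp_slope_z``; it informs ``eta_t`` only when
    ``config.beta_slope_true`` is nonzero, but is always recorded).
    """
    seed = config.seed if rng_seed is None else rng_seed
    if params is None:
        params = sample_subject_params(config, derive_seed(seed, "params"))
    frames = []
    for subj, prow in params.iterrows():
        a_par = ag.AgentParams(
            alpha_rl=prow["alpha"], bias=prow["bias"], phi=prow["phi"],
            rho=prow["rho"], capacity=prow["C"],
        )
        l_par = lb.LBAParams(
            start_range=prow["A"], rel_threshold=prow["k"], ndt=prow["tau"],
            eta=prow["eta"], drift_sd=config.drift_sd,
        )
        blocks = tk.make_blocks(config.design, derive_seed(seed, "design", subj), subject=subj)
        rng = np.random.default_rng(derive_seed(seed, "behavior", subj))
        trials: list = []
        latents: list = []
        for spec in blocks:
            responder = LBAResponder(
                a_par, l_par, spec.set_size, rng,
                beta_slope=config.beta_slope_true, eta_min=config.eta_min,
                stimulus_order=spec.stimulus_ids,
            )
            recs = _run_block_with_latents(spec, responder, seed, subj, latents)
            trials.extend(recs)
        trials = tk.compute_delay(trials)
        eeg_keys = {
            (t.block, t.stimulus, t.presentation_index)
            for t in tk.eeg_trial_filter(trials)
        }
        rows = []
        for tr, lat in zip(trials, latents):
            row = {
                "subject": tr.subject, "block": tr.block, "set_size": tr.set_size,
                "stimulus": tr.stimulus, "presentation_index": tr.presentation_index,
                "action": tr.action, "correct_action": tr.correct_action,
                "reward": tr.reward, "rt": tr.rt, "delay": tr.delay,
                "included_in_eeg": (tr.block, tr.stimulus, tr.presentation_index) in eeg_keys,
            }
            row.update(lat)
            rows.append(row)
        frames.append(pd.DataFrame(rows))
    out = pd.concat(frames, ignore_index=True)
    out["delay"] = out["delay"].astype("Float64")
    return out


def _run_block_with_latents(spec, responder, seed, subj, latents):
    """run_block wrapper that snapshots the responder's latents per trial."""
    collected = []

    class _Tap:
        def __call__(self, stimulus):
            out = responder(stimulus)
            collected.append(dict(responder.last_latents))
            return out

        def observe(self, stimulus, action, reward):
            responder.observe(stimulus, action, reward)

    recs = tk.run_block(spec, _Tap(), seed, subject=subj)
    latents.extend(collected)
    return recs


def _z(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def simulate_eeg(
    trials: pd.DataFrame,
    config: GeneratorConfig,
    rng_seed: Optional[int] = None,
) -> tuple[EpochSet, EpochSet]:
    """Generate stimulus- and response-locked epochs for the analysis set.

    Only trials flagged ``included_in_eeg`` receive epochs.  Per trial a
    continuous signal is synthesized from stimulus onset context
    (epoch_start_ms) to 700 ms past the response and both epochs are cut
    from it, so stimulus components bleed into response-locked windows
    exactly as they would in recorded data.
    """
    for col in ("drift_chosen", "q_rl_chosen", "included_in_eeg"):
        if col not in trials.columns:
            raise ValueError(f"missing latent column {col!r}")
    eeg = config.eeg
    seed = config.seed if rng_seed is None else rng_seed
    labels = list(eeg.channels)
    pos = channel_positions(labels)
    times = eeg.times_ms()
    step = 1000.0 / eeg.sampling_rate
    n_samp = eeg.epoch_samples

    def spatial(center: str) -> np.ndarray:
        # the center need not be a recorded channel (reduced montages)
        c = channel_positions([center])[0]
        d2 = ((pos - c) ** 2).sum(axis=1)
        return np.exp(-d2 / (2.0 * eeg.spatial_sigma**2))

    w_cpp = spatial(eeg.cpp_center)
    w_front = spatial(eeg.frontal_center)
    w_par = spatial(eeg.parietal_center)

    inc = trials[trials["included_in_eeg"].astype(bool)]
    stim_data = np.empty((len(inc), len(labels), n_samp), dtype=np.float32)
    resp_data = np.empty_like(stim_data)
    trial_index = inc.index.to_numpy()

    innov_scale = eeg.noise_sd * np.sqrt(max(1.0 - eeg.ar_coef**2, 1e-12))
    row_pos = 0
    for subj, sub in inc.groupby("subject", sort=True):
        rng = np.random.default_rng(derive_seed(seed, "eeg", int(subj)))
        z_drift = _z(sub["drift_chosen"].to_numpy())
        z_q = _z(sub["q_rl_chosen"].to_numpy())
        delay = sub["delay"].to_numpy(dtype=float)
        z_delay = np.zeros(len(sub))
        have = np.isfinite(delay)
        if have.sum() >= 2:
            z_delay[have] = _z(delay[have])
        z_ss = _z(sub["set_size"].to_numpy())
        rts_ms = sub["rt"].to_numpy(dtype=float) * 1000.0

        for i in range(len(sub)):
            rt_ms = rts_ms[i]
            resp_offset = int(round(rt_ms * eeg.sampling_rate / 1000.0))
            n_grid = resp_offset + n_samp + 1
            grid = eeg.epoch_start_ms + step * np.arange(n_grid)

            env = np.zeros(n_grid)
            # stimulus-locked components (negative frontal 300 ms, positive
            # parietal 540 ms)
            amp300 = -(eeg.q_effect * z_q[i] + eeg.delay_effect * z_delay[i])
            amp540 = eeg.setsize_effect * z_ss[i]
            g300 = amp300 * np.exp(
                -0.5 * ((grid - eeg.stim_component_ms[0]) / eeg.stim_component_sd_ms[0]) ** 2
            )
            g540 = amp540 * np.exp(
                -0.5 * ((grid - eeg.stim_component_ms[1]) / eeg.stim_component_sd_ms[1]) ** 2
            )
            # CPP: linear ramp toward the response at a drift-dependent rate
            rate = max(eeg.cpp_base_rate + eeg.cpp_gain * z_drift[i], eeg.cpp_min_rate)
            buildup = min(rt_ms, eeg.cpp_max_buildup_ms)
            onset = rt_ms - buildup
            peak = rate * buildup
            ramp = np.zeros(n_grid)
            rising = (grid >= onset) & (grid <= rt_ms)
            ramp[rising] = rate * (grid[rising] - onset)
            falling = (grid > rt_ms) & (grid <= rt_ms + eeg.cpp_fall_ms)
            ramp[falling] = peak * (1.0 - (grid[falling] - rt_ms) / eeg.cpp_fall_ms)

            signal = (
                w_front[:, None] * g300[None, :]
                + w_par[:, None] * g540[None, :]
                + w_cpp[:, None] * ramp[None, :]
            )
            if eeg.noise_sd > 0:
                innov = rng.normal(0.0, innov_scale, size=(len(labels), n_grid))
                noise = lfilter([1.0], [1.0, -eeg.ar_coef], innov, axis=1)
                signal = signal + noise
            stim_data[row_pos] = signal[:, :n_samp]
            resp_data[row_pos] = signal[:, resp_offset : resp_offset + n_samp]
            row_pos += 1

    stim = EpochSet(stim_data, times, labels, eeg.sampling_rate, "stimulus", trial_index)
    resp = EpochSet(resp_data, times, labels, eeg.sampling_rate, "response", trial_index)
    return stim, resp
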