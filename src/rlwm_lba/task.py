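"""Stimulus-response association task with adaptive stopping.

The task presents, block by block, a small set of stimuli (set size 2-5)
that must each be mapped onto one of three actions.  Feedback is
deterministic: a response is rewarded iff it matches the assigned correct
action.  Within a block each stimulus is presented repeatedly, in
pseudo-random order, until it has been answered correctly on at least 4 of
its last 5 presentations, with a floor of 9 and a ceiling of 15
presentations per stimulus.

This module also computes derived trial covariates (delay since the last
correct performance of a stimulus-response association, presentation
index), the trial filter used for EEG analyses (correct, non-first
presentations), and dataset-level QC arithmetic.
"""

from __future__ import annotations

import random
from collections import deque

from ._seeding import derive_seed
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

__all__ = [
    "Criterion",
    "BlockSpec",
    "DesignSpec",
    "TrialRecord",
    "QCReport",
    "DEFAULT_SET_SIZE_SEQUENCE",
    "make_blocks",
    "run_block",
    "compute_delay",
    "eeg_trial_filter",
    "qc_report",
]

#: Default block composition: 11 blocks covering set sizes 2-5.
DEFAULT_SET_SIZE_SEQUENCE = (2, 2, 3, 3, 3, 4, 4, 4, 5, 5, 4)

N_ACTIONS = 3


@dataclass(frozen=True)
class Criterion:
    """Learning criterion: ``hits`` correct out of the last ``window``."""

    hits: int = 4
    window: int = 5


@dataclass
class BlockSpec:
    """One task block: a stimulus set and its stimulus-to-action map.

    The map need not be injective -- several stimuli may share the same
    correct action, and participants are told the associations are
    independent.
    """

    block_index: int
    set_size: int
    stimulus_ids: Sequence[str]
    correct_action: Mapping[str, int]
    min_presentations: int = 9
    max_presentations: int = 15
    criterion: Criterion = field(default_factory=Criterion)

    def __post_init__(self) -> None:
        if not 2 <= self.set_size <= 5:
            raise ValueError(f"set_size must be in 2..5, got {self.set_size}")
        if len(self.stimulus_ids) != self.set_size:
            raise ValueError("stimulus_ids length must equal set_size")
        if len(self.stimulus_ids) == 0:
            raise ValueError("empty stimulus set")
        for s in self.stimulus_ids:
            a = self.correct_action.get(s)
            if a not in (1, 2, 3):
                raise ValueError(f"correct_action missing/invalid for stimulus {s!r}")
        if self.min_presentations > self.max_presentations:
            raise ValueError("min_presentations > max_presentations")


@dataclass
class DesignSpec:
    """Whole-session design: number of blocks and their set sizes.

    Timing fields document the task's nominal event durations (seconds);
    they are carried for completeness and used by the EEG generator to
    bound epoch windows, not to emulate a presentation clock.
    """

    n_blocks: int = 11
    set_size_sequence: Sequence[int] = DEFAULT_SET_SIZE_SEQUENCE
    n_actions: int = N_ACTIONS
    fixation_s: float = 0.5
    max_stimulus_s: float = 7.0
    feedback_s: float = 0.75
    min_presentations: int = 9
    max_presentations: int = 15
    criterion: Criterion = field(default_factory=Criterion)

    def __post_init__(self) -> None:
        if len(self.set_size_sequence) != self.n_blocks:
            raise ValueError("set_size_sequence length must equal n_blocks")
        for n_s in self.set_size_sequence:
            if not 2 <= n_s <= 5:
                raise ValueError("every set size must be in 2..5")


@dataclass
class TrialRecord:
    """One trial of the task, with derived covariates.

    ``delay`` is the number of trials (of any stimulus) since the most
    recent correct response to this same stimulus; ``None`` when no such
    trial exists (first presentations, or no prior correct).
    """

    subject: int
    block: int
    set_size: int
    stimulus: str
    presentation_index: int
    action: int
    correct_action: int
    reward: int
    rt: float
    delay: Optional[int] = None
    included_in_eeg: bool = False


@dataclass(frozen=True)
class QCReport:
    n_total: int
    n_excluded: int
    n_retained: int
    exclusion_rate_pct: float
    retained_fraction: float


def make_blocks(
    design: DesignSpec,
    rng_seed: int,
    subject: int = 0,
) -> list[BlockSpec]:
    """Instantiate the blocks of a design with random action assignments.

    Stimulus ids are generated as ``b{block}_s{i}``; each stimulus draws
    its correct action uniformly and independently from {1, 2, 3}, so
    several stimuli in a block may share an action.
    """
    rng = random.Random(derive_seed(rng_seed, "blocks", subject))
    blocks = []
    for b, n_s in enumerate(design.set_size_sequence):
        stimuli = [f"b{b}_s{i}" for i in range(n_s)]
        mapping = {s: rng.randint(1, design.n_actions) for s in stimuli}
        blocks.append(
            BlockSpec(
                block_index=b,
                set_size=n_s,
                stimulus_ids=stimuli,
                correct_action=mapping,
                min_presentations=design.min_presentations,
                max_presentations=design.max_presentations,
                criterion=design.criterion,
            )
        )
    return blocks


def run_block(
    spec: BlockSpec,
    responder: Callable,
    rng_seed: int,
    subject: int = 0,
) -> list[TrialRecord]:
    """Administer one block with the adaptive stopping rule.

    ``responder(stimulus)`` must return either an action in {1, 2, 3} or
    a ``(action, rt_seconds)`` pair.  If the responder exposes an
    ``observe(stimulus, action, reward)`` method it is called after each
    trial so stateful (learning) responders can update.

    A stimulus is retired at the first presentation count >= ``min_presentations``
    at which at least ``criterion.hits`` of its last ``criterion.window``
    presentations were answered correctly, or unconditionally at
    ``max_presentations``.  Presentation order is pseudo-randomized with no
    immediate repetition of the same stimulus while at least two stimuli
    remain active.
    """
    rng = random.Random(derive_seed(rng_seed, "block", subject, spec.block_index))
    active = list(spec.stimulus_ids)
    counts = {s: 0 for s in active}
    recent: dict[str, deque] = {s: deque(maxlen=spec.criterion.window) for s in active}
    trials: list[TrialRecord] = []
    last: Optional[str] = None

    while active:
        if len(active) >= 2:
            candidates = [s for s in active if s != last]
        else:
            candidates = active
        stim = rng.choice(candidates)
        counts[stim] += 1

        out = responder(stim)
        if isinstance(out, tuple):
            action, rt = out
        else:
            action, rt = out, 1.0  # nominal RT for RT-less responders
        action = int(action)
        if action not in (1, 2, 3):
            raise ValueError(f"responder returned invalid action {action!r}")
        correct = spec.correct_action[stim]
        reward = int(action == correct)
        trials.append(
            TrialRecord(
                subject=subject,
                block=spec.block_index,
                set_size=spec.set_size,
                stimulus=stim,
                presentation_index=counts[stim],
                action=action,
                correct_action=correct,
                reward=reward,
                rt=float(rt),
            )
        )
        observe = getattr(responder, "observe", None)
        if observe is not None:
            observe(stim, action, reward)

        recent[stim].append(reward)
        met = (
            counts[stim] >= spec.min_presentations
            and sum(recent[stim]) >= spec.criterion.hits
        )
        if met or counts[stim] >= spec.max_presentations:
            active.remove(stim)
        last = stim
    return trials


def compute_delay(trials: Sequence[TrialRecord]) -> list[TrialRecord]:
    """Fill the ``delay`` covariate for a presentation-ordered trial list.

    Delay counts the number of intervening trials (of any stimulus) since
    the most recent trial on which this same stimulus was answered
    correctly; it is left missing (``None``) when no prior correct trial
    exists.  Delays are computed within (subject, block) and the input
    must be in presentation order within each block.
    """
    out: list[TrialRecord] = []
    last_correct: dict[tuple, int] = {}
    position: dict[tuple, int] = {}
    seen_blocks: set[tuple] = set()
    prev_key = None
    for tr in trials:
        key = (tr.subject, tr.block)
        if key != prev_key:
            if key in seen_blocks:
                raise ValueError("trials are not grouped by (subject, block)")
            seen_blocks.add(key)
            prev_key = key
        i = position.get(key, 0)
        position[key] = i + 1
        skey = (tr.subject, tr.block, tr.stimulus)
        delay = i - last_correct[skey] if skey in last_correct else None
        out.append(replace(tr, delay=delay))
        if tr.reward == 1:
            last_correct[skey] = i
    return out


def eeg_trial_filter(trials: Iterable[TrialRecord]) -> list[TrialRecord]:
    """Select the trials that enter the EEG analyses.

    Keeps correct trials that are not the first presentation of their
    stimulus within a block; the returned records have
    ``included_in_eeg=True``.  (Error trials and first presentations are
    excluded by design.)
    """
    kept = []
    for tr in trials:
        if tr.reward == 1 and tr.presentation_index >= 2:
            kept.append(replace(tr, included_in_eeg=True))
    return kept


def qc_report(n_total: int, n_excluded: int) -> QCReport:
    """Dataset-level exclusion arithmetic (exact integer/decimal)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_excluded <= n_total:
        raise ValueError("n_excluded must be in [0, n_total]")
    n_retained = n_total - n_excluded
    return QCReport(
        n_total=n_total,
        n_excluded=n_excluded,
        n_retained=n_retained,
        exclusion_rate_pct=round(100.0 * n_excluded / n_total, 1),
        retained_fraction=n_retained / n_total,
    )
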