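"""Single-trial mass-univariate ERP statistics and CPP-slope analyses.

Workflow: per subject, every electrode x time-point voltage series is
regressed on z-scored trial covariates (set size, delay and the chosen
option's Q_RL value for stimulus-locked epochs; drift rate for
response-locked epochs) by ordinary least squares.  Subject beta maps
are aggregated with 20% trimmed means and tested against zero with
Yuen's one-sample trimmed-mean t, Bonferroni-corrected across
electrodes, time points and estimated parameters.  Corrected ERPs are
reconstructed from the betas; the CPP slope is read from CPz at fixed
pre-response landmarks; and slopes are regressed on within-condition
Q-value quartiles to compare the RL and WM contributions across load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import t as t_dist
from scipy.stats import trim_mean

from .synth import EpochSet

__all__ = [
    "RegressorTable",
    "BetaMaps",
    "GroupStatMap",
    "build_regressors",
    "single_trial_glm",
    "group_inference",
    "corrected_erp",
    "cpp_slope",
    "quartile_assign",
    "slope_regression",
    "yuen_onesample",
]

STIMULUS_PREDICTORS = ("set_size", "delay", "q_rl")
RESPONSE_PREDICTORS = ("drift",)

_SOURCE_COLUMNS = {
    "set_size": "set_size",
    "delay": "delay",
    "q_rl": "q_rl_chosen",
    "drift": "drift_chosen",
}


@dataclass
class RegressorTable:
    """Z-scored single-trial predictors aligned with an EpochSet."""

    frame: pd.DataFrame  # index aligns with the trial table rows
    lock: str
    subjects: np.ndarray
    warnings: list = field(default_factory=list)

    @property
    def predictors(self) -> list:
        return [c for c in self.frame.columns]


@dataclass
class BetaMaps:
    """One subject's GLM betas: (1 + predictors) x channels x samples."""

    subject: int
    betas: np.ndarray
    predictor_names: list  # without the leading intercept
    channels: list
    times: np.ndarray
    z_context: dict  # predictor -> (mean, sd) on the raw scale


@dataclass
class GroupStatMap:
    """Group-level trimmed-mean statistics per predictor map."""

    predictor_names: list  # including "intercept"
    trimmed_mean: np.ndarray  # P x channels x samples
    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    alpha: float
    n_electrodes: int
    n_timepoints: int
    n_predictors: int
    threshold: float
    channels: list
    times: np.ndarray


def _zscore(v: np.ndarray) -> tuple[np.ndarray, float, float]:
    m = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(v, dtype=float), m, sd
    return (v - m) / sd, m, sd


def build_regressors(trials: pd.DataFrame, lock: str) -> RegressorTable:
    """Z-score the lock's trial predictors within subject.

    For the stimulus lock, trials with missing delay are dropped (the
    covariate is undefined there); a zero-variance predictor within a
    subject is flagged and its column zeroed (dropped from inference)
    with a warning.
    """
    if lock not in ("stimulus", "response"):
        raise ValueError("lock must be 'stimulus' or 'response'")
    names = STIMULUS_PREDICTORS if lock == "stimulus" else RESPONSE_PREDICTORS
    df = trials[trials["included_in_eeg"].astype(bool)]
    if lock == "stimulus":
        df = df[pd.notna(df["delay"])]
    cols = {n: [] for n in names}
    idx = []
    subjects = []
    warn_list = []
    for subj, sub in df.groupby("subject", sort=True):
        idx.extend(sub.index.tolist())
        subjects.extend([subj] * len(sub))
        for n in names:
            raw = sub[_SOURCE_COLUMNS[n]].to_numpy(dtype=float)
            z, _, sd = _zscore(raw)
            if sd == 0:
                msg = f"subject {subj}: predictor {n!r} has zero variance; dropped"
                warn_list.append(msg)
                warnings.warn(msg)
            cols[n].append(z)
    frame = pd.DataFrame(
        {f"z_{n}": np.concatenate(cols[n]) if cols[n] else np.array([]) for n in names},
        index=pd.Index(idx),
    )
    return RegressorTable(
        frame=frame, lock=lock, subjects=np.asarray(subjects), warnings=warn_list
    )


def single_trial_glm(epochs: EpochSet, regressors: RegressorTable) -> list[BetaMaps]:
    """Per-subject OLS of every channel x sample on the z-scored predictors.

    The epochs' ``trial_index`` must cover the regressor rows; epochs
    without a regressor row (e.g. missing-delay trials under the stimulus
    lock) are ignored.
    """
    pos = {t: i for i, t in enumerate(epochs.trial_index)}
    missing = [t for t in regressors.frame.index if t not in pos]
    if missing:
        raise ValueError(f"epochs lack trials {missing[:5]} present in regressors")
    out = []
    n_ch, n_samp = epochs.data.shape[1], epochs.data.shape[2]
    for subj in np.unique(regressors.subjects):
        sel = regressors.subjects == subj
        rows = regressors.frame.index[sel]
        X = np.column_stack(
            [np.ones(sel.sum())] + [regressors.frame.loc[rows, c].to_numpy() for c in regressors.frame.columns]
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            keep = ~np.all(X[:, 1:] == 0.0, axis=0)
            if np.linalg.matrix_rank(X[:, np.r_[True, keep]]) < 1 + keep.sum():
                raise ValueError(f"rank-deficient design for subject {subj}")
        Y = epochs.data[[pos[t] for t in rows]].reshape(len(rows), -1).astype(float)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        out.append(
            BetaMaps(
                subject=int(subj),
                betas=beta.reshape(X.shape[1], n_ch, n_samp),
                predictor_names=list(regressors.frame.columns),
                channels=list(epochs.channels),
                times=np.asarray(epochs.times),
                z_context={},
            )
        )
    return out


def yuen_onesample(x: np.ndarray, trim: float = 0.2) -> tuple[float, float, int]:
    """Yuen's one-sample trimmed-mean t test against zero.

    Returns (t, p, df) with a 20% trim per tail by default: the test
    statistic is the trimmed mean over its winsorized standard error
    ``s_w / ((1 - 2*trim) * sqrt(n))`` with ``df = h - 1`` where
    ``h = n - 2*floor(trim*n)`` is the number of untrimmed values.
    A zero winsorized variance is treated as maximal significance when
    the trimmed mean is nonzero.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    g = int(np.floor(trim * n))
    h = n - 2 * g
    if h < 2:
        raise ValueError("insufficient subjects after trimming (h < 2)")
    tm = x[g : n - g].mean()
    xw = np.clip(x, x[g], x[n - g - 1])
    sw2 = xw.var(ddof=1)
    df = h - 1
    # guard against round-off from the mean subtraction of equal values
    if sw2 <= (1e-12 * (np.abs(x).max() + 1.0)) ** 2:
        if tm == 0.0:
            return 0.0, 1.0, df
        return float(np.sign(tm) * np.inf), 0.0, df
    se = np.sqrt(sw2) / ((1.0 - 2.0 * trim) * np.sqrt(n))
    t = tm / se
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(p), df


def group_inference(
    betas: Sequence[BetaMaps], alpha: float = 0.05, trim: float = 0.2
) -> GroupStatMap:
    """Trimmed-mean group statistics with Bonferroni control.

    The correction divides ``alpha`` by electrodes x time points x
    estimated parameters (the intercept counts as an estimated
    parameter, and is tested like the rest).
    """
    if len(betas) < 5:
        raise ValueError("need at least 5 subjects for group inference")
    names = ["intercept"] + list(betas[0].predictor_names)
    stack = np.stack([b.betas for b in betas])  # subjects x P x ch x samp
    n_subj, P, n_ch, n_samp = stack.shape
    threshold = alpha / (n_ch * n_samp * P)

    tmean = trim_mean(stack, trim, axis=0)
    flat = stack.reshape(n_subj, -1)
    tvals = np.empty(flat.shape[1])
    pvals = np.empty(flat.shape[1])
    srt = np.sort(flat, axis=0)
    g = int(np.floor(trim * n_subj))
    h = n_subj - 2 * g
    if h < 2:
        raise ValueError("insufficient subjects after trimming (h < 2)")
    tm = srt[g : n_subj - g].mean(axis=0)
    xw = np.clip(srt, srt[g][None, :], srt[n_subj - g - 1][None, :])
    sw2 = xw.var(axis=0, ddof=1)
    sw2 = np.where(sw2 <= (1e-12 * (np.abs(flat).max() + 1.0)) ** 2, 0.0, sw2)
    df = h - 1
    se = np.sqrt(sw2) / ((1.0 - 2.0 * trim) * np.sqrt(n_subj))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, tm / np.where(se > 0, se, 1.0), np.sign(tm) * np.inf)
    pvals = 2.0 * t_dist.sf(np.abs(tvals), df)
    pvals = np.where(np.isinf(tvals), 0.0, pvals)
    pvals = np.where((se == 0) & (tm == 0), 1.0, pvals)
    tvals = np.where((se == 0) & (tm == 0), 0.0, tvals)
    shape = (P, n_ch, n_samp)
    return GroupStatMap(
        predictor_names=names,
        trimmed_mean=tmean,
        t=tvals.reshape(shape),
        p=pvals.reshape(shape),
        mask=(pvals < threshold).reshape(shape),
        alpha=alpha,
        n_electrodes=n_ch,
        n_timepoints=n_samp,
        n_predictors=P,
        threshold=threshold,
        channels=list(betas[0].channels),
        times=np.asarray(betas[0].times),
    )


def corrected_erp(
    betas: BetaMaps,
    predictor: str,
    levels: Sequence[float],
    z_context: tuple,
) -> dict:
    """Reconstruct per-level ERPs from the GLM betas.

    ``waveform(level) = intercept + beta_predictor * z(level)`` with all
    other predictors held at their mean (z = 0).  ``z_context`` is the
    (mean, sd) pair of the predictor's raw values used at fit time.
    """
    if predictor not in betas.predictor_names:
        raise ValueError(f"predictor {predictor!r} not in model")
    mean, sd = z_context
    if sd <= 0:
        raise ValueError("z_context sd must be positive")
    j = 1 + betas.predictor_names.index(predictor)
    out = {}
    for level in levels:
        z = (level - mean) / sd
        if abs(z) > 5:
            warnings.warn(f"level {level} is {z:.1f} sd from the fitted mean")
        out[level] = betas.betas[0] + betas.betas[j] * z
    return out


def cpp_slope(
    epochs: EpochSet,
    channel: str = "CPz",
    landmarks_ms: tuple = (-200.0, -50.0),
) -> np.ndarray:
    """Per-trial CPP slope (uV/ms) from two pre-response landmarks.

    Amplitudes are read at the nearest sample to each landmark on the
    given channel of response-locked epochs; the slope is their
    difference divided by the actual time separation of the chosen
    samples (nominally 150 ms).
    """
    if epochs.lock != "response":
        raise ValueError("cpp_slope expects response-locked epochs")
    if channel not in epochs.channels:
        raise ValueError(f"channel {channel!r} not present")
    times = np.asarray(epochs.times, dtype=float)
    if landmarks_ms[0] < times[0] or landmarks_ms[1] > times[-1]:
        raise ValueError("epoch window does not cover the slope landmarks")
    ci = list(epochs.channels).index(channel)
    i0 = int(np.argmin(np.abs(times - landmarks_ms[0])))
    i1 = int(np.argmin(np.abs(times - landmarks_ms[1])))
    dt = times[i1] - times[i0]
    if dt <= 0:
        raise ValueError("degenerate landmark separation")
    return (epochs.data[:, ci, i1] - epochs.data[:, ci, i0]).astype(float) / dt


def quartile_assign(
    values: pd.Series,
    grouping: pd.DataFrame,
) -> pd.Series:
    """Rank-based quartiles (1-4) within each group (subject x set size).

    Ties are broken by stable trial order; groups with fewer than 4
    trials are flagged with a warning and assigned from the same rule.
    """
    if len(values) == 0:
        raise ValueError("empty input")
    out = pd.Series(index=values.index, dtype=int)
    keys = [grouping[c] for c in grouping.columns]
    for key, idx in values.groupby(keys).groups.items():
        n = len(idx)
        if n == 0:
            raise ValueError(f"empty group {key}")
        if n < 4:
            warnings.warn(f"group {key} has only {n} trials for quartiles")
        order = np.argsort(values.loc[idx].to_numpy(), kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        out.loc[idx] = np.ceil((ranks + 1) * 4 / n).astype(int)
    return out


def slope_regression(slopes: pd.DataFrame) -> dict:
    """CPP slope ~ Q-RL quartile * set size + Q-WM quartile * set size.

    Expects columns ``cpp_slope``, ``q_rl_quartile``, ``q_wm_quartile``,
    ``set_size`` and ``subject``.  Quartiles enter numerically (1-4), set
    size categorically, with per-subject intercepts; inference is OLS
    with cluster-robust (by subject) standard errors.  Returns the fitted
    results plus per-set-size simple slopes for both Q variables with
    95% intervals.
    """
    req = {"cpp_slope", "q_rl_quartile", "q_wm_quartile", "set_size", "subject"}
    if not req <= set(slopes.columns):
        raise ValueError(f"missing columns {sorted(req - set(slopes.columns))}")
    df = slopes.reset_index(drop=True)
    set_sizes = np.sort(df["set_size"].unique())
    ref = set_sizes[0]
    subjects = np.sort(df["subject"].unique())

    cols = {}
    # per-subject intercepts (cell-mean coding over subjects)
    for s in subjects:
        cols[f"subj_{s}"] = (df["subject"] == s).astype(float)
    qrl = df["q_rl_quartile"].astype(float)
    qwm = df["q_wm_quartile"].astype(float)
    cols["q_rl"] = qrl
    cols["q_wm"] = qwm
    for ss in set_sizes[1:]:
        d = (df["set_size"] == ss).astype(float)
        cols[f"ss_{ss}"] = d
        cols[f"q_rl:ss_{ss}"] = qrl * d
        cols[f"q_wm:ss_{ss}"] = qwm * d
    X = pd.DataFrame(cols)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design")
    model = sm.OLS(df["cpp_slope"].to_numpy(), X.to_numpy())
    res = model.fit(cov_type="cluster", cov_kwds={"groups": df["subject"].to_numpy()})
    names = list(X.columns)

    def simple_slope(base: str, ss) -> dict:
        vec = np.zeros(len(names))
        vec[names.index(base)] = 1.0
        inter = f"{base}:ss_{ss}"
        if inter in names:
            vec[names.index(inter)] = 1.0
        est = float(vec @ res.params)
        se = float(np.sqrt(vec @ res.cov_params() @ vec))
        return {
            "set_size": int(ss), "coef": est, "se": se,
            "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
        }

    table = []
    for ss in set_sizes:
        for base, label in (("q_rl", "q_rl"), ("q_wm", "q_wm")):
            row = simple_slope(base, ss)
            row["module"] = label
            table.append(row)
    return {
        "results": res,
        "design_columns": names,
        "simple_slopes": pd.DataFrame(table)[
            ["module", "set_size", "coef", "se", "ci_low", "ci_high"]
        ],
    }
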