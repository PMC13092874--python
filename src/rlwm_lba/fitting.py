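"""Hierarchical fitting of the RLWM-LBA model and ELPD model comparison.

The model is hierarchical: each subject's nine parameters live on an
unconstrained scale (see :mod:`rlwm_lba.transforms`) with normal group
priors; group means carry weakly informative normal priors and group
standard deviations an Exponential(0.1) prior.  The neurally informed
variant adds a coefficient ``beta_slope`` linking the per-trial
standardized CPP slope to the drift scaling: ``eta_t = eta +
z(slope) * beta_slope`` (floored at ``eta_min``), with a N(0, 1) prior.
The baseline model is the same likelihood with ``beta_slope = 0``.

The desk-scale estimator is empirical-Bayes flavored: per-subject MAP
under the current group prior, alternated with conjugate updates of the
group means and moment updates of the group sds, followed by a Laplace
(Gaussian) approximation at each subject's mode to obtain posterior
draws and pointwise log-likelihood draws for PSIS-LOO.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

from ._kernels import subject_pointwise_loglik as _kernel_loglik
from ._seeding import derive_seed
from .agent import EPS_H
from .transforms import PARAM_NAMES, constrain, phi_approx, transform_params, unconstrain

__all__ = [
    "PriorSpec",
    "FitResult",
    "ModelComparison",
    "subject_loglik",
    "fit",
    "fit_neural",
    "compare_elpd",
    "phi_approx",
    "transform_params",
]

ETA_MIN = 0.01
_SD_FLOOR = 0.25
_SD_CAP = 1.5
_BETA_SD_FLOOR = 0.05


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the hierarchy (unconstrained scale).

    ``group_mean_loc`` follows the reported prior centers for the group
    means; all group-mean priors have scale 3, group sds are
    Exponential(0.1), and subject-level deviations are standard normal.
    """

    #: The capacity prior is stated on the natural (2-5) scale with center
    #: 3; under the C = 2 + 3*Phi(x) transform that center maps to
    #: Phi^{-1}(1/3) ~ -0.43 on the unconstrained scale.
    group_mean_loc: dict = field(
        default_factory=lambda: {
            "alpha": -3.0, "bias": -1.0, "phi": -1.0, "rho": 2.0, "C": -0.43,
            "k": 1.0, "A": 2.0, "eta": 3.0, "tau": -1.0,
        }
    )
    group_mean_scale: float = 3.0
    group_sd_rate: float = 0.1
    subject_dev_sd: float = 1.0
    beta_slope_loc: float = 0.0
    beta_slope_scale: float = 1.0


@dataclass
class _SubjectData:
    """Per-subject trial arrays in kernel layout."""

    subject: int
    block_start: np.ndarray
    stim: np.ndarray
    set_size: np.ndarray
    action: np.ndarray
    reward: np.ndarray
    rt: np.ndarray
    slope_z: np.ndarray
    index: np.ndarray  # original row labels, for alignment

    @property
    def n_trials(self) -> int:
        return self.block_start.shape[0]


def _encode_subject(df: pd.DataFrame, slope_z: np.ndarray) -> _SubjectData:
    block = df["block"].to_numpy()
    block_start = np.zeros(len(df), dtype=np.int8)
    stim = np.empty(len(df), dtype=np.int64)
    mapping: dict = {}
    prev = None
    for i, (b, s) in enumerate(zip(block, df["stimulus"].to_numpy())):
        if b != prev:
            mapping = {}
            block_start[i] = 1
            prev = b
        if s not in mapping:
            mapping[s] = len(mapping)
        stim[i] = mapping[s]
    return _SubjectData(
        subject=int(df["subject"].iloc[0]),
        block_start=block_start,
        stim=stim,
        set_size=df["set_size"].to_numpy(dtype=np.int64),
        action=df["action"].to_numpy(dtype=np.int64) - 1,
        reward=df["reward"].to_numpy(dtype=np.float64),
        rt=df["rt"].to_numpy(dtype=np.float64),
        slope_z=slope_z,
        index=df.index.to_numpy(),
    )


def _standardize_slopes(raw: np.ndarray) -> np.ndarray:
    """Within-subject z-scoring; missing slopes contribute 0 (i.e. eta)."""
    z = np.zeros(len(raw))
    ok = np.isfinite(raw)
    if ok.sum() >= 2 and np.std(raw[ok], ddof=1) > 0:
        z[ok] = (raw[ok] - raw[ok].mean()) / np.std(raw[ok], ddof=1)
    return z


def _prepare(trials: pd.DataFrame, cpp_slopes: Optional[pd.Series]) -> list[_SubjectData]:
    required = {"subject", "block", "set_size", "stimulus", "action", "reward", "rt"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    if cpp_slopes is not None:
        if not trials.index.isin(cpp_slopes.index).all():
            raise ValueError("cpp_slopes misaligned with trial table index")
        raw_all = cpp_slopes.reindex(trials.index).to_numpy(dtype=float)
    else:
        raw_all = np.full(len(trials), np.nan)
    data = []
    for subj, sub in trials.groupby("subject", sort=True):
        raw = raw_all[trials.index.get_indexer(sub.index)]
        data.append(_encode_subject(sub, _standardize_slopes(raw)))
    return data


def _pointwise(sd: _SubjectData, x: np.ndarray, beta_slope: float,
               beta_rl: float, beta_wm: float, drift_sd: float) -> np.ndarray:
    p = constrain(x)
    return _kernel_loglik(
        sd.block_start, sd.stim, sd.set_size, sd.action, sd.reward, sd.rt,
        sd.slope_z,
        p["alpha"], p["bias"], p["phi"], p["rho"], p["C"], p["k"], p["A"],
        p["eta"], p["tau"], beta_slope, beta_rl, beta_wm, drift_sd, EPS_H,
        ETA_MIN,
    )


def subject_loglik(
    trials: pd.DataFrame,
    params: dict,
    cpp_slopes: Optional[pd.Series] = None,
    beta_slope: float = 0.0,
    beta_rl: float = 10.0,
    beta_wm: float = 10.0,
    drift_sd: float = 1.0,
) -> np.ndarray:
    """Pointwise log-likelihood for one subject's trials.

    Replays the learning model forward (policy -> prior entropy -> drift
    rates with ``eta`` or ``eta_t`` -> LBA log-density -> value update ->
    WM decay).  ``params`` is a model-scale dict with keys
    :data:`~rlwm_lba.transforms.PARAM_NAMES`.  With ``beta_slope = 0``
    the result is bit-identical to the baseline model.
    """
    if trials["subject"].nunique() != 1:
        raise ValueError("subject_loglik expects a single subject's trials")
    sd = _prepare(trials, cpp_slopes)[0]
    return _pointwise(sd, unconstrain(params), beta_slope, beta_rl, beta_wm, drift_sd)


@dataclass
class FitResult:
    """Posterior summaries and pointwise log-likelihoods of one fit."""

    model_tag: str
    seed: int
    param_names: tuple
    subjects: np.ndarray
    unconstrained: np.ndarray  # subjects x params (MAP)
    params: pd.DataFrame  # model-scale MAP per subject
    group_mean: dict
    group_sd: dict
    beta_slope: Optional[dict]
    pointwise_map: np.ndarray
    pointwise_draws: np.ndarray  # draws x total trials
    trial_index: np.ndarray
    diagnostics: dict

    @property
    def n_trials(self) -> int:
        return self.pointwise_map.shape[0]

    def total_loglik(self) -> float:
        return float(self.pointwise_map.sum())


def _neg_log_posterior(x, sd, mu, sigma, neural, beta_prior, beta_rl, beta_wm, drift_sd):
    beta = x[-1] if neural else 0.0
    theta = x[:-1] if neural else x
    if np.any(np.abs(theta) > 12.0):  # keep exp/Phi transforms well-defined
        return 1e12
    ll = _pointwise(sd, theta, beta, beta_rl, beta_wm, drift_sd).sum()
    lp = norm.logpdf(theta, mu, sigma).sum()
    if neural:
        lp += norm.logpdf(beta, beta_prior[0], beta_prior[1])
    val = -(ll + lp)
    if not np.isfinite(val):
        return 1e12
    return val


def _numerical_hessian(f, x, rel_step=1e-3):
    n = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _laplace_cov(f, x):
    H = _numerical_hessian(f, x)
    H = 0.5 * (H + H.T)
    evals, evecs = np.linalg.eigh(H)
    evals = np.maximum(evals, 1e-4)  # guard flat/indefinite directions
    return (evecs / evals) @ evecs.T


def _random_effects_meta(est: np.ndarray, se: np.ndarray) -> dict:
    """DerSimonian-Laird random-effects pooling of per-subject estimates."""
    w = 1.0 / se**2
    mu_fe = np.sum(w * est) / np.sum(w)
    q = np.sum(w * (est - mu_fe) ** 2)
    k = len(est)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (se**2 + tau2)
    mean = float(np.sum(w_re * est) / np.sum(w_re))
    se_mean = float(np.sqrt(1.0 / np.sum(w_re)))
    return {
        "mean": mean,
        "se": se_mean,
        "ci_low": mean - 1.96 * se_mean,
        "ci_high": mean + 1.96 * se_mean,
        "tau2": float(tau2),
        "subject_estimates": est.tolist(),
        "subject_ses": se.tolist(),
    }


def fit(
    trials: pd.DataFrame,
    priors: Optional[PriorSpec] = None,
    mode: str = "map",
    rng_seed: int = 0,
    *,
    model_tag: str = "baseline",
    cpp_slopes: Optional[pd.Series] = None,
    n_starts: int = 5,
    outer_iters: int = 3,
    n_draws: int = 200,
    beta_rl: float = 10.0,
    beta_wm: float = 10.0,
    drift_sd: float = 1.0,
) -> FitResult:
    """Fit the hierarchy to a multi-subject trial table.

    ``mode='map'`` (the desk-scale default) alternates per-subject MAP
    optimization (multi-start L-BFGS-B) with group-prior updates, then
    draws from a Laplace approximation at each subject's mode.  The
    ``vi``/``mcmc`` modes share this log-posterior but are not provided
    in this implementation.
    """
    if mode != "map":
        raise NotImplementedError(
            f"mode={mode!r} is not available; this implementation provides 'map'"
        )
    if trials["subject"].nunique() < 1:
        raise ValueError("need at least one subject")
    priors = priors or PriorSpec()
    neural = model_tag == "neural"
    data = _prepare(trials, cpp_slopes if neural else None)
    rng = np.random.default_rng(derive_seed(rng_seed, "fit", model_tag))

    mu = np.array([priors.group_mean_loc[n] for n in PARAM_NAMES])
    # start wide so the first pass is likelihood-driven; the outer loop
    # then re-centers the group prior empirically
    sigma = np.full(len(PARAM_NAMES), 2.0)
    beta_prior = (priors.beta_slope_loc, priors.beta_slope_scale)
    mu_beta, sigma_beta = priors.beta_slope_loc, 0.5

    p = len(PARAM_NAMES)
    dim = p + 1 if neural else p
    xs = np.tile(np.append(mu, mu_beta)[:dim], (len(data), 1))
    diag: dict = {"converged": [], "objective": [], "group_trace": []}

    for outer in range(outer_iters):
        diag["converged"] = []
        diag["objective"] = []
        for i, sd in enumerate(data):
            if sd.n_trials == 0:
                xs[i, :p] = mu
                if neural:
                    xs[i, p] = mu_beta
                diag["converged"].append(True)
                diag["objective"].append(0.0)
                continue
            beta_sub_prior = (mu_beta, sigma_beta)

            def obj(x):
                return _neg_log_posterior(
                    x, sd, mu, sigma, neural, beta_sub_prior, beta_rl, beta_wm, drift_sd
                )

            starts = [xs[i].copy()]
            base = np.append(mu, mu_beta)[:dim]
            starts.append(base.copy())
            for _ in range(max(0, n_starts - 2)):
                pert = rng.normal(0.0, 0.8, size=dim)
                if neural:
                    pert[p] = rng.normal(0.0, 0.1)
                starts.append(base + pert)
            bounds = [(-10.0, 10.0)] * p + ([(-5.0, 5.0)] if neural else [])
            best = None
            for x0 in starts[:n_starts]:
                res = minimize(
                    obj, np.clip(x0, -9.0, 9.0), method="L-BFGS-B",
                    bounds=bounds, options={"ftol": 1e-8, "maxiter": 400},
                )
                if best is None or res.fun < best.fun:
                    best = res
            xs[i] = best.x
            diag["converged"].append(bool(best.success))
            diag["objective"].append(float(best.fun))

        # group updates: conjugate mean given current sd, moment sd with floor
        n_subj = len(data)
        for j, name in enumerate(PARAM_NAMES):
            m0, s0 = priors.group_mean_loc[name], priors.group_mean_scale
            prec = 1.0 / s0**2 + n_subj / sigma[j] ** 2
            mu[j] = (m0 / s0**2 + xs[:, j].sum() / sigma[j] ** 2) / prec
            sigma[j] = float(
                np.clip(np.sqrt(np.mean((xs[:, j] - mu[j]) ** 2)), _SD_FLOOR, _SD_CAP)
            )
        if neural:
            prec = 1.0 / beta_prior[1] ** 2 + n_subj / sigma_beta**2
            mu_beta = (beta_prior[0] / beta_prior[1] ** 2 + xs[:, p].sum() / sigma_beta**2) / prec
            sigma_beta = max(float(np.sqrt(np.mean((xs[:, p] - mu_beta) ** 2))), _BETA_SD_FLOOR)
        diag["group_trace"].append(
            {"outer": outer, "mu": mu.tolist(), "sigma": sigma.tolist(),
             "mu_beta": mu_beta if neural else None}
        )

    # Laplace draws and pointwise log-likelihood draws
    total = sum(sd.n_trials for sd in data)
    pointwise_map = np.empty(total)
    pointwise_draws = np.empty((n_draws, total))
    trial_index = np.concatenate([sd.index for sd in data]) if total else np.array([])
    beta_se = np.empty(len(data))
    offset = 0
    for i, sd in enumerate(data):
        if sd.n_trials == 0:
            beta_se[i] = sigma_beta
            continue
        beta_sub_prior = (mu_beta, sigma_beta)

        def obj(x):
            return _neg_log_posterior(
                x, sd, mu, sigma, neural, beta_sub_prior, beta_rl, beta_wm, drift_sd
            )

        cov = _laplace_cov(obj, xs[i])
        if neural:
            beta_se[i] = float(np.sqrt(max(cov[p, p], 1e-12)))
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(dim))
        # truncate at 2.5 sd: the quadratic approximation overshoots into
        # zero-density regions (e.g. tau above the fastest RT), which would
        # otherwise produce floored log-densities and unstable PSIS weights.
        # The draw noise is seeded per subject independently of the model
        # tag (common random numbers), so pointwise log-likelihood draws of
        # nested models are positively correlated and their ELPD difference
        # has a much smaller Monte-Carlo variance.
        rng_draws = np.random.default_rng(derive_seed(rng_seed, "laplace", sd.subject))
        z = np.clip(rng_draws.standard_normal((dim, n_draws)), -2.5, 2.5).T
        draws = xs[i] + z @ chol.T
        sl = slice(offset, offset + sd.n_trials)
        beta_i = xs[i, p] if neural else 0.0
        pointwise_map[sl] = _pointwise(sd, xs[i, :p], beta_i, beta_rl, beta_wm, drift_sd)
        map_total = pointwise_map[sl].sum()
        for d in range(n_draws):
            # the quadratic approximation can cross likelihood cliffs (e.g.
            # tau beyond the fastest RT); shrink such draws toward the mode
            step = draws[d] - xs[i]
            for _ in range(8):
                cand = xs[i] + step
                bd = cand[p] if neural else 0.0
                pw = _pointwise(sd, cand[:p], bd, beta_rl, beta_wm, drift_sd)
                if pw.sum() >= map_total - 50.0:
                    break
                step *= 0.5
            pointwise_draws[d, sl] = pw
        offset += sd.n_trials

    params_df = pd.DataFrame(
        [constrain(xs[i, :p]) for i in range(len(data))],
        index=pd.Index([sd.subject for sd in data], name="subject"),
    )
    beta_summary = None
    if neural:
        beta_summary = _random_effects_meta(xs[:, p].copy(), beta_se)
        beta_summary["group_mean"] = float(mu_beta)
    return FitResult(
        model_tag=model_tag,
        seed=rng_seed,
        param_names=PARAM_NAMES + (("beta_slope",) if neural else ()),
        subjects=np.array([sd.subject for sd in data]),
        unconstrained=xs,
        params=params_df,
        group_mean={n: float(m) for n, m in zip(PARAM_NAMES, mu)},
        group_sd={n: float(s) for n, s in zip(PARAM_NAMES, sigma)},
        beta_slope=beta_summary,
        pointwise_map=pointwise_map,
        pointwise_draws=pointwise_draws,
        trial_index=trial_index,
        diagnostics=diag,
    )


def fit_neural(
    trials: pd.DataFrame,
    cpp_slopes: Optional[pd.Series] = None,
    priors: Optional[PriorSpec] = None,
    mode: str = "map",
    rng_seed: int = 0,
    **kwargs,
) -> FitResult:
    """Fit the neurally informed model (CPP slope regressor on eta).

    ``cpp_slopes`` is a per-trial series aligned with ``trials.index``
    (raw or standardized; slopes are z-scored within subject, and trials
    without a slope contribute ``eta_t = eta``).  When omitted, the
    table's ``cpp_slope_z`` / ``cpp_slope`` column is used.
    """
    if cpp_slopes is None:
        for col in ("cpp_slope_z", "cpp_slope"):
            if col in trials.columns:
                cpp_slopes = trials[col]
                break
        if cpp_slopes is None:
            raise ValueError("no cpp_slopes given and no slope column in table")
    return fit(
        trials, priors=priors, mode=mode, rng_seed=rng_seed,
        model_tag="neural", cpp_slopes=cpp_slopes, **kwargs,
    )


@dataclass
class ModelComparison:
    """PSIS-LOO comparison of two fits on the same trials."""

    elpd_a: float
    elpd_b: float
    model_a: str
    model_b: str
    better: str
    elpd_diff: float  # better minus worse, >= 0
    se_diff: float
    pointwise_diff: np.ndarray  # a minus b
    method: str
    pareto_k_max: float


def _loo_pointwise(draws: np.ndarray) -> tuple[np.ndarray, float, str]:
    """elpd_i per trial from log-likelihood draws via PSIS-LOO.

    Falls back to the plug-in (MAP-style) estimate when importance
    smoothing is unavailable or degenerate.
    """
    n_draws = draws.shape[0]
    if n_draws < 10:
        return draws.mean(axis=0), np.nan, "plugin"
    try:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lw, khat = az.psislw(-draws.T)  # (n_obs, n_samples)
        elpd_i = logsumexp(lw + draws.T, axis=1)
        return elpd_i, float(np.max(khat)), "psis-loo"
    except Exception:
        lppd = logsumexp(draws, axis=0) - np.log(n_draws)
        p_waic = draws.var(axis=0, ddof=1)
        return lppd - p_waic, np.nan, "waic"


def compare_elpd(fit_a: FitResult, fit_b: FitResult) -> ModelComparison:
    """Expected log predictive density difference between two fits."""
    if fit_a.n_trials != fit_b.n_trials:
        raise ValueError("fits cover different numbers of trials")
    if not np.array_equal(fit_a.trial_index, fit_b.trial_index):
        raise ValueError("fits cover different trial sets")
    ea, ka, method_a = _loo_pointwise(fit_a.pointwise_draws)
    eb, kb, method_b = _loo_pointwise(fit_b.pointwise_draws)
    diff = ea - eb
    n = diff.shape[0]
    se = float(np.sqrt(n * diff.var(ddof=0))) if n else 0.0
    total = float(diff.sum())
    better = fit_a.model_tag if total >= 0 else fit_b.model_tag
    return ModelComparison(
        elpd_a=float(ea.sum()),
        elpd_b=float(eb.sum()),
        model_a=fit_a.model_tag,
        model_b=fit_b.model_tag,
        better=better,
        elpd_diff=abs(total),
        se_diff=se,
        pointwise_diff=diff,
        method=f"{method_a}/{method_b}",
        pareto_k_max=float(np.nanmax([ka, kb])),
    )
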