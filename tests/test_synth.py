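import numpy as np
import pandas as pd
import pytest

from conftest import small_design, make_eeg_config
from rlwm_lba.synth import (
    BIOSEMI64_LABELS,
    GeneratorConfig,
    channel_positions,
    sample_subject_params,
    simulate_behavior,
    simulate_eeg,
)
from rlwm_lba.transforms import PARAM_NAMES, unconstrain
from rlwm_lba import eeg_stats as es


def test_channel_layout_is_complete_and_ordered():
    assert len(BIOSEMI64_LABELS) == 64
    assert "FCz" in BIOSEMI64_LABELS and "CPz" in BIOSEMI64_LABELS
    pos = channel_positions(BIOSEMI64_LABELS)
    labels = list(BIOSEMI64_LABELS)
    # midline electrodes on x=0, left odd negative, right even positive
    assert pos[labels.index("Cz")][0] == 0.0
    assert pos[labels.index("C3")][0] < 0 < pos[labels.index("C4")][0]
    # anterior rows above posterior rows
    assert pos[labels.index("Fpz")][1] > pos[labels.index("Oz")][1]
    # all 64 positions distinct
    assert len({tuple(p) for p in pos}) == 64


def test_sample_subject_params_degenerate_and_round_trip():
    cfg = GeneratorConfig(
        n_subjects=5, group_sds={n: 0.0 for n in PARAM_NAMES}, seed=0
    )
    df = sample_subject_params(cfg, rng_seed=4)
    assert (df.nunique() == 1).all()
    for n in PARAM_NAMES:
        assert df[f"x_{n}"].iloc[0] == pytest.approx(cfg.group_means[n])
    # constrained columns are the transform of the unconstrained ones
    x = unconstrain({n: df[n].iloc[0] for n in PARAM_NAMES})
    assert np.allclose(x, [df[f"x_{n}"].iloc[0] for n in PARAM_NAMES], atol=1e-10)


def test_sampled_rho_mean_matches_transformed_group_mean():
    cfg = GeneratorConfig(n_subjects=10_000, seed=0)
    df = sample_subject_params(cfg, rng_seed=9)
    from scipy.stats import norm

    mu, sd = cfg.group_means["rho"], cfg.group_sds["rho"]
    expected = norm.cdf(mu / np.sqrt(1 + sd**2))  # E[Phi(X)] for X~N(mu,sd)
    assert df["rho"].mean() == pytest.approx(expected, abs=0.01)


def test_perfect_wm_is_correct_after_first_success():
    # rho=1, C=5, phi=0 and a near-noiseless race: every presentation that
    # follows a prior correct response of the same stimulus is correct
    means = {"alpha": -1.5, "bias": 0.0, "phi": -8.0, "rho": 8.0, "C": 8.0,
             "k": -0.7, "A": -0.25, "eta": 1.0, "tau": -0.5}
    cfg = GeneratorConfig(
        n_subjects=2, seed=3, design=small_design(),
        group_means=means, group_sds={n: 0.0 for n in PARAM_NAMES},
        drift_sd=1e-6,
    )
    df = simulate_behavior(cfg)
    for (_, block), sub in df.groupby(["subject", "block"]):
        succeeded = set()
        for _, row in sub.iterrows():
            if row.stimulus in succeeded:
                assert row.reward == 1
            if row.reward == 1:
                succeeded.add(row.stimulus)


def test_no_learning_stays_at_chance():
    means = {"alpha": -8.0, "bias": 0.0, "phi": -0.5, "rho": -8.0, "C": 0.3,
             "k": -0.7, "A": -0.25, "eta": 1.0, "tau": -0.5}
    cfg = GeneratorConfig(
        n_subjects=4, seed=6, design=small_design(),
        group_means=means, group_sds={n: 0.0 for n in PARAM_NAMES},
    )
    df = simulate_behavior(cfg)
    acc = df["reward"].mean()
    assert acc == pytest.approx(1 / 3, abs=3 * np.sqrt((1 / 3) * (2 / 3) / len(df)))


def test_behavior_table_has_latents_and_valid_flags(small_cohort):
    df = small_cohort
    for col in ("pi_chosen", "h_prior", "drift_chosen", "q_rl_chosen",
                "q_wm_chosen", "cpp_slope_z", "eta_t", "w_wm"):
        assert col in df.columns
        assert np.isfinite(df[col].to_numpy(dtype=float)).all()
    inc = df[df.included_in_eeg]
    assert (inc.reward == 1).all()
    assert (inc.presentation_index >= 2).all()
    assert df["rt"].between(0, 7, inclusive="right").all()
    # deterministic feedback
    assert ((df.action == df.correct_action) == (df.reward == 1)).all()


def test_simulate_behavior_is_seed_reproducible():
    cfg = GeneratorConfig(n_subjects=2, seed=17, design=small_design())
    a = simulate_behavior(cfg)
    b = simulate_behavior(cfg)
    pd.testing.assert_frame_equal(a, b)


def test_noiseless_cpp_slope_equals_generating_rate(small_cohort):
    eeg = make_eeg_config(
        noise_sd=0.0, q_effect=0.0, delay_effect=0.0, setsize_effect=0.0
    )
    cfg = GeneratorConfig(n_subjects=6, seed=11, design=small_design(), eeg=eeg)
    _, resp = simulate_eeg(small_cohort, cfg)
    slopes = es.cpp_slope(resp)
    inc = small_cohort[small_cohort.included_in_eeg]
    for subj, sub in inc.groupby("subject"):
        z = sub["drift_chosen"].to_numpy()
        z = (z - z.mean()) / z.std(ddof=1)
        rate = np.maximum(eeg.cpp_base_rate + eeg.cpp_gain * z, eeg.cpp_min_rate)
        got = slopes[np.isin(resp.trial_index, sub.index)]
        ok = sub["rt"].to_numpy() * 1000 >= 200  # landmarks inside the ramp
        assert np.allclose(got[ok], rate[ok], atol=1e-9)
        order = np.argsort(z[ok])
        assert np.all(np.diff(np.maximum(rate[ok][order], eeg.cpp_min_rate)) >= 0)


def test_noiseless_injected_q_effect_recovered_exactly():
    # restrict the analysis set to delay-present trials so generation and
    # analysis z-score the identical sample, then the GLM is exact
    cfg0 = GeneratorConfig(n_subjects=3, seed=23, design=small_design())
    df = simulate_behavior(cfg0)
    df.loc[df["delay"].isna(), "included_in_eeg"] = False
    eeg = make_eeg_config(noise_sd=0.0, cpp_base_rate=0.0, cpp_gain=0.0, cpp_min_rate=0.0)
    cfg = GeneratorConfig(n_subjects=3, seed=23, design=small_design(), eeg=eeg)
    stim, _ = simulate_eeg(df, cfg)
    reg = es.build_regressors(df, "stimulus")
    maps = es.single_trial_glm(stim, reg)
    times = np.asarray(stim.times)
    i300 = int(np.argmin(np.abs(times - 300)))
    fcz = list(stim.channels).index("FCz")
    for m in maps:
        j = 1 + m.predictor_names.index("z_q_rl")
        assert m.betas[j, fcz, i300] == pytest.approx(-eeg.q_effect, abs=1e-6)


def test_epochs_cover_only_included_trials(small_cohort, small_eeg):
    stim, resp = small_eeg
    inc_idx = small_cohort.index[small_cohort.included_in_eeg].to_numpy()
    assert np.array_equal(np.sort(stim.trial_index), np.sort(inc_idx))
    assert np.array_equal(stim.trial_index, resp.trial_index)
    assert stim.lock == "stimulus" and resp.lock == "response"
    assert len(stim.times) == stim.data.shape[2]


def test_measured_cpp_slope_tracks_drift_at_default_noise(small_cohort, small_eeg):
    _, resp = small_eeg
    slopes = es.cpp_slope(resp)
    inc = small_cohort[small_cohort.included_in_eeg]
    rs = []
    for subj, sub in inc.groupby("subject"):
        got = slopes[np.isin(resp.trial_index, sub.index)]
        rs.append(np.corrcoef(got, sub["drift_chosen"])[0, 1])
    assert np.mean(rs) > 0.5
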