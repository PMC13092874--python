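import numpy as np
import pandas as pd
import pytest

from rlwm_lba import eeg_stats as es
from rlwm_lba.synth import EpochSet


def _epochs(data, times=None, channels=None, lock="response", trial_index=None, fs=128.0):
    n, c, s = data.shape
    return EpochSet(
        data=data.astype(np.float32),
        times=np.linspace(-700, 700, s) if times is None else times,
        channels=[f"ch{i}" for i in range(c)] if channels is None else channels,
        sampling_rate=fs,
        lock=lock,
        trial_index=np.arange(n) if trial_index is None else trial_index,
    )


def _trial_table(n_per_subj=12, n_subj=3, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for s in range(n_subj):
        for i in range(n_per_subj):
            rows.append(
                {
                    "subject": s, "block": 0, "set_size": int(rng.integers(2, 6)),
                    "stimulus": "a", "presentation_index": 2, "action": 1,
                    "correct_action": 1, "reward": 1, "rt": 1.0,
                    "delay": float(rng.integers(1, 6)),
                    "included_in_eeg": True,
                    "q_rl_chosen": float(rng.random()),
                    "q_wm_chosen": float(rng.random()),
                    "drift_chosen": float(rng.uniform(0.5, 3.0)),
                }
            )
    return pd.DataFrame(rows)


def test_hand_computed_z_scores():
    df = _trial_table(n_per_subj=4, n_subj=1)
    df["delay"] = [1.0, 2.0, 3.0, 4.0]
    reg = es.build_regressors(df, "stimulus")
    expected = np.array([-1.1619, -0.3873, 0.3873, 1.1619])
    assert np.allclose(reg.frame["z_delay"].to_numpy(), expected, atol=1e-4)
    for col in reg.frame.columns:
        z = reg.frame[col].to_numpy()
        assert z.mean() == pytest.approx(0.0, abs=1e-8)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-8)


def test_zero_variance_predictor_is_flagged_and_zeroed():
    df = _trial_table()
    df.loc[df.subject == 0, "set_size"] = 3
    with pytest.warns(UserWarning, match="zero variance"):
        reg = es.build_regressors(df, "stimulus")
    sel = reg.subjects == 0
    assert np.all(reg.frame["z_set_size"].to_numpy()[sel] == 0.0)
    assert any("set_size" in w for w in reg.warnings)


def test_missing_delay_trials_are_dropped_from_stimulus_lock():
    df = _trial_table()
    df.loc[df.index[:3], "delay"] = np.nan
    reg = es.build_regressors(df, "stimulus")
    assert len(reg.frame) == len(df) - 3
    reg_r = es.build_regressors(df, "response")
    assert len(reg_r.frame) == len(df)


def test_glm_recovers_exact_noiseless_coefficients():
    df = _trial_table(n_per_subj=20, n_subj=2)
    reg = es.build_regressors(df, "stimulus")
    n, c, s = len(df), 3, 5
    data = np.zeros((n, c, s))
    z = np.empty(len(df))
    for subj in (0, 1):
        sel = reg.subjects == subj
        z[df.subject == subj] = reg.frame["z_q_rl"].to_numpy()[sel]
    data[:, 1, 2] = 2.0 * z
    maps = es.single_trial_glm(_epochs(data, lock="stimulus"), reg)
    for m in maps:
        j = 1 + m.predictor_names.index("z_q_rl")
        assert m.betas[j, 1, 2] == pytest.approx(2.0, abs=1e-6)
        assert abs(m.betas[j, 0, 0]) < 1e-6


def test_glm_matches_pseudoinverse_oracle():
    rng = np.random.default_rng(42)
    df = _trial_table(n_per_subj=50, n_subj=1, rng=rng)
    reg = es.build_regressors(df, "stimulus")
    data = rng.normal(size=(50, 2, 4))
    maps = es.single_trial_glm(_epochs(data, lock="stimulus"), reg)
    X = np.column_stack([np.ones(50)] + [reg.frame[c] for c in reg.frame.columns])
    oracle = np.linalg.pinv(X) @ data.reshape(50, -1)
    assert np.allclose(maps[0].betas.reshape(X.shape[1], -1), oracle, atol=1e-8)


def test_adding_inert_predictor_leaves_other_betas_unchanged():
    rng = np.random.default_rng(1)
    n = 40
    x1 = rng.normal(size=n)
    x1 = (x1 - x1.mean()) / x1.std(ddof=1)
    x2 = rng.normal(size=n)
    Q = np.column_stack([np.ones(n), x1])
    x2 -= Q @ np.linalg.lstsq(Q, x2, rcond=None)[0]  # orthogonalize vs [1, x1]
    y = 1.5 * x1 + rng.normal(size=n)
    b_small = np.linalg.lstsq(np.column_stack([np.ones(n), x1]), y, rcond=None)[0]
    b_big = np.linalg.lstsq(np.column_stack([np.ones(n), x1, x2]), y, rcond=None)[0]
    assert b_small[1] == pytest.approx(b_big[1], abs=1e-10)


def test_yuen_matches_textbook_formula():
    rng = np.random.default_rng(8)
    x = rng.normal(0.4, 1.0, size=10)
    t, p, df = es.yuen_onesample(x)
    # independent textbook computation
    import math

    from scipy.stats import t as tdist

    xs = np.sort(x)
    g = math.floor(0.2 * 10)
    h = 10 - 2 * g
    tm = xs[g:-g].mean()
    w = xs.copy()
    w[w < xs[g]] = xs[g]
    w[w > xs[-g - 1]] = xs[-g - 1]
    sw = w.var(ddof=1)
    se = math.sqrt(sw) / ((1 - 0.4) * math.sqrt(10))
    t_ref = tm / se
    p_ref = 2 * tdist.sf(abs(t_ref), h - 1)
    assert t == pytest.approx(t_ref, abs=1e-10)
    assert p == pytest.approx(p_ref, abs=1e-10)
    assert df == h - 1


def test_yuen_degenerate_cases():
    t, p, _ = es.yuen_onesample(np.zeros(8))
    assert t == 0.0 and p == 1.0
    t, p, _ = es.yuen_onesample(np.full(8, 1.3))
    assert np.isinf(t) and p == 0.0
    with pytest.raises(ValueError):
        es.yuen_onesample(np.array([1.0]))


def _beta_maps(stack, channels=2, samples=3):
    maps = []
    for s, b in enumerate(stack):
        maps.append(
            es.BetaMaps(
                subject=s, betas=b, predictor_names=["z_q_rl"],
                channels=[f"ch{i}" for i in range(channels)],
                times=np.arange(samples, dtype=float), z_context={},
            )
        )
    return maps


def test_group_inference_all_zero_betas_nothing_significant():
    stack = np.zeros((8, 2, 2, 3))
    g = es.group_inference(_beta_maps(stack))
    assert not g.mask.any()
    assert g.threshold == pytest.approx(0.05 / (2 * 3 * 2))


def test_group_inference_constant_nonzero_is_maximal():
    stack = np.zeros((8, 2, 2, 3))
    stack[:, 1, 0, 1] = 0.7
    g = es.group_inference(_beta_maps(stack))
    assert g.mask[1, 0, 1]
    assert np.isinf(g.t[1, 0, 1])
    assert g.mask.sum() == 1


def test_group_inference_matches_scalar_yuen():
    rng = np.random.default_rng(5)
    stack = rng.normal(0.5, 1.0, size=(12, 2, 2, 3))
    g = es.group_inference(_beta_maps(stack))
    t_ref, p_ref, _ = es.yuen_onesample(stack[:, 1, 1, 2])
    assert g.t[1, 1, 2] == pytest.approx(t_ref, abs=1e-10)
    assert g.p[1, 1, 2] == pytest.approx(p_ref, abs=1e-10)


def test_group_inference_requires_enough_subjects():
    with pytest.raises(ValueError):
        es.group_inference(_beta_maps(np.zeros((3, 1, 2, 3))))


def test_corrected_erp_levels():
    betas = np.zeros((2, 2, 4))
    betas[0] = 1.0  # intercept map
    betas[1, 0, :] = 0.5
    m = es.BetaMaps(
        subject=0, betas=betas, predictor_names=["z_q_rl"],
        channels=["a", "b"], times=np.arange(4.0), z_context={},
    )
    # zero effect: all levels equal the intercept map
    m0 = es.BetaMaps(
        subject=0, betas=np.stack([betas[0], np.zeros_like(betas[0])]),
        predictor_names=["z_q_rl"], channels=["a", "b"], times=np.arange(4.0),
        z_context={},
    )
    out0 = es.corrected_erp(m0, "z_q_rl", [0.1, 0.9], z_context=(0.5, 0.2))
    assert np.allclose(out0[0.1], out0[0.9])
    # symmetric levels are symmetric about the intercept map
    out = es.corrected_erp(m, "z_q_rl", [0.3, 0.7], z_context=(0.5, 0.2))
    assert np.allclose((out[0.3] + out[0.7]) / 2, betas[0])
    # level ordering follows the sign of the beta
    assert np.all(out[0.7][0] >= out[0.3][0])


def test_cpp_slope_examples():
    times = np.arange(-700, 700, 1000 / 512)
    n_s = len(times)
    data = np.zeros((2, 2, n_s))
    i200 = np.argmin(abs(times + 200))
    i50 = np.argmin(abs(times + 50))
    data[0, 1, i200] = 2.0
    data[0, 1, i50] = 5.0
    ep = _epochs(data, times=times, channels=["Fz", "CPz"], fs=512.0)
    slopes = es.cpp_slope(ep)
    dt = times[i50] - times[i200]
    assert slopes[0] == pytest.approx(3.0 / dt)
    assert slopes[0] == pytest.approx(0.02, rel=0.01)
    assert slopes[1] == 0.0  # flat epoch
    # pure linear ramp of slope m
    m = 0.035
    data2 = np.tile(m * times, (1, 2, 1))
    slopes2 = es.cpp_slope(_epochs(data2, times=times, channels=["Fz", "CPz"], fs=512.0))
    assert slopes2[0] == pytest.approx(m, rel=1e-6)


def test_cpp_slope_validation():
    data = np.zeros((1, 1, 10))
    with pytest.raises(ValueError):
        es.cpp_slope(_epochs(data, channels=["Fz"]))
    ep = _epochs(np.zeros((1, 1, 10)), times=np.linspace(-100, 100, 10), channels=["CPz"])
    with pytest.raises(ValueError):
        es.cpp_slope(ep)
    ep_stim = _epochs(np.zeros((1, 1, 10)), channels=["CPz"], lock="stimulus")
    with pytest.raises(ValueError):
        es.cpp_slope(ep_stim)


def test_quartile_assignment():
    df = pd.DataFrame(
        {"v": np.arange(1, 9, dtype=float), "subject": 0, "set_size": 2}
    )
    q = es.quartile_assign(df["v"], df[["subject", "set_size"]])
    assert q.tolist() == [1, 1, 2, 2, 3, 3, 4, 4]
    # ties: stable order, balanced, flagged for tiny groups
    df2 = pd.DataFrame({"v": np.ones(8), "subject": 0, "set_size": 2})
    q2 = es.quartile_assign(df2["v"], df2[["subject", "set_size"]])
    assert sorted(q2.tolist()) == [1, 1, 2, 2, 3, 3, 4, 4]
    rng = np.random.default_rng(2)
    df3 = pd.DataFrame({"v": rng.normal(size=23), "subject": 0, "set_size": 3})
    q3 = es.quartile_assign(df3["v"], df3[["subject", "set_size"]])
    counts = q3.value_counts()
    assert counts.max() - counts.min() <= 1


def test_slope_regression_recovers_constructed_effect():
    rng = np.random.default_rng(0)
    rows = []
    for subj in range(6):
        for ss in (2, 3, 4, 5):
            for _ in range(12):
                qrl = rng.integers(1, 5)
                qwm = rng.integers(1, 5)
                rows.append(
                    {"subject": subj, "set_size": ss, "q_rl_quartile": qrl,
                     "q_wm_quartile": qwm, "cpp_slope": 0.1 * qrl}
                )
    df = pd.DataFrame(rows)
    out = es.slope_regression(df)
    ss_tab = out["simple_slopes"]
    for _, row in ss_tab.iterrows():
        expected = 0.1 if row["module"] == "q_rl" else 0.0
        assert row["coef"] == pytest.approx(expected, abs=1e-8)


def test_slope_regression_matches_lstsq_oracle():
    rng = np.random.default_rng(3)
    rows = []
    for subj in range(2):
        for i in range(20):
            rows.append(
                {"subject": subj, "set_size": int(rng.integers(2, 4)),
                 "q_rl_quartile": int(rng.integers(1, 5)),
                 "q_wm_quartile": int(rng.integers(1, 5)),
                 "cpp_slope": float(rng.normal())}
            )
    df = pd.DataFrame(rows)
    out = es.slope_regression(df)
    # oracle: identical design built independently, solved by lstsq
    X = []
    for _, r in df.iterrows():
        row = [1.0 if r.subject == s else 0.0 for s in (0, 1)]
        row += [r.q_rl_quartile, r.q_wm_quartile]
        d = 1.0 if r.set_size == 3 else 0.0
        row += [d, r.q_rl_quartile * d, r.q_wm_quartile * d]
        X.append(row)
    beta = np.linalg.lstsq(np.array(X), df["cpp_slope"].to_numpy(), rcond=None)[0]
    got = out["results"].params
    assert np.allclose(got, beta, atol=1e-8)
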