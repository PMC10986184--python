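"""Contrast engine: F/t identity, Benjamini-Hochberg, Tukey post-hocs,
tractwise detection of injected effects, microstructure contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tractopo import stats
from tractopo.stats import ContrastSpec, benjamini_hochberg, fit_factor, tukey_posthoc
from tractopo.wscore import WScoreTable


def _wt(frame):
    return WScoreTable(table=frame)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.05])[0] == pytest.approx(0.05)

    def test_hand_step_up(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_never_decreases_p_and_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        p = rng.random(97)
        q_ref = multipletests(p, method="fdr_bh")[1]
        assert benjamini_hochberg(p) == pytest.approx(q_ref)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([])


def test_two_level_factor_f_equals_t_squared():
    rng = np.random.default_rng(2)
    y = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.7, 1, 25)])
    factor = np.array(["CN"] * 20 + ["amnestic"] * 25, dtype=object)
    fit = fit_factor(y, factor)
    t, _ = sps.ttest_ind(y[20:], y[:20])
    assert fit.f_stat == pytest.approx(t * t, abs=1e-8)


def test_zero_variance_outcome_flagged_degenerate():
    y = np.ones(30)
    factor = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
    fit = fit_factor(y, factor)
    assert fit.degenerate
    assert np.isnan(fit.f_stat)


def test_null_pvalues_approximately_uniform():
    rng = np.random.default_rng(3)
    factor = np.array(["CN"] * 30 + ["amnestic"] * 30 + ["non-amnestic"] * 30,
                      dtype=object)
    ps = [fit_factor(rng.normal(0, 1, 90), factor).p_value
          for _ in range(300)]
    # Kolmogorov-Smirnov against uniform
    d, p = sps.kstest(ps, "uniform")
    assert p > 0.01


class TestTukey:
    def test_two_levels_reduce_to_t_test(self):
        rng = np.random.default_rng(4)
        y = np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 1, 18)])
        factor = np.array(["a"] * 15 + ["b"] * 18, dtype=object)
        fit = fit_factor(y, factor)
        ph = tukey_posthoc(fit)
        t, p = sps.ttest_ind(y[15:], y[:15])
        assert ph.loc[0, "t"] == pytest.approx(t, abs=1e-8)
        assert ph.loc[0, "p_tukey"] == pytest.approx(p, abs=1e-8)

    def test_identical_group_samples_give_p_one(self):
        rng = np.random.default_rng(5)
        block = rng.normal(0, 1, 100)
        y = np.concatenate([block, block, block])  # equal sample means
        factor = np.array((["a"] * 100) + (["b"] * 100) + (["c"] * 100),
                          dtype=object)
        ph = tukey_posthoc(fit_factor(y, factor))
        assert ph["estimate"].to_numpy() == pytest.approx([0.0] * 3, abs=1e-12)
        assert (ph["p_tukey"] > 0.999).all()

    def test_matches_statsmodels_tukeyhsd_without_covariates(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        rng = np.random.default_rng(6)
        y = np.concatenate([rng.normal(0, 1, 5), rng.normal(0.8, 1, 5),
                            rng.normal(2.0, 1, 5)])
        factor = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5, dtype=object)
        ref = pairwise_tukeyhsd(y, factor)
        ph = tukey_posthoc(fit_factor(y, factor)).sort_values(
            ["level_b", "level_a"], ignore_index=True)
        ref_p = np.asarray(ref.pvalues)
        assert ph["p_tukey"].to_numpy() == pytest.approx(ref_p, abs=1e-6)
        assert ph["estimate"].to_numpy() == pytest.approx(
            np.asarray(ref.meandiffs), abs=1e-10)


def _make_wtable(rng, meta, n_tracts, effect_tracts=(), effect=0.0):
    """Unit-variance w-score table with an optional non-amnestic shift."""
    rows = []
    na = meta["group"] == "non-amnestic"
    for k in range(n_tracts):
        w = rng.normal(0, 1, len(meta))
        if k in effect_tracts:
            w = w + np.where(na, effect, 0.0)
        rows.append(pd.DataFrame({
            "participant_id": meta["participant_id"],
            "target_id": f"a{k:03d}--b{k:03d}", "w": w}))
    return _wt(pd.concat(rows, ignore_index=True))


def _table2_meta(rng):
    groups = ["CN"] * 45 + ["amnestic"] * 41 + ["non-amnestic"] * 67
    return pd.DataFrame({
        "participant_id": [f"s{i:03d}" for i in range(153)],
        "group": groups,
        "mmse": np.clip(rng.normal(25, 3, 153), 0, 30),
    })


def test_injected_effect_detected_with_correct_sign():
    """-1 SD non-amnestic shift on 20 of 200 tracts: most are discovered
    and every significant injected tract has a negative CN contrast."""
    rng = np.random.default_rng(7)
    meta = _table2_meta(rng)
    wt = _make_wtable(rng, meta, 200, effect_tracts=range(20), effect=-1.0)
    res = stats.fit_tractwise(wt, meta, ContrastSpec())
    injected = {f"a{k:03d}--b{k:03d}" for k in range(20)}
    sig = set(res.table.loc[res.table["significant"], "target_id"])
    assert len(sig & injected) >= 16
    ph = res.posthoc
    ph = ph[(ph["target_id"].isin(injected))
            & (ph["level_a"] == "non-amnestic") & (ph["level_b"] == "CN")]
    assert (ph["estimate"] < 0).all()


def test_tract_with_empty_level_is_skipped():
    rng = np.random.default_rng(8)
    meta = _table2_meta(rng)
    wt = _make_wtable(rng, meta, 3)
    t = wt.table.copy()
    mask = (t["target_id"] == "a000--b000") & t["participant_id"].isin(
        meta.loc[meta["group"] == "amnestic", "participant_id"])
    t.loc[mask, "w"] = np.nan
    res = stats.fit_tractwise(_wt(t), meta, ContrastSpec())
    assert "a000--b000" in res.skipped
    assert len(res.table) == 2


def test_posthoc_rows_only_for_significant_tracts():
    rng = np.random.default_rng(9)
    meta = _table2_meta(rng)
    wt = _make_wtable(rng, meta, 40, effect_tracts=(0,), effect=-1.5)
    res = stats.fit_tractwise(wt, meta, ContrastSpec())
    sig = set(res.table.loc[res.table["significant"], "target_id"])
    assert set(res.posthoc["target_id"]) == sig
    assert (res.table["q"] >= res.table["p"] - 1e-15).all()


def test_micro_contrast_recovers_group_shift_direction():
    rng = np.random.default_rng(10)
    meta = _table2_meta(rng)
    meta["age"] = rng.uniform(55, 80, len(meta))
    meta["sex"] = rng.choice(["F", "M"], len(meta))
    delta = -0.015
    fa = 0.4 + np.where(meta["group"] == "non-amnestic", delta, 0.0) \
        + rng.normal(0, 0.01, len(meta))
    micro = pd.DataFrame({
        "participant_id": meta["participant_id"],
        "mean_fa": fa,
        "mean_md": rng.normal(7e-4, 3e-5, len(meta)),
        "mean_iso": rng.normal(0.15, 0.02, len(meta)),
    })
    res = stats.global_micro_contrast(micro, meta)
    assert set(res.table["target_id"]) == {"mean_fa", "mean_md", "mean_iso"}
    row = res.table[res.table["target_id"] == "mean_fa"].iloc[0]
    assert row["significant"]
    ph = res.posthoc
    ph = ph[(ph["target_id"] == "mean_fa") & (ph["level_a"] == "non-amnestic")
            & (ph["level_b"] == "CN")]
    est = ph["estimate"].iloc[0]
    se = ph["se"].iloc[0]
    assert est < 0
    assert abs(est - delta) < 2 * se


def test_missing_micro_column_raises():
    micro = pd.DataFrame({"participant_id": ["a"], "mean_fa": [0.4]})
    with pytest.raises(ValueError, match="missing columns"):
        stats.global_micro_contrast(micro, pd.DataFrame())
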