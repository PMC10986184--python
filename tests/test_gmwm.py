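"""Grey/white-matter coupling: region summaries, the random-intercept
mixed model, Satterthwaite inference (validated against a frozen lmerTest
fit), and the OLS degenerate case."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from tractopo import gmwm
from tractopo.gmwm import _build_design, _fit_random_intercept, summarize_region_wm
from tractopo.wscore import WScoreTable

FIXTURE = Path(__file__).parent / "data" / "gmwm_synthetic_fixture.csv"


def _wt(rows):
    return WScoreTable(table=pd.DataFrame(rows))


class TestRegionSummary:
    def test_simple_mean_over_incident_tracts(self):
        wt = _wt([
            {"participant_id": "p", "target_id": "r1--r2", "w": 1.0},
            {"participant_id": "p", "target_id": "r1--r3", "w": 3.0},
        ])
        out = summarize_region_wm(wt).set_index("region")
        assert out.loc["r1", "mean_wm_w"] == pytest.approx(2.0)
        assert out.loc["r1", "n_tracts_used"] == 2
        # each tract counts toward both endpoints
        assert out.loc["r2", "mean_wm_w"] == pytest.approx(1.0)
        assert out.loc["r3", "mean_wm_w"] == pytest.approx(3.0)

    def test_missing_tracts_excluded_from_mean(self):
        wt = _wt([
            {"participant_id": "p", "target_id": "r1--r2", "w": 2.0},
            {"participant_id": "p", "target_id": "r1--r3", "w": np.nan},
        ])
        out = summarize_region_wm(wt).set_index("region")
        assert out.loc["r1", "mean_wm_w"] == pytest.approx(2.0)
        assert out.loc["r1", "n_tracts_used"] == 1
        assert "r3" not in out.index  # zero usable tracts: row omitted

    def test_matches_brute_force_and_row_order_invariant(self, small_wscores):
        _, _, wt = small_wscores
        out = summarize_region_wm(wt)
        # independent accumulation
        acc = {}
        for row in wt.table.itertuples(index=False):
            if not np.isfinite(row.w):
                continue
            a, _, b = row.target_id.partition("--")
            for region in (a, b):
                acc.setdefault((row.participant_id, region), []).append(row.w)
        assert len(out) == len(acc)
        for rec in out.itertuples(index=False):
            vals = acc[(rec.participant_id, rec.region)]
            assert rec.mean_wm_w == pytest.approx(np.mean(vals))
            assert rec.n_tracts_used == len(vals)
        shuffled = WScoreTable(
            table=wt.table.sample(frac=1.0, random_state=0))
        out2 = summarize_region_wm(shuffled)
        pd.testing.assert_frame_equal(out, out2)


class TestAgainstLmerTest:
    """Frozen oracle: the same fixture fitted with R lmerTest (REML,
    Satterthwaite df, Type III ANOVA)."""

    @pytest.fixture(scope="class")
    def fit(self):
        df = pd.read_csv(FIXTURE)
        design = _build_design(
            df, {"group": ["CN", "amnestic", "non-amnestic"]}, ["gm_w"],
            [("group", "gm_w")])
        codes = pd.factorize(df["participant_id"])[0]
        return _fit_random_intercept(
            df["mean_wm_w"].to_numpy(float), codes, design)

    # term -> (coef, se, df, t, p) from lmerTest::summary
    LMER_COEFS = {
        "groupamnestic": (-0.19086711366, 0.12352775641, 11.734, -1.54514, 0.148844),
        "groupnon-amnestic": (-0.18328062598, 0.11483249755, 11.088, -1.59607, 0.138559),
        "gm_w": (0.02641036083, 0.04002601926, 112.961, 0.65983, 0.510706),
        "groupamnestic:gm_w": (0.10201219929, 0.05266501327, 111.417, 1.93700, 0.055277),
        "groupnon-amnestic:gm_w": (0.02356088380, 0.05091747232, 112.776, 0.46273, 0.644452),
    }
    # term -> (F, df_den, p) from lmerTest::anova (Type III, Satterthwaite)
    LMER_ANOVA = {
        "group": (1.69134, 11.5587, 0.2268344),
        "gm_w": (11.14333, 111.7003, 0.0011464),
        "group:gm_w": (2.25103, 111.5983, 0.1100508),
    }

    def test_variance_components(self, fit):
        assert fit.residual_var == pytest.approx(0.036259, rel=1e-3)
        assert fit.random_intercept_var == pytest.approx(0.02856, rel=2e-3)

    def test_fixed_effect_table(self, fit):
        fe = fit.fixed_effects.set_index("term")
        for term, (coef, se, df, t, p) in self.LMER_COEFS.items():
            row = fe.loc[term]
            assert row["coef"] == pytest.approx(coef, abs=5e-6)
            assert row["se"] == pytest.approx(se, rel=1e-3)
            assert row["df"] == pytest.approx(df, abs=0.5)
            assert row["t"] == pytest.approx(t, rel=2e-3)
            assert row["p"] == pytest.approx(p, abs=2e-3)

    def test_type3_anova_with_satterthwaite_df(self, fit):
        an = fit.anova.set_index("term")
        for term, (F, df_den, p) in self.LMER_ANOVA.items():
            row = an.loc[term]
            assert row["F"] == pytest.approx(F, rel=2e-3)
            assert row["df_den"] == pytest.approx(df_den, abs=0.5)
            assert row["p"] == pytest.approx(p, abs=2e-3)


def _flat_cohort_tables(rng, n_participants=40, n_regions=12,
                        slopes=(0.03, 0.08, 0.08), tau=0.0, noise=0.3):
    """Summary/volume tables with known coupling and controllable
    between-participant variance."""
    groups = (["CN"] * (n_participants // 2)
              + ["amnestic"] * (n_participants // 4)
              + ["non-amnestic"] * (n_participants
                                    - n_participants // 2
                                    - n_participants // 4))
    slope_of = dict(zip(["CN", "amnestic", "non-amnestic"], slopes))
    sum_rows, vol_rows, meta_rows = [], [], []
    for i, g in enumerate(groups):
        pid = f"p{i:03d}"
        u = rng.normal(0, tau) if tau > 0 else 0.0
        meta_rows.append({"participant_id": pid, "group": g,
                          "phenotype": {"CN": "CN", "amnestic": "aAD",
                                        "non-amnestic": "lvPPA"}[g],
                          "apoe_e4_count": float(rng.integers(0, 3))})
        for r in range(n_regions):
            gm = rng.normal(0, 1)
            wm = u + slope_of[g] * gm + rng.normal(0, noise)
            sum_rows.append({"participant_id": pid, "region": f"r{r:02d}",
                             "mean_wm_w": wm, "n_tracts_used": 5})
            vol_rows.append({"participant_id": pid, "target_id": f"r{r:02d}",
                             "w": gm})
    return (pd.DataFrame(sum_rows), _wt(vol_rows), pd.DataFrame(meta_rows))


def test_zero_between_participant_variance_matches_ols():
    import statsmodels.api as sm
    rng = np.random.default_rng(12)
    summary, vol, meta = _flat_cohort_tables(rng, tau=0.0)
    mixed = gmwm.fit_gmwm(summary, vol, meta, "group")
    ols = gmwm.fit_gmwm(summary, vol, meta, "group", random_intercept=False)
    np.testing.assert_allclose(
        mixed.fixed_effects["coef"].to_numpy(),
        ols.fixed_effects["coef"].to_numpy(), atol=1e-6)
    # and the OLS path agrees with statsmodels
    design = _build_design(
        vol.table.rename(columns={"target_id": "region", "w": "gm_w"})
        .merge(summary, on=["participant_id", "region"])
        .merge(meta, on="participant_id"),
        {"group": ["CN", "amnestic", "non-amnestic"]}, ["gm_w"],
        [("group", "gm_w")])
    ref = sm.OLS(summary.sort_values(["participant_id", "region"])
                 ["mean_wm_w"].to_numpy(), design.X).fit()
    np.testing.assert_allclose(
        ols.fixed_effects["coef"].to_numpy(), ref.params, atol=1e-10)


def test_group_slopes_recovered_within_two_se():
    rng = np.random.default_rng(23)
    summary, vol, meta = _flat_cohort_tables(
        rng, n_participants=60, n_regions=40, tau=0.2, noise=0.25)
    res = gmwm.fit_gmwm(summary, vol, meta, "group")
    fe = res.fixed_effects.set_index("term")
    assert abs(fe.loc["gm_w", "coef"] - 0.03) < 2 * fe.loc["gm_w", "se"]
    for term in ("groupamnestic:gm_w", "groupnon-amnestic:gm_w"):
        assert abs(fe.loc[term, "coef"] - 0.05) < 2 * fe.loc[term, "se"]
    assert 0.0 <= res.var_explained <= 1.0


def test_noiseless_fixed_effects_explain_all_variance():
    rng = np.random.default_rng(14)
    summary, vol, meta = _flat_cohort_tables(
        rng, slopes=(0.5, 1.0, 1.5), tau=0.0, noise=1e-8)
    res = gmwm.fit_gmwm(summary, vol, meta, "group", random_intercept=False)
    assert res.var_explained == pytest.approx(1.0, abs=1e-6)


def test_variance_explained_invariant_to_covariate_rescaling():
    rng = np.random.default_rng(15)
    summary, vol, meta = _flat_cohort_tables(rng, tau=0.1)
    res1 = gmwm.fit_gmwm(summary, vol, meta, "group")
    vol2 = _wt(vol.table.assign(w=vol.table["w"] * 7.0 + 3.0))
    res2 = gmwm.fit_gmwm(summary, vol2, meta, "group")
    assert res1.var_explained == pytest.approx(res2.var_explained, abs=1e-6)


def test_apoe_models_report_expected_terms():
    rng = np.random.default_rng(16)
    summary, vol, meta = _flat_cohort_tables(rng, n_participants=48, tau=0.2)
    base = gmwm.fit_gmwm(summary, vol, meta, "apoe_e4_count")
    assert set(base.anova["term"]) == {
        "apoe_e4_count", "gm_w", "apoe_e4_count:gm_w"}
    add = gmwm.fit_gmwm_apoe(summary, vol, meta, model="additive")
    assert set(add.anova["term"]) == {"group", "apoe_e4_count", "gm_w"}
    full = gmwm.fit_gmwm_apoe(summary, vol, meta, model="full")
    assert "group:apoe_e4_count:gm_w" in set(full.anova["term"])
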