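"""Mass-univariate linear contrasts with FDR and Tukey post-hoc tests.

The same engine serves three uses: tractwise contrasts of w-scored GFA on
diagnostic group or phenotype (adjusting for MMSE), contrasts of global
white-matter microstructure metrics (adjusting for age, sex and MMSE), and
generic factor contrasts of behavioural outcomes.

Per outcome, an ordinary least squares model of ``y ~ factor + covariates``
is fitted; the factor is tested with a Type II F (factor adjusted for
covariates), p-values are Benjamini-Hochberg adjusted across the tested
family, and FDR-significant outcomes receive all pairwise Tukey-adjusted
comparisons of estimated marginal means (evaluated at the grand covariate
means, where pairwise level differences reduce to coefficient differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import GROUPS, PHENOTYPES
from .wscore import WScoreTable, design_matrix

_CANONICAL_ORDERS = [list(GROUPS), list(PHENOTYPES)]


@dataclass
class ContrastSpec:
    factor: str = "group"  # metadata column holding the factor of interest
    covariates: Sequence[str] = ("mmse",)
    fdr_alpha: float = 0.05
    posthoc_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.fdr_alpha < 1) or not (0 < self.posthoc_alpha < 1):
            raise ValueError("alphas must lie in (0, 1)")


@dataclass
class FactorFit:
    """One fitted factor contrast: omnibus F plus what Tukey needs."""

    levels: List[str]
    n_used: int
    f_stat: float
    p_value: float
    df_num: int
    df_den: int
    coef: np.ndarray
    cov_coef: np.ndarray
    degenerate: bool = False


@dataclass
class TractStatResult:
    table: pd.DataFrame      # per-tract omnibus results with q-values
    posthoc: pd.DataFrame    # pairwise Tukey rows for significant tracts only
    skipped: List[str] = field(default_factory=list)
    spec: Optional[ContrastSpec] = None


def level_order(levels: Sequence[str]) -> List[str]:
    """Canonical level ordering: diagnostic order where known, else sorted."""
    lv = set(levels)
    for order in _CANONICAL_ORDERS:
        if lv <= set(order):
            return [l for l in order if l in lv]
    return sorted(lv)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment with enforced monotonicity, capped at 1.

    NaN entries propagate as NaN and do not count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    pv = p[ok]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        q[ok] = out
    return q


def fit_factor(
    y: np.ndarray,
    factor: Sequence[str],
    covariates: Optional[np.ndarray] = None,
) -> FactorFit:
    """OLS of y on factor dummies + covariates; Type II F for the factor."""
    y = np.asarray(y, dtype=float)
    factor = np.asarray(factor, dtype=object)
    n = y.size
    levels = level_order(np.unique(factor))
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels with data")
    dummies = np.column_stack(
        [(factor == lev).astype(float) for lev in levels[1:]])
    Z = covariates if covariates is not None else np.empty((n, 0))
    X_full = np.column_stack([np.ones(n), dummies, Z])
    X_red = np.column_stack([np.ones(n), Z])
    p_full = X_full.shape[1]
    if n <= p_full:
        raise ValueError("too few observations for the requested model")

    coef, _, rank, _ = np.linalg.lstsq(X_full, y, rcond=None)
    resid = y - X_full @ coef
    rss_full = float(resid @ resid)
    coef_r, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
    rss_red = float((y - X_red @ coef_r) @ (y - X_red @ coef_r))

    df_num = len(levels) - 1
    df_den = n - p_full
    sigma2 = rss_full / df_den
    scale = float(np.mean(y * y))
    degenerate = rank < p_full or sigma2 <= 1e-12 * max(scale, 1e-300)
    if degenerate or sigma2 == 0.0:
        f_stat, p_value = np.nan, np.nan
        cov_coef = np.full((p_full, p_full), np.nan)
        degenerate = True
    else:
        f_stat = ((rss_red - rss_full) / df_num) / sigma2
        p_value = float(sps.f.sf(f_stat, df_num, df_den))
        cov_coef = sigma2 * np.linalg.inv(X_full.T @ X_full)
    return FactorFit(levels=levels, n_used=n, f_stat=float(f_stat),
                     p_value=p_value, df_num=df_num, df_den=df_den,
                     coef=coef, cov_coef=cov_coef, degenerate=degenerate)


def tukey_posthoc(fit: FactorFit) -> pd.DataFrame:
    """All pairwise level contrasts with studentized-range adjusted p.

    Differences of estimated marginal means at the grand covariate mean
    equal differences of the level coefficients, so covariate terms cancel.
    """
    if fit.degenerate:
        raise ValueError("cannot run post-hoc tests on a degenerate fit")
    k = len(fit.levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(fit.coef.size)
            # column 0 is the intercept; level l>0 sits at column l
            if i > 0:
                c[i] = -1.0
            if j > 0:
                c[j] = 1.0
            est = float(c @ fit.coef)   # level_j minus level_i
            se = float(np.sqrt(c @ fit.cov_coef @ c))
            t = est / se if se > 0 else np.nan
            p_adj = float(sps.studentized_range.sf(
                abs(t) * np.sqrt(2.0), k, fit.df_den)) if np.isfinite(t) else np.nan
            rows.append({
                "level_a": fit.levels[j], "level_b": fit.levels[i],
                "estimate": est, "se": se, "t": t,
                "p_tukey": min(p_adj, 1.0) if np.isfinite(p_adj) else np.nan,
            })
    return pd.DataFrame(rows)


def _batched_factor_f(
    Y: np.ndarray,
    factor: np.ndarray,
    cov: np.ndarray,
    levels: List[str],
) -> Tuple[np.ndarray, np.ndarray, int, int]:
    """Type II factor F for many complete-data outcomes sharing one design."""
    n, m = Y.shape
    dummies = np.column_stack(
        [(factor == lev).astype(float) for lev in levels[1:]])
    X_full = np.column_stack([np.ones(n), dummies, cov])
    X_red = np.column_stack([np.ones(n), cov])
    p_full = X_full.shape[1]
    df_num = len(levels) - 1
    df_den = n - p_full

    def _rss(X):
        coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coef
        return np.einsum("ij,ij->j", resid, resid)

    rss_full = _rss(X_full)
    rss_red = _rss(X_red)
    scale = np.mean(Y * Y, axis=0)
    sigma2 = rss_full / df_den
    degenerate = sigma2 <= 1e-12 * np.maximum(scale, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / df_num) / sigma2
    F = np.where(degenerate, np.nan, F)
    p = np.where(np.isfinite(F), sps.f.sf(F, df_num, df_den), np.nan)
    return F, p, df_num, df_den


def _clean_rows(
    meta: pd.DataFrame, spec: ContrastSpec
) -> Tuple[pd.DataFrame, np.ndarray]:
    cov = design_matrix(meta, spec.covariates)
    ok = np.isfinite(cov).all(axis=1) & meta[spec.factor].notna().to_numpy()
    return meta.loc[ok].reset_index(drop=True), cov[ok]


def fit_tractwise(
    wtable: WScoreTable,
    meta: pd.DataFrame,
    spec: Optional[ContrastSpec] = None,
) -> TractStatResult:
    """Mass-univariate contrasts over every retained tract.

    Rows with a missing tract value are excluded tract-by-tract; tracts
    where any factor level loses all its data are skipped and listed in the
    result.  Benjamini-Hochberg runs across all tested tracts; Tukey
    post-hoc tables are emitted for FDR-significant tracts only.
    """
    spec = spec or ContrastSpec()
    wide = wtable.wide()
    meta_use = meta.set_index("participant_id").loc[wide.index].reset_index()
    meta_use, cov = _clean_rows(meta_use, spec)
    wide = wide.loc[meta_use["participant_id"]]
    factor_all = meta_use[spec.factor].to_numpy(object)
    all_levels = level_order(np.unique(factor_all))

    records = []
    skipped: List[str] = []
    Y = wide.to_numpy(float)
    finite = np.isfinite(Y)
    complete = finite.all(axis=0)

    def _record(target, n_used, F, p, df_num, df_den):
        a, _, b = str(target).partition("--")
        records.append({
            "target_id": str(target), "region_a": a, "region_b": b,
            "n_used": n_used, "F": F, "p": p,
            "df_num": df_num, "df_den": df_den,
            "degenerate": not np.isfinite(F),
        })

    # complete-data tracts share one design matrix: test them in a batch
    if complete.any():
        Fb, pb, df_num, df_den = _batched_factor_f(
            Y[:, complete], factor_all, cov, all_levels)
        for target, F, p in zip(wide.columns[complete], Fb, pb):
            _record(target, Y.shape[0], float(F), float(p), df_num, df_den)
    for k in np.flatnonzero(~complete):
        target = wide.columns[k]
        ok = finite[:, k]
        present_levels = set(factor_all[ok])
        if any(lev not in present_levels for lev in all_levels):
            skipped.append(str(target))
            continue
        try:
            fit = fit_factor(Y[ok, k], factor_all[ok], cov[ok])
        except ValueError:
            skipped.append(str(target))
            continue
        _record(target, fit.n_used, fit.f_stat, fit.p_value,
                fit.df_num, fit.df_den)
    if not records:
        raise ValueError("no tract could be tested")
    table = pd.DataFrame(records).sort_values("target_id",
                                              ignore_index=True)
    table["q"] = benjamini_hochberg(table["p"].to_numpy())
    table["significant"] = table["q"] < spec.fdr_alpha

    posthoc_rows = []
    col_of = {str(t): k for k, t in enumerate(wide.columns)}
    for rec in table.itertuples(index=False):
        if not rec.significant:
            continue
        k = col_of[rec.target_id]
        ok = finite[:, k]
        fit = fit_factor(Y[ok, k], factor_all[ok], cov[ok])
        ph = tukey_posthoc(fit)
        ph.insert(0, "target_id", rec.target_id)
        posthoc_rows.append(ph)
    posthoc = (pd.concat(posthoc_rows, ignore_index=True) if posthoc_rows
               else pd.DataFrame(columns=["target_id", "level_a", "level_b",
                                          "estimate", "se", "t", "p_tukey"]))
    return TractStatResult(table=table, posthoc=posthoc, skipped=skipped,
                           spec=spec)


def global_micro_contrast(
    micro: pd.DataFrame,
    meta: pd.DataFrame,
    spec: Optional[ContrastSpec] = None,
) -> TractStatResult:
    """Group contrasts of mean FA, MD and isotropic diffusion.

    Same engine as the tractwise contrasts, with covariates age, sex and
    MMSE by default, and BH correction across the three metrics.
    """
    spec = spec or ContrastSpec(factor="group",
                                covariates=("age", "sex", "mmse"))
    metrics = ["mean_fa", "mean_md", "mean_iso"]
    missing = [m for m in metrics if m not in micro.columns]
    if missing:
        raise ValueError(f"microstructure table missing columns: {missing}")
    long = micro.melt(id_vars="participant_id", value_vars=metrics,
                      var_name="target_id", value_name="w")
    wt = WScoreTable(table=long.rename(columns={"value": "w"}),
                     modality="micro")
    return fit_tractwise(wt, meta, spec)


def edge_list(result: TractStatResult) -> pd.DataFrame:
    """Per-tract (region_a, region_b, t, q) export for network plotting."""
    ph = result.posthoc.merge(
        result.table[["target_id", "region_a", "region_b", "q"]],
        on="target_id", how="left")
    return ph[["region_a", "region_b", "level_a", "level_b", "t", "q"]]
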