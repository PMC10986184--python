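"""Clinical and microstructural correlates of topological metrics.

Individual Betti-0, Betti-1 and Betti-1/Betti-0 ratio values (taken at the
maximum-distance filtration threshold) are related to global cognition
(MMSE, all participants) and disease duration (patients only, since
duration is undefined for cognitively normal participants) by one OLS model
per metric: ``outcome ~ metric + age + sex``, alpha 0.05 uncorrected.
Simple Pearson correlations link the same metrics to global white-matter
microstructure (FA, MD, isotropic diffusion).
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .wscore import design_matrix

BETTI_METRICS = ("betti0", "betti1", "betti_ratio")
MICRO_METRICS = ("mean_fa", "mean_md", "mean_iso")


def _ols_table(y: np.ndarray, X: np.ndarray, names: Sequence[str]
               ) -> pd.DataFrame:
    n, p = X.shape
    if n < p + 2:
        raise ValueError("fewer complete cases than model parameters + 2")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("singular design (constant predictor column?)")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    return pd.DataFrame({
        "term": list(names), "coef": beta, "se": se, "t": t,
        "df": df, "p": 2 * sps.t.sf(np.abs(t), df),
    })


def regress_clinical(
    metrics: pd.DataFrame,
    meta: pd.DataFrame,
    outcome: str,
    weight_source: Optional[str] = None,
) -> pd.DataFrame:
    """Per-metric OLS of a clinical outcome on a Betti metric + age + sex.

    ``outcome`` is ``mmse`` (all participants) or ``duration`` (amnestic and
    non-amnestic patients only).  ``metrics`` carries participant_id plus
    betti0 / betti1 / betti_ratio columns.  Output is a long coefficient
    table with one block per metric.
    """
    if outcome not in ("mmse", "duration"):
        raise ValueError("outcome must be 'mmse' or 'duration'")
    df = metrics.merge(meta, on="participant_id", how="inner")
    if outcome == "duration":
        df = df[df["group"] != "CN"]
    df = df[df[outcome].notna()].reset_index(drop=True)

    blocks = []
    for metric in BETTI_METRICS:
        sub = df[np.isfinite(df[metric])]
        y = sub[outcome].to_numpy(float)
        Z = design_matrix(sub, ("age", "sex"))
        X = np.column_stack([np.ones(len(sub)), sub[metric].to_numpy(float), Z])
        tab = _ols_table(y, X, ["(Intercept)", metric, "age", "sexM"])
        tab.insert(0, "metric", metric)
        tab.insert(0, "outcome", outcome)
        if weight_source is not None:
            tab.insert(0, "weight_source", weight_source)
        blocks.append(tab)
    return pd.concat(blocks, ignore_index=True)


def correlate_microstructure(
    metrics: pd.DataFrame,
    micro: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r (two-sided p) between each Betti metric and each
    global microstructure metric."""
    df = metrics.merge(micro, on="participant_id", how="inner")
    rows = []
    for bm in BETTI_METRICS:
        for mm in MICRO_METRICS:
            sub = df[np.isfinite(df[bm]) & np.isfinite(df[mm])]
            if len(sub) < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for ({bm}, {mm})")
            r, p = sps.pearsonr(sub[bm], sub[mm])
            rows.append({"betti_metric": bm, "micro_metric": mm,
                         "r": float(r), "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows)
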