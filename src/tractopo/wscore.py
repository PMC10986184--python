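"""Normative w-scoring against the cognitively normal group.

A w-score is a covariate-adjusted z-score:

    w = (observed - predicted_from_controls) / control_residual_SD

with per-target ordinary least squares fitted on CN participants only.
Tractwise GFA adjusts for age and sex; regional grey-matter volume
additionally adjusts for intracranial volume.  Higher scores mean greater
GFA or volume than expected for a cognitively normal person with the same
covariates; lower scores mean more degeneration.

Truncation clamps extreme w-scores at pooled per-modality percentiles
(default 0.1 and 99.9), and min/max normalization maps the table onto [0, 1]
for the topology branch, where missing tracts are represented as zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

GFA_COVARIATES: Tuple[str, ...] = ("age", "sex")
VOLUME_COVARIATES: Tuple[str, ...] = ("icv", "age", "sex")


@dataclass
class NormativeModel:
    """Control-group OLS for one target (a tract or a region)."""

    target_id: str
    covariates: List[str]
    coef: np.ndarray  # intercept first, then one slope per covariate
    residual_sd: float
    n_train: int
    degenerate: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.coef[0] + X @ self.coef[1:]

    def to_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "covariates": self.covariates,
            "coef": [float(c) for c in self.coef],
            "residual_sd": float(self.residual_sd),
            "n_train": int(self.n_train),
            "degenerate": bool(self.degenerate),
        }


@dataclass
class WScoreTable:
    """Long-format w-score table with its transformation constants."""

    table: pd.DataFrame  # participant_id, target_id, w
    modality: str = "gfa"
    truncation_bounds: Optional[Tuple[float, float]] = None
    norm_constants: Optional[Tuple[float, float]] = None

    def wide(self) -> pd.DataFrame:
        return self.table.pivot(index="participant_id", columns="target_id",
                                values="w")


def design_matrix(meta: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    """Covariate columns with sex coded as a male indicator (reference F)."""
    cols = []
    for cov in covariates:
        if cov == "sex":
            cols.append((meta["sex"] == "M").to_numpy(float))
        else:
            cols.append(meta[cov].to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(meta), 0))


def tracts_wide(tract_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy tract table to participants x tract-id, NaN = missing."""
    t = tract_table.copy()
    t["target_id"] = t["region_a"] + "--" + t["region_b"]
    return t.pivot(index="participant_id", columns="target_id", values="gfa")


def volumes_wide(volumes: pd.DataFrame) -> pd.DataFrame:
    return volumes.pivot(index="participant_id", columns="region",
                         values="gm_volume")


def fit_normative(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: Sequence[str] = GFA_COVARIATES,
) -> Dict[str, NormativeModel]:
    """Per-target OLS on CN participants only.

    ``values`` is a wide participants-by-targets table (NaN = missing).
    Residual SD uses ``df = n_train - p`` with p the number of fitted
    parameters.  Targets with singular designs or too few training rows are
    dropped with a warning.
    """
    meta_idx = meta.set_index("participant_id")
    cn_ids = [pid for pid in values.index
              if meta_idx.loc[pid, "group"] == "CN"]
    if not cn_ids:
        raise ValueError("no CN participants available for normative fitting")
    cn_meta = meta_idx.loc[cn_ids]
    X_all = design_matrix(cn_meta.reset_index(), covariates)
    y_all = values.loc[cn_ids].to_numpy(float)
    p = X_all.shape[1] + 1

    models: Dict[str, NormativeModel] = {}
    dropped = []
    for k, target in enumerate(values.columns):
        y = y_all[:, k]
        ok = np.isfinite(y)
        n_train = int(ok.sum())
        if n_train < p + 1:
            dropped.append(target)
            continue
        X = np.column_stack([np.ones(n_train), X_all[ok]])
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            dropped.append(target)
            continue
        coef, _, _, _ = np.linalg.lstsq(X, y[ok], rcond=None)
        resid = y[ok] - X @ coef
        rss = float(resid @ resid)
        residual_sd = float(np.sqrt(max(rss, 0.0) / (n_train - p)))
        degenerate = residual_sd < 1e-12
        models[str(target)] = NormativeModel(
            target_id=str(target),
            covariates=list(covariates),
            coef=coef,
            residual_sd=residual_sd if not degenerate else residual_sd,
            n_train=n_train,
            degenerate=degenerate,
        )
    if dropped:
        warnings.warn(
            f"{len(dropped)} targets dropped from normative fitting "
            f"(singular design or too few CN observations)", stacklevel=2)
    return models


def transform(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    models: Dict[str, NormativeModel],
    modality: str = "gfa",
) -> WScoreTable:
    """w = (observed - predicted) / residual_sd for every participant.

    Missing observations stay missing; targets without a model are omitted.
    Degenerate models (residual SD ~ 0) produce NaN w-scores rather than
    dividing by zero.
    """
    meta_idx = meta.set_index("participant_id").loc[values.index]
    rows = []
    for target, model in models.items():
        if target not in values.columns:
            raise KeyError(f"no observations for modelled target {target!r}")
        X = design_matrix(meta_idx.reset_index(), model.covariates)
        y = values[target].to_numpy(float)
        if model.degenerate:
            w = np.full_like(y, np.nan)
        else:
            w = (y - model.predict(X)) / model.residual_sd
        rows.append(pd.DataFrame({
            "participant_id": values.index,
            "target_id": target,
            "w": w,
        }))
    table = pd.concat(rows, ignore_index=True)
    table = table.sort_values(["participant_id", "target_id"],
                              ignore_index=True)
    return WScoreTable(table=table, modality=modality)


def truncate(
    wtable: WScoreTable,
    lower_pct: float = 0.1,
    upper_pct: float = 99.9,
) -> WScoreTable:
    """Clamp w-scores to pooled per-modality percentiles.

    Percentiles are computed on the pooled distribution of all participants
    and all targets of the modality (linear interpolation between order
    statistics).
    """
    vals = wtable.table["w"].to_numpy(float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("w-score table has no finite values")
    if finite.size < 1000:
        warnings.warn(
            f"only {finite.size} finite w-scores; {lower_pct}/{upper_pct} "
            "percentiles are unstable at this size", stacklevel=2)
    lo, hi = np.percentile(finite, [lower_pct, upper_pct])
    out = wtable.table.copy()
    out["w"] = np.clip(vals, lo, hi)
    return WScoreTable(table=out, modality=wtable.modality,
                       truncation_bounds=(float(lo), float(hi)),
                       norm_constants=wtable.norm_constants)


def minmax_normalize(
    wtable: WScoreTable,
    fill_missing: float = 0.0,
) -> WScoreTable:
    """Map w-scores onto [0, 1] by the global min/max, then set missing to 0.

    The zero fill ties missing tracts with the global minimum, so that in
    the filtration they never appear at any non-negative threshold.
    """
    vals = wtable.table["w"].to_numpy(float)
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("w-score table has no finite values")
    vmin = float(vals[finite].min())
    vmax = float(vals[finite].max())
    if vmax <= vmin:
        raise ValueError("degenerate range: global max must exceed global min")
    out = wtable.table.copy()
    normed = (vals - vmin) / (vmax - vmin)
    normed[~finite] = fill_missing
    out["w"] = normed
    return WScoreTable(table=out, modality=wtable.modality,
                       truncation_bounds=wtable.truncation_bounds,
                       norm_constants=(vmin, vmax))
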