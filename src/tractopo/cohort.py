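"""Core domain containers for structural-connectome cohorts.

A cohort bundles per-participant metadata, symmetric tractwise mean-GFA
connectivity matrices, regional grey-matter volumes, and global white-matter
microstructure scalars (FA, MD, isotropic diffusion).  Missing tracts are
represented explicitly as NaN so that downstream stages can apply
tract-by-tract exclusion rather than silent imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

#: Clinical phenotypes: cognitively normal, amnestic AD/MCI, and the four
#: non-amnestic AD syndromes (logopenic-variant PPA, posterior cortical
#: atrophy, behavioural-variant AD, corticobasal syndrome).
PHENOTYPES: Tuple[str, ...] = ("CN", "aAD", "lvPPA", "PCA", "bvAD", "CBS")

#: Diagnostic group is a pure function of phenotype.
GROUP_OF: Dict[str, str] = {
    "CN": "CN",
    "aAD": "amnestic",
    "lvPPA": "non-amnestic",
    "PCA": "non-amnestic",
    "bvAD": "non-amnestic",
    "CBS": "non-amnestic",
}

GROUPS: Tuple[str, ...] = ("CN", "amnestic", "non-amnestic")

#: Metadata table columns expected throughout the pipeline.
META_COLUMNS = [
    "participant_id",
    "phenotype",
    "group",
    "age",
    "sex",
    "mmse",
    "duration",
    "icv",
    "apoe_e4_count",
    "biomarker_confirmed",
    "mmse_imputed",
    "duration_imputed",
]


def group_of(phenotype: str) -> str:
    """Map a phenotype label to its diagnostic group."""
    try:
        return GROUP_OF[phenotype]
    except KeyError:
        raise ValueError(f"unknown phenotype: {phenotype!r}") from None


def tract_key(region_a: str, region_b: str) -> Tuple[str, str]:
    """Canonical (lexicographically ordered) key for an undirected tract."""
    if region_a == region_b:
        raise ValueError(f"self-connection is not a tract: {region_a!r}")
    return (region_a, region_b) if region_a < region_b else (region_b, region_a)


def tract_id(region_a: str, region_b: str) -> str:
    """String identifier ``A--B`` in canonical order."""
    a, b = tract_key(region_a, region_b)
    return f"{a}--{b}"


def split_tract_id(tid: str) -> Tuple[str, str]:
    a, _, b = tid.partition("--")
    return a, b


@dataclass
class ConnectivityMatrix:
    """Symmetric region-by-region matrix of tractwise mean GFA.

    ``values`` holds NaN for missing tracts and on the diagonal (a region has
    no tract to itself).  Defined entries lie in [0, 1].
    """

    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.labels)} region labels"
            )
        np.fill_diagonal(self.values, np.nan)

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def defined_mask(self) -> np.ndarray:
        """Boolean mask of defined (non-missing, off-diagonal) cells."""
        return ~np.isnan(self.values)

    def validate(self) -> None:
        """Raise ValueError naming the offending cell on any violation."""
        v = self.values
        bad = np.argwhere(
            ~(np.isclose(v, v.T, equal_nan=True) | (np.isnan(v) & np.isnan(v.T)))
        )
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"asymmetric matrix at cell ({self.labels[i]}, {self.labels[j]}): "
                f"{v[i, j]!r} != {v[j, i]!r}"
            )
        defined = self.defined_mask()
        out = defined & ((v < 0) | (v > 1))
        if out.any():
            i, j = np.argwhere(out)[0]
            raise ValueError(
                f"GFA out of [0, 1] at cell ({self.labels[i]}, {self.labels[j]}): "
                f"{v[i, j]}"
            )

    def subset(self, keep_labels: Iterable[str]) -> "ConnectivityMatrix":
        keep = [l for l in self.labels if l in set(keep_labels)]
        idx = [self.labels.index(l) for l in keep]
        return ConnectivityMatrix(keep, self.values[np.ix_(idx, idx)].copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ConnectivityMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("matrix rows and columns must carry identical labels")
        return cls(list(df.index), df.to_numpy(dtype=float))

    def isolated_regions(self) -> List[str]:
        """Regions with zero defined off-diagonal connections ("islands")."""
        defined = self.defined_mask()
        return [l for l, d in zip(self.labels, defined.sum(axis=1)) if d == 0]


@dataclass
class Cohort:
    """Bundle of everything the analysis pipeline consumes."""

    meta: pd.DataFrame
    matrices: Dict[str, ConnectivityMatrix]
    volumes: pd.DataFrame  # participant_id, region, gm_volume
    micro: pd.DataFrame  # participant_id, mean_fa, mean_md, mean_iso
    template: ConnectivityMatrix
    config: dict = field(default_factory=dict)

    def validate(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata table missing columns: {missing}")
        bad_pheno = set(self.meta["phenotype"]) - set(PHENOTYPES)
        if bad_pheno:
            raise ValueError(f"unknown phenotypes in metadata: {sorted(bad_pheno)}")
        derived = self.meta["phenotype"].map(GROUP_OF)
        if not (derived == self.meta["group"]).all():
            raise ValueError("group column is not the pure function of phenotype")
        mmse = self.meta["mmse"].dropna()
        if ((mmse < 0) | (mmse > 30)).any():
            raise ValueError("MMSE outside [0, 30]")
        cn = self.meta[self.meta["group"] == "CN"]
        if cn["duration"].notna().any():
            raise ValueError("disease duration must be missing for CN participants")
        if (self.volumes["gm_volume"] <= 0).any():
            raise ValueError("grey-matter volumes must be strictly positive")
        for pid, mat in self.matrices.items():
            mat.validate()


def impute_missing_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Fill missing MMSE and disease duration by stratum means.

    Missing CN MMSE is replaced by the mean MMSE of the remaining CN sample;
    missing patient MMSE by the mean MMSE across all patients (amnestic and
    non-amnestic pooled); missing patient duration by the mean duration among
    all other patients.  Per-cell imputation flags are recorded in the
    ``mmse_imputed`` / ``duration_imputed`` columns.
    """
    out = meta.copy()
    if "mmse_imputed" not in out.columns:
        out["mmse_imputed"] = False
    if "duration_imputed" not in out.columns:
        out["duration_imputed"] = False

    is_cn = out["group"] == "CN"
    is_patient = ~is_cn

    cn_missing = is_cn & out["mmse"].isna()
    if cn_missing.any():
        donor = out.loc[is_cn & out["mmse"].notna(), "mmse"]
        if donor.empty:
            raise ValueError("cannot impute CN MMSE: stratum entirely missing")
        out.loc[cn_missing, "mmse"] = donor.mean()
        out.loc[cn_missing, "mmse_imputed"] = True

    pt_missing = is_patient & out["mmse"].isna()
    if pt_missing.any():
        donor = out.loc[is_patient & out["mmse"].notna(), "mmse"]
        if donor.empty:
            raise ValueError("cannot impute patient MMSE: stratum entirely missing")
        out.loc[pt_missing, "mmse"] = donor.mean()
        out.loc[pt_missing, "mmse_imputed"] = True

    dur_missing = is_patient & out["duration"].isna()
    if dur_missing.any():
        for idx in out.index[dur_missing]:
            donor = out.loc[is_patient & out["duration"].notna() & (out.index != idx),
                            "duration"]
            if donor.empty:
                raise ValueError(
                    "cannot impute disease duration: stratum entirely missing"
                )
            out.loc[idx, "duration"] = donor.mean()
            out.loc[idx, "duration_imputed"] = True

    return out
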