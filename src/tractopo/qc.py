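"""Connectome quality control.

Three rules, applied in a fixed order, decide which tracts enter analysis:

1. *Island exclusion* — parcellation regions that have zero detected
   connections ("islands") in more than a threshold fraction of scans
   (default 25%, strict inequality) are dropped from every matrix.
2. *Coverage ("50% rule")* — a tract is kept only if it is present in at
   least 50% (inclusive) of the participants of every phenotype in a
   configurable phenotype set.
3. *Template masking* — tracts whose value in a population-average template
   matrix is zero or undefined are dropped.

Re-running any rule on its own output is a no-op (idempotence), and the
coverage rule is monotone in its threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import ConnectivityMatrix, tract_key

#: Phenotype set used by the coverage rule by default.  aAD is deliberately
#: absent (configurable); a warning is emitted so users confirm the choice.
DEFAULT_COVERAGE_PHENOTYPES: Tuple[str, ...] = ("CN", "lvPPA", "PCA", "bvAD", "CBS")

TractKey = Tuple[str, str]


@dataclass
class QCReport:
    island_frequency: Dict[str, float]
    excluded_regions: List[str]
    coverage: pd.DataFrame  # region_a, region_b, phenotype ('overall' incl.), fraction
    retained_tracts: List[TractKey]
    template_excluded: List[TractKey]
    n_candidate_tracts: int = 0
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "island_frequency": self.island_frequency,
            "excluded_regions": self.excluded_regions,
            "coverage": self.coverage.to_dict(orient="records"),
            "retained_tracts": [list(t) for t in self.retained_tracts],
            "template_excluded": [list(t) for t in self.template_excluded],
            "n_candidate_tracts": self.n_candidate_tracts,
            "params": self.params,
        }


def tract_universe_size(region_count: int) -> int:
    """Number of candidate pairwise connections among ``region_count`` regions."""
    return region_count * (region_count - 1) // 2


def _check_labels(matrices: Dict[str, ConnectivityMatrix]) -> List[str]:
    if not matrices:
        raise ValueError("no participants given")
    labels = None
    for pid, mat in matrices.items():
        if labels is None:
            labels = mat.labels
        elif mat.labels != labels:
            raise ValueError(
                f"inconsistent region labels across participants (at {pid})")
    return list(labels)


def detect_islands(matrices: Dict[str, ConnectivityMatrix]) -> Dict[str, float]:
    """Fraction of scans in which each region has zero defined connections."""
    labels = _check_labels(matrices)
    counts = np.zeros(len(labels), dtype=int)
    for mat in matrices.values():
        defined = mat.defined_mask().sum(axis=1)
        counts += (defined == 0)
    n = len(matrices)
    return {lab: counts[k] / n for k, lab in enumerate(labels)}


def exclude_regions(
    matrices: Dict[str, ConnectivityMatrix],
    threshold: float = 0.25,
) -> Tuple[Dict[str, ConnectivityMatrix], List[str]]:
    """Drop regions whose island frequency strictly exceeds ``threshold``."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    freq = detect_islands(matrices)
    excluded = [r for r, f in freq.items() if f > threshold]
    keep = [r for r in next(iter(matrices.values())).labels if r not in excluded]
    if not keep:
        raise ValueError("island exclusion removed every region")
    out = {pid: mat.subset(keep) for pid, mat in matrices.items()}
    return out, excluded


def presence_table(
    matrices: Dict[str, ConnectivityMatrix],
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-tract presence fraction by phenotype plus 'overall'.

    Only tracts present in at least one scan appear as rows.
    """
    labels = _check_labels(matrices)
    n_regions = len(labels)
    pheno_of = dict(zip(meta["participant_id"], meta["phenotype"]))
    groups: Dict[str, List[str]] = {}
    for pid in matrices:
        groups.setdefault(pheno_of[pid], []).append(pid)

    iu = np.triu_indices(n_regions, k=1)
    rows = []
    overall = np.zeros(len(iu[0]))
    per_ph = {}
    for ph, pids in groups.items():
        cnt = np.zeros(len(iu[0]))
        for pid in pids:
            cnt += matrices[pid].defined_mask()[iu]
        per_ph[ph] = cnt / len(pids)
        overall += cnt
    overall /= len(matrices)

    ever = overall > 0
    idx = np.flatnonzero(ever)
    for k in idx:
        a, b = labels[iu[0][k]], labels[iu[1][k]]
        rows.append({"region_a": a, "region_b": b,
                     "phenotype": "overall", "fraction": overall[k]})
        for ph, frac in per_ph.items():
            rows.append({"region_a": a, "region_b": b,
                         "phenotype": ph, "fraction": frac[k]})
    return pd.DataFrame(rows)


def coverage_filter(
    matrices: Dict[str, ConnectivityMatrix],
    meta: pd.DataFrame,
    phenotype_set: Sequence[str] = DEFAULT_COVERAGE_PHENOTYPES,
    min_fraction: float = 0.5,
) -> List[TractKey]:
    """Tracts present in at least ``min_fraction`` of every listed phenotype."""
    if not phenotype_set:
        raise ValueError("phenotype_set must be non-empty")
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in (0, 1]")
    if "aAD" not in phenotype_set:
        warnings.warn(
            "coverage rule is evaluated without the amnestic (aAD) phenotype; "
            "pass phenotype_set including 'aAD' to change this",
            stacklevel=2)
    labels = _check_labels(matrices)
    pheno_of = dict(zip(meta["participant_id"], meta["phenotype"]))
    by_ph: Dict[str, List[str]] = {}
    for pid in matrices:
        by_ph.setdefault(pheno_of[pid], []).append(pid)
    for ph in phenotype_set:
        if not by_ph.get(ph):
            raise ValueError(f"phenotype {ph!r} has zero participants")

    n_regions = len(labels)
    iu = np.triu_indices(n_regions, k=1)
    keep = np.ones(len(iu[0]), dtype=bool)
    for ph in phenotype_set:
        pids = by_ph[ph]
        cnt = np.zeros(len(iu[0]))
        for pid in pids:
            cnt += matrices[pid].defined_mask()[iu]
        keep &= (cnt / len(pids)) >= min_fraction
    return [tract_key(labels[i], labels[j])
            for i, j in zip(iu[0][keep], iu[1][keep])]


def template_filter(
    tracts: Sequence[TractKey],
    template: ConnectivityMatrix,
) -> Tuple[List[TractKey], List[TractKey]]:
    """Keep tracts with a defined, strictly positive template value."""
    pos = {lab: k for k, lab in enumerate(template.labels)}
    kept, dropped = [], []
    for a, b in tracts:
        if a not in pos or b not in pos:
            raise ValueError(f"tract endpoints ({a}, {b}) absent from template")
        v = template.values[pos[a], pos[b]]
        if np.isfinite(v) and v > 0:
            kept.append((a, b))
        else:
            dropped.append((a, b))
    return kept, dropped


def build_tract_table(
    matrices: Dict[str, ConnectivityMatrix],
    retained: Sequence[TractKey],
) -> pd.DataFrame:
    """Tidy table: one row per participant x retained tract.

    Missing tracts are flagged ``present=False`` with NaN GFA, so downstream
    contrasts can exclude them tract-by-tract.
    """
    if not retained:
        raise ValueError("retained tract list is empty")
    labels = _check_labels(matrices)
    pos = {lab: k for k, lab in enumerate(labels)}
    retained = sorted(tract_key(a, b) for a, b in retained)
    ai = np.array([pos[a] for a, _ in retained])
    bi = np.array([pos[b] for _, b in retained])
    frames = []
    for pid in matrices:
        vals = matrices[pid].values[ai, bi]
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "region_a": [a for a, _ in retained],
            "region_b": [b for _, b in retained],
            "gfa": vals,
            "present": ~np.isnan(vals),
        }))
    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(
        ["participant_id", "region_a", "region_b"], ignore_index=True)


def run_qc(
    matrices: Dict[str, ConnectivityMatrix],
    meta: pd.DataFrame,
    template: ConnectivityMatrix,
    island_threshold: float = 0.25,
    coverage_phenotypes: Sequence[str] = DEFAULT_COVERAGE_PHENOTYPES,
    coverage_fraction: float = 0.5,
) -> Tuple[Dict[str, ConnectivityMatrix], pd.DataFrame, QCReport]:
    """Full QC chain: island exclusion -> coverage rule -> template mask.

    Returns the region-reduced matrices, the tidy tract table, and a report
    recording every intermediate decision.
    """
    freq = detect_islands(matrices)
    reduced, excluded = exclude_regions(matrices, island_threshold)
    template_red = template.subset(next(iter(reduced.values())).labels)
    covered = coverage_filter(reduced, meta, coverage_phenotypes,
                              coverage_fraction)
    retained, template_dropped = template_filter(covered, template_red)
    if not retained:
        raise ValueError("QC retained no tracts")
    table = build_tract_table(reduced, retained)
    coverage = presence_table(reduced, meta)
    report = QCReport(
        island_frequency=freq,
        excluded_regions=excluded,
        coverage=coverage,
        retained_tracts=sorted(retained),
        template_excluded=sorted(template_dropped),
        n_candidate_tracts=tract_universe_size(
            len(next(iter(matrices.values())).labels)),
        params={
            "island_threshold": island_threshold,
            "coverage_phenotypes": list(coverage_phenotypes),
            "coverage_fraction": coverage_fraction,
        },
    )
    return reduced, table, report
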