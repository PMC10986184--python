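"""End-to-end orchestration of the connectome analysis pipeline.

Stage order is fixed: qc -> wscore -> stats (tractwise, GM-WM coupling,
global microstructure) -> topology -> inference -> clinical.  A run is
deterministic given its seed and configuration; every output table carries
a provenance comment (package version, configuration hash, seed) and the
run log records row counts in and out of each filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import clinical as clin
from . import gmwm, inference, io, qc as qcmod, stats, topology, wscore
from .cohort import Cohort, impute_missing_meta
from .wscore import WScoreTable

log = logging.getLogger("tractopo")

STAGE_ORDER = ("qc", "wscore", "stats", "topology", "inference", "clinical")

GROUP_CONTRASTS = (
    ("CN", "non-amnestic"),
    ("CN", "amnestic"),
    ("amnestic", "non-amnestic"),
)


@dataclass
class RunConfig:
    stages: Sequence[str] = STAGE_ORDER
    island_threshold: float = 0.25
    coverage_phenotypes: Sequence[str] = qcmod.DEFAULT_COVERAGE_PHENOTYPES
    coverage_fraction: float = 0.5
    truncation_pcts: Tuple[float, float] = (0.1, 99.9)
    fdr_alpha: float = 0.05
    grid_size: int = 100
    augment_mst: bool = True
    n_perm: int = 0
    seed: int = 0

    def validate(self) -> None:
        stages = tuple(self.stages)
        if stages != STAGE_ORDER[: len(stages)]:
            raise ValueError(
                f"stages must be a prefix of {STAGE_ORDER}, got {stages}")


@dataclass
class PipelineResult:
    meta: pd.DataFrame
    qc_report: Optional[qcmod.QCReport] = None
    tract_table: Optional[pd.DataFrame] = None
    gfa_w: Optional[WScoreTable] = None
    gfa_w_norm: Optional[WScoreTable] = None
    vol_w: Optional[WScoreTable] = None
    tract_group: Optional[stats.TractStatResult] = None
    tract_phenotype: Optional[stats.TractStatResult] = None
    gmwm_group: Optional[gmwm.MixedModelResult] = None
    gmwm_phenotype: Optional[gmwm.MixedModelResult] = None
    micro_result: Optional[stats.TractStatResult] = None
    curves: Dict[str, Dict[str, topology.BettiCurve]] = field(default_factory=dict)
    graphs: Dict[str, Dict[str, topology.ParticipantGraph]] = field(default_factory=dict)
    topo_tests: List[inference.ExactTestResult] = field(default_factory=list)
    betti_metrics: Dict[str, pd.DataFrame] = field(default_factory=dict)
    clinical_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    micro_correlations: Dict[str, pd.DataFrame] = field(default_factory=dict)


def _gfa_as_weight_table(tract_table: pd.DataFrame) -> WScoreTable:
    """Untransformed GFA as topology edge weights (missing -> 0)."""
    t = tract_table.copy()
    t["target_id"] = t["region_a"] + "--" + t["region_b"]
    w = t["gfa"].to_numpy(float)
    out = pd.DataFrame({
        "participant_id": t["participant_id"],
        "target_id": t["target_id"],
        "w": np.where(np.isfinite(w), w, 0.0),
    })
    return WScoreTable(table=out.sort_values(
        ["participant_id", "target_id"], ignore_index=True), modality="gfa")


def run_pipeline(
    cohort: Cohort,
    config: Optional[RunConfig] = None,
    outdir: Optional[Path] = None,
) -> PipelineResult:
    """Run the requested stage prefix on a cohort; optionally write outputs."""
    config = config or RunConfig()
    config.validate()
    stages = set(config.stages)
    chash = io.config_hash(
        {"run": config.__dict__, "cohort": {k: v for k, v in
                                            cohort.config.items()
                                            if k != "_truth"}})
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    meta = impute_missing_meta(cohort.meta)
    n_imputed = int(meta["mmse_imputed"].sum() + meta["duration_imputed"].sum())
    log.info("metadata: %d participants, %d imputed cells", len(meta), n_imputed)
    result = PipelineResult(meta=meta)

    def _save(df: pd.DataFrame, name: str) -> None:
        if outdir is not None:
            io.write_table(df, outdir / name, chash, config.seed)

    # ---- qc --------------------------------------------------------------
    if "qc" not in stages:
        return result
    matrices, tract_table, report = qcmod.run_qc(
        cohort.matrices, meta, cohort.template,
        island_threshold=config.island_threshold,
        coverage_phenotypes=config.coverage_phenotypes,
        coverage_fraction=config.coverage_fraction)
    result.qc_report = report
    result.tract_table = tract_table
    log.info("qc: %d regions excluded, %d/%d tracts retained",
             len(report.excluded_regions), len(report.retained_tracts),
             report.n_candidate_tracts)
    if outdir is not None:
        io.write_json(report.to_dict(), outdir / "qc_report.json")
    _save(tract_table, "tracts.tsv")

    # ---- wscore ----------------------------------------------------------
    if "wscore" not in stages:
        return result
    lo_pct, hi_pct = config.truncation_pcts
    tr_wide = wscore.tracts_wide(tract_table)
    gfa_models = wscore.fit_normative(tr_wide, meta, wscore.GFA_COVARIATES)
    gfa_w = wscore.transform(tr_wide, meta, gfa_models, modality="gfa")
    gfa_w = wscore.truncate(gfa_w, lo_pct, hi_pct)
    result.gfa_w = gfa_w
    result.gfa_w_norm = wscore.minmax_normalize(gfa_w)

    vol_wide = wscore.volumes_wide(cohort.volumes)
    vol_models = wscore.fit_normative(vol_wide, meta, wscore.VOLUME_COVARIATES)
    vol_w = wscore.transform(vol_wide, meta, vol_models, modality="volume")
    vol_w = wscore.truncate(vol_w, lo_pct, hi_pct)
    result.vol_w = vol_w
    log.info("wscore: %d tract models, %d volume models",
             len(gfa_models), len(vol_models))
    if outdir is not None:
        io.write_json({t: m.to_dict() for t, m in gfa_models.items()},
                      outdir / "gfa_models.json")
        io.write_json({t: m.to_dict() for t, m in vol_models.items()},
                      outdir / "vol_models.json")
    _save(gfa_w.table, "wscores_gfa.tsv")
    _save(vol_w.table, "wscores_vol.tsv")
    _save(result.gfa_w_norm.table, "wscores_gfa_norm.tsv")

    # ---- stats -----------------------------------------------------------
    if "stats" not in stages:
        return result
    spec_g = stats.ContrastSpec(factor="group", covariates=("mmse",),
                                fdr_alpha=config.fdr_alpha)
    spec_p = stats.ContrastSpec(factor="phenotype", covariates=("mmse",),
                                fdr_alpha=config.fdr_alpha)
    result.tract_group = stats.fit_tractwise(gfa_w, meta, spec_g)
    result.tract_phenotype = stats.fit_tractwise(gfa_w, meta, spec_p)
    log.info("tractwise: %d group-significant, %d phenotype-significant of %d",
             int(result.tract_group.table["significant"].sum()),
             int(result.tract_phenotype.table["significant"].sum()),
             len(result.tract_group.table))
    _save(result.tract_group.table, "tracts_group.tsv")
    _save(result.tract_group.posthoc, "tracts_group_posthoc.tsv")
    _save(result.tract_phenotype.table, "tracts_phenotype.tsv")
    _save(result.tract_phenotype.posthoc, "tracts_phenotype_posthoc.tsv")

    summary = gmwm.summarize_region_wm(gfa_w)
    result.gmwm_group = gmwm.fit_gmwm(summary, vol_w, meta, "group")
    result.gmwm_phenotype = gmwm.fit_gmwm(summary, vol_w, meta, "phenotype")
    _save(result.gmwm_group.fixed_effects, "gmwm_group_fixed.tsv")
    _save(result.gmwm_group.anova, "gmwm_group_anova.tsv")
    _save(result.gmwm_phenotype.fixed_effects, "gmwm_phenotype_fixed.tsv")
    _save(result.gmwm_phenotype.anova, "gmwm_phenotype_anova.tsv")

    result.micro_result = stats.global_micro_contrast(cohort.micro, meta)
    _save(result.micro_result.table, "micro_anova.tsv")
    _save(result.micro_result.posthoc, "micro_posthoc.tsv")

    # ---- topology --------------------------------------------------------
    if "topology" not in stages:
        return result
    node_labels = result.qc_report and sorted(
        {r for t in result.qc_report.retained_tracts for r in t})
    weight_tables = {
        "wscore": result.gfa_w_norm,
        "gfa": _gfa_as_weight_table(tract_table),
    }
    for source, wt in weight_tables.items():
        graphs = topology.graphs_from_wtable(wt, node_labels)
        grid = topology.build_grid(graphs, n_linear=config.grid_size,
                                   augment_mst=config.augment_mst)
        curves = topology.betti_curves(graphs, grid)
        result.graphs[source] = graphs
        result.curves[source] = curves
        _save(topology.curves_frame(curves), f"betti_curves_{source}.tsv")

    # ---- inference -------------------------------------------------------
    if "inference" not in stages:
        return result
    labels = dict(zip(meta["participant_id"], meta["group"]))
    argmax_by_source: Dict[str, float] = {}
    for source, curves in result.curves.items():
        for ga, gb in GROUP_CONTRASTS:
            for ct in ("betti0", "betti1"):
                res = inference.compare_groups(
                    curves, labels, ga, gb, curve_type=ct,
                    n_perm=config.n_perm, seed=config.seed)
                result.topo_tests.append(res)
                if (source, ga, gb, ct) == (source, "CN", "non-amnestic",
                                            "betti0"):
                    argmax_by_source[source] = res.argmax_threshold
        metrics = inference.subnetwork_betti_at(
            argmax_by_source[source], result.graphs[source])
        result.betti_metrics[source] = metrics
        _save(metrics, f"betti_metrics_{source}.tsv")
    if outdir is not None:
        io.write_json(
            {"tests": [r.to_dict() for r in result.topo_tests],
             "argmax_threshold": argmax_by_source},
            outdir / "topo_inference.json")

    # ---- clinical --------------------------------------------------------
    if "clinical" not in stages:
        return result
    for source, metrics in result.betti_metrics.items():
        blocks = [clin.regress_clinical(metrics, meta, oc, source)
                  for oc in ("mmse", "duration")]
        result.clinical_tables[source] = pd.concat(blocks, ignore_index=True)
        result.micro_correlations[source] = clin.correlate_microstructure(
            metrics, cohort.micro)
        _save(result.clinical_tables[source], f"betti_clinical_{source}.tsv")
        _save(result.micro_correlations[source],
              f"betti_micro_corr_{source}.tsv")

    if outdir is not None:
        io.write_json({"config_hash": chash, "seed": config.seed,
                       "stages": list(config.stages)},
                      outdir / "provenance.json")
    return result


# --------------------------------------------------------------------------
# subset / concordance re-analysis
# --------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    n_full: int
    n_subset: int
    shared_tracts: int
    only_full: List[str]
    only_subset: List[str]
    f_correlation_group: float
    f_correlation_phenotype: float
    concordant_group: int
    discordant_group: int
    concordant_phenotype: int
    discordant_phenotype: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def subset_cohort(cohort: Cohort, meta: pd.DataFrame) -> Cohort:
    """Drop patients without biomarker confirmation and anyone with imputed
    MMSE or disease duration."""
    keep = meta["biomarker_confirmed"].fillna(True).astype(bool) \
        & ~meta["mmse_imputed"].astype(bool) \
        & ~meta["duration_imputed"].astype(bool)
    ids = set(meta.loc[keep, "participant_id"])
    sub_meta = cohort.meta[cohort.meta["participant_id"].isin(ids)].reset_index(
        drop=True)
    return Cohort(
        meta=sub_meta,
        matrices={p: m for p, m in cohort.matrices.items() if p in ids},
        volumes=cohort.volumes[cohort.volumes["participant_id"].isin(ids)],
        micro=cohort.micro[cohort.micro["participant_id"].isin(ids)],
        template=cohort.template,
        config=cohort.config)


def _f_map(result: stats.TractStatResult) -> pd.Series:
    return result.table.set_index("target_id")["F"]


def _sig_map(result: stats.TractStatResult) -> pd.Series:
    return result.table.set_index("target_id")["significant"]


def subset_concordance(
    cohort: Cohort,
    full: PipelineResult,
    config: Optional[RunConfig] = None,
) -> Tuple[ConcordanceReport, PipelineResult]:
    """Re-run QC + w-scoring + tractwise contrasts on the biomarker-confirmed,
    non-imputed subset and compare with the full-cohort results."""
    config = config or RunConfig(stages=("qc", "wscore", "stats"))
    config = RunConfig(**{**config.__dict__, "stages": ("qc", "wscore", "stats")})
    sub = subset_cohort(cohort, full.meta)
    sub_res = run_pipeline(sub, config)

    full_g, sub_g = _f_map(full.tract_group), _f_map(sub_res.tract_group)
    full_p, sub_p = _f_map(full.tract_phenotype), _f_map(sub_res.tract_phenotype)
    shared = sorted(set(full_g.index) & set(sub_g.index))
    only_full = sorted(set(full_g.index) - set(sub_g.index))
    only_subset = sorted(set(sub_g.index) - set(full_g.index))
    if len(shared) < 3:
        raise ValueError("too few shared tracts for a concordance analysis")

    r_g = float(np.corrcoef(full_g[shared], sub_g[shared])[0, 1])
    r_p = float(np.corrcoef(full_p[shared], sub_p[shared])[0, 1])
    sig_full_g, sig_sub_g = _sig_map(full.tract_group), _sig_map(sub_res.tract_group)
    sig_full_p = _sig_map(full.tract_phenotype)
    sig_sub_p = _sig_map(sub_res.tract_phenotype)
    conc_g = int((sig_full_g[shared] == sig_sub_g[shared]).sum())
    conc_p = int((sig_full_p[shared] == sig_sub_p[shared]).sum())

    report = ConcordanceReport(
        n_full=len(full.meta), n_subset=len(sub.meta),
        shared_tracts=len(shared),
        only_full=only_full, only_subset=only_subset,
        f_correlation_group=r_g, f_correlation_phenotype=r_p,
        concordant_group=conc_g, discordant_group=len(shared) - conc_g,
        concordant_phenotype=conc_p,
        discordant_phenotype=len(shared) - conc_p)
    return report, sub_res
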