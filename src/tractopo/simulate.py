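"""Synthetic structural-connectome cohort generator.

Emulates the statistical structure the downstream analysis assumes: six
clinical phenotypes with realistic group sizes, a 152-region parcellation
with hemispheric block structure, sparse symmetric tractwise mean-GFA
matrices with per-tract presence averaging ~80%, group- and
phenotype-specific tract degeneration, linear age/sex effects, grey-matter
volumes coupled to incident-tract GFA with group-dependent slopes, and
group-shifted global white-matter microstructure (FA, MD, isotropic
diffusion).

The generator works forward from latent per-participant, per-region
grey-matter deviations: a tract's GFA carries a group-specific multiple of
the sum of its two endpoint deviations, so that the grey-matter/white-matter
coupling slope fitted downstream recovers the configured
``gm_coupling_slopes`` directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    ConnectivityMatrix,
    GROUP_OF,
    PHENOTYPES,
    group_of,
    tract_key,
)

#: Group sizes of the emulated study cohort.
DEFAULT_N_PER_PHENOTYPE: Dict[str, int] = {
    "CN": 45, "aAD": 41, "lvPPA": 32, "PCA": 17, "bvAD": 10, "CBS": 8,
}

# Per-phenotype demographic distributions (mean age, age SD, male fraction,
# MMSE mean, MMSE SD) loosely matching the published cohort summaries.
_DEMOGRAPHICS = {
    "CN": (64.4, 7.0, 0.422, 29.2, 0.9),
    "aAD": (67.0, 9.0, 0.512, 22.5, 3.5),
    "lvPPA": (63.0, 7.0, 0.500, 23.0, 4.5),
    "PCA": (58.0, 5.0, 0.294, 23.0, 4.5),
    "bvAD": (61.0, 8.0, 0.800, 19.5, 4.0),
    "CBS": (57.5, 5.0, 0.375, 19.5, 4.5),
}

# APOE e4 copy-number probabilities (0, 1, 2 copies, genotype unavailable).
_APOE_PROBS = {
    "CN": (8, 2, 2, 33),
    "aAD": (6, 18, 6, 11),
    "lvPPA": (20, 11, 0, 1),
    "PCA": (10, 4, 3, 0),
    "bvAD": (5, 5, 0, 0),
    "CBS": (1, 2, 1, 4),
}


@dataclass
class Effect:
    """A mean GFA shift, in control-SD units, on a set of tracts.

    ``target`` is a phenotype or diagnostic-group name; ``tracts`` is either
    an explicit list of canonical tract keys or a selector string
    ``"random:<n>"`` resolved deterministically from the cohort seed.
    """

    target: str
    tracts: Union[str, Sequence[Tuple[str, str]]]
    shift_sd: float


def default_effect_spec() -> List[Effect]:
    """Disease-like default: widespread non-amnestic degeneration, a more
    restricted amnestic pattern, and an extra left-lateralized lvPPA effect."""
    return [
        Effect("amnestic", "random:40", -0.5),
        Effect("non-amnestic", "random:60", -0.8),
        Effect("lvPPA", "random:20", -0.5),
    ]


@dataclass
class CohortConfig:
    """Generating conditions for a synthetic cohort."""

    n_per_phenotype: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_PHENOTYPE))
    region_count: int = 152
    intra_density: float = 0.085  # within-hemisphere candidate edge density
    inter_density: float = 0.018  # between-hemisphere candidate edge density
    presence_mean: float = 0.805
    presence_sd: float = 0.119
    effect_spec: List[Effect] = field(default_factory=default_effect_spec)
    gm_coupling_slopes: Dict[str, float] = field(
        default_factory=lambda: {"CN": 0.03, "amnestic": 0.08, "non-amnestic": 0.08})
    gm_group_shift: Dict[str, float] = field(
        default_factory=lambda: {"CN": 0.0, "amnestic": -1.0, "non-amnestic": -1.2})
    age_effect: float = -0.0008   # GFA units per year (centred at 65)
    sex_effect: float = 0.010     # GFA units, male minus female
    noise_sd: float = 0.04        # GFA units; also the control SD for effects
    vol_age_effect: float = -15.0  # mm^3 per year
    vol_sex_effect: float = 200.0  # mm^3, male minus female
    vol_icv_coef: float = 0.003    # mm^3 of regional volume per mm^3 ICV
    gm_noise_sd: float = 300.0     # mm^3; scales the latent GM deviations
    micro_means: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {
            "CN": (0.400, 7.00e-4, 0.150),
            "amnestic": (0.393, 7.20e-4, 0.160),
            "non-amnestic": (0.383, 7.45e-4, 0.175),
        })
    micro_sd: Tuple[float, float, float] = (0.012, 0.30e-4, 0.020)
    island_prob: float = 0.35      # isolation probability for island regions
    n_island_regions: int = 4
    presence_group_factor: Optional[Dict[str, float]] = None
    missing_mmse: Dict[str, int] = field(
        default_factory=lambda: {"CN": 4, "aAD": 2})
    missing_duration: Dict[str, int] = field(
        default_factory=lambda: {"lvPPA": 1})
    biomarker_unconfirmed: Dict[str, int] = field(
        default_factory=lambda: {"aAD": 11, "lvPPA": 3})
    seed: int = 0

    def validate(self) -> None:
        for ph, n in self.n_per_phenotype.items():
            if ph not in PHENOTYPES:
                raise ValueError(f"unknown phenotype in n_per_phenotype: {ph!r}")
            if n < 0:
                raise ValueError(f"negative count for phenotype {ph}")
        if self.region_count < 4:
            raise ValueError("region_count must be >= 4")
        if not (0 < self.presence_mean <= 1):
            raise ValueError("presence_mean must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for eff in self.effect_spec:
            if eff.target not in PHENOTYPES and eff.target not in GROUP_OF.values():
                raise ValueError(
                    f"effect target {eff.target!r} is neither a phenotype "
                    "nor a group")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_spec"] = [
            {"target": e.target,
             "tracts": e.tracts if isinstance(e.tracts, str)
             else [list(t) for t in e.tracts],
             "shift_sd": e.shift_sd}
            for e in self.effect_spec
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        effects = []
        for e in d.get("effect_spec", []):
            tracts = e["tracts"]
            if not isinstance(tracts, str):
                tracts = [tuple(t) for t in tracts]
            effects.append(Effect(e["target"], tracts, e["shift_sd"]))
        d["effect_spec"] = effects
        if "micro_sd" in d:
            d["micro_sd"] = tuple(d["micro_sd"])
        if "micro_means" in d:
            d["micro_means"] = {k: tuple(v) for k, v in d["micro_means"].items()}
        return cls(**d)


def region_labels(region_count: int) -> List[str]:
    """Parcellation labels split into left/right hemispheric blocks."""
    n_left = region_count // 2
    left = [f"L{i + 1:03d}" for i in range(n_left)]
    right = [f"R{i + 1:03d}" for i in range(region_count - n_left)]
    return left + right


def _beta_params(mean: float, sd: float) -> Tuple[float, float]:
    var = sd * sd
    cap = mean * (1 - mean)
    if var >= cap:  # degenerate request; fall back to a broad Beta
        var = 0.99 * cap
    if var <= 0:
        return math.inf, math.inf
    nu = cap / var - 1.0
    return mean * nu, (1 - mean) * nu


def _candidate_edges(labels: List[str], cfg: CohortConfig,
                     rng: np.random.Generator) -> List[Tuple[int, int]]:
    """Sparse candidate tract set: two dense hemispheric blocks plus sparse
    inter-hemispheric edges, so filtration topology has community structure."""
    n = len(labels)
    n_left = n // 2
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            same = (i < n_left) == (j < n_left)
            p = cfg.intra_density if same else cfg.inter_density
            if rng.random() < p:
                edges.append((i, j))
    # guarantee every region touches at least one candidate tract
    degree = np.zeros(n, dtype=int)
    for i, j in edges:
        degree[i] += 1
        degree[j] += 1
    for i in np.flatnonzero(degree == 0):
        j = int(rng.integers(0, n - 1))
        if j >= i:
            j += 1
        a, b = (i, j) if i < j else (j, i)
        edges.append((a, b))
        degree[i] += 1
        degree[j] += 1
    edges.sort()
    return edges


def _resolve_effect_tracts(
    eff: Effect,
    candidates: List[Tuple[str, str]],
    rng: np.random.Generator,
) -> List[Tuple[str, str]]:
    if isinstance(eff.tracts, str):
        kind, _, arg = eff.tracts.partition(":")
        if kind != "random":
            raise ValueError(f"unknown tract selector {eff.tracts!r}")
        n = int(arg)
        if n > len(candidates):
            raise ValueError("selector requests more tracts than exist")
        idx = rng.choice(len(candidates), size=n, replace=False)
        return [candidates[i] for i in sorted(idx)]
    resolved = []
    for a, b in eff.tracts:
        k = tract_key(a, b)
        if k not in set(candidates):
            raise ValueError(f"effect tract {k} is not a candidate tract")
        resolved.append(k)
    return resolved


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a complete synthetic cohort, deterministically from the seed.

    Returns a :class:`~tractopo.cohort.Cohort`; the attached ``config`` dict
    records the generating parameters plus the resolved ground truth
    (candidate tracts, per-effect tract sets, island regions) so tests can
    check parameter recovery against the generator's own bookkeeping.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    labels = region_labels(config.region_count)
    n_regions = len(labels)
    edge_idx = _candidate_edges(labels, config, rng)
    candidates = [tract_key(labels[i], labels[j]) for i, j in edge_idx]
    n_edges = len(edge_idx)

    # per-tract presence probability: Beta with the configured mean/SD
    a, b = _beta_params(config.presence_mean, config.presence_sd)
    if math.isinf(a):
        presence_prob = np.full(n_edges, config.presence_mean)
    else:
        presence_prob = rng.beta(a, b, size=n_edges)

    # per-tract control baseline GFA
    base_gfa = rng.uniform(0.3, 0.7, size=n_edges)

    # resolve effect tract sets and accumulate per-(phenotype, tract) shifts
    effect_truth = []
    shift = {ph: np.zeros(n_edges) for ph in PHENOTYPES}
    cand_pos = {k: i for i, k in enumerate(candidates)}
    for eff in config.effect_spec:
        tracts = _resolve_effect_tracts(eff, candidates, rng)
        phenos = ([eff.target] if eff.target in PHENOTYPES
                  else [ph for ph in PHENOTYPES if GROUP_OF[ph] == eff.target])
        for ph in phenos:
            for k in tracts:
                shift[ph][cand_pos[k]] += eff.shift_sd * config.noise_sd
        effect_truth.append({
            "target": eff.target, "shift_sd": eff.shift_sd,
            "tracts": [list(t) for t in tracts],
        })

    # island regions: chronically low-coverage parcels (the last few labels)
    island = labels[-config.n_island_regions:] if config.n_island_regions else []
    island_set = set(island)

    # regional grey-matter baseline volumes
    vol_base = rng.uniform(3000.0, 12000.0, size=n_regions)

    # ---- participants ----------------------------------------------------
    rows = []
    pid_counter = 0
    for ph in PHENOTYPES:
        n = config.n_per_phenotype.get(ph, 0)
        mean_age, sd_age, male_frac, mean_mmse, sd_mmse = _DEMOGRAPHICS[ph]
        apoe_counts = np.asarray(_APOE_PROBS[ph], dtype=float)
        apoe_p = apoe_counts / apoe_counts.sum()
        for _ in range(n):
            pid_counter += 1
            pid = f"sub-{pid_counter:04d}"
            age = float(np.clip(rng.normal(mean_age, sd_age), 45.0, 90.0))
            sex = "M" if rng.random() < male_frac else "F"
            mmse = float(np.clip(round(rng.normal(mean_mmse, sd_mmse)), 0, 30))
            if ph == "CN":
                duration = np.nan
            else:
                duration = float(np.round(rng.gamma(3.0, 1.2), 1))
            icv_mean = 1.50e6 if sex == "M" else 1.35e6
            icv = float(rng.normal(icv_mean, 1.1e5))
            apoe_draw = rng.choice(4, p=apoe_p)
            apoe = np.nan if apoe_draw == 3 else float(apoe_draw)
            rows.append({
                "participant_id": pid, "phenotype": ph, "group": group_of(ph),
                "age": age, "sex": sex, "mmse": mmse, "duration": duration,
                "icv": icv, "apoe_e4_count": apoe,
                "biomarker_confirmed": True,
                "mmse_imputed": False, "duration_imputed": False,
            })
    meta = pd.DataFrame(rows)

    # planted missingness and biomarker flags (drawn per phenotype)
    for ph, k in config.missing_mmse.items():
        idx = meta.index[meta["phenotype"] == ph]
        if k > 0 and len(idx):
            pick = rng.choice(idx, size=min(k, len(idx)), replace=False)
            meta.loc[pick, "mmse"] = np.nan
    for ph, k in config.missing_duration.items():
        idx = meta.index[meta["phenotype"] == ph]
        if k > 0 and len(idx):
            pick = rng.choice(idx, size=min(k, len(idx)), replace=False)
            meta.loc[pick, "duration"] = np.nan
    for ph, k in config.biomarker_unconfirmed.items():
        idx = meta.index[meta["phenotype"] == ph]
        if k > 0 and len(idx):
            pick = rng.choice(idx, size=min(k, len(idx)), replace=False)
            meta.loc[pick, "biomarker_confirmed"] = False

    # ---- per-participant data -------------------------------------------
    ii = np.array([e[0] for e in edge_idx], dtype=int)
    jj = np.array([e[1] for e in edge_idx], dtype=int)
    island_idx = np.array([labels.index(r) for r in island], dtype=int)

    matrices: Dict[str, ConnectivityMatrix] = {}
    vol_rows = []
    micro_rows = []
    island_truth: Dict[str, List[str]] = {r: [] for r in island}

    sd_fa, sd_md, sd_iso = config.micro_sd
    for row in meta.itertuples(index=False):
        ph = row.phenotype
        grp = row.group
        male = 1.0 if row.sex == "M" else 0.0
        slope = config.gm_coupling_slopes.get(grp, 0.0)

        # latent per-region grey-matter deviation (w-score scale)
        g = rng.normal(config.gm_group_shift.get(grp, 0.0), 1.0, size=n_regions)

        # tract presence
        p = presence_prob
        if config.presence_group_factor:
            p = np.clip(p * config.presence_group_factor.get(grp, 1.0), 0.0, 1.0)
        present = rng.random(n_edges) < p

        # island scans: region loses every tract in this scan
        if island_idx.size:
            iso = rng.random(island_idx.size) < config.island_prob
            for r_i, is_iso in zip(island_idx, iso):
                if is_iso:
                    island_truth[labels[r_i]].append(row.participant_id)
                    present &= (ii != r_i) & (jj != r_i)

        noise = rng.normal(0.0, config.noise_sd, size=n_edges) \
            if config.noise_sd > 0 else np.zeros(n_edges)
        gfa = (base_gfa
               + config.age_effect * (row.age - 65.0)
               + config.sex_effect * male
               + shift[ph]
               + slope * (g[ii] + g[jj]) * config.noise_sd
               + noise)
        gfa = np.clip(gfa, 0.0, 1.0)

        values = np.full((n_regions, n_regions), np.nan)
        sel = present
        values[ii[sel], jj[sel]] = gfa[sel]
        values[jj[sel], ii[sel]] = gfa[sel]
        matrices[row.participant_id] = ConnectivityMatrix(list(labels), values)

        vols = (vol_base
                + config.vol_icv_coef * (row.icv - 1.4e6)
                + config.vol_age_effect * (row.age - 65.0)
                + config.vol_sex_effect * male
                + config.gm_noise_sd * g)
        vols = np.clip(vols, 100.0, None)
        for r_label, v in zip(labels, vols):
            vol_rows.append({"participant_id": row.participant_id,
                             "region": r_label, "gm_volume": float(v)})

        mu_fa, mu_md, mu_iso = config.micro_means.get(
            grp, config.micro_means["CN"])
        micro_rows.append({
            "participant_id": row.participant_id,
            "mean_fa": float(np.clip(rng.normal(mu_fa, sd_fa), 0.0, 1.0)),
            "mean_md": float(max(rng.normal(mu_md, sd_md), 1e-6)),
            "mean_iso": float(max(rng.normal(mu_iso, sd_iso), 0.0)),
        })

    volumes = pd.DataFrame(vol_rows)
    micro = pd.DataFrame(micro_rows)

    # template: nonzero exactly on the candidate tracts the generator can emit
    tmpl = np.zeros((n_regions, n_regions))
    tmpl[ii, jj] = base_gfa
    tmpl[jj, ii] = base_gfa
    np.fill_diagonal(tmpl, np.nan)
    template = ConnectivityMatrix(list(labels), tmpl)

    truth = {
        "candidate_tracts": [list(t) for t in candidates],
        "presence_prob": presence_prob.tolist(),
        "base_gfa": base_gfa.tolist(),
        "effects": effect_truth,
        "island_regions": island,
        "island_scans": island_truth,
    }
    cfg_dict = config.to_dict()
    cfg_dict["_truth"] = truth

    return Cohort(meta=meta, matrices=matrices, volumes=volumes,
                  micro=micro, template=template, config=cfg_dict)
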