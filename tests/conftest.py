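"""Shared fixtures: a reduced synthetic cohort sized for fast unit tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

import tractopo as tp
from tractopo.simulate import CohortConfig, Effect


SMALL_N = {"CN": 20, "aAD": 12, "lvPPA": 10, "PCA": 8, "bvAD": 6, "CBS": 6}


def small_config(**overrides) -> CohortConfig:
    base = dict(
        n_per_phenotype=dict(SMALL_N),
        region_count=40,
        intra_density=0.25,
        inter_density=0.06,
        n_island_regions=2,
        island_prob=0.5,
        missing_mmse={"CN": 2, "aAD": 1},
        missing_duration={"lvPPA": 1},
        biomarker_unconfirmed={"aAD": 3, "lvPPA": 1},
        seed=11,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort() -> tp.Cohort:
    return tp.generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_qc(small_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrices, table, report = tp.run_qc(
            small_cohort.matrices, small_cohort.meta, small_cohort.template)
    return matrices, table, report


@pytest.fixture(scope="session")
def small_wscores(small_cohort, small_qc):
    from tractopo import wscore
    _, table, _ = small_qc
    meta = tp.impute_missing_meta(small_cohort.meta)
    wide = wscore.tracts_wide(table)
    models = wscore.fit_normative(wide, meta, wscore.GFA_COVARIATES)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt = wscore.transform(wide, meta, models, modality="gfa")
        wt = wscore.truncate(wt)
    return meta, models, wt
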