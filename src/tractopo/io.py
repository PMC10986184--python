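"""Readers and writers for the pipeline's on-disk formats.

Matrices travel as labelled CSV (region labels as header row and first
column, empty cells for missing tracts); tables as TSV with a provenance
comment header; nested results as JSON.  Everything is UTF-8 and
round-trips losslessly through its reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from .cohort import Cohort, ConnectivityMatrix

PathLike = Union[str, Path]


def provenance_header(config_hash: str, seed: Optional[int]) -> str:
    from . import __version__
    seed_txt = "none" if seed is None else str(seed)
    return f"# tractopo {__version__} config={config_hash} seed={seed_txt}\n"


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_matrix_csv(mat: ConnectivityMatrix, path: PathLike) -> None:
    mat.to_dataframe().to_csv(path, float_format="%.10g")


def read_matrix_csv(path: PathLike) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    mat = ConnectivityMatrix.from_dataframe(df)
    mat.validate()
    return mat


def write_table(
    df: pd.DataFrame, path: PathLike,
    config_hash_: str = "", seed: Optional[int] = None,
) -> None:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash_:
            fh.write(provenance_header(config_hash_, seed))
        df.to_csv(fh, sep=sep, index=False, float_format="%.10g")


def read_table(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    return pd.read_csv(path, sep=sep, comment="#",
                       float_precision="round_trip")


def write_json(obj: dict, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def read_json(path: PathLike) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# --------------------------------------------------------------------------
# whole-cohort round trip
# --------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: PathLike) -> None:
    """Write a cohort directory: metadata, matrices, volumes, microstructure,
    template, long-format tract list, and the generating-config sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "matrices").mkdir(exist_ok=True)
    cohort.meta.to_csv(outdir / "meta.csv", index=False)
    cohort.volumes.to_csv(outdir / "volumes.csv", index=False,
                          float_format="%.10g")
    cohort.micro.to_csv(outdir / "micro.csv", index=False,
                        float_format="%.10g")
    write_matrix_csv(cohort.template, outdir / "template.csv")
    long_rows = []
    for pid, mat in cohort.matrices.items():
        write_matrix_csv(mat, outdir / "matrices" / f"{pid}.csv")
        iu = np.triu_indices(mat.n_regions, k=1)
        vals = mat.values[iu]
        ok = np.isfinite(vals)
        long_rows.append(pd.DataFrame({
            "participant_id": pid,
            "region_a": [mat.labels[i] for i in iu[0][ok]],
            "region_b": [mat.labels[j] for j in iu[1][ok]],
            "gfa": vals[ok],
        }))
    pd.concat(long_rows, ignore_index=True).to_csv(
        outdir / "connections_long.tsv", sep="\t", index=False,
        float_format="%.10g")
    cfg = {k: v for k, v in cohort.config.items() if k != "_truth"}
    write_json(cfg, outdir / "config.json")


def read_cohort(indir: PathLike) -> Cohort:
    indir = Path(indir)
    meta = pd.read_csv(indir / "meta.csv", float_precision="round_trip")
    volumes = pd.read_csv(indir / "volumes.csv",
                          float_precision="round_trip")
    micro = pd.read_csv(indir / "micro.csv",
                        float_precision="round_trip")
    template = read_matrix_csv(indir / "template.csv")
    matrices: Dict[str, ConnectivityMatrix] = {}
    for f in sorted((indir / "matrices").glob("*.csv")):
        matrices[f.stem] = read_matrix_csv(f)
    config = {}
    if (indir / "config.json").exists():
        config = read_json(indir / "config.json")
    cohort = Cohort(meta=meta, matrices=matrices, volumes=volumes,
                    micro=micro, template=template, config=config)
    cohort.validate()
    return cohort
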