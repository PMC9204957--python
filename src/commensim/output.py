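"""Writers for the fixed tabular output schema.

All tables are tab-separated text with a leading ``# commensim table v1``
header line; the manifest is YAML and records the full effective config,
seed and library versions, so that any output file is byte-reproducible
from (config, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .observables import summarize
from .population import PopulationSnapshot

__all__ = ["write_table", "write_outputs", "write_manifest"]

SCHEMA_HEADER = "# commensim table v1\n"


def write_table(df: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(SCHEMA_HEADER)
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def snapshots_frame(snapshots: list[PopulationSnapshot]) -> pd.DataFrame:
    """Long-format snapshot table: time, host_id, taxon, count_or_freq."""
    rows = []
    for snap in snapshots:
        arr = snap.counts if snap.counts is not None else snap.freqs
        H, K = arr.shape
        for h in range(H):
            for k in range(K):
                rows.append((snap.time, h, k, arr[h, k]))
    return pd.DataFrame(
        rows, columns=["time", "host_id", "taxon", "count_or_freq"]
    )


def summary_frame(snapshots: list[PopulationSnapshot]) -> pd.DataFrame:
    """Long-format summary table: one row per time x statistic."""
    rows = []
    for snap in snapshots:
        s = summarize(snap)
        rows.append((snap.time, "occurrence_any", s.occurrence_any))
        rows.append((snap.time, "mean_load", s.mean_load))
        rows.append((snap.time, "load_spread", s.spread))
        for k, (occ, mf) in enumerate(zip(s.occurrence_taxon, s.mean_freq)):
            rows.append((snap.time, f"occurrence_taxon_{k}", float(occ)))
            rows.append((snap.time, f"mean_freq_taxon_{k}", float(mf)))
    return pd.DataFrame(rows, columns=["time", "statistic", "value"])


def write_manifest(config: RunConfig, path: str, extra: dict | None = None) -> None:
    manifest = {
        "schema": "commensim manifest v1",
        "config": config.to_dict(),
        "seed": int(config.seed),
        "versions": {
            "commensim": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def write_outputs(
    outdir: str,
    config: RunConfig,
    snapshots: list[PopulationSnapshot],
    lineage_tables: dict[str, pd.DataFrame] | None = None,
) -> dict[str, str]:
    """Write the standard output set; returns {name: path}."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    paths["snapshots"] = os.path.join(outdir, "snapshots.tsv")
    write_table(snapshots_frame(snapshots), paths["snapshots"])
    paths["summary"] = os.path.join(outdir, "summary.tsv")
    write_table(summary_frame(snapshots), paths["summary"])
    for name, df in (lineage_tables or {}).items():
        paths[name] = os.path.join(outdir, f"{name}.tsv")
        write_table(df, paths[name])
    paths["manifest"] = os.path.join(outdir, "manifest.yaml")
    write_manifest(config, paths["manifest"])
    return paths
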