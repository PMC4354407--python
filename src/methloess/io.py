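"""Delimited-text readers and writers for manifests, intensity matrices and lists.

Dialect is fixed: tab-separated, header row, missing values encoded as "NA".
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import ArraySet, Measure, MethylationMatrix, ProbeManifest

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"
SEP = "\t"

PathLike = Union[str, Path]


def read_manifest(path: PathLike) -> ProbeManifest:
    table = pd.read_csv(path, sep=SEP, dtype={"probe_id": str, "chromosome": str})
    if "probe_id" not in table.columns:
        raise ValueError(f"{path}: manifest needs a probe_id column")
    table = table.set_index("probe_id")
    return ProbeManifest(table[["probe_class", "chromosome", "is_cpg"]])


def write_manifest(manifest: ProbeManifest, path: PathLike) -> None:
    manifest.table.to_csv(path, sep=SEP, index_label="probe_id")


def read_matrix(path: PathLike) -> pd.DataFrame:
    """Read a probes x samples matrix; first column is probe_id."""
    df = pd.read_csv(path, sep=SEP, na_values=[NA_TOKEN], keep_default_na=False)
    df = df.set_index(df.columns[0])
    df.index.name = "probe_id"
    return df.astype(float)

def write_matrix(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep=SEP, na_rep=NA_TOKEN, index_label="probe_id", float_format="%.10g")


def read_array_set(
    m_path: PathLike,
    u_path: PathLike,
    manifest_path: PathLike,
    sample_meta_path: Optional[PathLike] = None,
) -> ArraySet:
    """Assemble an ArraySet from M/U matrix files and a manifest file.

    Matrices are reindexed to the manifest's probe order; probes absent from a
    matrix become missing.
    """
    manifest = read_manifest(manifest_path)
    m_df = read_matrix(m_path)
    u_df = read_matrix(u_path)
    if list(m_df.columns) != list(u_df.columns):
        raise ValueError("M and U matrices have different sample columns")
    m_df = m_df.reindex(manifest.probe_ids)
    u_df = u_df.reindex(manifest.probe_ids)
    meta = None
    if sample_meta_path is not None:
        meta = pd.read_csv(sample_meta_path, sep=SEP, na_values=[NA_TOKEN], keep_default_na=False)
        meta = meta.set_index("sample_id")
    return ArraySet(m_df.to_numpy(), u_df.to_numpy(), manifest, list(m_df.columns), meta)


def write_array_set(aset: ArraySet, directory: PathLike) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "M": directory / "M.tsv",
        "U": directory / "U.tsv",
        "manifest": directory / "manifest.tsv",
    }
    write_matrix(pd.DataFrame(aset.M, index=aset.probe_ids, columns=list(aset.sample_ids)), paths["M"])
    write_matrix(pd.DataFrame(aset.U, index=aset.probe_ids, columns=list(aset.sample_ids)), paths["U"])
    write_manifest(aset.manifest, paths["manifest"])
    if aset.sample_meta is not None:
        paths["samples"] = directory / "samples.tsv"
        aset.sample_meta.to_csv(paths["samples"], sep=SEP, na_rep=NA_TOKEN, index_label="sample_id")
    return paths


def read_methylation_matrix(path: PathLike, measure: Measure) -> MethylationMatrix:
    df = read_matrix(path)
    return MethylationMatrix(df.to_numpy(), measure, df.index, list(df.columns))


def write_methylation_matrix(mm: MethylationMatrix, path: PathLike) -> None:
    write_matrix(mm.as_dataframe(), path)


def read_probe_list(path: PathLike) -> list[str]:
    """One probe_id per line; '#' starts a comment; blank lines ignored."""
    ids: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    return ids


def write_probe_list(ids: Sequence[str], path: PathLike, header: str = "") -> None:
    lines = [f"# {header}"] if header else []
    lines.extend(str(i) for i in ids)
    Path(path).write_text("\n".join(lines) + "\n")


def read_key_value_config(path: PathLike) -> dict[str, str]:
    """Plain ``key = value`` configuration text; '#' comments allowed."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line (expected key = value): {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
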