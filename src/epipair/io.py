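"""Readers and writers for the pipeline's tabular formats.

Conventions: β and expression matrices are TSV with the feature id in the
first column and sample headers; sample sheets are CSV; reports are JSON;
gene sets are GMT; genomic exports are BED (0-based, half-open — manifests
are 1-based inclusive internally).  Every table written here carries a
``# epipair:`` schema comment on its first line, which the readers skip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1


def _schema_comment(kind: str) -> str:
    return f"# epipair: {kind} schema v{SCHEMA_VERSION}\n"


def write_matrix(matrix: pd.DataFrame, path, kind: str = "matrix") -> None:
    """Write a feature x sample matrix as TSV with a schema comment."""
    with open(path, "w") as fh:
        fh.write(_schema_comment(kind))
        matrix.to_csv(fh, sep="\t", index_label="feature_id")


def read_beta_matrix(path, allow_na: bool = False) -> pd.DataFrame:
    """Read and validate a β-value matrix (probes x samples TSV).

    Values must lie in [0, 1]; a violation is reported with its probe and
    sample coordinates.  Missing values are an error unless ``allow_na``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    vals = df.to_numpy(dtype=float)
    if not allow_na and np.isnan(vals).any():
        r, c = np.argwhere(np.isnan(vals))[0]
        raise ValueError(
            f"missing value at probe {df.index[r]!r}, sample "
            f"{df.columns[c]!r} (pass allow_na to accept)"
        )
    with np.errstate(invalid="ignore"):
        bad = (vals < 0) | (vals > 1)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"beta value {vals[r, c]} out of [0, 1] at probe "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return df


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes x samples log2 expression TSV."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_manifest(manifest: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_schema_comment("manifest"))
        manifest.to_csv(fh, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     keep_default_na=False, na_values=[])
    df["pos"] = df["pos"].astype(int)
    return df


def write_table(table: pd.DataFrame, path, kind: str = "table",
                index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_schema_comment(kind))
        table.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def read_probe_list(path) -> list:
    """One probe id per line; blank lines and comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_probe_list(probes, path) -> None:
    Path(path).write_text("".join(f"{p}\n" for p in probes))


def read_gmt(path) -> dict:
    """Read gene sets from GMT (name, description, members...)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict, path, description: str = "epipair") -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write genomic intervals as BED (0-based, half-open).

    Expects 1-based inclusive ``chrom/start/end`` columns plus optional
    ``direction`` (name field) and ``mean_delta_beta`` (score field).
    """
    with open(path, "w") as fh:
        for _, row in intervals.iterrows():
            name = str(row.get("direction", "."))
            score = row.get("mean_delta_beta", 0.0)
            fh.write(
                f"{row['chrom']}\t{int(row['start']) - 1}\t"
                f"{int(row['end'])}\t{name}\t{score:.4f}\n"
            )


def write_dmp_bed(dmps: pd.DataFrame, manifest: pd.DataFrame, path) -> None:
    """Export passing DMPs as single-base BED intervals."""
    ann = manifest.set_index("probe_id")
    with open(path, "w") as fh:
        for probe, row in dmps.iterrows():
            pos = int(ann.loc[probe, "pos"])
            fh.write(
                f"{ann.loc[probe, 'chrom']}\t{pos - 1}\t{pos}\t"
                f"{row['direction']}\t{row['delta_beta']:.4f}\n"
            )


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True,
                                     default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
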