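"""Readers and writers for the plain-text formats the package exchanges.

BED and bedGraph files are plain tab-separated text without headers;
expression matrices and annotation tables are TSV with a header row.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .errors import FormatError
from .intervals import as_intervals

FLOAT_FORMAT = "%.10g"


def read_bed3(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={"chrom": str})
    return as_intervals(df)


def write_bed3(df: pd.DataFrame, path) -> None:
    as_intervals(df).to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"], dtype={"chrom": str})
    df = df[~df["chrom"].astype(str).str.startswith("track")]
    track = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        if (starts >= ends).any() or (starts[1:] < ends[:-1]).any():
            raise FormatError(f"{path}: malformed bedGraph on {chrom}")
        track[chrom] = (starts, ends, grp["value"].to_numpy(float))
    return track


def write_bedgraph(track: Mapping[str, Tuple[np.ndarray, np.ndarray, np.ndarray]], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track):
            starts, ends, values = track[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x cell types matrix; first column gene id, header row of cell types."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_gene_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene", "chrom", "tss", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: gene table needs columns {sorted(required)}")
    return df


def write_gene_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, files, extra: Mapping[str, str] | None = None) -> Path:
    """Write ``manifest.txt`` with one ``sha256  relpath`` line per file."""
    out_dir = Path(out_dir)
    lines = []
    for key, value in sorted((extra or {}).items()):
        lines.append(f"# {key}: {value}")
    for f in sorted(str(Path(f).relative_to(out_dir)) for f in files):
        lines.append(f"{sha256_file(out_dir / f)}  {f}")
    path = out_dir / "manifest.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


def config_hash(obj) -> str:
    """Stable hash of a JSON-serialisable configuration object."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()
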