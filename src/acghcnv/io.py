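"""Readers and writers for the plain-text formats used by the pipeline.

All genomic records are 0-based and end-exclusive on disk and in memory:

* probe matrix: TSV with ``chrom, start, end, probe_id`` plus one column per
  sample (log2 ratios);
* SEG: ``sample, chrom, start, end, num_probes, seg_mean``;
* BED: ``chrom, start, end, name`` (tab-separated);
* GMT: one gene set per line (``term<TAB>description<TAB>gene1<TAB>...``);
* symbol lists: one symbol per line.

Every writer round-trips with its reader.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

PROBE_KEY_COLUMNS = ["chrom", "start", "end", "probe_id"]
SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_probes", "seg_mean"]
CALL_COLUMNS = ["chrom", "start", "end", "sample", "status", "num_probes", "mean_log2"]


def write_probe_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    missing = [c for c in PROBE_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe matrix is missing columns: {missing}")
    df.to_csv(path, sep="\t", index=False)


def read_probe_matrix(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBE_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe matrix is missing columns: {missing}")
    return df


def sample_columns(probe_df: pd.DataFrame) -> list[str]:
    """Sample identifier columns of a probe matrix (everything non-positional)."""
    return [c for c in probe_df.columns if c not in PROBE_KEY_COLUMNS]


def write_seg(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.loc[:, SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_seg(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calls(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_calls(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write ``chrom, start, end, name`` (plus any extra columns), no header."""
    cols = ["chrom", "start", "end", "name"]
    extra = [c for c in df.columns if c not in cols]
    df.loc[:, cols + extra].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | os.PathLike, extra_columns: Iterable[str] = ()) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", *extra_columns]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    return df


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path: str | os.PathLike) -> None:
    """``sets`` maps term id -> (description, member symbols)."""
    with open(path, "w") as fh:
        for term, (desc, members) in sets.items():
            fh.write("\t".join([term, desc, *members]) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, tuple[str, list[str]]]:
    out: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = (parts[1], parts[2:])
    return out


def write_symbol_list(symbols: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in symbols:
            fh.write(s + "\n")


def read_symbol_list(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_regions(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_regions(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
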