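"""Readers and writers for the on-disk exchange formats.

Conventions enforced at this boundary:

* Bismark-coverage TSV is 1-based inclusive; converted to internal 0-based.
* BED / bedGraph are 0-based half-open, matching the internal convention.
* Dyad TSV: sample, class, n_UU, n_MU, n_UM, n_MM.
* Long-read TSV: read_id, chrom, block_start, block_end, cpg_pos, call; rows
  with cpg_pos "." carry a block with no calls.
* LFQ TSV: protein_id + one column per sample; missing values are empty or NA.

Writers emit a ``#`` header comment with the tool version and a short config
hash; all readers skip ``#`` lines. Malformed lines raise ``ParseError`` with
the line number — records are never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    LongReadCallSet,
    MethylomeTable,
    RegionSet,
    ValidationError,
)

logger = logging.getLogger("dyadkin")

DYAD_STATES = ("UU", "MU", "UM", "MM")


class ParseError(ValueError):
    """A malformed record, reported with its line number."""


def _header(config=None) -> str:
    h = hashlib.sha1(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:10] if config is not None else "none"
    return f"# dyadkin v{__version__} config_hash={h}\n"


def _data_lines(path):
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield i, line


# ---------------------------------------------------------------------------
# Bismark coverage / bedGraph


def read_bismark_cov(path) -> MethylomeTable:
    """Read a Bismark-coverage-style TSV.

    Columns: chrom, start(1-based), end(1-based inclusive), percent_meth,
    count_M, count_U. The percent column is ignored in favour of the counts;
    zero-coverage rows are retained (their beta is NaN).
    """
    rows = []
    for i, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 6:
            raise ParseError(f"{path}:{i}: expected 6 tab-separated fields, got {len(parts)}")
        try:
            contig = parts[0]
            pos = int(parts[1]) - 1  # 1-based inclusive -> 0-based
            count_m = int(parts[4])
            count_u = int(parts[5])
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from None
        rows.append((contig, pos, count_m, count_u))
    df = pd.DataFrame(rows, columns=["contig", "pos", "count_M", "count_U"])
    return MethylomeTable(df)


def write_bismark_cov(m: MethylomeTable, path, config=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        cov = m.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(cov > 0, 100.0 * m.df["count_M"].to_numpy() / cov, 0.0)
        for (contig, pos, cm, cu), p in zip(
            m.df[["contig", "pos", "count_M", "count_U"]].itertuples(index=False), pct
        ):
            fh.write(f"{contig}\t{pos + 1}\t{pos + 1}\t{p:.6g}\t{cm}\t{cu}\n")


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph (chrom, start, end, value), 0-based half-open."""
    rows = []
    for i, line in _data_lines(path):
        if line.startswith("track"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(f"{path}:{i}: expected 4 fields, got {len(parts)}")
        try:
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from None
    return pd.DataFrame(rows, columns=["contig", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path, config=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        for row in df[["contig", "start", "end", "value"]].itertuples(index=False):
            fh.write(f"{row.contig}\t{row.start}\t{row.end}\t{row.value:.6g}\n")


# ---------------------------------------------------------------------------
# BED6


def read_bed(path) -> RegionSet:
    rows = []
    for i, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{i}: expected >=3 fields, got {len(parts)}")
        try:
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from None
        label = parts[3] if len(parts) > 3 else "."
        score = np.nan
        if len(parts) > 4 and parts[4] not in (".", ""):
            score = float(parts[4])
        if start < 0 or start >= end:
            raise ValidationError(f"{path}:{i}: invalid interval {start}-{end}")
        rows.append((contig, start, end, label, score))
    return RegionSet(pd.DataFrame(rows, columns=["contig", "start", "end", "label", "score"]))


def write_bed(regions: RegionSet, path, config=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        for row in regions.df.itertuples(index=False):
            score = "." if pd.isna(row.score) else f"{row.score:.6g}"
            fh.write(f"{row.contig}\t{row.start}\t{row.end}\t{row.label}\t{score}\t+\n")


# ---------------------------------------------------------------------------
# dyad counts


def read_dyad_tsv(path) -> pd.DataFrame:
    """Read per (sample, class) dyad-state counts."""
    rows = []
    for i, line in _data_lines(path):
        parts = line.split("\t")
        if parts[0] == "sample" and parts[1] == "class":
            continue
        if len(parts) != 6:
            raise ParseError(f"{path}:{i}: expected 6 fields, got {len(parts)}")
        try:
            rows.append((parts[0], parts[1], *(int(x) for x in parts[2:])))
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from None
    df = pd.DataFrame(rows, columns=["sample", "class", "n_UU", "n_MU", "n_UM", "n_MM"])
    if len(df) and (df[[f"n_{s}" for s in DYAD_STATES]] < 0).any().any():
        raise ValidationError("negative dyad counts")
    return df


def write_dyad_tsv(df: pd.DataFrame, path, config=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("sample\tclass\tn_UU\tn_MU\tn_UM\tn_MM\n")
        cols = ["sample", "class", "n_UU", "n_MU", "n_UM", "n_MM"]
        for row in df[cols].to_numpy():
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# long reads


def read_longread_tsv(path) -> LongReadCallSet:
    blocks, calls = [], []
    for i, line in _data_lines(path):
        parts = line.split("\t")
        if parts[0] == "read_id":
            continue
        if len(parts) != 6:
            raise ParseError(f"{path}:{i}: expected 6 fields, got {len(parts)}")
        read_id, contig = parts[0], parts[1]
        try:
            start, end = int(parts[2]), int(parts[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from None
        blocks.append((read_id, contig, start, end))
        if parts[4] != ".":
            if parts[5] not in ("M", "U"):
                raise ParseError(f"{path}:{i}: call must be M or U, got {parts[5]!r}")
            calls.append((read_id, contig, int(parts[4]), parts[5]))
    blocks_df = pd.DataFrame(
        blocks, columns=["read_id", "contig", "start", "end"]
    ).drop_duplicates(ignore_index=True)
    calls_df = pd.DataFrame(calls, columns=["read_id", "contig", "pos", "call"])
    return LongReadCallSet(blocks_df, calls_df)


def write_longread_tsv(reads: LongReadCallSet, path, config=None) -> None:
    calls_by_block = reads.calls.merge(
        reads.blocks, on=["read_id", "contig"], how="left"
    )
    calls_by_block = calls_by_block[
        (calls_by_block["pos"] >= calls_by_block["start"])
        & (calls_by_block["pos"] < calls_by_block["end"])
    ]
    keyed = calls_by_block.groupby(["read_id", "contig", "start", "end"])
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("read_id\tchrom\tblock_start\tblock_end\tcpg_pos\tcall\n")
        for row in reads.blocks.itertuples(index=False):
            key = (row.read_id, row.contig, row.start, row.end)
            try:
                sub = keyed.get_group(key)
            except KeyError:
                fh.write(f"{row.read_id}\t{row.contig}\t{row.start}\t{row.end}\t.\t.\n")
                continue
            for c in sub.sort_values("pos").itertuples(index=False):
                fh.write(
                    f"{row.read_id}\t{row.contig}\t{row.start}\t{row.end}\t{c.pos}\t{c.call}\n"
                )


# ---------------------------------------------------------------------------
# LFQ matrices


def read_lfq_tsv(path) -> pd.DataFrame:
    """Read an LFQ intensity matrix (protein_id index, sample columns)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col="protein_id")
    return df


def write_lfq_tsv(df: pd.DataFrame, path, config=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index_label="protein_id", na_rep="NA")


def read_group_map(path) -> pd.Series:
    """Read a two-column sample-to-group TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["sample", "group"])
    return df.set_index("sample")["group"]
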