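"""Core containers and interval arithmetic.

All internal coordinates are 0-based, half-open ``[start, end)``. Conversions
to 1-based formats (Bismark coverage) happen only at the I/O boundary.

The containers are thin, validated wrappers around :class:`pandas.DataFrame`
so every stage of the pipeline shares one coordinate convention and one
notion of a methylation table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("dyadkin")

REGION_COLUMNS = ["contig", "start", "end", "label", "score"]
METHYLOME_COLUMNS = ["contig", "pos", "count_M", "count_U"]


class ValidationError(ValueError):
    """A container invariant was violated."""


@dataclass
class RegionSet:
    """Labeled genomic intervals (DMRs, control regions, annotations, deletions).

    ``df`` columns: contig, start, end, label, score (extra columns are kept).
    Intervals are 0-based half-open.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df)
        for col, default in (("label", "."), ("score", np.nan)):
            if col not in df.columns:
                df[col] = default
        missing = [c for c in ("contig", "start", "end") if c not in df.columns]
        if missing:
            raise ValidationError(f"RegionSet missing columns: {missing}")
        df = df.reset_index(drop=True)
        if len(df):
            starts = df["start"].to_numpy()
            ends = df["end"].to_numpy()
            if (starts < 0).any():
                raise ValidationError("negative region start")
            if (starts >= ends).any():
                bad = int(np.argmax(starts >= ends))
                raise ValidationError(
                    f"region start >= end at row {bad}: "
                    f"{df.iloc[bad]['contig']}:{starts[bad]}-{ends[bad]}"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def sort(self) -> "RegionSet":
        return RegionSet(self.df.sort_values(["contig", "start", "end"], kind="mergesort"))

    def subset(self, mask) -> "RegionSet":
        return RegionSet(self.df.loc[mask])

    def select_label(self, label: str) -> "RegionSet":
        return RegionSet(self.df[self.df["label"] == label])

    def merged(self) -> "RegionSet":
        """Union of the intervals: overlapping/adjacent intervals collapsed."""
        rows = []
        for contig, sub in self.df.groupby("contig", sort=True):
            starts, ends = merge_intervals(
                sub["start"].to_numpy(), sub["end"].to_numpy()
            )
            rows.append(pd.DataFrame({"contig": contig, "start": starts, "end": ends}))
        if not rows:
            return RegionSet(pd.DataFrame(columns=REGION_COLUMNS))
        return RegionSet(pd.concat(rows, ignore_index=True))

    def total_length(self) -> int:
        return int(self.merged().lengths.sum())


@dataclass
class MethylomeTable:
    """Per-CpG methylated/unmethylated counts for one sample.

    CpGs are keyed by the plus-strand C position; rows are unique and sorted
    by (contig, pos). Beta = count_M / (count_M + count_U), defined only where
    coverage > 0 (undefined betas are NaN).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df)
        missing = [c for c in METHYLOME_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"MethylomeTable missing columns: {missing}")
        if len(df):
            if (df["count_M"] < 0).any() or (df["count_U"] < 0).any():
                raise ValidationError("negative methylation counts")
            key = df[["contig", "pos"]]
            if key.duplicated().any():
                raise ValidationError("duplicate (contig, pos) rows")
            if not df.sort_values(["contig", "pos"]).index.equals(df.index):
                logger.info("MethylomeTable input unsorted; sorting on load")
                df = df.sort_values(["contig", "pos"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def coverage(self) -> np.ndarray:
        return (self.df["count_M"] + self.df["count_U"]).to_numpy()

    @property
    def beta(self) -> np.ndarray:
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.df["count_M"].to_numpy() / cov, np.nan)

    def global_mean(self, min_cov: int = 1) -> float:
        """Unweighted mean beta over CpGs with coverage >= min_cov."""
        keep = self.coverage >= min_cov
        return float(np.nanmean(self.beta[keep])) if keep.any() else float("nan")


@dataclass
class LongReadCallSet:
    """Per-read aligned blocks plus per-CpG hard methylation calls.

    ``blocks``: read_id, contig, start, end (one row per aligned block,
    non-overlapping and ordered within a read).
    ``calls``: read_id, contig, pos, call in {"M", "U"}; every call position
    lies inside one of the read's blocks.
    """

    blocks: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        self.blocks = pd.DataFrame(self.blocks).reset_index(drop=True)
        self.calls = pd.DataFrame(self.calls).reset_index(drop=True)
        for col in ("read_id", "contig", "start", "end"):
            if col not in self.blocks.columns:
                raise ValidationError(f"blocks missing column {col}")
        for col in ("read_id", "contig", "pos", "call"):
            if col not in self.calls.columns:
                raise ValidationError(f"calls missing column {col}")
        if len(self.blocks):
            if (self.blocks["start"] >= self.blocks["end"]).any():
                raise ValidationError("block start >= end")
        if len(self.calls):
            bad = ~self.calls["call"].isin(["M", "U"])
            if bad.any():
                raise ValidationError(f"invalid call values: {self.calls.loc[bad, 'call'].unique()}")
        self._check_containment()

    def _check_containment(self) -> None:
        if not len(self.calls):
            return
        calls = self.calls.reset_index().rename(columns={"index": "_call_id"})
        merged = calls.merge(self.blocks, on=["read_id", "contig"], how="left")
        inside = (
            (merged["pos"] >= merged["start"]) & (merged["pos"] < merged["end"])
        ).to_numpy()
        hit = np.bincount(
            merged.loc[inside, "_call_id"].to_numpy(), minlength=len(self.calls)
        )
        if not (hit > 0).all():
            raise ValidationError("call position outside every aligned block of its read")

    @property
    def read_ids(self) -> np.ndarray:
        return self.blocks["read_id"].unique()

    def __len__(self) -> int:
        return len(self.read_ids)


@dataclass
class GenomeModel:
    """Toy genome: contigs, CpG positions, feature annotation, gap mask."""

    contigs: list  # list of (name, length)
    cpg_sites: dict  # contig -> sorted np.ndarray of plus-strand C positions
    features: RegionSet
    gap_mask: RegionSet = field(
        default_factory=lambda: RegionSet(pd.DataFrame(columns=REGION_COLUMNS))
    )

    def __post_init__(self) -> None:
        lengths = dict(self.contigs)
        for contig, sites in self.cpg_sites.items():
            sites = np.asarray(sites)
            if len(sites) and (np.diff(sites) <= 0).any():
                raise ValidationError(f"CpG positions not strictly increasing on {contig}")
            if len(sites) and (sites[-1] >= lengths.get(contig, -1) or sites[0] < 0):
                raise ValidationError(f"CpG position out of contig bounds on {contig}")
            self.cpg_sites[contig] = sites
        for rs in (self.features, self.gap_mask):
            for _, row in rs.df.iterrows():
                if row["contig"] not in lengths or row["end"] > lengths[row["contig"]]:
                    raise ValidationError(
                        f"feature {row['contig']}:{row['start']}-{row['end']} outside contig bounds"
                    )

    @property
    def contig_lengths(self) -> dict:
        return dict(self.contigs)

    def feature_classes(self) -> list:
        return sorted(self.features.df["label"].unique())


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(starts, ends):
    """Collapse intervals to their union. Returns (starts, ends) sorted."""
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def _overlap_with_sorted(q_start, q_end, b_starts, b_ends, b_cum):
    """Vectorized total overlap of query intervals with disjoint sorted intervals.

    b_cum[i] = total length of b intervals 0..i-1; b must be disjoint & sorted.
    """
    i0 = np.searchsorted(b_ends, q_start, side="right")
    i1 = np.searchsorted(b_starts, q_end, side="left")
    full = b_cum[i1] - b_cum[i0]
    has = i1 > i0
    left_clip = np.where(has, np.maximum(0, q_start - b_starts[np.minimum(i0, len(b_starts) - 1)]), 0)
    right_clip = np.where(has, np.maximum(0, b_ends[np.maximum(i1 - 1, 0)] - q_end), 0)
    return np.where(has, full - left_clip - right_clip, 0)


def intersect_length(a: RegionSet, b: RegionSet, merge_b: bool = True) -> pd.DataFrame:
    """Per-region total overlap (bp) of ``a`` with ``b``.

    ``b`` is self-merged first by default so overlapping b-intervals are not
    double counted. With ``merge_b=False`` overlaps count multiplicity (used
    for read-depth computation from alignment blocks).
    """
    out = np.zeros(len(a), dtype=np.int64)
    a_df = a.df
    for contig, sub_b in b.df.groupby("contig", sort=False):
        sel = a_df["contig"] == contig
        if not sel.any():
            continue
        bs = sub_b["start"].to_numpy()
        be = sub_b["end"].to_numpy()
        qs = a_df.loc[sel, "start"].to_numpy()
        qe = a_df.loc[sel, "end"].to_numpy()
        if merge_b:
            bs, be = merge_intervals(bs, be)
            cum = np.concatenate([[0], np.cumsum(be - bs)])
            out[sel.to_numpy()] = _overlap_with_sorted(qs, qe, bs, be, cum)
        else:
            # multiplicity-preserving: sum clipped overlaps per query
            order = np.argsort(bs, kind="mergesort")
            bs, be = bs[order], be[order]
            acc = np.zeros(sel.sum(), dtype=np.int64)
            for s, e in zip(bs, be):
                acc += np.maximum(0, np.minimum(qe, e) - np.maximum(qs, s))
            out[sel.to_numpy()] = acc
    res = a.df[["contig", "start", "end", "label"]].copy()
    res["overlap_bp"] = out
    return res


def region_mean_methylation(
    m: MethylomeTable,
    regions: RegionSet,
    min_cov: int = 1,
    min_cpgs: int = 1,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-region methylation mean over sufficiently covered CpGs.

    Default is the unweighted mean of per-CpG betas over CpGs with coverage >=
    ``min_cov``; with ``pooled=True`` counts are pooled before dividing. The
    mean is NaN (undefined) when fewer than ``min_cpgs`` CpGs qualify.
    """
    if min_cov < 1:
        raise ValidationError("min_cov must be >= 1")
    cov = m.coverage
    keep = cov >= min_cov
    sub = m.df[keep]
    beta = m.beta[keep]

    n_out = np.zeros(len(regions), dtype=int)
    mean_out = np.full(len(regions), np.nan)
    for contig, idx in regions.df.groupby("contig", sort=False).groups.items():
        msk = sub["contig"] == contig
        pos = sub.loc[msk, "pos"].to_numpy()
        b = beta[msk.to_numpy()]
        cm = sub.loc[msk, "count_M"].to_numpy()
        cu = sub.loc[msk, "count_U"].to_numpy()
        cum_b = np.concatenate([[0.0], np.cumsum(b)])
        cum_m = np.concatenate([[0], np.cumsum(cm)])
        cum_t = np.concatenate([[0], np.cumsum(cm + cu)])
        starts = regions.df.loc[idx, "start"].to_numpy()
        ends = regions.df.loc[idx, "end"].to_numpy()
        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, ends, side="left")
        n = i1 - i0
        loc = regions.df.index.get_indexer(idx)
        n_out[loc] = n
        ok = n >= min_cpgs
        if pooled:
            tot = cum_t[i1] - cum_t[i0]
            ok = ok & (tot > 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = (cum_m[i1] - cum_m[i0]) / np.where(tot > 0, tot, 1)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = (cum_b[i1] - cum_b[i0]) / np.where(n > 0, n, 1)
        mean_out[loc] = np.where(ok, vals, np.nan)
    res = regions.df[["contig", "start", "end", "label"]].copy()
    res["n_cpgs_used"] = n_out
    res["mean_beta"] = mean_out
    return res
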