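"""Long-read cross-validation of WGBS DMRs.

Long single-molecule reads map uniquely across repeats and carry direct
methylation calls, so they serve three roles here: detecting sample-specific
deletions relative to the reference (whose CpGs are then masked out of DMR
calling), recomputing region methylation independently of bisulfite
short reads, and checking for mapping bias by normalising DMR read depth to
the depth over each DMR's own control regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    GenomeModel,
    LongReadCallSet,
    MethylomeTable,
    RegionSet,
    ValidationError,
    intersect_length,
)

_EMPTY_REGIONS = lambda: RegionSet(  # noqa: E731
    pd.DataFrame(columns=["contig", "start", "end", "label", "score"])
)


def detect_deletions(
    reads: LongReadCallSet,
    genome: GenomeModel | None = None,
    min_span_support: int = 5,
    max_internal_reads: int = 0,
) -> RegionSet:
    """Detect deletions from alignment gaps within reads.

    A candidate interval is called when at least ``min_span_support`` reads
    have an alignment gap covering the whole interval and at most
    ``max_internal_reads`` reads have any aligned block inside it.
    """
    blocks = reads.blocks.sort_values(["read_id", "contig", "start"])
    # gaps between consecutive blocks of the same read
    gaps = []
    for (read_id, contig), sub in blocks.groupby(["read_id", "contig"], sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for g_start, g_end in zip(ends[:-1], starts[1:]):
            if g_end > g_start:
                gaps.append((contig, int(g_start), int(g_end), read_id))
    if not gaps:
        return _EMPTY_REGIONS()
    gaps_df = pd.DataFrame(gaps, columns=["contig", "start", "end", "read_id"])

    calls = []
    for (contig, start, end), sub in gaps_df.groupby(["contig", "start", "end"]):
        # support: gaps fully covering [start, end) -- identical plus supersets
        covering = gaps_df[
            (gaps_df["contig"] == contig)
            & (gaps_df["start"] <= start)
            & (gaps_df["end"] >= end)
        ]["read_id"].nunique()
        if covering < min_span_support:
            continue
        internal = blocks[
            (blocks["contig"] == contig)
            & (blocks["start"] < end)
            & (blocks["end"] > start)
        ]["read_id"].nunique()
        if internal > max_internal_reads:
            continue
        calls.append(
            {
                "contig": contig,
                "start": start,
                "end": end,
                "label": f"del_{contig}_{start}",
                "score": covering,
                "n_spanning_gap_reads": covering,
                "n_internal_reads": internal,
            }
        )
    if not calls:
        return _EMPTY_REGIONS()
    out = RegionSet(pd.DataFrame(calls)).sort()
    # keep maximal intervals: drop calls strictly contained in another call
    df = out.df
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        contained = (
            (df["contig"] == row["contig"])
            & (df["start"] <= row["start"])
            & (df["end"] >= row["end"])
            & (df.index != i)
            & ((df["start"] < row["start"]) | (df["end"] > row["end"]))
        )
        if contained.any():
            keep[df.index.get_loc(i)] = False
    return RegionSet(df[keep])


def mask_cpgs(methylome, deletions: RegionSet):
    """Remove CpGs inside deletions (half-open intervals).

    ``methylome`` may be a MethylomeTable or a dict of contig -> positions.
    Returns (filtered, report) where report holds n_removed, n_regions and
    total bp masked.
    """
    merged = deletions.merged().df
    bp = int((merged["end"] - merged["start"]).sum()) if len(merged) else 0

    def _mask_positions(contig, pos):
        keep = np.ones(len(pos), dtype=bool)
        sub = merged[merged["contig"] == contig]
        for _, d in sub.iterrows():
            keep &= ~((pos >= d["start"]) & (pos < d["end"]))
        return keep

    if isinstance(methylome, MethylomeTable):
        keep_all = np.ones(len(methylome), dtype=bool)
        for contig, idx in methylome.df.groupby("contig").groups.items():
            pos = methylome.df.loc[idx, "pos"].to_numpy()
            keep_all[methylome.df.index.get_indexer(idx)] = _mask_positions(contig, pos)
        filtered = MethylomeTable(methylome.df[keep_all])
        n_removed = int((~keep_all).sum())
    else:
        filtered = {}
        n_removed = 0
        for contig, pos in methylome.items():
            pos = np.asarray(pos)
            keep = _mask_positions(contig, pos)
            filtered[contig] = pos[keep]
            n_removed += int((~keep).sum())
    report = {"n_removed": n_removed, "n_regions": len(merged), "bp_masked": bp}
    return filtered, report


def nanopore_region_methylation(
    reads: LongReadCallSet, regions: RegionSet, min_cpgs: int = 10
) -> pd.DataFrame:
    """Per-region mean methylation from long-read calls.

    Per CpG, beta = M calls / total calls pooled over reads; the region mean
    averages CpGs with at least one call and is NaN (undefined) when fewer
    than ``min_cpgs`` such CpGs exist.
    """
    if min_cpgs < 1:
        raise ValidationError("min_cpgs must be >= 1")
    calls = reads.calls
    out = regions.df[["contig", "start", "end", "label"]].copy()
    n_cpgs = np.zeros(len(out), dtype=int)
    means = np.full(len(out), np.nan)
    by_contig = {}
    for contig, sub in calls.groupby("contig"):
        pos = sub["pos"].to_numpy()
        is_m = (sub["call"] == "M").to_numpy().astype(int)
        upos, inv = np.unique(pos, return_inverse=True)
        n = np.bincount(inv)
        n_m = np.bincount(inv, weights=is_m)
        cum_beta = np.concatenate([[0.0], np.cumsum(n_m / n)])
        by_contig[contig] = (upos, cum_beta)
    for i, (_, r) in enumerate(out.iterrows()):
        per_cpg = by_contig.get(r["contig"])
        if per_cpg is None:
            continue
        upos, cum_beta = per_cpg
        i0, i1 = np.searchsorted(upos, (r["start"], r["end"]))
        n_cpgs[i] = i1 - i0
        if i1 - i0 >= min_cpgs:
            means[i] = (cum_beta[i1] - cum_beta[i0]) / (i1 - i0)
    out["n_cpgs_covered"] = n_cpgs
    out["mean_beta"] = means
    return out


@dataclass
class FilterReport:
    """Exact partition of input DMRs after the long-read confidence filter."""

    input_dmrs: RegionSet
    excluded_low_delta: RegionSet
    excluded_uncovered: RegionSet
    retained: RegionSet
    retained_uncovered_flags: np.ndarray = field(default_factory=lambda: np.array([]))
    table: pd.DataFrame | None = None

    def check_partition(self) -> bool:
        return len(self.input_dmrs) == (
            len(self.excluded_low_delta) + len(self.excluded_uncovered) + len(self.retained)
        )


def high_confidence_filter(
    dmrs: RegionSet,
    baseline_means: pd.DataFrame,
    sample_means: pd.DataFrame,
    min_delta: float = 0.05,
    uncovered: str = "retain",
) -> FilterReport:
    """Filter DMRs by the long-read methylation difference.

    A DMR whose long-read delta (sample - baseline) is below ``min_delta`` is
    excluded (delta exactly equal to ``min_delta`` is retained: the rule is
    "difference of less than min_delta" excluded). DMRs with an undefined
    mean in either sample are retained with an uncovered flag by default
    ("retained if covered" semantics); ``uncovered="exclude"`` drops them
    into the excluded_uncovered partition instead.

    ``baseline_means``/``sample_means`` are outputs of
    :func:`nanopore_region_methylation` aligned to ``dmrs`` by label.
    """
    if uncovered not in ("retain", "exclude"):
        raise ValidationError("uncovered must be 'retain' or 'exclude'")
    b = baseline_means.set_index("label")["mean_beta"]
    s = sample_means.set_index("label")["mean_beta"]
    labels = dmrs.df["label"]
    if not labels.isin(b.index).all() or not labels.isin(s.index).all():
        missing = labels[~(labels.isin(b.index) & labels.isin(s.index))].tolist()[:5]
        raise ValidationError(f"mean tables do not cover all DMRs (e.g. {missing})")
    delta = s.loc[labels].to_numpy() - b.loc[labels].to_numpy()
    defined = ~np.isnan(delta)
    with np.errstate(invalid="ignore"):
        low = defined & (delta < min_delta)
    if uncovered == "retain":
        retained_mask = ~low
        uncov_mask = np.zeros(len(dmrs), dtype=bool)
    else:
        retained_mask = defined & ~low
        uncov_mask = ~defined
    table = dmrs.df[["contig", "start", "end", "label"]].copy()
    table["nanopore_baseline"] = b.loc[labels].to_numpy()
    table["nanopore_sample"] = s.loc[labels].to_numpy()
    table["delta"] = delta
    table["partition"] = np.where(
        low, "excluded_low_delta", np.where(uncov_mask, "excluded_uncovered", "retained")
    )
    table["uncovered_flag"] = ~defined
    report = FilterReport(
        input_dmrs=dmrs,
        excluded_low_delta=dmrs.subset(low),
        excluded_uncovered=dmrs.subset(uncov_mask),
        retained=dmrs.subset(retained_mask),
        retained_uncovered_flags=(~defined)[retained_mask],
        table=table,
    )
    assert report.check_partition()
    return report


def region_read_depth(reads: LongReadCallSet, regions: RegionSet) -> np.ndarray:
    """Mean aligned-block depth per region (overlap bp / region length)."""
    blocks = RegionSet(
        reads.blocks.rename(columns={"read_id": "label"})[["contig", "start", "end", "label"]]
    )
    ov = intersect_length(regions, blocks, merge_b=False)
    return (ov["overlap_bp"] / (ov["end"] - ov["start"])).to_numpy()


def coverage_normalization(
    reads: LongReadCallSet, dmrs: RegionSet, crs: RegionSet
) -> pd.DataFrame:
    """Per-DMR depth normalised to the mean depth over its own CRs.

    CRs are matched to DMRs by label. A ratio near 1 indicates no mapping
    bias at DMRs; zero CR depth yields an undefined (NaN) ratio, reported.
    """
    dmr_depth = region_read_depth(reads, dmrs)
    cr_depth = region_read_depth(reads, crs)
    cr_mean = pd.Series(cr_depth).groupby(crs.df["label"].to_numpy()).mean()
    out = dmrs.df[["contig", "start", "end", "label"]].copy()
    out["dmr_depth"] = dmr_depth
    out["cr_depth"] = cr_mean.reindex(out["label"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio"] = np.where(out["cr_depth"] > 0, out["dmr_depth"] / out["cr_depth"], np.nan)
    return out
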