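"""Pairwise methylome comparison: fixed genomic windows, per-element deltas,
gain/loss classification, and read-level methylation classes.

A unit (window or annotated element) is *defined* when both methylomes yield
a mean beta over it; undefined units are excluded from summary denominators
and the exclusion count is reported.
"""

from __future__ import annotations

import logging
import operator

import numpy as np
import pandas as pd

from .core import MethylomeTable, RegionSet, ValidationError, region_mean_methylation

logger = logging.getLogger("dyadkin")


def tile_windows(contig_lengths: dict, window_bp: int = 5000) -> RegionSet:
    """Non-overlapping tiling from position 0; last window may be short."""
    if window_bp < 1:
        raise ValidationError("window_bp must be >= 1")
    rows = []
    for contig, length in contig_lengths.items():
        starts = np.arange(0, length, window_bp)
        ends = np.minimum(starts + window_bp, length)
        for s, e in zip(starts, ends):
            rows.append((contig, int(s), int(e), f"{contig}:{s}-{e}"))
    return RegionSet(pd.DataFrame(rows, columns=["contig", "start", "end", "label"]))


def window_means(
    m: MethylomeTable,
    window_bp: int = 5000,
    contig_lengths: dict | None = None,
    min_cov: int = 1,
) -> pd.DataFrame:
    """Mean methylation in fixed windows tiled from 0.

    Windows with no covered CpG have mean NaN and are excluded from any
    downstream fraction. When contig lengths are not given they are inferred
    as the last CpG position + 1.
    """
    if contig_lengths is None:
        contig_lengths = {
            contig: int(sub["pos"].max()) + 1 for contig, sub in m.df.groupby("contig")
        }
    windows = tile_windows(contig_lengths, window_bp)
    return region_mean_methylation(m, windows, min_cov=min_cov, min_cpgs=1)


def classify_delta(
    a: MethylomeTable,
    b: MethylomeTable,
    units: RegionSet,
    threshold: float = 0.05,
    min_cov: int = 1,
    min_cpgs: int = 1,
    comparator: str = "gt",
) -> tuple[pd.DataFrame, dict]:
    """Per-unit delta = mean(b) - mean(a) and gain/loss classification.

    gain iff delta > threshold, loss iff delta < -threshold (strict by
    default; ``comparator="ge"`` makes the boundary inclusive). Returns the
    per-unit table and summary fractions over defined units.
    """
    contigs_a = set(a.df["contig"].unique())
    contigs_b = set(b.df["contig"].unique())
    if contigs_a and contigs_b and not (contigs_a & contigs_b):
        raise ValidationError(
            f"methylomes share no contigs: {sorted(contigs_a)[:3]} vs {sorted(contigs_b)[:3]}"
        )
    op = {"gt": operator.gt, "ge": operator.ge}[comparator]
    ma = region_mean_methylation(a, units, min_cov=min_cov, min_cpgs=min_cpgs)
    mb = region_mean_methylation(b, units, min_cov=min_cov, min_cpgs=min_cpgs)
    table = ma.rename(columns={"mean_beta": "mean_a", "n_cpgs_used": "n_cpgs_a"}).copy()
    table["mean_b"] = mb["mean_beta"].to_numpy()
    table["n_cpgs_b"] = mb["n_cpgs_used"].to_numpy()
    table["delta"] = table["mean_b"] - table["mean_a"]
    defined = table["delta"].notna().to_numpy()
    delta = table["delta"].to_numpy()
    cls = np.full(len(table), "undefined", dtype=object)
    with np.errstate(invalid="ignore"):
        cls[defined & op(delta, threshold)] = "gain"
        cls[defined & op(-delta, threshold)] = "loss"
        cls[defined & (cls == "undefined")] = "unchanged"
    table["class"] = cls
    n_def = int(defined.sum())
    if (~defined).any():
        logger.info("classify_delta: %d undefined units excluded", int((~defined).sum()))
    summary = {
        "n_units": len(table),
        "n_defined": n_def,
        "n_undefined": len(table) - n_def,
        "frac_gain": float((cls == "gain").sum() / n_def) if n_def else float("nan"),
        "frac_loss": float((cls == "loss").sum() / n_def) if n_def else float("nan"),
        "frac_unchanged": float((cls == "unchanged").sum() / n_def) if n_def else float("nan"),
    }
    return table, summary


def read_level_classes(reads, region: RegionSet, min_calls: int = 1) -> dict:
    """Fractions of fully unmethylated / partially methylated / fully
    methylated reads over a region.

    ``reads`` is a LongReadCallSet (or anything with a ``calls`` DataFrame of
    read_id, contig, pos, call). A read counts only when it has at least
    ``min_calls`` calls inside the region; fully_unmethylated means zero M
    calls among them.
    """
    if min_calls < 1:
        raise ValidationError("min_calls must be >= 1")
    calls = reads.calls if hasattr(reads, "calls") else reads
    counts = {"fully_unmethylated": 0, "partially_methylated": 0, "fully_methylated": 0}
    n_reads = 0
    for _, r in region.df.iterrows():
        sub = calls[
            (calls["contig"] == r["contig"])
            & (calls["pos"] >= r["start"])
            & (calls["pos"] < r["end"])
        ]
        for _, g in sub.groupby("read_id"):
            if len(g) < min_calls:
                continue
            n_m = (g["call"] == "M").sum()
            n_reads += 1
            if n_m == 0:
                counts["fully_unmethylated"] += 1
            elif n_m == len(g):
                counts["fully_methylated"] += 1
            else:
                counts["partially_methylated"] += 1
    fracs = {
        k: (v / n_reads if n_reads else float("nan")) for k, v in counts.items()
    }
    fracs["n_reads"] = n_reads
    return fracs
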