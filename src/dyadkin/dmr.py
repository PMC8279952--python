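"""Focal differentially-methylated-region calling, length-matched random
control regions, and repeat-class enrichment testing.

The caller slides a window of ``min_cpgs_per_window`` consecutive covered
CpGs (step 1), tests pooled counts between the two samples with a
two-proportion z-test, adjusts across windows by Benjamini-Hochberg, and
merges significant gain windows separated by at most ``merge_gap_bp``.
A merged region is reported when it holds at least ``min_region_cpgs``
covered CpGs and its unweighted mean-beta delta reaches ``min_delta``.

Control regions (CRs) are the matched null: for every DMR,
``n_per_dmr`` regions of identical length placed uniformly at random over
the non-gap genome, overlaps allowed. Enrichment of a feature class in DMRs
over CRs is a one-sided rank-sum (Mann-Whitney) test on the per-region
overlap fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GenomeModel,
    MethylomeTable,
    RegionSet,
    ValidationError,
    intersect_length,
    merge_intervals,
)


@dataclass
class DmrParams:
    min_cpgs_per_window: int = 5
    min_cov: int = 5
    min_delta: float = 0.1
    fdr_q: float = 0.05
    merge_gap_bp: int = 250
    min_region_cpgs: int = 10

    def __post_init__(self):
        if min(self.min_cpgs_per_window, self.min_cov, self.merge_gap_bp, self.min_region_cpgs) < 1:
            raise ValidationError("DmrParams fields must be positive")
        if not (0 < self.min_delta <= 1):
            raise ValidationError("min_delta must be in (0, 1]")
        if not (0 < self.fdr_q < 1):
            raise ValidationError("fdr_q must be in (0, 1)")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _two_proportion_p(m1, n1, m2, n2):
    """Two-sided two-proportion z-test on pooled counts (vectorized)."""
    p1 = m1 / n1
    p2 = m2 / n2
    pooled = (m1 + m2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (p2 - p1) / np.sqrt(np.where(var > 0, var, 1)), 0.0)
    return 2 * stats.norm.sf(np.abs(z)), p2 - p1


def call_dmrs(
    baseline: MethylomeTable, sample: MethylomeTable, params: DmrParams | None = None
) -> RegionSet:
    """Call gain DMRs of ``sample`` over ``baseline``.

    Returned regions are disjoint and sorted; each carries mean_baseline,
    mean_sample, delta and n_cpgs columns.
    """
    params = params or DmrParams()
    joined = baseline.df.merge(
        sample.df, on=["contig", "pos"], suffixes=("_b", "_s"), how="inner"
    )
    joined["cov_b"] = joined["count_M_b"] + joined["count_U_b"]
    joined["cov_s"] = joined["count_M_s"] + joined["count_U_s"]
    joined = joined[(joined["cov_b"] >= params.min_cov) & (joined["cov_s"] >= params.min_cov)]
    if not len(joined):
        raise ValidationError("no CpG covered >= min_cov in both samples")

    w = params.min_cpgs_per_window
    win_rows = []
    for contig, sub in joined.groupby("contig", sort=True):
        sub = sub.sort_values("pos")
        n = len(sub)
        if n < w:
            continue
        pos = sub["pos"].to_numpy()
        mb = np.concatenate([[0], np.cumsum(sub["count_M_b"].to_numpy())])
        nb = np.concatenate([[0], np.cumsum(sub["cov_b"].to_numpy())])
        ms = np.concatenate([[0], np.cumsum(sub["count_M_s"].to_numpy())])
        ns = np.concatenate([[0], np.cumsum(sub["cov_s"].to_numpy())])
        i = np.arange(n - w + 1)
        p, delta = _two_proportion_p(
            mb[i + w] - mb[i], nb[i + w] - nb[i], ms[i + w] - ms[i], ns[i + w] - ns[i]
        )
        win_rows.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "start": pos[i],
                    "end": pos[i + w - 1] + 2,  # include last CpG dinucleotide
                    "p": p,
                    "delta": delta,
                }
            )
        )
    if not win_rows:
        return RegionSet(pd.DataFrame(columns=["contig", "start", "end", "label", "score"]))
    windows = pd.concat(win_rows, ignore_index=True)
    windows["q"] = _bh_adjust(windows["p"].to_numpy())
    sig = windows[
        (windows["q"] < params.fdr_q) & (windows["delta"] >= params.min_delta)
    ]
    if not len(sig):
        return RegionSet(pd.DataFrame(columns=["contig", "start", "end", "label", "score"]))

    # merge significant windows separated by <= merge_gap_bp
    regions = []
    for contig, sub in sig.groupby("contig", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        s, e = merge_intervals(starts, ends + params.merge_gap_bp)
        e = e - params.merge_gap_bp
        # trimming the padding can leave e < original window end; clip to data
        for ss, ee in zip(s, e):
            regions.append((contig, int(ss), int(max(ee, ss + 2))))

    # per-region stats and filters
    out = []
    for contig, start, end in regions:
        sub = joined[
            (joined["contig"] == contig) & (joined["pos"] >= start) & (joined["pos"] < end)
        ]
        n_cpgs = len(sub)
        if n_cpgs < params.min_region_cpgs:
            continue
        mean_b = float((sub["count_M_b"] / sub["cov_b"]).mean())
        mean_s = float((sub["count_M_s"] / sub["cov_s"]).mean())
        delta = mean_s - mean_b
        if delta < params.min_delta:
            continue
        out.append(
            {
                "contig": contig,
                "start": start,
                "end": end,
                "label": f"DMR_{contig}_{start}",
                "score": delta,
                "mean_baseline": mean_b,
                "mean_sample": mean_s,
                "delta": delta,
                "n_cpgs": n_cpgs,
            }
        )
    cols = [
        "contig", "start", "end", "label", "score",
        "mean_baseline", "mean_sample", "delta", "n_cpgs",
    ]
    df = pd.DataFrame(out, columns=cols)
    return RegionSet(df).sort()


def generate_control_regions(
    dmrs: RegionSet, genome: GenomeModel, n_per_dmr: int = 1000, seed: int = 0
) -> RegionSet:
    """Length-matched, randomly placed control regions (CRs).

    Exactly ``n_per_dmr`` CRs per DMR, each of identical length to its source
    DMR, placed uniformly at random over the non-gap genome (overlaps among
    CRs are allowed). Each CR's label is its source DMR's label.
    """
    rng = np.random.default_rng(seed)
    # allowed placement space: contigs minus gap mask
    segments = []
    gap = genome.gap_mask.merged().df
    for contig, length in genome.contigs:
        sub = gap[gap["contig"] == contig]
        prev = 0
        for _, g in sub.sort_values("start").iterrows():
            if g["start"] > prev:
                segments.append((contig, prev, int(g["start"])))
            prev = max(prev, int(g["end"]))
        if prev < length:
            segments.append((contig, prev, length))
    seg_len = np.array([e - s for _, s, e in segments])

    rows = []
    for _, d in dmrs.df.iterrows():
        L = int(d["end"] - d["start"])
        slots = seg_len - L + 1
        ok = slots > 0
        if not ok.any():
            raise ValidationError(f"DMR {d['label']} (len {L}) cannot be placed anywhere")
        weights = np.where(ok, slots, 0).astype(float)
        weights /= weights.sum()
        seg_idx = rng.choice(len(segments), size=n_per_dmr, p=weights)
        offsets = rng.integers(0, slots[seg_idx])
        for si, off in zip(seg_idx, offsets):
            contig, s, _ = segments[si]
            rows.append((contig, s + int(off), s + int(off) + L, d["label"]))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "label"])
    return RegionSet(df)


def class_overlap_fractions(
    regions: RegionSet, features: RegionSet, class_label: str
) -> np.ndarray:
    """Per-region fraction of length overlapped by a (merged) feature class."""
    cls = features.select_label(class_label)
    ov = intersect_length(regions, cls, merge_b=True)
    return (ov["overlap_bp"] / (ov["end"] - ov["start"])).to_numpy()


@dataclass
class EnrichmentResult:
    feature_class: str
    statistic: float  # Mann-Whitney U (first sample = DMRs)
    p_value: float
    effect_size: float  # common-language: P(DMR frac > CR frac) + 0.5 P(=)
    n_dmr: int
    n_cr: int
    method: str
    direction: str = "greater"


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _exact_rank_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact one-sided rank-sum p by enumeration over all rank assignments.

    Valid with ties (midranks). Feasible for min(n, m) <= 8-ish.
    """
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n, m = len(x), len(y)
    obs = ranks[:n].sum()
    total = comb(n + m, n)
    count = 0
    for idx in combinations(range(n + m), n):
        if ranks[list(idx)].sum() >= obs - 1e-9:
            count += 1
    u = obs - n * (n + 1) / 2
    return u, count / total


def enrichment_test(dmr_fracs, cr_fracs, small_n: int = 8) -> EnrichmentResult:
    """One-sided rank-sum test: DMR overlap fractions stochastically greater
    than CR fractions. Small samples (min n <= ``small_n``) use exact
    enumeration with midranks; larger samples use the tie-corrected normal
    approximation."""
    x = np.asarray(dmr_fracs, dtype=float)
    y = np.asarray(cr_fracs, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("empty fraction vector")
    if min(len(x), len(y)) <= small_n:
        u, p = _exact_rank_p(x, y)
        method = "exact-enumeration"
    else:
        if np.ptp(np.concatenate([x, y])) == 0:
            # degenerate: all values identical; every labelling is equivalent
            u = len(x) * len(y) / 2
            p = 1.0
            method = "degenerate"
        else:
            res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
            method = "normal-approximation"
    effect = u / (len(x) * len(y))
    return EnrichmentResult(
        feature_class="",
        statistic=float(u),
        p_value=float(p),
        effect_size=float(effect),
        n_dmr=len(x),
        n_cr=len(y),
        method=method,
    )


def enrichment_table(
    dmrs: RegionSet, crs: RegionSet, features: RegionSet, classes=None
) -> pd.DataFrame:
    """Enrichment test per feature class; convenience over the full pipeline."""
    if classes is None:
        classes = sorted(features.df["label"].unique())
    rows = []
    for cls in classes:
        d = class_overlap_fractions(dmrs, features, cls)
        c = class_overlap_fractions(crs, features, cls)
        r = enrichment_test(d, c)
        rows.append(
            {
                "class": cls,
                "U": r.statistic,
                "p_value": r.p_value,
                "effect_size": r.effect_size,
                "mean_dmr_frac": float(d.mean()),
                "mean_cr_frac": float(c.mean()),
                "method": r.method,
            }
        )
    return pd.DataFrame(rows)
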