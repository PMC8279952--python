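"""Synthetic data generators emulating the study designs.

Everything downstream is testable without downloads: a toy genome with a
retrotransposon-like annotation (IAPEz-int internal elements, IAP LTRs,
ERV1, LINE, SINE, CpG islands, genes, intergenic space and unplaceable
gaps), bisulfite count tables over it, a passage series whose dyad counts
are multinomial draws from the kinetics model in :mod:`dyadkin.kinetics`
(the single source of truth for the transition law), long reads with
sample-specific deletions, and an LFQ matrix with spiked interactors and
missing-not-at-random dropout.

Every generator is deterministic given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeModel, LongReadCallSet, MethylomeTable, RegionSet
from .kinetics import (
    observation_matrix,
    strand_marginals,
    transition_matrix,
)

FEATURE_CLASSES = ("IAPEz_int", "IAP_LTR", "ERV1", "LINE", "SINE", "CGI", "gene")


class ConfigError(ValueError):
    pass


@dataclass
class LfqSpec:
    n_proteins: int = 1000
    n_spiked: int = 20
    effect_log2: float = 4.0
    n_reps: int = 3
    base_mean: float = 26.0
    base_sd: float = 2.5
    noise_sd: float = 0.3
    dropout_midpoint: float = 22.5
    dropout_steepness: float = 1.0
    dropout_max: float = 1.0  # 0 disables dropout entirely


@dataclass
class SimulationConfig:
    seed: int = 0
    contig_length: int = 2_000_000
    coverage_mean: float = 30.0
    conversion_failure: float = 0.005  # e: U read as M
    inappropriate_conversion: float = 0.005  # c: M read as U
    read_length_median: int = 25_000
    read_length_sigma: float = 0.5
    call_error: float = 0.01
    n_reads: int = 2000
    deletion_spec: list = field(default_factory=list)  # (contig, start, end, samples)
    lfq: LfqSpec = field(default_factory=LfqSpec)
    # feature layout
    n_features: dict = field(
        default_factory=lambda: {
            "IAPEz_int": 30, "IAP_LTR": 25, "ERV1": 15, "LINE": 30,
            "SINE": 40, "CGI": 30, "gene": 20,
        }
    )
    n_gaps: int = 2
    gap_length: int = 10_000
    # CpGs per bp by class
    cpg_density: dict = field(
        default_factory=lambda: {
            "IAPEz_int": 0.012, "IAP_LTR": 0.012, "ERV1": 0.01, "LINE": 0.01,
            "SINE": 0.01, "CGI": 0.06, "gene": 0.01, "intergenic": 0.01,
        }
    )

    def validate(self):
        for name in ("conversion_failure", "inappropriate_conversion", "call_error"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.coverage_mean <= 0:
            raise ConfigError(f"coverage_mean={self.coverage_mean} must be > 0")
        if self.contig_length < 100_000:
            raise ConfigError("contig_length too small for the feature layout")
        if self.lfq.n_spiked > self.lfq.n_proteins:
            raise ConfigError("n_spiked > n_proteins")
        return self


@dataclass
class MethylationProfile:
    """True methylation level per feature class, plus the global background."""

    class_levels: dict
    background: float = 0.005
    passage: int = 0

    def __post_init__(self):
        for cls, lvl in self.class_levels.items():
            if not (0 <= lvl <= 1):
                raise ConfigError(f"level for {cls} outside [0, 1]")
        if not (0 <= self.background <= 1):
            raise ConfigError("background outside [0, 1]")

    def level(self, cls: str) -> float:
        return self.class_levels.get(cls, self.background)

    @classmethod
    def baseline(cls, classes=FEATURE_CLASSES, level: float = 0.005):
        """Near-zero methylome baseline (methylation-depleted line)."""
        if level > 0.02:
            raise ConfigError("baseline profile must be <= 0.02 at every class")
        return cls({c: level for c in classes}, background=level, passage=0)


_FEATURE_LENGTHS = {
    "IAPEz_int": (5000, 7000),
    "IAP_LTR": (300, 600),
    "ERV1": (1000, 3000),
    "LINE": (1000, 6000),
    "SINE": (100, 300),
    "CGI": (500, 2000),
    "gene": (2000, 10000),
}


def build_toy_genome(config: SimulationConfig) -> GenomeModel:
    """Deterministic toy genome with a repeat-landscape annotation.

    Features (plus gaps) are laid out left to right in seeded random order
    with Dirichlet-split intergenic spacers, so classes never overlap and the
    whole contig is partitioned into features + intergenic + gaps.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    contig = "chrS"

    items = []
    for cls, n in config.n_features.items():
        lo, hi = _FEATURE_LENGTHS[cls]
        for _ in range(n):
            items.append((cls, int(rng.integers(lo, hi + 1))))
    for _ in range(config.n_gaps):
        items.append(("gap", config.gap_length))
    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    total_feat = sum(length for _, length in items)
    slack = config.contig_length - total_feat
    if slack < len(items) + 1:
        raise ConfigError("contig_length too small for requested features")
    spacers = rng.dirichlet(np.ones(len(items) + 1)) * slack
    spacers = np.floor(spacers).astype(int)

    rows = []
    pos = int(spacers[0])
    prev_end = 0
    for (cls, length), spacer in zip(items, spacers[1:]):
        if pos > prev_end:
            rows.append((contig, prev_end, pos, "intergenic"))
        rows.append((contig, pos, pos + length, cls))
        prev_end = pos + length
        pos = prev_end + int(spacer)
    if prev_end < config.contig_length:
        rows.append((contig, prev_end, config.contig_length, "intergenic"))

    feat_df = pd.DataFrame(rows, columns=["contig", "start", "end", "label"])
    gap_mask = RegionSet(feat_df[feat_df["label"] == "gap"])
    features = RegionSet(feat_df[feat_df["label"] != "gap"])

    # CpG sites: per feature, deterministic count = round(length * density),
    # positions on the even grid so dyads never overlap
    sites = []
    for _, r in feat_df.iterrows():
        if r["label"] == "gap":
            continue
        density = config.cpg_density.get(r["label"], config.cpg_density["intergenic"])
        length = r["end"] - r["start"]
        n_cpg = int(round(length * density))
        n_slots = length // 2
        n_cpg = min(n_cpg, n_slots)
        if n_cpg == 0:
            continue
        slots = rng.choice(n_slots, size=n_cpg, replace=False)
        sites.append(r["start"] + 2 * np.sort(slots))
    cpg = np.sort(np.concatenate(sites)) if sites else np.array([], dtype=int)
    return GenomeModel(
        contigs=[(contig, config.contig_length)],
        cpg_sites={contig: cpg},
        features=features,
        gap_mask=gap_mask,
    )


def _class_of_sites(genome: GenomeModel, contig: str, pos: np.ndarray) -> np.ndarray:
    """Feature class per CpG (features partition the non-gap genome)."""
    sub = genome.features.df[genome.features.df["contig"] == contig].sort_values("start")
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    labels = sub["label"].to_numpy()
    idx = np.searchsorted(starts, pos, side="right") - 1
    out = np.full(len(pos), "intergenic", dtype=object)
    valid = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
    out[valid] = labels[idx[valid]]
    return out


def simulate_wgbs(
    genome: GenomeModel,
    profile: MethylationProfile,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> MethylomeTable:
    """Bisulfite count table: Poisson coverage, binomial methylated counts.

    Observed success probability folds in the bisulfite error model:
    ``p_obs = p_true (1 - c) + (1 - p_true) e``. CpGs drawing zero coverage
    are dropped (as in real coverage files after filtering).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    frames = []
    for contig, pos in genome.cpg_sites.items():
        cls = _class_of_sites(genome, contig, pos)
        p_true = np.array([profile.level(c) for c in cls])
        e, c = config.conversion_failure, config.inappropriate_conversion
        p_obs = p_true * (1 - c) + (1 - p_true) * e
        cov = rng.poisson(config.coverage_mean, size=len(pos))
        keep = cov > 0
        count_m = rng.binomial(cov[keep], p_obs[keep])
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "pos": pos[keep],
                    "count_M": count_m,
                    "count_U": cov[keep] - count_m,
                }
            )
        )
    return MethylomeTable(pd.concat(frames, ignore_index=True))


def simulate_passage_series(
    genome: GenomeModel,
    kinetics_by_class: dict,
    divisions_per_passage: int,
    config: SimulationConfig,
    passages=(0, 1, 5, 15, 25),
    baseline_profile: MethylationProfile | None = None,
    n_dyads_per_class: int = 50_000,
):
    """Passage series of methylomes plus hairpin dyad count tables.

    Per feature class the true dyad distribution starts from the baseline
    profile level f as (1-f) UU + f MM and evolves by the kinetics model for
    ``divisions_per_passage`` divisions per passage. At each sampled passage,
    dyad counts are multinomial draws from the evolved distribution pushed
    through the observation (bisulfite-error) matrix, and the WGBS table is
    simulated from the per-strand marginals of the same distribution.

    Returns (methylomes, dyad_tables): lists aligned with ``passages``
    (passage 0 = the baseline), dyad tables as DataFrames in the dyad TSV
    schema.
    """
    if divisions_per_passage < 1:
        raise ConfigError("divisions_per_passage must be >= 1")
    config.validate()
    classes = set(genome.feature_classes()) | {"intergenic"}
    missing = classes - set(kinetics_by_class)
    if missing:
        raise ConfigError(f"kinetics missing for classes: {sorted(missing)}")
    baseline_profile = baseline_profile or MethylationProfile.baseline(sorted(classes))
    rng = np.random.default_rng(config.seed + 2)
    e, c = config.conversion_failure, config.inappropriate_conversion
    O = observation_matrix(e, c)

    state = {}
    for cls in sorted(classes):
        f = baseline_profile.level(cls)
        state[cls] = np.array([1 - f, 0.0, 0.0, f])
    T = {cls: transition_matrix(kinetics_by_class[cls]) for cls in sorted(classes)}

    methylomes, dyad_tables = [], []
    current_passage = 0
    for target in passages:
        steps = (target - current_passage) * divisions_per_passage
        if steps < 0:
            raise ConfigError("passages must be non-decreasing")
        for cls in sorted(classes):
            for _ in range(steps):
                state[cls] = state[cls] @ T[cls]
        current_passage = target

        rows = []
        levels = {}
        for cls in sorted(classes):
            q = state[cls] @ O
            counts = rng.multinomial(n_dyads_per_class, q)
            rows.append((f"P{target}", cls, *counts))
            plus, minus = strand_marginals(state[cls])
            levels[cls] = (plus + minus) / 2.0
        dyad_tables.append(
            pd.DataFrame(rows, columns=["sample", "class", "n_UU", "n_MU", "n_UM", "n_MM"])
        )
        profile = MethylationProfile(
            levels, background=levels["intergenic"], passage=target
        )
        methylomes.append(simulate_wgbs(genome, profile, config, rng=rng))
    return methylomes, dyad_tables


def simulate_long_reads(
    genome: GenomeModel,
    methylome: MethylomeTable,
    deletions: RegionSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> LongReadCallSet:
    """Long reads with aligned blocks jumping over sample deletions.

    Read lengths are lognormal (median ``read_length_median``), truncated at
    contig ends. Per-CpG calls sample the methylome beta with a symmetric
    call-error probability; no calls fall inside deletions.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 3)
    lengths = dict(genome.contigs)
    del_df = deletions.merged().df
    beta_by_contig = {}
    meth_df = methylome.df.assign(beta=methylome.beta)
    for contig, sub in meth_df.groupby("contig"):
        sub = sub.sort_values("pos")
        beta_by_contig[contig] = (sub["pos"].to_numpy(), sub["beta"].to_numpy())

    del_by_contig = {
        contig: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for contig, sub in del_df.sort_values("start").groupby("contig")
    }
    blocks, calls = [], []
    contigs = list(lengths)
    for i in range(config.n_reads):
        contig = contigs[int(rng.integers(len(contigs)))]
        L = lengths[contig]
        start = int(rng.integers(0, L))
        d_starts, d_ends = del_by_contig.get(contig, (np.array([]), np.array([])))
        # a read cannot start inside a deleted segment of this sample
        inside = (d_starts <= start) & (start < d_ends)
        if inside.any():
            start = int(d_ends[inside][0])
            if start >= L:
                continue
        read_len = int(rng.lognormal(np.log(config.read_length_median), config.read_length_sigma))
        end = min(start + max(read_len, 100), L)
        read_id = f"read_{i}"
        # split [start, end) around deletions
        block_list = []
        cursor = start
        for ds, de in zip(d_starts, d_ends):
            if ds >= end or de <= start:
                continue
            if ds > cursor:
                block_list.append((cursor, int(ds)))
            cursor = max(cursor, int(de))
        if cursor < end:
            block_list.append((cursor, end))
        if not block_list:
            continue
        per_cpg = beta_by_contig.get(contig)
        for bs, be in block_list:
            blocks.append((read_id, contig, bs, be))
            if per_cpg is None:
                continue
            pos_all, beta_all = per_cpg
            i0, i1 = np.searchsorted(pos_all, (bs, be))
            pos_arr = pos_all[i0:i1]
            betas = beta_all[i0:i1]
            ok = ~np.isnan(betas)
            pos_arr, betas = pos_arr[ok], betas[ok]
            meth = rng.random(len(betas)) < betas
            flip = rng.random(len(betas)) < config.call_error
            meth = meth ^ flip
            calls.append((read_id, contig, pos_arr, meth))
    blocks_df = pd.DataFrame(blocks, columns=["read_id", "contig", "start", "end"])
    if calls:
        calls_df = pd.DataFrame(
            {
                "read_id": np.repeat(
                    [c[0] for c in calls], [len(c[2]) for c in calls]
                ),
                "contig": np.repeat(
                    [c[1] for c in calls], [len(c[2]) for c in calls]
                ),
                "pos": np.concatenate([c[2] for c in calls]).astype(int),
                "call": np.where(np.concatenate([c[3] for c in calls]), "M", "U"),
            }
        )
    else:
        calls_df = pd.DataFrame(columns=["read_id", "contig", "pos", "call"])
    return LongReadCallSet(blocks_df, calls_df)


@dataclass
class LfqSimulation:
    matrix: pd.DataFrame  # log2 intensities with NaN for missing
    groups: pd.Series  # sample -> "bait" | "control"
    spiked: list  # protein ids with a true effect
    truth: pd.DataFrame  # pre-noise, pre-dropout group means


def simulate_lfq(config: SimulationConfig, rng: np.random.Generator | None = None) -> LfqSimulation:
    """Bait-vs-control LFQ matrix with spiked interactors and MNAR dropout.

    Spiked proteins are shifted by ``effect_log2`` in the bait group.
    Missingness probability rises as true intensity falls:
    ``p_missing = dropout_max / (1 + exp((x - midpoint) / steepness))``;
    ``dropout_max = 0`` disables dropout.
    """
    config.validate()
    spec = config.lfq
    rng = rng or np.random.default_rng(config.seed + 4)
    ids = [f"prot_{i:04d}" for i in range(spec.n_proteins)]
    spiked = ids[: spec.n_spiked]
    base = rng.normal(spec.base_mean, spec.base_sd, size=spec.n_proteins)
    effect = np.zeros(spec.n_proteins)
    effect[: spec.n_spiked] = spec.effect_log2

    cols, groups = [], {}
    for grp, shift in (("bait", effect), ("control", np.zeros(spec.n_proteins))):
        for r in range(spec.n_reps):
            name = f"{grp}_{r + 1}"
            groups[name] = grp
            cols.append((name, base + shift))
    truth = pd.DataFrame(
        {name: vals for name, vals in cols}, index=ids
    )
    noisy = truth + rng.normal(0, spec.noise_sd, size=truth.shape)
    if spec.dropout_max > 0:
        p_miss = spec.dropout_max / (
            1 + np.exp((noisy.to_numpy() - spec.dropout_midpoint) / spec.dropout_steepness)
        )
        drop = rng.random(noisy.shape) < p_miss
        matrix = noisy.mask(drop)
    else:
        matrix = noisy
    return LfqSimulation(
        matrix=matrix,
        groups=pd.Series(groups),
        spiked=spiked,
        truth=truth,
    )
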