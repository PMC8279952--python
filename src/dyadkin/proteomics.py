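"""Label-free interaction-proteomics statistics.

Workflow for a bait-vs-control co-immunoprecipitation LFQ matrix:
log2 intensities -> missing-value imputation from a down-shifted normal
distribution (missing-not-at-random values sit near the detection limit) ->
per-protein two-sample t-test -> SAM-style permutation-based FDR with a
fudge factor ``s0`` stabilising low-variance proteins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

logger = logging.getLogger("dyadkin")


def _as_matrix(m: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(m, pd.DataFrame):
        raise ValidationError("LFQ matrix must be a DataFrame (proteins x samples)")
    return m.astype(float)


def impute_downshift(
    m: pd.DataFrame, width: float = 0.3, shift: float = 1.8, seed: int = 0
) -> pd.DataFrame:
    """Impute missing log2 intensities from a down-shifted normal.

    Per sample column with mean ``mu`` and standard deviation ``sd`` of the
    observed values, missing entries are drawn from
    Normal(mu - shift * sd, (width * sd)^2). Observed values are never
    altered. Columns with fewer than 3 observed values fall back to the
    whole-matrix mean/sd (flagged with a warning).
    """
    m = _as_matrix(m)
    rng = np.random.default_rng(seed)
    out = m.copy()
    global_vals = m.to_numpy().ravel()
    global_vals = global_vals[~np.isnan(global_vals)]
    for col in m.columns:
        vals = m[col].to_numpy()
        missing = np.isnan(vals)
        if not missing.any():
            continue
        observed = vals[~missing]
        if len(observed) < 3:
            if len(global_vals) < 3:
                raise ValidationError(f"column {col}: too few observed values to impute")
            warnings.warn(
                f"column {col}: <3 observed values, using whole-matrix mean/sd",
                stacklevel=2,
            )
            mu, sd = float(global_vals.mean()), float(global_vals.std(ddof=1))
        else:
            mu, sd = float(observed.mean()), float(observed.std(ddof=1))
        draws = rng.normal(mu - shift * sd, width * sd, size=int(missing.sum()))
        col_vals = vals.copy()
        col_vals[missing] = draws
        out[col] = col_vals
    return out


def two_sample_test(
    m: pd.DataFrame, groups: pd.Series, equal_var: bool = True
) -> pd.DataFrame:
    """Per-protein two-sample t-test (bait vs control), two-tailed.

    ``groups`` maps sample column -> group name; exactly two groups, the
    first (sorted) treated as bait unless named 'bait'/'control'. Returns
    mean_diff (bait - control), t, p. Zero-variance degenerate proteins get
    t = 0, p = 1 with a flag column.
    """
    m = _as_matrix(m)
    groups = groups.reindex(m.columns)
    if groups.isna().any():
        raise ValidationError("groups must cover every sample column")
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValidationError(f"expected 2 groups, got {names}")
    bait = "bait" if "bait" in names else names[0]
    ctrl = [g for g in names if g != bait][0]
    a = m.loc[:, groups[groups == bait].index].to_numpy()
    b = m.loc[:, groups[groups == ctrl].index].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("need >=2 samples per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {
            "mean_diff": diff,
            "t_statistic": t,
            "p_value": p,
            "degenerate": degenerate,
        },
        index=m.index,
    )


def _sam_statistic(a: np.ndarray, b: np.ndarray, s0: float) -> np.ndarray:
    """Moderated t: mean difference over (pooled SE + s0)."""
    n1, n2 = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    sp2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return diff / (se + s0)


def _balanced_partitions(columns, group_mask, n_perm, rng):
    """Distinct relabelings preserving group sizes, excluding the observed
    labelling and its mirror."""
    n = len(columns)
    n1 = int(group_mask.sum())
    identity = frozenset(np.flatnonzero(group_mask))
    mirror = frozenset(np.flatnonzero(~group_mask)) if n - n1 == n1 else None
    all_combos = None
    from math import comb

    total = comb(n, n1)
    if total <= 4 * n_perm or total <= 200:
        all_combos = [frozenset(c) for c in combinations(range(n), n1)]
        pool = [c for c in all_combos if c != identity and c != mirror]
        order = rng.permutation(len(pool))
        return [pool[i] for i in order[:n_perm]]
    seen, out = set(), []
    attempts = 0
    while len(out) < n_perm and attempts < 50 * n_perm:
        attempts += 1
        pick = frozenset(rng.choice(n, size=n1, replace=False).tolist())
        if pick in seen or pick == identity or pick == mirror:
            continue
        seen.add(pick)
        out.append(pick)
    return out


@dataclass
class FdrResult:
    table: pd.DataFrame  # per protein: mean_diff, d_statistic, t, p, significant
    cutoff: float | None
    estimated_fdr: float | None
    n_significant: int
    n_permutations: int
    method: str


def permutation_fdr(
    m: pd.DataFrame,
    groups: pd.Series,
    s0: float = 0.1,
    n_perm: int = 250,
    fdr_q: float = 0.05,
    seed: int = 0,
) -> FdrResult:
    """SAM-style permutation FDR on a complete (post-imputation) matrix.

    The moderated statistic d = mean_diff / (SE + s0) is computed for the
    observed labelling and for distinct label permutations; for a candidate
    cutoff t the estimated FDR is the median permutation count of
    |d_perm| >= t divided by the observed count of |d| >= t. The largest
    rejection set with estimated FDR <= ``fdr_q`` is flagged significant.

    When no informative permutation exists (degenerate tiny designs) the
    method falls back to Bonferroni on the plain t-test.
    """
    m = _as_matrix(m)
    if m.isna().any().any():
        raise ValidationError("matrix has missing values; impute first")
    groups = groups.reindex(m.columns)
    names = sorted(groups.unique())
    bait = "bait" if "bait" in names else names[0]
    mask = (groups == bait).to_numpy()
    X = m.to_numpy()
    a, b = X[:, mask], X[:, ~mask]
    d_obs = _sam_statistic(a, b, s0)
    ttest = two_sample_test(m, groups)

    rng = np.random.default_rng(seed)
    parts = _balanced_partitions(list(m.columns), mask, n_perm, rng)
    if not parts:
        logger.warning("no informative permutations; Bonferroni fallback")
        sig = ttest["p_value"].to_numpy() * len(m) < fdr_q
        table = ttest.assign(d_statistic=d_obs, significant=sig)
        return FdrResult(table, None, None, int(sig.sum()), 0, "bonferroni")

    abs_obs = np.abs(d_obs)
    perm_abs = np.empty((len(parts), len(m)))
    idx_all = np.arange(X.shape[1])
    for i, part in enumerate(parts):
        pa = np.array(sorted(part))
        pb = np.array(sorted(set(idx_all) - part))
        perm_abs[i] = np.abs(_sam_statistic(X[:, pa], X[:, pb], s0))

    # candidate cutoffs: observed |d| values, descending
    candidates = np.sort(np.unique(abs_obs))[::-1]
    best_cut, best_fdr, best_n = None, None, 0
    for t in candidates:
        n_pos = int((abs_obs >= t).sum())
        fp_median = float(np.median((perm_abs >= t).sum(axis=1)))
        fdr = fp_median / n_pos if n_pos else 0.0
        if fdr <= fdr_q and n_pos > best_n:
            best_cut, best_fdr, best_n = float(t), fdr, n_pos
    sig = (
        abs_obs >= best_cut if best_cut is not None else np.zeros(len(m), dtype=bool)
    )
    table = ttest.assign(d_statistic=d_obs, significant=sig)
    return FdrResult(
        table=table,
        cutoff=best_cut,
        estimated_fdr=best_fdr,
        n_significant=int(sig.sum()),
        n_permutations=len(parts),
        method="sam-permutation",
    )
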