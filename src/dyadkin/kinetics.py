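"""CpG-dyad methylation kinetics: a discrete-generation hidden Markov model
separating maintenance from de novo methylation efficiency.

A CpG dyad is the pair of complementary-strand cytosines at one CpG; its
state is one of UU, MU, UM, MM (plus-strand letter first). Hairpin-bisulfite
sequencing reads both strands of a single molecule, so the dyad state is
directly observable up to bisulfite conversion errors.

Per cell division, a daughter molecule keeps one parental strand (either with
probability 1/2) and synthesizes a nascent strand:

* an existing methyl mark on the kept strand persists with probability
  ``1 - lam`` (loss rate ``lam``, default 0);
* an unmethylated kept-strand site gains methylation with probability
  ``delta_p`` (parental-strand de novo, default 0);
* the nascent cytosine is methylated with probability ``mu`` (maintenance
  efficiency) if the kept strand is methylated after loss/gain, else with
  probability ``delta_n`` (nascent-strand de novo efficiency).

Observation errors are per-strand independent: an unmethylated C is read as
methylated with probability ``e`` (conversion failure) and a methylated C as
unmethylated with probability ``c`` (inappropriate conversion).

With ``delta_p = lam = 0`` the per-strand marginal f evolves as
``f' = (f (1 + mu) + (1 - f) delta_n) / 2`` with fixed point
``f* = delta_n / (1 - mu + delta_n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

STATES = ("UU", "MU", "UM", "MM")
_STATE_BITS = [(0, 0), (1, 0), (0, 1), (1, 1)]  # (plus, minus) methylation


class KineticsError(ValueError):
    pass


def _check_prob(name, x):
    if not (0.0 <= x <= 1.0):
        raise KineticsError(f"{name}={x} outside [0, 1]")


@dataclass
class KineticParams:
    """Rates of the dyad inheritance model; all probabilities per division."""

    mu: float = 0.0          # maintenance efficiency
    delta_n: float = 0.0     # de novo on the nascent strand
    delta_p: float = 0.0     # de novo on the parental strand
    lam: float = 0.0         # loss of an existing mark
    e: float = 0.0           # conversion failure (U read as M)
    c: float = 0.0           # inappropriate conversion (M read as U)
    p0: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))

    def __post_init__(self):
        for name in ("mu", "delta_n", "delta_p", "lam", "e", "c"):
            _check_prob(name, getattr(self, name))
        self.p0 = np.asarray(self.p0, dtype=float)
        if self.p0.shape != (4,) or (self.p0 < 0).any() or abs(self.p0.sum() - 1) > 1e-9:
            raise KineticsError("p0 must be a distribution over the 4 dyad states")


def transition_matrix(params: KineticParams) -> np.ndarray:
    """4x4 stochastic matrix T with p' = p @ T (one cell division)."""
    mu, dn, dp, lam = params.mu, params.delta_n, params.delta_p, params.lam
    T = np.zeros((4, 4))
    for i, (a, b) in enumerate(_STATE_BITS):
        for kept, strand_is_plus in ((a, True), (b, False)):
            # kept parental mark after loss / parental de novo
            p_kept_m = (1 - lam) if kept else dp
            for m_kept, w_kept in ((1, p_kept_m), (0, 1 - p_kept_m)):
                p_nasc_m = mu if m_kept else dn
                for m_nasc, w_nasc in ((1, p_nasc_m), (0, 1 - p_nasc_m)):
                    child = (m_kept, m_nasc) if strand_is_plus else (m_nasc, m_kept)
                    j = _STATE_BITS.index(child)
                    T[i, j] += 0.5 * w_kept * w_nasc
    return T


def transition_step(p: np.ndarray, params: KineticParams) -> np.ndarray:
    """Evolve a dyad distribution by one division."""
    p = np.asarray(p, dtype=float)
    if p.shape != (4,) or (p < -1e-12).any() or abs(p.sum() - 1) > 1e-9:
        raise KineticsError("p must be a distribution over the 4 dyad states")
    return p @ transition_matrix(params)


def evolve(p: np.ndarray, params: KineticParams, divisions: int) -> np.ndarray:
    T = transition_matrix(params)
    out = np.asarray(p, dtype=float)
    for _ in range(divisions):
        out = out @ T
    return out


def strand_marginals(p: np.ndarray) -> tuple:
    """(plus, minus) per-strand methylation of a dyad distribution."""
    p = np.asarray(p, dtype=float)
    return float(p[1] + p[3]), float(p[2] + p[3])


def stationary_marginal(params: KineticParams, tol: float = 1e-12, max_iter: int = 100000) -> float:
    """Equilibrium per-strand methylation level.

    Closed form ``delta_n / (1 - mu + delta_n)`` when ``delta_p = lam = 0``;
    otherwise the marginal map is iterated to ``tol``. The corner
    ``mu = 1, delta_n = delta_p = lam = 0`` conserves the marginal and has no
    unique fixed point; that case raises.
    """
    mu, dn, dp, lam = params.mu, params.delta_n, params.delta_p, params.lam
    if dp == 0.0 and lam == 0.0:
        if mu == 1.0 and dn == 0.0:
            raise KineticsError(
                "marginal is conserved (mu=1, delta_n=0): no unique fixed point"
            )
        return dn / (1.0 - mu + dn)
    f = 0.5
    for _ in range(max_iter):
        q = f * (1 - lam) + (1 - f) * dp
        f_new = (q + q * mu + (1 - q) * dn) / 2.0
        if abs(f_new - f) < tol:
            return f_new
        f = f_new
    raise KineticsError("stationary marginal iteration did not converge")


def observation_matrix(e: float, c: float) -> np.ndarray:
    """4x4 stochastic matrix mapping true dyad states to observed states.

    Per-strand independent errors: U observed as M with probability ``e``,
    M observed as U with probability ``c``.
    """
    _check_prob("e", e)
    _check_prob("c", c)
    o2 = np.array([[1 - e, e], [c, 1 - c]])  # rows: true U, M; cols: obs U, M
    O = np.zeros((4, 4))
    for i, (a, b) in enumerate(_STATE_BITS):
        for j, (x, y) in enumerate(_STATE_BITS):
            O[i, j] = o2[a, x] * o2[b, y]
    return O


# ---------------------------------------------------------------------------
# time courses and likelihood


@dataclass
class TimeCourse:
    """Ordered dyad-count observations along a passage series.

    Each entry: (label, divisions_since_previous, counts over (UU, MU, UM, MM)).
    The first entry defines t = 0 (its divisions field must be 0).
    """

    observations: list

    def __post_init__(self):
        obs = []
        for label, divisions, counts in self.observations:
            counts = np.asarray(counts, dtype=float)
            if counts.shape != (4,) or (counts < 0).any():
                raise KineticsError(f"bad counts for {label}")
            if divisions < 0:
                raise KineticsError(f"negative divisions for {label}")
            obs.append((label, int(divisions), counts))
        if obs and obs[0][1] != 0:
            raise KineticsError("first observation must have divisions_since_previous=0")
        self.observations = obs

    def __len__(self):
        return len(self.observations)


def _multinomial_logpmf(counts, probs):
    counts = np.asarray(counts, dtype=float)
    probs = np.asarray(probs, dtype=float)
    n = counts.sum()
    if n == 0:
        return 0.0
    if ((probs <= 0) & (counts > 0)).any():
        return -np.inf
    with np.errstate(divide="ignore"):
        logp = np.where(counts > 0, counts * np.log(np.where(probs > 0, probs, 1)), 0.0)
    return float(gammaln(n + 1) - gammaln(counts + 1).sum() + logp.sum())


def loglik(params: KineticParams, tc: TimeCourse) -> float:
    """Multinomial log-likelihood of a dyad time course under the model.

    The model state starts at ``params.p0``, evolves by ``transition_step``
    for each observation's division count, and is pushed through the
    observation matrix before being compared with the observed counts.
    """
    if len(tc) == 0:
        return 0.0
    O = observation_matrix(params.e, params.c)
    T = transition_matrix(params)
    p = params.p0.copy()
    total = 0.0
    for _, divisions, counts in tc.observations:
        for _ in range(divisions):
            p = p @ T
        q = p @ O
        total += _multinomial_logpmf(counts, q)
    return total


@dataclass
class FitResult:
    params: KineticParams
    loglik: float
    converged: bool
    starts: list  # (x0, final_loglik, success) per start
    fixed: dict


def _observed_freqs(counts):
    total = counts.sum()
    if total <= 0:
        raise KineticsError("zero total dyad count at first timepoint")
    return counts / total


def fit_kinetics(
    tc: TimeCourse,
    fixed: dict | None = None,
    n_starts: int = 8,
    seed: int = 0,
    bounds: dict | None = None,
    free: tuple = ("mu", "delta_n"),
    p0: np.ndarray | None = None,
) -> FitResult:
    """Bounded multi-start maximum-likelihood fit of the dyad model.

    By default only ``mu`` and ``delta_n`` are free (the two-parameter
    maintenance/de-novo model); ``e``/``c`` and any other rate come from
    ``fixed`` (defaulting to e = c = 0.005 when unset). ``p0`` defaults to
    the observed state frequencies at the first timepoint.

    A single-timepoint course cannot jointly identify ``mu`` and
    ``delta_n`` (the likelihood depends on the parameters only through the
    unreached dynamics); fitting refuses unless one of them is fixed.
    """
    fixed = dict(fixed or {})
    fixed.setdefault("e", 0.005)
    fixed.setdefault("c", 0.005)
    free = tuple(f for f in free if f not in fixed)
    if len(tc) < 2 and {"mu", "delta_n"} <= set(free):
        raise KineticsError(
            "mu and delta_n are not jointly identifiable from a single "
            "timepoint; fix one of them or provide >=2 timepoints"
        )
    if len(tc) < 1:
        raise KineticsError("empty time course")
    if p0 is None:
        p0 = _observed_freqs(tc.observations[0][2])
    bounds = dict(bounds or {})
    box = [bounds.get(name, (0.0, 1.0)) for name in free]

    base = {name: fixed.get(name, 0.0) for name in ("mu", "delta_n", "delta_p", "lam")}
    base["e"], base["c"] = fixed["e"], fixed["c"]

    def make_params(x):
        kw = dict(base)
        for name, val in zip(free, x):
            kw[name] = float(np.clip(val, 0.0, 1.0))
        return KineticParams(p0=p0, **kw)

    def nll(x):
        val = loglik(make_params(x), tc)
        return -val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    starts = [np.array([0.5 * (lo + hi) for lo, hi in box])]
    while len(starts) < n_starts:
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in box]))

    trace, best = [], None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=box)
        trace.append((x0.tolist(), -float(res.fun), bool(res.success)))
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise KineticsError(f"no optimizer start converged; trace: {trace}")
    return FitResult(
        params=make_params(best.x),
        loglik=-float(best.fun),
        converged=True,
        starts=trace,
        fixed=fixed,
    )


# ---------------------------------------------------------------------------
# dyad classification and descriptive statistics


def classify_dyads(molecules) -> np.ndarray:
    """Tally dyad states from paired strand calls.

    ``molecules``: iterable of (plus_calls, minus_calls) per molecule, where
    each element is a sequence over dyads with values in {"M", "U"} (anything
    else is ambiguous and skips that dyad). Molecules whose strand call
    vectors differ in length are rejected and counted.

    Returns ``(counts, n_rejected)`` with counts over (UU, MU, UM, MM).
    """
    counts = np.zeros(4, dtype=np.int64)
    rejected = 0
    for plus, minus in molecules:
        if len(plus) != len(minus):
            rejected += 1
            continue
        for a, b in zip(plus, minus):
            if a not in ("M", "U") or b not in ("M", "U"):
                continue
            i = _STATE_BITS.index((int(a == "M"), int(b == "M")))
            counts[i] += 1
    return counts, rejected


def dyad_log2fc(sample_counts, reference_counts, pseudo: float | None = None) -> np.ndarray:
    """Per-state log2 fold change of dyad-state frequencies vs a reference.

    ``pseudo`` is added on the frequency scale; default is 1/total of the
    respective table (a one-count pseudocount).
    """
    s = np.asarray(sample_counts, dtype=float)
    r = np.asarray(reference_counts, dtype=float)
    if s.sum() <= 0 or r.sum() <= 0:
        raise KineticsError("zero total dyad count")
    fs = s / s.sum()
    fr = r / r.sum()
    ps = (1.0 / s.sum()) if pseudo is None else pseudo
    pr = (1.0 / r.sum()) if pseudo is None else pseudo
    return np.log2((fs + ps) / (fr + pr))
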