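"""Inter-sample feature analysis: bootstrapped Wilcoxon comparison of two
environments' function profiles.

Rather than a single two-group test per feature, a random subset of samples
is drawn from each environment many times; the Wilcoxon rank-sum test is run
on each draw and a feature is called significantly different only when the
per-iteration p-value falls below alpha in at least a consensus fraction of
iterations. Defaults follow the standard operating point: 70% subsample,
alpha 0.01, 1000 iterations, 70% consensus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

# Exact permutation enumeration is used up to this pooled size; it handles
# ties via mid-ranks, which the classical exact tables cannot.
_EXACT_PERMUTATION_MAX_N = 14
_EXACT_NOTIES_MAX_MIN_N = 8


@dataclass
class ISFAParams:
    """Operating parameters of the bootstrapped comparison."""

    subsample_fraction: float = 0.7
    alpha: float = 0.01
    n_iterations: int = 1000
    consensus_threshold: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if not 0 < self.consensus_threshold <= 1:
            raise ValueError("consensus_threshold must be in (0, 1]")


@dataclass
class ISFAResult:
    """Per-feature consensus significance calls.

    ``table`` has one row per feature with columns: consensus_fraction,
    significant, direction (A_higher / B_higher / none, from full-data
    medians), median_p, n_iterations, p_full and q_full_bh (full-data test
    and its BH adjustment — supplementary diagnostics, not part of the
    consensus procedure).
    """

    table: pd.DataFrame
    params: ISFAParams
    warnings: list[str] = field(default_factory=list)

    @property
    def significant_features(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _exact_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all group assignments of the pooled
    mid-ranks: p = P(|W - E[W]| >= |w_obs - E[W]|)."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    expect = n1 * (n + 1) / 2.0
    dev_obs = abs(w_obs - expect)
    hits = total = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - expect) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Small pooled samples (n <= 14) use exact mid-rank permutation
    enumeration, which is tie-safe; larger samples use the classical exact
    distribution when tie-free and one group has <= 8 observations, and the
    tie-corrected normal approximation with continuity correction otherwise.
    Always returns p in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    n = x.size + y.size
    has_ties = np.unique(pooled).size < n
    if n <= _EXACT_PERMUTATION_MAX_N:
        return _exact_permutation_p(x, y)
    if not has_ties and min(x.size, y.size) <= _EXACT_NOTIES_MAX_MIN_N:
        return float(stats.mannwhitneyu(x, y, method="exact").pvalue)
    p = float(
        stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=True).pvalue
    )
    return min(max(p, np.finfo(float).tiny), 1.0)


def _pvalue_matrix(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Per-feature two-sided p-values for two samples × features blocks,
    routed through the same branch rules as wilcoxon_rank_sum."""
    na, nb = xa.shape[0], xb.shape[0]
    n = na + nb
    n_feat = xa.shape[1]
    if n <= _EXACT_PERMUTATION_MAX_N or min(na, nb) <= _EXACT_NOTIES_MAX_MIN_N:
        return np.array(
            [wilcoxon_rank_sum(xa[:, j], xb[:, j]) for j in range(n_feat)]
        )
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.mannwhitneyu(
            xa, xb, axis=0, method="asymptotic", use_continuity=True
        ).pvalue
    p = np.asarray(p, dtype=float)
    constant = np.ptp(np.vstack([xa, xb]), axis=0) == 0
    p[constant] = 1.0
    p = np.nan_to_num(p, nan=1.0)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _as_frame(profile) -> pd.DataFrame:
    if hasattr(profile, "values") and isinstance(profile.values, pd.DataFrame):
        return profile.values
    if isinstance(profile, pd.DataFrame):
        return profile
    raise TypeError("expected a FunctionProfile or a samples × features DataFrame")


def isfa_compare(profile_a, profile_b, params: ISFAParams | None = None) -> ISFAResult:
    """Bootstrapped Wilcoxon comparison of two environments.

    Each iteration draws ceil(f * n) samples per group without replacement,
    tests every feature, and flags those with p < alpha; a feature is
    significant when flagged in at least the consensus fraction of
    iterations. Feature spaces are unioned with missing features filled with
    zero. Deterministic for a fixed params.seed.
    """
    if params is None:
        params = ISFAParams()
    a = _as_frame(profile_a)
    b = _as_frame(profile_b)
    features = sorted(set(a.columns) | set(b.columns))
    a = a.reindex(columns=features, fill_value=0.0)
    b = b.reindex(columns=features, fill_value=0.0)
    na, nb = len(a.index), len(b.index)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    ka = math.ceil(params.subsample_fraction * na)
    kb = math.ceil(params.subsample_fraction * nb)
    warns: list[str] = []
    if ka >= na and kb >= nb:
        warns.append(
            "subsample covers both full groups; every iteration runs the same "
            "full-data test"
        )
    xa, xb = a.values, b.values
    # Subsample streams are keyed by group size (not argument position), so
    # swapping the group labels pairs exactly the same subsets per iteration.
    rng_a = np.random.default_rng([params.seed, 101, na, ka])
    rng_b = np.random.default_rng([params.seed, 101, nb, kb])
    n_iter = params.n_iterations
    flags = np.zeros(len(features))
    all_p = np.empty((n_iter, len(features)))
    for it in range(n_iter):
        ia = rng_a.choice(na, size=ka, replace=False)
        ib = rng_b.choice(nb, size=kb, replace=False)
        p = _pvalue_matrix(xa[ia], xb[ib])
        all_p[it] = p
        flags += p < params.alpha
    consensus = flags / n_iter
    med_a = np.median(xa, axis=0)
    med_b = np.median(xb, axis=0)
    direction = np.where(
        med_a > med_b, "A_higher", np.where(med_b > med_a, "B_higher", "none")
    )
    p_full = _pvalue_matrix(xa, xb)
    q_full = multipletests(p_full, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "consensus_fraction": consensus,
            "significant": consensus >= params.consensus_threshold,
            "direction": direction,
            "median_p": np.median(all_p, axis=0),
            "n_iterations": n_iter,
            "p_full": p_full,
            "q_full_bh": q_full,
        },
        index=pd.Index(features, name="feature"),
    )
    return ISFAResult(table=table, params=params, warnings=warns)


def isfa_sweep(
    profiles_a: dict[int, pd.DataFrame],
    profiles_b: dict[int, pd.DataFrame],
    params: ISFAParams | None = None,
) -> pd.DataFrame:
    """Run the comparison for every PEC present in both inputs and return a
    features × PEC presence/absence (1/0 significance) matrix."""
    if params is None:
        params = ISFAParams()
    pecs = sorted(set(profiles_a) & set(profiles_b))
    if not pecs:
        raise ValueError("no common PEC values between the two profile sets")
    cols = {}
    for pec in pecs:
        res = isfa_compare(profiles_a[pec], profiles_b[pec], params)
        cols[pec] = res.table["significant"].astype(int)
    out = pd.DataFrame(cols).fillna(0).astype(int)
    out.index.name = "feature"
    out.columns.name = "pec"
    return out
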