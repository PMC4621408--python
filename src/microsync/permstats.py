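"""Permutation tests on distance matrices and rank-based screening.

PERMANOVA (one-way, Anderson's pseudo-F on a distance matrix), the Mantel
test between two distance matrices, and a per-taxon Kruskal-Wallis screen
with Bonferroni correction.

All permutation p-values use the add-one convention
p = (#{permuted statistic >= observed} + 1) / (n_permutations + 1),
whose smallest attainable value at n = 9999 is 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skbio import DistanceMatrix

from .table import OtuTable

__all__ = [
    "PermutationTestResult",
    "permanova",
    "permanova_ss",
    "mantel",
    "kruskal_wallis_screen",
]

_REL_TOL = 1e-10  # treat permuted statistics this close to observed as ties


class PermStatsError(ValueError):
    pass


@dataclass
class PermutationTestResult:
    statistic: float        # pseudo-F (PERMANOVA) or r (Mantel)
    effect_size: float      # R^2 for PERMANOVA, r for Mantel
    p_value: float          # (b + 1) / (n + 1)
    n_permutations: int
    seed: int | None
    method: str = "monte-carlo"


def _as_labels(grouping, ids) -> np.ndarray:
    if isinstance(grouping, dict):
        return np.array([grouping[i] for i in ids])
    labels = np.asarray(grouping)
    if labels.shape[0] != len(ids):
        raise PermStatsError("grouping length does not match distance matrix")
    return labels


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float, float, float]:
    """Pseudo-F, R^2 and the SS decomposition from squared distances.

    SS_total = sum_{i<j} d_ij^2 / N; SS_within = sum over groups of the
    within-group squared distances divided by the group size.
    """
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_between = ss_total - ss_within
    a = n_groups
    if ss_within <= 0:
        f = np.inf
    else:
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else np.nan
    return f, r2, ss_between, ss_total


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
    method: str = "monte-carlo",
) -> PermutationTestResult:
    """One-way PERMANOVA of a distance matrix against a single factor.

    ``method="exact"`` enumerates every permutation of the label vector
    (only sensible for very small N) and ignores ``n_permutations``.
    """
    labels = _as_labels(grouping, dm.ids)
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise PermStatsError("need at least 2 groups")
    if n_permutations < 1 and method != "exact":
        raise PermStatsError("n_permutations must be >= 1")
    d2 = dm.data ** 2
    if d2.max() == 0:
        raise PermStatsError("constant (all-zero) distance matrix: statistic undefined")
    f_obs, r2, _, ss_total = _pseudo_f(d2, codes, uniq.size)
    if ss_total <= 0:
        raise PermStatsError("zero total sum of squares: statistic undefined")

    threshold = f_obs - _REL_TOL * abs(f_obs)
    if method == "exact":
        perms = list(iter_permutations(range(len(codes))))
        hits = sum(
            _pseudo_f(d2, codes[list(p)], uniq.size)[0] >= threshold for p in perms
        )
        return PermutationTestResult(
            f_obs, r2, hits / len(perms), len(perms), seed, "exact"
        )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm_codes = rng.permutation(codes)
        f_perm = _pseudo_f(d2, perm_codes, uniq.size)[0]
        if f_perm >= threshold:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermutationTestResult(f_obs, r2, p, n_permutations, seed)


def permanova_ss(dm: DistanceMatrix, grouping) -> dict[str, float]:
    """The SS decomposition (between/within/total) behind the pseudo-F."""
    labels = _as_labels(grouping, dm.ids)
    uniq, codes = np.unique(labels, return_inverse=True)
    f, r2, ss_between, ss_total = _pseudo_f(dm.data ** 2, codes, uniq.size)
    return {
        "ss_between": ss_between,
        "ss_within": ss_total - ss_between,
        "ss_total": ss_total,
        "pseudo_f": f,
        "r_squared": r2,
    }


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
    alternative: str = "two-sided",
    method: str = "monte-carlo",
) -> PermutationTestResult:
    """Mantel test: Pearson correlation of two distance matrices.

    The second matrix is aligned to the first by id; permutations shuffle
    its rows and columns jointly. ``alternative`` is "two-sided" (on |r|),
    "greater" or "less".
    """
    if set(dm1.ids) != set(dm2.ids):
        raise PermStatsError("distance matrices have different id sets")
    dm2 = dm2.filter(dm1.ids)
    n = len(dm1.ids)
    tril = np.tril_indices(n, k=-1)
    x = dm1.data[tril]

    def corr_with(mat: np.ndarray) -> float:
        y = mat[tril]
        xc, yc = x - x.mean(), y - y.mean()
        denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        if denom == 0:
            raise PermStatsError("constant distance matrix: r undefined")
        return float((xc * yc).sum() / denom)

    r_obs = corr_with(dm2.data)

    def is_hit(r_perm: float) -> bool:
        if alternative == "two-sided":
            return abs(r_perm) >= abs(r_obs) - _REL_TOL
        if alternative == "greater":
            return r_perm >= r_obs - _REL_TOL
        if alternative == "less":
            return r_perm <= r_obs + _REL_TOL
        raise PermStatsError(f"unknown alternative {alternative!r}")

    if method == "exact":
        perms = list(iter_permutations(range(n)))
        hits = 0
        for p in perms:
            p = np.array(p)
            hits += is_hit(corr_with(dm2.data[np.ix_(p, p)]))
        return PermutationTestResult(
            r_obs, r_obs, hits / len(perms), len(perms), seed, "exact"
        )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        if is_hit(corr_with(dm2.data[np.ix_(p, p)])):
            hits += 1
    p_val = (hits + 1) / (n_permutations + 1)
    return PermutationTestResult(r_obs, r_obs, p_val, n_permutations, seed)


def kruskal_wallis_screen(
    table: OtuTable | pd.DataFrame,
    grouping,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-taxon Kruskal-Wallis rank-sum test with Bonferroni correction.

    Returns a DataFrame indexed by taxon with columns H, p_value,
    p_bonferroni (raw p times the number of taxa tested, capped at 1) and
    significant (corrected p < alpha). Taxa constant across all samples get
    H = 0, p = 1.
    """
    df = table.data if isinstance(table, OtuTable) else table
    labels = _as_labels(grouping, df.index)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise PermStatsError("need at least 2 groups")
    group_rows = [df.loc[labels == g] for g in uniq]
    if any(len(g) < 1 for g in group_rows):
        raise PermStatsError("every group needs at least one sample")
    records = {}
    for taxon in df.columns:
        samples = [g[taxon].to_numpy(dtype=float) for g in group_rows]
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            records[taxon] = {"H": 0.0, "p_value": 1.0}
            continue
        h, p = sstats.kruskal(*samples)
        records[taxon] = {"H": float(h), "p_value": float(p)}
    out = pd.DataFrame.from_dict(records, orient="index")
    m = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p_value"] * m)
    out["significant"] = out["p_bonferroni"] < alpha
    return out
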