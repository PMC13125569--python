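"""Estimation statistics: Cohen's d, permutation p-values, 2^−ΔCt expression.

Group comparisons throughout the toolkit are reported as effect sizes with
permutation p-values rather than parametric tests alone. The permutation test
uses the two-sided mean difference, enumerating all label arrangements
exactly when feasible and otherwise Monte-Carlo sampling with the add-one
rule (p is never exactly zero). qPCR relative expression uses the comparative
2^−ΔCt method against the mean of one or more reference genes.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "TwoSample",
    "cohens_d",
    "permutation_pvalue",
    "relative_expression",
]


class TwoSample:
    """Two numeric samples to be compared (a vs b)."""

    def __init__(self, group_a, group_b, labels=("a", "b")):
        self.group_a = np.asarray(group_a, dtype=float)
        self.group_b = np.asarray(group_b, dtype=float)
        self.labels = labels
        if self.group_a.ndim != 1 or self.group_b.ndim != 1:
            raise InputError("groups must be 1-D sequences")


def cohens_d(s: TwoSample) -> float:
    """Cohen's d = (mean_a − mean_b)/pooled SD, with (n−1)-weighted pooling.

    Raises on zero pooled SD (degenerate). Sign convention: negative when
    group a has the smaller mean.
    """
    a, b = s.group_a, s.group_b
    if a.size < 2 or b.size < 2:
        raise InputError("Cohen's d needs ≥2 observations per group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb)
                     / (a.size + b.size - 2))
    if pooled == 0:
        raise InputError("zero pooled SD: effect size undefined")
    return float((a.mean() - b.mean()) / pooled)


def permutation_pvalue(
    s: TwoSample,
    n_perm: int = 5000,
    seed: Optional[int] = None,
    exact_limit: int = 20000,
) -> float:
    """Two-sided permutation p-value for the difference in group means.

    When the number of distinct label arrangements C(n_a+n_b, n_a) is at most
    ``exact_limit``, all splits are enumerated and p = #{|stat| ≥ |obs|}/total.
    Otherwise ``n_perm`` random relabelings are drawn from ``seed`` and
    p = (1 + #{|stat_perm| ≥ |stat_obs|})/(1 + n_perm).
    """
    a, b = s.group_a, s.group_b
    na, nb = a.size, b.size
    if na + nb < 3 or na < 1 or nb < 1:
        raise InputError("permutation test needs ≥3 observations in total")
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    n = na + nb
    total_sum = pooled.sum()

    if comb(n, na) <= exact_limit:
        count = 0
        n_arr = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            stat = abs(sa / na - (total_sum - sa) / nb)
            n_arr += 1
            if stat >= obs - 1e-12:
                count += 1
        return count / n_arr

    rng = np.random.default_rng(seed)
    mat = rng.permuted(np.broadcast_to(pooled, (n_perm, n)).copy(), axis=1)
    sa = mat[:, :na].sum(axis=1)
    stats = np.abs(sa / na - (total_sum - sa) / nb)
    count = int(np.sum(stats >= obs - 1e-12))
    return (1 + count) / (1 + n_perm)


def relative_expression(ct_target: float, ct_references: Sequence[float]) -> float:
    """Comparative 2^−ΔCt: ΔCt = Ct_target − mean(Ct_references).

    Reference genes are combined by the arithmetic mean of their Ct values
    (the geometric mean of their linear quantities).
    """
    refs = np.asarray(ct_references, dtype=float)
    if refs.size < 1:
        raise InputError("need at least one reference gene Ct")
    if not np.isfinite(ct_target) or not np.all(np.isfinite(refs)):
        raise InputError("Ct values must be finite")
    delta = ct_target - refs.mean()
    return float(2.0 ** (-delta))
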