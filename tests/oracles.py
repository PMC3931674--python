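"""Independent brute-force reference implementations used only by tests.

These deliberately use plain loops and O(n^2) rank counting so that they
share no code path with the package implementation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def _avg_ranks_desc(values: np.ndarray) -> np.ndarray:
    """Rank 1 = largest value; ties get the average of their positions."""
    n = len(values)
    ranks = np.empty(n)
    for i in range(n):
        stronger = sum(1 for j in range(n) if values[j] > values[i])
        ties = sum(1 for j in range(n) if values[j] == values[i])
        ranks[i] = stronger + (ties + 1) / 2.0
    return ranks


def brute_rank_product(
    values: np.ndarray, case_mask: np.ndarray, direction: str
) -> np.ndarray:
    """Geometric mean of per-comparison fold-change ranks, by enumeration."""
    case = np.flatnonzero(case_mask)
    ctrl = np.flatnonzero(~case_mask)
    n_genes = values.shape[0]
    rank_lists: list[np.ndarray] = []
    for i in case:
        for j in ctrl:
            fc = values[:, i] - values[:, j]
            if direction == "up":
                rank_lists.append(_avg_ranks_desc(fc))
            else:
                rank_lists.append(_avg_ranks_desc(-fc))
    k = len(rank_lists)
    rp = np.ones(n_genes)
    for ranks in rank_lists:
        rp *= ranks
    return rp ** (1.0 / k)


def brute_pfp(values: np.ndarray, case_mask: np.ndarray, direction: str) -> np.ndarray:
    """Exhaustive-permutation pfp: mean null exceedance count over rank position,
    monotonized along the RP ranking and clipped to [0, 1]."""
    n = values.shape[1]
    n_case = int(case_mask.sum())
    # RP values are compared rounded to 9 decimals (the tie rule: rank
    # patterns that are mathematically equal must compare equal)
    rp_obs = np.round(brute_rank_product(values, case_mask, direction), 9)
    n_genes = len(rp_obs)

    perm_rps = []
    for case_idx in combinations(range(n), n_case):
        mask = np.zeros(n, dtype=bool)
        mask[list(case_idx)] = True
        perm_rps.append(np.round(brute_rank_product(values, mask, direction), 9))

    pfp = np.empty(n_genes)
    for g in range(n_genes):
        rank_pos = sum(1 for h in range(n_genes) if rp_obs[h] <= rp_obs[g])
        mean_count = np.mean(
            [sum(1 for h in range(n_genes) if rp[h] <= rp_obs[g]) for rp in perm_rps]
        )
        pfp[g] = mean_count / rank_pos
    order = np.argsort(rp_obs, kind="stable")
    running = -np.inf
    for g in order:
        running = max(running, pfp[g])
        pfp[g] = running
    return np.clip(pfp, 0.0, 1.0)


def brute_cross_cohort(per_cohort_sets, min_datasets):
    """Membership counting over the union of all cohort sets."""
    all_gain = set().union(*(set(g) for g, _ in per_cohort_sets))
    all_loss = set().union(*(set(l) for _, l in per_cohort_sets))
    amplified = {
        g
        for g in all_gain
        if sum(1 for gain, _ in per_cohort_sets if g in gain) >= min_datasets
    }
    deleted = {
        g
        for g in all_loss
        if sum(1 for _, loss in per_cohort_sets if g in loss) >= min_datasets
    }
    return amplified, deleted
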