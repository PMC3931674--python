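"""Rank-product differential expression with permutation-estimated pfp.

Implements the two-sample rank product: for every one of the K = n1*n2
case-vs-control sample pairs, genes are ranked by fold change in the
requested direction (rank 1 = strongest), and a gene's rank product is the
geometric mean of its K ranks.  Small RP means the gene is consistently
regulated in that direction.

Significance is expressed as the estimated percentage of false predictions
(pfp): class labels are permuted, the rank products recomputed, and

    pfp(g) = E_perm[ #{g' : RP*(g') <= RP(g)} ] / #{g' : RP(g') <= RP(g)}

i.e. the expected number of null genes at least as extreme divided by the
gene's rank position.  pfp is made monotone non-decreasing along the RP
ranking and clipped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .simulate import STAGE_INDEX

logger = logging.getLogger(__name__)

#: label-assignment count below which pfp enumeration is exhaustive
EXHAUSTIVE_LIMIT = 10_000
DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 100

_DIRECTIONS = ("up", "down")


def _as_matrix(expr) -> tuple[np.ndarray, list[str]]:
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(dtype=float), list(expr.index)
    arr = np.asarray(expr, dtype=float)
    return arr, [f"g{i}" for i in range(arr.shape[0])]


def _case_mask(labels, n_samples: int) -> np.ndarray:
    """Normalize two-class labels to a boolean case mask.

    Accepts 0/1 (control/case) labels or stage names, in which case the
    higher stage is the case group.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != n_samples:
        raise ValueError(
            f"got {labels.shape[0]} labels for {n_samples} samples"
        )
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {list(uniq)}")
    if all(str(u) in STAGE_INDEX for u in uniq):
        case = max(uniq, key=lambda u: STAGE_INDEX[str(u)])
    else:
        try:
            case = max(uniq)
        except TypeError:
            raise ValueError(f"cannot order labels {list(uniq)}") from None
    mask = labels == case
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    return mask


def _rank_columns(a: np.ndarray) -> np.ndarray:
    """Ascending ranks along axis 0; average ranks on ties.

    Fast ordinal path when a column-wise tie check passes (ties are almost
    surely absent in continuous data); falls back to scipy's average ranks.
    """
    order = np.argsort(a, axis=0, kind="stable")
    srt = np.take_along_axis(a, order, axis=0)
    if np.any(srt[1:] == srt[:-1]):
        return rankdata(a, axis=0, method="average")
    ranks = np.empty(a.shape, dtype=float)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(1.0, a.shape[0] + 1)[:, None], a.shape), axis=0
    )
    return ranks


def _rp_both(values: np.ndarray, case_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank products for both directions from one ranking pass.

    With average ranks, rank_down = n_genes + 1 - rank_up columnwise, so the
    down-direction RP comes for free.
    """
    case = values[:, case_mask]
    ctrl = values[:, ~case_mask]
    n_genes = values.shape[0]
    fc = (case[:, :, None] - ctrl[:, None, :]).reshape(n_genes, -1)
    rank_up = _rank_columns(-fc)  # rank 1 = largest fold change
    log_up = np.log(rank_up).mean(axis=1)
    log_down = np.log(n_genes + 1 - rank_up).mean(axis=1)
    return np.exp(log_up), np.exp(log_down)


def rank_product(expr, labels, direction: str = "up") -> pd.Series:
    """Per-gene rank product over all pairwise case-vs-control comparisons.

    ``expr`` is a genes x samples matrix (DataFrame or array); ``labels``
    give the two classes (0/1 or stage names).  Smaller RP = stronger,
    more consistent regulation in ``direction``.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    values, genes = _as_matrix(expr)
    if np.isnan(values).any():
        raise ValueError("expression matrix contains missing values")
    mask = _case_mask(labels, values.shape[1])
    rp_up, rp_down = _rp_both(values, mask)
    return pd.Series(rp_up if direction == "up" else rp_down, index=genes, name=f"RP_{direction}")


def _label_permutations(mask: np.ndarray, n_perm: int, seed) -> tuple[list[np.ndarray], bool]:
    """Case-mask permutations: exhaustive when the space is small enough."""
    n = mask.size
    n_case = int(mask.sum())
    if comb(n, n_case) <= EXHAUSTIVE_LIMIT:
        perms = []
        for case_idx in combinations(range(n), n_case):
            m = np.zeros(n, dtype=bool)
            m[list(case_idx)] = True
            perms.append(m)
        return perms, True
    rng = np.random.default_rng(seed)
    perms = []
    for _ in range(n_perm):
        m = mask.copy()
        rng.shuffle(m)
        perms.append(m)
    return perms, False


#: RP values are compared after rounding to this many decimals so that
#: mathematically tied rank patterns compare equal regardless of the
#: floating-point path that produced them (distinct small-sample rank
#: products are separated by far more than this)
_RP_DECIMALS = 9


def _pfp_from_rp(rp: np.ndarray, perm_rps: list[np.ndarray]) -> np.ndarray:
    rp = np.round(rp, _RP_DECIMALS)
    sorted_rp = np.sort(rp)
    rank_pos = np.searchsorted(sorted_rp, rp, side="right")  # #{RP <= RP_g}
    counts = np.zeros_like(rp)
    for rp_star in perm_rps:
        counts += np.searchsorted(np.sort(np.round(rp_star, _RP_DECIMALS)), rp, side="right")
    pfp = counts / len(perm_rps) / rank_pos
    # enforce monotone non-decreasing pfp along the RP ranking
    order = np.argsort(rp, kind="stable")
    pfp[order] = np.maximum.accumulate(pfp[order])
    return np.clip(pfp, 0.0, 1.0)


def estimate_pfp(
    expr,
    labels,
    direction: str = "up",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> pd.Series:
    """Permutation-estimated percentage of false predictions per gene.

    Uses exhaustive enumeration of the label assignments when there are at
    most 10,000 of them, otherwise ``n_perm`` random permutations seeded by
    ``seed``.  Deterministic given the seed.
    """
    result = de_analysis(expr, labels, n_perm=n_perm, seed=seed)
    return result.pfp_up if direction == "up" else result.pfp_down


@dataclass
class DEResult:
    """Rank products, pfp values and selected gene sets for both directions."""

    rp_up: pd.Series
    pfp_up: pd.Series
    rp_down: pd.Series
    pfp_down: pd.Series
    alpha: float
    exhaustive: bool
    n_perm: int

    @property
    def up_set(self) -> frozenset[str]:
        return select_de(self, self.alpha)[0]

    @property
    def down_set(self) -> frozenset[str]:
        return select_de(self, self.alpha)[1]

    def to_frame(self) -> pd.DataFrame:
        up, down = select_de(self, self.alpha)
        return pd.DataFrame(
            {
                "RP_up": self.rp_up,
                "pfp_up": self.pfp_up,
                "RP_down": self.rp_down,
                "pfp_down": self.pfp_down,
                "selected_up": self.rp_up.index.isin(list(up)),
                "selected_down": self.rp_down.index.isin(list(down)),
            }
        )


def de_analysis(
    expr,
    labels,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> DEResult:
    """Rank products plus pfp for both directions in a single permutation pass."""
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    values, genes = _as_matrix(expr)
    if np.isnan(values).any():
        raise ValueError("expression matrix contains missing values")
    mask = _case_mask(labels, values.shape[1])
    rp_up, rp_down = _rp_both(values, mask)
    perms, exhaustive = _label_permutations(mask, n_perm, seed)
    ups, downs = [], []
    for m in perms:
        u, d = _rp_both(values, m)
        ups.append(u)
        downs.append(d)
    return DEResult(
        rp_up=pd.Series(rp_up, index=genes, name="RP_up"),
        pfp_up=pd.Series(_pfp_from_rp(rp_up, ups), index=genes, name="pfp_up"),
        rp_down=pd.Series(rp_down, index=genes, name="RP_down"),
        pfp_down=pd.Series(_pfp_from_rp(rp_down, downs), index=genes, name="pfp_down"),
        alpha=alpha,
        exhaustive=exhaustive,
        n_perm=len(perms),
    )


def select_de(de: DEResult, alpha: float) -> tuple[frozenset[str], frozenset[str]]:
    """Genes with pfp below the cutoff, per direction.

    ``alpha`` must lie in (0, 1]; ``alpha=1`` disables filtering and selects
    every gene (pfp is reported clipped to [0, 1]).
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if alpha >= 1.0:
        every = frozenset(de.pfp_up.index)
        return every, every
    up = frozenset(de.pfp_up.index[de.pfp_up < alpha])
    down = frozenset(de.pfp_down.index[de.pfp_down < alpha])
    return up, down


def intersect_datasets(
    sets_per_cohort: list[tuple[frozenset[str], frozenset[str]]],
) -> tuple[frozenset[str], frozenset[str]]:
    """Direction-consistent intersection of (up, down) sets across cohorts.

    A gene counts as differentially expressed only when every cohort calls
    it in the same direction.
    """
    if len(sets_per_cohort) < 2:
        raise ValueError("need DE sets from at least two cohorts to intersect")
    up = frozenset.intersection(*(frozenset(u) for u, _ in sets_per_cohort))
    down = frozenset.intersection(*(frozenset(d) for _, d in sets_per_cohort))
    return up, down


def de_for_task(
    cohorts,
    control_stage: str,
    case_stage: str,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[frozenset[str], frozenset[str], list[DEResult]]:
    """Per-cohort rank-product analysis for one stage pair, then intersect.

    Returns the cross-cohort (up, down) sets and the per-cohort results.
    """
    results, sets = [], []
    for i, cohort in enumerate(cohorts):
        samples = cohort.samples_of_stage(control_stage) + cohort.samples_of_stage(
            case_stage
        )
        sub = cohort.values[samples]
        labels = cohort.stages[samples].to_numpy()
        res = de_analysis(sub, labels, alpha=alpha, n_perm=n_perm, seed=seed + i)
        results.append(res)
        sets.append(select_de(res, alpha))
    up, down = intersect_datasets(sets)
    logger.info(
        "DE %s vs %s: %d up, %d down after intersecting %d cohorts",
        control_stage, case_stage, len(up), len(down), len(cohorts),
    )
    return up, down, results
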