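"""Statistical evaluation of the AUC result table.

AUC cells are dichotomized at a cutoff (0.60 and 0.80 by default) into
observed successes S0 and failures F0 per criterion, and compared with the
expected 75%/25% success/failure composition by a chi-square goodness-of-fit
test (df = 1), with residuals (|Se - S0|, |Fe - F0|).  Per-criterion AUC
means with standard errors summarize the table across (dataset, task) cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CUTOFFS: tuple[float, ...] = (0.60, 0.80)
DEFAULT_P_SUCCESS = 0.75


def _as_table(table) -> pd.DataFrame:
    if hasattr(table, "table"):  # ExperimentResult
        table = table.table
    if not {"criterion", "auc"}.issubset(table.columns):
        raise ValueError("result table needs 'criterion' and 'auc' columns")
    return table


def success_failure_counts(
    table, criterion: str, cutoff: float
) -> tuple[int, int]:
    """Observed successes (AUC > cutoff) and failures among a criterion's cells."""
    table = _as_table(table)
    aucs = table.loc[table["criterion"] == criterion, "auc"].dropna()
    if aucs.empty:
        raise ValueError(f"no cells for criterion {criterion!r}")
    s0 = int((aucs > cutoff).sum())
    return s0, len(aucs) - s0


@dataclass(frozen=True)
class GoodnessOfFit:
    """Chi-square goodness of fit of observed vs expected success counts."""

    s0: int
    f0: int
    se: float
    fe: float
    chi2: float
    p_value: float
    residuals: tuple[float, float]  # (|Se - S0|, |Fe - F0|)
    criterion: str | None = None
    cutoff: float | None = None

    @property
    def n_cells(self) -> int:
        return self.s0 + self.f0


def gof_test(
    counts: tuple[int, int],
    p_success: float = DEFAULT_P_SUCCESS,
    criterion: str | None = None,
    cutoff: float | None = None,
) -> GoodnessOfFit:
    """Chi-square test of (S0, F0) against expected (p*n, (1-p)*n), df=1."""
    s0, f0 = counts
    n = s0 + f0
    if n < 1:
        raise ValueError("need at least one observed cell")
    if not 0 < p_success < 1:
        raise ValueError(f"p_success must be in (0, 1), got {p_success}")
    se = p_success * n
    fe = (1.0 - p_success) * n
    chi2 = (s0 - se) ** 2 / se + (f0 - fe) ** 2 / fe
    p_value = float(stats.chi2.sf(chi2, df=1))
    return GoodnessOfFit(
        s0=s0,
        f0=f0,
        se=se,
        fe=fe,
        chi2=float(chi2),
        p_value=p_value,
        residuals=(abs(se - s0), abs(fe - f0)),
        criterion=criterion,
        cutoff=cutoff,
    )


def compare_criteria(
    table,
    criteria=None,
    cutoffs=DEFAULT_CUTOFFS,
    p_success: float = DEFAULT_P_SUCCESS,
) -> pd.DataFrame:
    """Goodness-of-fit table over criteria x cutoffs (the Table-5/6 analogue)."""
    table = _as_table(table)
    if criteria is None:
        criteria = list(pd.unique(table["criterion"]))
    rows = []
    for criterion in criteria:
        for cutoff in cutoffs:
            counts = success_failure_counts(table, criterion, cutoff)
            g = gof_test(counts, p_success, criterion=criterion, cutoff=cutoff)
            rows.append(
                {
                    "criterion": criterion,
                    "cutoff": cutoff,
                    "S0": g.s0,
                    "F0": g.f0,
                    "Se": g.se,
                    "Fe": g.fe,
                    "chi2": g.chi2,
                    "p_value": g.p_value,
                    "residual_S": g.residuals[0],
                    "residual_F": g.residuals[1],
                }
            )
    return pd.DataFrame(rows)


def compare_pair(
    table,
    criterion_a: str,
    criterion_b: str,
    cutoff: float,
    p_success: float = DEFAULT_P_SUCCESS,
) -> tuple[GoodnessOfFit, GoodnessOfFit]:
    """Pairwise model comparison: one goodness-of-fit test per criterion,
    reported jointly (each with its own residual pair)."""
    table = _as_table(table)
    return tuple(
        gof_test(
            success_failure_counts(table, criterion, cutoff),
            p_success,
            criterion=criterion,
            cutoff=cutoff,
        )
        for criterion in (criterion_a, criterion_b)
    )


def summarize_by_criterion(table) -> pd.DataFrame:
    """Mean AUC and its standard error per criterion over all cells.

    SEM is reported as NaN (undefined) for criteria with fewer than two cells.
    """
    table = _as_table(table)
    rows = []
    for criterion, group in table.groupby("criterion", sort=False):
        aucs = group["auc"].dropna().to_numpy()
        mean = float(np.mean(aucs)) if aucs.size else float("nan")
        sem = float(stats.sem(aucs, ddof=1)) if aucs.size >= 2 else float("nan")
        rows.append(
            {"criterion": criterion, "mean_auc": mean, "sem": sem, "n_cells": aucs.size}
        )
    return pd.DataFrame(rows)
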