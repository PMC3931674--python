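"""Recurrent copy-number alteration calling from gene-level log2 ratios.

A sample's gene is called a gain when its tumor/normal log2 ratio reaches
``gain_thr``, a loss when it falls to ``loss_thr``, neutral otherwise.  A
gene is recurrently altered within a cohort when the call frequency reaches
``min_freq``, and counted as amplified/deleted overall when the same-direction
call recurs in at least ``min_datasets`` cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GAIN, NEUTRAL, LOSS = 1, 0, -1

DEFAULT_GAIN_THR = 0.3
DEFAULT_LOSS_THR = -0.3
DEFAULT_MIN_FREQ = 0.25
DEFAULT_MIN_DATASETS = 2


def call_sample_alterations(
    logratio,
    gain_thr: float = DEFAULT_GAIN_THR,
    loss_thr: float = DEFAULT_LOSS_THR,
):
    """Per-gene gain/loss/neutral calls from log2 ratios.

    Works on a vector (one sample) or a genes x samples matrix; returns the
    same shape with values GAIN=1, NEUTRAL=0, LOSS=-1.  Gains and losses are
    mutually exclusive by construction (``gain_thr > 0 > loss_thr``).
    """
    if not gain_thr > 0 > loss_thr:
        raise ValueError(
            f"thresholds must satisfy gain_thr > 0 > loss_thr, "
            f"got gain_thr={gain_thr}, loss_thr={loss_thr}"
        )
    frame = isinstance(logratio, (pd.DataFrame, pd.Series))
    values = np.asarray(logratio, dtype=float)
    calls = np.where(values >= gain_thr, GAIN, np.where(values <= loss_thr, LOSS, NEUTRAL))
    if frame:
        if isinstance(logratio, pd.DataFrame):
            return pd.DataFrame(calls, index=logratio.index, columns=logratio.columns)
        return pd.Series(calls, index=logratio.index)
    return calls


def alteration_frequencies(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-gene gain and loss call frequencies across a cohort's samples."""
    if calls.size == 0:
        raise ValueError("empty call matrix")
    return pd.DataFrame(
        {
            "gain_freq": (calls == GAIN).mean(axis=1),
            "loss_freq": (calls == LOSS).mean(axis=1),
        }
    )


def cohort_recurrent(
    calls: pd.DataFrame, min_freq: float = DEFAULT_MIN_FREQ
) -> tuple[frozenset[str], frozenset[str]]:
    """Genes altered in at least ``min_freq`` of a cohort's samples."""
    if not 0 < min_freq <= 1:
        raise ValueError(f"min_freq must be in (0, 1], got {min_freq}")
    freq = alteration_frequencies(calls)
    gain = frozenset(freq.index[freq["gain_freq"] >= min_freq])
    loss = frozenset(freq.index[freq["loss_freq"] >= min_freq])
    return gain, loss


def cross_cohort_altered(
    per_cohort_sets: list[tuple[frozenset[str], frozenset[str]]],
    min_datasets: int = DEFAULT_MIN_DATASETS,
) -> tuple[frozenset[str], frozenset[str]]:
    """Genes whose alteration is verified in >= ``min_datasets`` cohorts."""
    if not per_cohort_sets:
        raise ValueError("no cohort alteration sets given")
    if not 1 <= min_datasets <= len(per_cohort_sets):
        raise ValueError(
            f"min_datasets={min_datasets} out of range for "
            f"{len(per_cohort_sets)} cohorts"
        )
    gain_counts: dict[str, int] = {}
    loss_counts: dict[str, int] = {}
    for gain, loss in per_cohort_sets:
        for g in gain:
            gain_counts[g] = gain_counts.get(g, 0) + 1
        for g in loss:
            loss_counts[g] = loss_counts.get(g, 0) + 1
    amplified = frozenset(g for g, c in gain_counts.items() if c >= min_datasets)
    deleted = frozenset(g for g, c in loss_counts.items() if c >= min_datasets)
    return amplified, deleted


@dataclass
class AlterationResult:
    """Per-cohort alteration frequencies/sets and the cross-cohort consensus."""

    frequencies: dict[str, pd.DataFrame]  # cohort name -> gain/loss frequencies
    per_cohort_sets: dict[str, tuple[frozenset[str], frozenset[str]]]
    amplified_set: frozenset[str]
    deleted_set: frozenset[str]

    def consensus_frame(self) -> pd.DataFrame:
        rows = [(g, "amplified") for g in sorted(self.amplified_set)]
        rows += [(g, "deleted") for g in sorted(self.deleted_set)]
        return pd.DataFrame(rows, columns=["gene_id", "direction"])

    def write(self, directory) -> None:
        """Per-cohort frequency tables plus the consensus gene sets, as TSV."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, freq in self.frequencies.items():
            freq.to_csv(directory / f"{name}_alteration_freq.tsv", sep="\t",
                        index_label="gene_id")
        self.consensus_frame().to_csv(
            directory / "altered_genes.tsv", sep="\t", index=False
        )


def alterations_for_task(
    cna_cohorts,
    case_stage: str,
    gain_thr: float = DEFAULT_GAIN_THR,
    loss_thr: float = DEFAULT_LOSS_THR,
    min_freq: float = DEFAULT_MIN_FREQ,
    min_datasets: int = DEFAULT_MIN_DATASETS,
) -> AlterationResult:
    """Recurrent alterations among a task's case-stage samples, per cohort,
    then verified across cohorts.

    Recurrence is evaluated on the case-stage samples because the alteration
    burden relevant to a progression task is the one acquired by the more
    advanced stage.
    """
    frequencies: dict[str, pd.DataFrame] = {}
    per_cohort: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    for cohort in cna_cohorts:
        samples = cohort.samples_of_stage(case_stage)
        if not samples:
            raise ValueError(f"cohort {cohort.name} has no stage-{case_stage} samples")
        calls = call_sample_alterations(cohort.values[samples], gain_thr, loss_thr)
        frequencies[cohort.name] = alteration_frequencies(calls)
        per_cohort[cohort.name] = cohort_recurrent(calls, min_freq)
    amplified, deleted = cross_cohort_altered(list(per_cohort.values()), min_datasets)
    logger.info(
        "CNA stage %s: %d amplified, %d deleted across %d cohorts",
        case_stage, len(amplified), len(deleted), len(cna_cohorts),
    )
    return AlterationResult(
        frequencies=frequencies,
        per_cohort_sets=per_cohort,
        amplified_set=amplified,
        deleted_set=deleted,
    )
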