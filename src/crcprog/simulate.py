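"""Multi-cohort synthetic study generator with planted ground truth.

The generator emulates the structure of a multi-cohort colorectal-cancer
study: several expression cohorts and several copy-number cohorts, each with
stage II/III/IV patients.  A planted subset of genes is concurrently
up-regulated and gained (``up_amplified``) or down-regulated and lost
(``down_deleted``); further subsets carry expression-only (``de_only``) or
copy-number-only (``cna_only``) signal; the rest are ``null``.

Expression is simulated directly on the log2 summary scale.  Copy number is
simulated as gene-level log2 tumor/normal ratios.  The dosage model couples
the two: for coupled genes the expression shift is applied only in samples
that carry the alteration, drawn per sample with probability
``cna_penetrance`` in stages above the baseline stage II.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import tsv

#: ordered tumor stages used throughout the package
STAGES: tuple[str, ...] = ("II", "III", "IV")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: gene classes of the planted ground truth
GENE_CLASSES: tuple[str, ...] = (
    "up_amplified",
    "down_deleted",
    "de_only",
    "cna_only",
    "null",
)


class SimulationConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic multi-cohort study.

    Effect sizes are in log2 units: ``de_effect`` is the expression shift per
    stage step (stage II -> 0, III -> 1x, IV -> 2x), ``cna_effect`` the
    log2-ratio magnitude of a gain/loss.  ``cna_penetrance`` is the fraction
    of above-baseline-stage samples carrying a planted alteration.
    """

    n_expression_cohorts: int = 3
    n_cna_cohorts: int = 3
    n_genes: int = 600
    samples_per_stage: Mapping[str, int] = field(
        default_factory=lambda: {"II": 30, "III": 30, "IV": 30}
    )
    n_up_amplified: int = 50
    n_down_deleted: int = 50
    n_de_only: int = 50
    n_cna_only: int = 50
    de_effect: float = 1.0
    cna_effect: float = 0.8
    cna_penetrance: float = 0.8
    noise_sd: float = 0.5
    batch_sd: float = 0.5
    cna_noise_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_expression_cohorts": self.n_expression_cohorts,
            "n_cna_cohorts": self.n_cna_cohorts,
            "n_genes": self.n_genes,
            "n_up_amplified": self.n_up_amplified,
            "n_down_deleted": self.n_down_deleted,
            "n_de_only": self.n_de_only,
            "n_cna_only": self.n_cna_only,
        }
        for name, value in counts.items():
            if value < 0:
                raise SimulationConfigError(f"{name} must be >= 0, got {value}")
        planted = (
            self.n_up_amplified
            + self.n_down_deleted
            + self.n_de_only
            + self.n_cna_only
        )
        if planted > self.n_genes:
            raise SimulationConfigError(
                f"n_genes={self.n_genes} is smaller than the {planted} planted genes"
            )
        for stage, count in self.samples_per_stage.items():
            if stage not in STAGE_INDEX:
                raise SimulationConfigError(
                    f"samples_per_stage contains unknown stage {stage!r}"
                )
            if count < 0:
                raise SimulationConfigError(
                    f"samples_per_stage[{stage!r}] must be >= 0, got {count}"
                )
        if self.noise_sd <= 0:
            raise SimulationConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.cna_noise_sd <= 0:
            raise SimulationConfigError(
                f"cna_noise_sd must be > 0, got {self.cna_noise_sd}"
            )
        if self.batch_sd < 0:
            raise SimulationConfigError(f"batch_sd must be >= 0, got {self.batch_sd}")
        if not 0 < self.cna_penetrance <= 1:
            raise SimulationConfigError(
                f"cna_penetrance must be in (0, 1], got {self.cna_penetrance}"
            )


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration with all planted effects set to zero.

    Stage labels are then exchangeable: every downstream selection is a false
    positive by construction.
    """
    base = SimulationConfig(seed=seed, de_effect=0.0, cna_effect=0.0)
    return replace(base, **overrides)


def cna_concentrated_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Defaults with all differential-expression signal in CNA-altered genes.

    ``n_de_only=0`` so the DE gene set and the combined signature carry the
    same information; this is the regime in which combined and relational
    criteria are expected to keep up with the expression-only criterion.
    """
    base = SimulationConfig(seed=seed, n_de_only=0)
    return replace(base, **overrides)


@dataclass(frozen=True)
class GroundTruth:
    """Planted gene classes, directions and effect sizes of a simulated study.

    ``expression_direction`` and ``cna_direction`` map gene_id to +1/-1/0
    (up/down/none); ``de_only`` genes are split half up-, half down-regulated.
    """

    classes: pd.Series  # gene_id -> class name
    expression_direction: pd.Series
    cna_direction: pd.Series
    de_effect: float
    cna_effect: float
    cna_penetrance: float

    def genes_of(self, cls: str) -> frozenset[str]:
        if cls not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {cls!r}")
        return frozenset(self.classes.index[self.classes == cls])

    def expected_expression_shift(self, control_stage: str, case_stage: str) -> float:
        """Planted per-gene log2 shift between two stages (de/up/down classes)."""
        steps = STAGE_INDEX[case_stage] - STAGE_INDEX[control_stage]
        return self.de_effect * steps


@dataclass
class ExpressionCohort:
    """Log2 expression values (genes x samples) with per-sample stages."""

    name: str
    values: pd.DataFrame
    stages: pd.Series  # sample_id -> stage

    def samples_of_stage(self, stage: str) -> list[str]:
        return list(self.stages.index[self.stages == stage])

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        tsv.write_matrix(self.values, directory / f"{self.name}_matrix.tsv")
        tsv.write_sample_annotations(
            self.stages, self.name, directory / f"{self.name}_samples.tsv"
        )


class CNACohort(ExpressionCohort):
    """Gene-level log2 tumor/normal copy-number ratios with stages."""


def _sample_ids(name: str, samples_per_stage: Mapping[str, int]) -> pd.Series:
    ids, stages = [], []
    for stage in STAGES:
        for j in range(samples_per_stage.get(stage, 0)):
            ids.append(f"{name}_{stage}_{j + 1:02d}")
            stages.append(stage)
    return pd.Series(stages, index=ids, name="stage")


def generate_study(
    config: SimulationConfig,
) -> tuple[list[ExpressionCohort], list[CNACohort], GroundTruth]:
    """Generate expression cohorts, CNA cohorts and the planted ground truth.

    Deterministic given ``config.seed`` (bit-identical matrices on repeat).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    width = max(4, len(str(config.n_genes)))
    genes = pd.Index(
        [f"G{i + 1:0{width}d}" for i in range(config.n_genes)], name="gene_id"
    )
    classes = np.array(["null"] * config.n_genes, dtype=object)
    bounds = np.cumsum(
        [
            config.n_up_amplified,
            config.n_down_deleted,
            config.n_de_only,
            config.n_cna_only,
        ]
    )
    classes[: bounds[0]] = "up_amplified"
    classes[bounds[0] : bounds[1]] = "down_deleted"
    classes[bounds[1] : bounds[2]] = "de_only"
    classes[bounds[2] : bounds[3]] = "cna_only"

    # expression direction of the shift (+1 up, -1 down, 0 none);
    # de_only genes are split half up, half down to keep directions balanced
    expr_dir = np.zeros(config.n_genes)
    expr_dir[classes == "up_amplified"] = 1.0
    expr_dir[classes == "down_deleted"] = -1.0
    de_only_idx = np.flatnonzero(classes == "de_only")
    expr_dir[de_only_idx[: len(de_only_idx) // 2 + len(de_only_idx) % 2]] = 1.0
    expr_dir[de_only_idx[len(de_only_idx) // 2 + len(de_only_idx) % 2 :]] = -1.0
    # copy-number direction (+gain / -loss)
    cna_dir = np.zeros(config.n_genes)
    cna_dir[classes == "up_amplified"] = 1.0
    cna_dir[classes == "cna_only"] = 1.0
    cna_dir[classes == "down_deleted"] = -1.0

    truth = GroundTruth(
        classes=pd.Series(classes, index=genes, name="class"),
        expression_direction=pd.Series(expr_dir, index=genes, name="expr_dir"),
        cna_direction=pd.Series(cna_dir, index=genes, name="cna_dir"),
        de_effect=config.de_effect,
        cna_effect=config.cna_effect,
        cna_penetrance=config.cna_penetrance,
    )

    # per-gene log2 baselines, shared across cohorts
    baseline = rng.uniform(4.0, 12.0, config.n_genes)
    coupled = (classes == "up_amplified") | (classes == "down_deleted")
    de_only = classes == "de_only"

    expression_cohorts: list[ExpressionCohort] = []
    for c in range(config.n_expression_cohorts):
        name = f"EXPR{c + 1}"
        stages = _sample_ids(name, config.samples_per_stage)
        n = len(stages)
        stage_steps = stages.map(STAGE_INDEX).to_numpy(dtype=float)
        batch = rng.normal(0.0, config.batch_sd, config.n_genes)
        values = (
            baseline[:, None]
            + batch[:, None]
            + rng.normal(0.0, config.noise_sd, (config.n_genes, n))
        )
        # dosage model: coupled genes shift only in alteration carriers
        carrier = (rng.random((config.n_genes, n)) < config.cna_penetrance) & (
            stage_steps[None, :] > 0
        )
        shift = expr_dir[:, None] * config.de_effect * stage_steps[None, :]
        values += np.where(coupled[:, None] & carrier, shift, 0.0)
        values += np.where(de_only[:, None], shift, 0.0)
        expression_cohorts.append(
            ExpressionCohort(
                name=name,
                values=pd.DataFrame(values, index=genes, columns=stages.index),
                stages=stages,
            )
        )

    cna_cohorts: list[CNACohort] = []
    for c in range(config.n_cna_cohorts):
        name = f"CNA{c + 1}"
        stages = _sample_ids(name, config.samples_per_stage)
        n = len(stages)
        stage_steps = stages.map(STAGE_INDEX).to_numpy(dtype=float)
        ratios = rng.normal(0.0, config.cna_noise_sd, (config.n_genes, n))
        carrier = (rng.random((config.n_genes, n)) < config.cna_penetrance) & (
            stage_steps[None, :] > 0
        )
        altered = cna_dir != 0.0
        ratios += np.where(
            altered[:, None] & carrier, cna_dir[:, None] * config.cna_effect, 0.0
        )
        cna_cohorts.append(
            CNACohort(
                name=name,
                values=pd.DataFrame(ratios, index=genes, columns=stages.index),
                stages=stages,
            )
        )

    return expression_cohorts, cna_cohorts, truth


def write_study(
    expression_cohorts: list[ExpressionCohort],
    cna_cohorts: list[CNACohort],
    truth: GroundTruth,
    directory: str | Path,
) -> None:
    """Write all cohorts plus the gene-annotation table in the TSV dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cohort in [*expression_cohorts, *cna_cohorts]:
        cohort.write(directory)
    tsv.write_gene_annotations(truth.classes, directory / "gene_classes.tsv")
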