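"""Stage-progression inference: grid-optimized linear SVM AUC per criterion.

For every (criterion, dataset, task) cell the classifier is a linear SVM
whose cost parameter C runs over a fixed linear grid (default: 1101 points
from -10 to 10000, non-positive values floored at 1e-3); each grid point is
scored by stratified 10-fold cross-validated AUC and the cell reports the
grid maximum.  This mirrors a parameter-optimization loop wrapped around
cross-validation and is therefore an optimistically biased protocol by
design; the bias applies equally to every criterion being compared.

Criteria (feature spaces):

* ``NCOMB`` – expression of the differentially expressed genes (SA datatype);
* ``COMB`` – expression of the combined up-amplified/down-deleted signature;
* ``COMBDE``/``COMBDM``/``COMBDK``/``COMBDT`` – dissimilarities to the
  stage-II prototype patients over the signature genes (RA datatype), with
  Euclidean / Manhattan / Kullback-Leibler / Kendall-tau distances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from . import cna_calls, expression_de
from .cna_calls import AlterationResult, alterations_for_task
from .dissim import PrototypeSet, build_dissimilarity_matrix, select_prototypes, signature_gene_index
from .expression_de import DEFAULT_ALPHA, DEFAULT_N_PERM, de_for_task
from .signature import CombinedSignature, combine_signature
from .simulate import (
    STAGE_INDEX,
    ExpressionCohort,
    GroundTruth,
    SimulationConfig,
    generate_study,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProgressionTask:
    """A control-vs-case stage pair; controls are labeled 0, cases 1."""

    control_stage: str
    case_stage: str

    def __post_init__(self) -> None:
        for stage in (self.control_stage, self.case_stage):
            if stage not in STAGE_INDEX:
                raise ValueError(f"unknown stage {stage!r}")
        if STAGE_INDEX[self.control_stage] >= STAGE_INDEX[self.case_stage]:
            raise ValueError(
                f"control stage must precede case stage, got "
                f"{self.control_stage} vs {self.case_stage}"
            )

    @property
    def name(self) -> str:
        return f"{self.control_stage}_vs_{self.case_stage}"


#: the three canonical progression tasks
DEFAULT_TASKS: tuple[ProgressionTask, ...] = (
    ProgressionTask("II", "III"),
    ProgressionTask("II", "IV"),
    ProgressionTask("III", "IV"),
)


@dataclass(frozen=True)
class Criterion:
    """An evaluation criterion: which datatype feeds the classifier."""

    name: str
    datatype: str  # SA | COMB | RA
    metric: str | None = None

    def __post_init__(self) -> None:
        if self.datatype not in ("SA", "COMB", "RA"):
            raise ValueError(f"unknown datatype {self.datatype!r}")
        if (self.datatype == "RA") != (self.metric is not None):
            raise ValueError("exactly the RA datatype carries a metric")


CRITERIA: dict[str, Criterion] = {
    "NCOMB": Criterion("NCOMB", "SA"),
    "COMB": Criterion("COMB", "COMB"),
    "COMBDE": Criterion("COMBDE", "RA", "euclidean"),
    "COMBDM": Criterion("COMBDM", "RA", "manhattan"),
    "COMBDK": Criterion("COMBDK", "RA", "kl"),
    "COMBDT": Criterion("COMBDT", "RA", "kendall_tau"),
}
DEFAULT_CRITERIA: tuple[Criterion, ...] = tuple(CRITERIA.values())


@dataclass(frozen=True)
class SVMGrid:
    """Linear grid of SVM cost values.

    The printed grid starts below zero; non-positive points are floored at
    ``c_floor`` and still count toward the model total, so the default grid
    always contains ``c_steps + 1 = 1101`` evaluated models.
    """

    c_min: float = -10.0
    c_max: float = 10000.0
    c_steps: int = 1100
    c_floor: float = 1e-3

    def values(self) -> np.ndarray:
        grid = np.linspace(self.c_min, self.c_max, self.c_steps + 1)
        return np.where(grid <= 0.0, self.c_floor, grid)

    @property
    def n_models(self) -> int:
        return self.c_steps + 1


def extract_features(
    cohort: ExpressionCohort,
    criterion: Criterion,
    task: ProgressionTask,
    de_sets: tuple[frozenset[str], frozenset[str]],
    signature: CombinedSignature,
    prototypes: PrototypeSet | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix (patients x features), 0/1 labels and feature names.

    SA uses the DE genes' expression, COMB the signature genes' expression,
    RA the rows of the patient-to-prototype dissimilarity matrix.
    """
    controls = cohort.samples_of_stage(task.control_stage)
    cases = cohort.samples_of_stage(task.case_stage)
    if not controls or not cases:
        raise ValueError(
            f"cohort {cohort.name} lacks samples for task {task.name}"
        )
    samples = controls + cases
    y = np.array([0] * len(controls) + [1] * len(cases))

    if criterion.datatype == "SA":
        up, down = de_sets
        genes = frozenset(up) | frozenset(down)
        if not genes:
            raise ValueError(
                f"differential expression produced no genes for task {task.name}"
            )
        index = cohort.values.index[cohort.values.index.isin(genes)]
        X = cohort.values.loc[index, samples].to_numpy(dtype=float).T
        return X, y, list(index)

    if criterion.datatype == "COMB":
        if not signature.genes:
            raise ValueError(
                f"combined signature is empty for task {task.name}"
            )
        index = signature_gene_index(cohort.values, signature)
        X = cohort.values.loc[index, samples].to_numpy(dtype=float).T
        return X, y, list(index)

    # RA
    if prototypes is None:
        prototypes = select_prototypes(cohort, "II", signature)
    index = prototypes.vectors.index
    patients = cohort.values.loc[index, samples]
    D = build_dissimilarity_matrix(patients, prototypes, criterion.metric)
    return D.values.to_numpy(dtype=float), y, list(D.values.columns)


@dataclass
class AUCResult:
    auc: float
    best_c: float
    n_models: int
    n_folds: int


def _prepare_folds(X: np.ndarray, y: np.ndarray, splits) -> list[tuple]:
    """Per-fold standardized train/test arrays (scaling is C-independent)."""
    folds = []
    for train, test in splits:
        scaler = StandardScaler().fit(X[train])
        folds.append(
            (scaler.transform(X[train]), y[train], scaler.transform(X[test]), y[test])
        )
    return folds


def _cv_auc(folds, C: float) -> float:
    """Cross-validated AUC: held-out decision scores are pooled within each
    fold into one ROC, and the per-fold AUCs are averaged."""
    aucs = [
        roc_auc_score(y_test, LinearSVC(C=C, random_state=0, max_iter=20000)
                      .fit(X_train, y_train).decision_function(X_test))
        for X_train, y_train, X_test, y_test in folds
    ]
    return float(np.mean(aucs))


def evaluate_auc(
    X,
    y,
    grid: SVMGrid = SVMGrid(),
    k: int = 10,
    seed: int = 0,
    nested: bool = False,
) -> AUCResult:
    """Grid-maximal stratified k-fold cross-validated AUC.

    Every grid point is an evaluated model; the reported AUC is the maximum
    over the grid and ``best_c`` the smallest C attaining it.  Fold
    assignment is stratified, shuffled with ``seed``, and shared across the
    whole grid, so the result is deterministic given the seed.

    The default reproduces the optimization-around-cross-validation
    protocol, an optimistically biased estimate.  ``nested=True`` instead
    selects C inside each training fold and scores only held-out data,
    giving an unbiased (and typically lower) estimate; it is not the
    default because the comparisons between criteria use the biased
    protocol uniformly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    class_counts = np.bincount(y.astype(int)) if y.dtype.kind in "iub" else None
    uniq = np.unique(y)
    if len(uniq) < 2:
        raise ValueError("labels contain a single class")
    min_class = min(int((y == u).sum()) for u in uniq)
    k_eff = max(2, min(k, min_class))
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=int(seed) % (2**31))
    folds = _prepare_folds(X, y, list(skf.split(X, y)))

    grid_values = grid.values()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if nested:
            # unbiased variant: the grid search runs inside each training
            # fold; the outer folds only ever score the selected model
            aucs, chosen = [], []
            for X_train, y_train, X_test, y_test in folds:
                inner = evaluate_auc(
                    X_train, y_train, grid=grid, k=k, seed=seed + 1, nested=False
                )
                clf = LinearSVC(C=inner.best_c, random_state=0, max_iter=20000)
                clf.fit(X_train, y_train)
                aucs.append(roc_auc_score(y_test, clf.decision_function(X_test)))
                chosen.append(inner.best_c)
            return AUCResult(
                auc=float(np.mean(aucs)),
                best_c=float(np.median(chosen)),
                n_models=len(grid_values),
                n_folds=k_eff,
            )
        cache: dict[float, float] = {}
        best_auc, best_c = -np.inf, None
        for C in grid_values:
            c_key = float(C)
            if c_key not in cache:
                cache[c_key] = _cv_auc(folds, c_key)
            if cache[c_key] > best_auc:
                best_auc, best_c = cache[c_key], c_key
    return AUCResult(
        auc=best_auc, best_c=best_c, n_models=len(grid_values), n_folds=k_eff
    )


@dataclass
class ExperimentResult:
    """Full factorial AUC table plus any per-cell failures."""

    table: pd.DataFrame  # columns: criterion, dataset, task, auc, best_c
    failures: list[tuple[str, str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def run_experiment(
    datasets: list[ExpressionCohort],
    tasks,
    criteria,
    de_sets: dict[str, tuple[frozenset[str], frozenset[str]]],
    signatures: dict[str, CombinedSignature],
    grid: SVMGrid = SVMGrid(),
    k: int = 10,
    seed: int = 0,
    prototype_stage: str = "II",
) -> ExperimentResult:
    """AUC for every (criterion, dataset, task) cell.

    ``de_sets`` and ``signatures`` are keyed by task name.  A failing cell is
    recorded and the run continues; the result's ``ok`` flag reflects
    partial failure.
    """
    rows, failures = [], []
    for dataset in datasets:
        for task in tasks:
            prototypes = None
            sig = signatures[task.name]
            if sig.genes:
                try:
                    prototypes = select_prototypes(dataset, prototype_stage, sig)
                except ValueError:
                    prototypes = None
            for criterion in criteria:
                try:
                    X, y, _ = extract_features(
                        dataset, criterion, task, de_sets[task.name], sig, prototypes
                    )
                    result = evaluate_auc(X, y, grid=grid, k=k, seed=seed)
                    rows.append(
                        (criterion.name, dataset.name, task.name, result.auc, result.best_c)
                    )
                except Exception as exc:  # noqa: BLE001 - cell isolation is the contract
                    logger.error(
                        "cell (%s, %s, %s) failed: %s",
                        criterion.name, dataset.name, task.name, exc,
                    )
                    failures.append((criterion.name, dataset.name, task.name, str(exc)))
    table = pd.DataFrame(rows, columns=["criterion", "dataset", "task", "auc", "best_c"])
    return ExperimentResult(table=table, failures=failures)


@dataclass
class StudyResult:
    """All artifacts of one synthetic end-to-end study."""

    config: SimulationConfig
    truth: GroundTruth
    de_sets: dict[str, tuple[frozenset[str], frozenset[str]]]
    alterations: dict[str, AlterationResult]
    signatures: dict[str, CombinedSignature]
    experiment: ExperimentResult


def build_signatures(
    expression_cohorts,
    cna_cohorts,
    tasks=DEFAULT_TASKS,
    n_de_cohorts: int = 2,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    gain_thr: float = cna_calls.DEFAULT_GAIN_THR,
    loss_thr: float = cna_calls.DEFAULT_LOSS_THR,
    min_freq: float = cna_calls.DEFAULT_MIN_FREQ,
    min_datasets: int = cna_calls.DEFAULT_MIN_DATASETS,
    seed: int = 0,
):
    """Per-task DE sets, CNA consensus and combined signatures.

    Differential expression uses the first ``n_de_cohorts`` expression
    cohorts (two in the reference design); every expression cohort is still
    available downstream for classification.
    """
    de_sets: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    alterations: dict[str, AlterationResult] = {}
    signatures: dict[str, CombinedSignature] = {}
    for t, task in enumerate(tasks):
        up, down, _ = de_for_task(
            expression_cohorts[:n_de_cohorts],
            task.control_stage,
            task.case_stage,
            alpha=alpha,
            n_perm=n_perm,
            seed=seed + 10 * t,
        )
        de_sets[task.name] = (up, down)
        alt = alterations_for_task(
            cna_cohorts,
            task.case_stage,
            gain_thr=gain_thr,
            loss_thr=loss_thr,
            min_freq=min_freq,
            min_datasets=min_datasets,
        )
        alterations[task.name] = alt
        signatures[task.name] = combine_signature(
            up, down, alt.amplified_set, alt.deleted_set, task=task.name
        )
    return de_sets, alterations, signatures


def run_study(
    config: SimulationConfig,
    tasks=DEFAULT_TASKS,
    criteria=DEFAULT_CRITERIA,
    grid: SVMGrid = SVMGrid(),
    k: int = 10,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    n_de_cohorts: int = 2,
    **signature_kwargs,
) -> StudyResult:
    """Simulate a study and run the whole pipeline on it.

    All randomness (simulation, pfp permutations, CV folds) derives from
    ``config.seed``.
    """
    expression_cohorts, cna_cohorts, truth = generate_study(config)
    ss = np.random.SeedSequence(config.seed)
    de_seed, cv_seed = (int(s) % (2**31) for s in ss.generate_state(2))
    de_sets, alterations, signatures = build_signatures(
        expression_cohorts,
        cna_cohorts,
        tasks=tasks,
        n_de_cohorts=n_de_cohorts,
        alpha=alpha,
        n_perm=n_perm,
        seed=de_seed,
        **signature_kwargs,
    )
    experiment = run_experiment(
        expression_cohorts, tasks, criteria, de_sets, signatures,
        grid=grid, k=k, seed=cv_seed,
    )
    return StudyResult(
        config=config,
        truth=truth,
        de_sets=de_sets,
        alterations=alterations,
        signatures=signatures,
        experiment=experiment,
    )
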