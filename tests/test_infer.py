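import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import crcprog as cp
from crcprog.infer import CRITERIA, SVMGrid, extract_features

TINY_GRID = SVMGrid(c_min=0.01, c_max=10.0, c_steps=4)


def test_printed_grid_has_1101_points_with_floored_negatives():
    grid = SVMGrid()
    values = grid.values()
    assert grid.n_models == 1101
    assert len(values) == 1101
    assert values.min() == pytest.approx(1e-3)
    # the linear grid from -10 to 10000 has exactly two non-positive points
    assert (values == 1e-3).sum() == 2
    assert values.max() == pytest.approx(10000.0)


def test_task_and_criterion_validation():
    with pytest.raises(ValueError):
        cp.ProgressionTask("III", "II")
    with pytest.raises(ValueError):
        cp.ProgressionTask("II", "II")
    with pytest.raises(ValueError):
        cp.ProgressionTask("I", "II")
    assert cp.ProgressionTask("II", "IV").name == "II_vs_IV"
    with pytest.raises(ValueError):
        cp.Criterion("X", "RA")  # RA needs a metric
    with pytest.raises(ValueError):
        cp.Criterion("X", "SA", metric="euclidean")
    assert {c.datatype for c in CRITERIA.values()} == {"SA", "COMB", "RA"}


def test_perfect_separation_gives_auc_one(rng):
    y = np.array([0, 1] * 15)
    X = y[:, None].astype(float) + rng.normal(0, 0.01, size=(30, 1))
    result = cp.evaluate_auc(X, y, grid=TINY_GRID, seed=0)
    assert result.auc == pytest.approx(1.0)
    assert result.n_models == 5


def test_single_class_labels_rejected(rng):
    X = rng.normal(size=(10, 2))
    with pytest.raises(ValueError, match="single class"):
        cp.evaluate_auc(X, np.zeros(10, dtype=int), grid=TINY_GRID)


def test_best_auc_dominates_every_fixed_grid_point(rng):
    X = rng.normal(size=(40, 3))
    y = np.array([0] * 20 + [1] * 20)
    X[y == 1] += 0.6
    best = cp.evaluate_auc(X, y, grid=TINY_GRID, k=5, seed=3)
    for c in TINY_GRID.values():
        single = SVMGrid(c_min=c, c_max=c, c_steps=0)
        fixed = cp.evaluate_auc(X, y, grid=single, k=5, seed=3)
        assert best.auc >= fixed.auc - 1e-12


def test_label_inversion_flips_auc(rng):
    y = np.array([0] * 10 + [1] * 10)
    scores = rng.normal(size=20) + y  # fixed decision function
    assert roc_auc_score(y, scores) == pytest.approx(1.0 - roc_auc_score(1 - y, scores))


def test_shuffled_labels_give_chance_auc():
    # null band frozen from this very permutation simulation: the 10-fold CV
    # AUC has sd ~0.07 under the null (held-out folds share training data),
    # so individual seeds spread well beyond [0.4, 0.6] while centering on 0.5
    aucs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(200, 5))
        y = np.array([0, 1] * 100)
        rng.shuffle(y)
        result = cp.evaluate_auc(X, y, grid=SVMGrid(c_min=1.0, c_max=1.0, c_steps=0), seed=seed)
        aucs.append(result.auc)
    aucs = np.asarray(aucs)
    assert ((aucs >= 0.30) & (aucs <= 0.70)).mean() >= 0.9
    assert 0.45 <= aucs.mean() <= 0.55


def test_nested_cv_is_honest_on_null_data(rng):
    X = rng.normal(size=(60, 4))
    y = np.array([0, 1] * 30)
    grid = SVMGrid(c_min=0.01, c_max=100.0, c_steps=8)
    biased = cp.evaluate_auc(X, y, grid=grid, k=5, seed=2)
    nested = cp.evaluate_auc(X, y, grid=grid, k=5, seed=2, nested=True)
    assert 0.0 <= nested.auc <= 1.0
    # the grid-maximal estimate is optimistically biased on null data;
    # the nested estimate must not exceed it by more than fold noise
    assert nested.auc <= biased.auc + 0.05
    again = cp.evaluate_auc(X, y, grid=grid, k=5, seed=2, nested=True)
    assert again.auc == nested.auc


def test_nested_cv_still_separates_signal(rng):
    y = np.array([0, 1] * 20)
    X = y[:, None] + rng.normal(0, 0.05, size=(40, 2))
    nested = cp.evaluate_auc(X, y, grid=TINY_GRID, k=5, seed=1, nested=True)
    assert nested.auc == pytest.approx(1.0)


def test_evaluate_auc_deterministic(rng):
    X = rng.normal(size=(30, 4))
    y = np.array([0] * 15 + [1] * 15)
    a = cp.evaluate_auc(X, y, grid=TINY_GRID, seed=11)
    b = cp.evaluate_auc(X, y, grid=TINY_GRID, seed=11)
    assert (a.auc, a.best_c) == (b.auc, b.best_c)


def test_folds_adjust_to_small_classes(rng):
    X = rng.normal(size=(23, 3))
    y = np.array([0] * 20 + [1] * 3)
    result = cp.evaluate_auc(X, y, grid=TINY_GRID, k=10, seed=0)
    assert result.n_folds == 3


def test_feature_shapes_per_datatype(small_study, small_artifacts):
    expression, _, _ = small_study
    de_sets, _, signatures = small_artifacts
    task = cp.ProgressionTask("II", "IV")
    cohort = expression[2]
    sig = signatures[task.name]
    n_patients = 20  # 10 controls + 10 cases

    X_sa, y, genes_sa = extract_features(cohort, CRITERIA["NCOMB"], task, de_sets[task.name], sig)
    assert X_sa.shape == (n_patients, len(set(de_sets[task.name][0]) | set(de_sets[task.name][1])))
    assert list(y) == [0] * 10 + [1] * 10

    X_comb, _, genes_comb = extract_features(cohort, CRITERIA["COMB"], task, de_sets[task.name], sig)
    assert X_comb.shape == (n_patients, len(sig))
    # the signature is the CNA-filtered subset of the DE genes
    assert set(genes_comb) <= set(genes_sa)

    prototypes = cp.select_prototypes(cohort, "II", sig)
    X_ra, _, _ = extract_features(
        cohort, CRITERIA["COMBDE"], task, de_sets[task.name], sig, prototypes
    )
    assert X_ra.shape == (n_patients, len(prototypes))
    direct = cp.build_dissimilarity_matrix(
        cohort.values.loc[prototypes.vectors.index,
                          cohort.samples_of_stage("II") + cohort.samples_of_stage("IV")],
        prototypes,
        "euclidean",
    )
    np.testing.assert_allclose(X_ra, direct.values.to_numpy())


def test_empty_feature_sets_error_names_upstream_stage(small_study, small_artifacts):
    expression, _, _ = small_study
    de_sets, _, signatures = small_artifacts
    task = cp.ProgressionTask("II", "III")
    empty_sig = cp.CombinedSignature(frozenset(), frozenset(), task=task.name)
    with pytest.raises(ValueError, match="signature"):
        extract_features(expression[0], CRITERIA["COMB"], task, de_sets[task.name], empty_sig)
    with pytest.raises(ValueError, match="differential expression"):
        extract_features(
            expression[0], CRITERIA["NCOMB"], task, (frozenset(), frozenset()), signatures[task.name]
        )


@pytest.fixture(scope="module")
def small_experiment(small_study, small_artifacts):
    expression, _, _ = small_study
    de_sets, _, signatures = small_artifacts
    return cp.run_experiment(
        expression,
        cp.DEFAULT_TASKS,
        cp.DEFAULT_CRITERIA,
        de_sets,
        signatures,
        grid=SVMGrid(c_min=1.0, c_max=1.0, c_steps=0),
        k=5,
        seed=9,
    )


def test_experiment_is_full_factorial(small_experiment):
    table = small_experiment.table
    assert len(table) == 6 * 3 * 3  # criteria x datasets x tasks
    assert small_experiment.ok
    assert table["auc"].between(0, 1).all()
    assert not table.duplicated(["criterion", "dataset", "task"]).any()


def test_experiment_rerun_is_identical(small_study, small_artifacts, small_experiment):
    expression, _, _ = small_study
    de_sets, _, signatures = small_artifacts
    again = cp.run_experiment(
        expression,
        cp.DEFAULT_TASKS,
        cp.DEFAULT_CRITERIA,
        de_sets,
        signatures,
        grid=SVMGrid(c_min=1.0, c_max=1.0, c_steps=0),
        k=5,
        seed=9,
    )
    pd.testing.assert_frame_equal(again.table, small_experiment.table)


def test_failing_cells_are_recorded_and_run_continues(small_study, small_artifacts):
    expression, _, _ = small_study
    de_sets, _, signatures = small_artifacts
    broken = dict(signatures)
    broken["II_vs_III"] = cp.CombinedSignature(frozenset(), frozenset(), task="II_vs_III")
    result = cp.run_experiment(
        expression[:1],
        cp.DEFAULT_TASKS,
        [CRITERIA["COMB"], CRITERIA["NCOMB"]],
        de_sets,
        broken,
        grid=SVMGrid(c_min=1.0, c_max=1.0, c_steps=0),
        k=3,
        seed=0,
    )
    assert not result.ok
    assert {f[0] for f in result.failures} == {"COMB"}
    # NCOMB cells for the same task still ran
    assert len(result.table) == 5
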