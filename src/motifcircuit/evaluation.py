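"""Nested evaluation protocol for motif feature selection.

Stratified 5-fold cross-validation assigns each fold once as the test
set (20%); among the remaining four folds each is once the validation
set (20%) with the other three merged for training (60%), giving four
runs per test fold (20 runs at k = 5). Per run, an ordinary random
forest supplies guidance importances, GRRF models over a gamma grid are
tuned by validation accuracy, and the tuned model is scored by ACC, MCC
and F1. The best of the four runs (maximum ACC x MCC x F1) predicts the
test fold (auROC / auPRC); the cluster's best model is the test fold
winner by auROC, and its selected features provide the GRRF ranking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)

from .forest import (
    ForestConfig,
    GuidedRegularizedForest,
    RandomForestGini,
    guidance_importance,
    penalties,
    rank_grrf,
)
from .scan import HitCountMatrix

DEFAULT_GAMMA_GRID = tuple(round(g, 1) for g in np.arange(0.0, 1.01, 0.1))


@dataclass
class FoldPlan:
    """Stratified fold assignment plus the (test, validation) run list."""

    k: int
    assignments: np.ndarray  # fold id per sample
    runs: list[tuple[int, int]]  # (test_fold, validation_fold)

    def test_mask(self, fold: int) -> np.ndarray:
        return self.assignments == fold

    def train_mask(self, test_fold: int, val_fold: int) -> np.ndarray:
        return (self.assignments != test_fold) & (self.assignments != val_fold)


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified partition: per-class counts per fold differ by <= 1.

    Each class is shuffled and dealt round-robin across folds, the
    starting fold rotating per class so remainders spread evenly.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignments = np.full(y.shape[0], -1, dtype=np.int64)
    offset = 0
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if idx.size < k:
            raise ValueError(f"class {cls!r} has fewer than k={k} members")
        perm = rng.permutation(idx)
        for i, sample in enumerate(perm):
            assignments[sample] = (i + offset) % k
        offset += idx.size % k
    runs = [(t, v) for t in range(k) for v in range(k) if v != t]
    return FoldPlan(k=k, assignments=assignments, runs=runs)


@dataclass
class ModelScore:
    acc: float
    mcc: float
    f1: float

    @property
    def product(self) -> float:
        return self.acc * self.mcc * self.f1


def metrics(y_true, y_pred, y_score=None):
    """ACC / MCC / F1 (and auROC, auPRC when scores are given).

    MCC with a zero denominator is defined as 0. auROC uses the
    average-rank tie convention; auPRC is step-interpolated average
    precision. Returns ``ModelScore`` or ``(ModelScore, auroc, auprc)``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        score = ModelScore(
            acc=float(accuracy_score(y_true, y_pred)),
            mcc=float(matthews_corrcoef(y_true, y_pred)),
            f1=float(f1_score(y_true, y_pred, zero_division=0.0)),
        )
    if y_score is None:
        return score
    if np.unique(y_true).size < 2:
        raise ValueError("auROC needs both classes in y_true")
    auroc = float(roc_auc_score(y_true, y_score))
    auprc = float(average_precision_score(y_true, y_score))
    return score, auroc, auprc


@dataclass
class RunRecord:
    test_fold: int
    val_fold: int
    gamma: float
    val_score: ModelScore


@dataclass
class TestFoldRecord:
    test_fold: int
    best_val_fold: int
    gamma: float
    auroc: float
    auprc: float


@dataclass
class EvaluationReport:
    cluster: str
    k: int
    gamma_grid: list[float]
    runs: list[RunRecord] = field(default_factory=list)
    test_folds: list[TestFoldRecord] = field(default_factory=list)
    best_test_fold: int = -1
    best_gamma: float = np.nan
    mean_test_auroc: float = np.nan
    mean_test_auprc: float = np.nan
    grrf_top10: list[str] = field(default_factory=list)
    grrf_importances: dict[str, float] = field(default_factory=dict)
    n_selected: int = 0

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["runs"] = [asdict(r) for r in self.runs]
        payload["test_folds"] = [asdict(t) for t in self.test_folds]
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_nested_cv(
    matrix: HitCountMatrix,
    fold_plan: FoldPlan,
    gamma_grid=DEFAULT_GAMMA_GRID,
    config: ForestConfig | None = None,
    cluster: str = "cluster",
) -> EvaluationReport:
    """Execute the full nested protocol on a labeled hit-count matrix."""
    config = config or ForestConfig()
    X = matrix.counts.astype(np.float64)
    y = matrix.label_array()
    report = EvaluationReport(
        cluster=cluster, k=fold_plan.k, gamma_grid=[float(g) for g in gamma_grid]
    )
    best_models: dict[int, GuidedRegularizedForest] = {}

    run_index = 0
    for test_fold in range(fold_plan.k):
        fold_runs: list[tuple[RunRecord, GuidedRegularizedForest]] = []
        for tf, val_fold in [r for r in fold_plan.runs if r[0] == test_fold]:
            train = fold_plan.train_mask(test_fold, val_fold)
            val = fold_plan.test_mask(val_fold)
            run_index += 1
            if np.unique(y[val]).size < 2 or np.unique(y[train]).size < 2:
                warnings.warn(
                    f"fold run (test={test_fold}, val={val_fold}): degenerate "
                    "fold, skipped"
                )
                continue
            run_seed = config.seed + 1000 * run_index
            rf_cfg = ForestConfig(
                n_trees=config.n_trees,
                mtry=config.mtry,
                min_leaf=config.min_leaf,
                bootstrap=config.bootstrap,
                seed=run_seed,
            )
            rf = RandomForestGini(rf_cfg).fit(X[train], y[train])
            imp_norm = guidance_importance(rf)
            # gamma tuned by validation accuracy; ties toward larger gamma
            best = None
            for gi, gamma in enumerate(gamma_grid):
                lam = penalties(imp_norm, float(gamma))
                g_cfg = ForestConfig(
                    n_trees=config.n_trees,
                    mtry=config.mtry,
                    min_leaf=config.min_leaf,
                    bootstrap=config.bootstrap,
                    seed=run_seed + gi + 1,
                )
                model = GuidedRegularizedForest(g_cfg).fit(X[train], y[train], lam)
                acc = float(accuracy_score(y[val], model.predict(X[val])))
                if best is None or acc >= best[0]:
                    best = (acc, float(gamma), model)
            _, gamma_star, model_star = best
            val_score = metrics(y[val], model_star.predict(X[val]))
            fold_runs.append(
                (
                    RunRecord(test_fold, val_fold, gamma_star, val_score),
                    model_star,
                )
            )
        if not fold_runs:
            continue
        report.runs.extend(r for r, _ in fold_runs)
        # best of the four runs by ACC x MCC x F1 (ties: first run order)
        best_run, best_model = max(
            fold_runs, key=lambda rm: (rm[0].val_score.product, -rm[0].val_fold)
        )
        test = fold_plan.test_mask(test_fold)
        if np.unique(y[test]).size < 2:
            warnings.warn(f"test fold {test_fold}: single class, skipped")
            continue
        proba = best_model.predict_proba(X[test])
        _, auroc, auprc = metrics(y[test], (proba >= 0.5).astype(int), proba)
        report.test_folds.append(
            TestFoldRecord(test_fold, best_run.val_fold, best_run.gamma, auroc, auprc)
        )
        best_models[test_fold] = best_model

    if report.test_folds:
        report.mean_test_auroc = float(
            np.mean([t.auroc for t in report.test_folds])
        )
        report.mean_test_auprc = float(
            np.mean([t.auprc for t in report.test_folds])
        )
        winner = max(report.test_folds, key=lambda t: (t.auroc, -t.test_fold))
        report.best_test_fold = winner.test_fold
        report.best_gamma = winner.gamma
        final = best_models[winner.test_fold]
        ranked = rank_grrf(final, matrix.motifs, k=10)
        report.grrf_top10 = [r.motif for r in ranked]
        report.grrf_importances = {
            matrix.motifs[i]: float(final.importances_[i])
            for i in sorted(set(final.selected_features_))
        }
        report.n_selected = len(set(final.selected_features_))
    return report


def topn_curves(
    rankings: dict[str, list[str]],
    matrix: HitCountMatrix,
    fold_plan: FoldPlan,
    config: ForestConfig | None = None,
) -> pd.DataFrame:
    """Test auROC/auPRC of plain RFs retrained on top-N features, N=1..10.

    For each method's ranking and each test fold, a plain random forest
    is trained on all non-test samples restricted to the top-N motifs
    and evaluated on the test fold. Curves are truncated at the ranking
    length.
    """
    config = config or ForestConfig()
    X = matrix.counts.astype(np.float64)
    y = matrix.label_array()
    name_to_col = {m: j for j, m in enumerate(matrix.motifs)}
    rows = []
    for method, ranking in rankings.items():
        cols_full = [name_to_col[m] for m in ranking]
        for test_fold in range(fold_plan.k):
            test = fold_plan.test_mask(test_fold)
            train = ~test
            if np.unique(y[test]).size < 2 or np.unique(y[train]).size < 2:
                continue
            for n_top in range(1, min(len(cols_full), 10) + 1):
                cols = cols_full[:n_top]
                cfg = ForestConfig(
                    n_trees=config.n_trees,
                    mtry=min(config.resolve_mtry(len(cols)), len(cols)),
                    min_leaf=config.min_leaf,
                    bootstrap=config.bootstrap,
                    seed=config.seed + 7919 * (test_fold + 1) + n_top,
                )
                rf = RandomForestGini(cfg).fit(X[train][:, cols], y[train])
                proba = rf.predict_proba(X[test][:, cols])
                _, auroc, auprc = metrics(
                    y[test], (proba >= 0.5).astype(int), proba
                )
                rows.append(
                    {
                        "method": method,
                        "fold": test_fold,
                        "N": n_top,
                        "auroc": auroc,
                        "auprc": auprc,
                    }
                )
    return pd.DataFrame(rows, columns=["method", "fold", "N", "auroc", "auprc"])


def mean_topn(curves: pd.DataFrame) -> pd.DataFrame:
    """Cross-fold mean auROC/auPRC per method per N."""
    return (
        curves.groupby(["method", "N"], as_index=False)[["auroc", "auprc"]]
        .mean()
        .sort_values(["method", "N"])
        .reset_index(drop=True)
    )


def coverage_curve(
    ranking: list[str], matrix: HitCountMatrix, positive_genes: list[str]
) -> list[float]:
    """Cumulative fraction of positive genes hit by the top-N motifs."""
    if not ranking:
        raise ValueError("ranking must be non-empty")
    frame = matrix.to_frame()
    pos = [g for g in positive_genes if g in frame.index]
    if not pos:
        return [0.0] * min(len(ranking), 10)
    sub = frame.loc[pos]
    covered = np.zeros(len(pos), dtype=bool)
    fractions = []
    for motif in ranking[:10]:
        covered |= sub[motif].to_numpy() >= 1
        fractions.append(float(covered.mean()))
    return fractions
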