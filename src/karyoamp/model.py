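"""Binary and multi-output ecDNA / HSR classifiers over karyotype features.

The protocol: z-score scaling fitted on the training rows only, an 80/20
stratified split, tree-ensemble classifiers (random forest / gradient
boosting by default, with decision-tree, SVM, bagging and stacking
alternatives), ROC-AUC as a rank statistic over predicted scores, and a
Mann–Whitney U test for per-feature separation between label groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
    StackingClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef, roc_auc_score
from sklearn.multioutput import MultiOutputClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable, split_train_test

BINARY_ALGORITHMS = (
    "decision_tree",
    "svm",
    "random_forest",
    "gradient_boosting",
    "bagging",
    "stacking",
)
MULTI_OUTPUT_ALGORITHMS = ("multi_output_rf", "multi_output_gb")

#: Algorithms exposing tree-ensemble feature importances.
_IMPORTANCE_ALGORITHMS = frozenset(
    {"decision_tree", "random_forest", "gradient_boosting", "multi_output_rf", "multi_output_gb"}
)


def _make_estimator(algorithm: str, seed: int, **hyper):
    if algorithm == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed, **hyper)
    elif algorithm == "svm":
        est = SVC(probability=True, random_state=seed, **hyper)
    elif algorithm == "random_forest":
        est = RandomForestClassifier(random_state=seed, **hyper)
    elif algorithm == "gradient_boosting":
        est = GradientBoostingClassifier(random_state=seed, **hyper)
    elif algorithm == "bagging":
        est = BaggingClassifier(random_state=seed, **hyper)
    elif algorithm == "stacking":
        est = StackingClassifier(
            estimators=[
                ("rf", RandomForestClassifier(random_state=seed)),
                ("gb", GradientBoostingClassifier(random_state=seed)),
            ],
            final_estimator=LogisticRegression(max_iter=1000),
            **hyper,
        )
    elif algorithm == "multi_output_rf":
        est = MultiOutputClassifier(RandomForestClassifier(random_state=seed, **hyper))
    elif algorithm == "multi_output_gb":
        est = MultiOutputClassifier(GradientBoostingClassifier(random_state=seed, **hyper))
    else:
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    return est


@dataclass
class TrainedModel:
    """A fitted classifier with the metadata needed to reproduce it."""

    algorithm: str
    targets: tuple[str, ...]
    seed: int
    pipeline: Pipeline
    hyperparameters: Mapping[str, object]
    feature_names: tuple[str, ...]


@dataclass
class EvalReport:
    """Held-out evaluation metrics (per-target AUC/F1, scalar accuracy/MCC)."""

    auc: dict[str, float]
    accuracy: float
    f1: dict[str, float]
    mcc: float
    feature_importances: list[tuple[str, float]]

    def __post_init__(self) -> None:
        for v in self.auc.values():
            assert 0.0 <= v <= 1.0
        for v in self.f1.values():
            assert 0.0 <= v <= 1.0
        assert 0.0 <= self.accuracy <= 1.0 and -1.0 <= self.mcc <= 1.0


def _target_matrix(table: FeatureTable, targets: Sequence[str]) -> np.ndarray:
    y = table.labels[list(targets)].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("training/evaluation labels contain unknowns; drop them first")
    return y.astype(int)


def _fit(table: FeatureTable, algorithm: str, seed: int, targets: Sequence[str], scale: bool, **hyper) -> TrainedModel:
    y = _target_matrix(table, targets)
    for j, t in enumerate(targets):
        if len(np.unique(y[:, j])) < 2:
            raise ValueError(f"target {t!r} is single-class in the training data")
    steps = ([("scale", StandardScaler())] if scale else []) + [
        ("clf", _make_estimator(algorithm, seed, **hyper))
    ]
    pipe = Pipeline(steps)
    pipe.fit(table.features.to_numpy(), y[:, 0] if len(targets) == 1 else y)
    return TrainedModel(
        algorithm=algorithm,
        targets=tuple(targets),
        seed=seed,
        pipeline=pipe,
        hyperparameters=dict(hyper),
        feature_names=tuple(table.features.columns),
    )


def train_binary(
    train: FeatureTable,
    algorithm: str = "random_forest",
    seed: int = 0,
    target: str = "ecdna",
    scale: bool = True,
    **hyper,
) -> TrainedModel:
    """Fit a binary classifier on the training rows only."""
    if algorithm not in BINARY_ALGORITHMS:
        raise ValueError(f"algorithm must be one of {BINARY_ALGORITHMS}")
    return _fit(train, algorithm, seed, (target,), scale, **hyper)


def train_multi_output(
    train: FeatureTable,
    algorithm: str = "multi_output_gb",
    seed: int = 0,
    targets: Sequence[str] = ("ecdna", "hsr"),
    scale: bool = True,
    **hyper,
) -> TrainedModel:
    """Fit a joint ecDNA + HSR classifier (per-target metrics on evaluation)."""
    if algorithm not in MULTI_OUTPUT_ALGORITHMS:
        raise ValueError(f"algorithm must be one of {MULTI_OUTPUT_ALGORITHMS}")
    return _fit(train, algorithm, seed, tuple(targets), scale, **hyper)


def predict_scores(model: TrainedModel, table: FeatureTable) -> pd.DataFrame:
    """Positive-class probability per target for each sample."""
    X = table.features.to_numpy()
    proba = model.pipeline.predict_proba(X)
    if len(model.targets) == 1:
        scores = {model.targets[0]: proba[:, 1]}
    else:
        scores = {t: proba[j][:, 1] for j, t in enumerate(model.targets)}
    return pd.DataFrame(scores, index=table.sample_ids)


def evaluate(model: TrainedModel, test: FeatureTable) -> EvalReport:
    """Score a fitted model on held-out rows; AUC is the rank statistic over
    the predicted positive-class scores."""
    y = _target_matrix(test, model.targets)
    scores = predict_scores(model, test).to_numpy()
    preds = (scores > 0.5).astype(int)
    auc = {t: float(roc_auc_score(y[:, j], scores[:, j])) for j, t in enumerate(model.targets)}
    f1 = {t: float(f1_score(y[:, j], preds[:, j])) for j, t in enumerate(model.targets)}
    accuracy = float(accuracy_score(y, preds) if len(model.targets) > 1 else accuracy_score(y[:, 0], preds[:, 0]))
    mcc = float(np.mean([matthews_corrcoef(y[:, j], preds[:, j]) for j in range(len(model.targets))]))
    try:
        importances = rank_feature_importance(model)
    except ValueError:
        importances = []
    return EvalReport(auc=auc, accuracy=accuracy, f1=f1, mcc=mcc, feature_importances=importances)


def rank_feature_importance(model: TrainedModel) -> list[tuple[str, float]]:
    """Tree-ensemble importances: non-negative, normalised to sum to 1,
    sorted descending (deterministic given the seed)."""
    if model.algorithm not in _IMPORTANCE_ALGORITHMS:
        raise ValueError(f"algorithm {model.algorithm!r} does not expose feature importances")
    clf = model.pipeline.named_steps["clf"]
    if isinstance(clf, MultiOutputClassifier):
        imp = np.mean([e.feature_importances_ for e in clf.estimators_], axis=0)
    else:
        imp = clf.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    ranked = sorted(zip(model.feature_names, imp.astype(float)), key=lambda kv: (-kv[1], kv[0]))
    return ranked


def feature_separation_test(values: Sequence[float], group_labels: Sequence[int]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U for one feature between two label groups.

    Exact null distribution for combined n <= 20 without ties; normal
    approximation with tie correction otherwise. Returns (U, p) with U the
    statistic of the first group. All-constant input returns p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError("group_labels must contain exactly two groups")
    x = values[groups == uniq[0]]
    y = values[groups == uniq[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("each group needs at least one sample")
    if np.all(values == values[0]):
        return len(x) * len(y) / 2.0, 1.0
    n = len(x) + len(y)
    has_ties = len(np.unique(values)) < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# --- model/results surface ---------------------------------------------------


class KaryotypeAmplificationModel:
    """ecDNA / HSR predictor over an engineered karyotype feature table.

    Parameters
    ----------
    table
        Feature table (built with :func:`karyoamp.features.engineer_features`,
        imputed via :func:`karyoamp.features.impute_by_ploidy`). Rows with
        unknown labels for the requested targets are dropped at fit time.
    targets
        ``("ecdna",)`` for the binary model or ``("ecdna", "hsr")`` for the
        multi-output model.
    algorithm
        One of the supported sklearn-backed algorithms; multi-output targets
        require a ``multi_output_*`` algorithm.
    """

    def __init__(
        self,
        table: FeatureTable,
        targets: Sequence[str] = ("ecdna",),
        algorithm: str = "random_forest",
        scale: bool = True,
        **hyper,
    ) -> None:
        self.targets = tuple(targets)
        self.algorithm = algorithm
        self.scale = scale
        self.hyper = hyper
        mask = table.labels[list(self.targets)].notna().all(axis=1)
        self.table = table.subset(table.sample_ids[mask])

    @classmethod
    def from_profiles(cls, profiles, sample_ids, ecdna, hsr=None, **kw):
        from .features import engineer_features, impute_by_ploidy

        table = impute_by_ploidy(engineer_features(profiles, sample_ids, ecdna=ecdna, hsr=hsr))
        return cls(table, **kw)

    def fit(self, seed: int = 0, train_fraction: float = 0.8) -> "AmplificationResults":
        train, test = split_train_test(
            self.table, train_fraction=train_fraction, seed=seed, stratify_on=self.targets
        )
        if len(self.targets) == 1:
            fitted = train_binary(train, self.algorithm, seed, target=self.targets[0], scale=self.scale, **self.hyper)
        else:
            fitted = train_multi_output(train, self.algorithm, seed, targets=self.targets, scale=self.scale, **self.hyper)
        report = evaluate(fitted, test)
        return AmplificationResults(model=self, fitted=fitted, train=train, test=test, report=report)


@dataclass
class AmplificationResults:
    """Fit results: the trained estimator, the split, and held-out metrics."""

    model: KaryotypeAmplificationModel
    fitted: TrainedModel
    train: FeatureTable
    test: FeatureTable
    report: EvalReport

    @property
    def auc(self) -> dict[str, float]:
        return self.report.auc

    @property
    def feature_importances_(self) -> pd.Series:
        return pd.Series(dict(self.report.feature_importances)).sort_values(ascending=False)

    def predict(self, table: FeatureTable) -> pd.DataFrame:
        return predict_scores(self.fitted, table)

    def summary(self, top_features: int = 8) -> str:
        lines = [
            "Karyotype amplification model",
            "=============================",
            f"algorithm:        {self.fitted.algorithm}",
            f"targets:          {', '.join(self.fitted.targets)}",
            f"seed:             {self.fitted.seed}",
            f"train / test n:   {len(self.train)} / {len(self.test)}",
            f"accuracy:         {self.report.accuracy:.3f}",
            f"MCC:              {self.report.mcc:.3f}",
        ]
        for t in self.fitted.targets:
            lines.append(f"AUC[{t}]:        {self.report.auc[t]:.3f}   F1[{t}]: {self.report.f1[t]:.3f}")
        if self.report.feature_importances:
            lines.append("top features:")
            for name, w in self.report.feature_importances[:top_features]:
                lines.append(f"  {name:<24s} {w:.4f}")
        return "\n".join(lines)

    def plot_importances(self, top: int = 15, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        imp = self.feature_importances_.head(top)[::-1]
        ax.barh(imp.index, imp.to_numpy())
        ax.set_xlabel("importance")
        return ax
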