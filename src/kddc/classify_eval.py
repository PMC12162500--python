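"""Classifier comparison over k-mer datasets.

Seven classifier families — logistic regression (LR), support vector machine
(SVM), multi-layer perceptron (MLP), k-nearest neighbours (KNN), decision
tree (DC), random forest (RF) and gradient-boosted trees (XGB) — are trained
on each k-mer dataset after a stratified 4:1 train/test split, tuned by
exhaustive grid search with stratified cross-validation, and scored by
one-vs-rest macro AUC with per-class AUCs.

Feature selection (zero screen + ANOVA) is part of the fitted pipeline, so
it is re-estimated inside every cross-validation fold and on every
permutation: the test partition never informs which features are used.

Model significance is a label-permutation test: the full pipeline is re-run
on shuffled labels and the p-value is the fraction of permutations whose
test macro AUC reaches the observed one, with the add-one correction
p = (1 + #{perm >= obs}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .feature_select import SelectionConfig, select_features
from .kmer_features import FeatureSpace, KmerCountMatrix
from .repertoire_io import STATE_NAMES

logger = logging.getLogger(__name__)

#: Fixed family order; also the tie-break order (simpler families first).
FAMILY_ORDER = ("LR", "SVM", "MLP", "KNN", "DC", "RF", "XGB")


def derive_seed(seed: int, *tags) -> int:
    """Deterministic sub-seed (< 2^31) for a named stage of a run."""
    h = zlib.crc32("|".join(map(str, tags)).encode("utf-8"))
    return int((int(seed) * 1_000_003 + h) % (2**31 - 1))


# ---------------------------------------------------------------------------
# configuration dataclasses


@dataclass(frozen=True)
class SplitConfig:
    """Train/test partition parameters (default 4:1, stratified)."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )


@dataclass(frozen=True)
class ClassifierGrid:
    """Hyperparameter grid for one classifier family.

    ``grid`` maps classifier parameter names to candidate values; scoring is
    always one-vs-rest macro AUC.
    """

    family: str
    grid: Mapping[str, Sequence] = field(default_factory=dict)
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.family not in FAMILY_ORDER:
            raise ValueError(f"unknown family {self.family!r}; expected {FAMILY_ORDER}")


#: Deliberately small default grids so a full 7 x 7 sweep stays desk-scale.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "LR": {"C": [0.1, 1.0, 10.0]},
    "SVM": {"C": [0.1, 1.0, 10.0]},
    "MLP": {"alpha": [1e-4, 1e-2]},
    "KNN": {"n_neighbors": [3, 5]},
    "DC": {"max_depth": [None, 5]},
    "RF": {"max_depth": [None, 10]},
    "XGB": {"max_depth": [3, 6]},
}


def default_grid(family: str, cv_folds: int = 5) -> ClassifierGrid:
    return ClassifierGrid(family=family, grid=dict(DEFAULT_GRIDS[family]),
                          cv_folds=cv_folds)


def make_classifier(family: str, seed: int = 0):
    """A fresh estimator of the given family, seeded where stochastic."""
    if family == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if family == "SVM":
        return SVC(kernel="rbf", decision_function_shape="ovr", random_state=seed)
    if family == "MLP":
        return MLPClassifier(hidden_layer_sizes=(64,), max_iter=600,
                             random_state=seed)
    if family == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    if family == "DC":
        return DecisionTreeClassifier(random_state=seed)
    if family == "RF":
        return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    if family == "XGB":
        return XGBClassifier(
            n_estimators=100, random_state=seed, n_jobs=1,
            eval_metric="mlogloss", verbosity=0, tree_method="hist",
        )
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILY_ORDER}")


# ---------------------------------------------------------------------------
# in-pipeline feature selection


class AnovaSelector(BaseEstimator, TransformerMixin):
    """Zero-count screen + per-feature ANOVA as an sklearn transformer.

    Fitting on a training partition learns the retained-feature mask; the
    same mask is then applied to any partition, which keeps selection free
    of test-set information. If nothing passes the screen, the
    ``min_features`` smallest-p features are kept so downstream fits remain
    well-defined.
    """

    def __init__(self, zero_fraction_threshold: float = 0.95, alpha: float = 0.05,
                 adjust: str = "none", min_features: int = 1):
        self.zero_fraction_threshold = zero_fraction_threshold
        self.alpha = alpha
        self.adjust = adjust
        self.min_features = min_features

    def fit(self, X, y):
        config = SelectionConfig(
            zero_fraction_threshold=self.zero_fraction_threshold,
            alpha=self.alpha,
            adjust=self.adjust,
        )
        result = select_features(X, y, config)
        mask = result.kept.copy()
        if mask.sum() < self.min_features:
            p = np.where(np.isfinite(result.p_value), result.p_value, np.inf)
            order = np.argsort(p, kind="stable")[: self.min_features]
            mask[:] = False
            mask[order] = True
        self.selection_ = result
        self.mask_ = mask
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return X[:, self.mask_]


def build_pipeline(
    family: str,
    seed: int = 0,
    selection: SelectionConfig | None = None,
) -> Pipeline:
    """Selection -> scaling -> classifier pipeline for one family.

    Scaling is variance-only (sparse-safe) and shared across families so the
    distance- and margin-based ones are not dominated by high-count k-mers.
    """
    steps = []
    if selection is not None:
        steps.append((
            "select",
            AnovaSelector(
                zero_fraction_threshold=selection.zero_fraction_threshold,
                alpha=selection.alpha,
                adjust=selection.adjust,
            ),
        ))
    steps.append(("scale", StandardScaler(with_mean=False)))
    steps.append(("clf", make_classifier(family, seed)))
    return Pipeline(steps)


# ---------------------------------------------------------------------------
# scoring


def class_scores(model, X) -> np.ndarray:
    """Per-class score matrix (n_rows x n_classes) for a fitted model.

    Uses predicted probabilities where the family provides them; otherwise
    one-vs-rest decision values (valid ROC scores as-is), mapped through a
    softmax only to present them on a probability-like scale.
    """
    if hasattr(model, "predict_proba"):
        try:
            return np.asarray(model.predict_proba(X))
        except AttributeError:  # e.g. SVC(probability=False) inside a pipeline
            pass
    d = np.asarray(model.decision_function(X))
    if d.ndim == 1:
        d = np.column_stack([-d, d])
    d = d - d.max(axis=1, keepdims=True)
    e = np.exp(d)
    return e / e.sum(axis=1, keepdims=True)


def macro_auc(
    scores: np.ndarray,
    labels: Sequence,
    classes: Sequence | None = None,
) -> tuple[float, dict]:
    """One-vs-rest macro AUC and per-class AUCs.

    ``classes`` gives the class order of the score columns (default: sorted
    unique labels). Classes absent from ``labels`` get no AUC and are
    excluded from the macro mean, with a warning.
    """
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    classes = list(classes)
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise ValueError(
            f"scores must be (n, {len(classes)}) for classes {classes}, "
            f"got shape {scores.shape}"
        )
    present = set(np.unique(labels).tolist())
    if len(present) < 2:
        raise ValueError("macro AUC needs >= 2 classes present in labels")
    per_class: dict = {}
    for j, c in enumerate(classes):
        if c not in present or len(present - {c}) == 0:
            logger.warning("class %r absent from labels; AUC undefined", c)
            continue
        per_class[c] = float(roc_auc_score((labels == c).astype(int), scores[:, j]))
    macro = float(np.mean(list(per_class.values())))
    return macro, per_class


def stratified_split(
    labels: Sequence,
    config: SplitConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test indices (default 4:1, stratified)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if config.stratified and (counts < 2).any():
        bad = classes[counts < 2].tolist()
        raise ValueError(
            f"class(es) {bad} have a single row; merge or remove them before "
            "a stratified split"
        )
    splitter = StratifiedShuffleSplit(
        n_splits=1,
        train_size=config.train_fraction,
        random_state=config.seed,
    )
    strat = labels if config.stratified else np.zeros_like(labels)
    train_idx, test_idx = next(splitter.split(np.zeros((len(labels), 1)), strat))
    return np.sort(train_idx), np.sort(test_idx)


# ---------------------------------------------------------------------------
# fitting and significance


def _macro_auc_scorer(estimator, X, y) -> float:
    scores = class_scores(estimator, X)
    macro, _ = macro_auc(scores, y, classes=getattr(estimator, "classes_", None))
    return macro


def grid_search_fit(
    X,
    y,
    spec: ClassifierGrid,
    seed: int = 0,
    selection: SelectionConfig | None = None,
) -> GridSearchCV:
    """Exhaustive grid search by stratified CV on the training partition.

    The grid addresses the classifier step of the pipeline; the best
    configuration is refitted on the full training partition. Folds are
    reduced (with a warning) when the rarest class cannot fill them; fewer
    than 2 feasible folds is an error.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training partition must contain every class (>= 2)")
    n_splits = min(spec.cv_folds, int(counts.min()))
    if n_splits < 2:
        raise ValueError(
            f"rarest class has {int(counts.min())} training row(s); "
            "cannot form >= 2 stratified CV folds"
        )
    if n_splits < spec.cv_folds:
        logger.warning(
            "reducing CV folds from %d to %d (rarest class has %d rows)",
            spec.cv_folds, n_splits, int(counts.min()),
        )
    pipe = build_pipeline(spec.family, seed=derive_seed(seed, "clf"), selection=selection)
    param_grid = {f"clf__{k}": list(v) for k, v in spec.grid.items()}
    gs = GridSearchCV(
        pipe,
        param_grid=param_grid,
        scoring=_macro_auc_scorer,
        cv=StratifiedKFold(n_splits=n_splits, shuffle=True,
                           random_state=derive_seed(seed, "cv")),
        refit=True,
        n_jobs=None,
        error_score="raise",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter from MLP/LR on tiny folds
        gs.fit(X, y)
    return gs


def _split_fit_score(estimator, X, y, split: SplitConfig) -> float:
    """Fit a clone on a stratified train partition, return test macro AUC."""
    tr, te = stratified_split(y, split)
    model = clone(estimator)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X[tr], y[tr])
    macro, _ = macro_auc(class_scores(model, X[te]), y[te], classes=model.classes_)
    return macro


def permutation_pvalue(
    estimator,
    X,
    y,
    n_perm: int = 999,
    seed: int = 0,
    split: SplitConfig | None = None,
) -> float:
    """Label-permutation significance of a pipeline's test macro AUC.

    Every permutation shuffles the labels of the whole dataset and re-runs
    the full pipeline — stratified split, in-pipeline feature selection,
    fitting — so the null distribution reflects the entire procedure.
    Returns p = (1 + #{permuted AUC >= observed}) / (1 + n_perm), which is
    always in (0, 1].
    """
    if n_perm < 19:
        raise ValueError(f"n_perm must be >= 19, got {n_perm}")
    y = np.asarray(y)
    split = split or SplitConfig(seed=derive_seed(seed, "perm-split"))
    observed = _split_fit_score(estimator, X, y, split)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        if _split_fit_score(estimator, X, y_perm, split) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


# ---------------------------------------------------------------------------
# reports


@dataclass
class EvalReport:
    """Evaluation of one (dataset, classifier family) pair."""

    dataset_name: str
    family: str
    macro_auc: float
    per_class_auc: dict
    p_value: float | None
    best_params: dict
    roc_points: dict = field(default_factory=dict)
    n_train: int = 0
    n_test: int = 0
    n_features_selected: int | None = None
    cv_macro_auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset_name,
            "family": self.family,
            "macro_auc": self.macro_auc,
            "per_class_auc": {str(k): v for k, v in self.per_class_auc.items()},
            "p_value": self.p_value,
            "best_params": {k: (None if v is None else v) for k, v in self.best_params.items()},
            "roc_points": {
                str(c): {"fpr": list(map(float, fpr)), "tpr": list(map(float, tpr))}
                for c, (fpr, tpr) in self.roc_points.items()
            },
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_features_selected": self.n_features_selected,
            "cv_macro_auc": self.cv_macro_auc,
        }


@dataclass
class SharedKmerReport:
    """Top-k-mer intersection between two cell subsets."""

    subset_pair: tuple[str, str]
    shared: list  # (kmer, importance_a, importance_b)


def evaluate_dataset(
    matrix: KmerCountMatrix,
    dataset: str,
    families: Sequence[str] = FAMILY_ORDER,
    selection: SelectionConfig | None = None,
    split: SplitConfig | None = None,
    grids: Mapping[str, ClassifierGrid] | None = None,
    n_perm: int | None = 99,
    seed: int = 0,
    cv_folds: int = 5,
    selection_mode: str = "split-safe",
) -> list[EvalReport]:
    """Train/evaluate every requested family on one k-mer dataset.

    Selection defaults to the standard zero screen + ANOVA. In the default
    ``split-safe`` mode it happens inside the fitted pipeline (re-estimated
    per CV fold, never seeing the test partition). ``pre-split`` applies it
    once to the whole dataset before splitting — the ordering some analyses
    report — which leaks test information and is offered for comparability
    only. ``n_perm=None`` skips permutation p-values.
    """
    if selection_mode not in {"split-safe", "pre-split"}:
        raise ValueError(
            f"selection_mode must be 'split-safe' or 'pre-split', got {selection_mode!r}"
        )
    selection = selection if selection is not None else SelectionConfig()
    split = split or SplitConfig(seed=derive_seed(seed, dataset, "split"))
    X, y = matrix.counts, matrix.labels
    pre_selected = None
    if selection_mode == "pre-split":
        result = select_features(X, y, selection)
        keep = result.kept
        if not keep.any():
            p = np.where(np.isfinite(result.p_value), result.p_value, np.inf)
            keep = np.zeros_like(keep)
            keep[np.argmin(p)] = True
        X = X[:, keep]
        pre_selected = int(keep.sum())
        selection = None
    tr, te = stratified_split(y, split)
    reports: list[EvalReport] = []
    for family in families:
        spec = (grids or {}).get(family) or default_grid(family, cv_folds)
        fam_seed = derive_seed(seed, dataset, family)
        gs = grid_search_fit(X[tr], y[tr], spec, seed=fam_seed, selection=selection)
        best = gs.best_estimator_
        scores = class_scores(best, X[te])
        macro, per_class = macro_auc(scores, y[te], classes=best.classes_)
        roc_points = {}
        for j, c in enumerate(best.classes_):
            if c in per_class:
                fpr, tpr, _ = roc_curve((y[te] == c).astype(int), scores[:, j])
                roc_points[c] = (fpr, tpr)
        n_selected = pre_selected
        if "select" in best.named_steps:
            n_selected = int(best.named_steps["select"].mask_.sum())
        p_value = None
        if n_perm:
            p_value = permutation_pvalue(
                best, X, y, n_perm=n_perm,
                seed=derive_seed(fam_seed, "perm"), split=split,
            )
        reports.append(
            EvalReport(
                dataset_name=dataset,
                family=family,
                macro_auc=macro,
                per_class_auc=per_class,
                p_value=p_value,
                best_params={k.removeprefix("clf__"): v for k, v in gs.best_params_.items()},
                roc_points=roc_points,
                n_train=len(tr),
                n_test=len(te),
                n_features_selected=n_selected,
                cv_macro_auc=float(gs.best_score_),
            )
        )
        logger.info(
            "%s/%s: macro AUC %.3f (CV %.3f), p=%s",
            dataset, family, macro, gs.best_score_, p_value,
        )
    return reports


def _state_column(per_class: Mapping, state: int):
    value = per_class.get(state, per_class.get(str(state)))
    return float(value) if value is not None else np.nan


def reports_to_frame(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """All evaluations as a flat table (one row per dataset x family)."""
    rows = []
    for r in reports:
        rows.append(
            {
                "kmer": r.dataset_name,
                "Model": r.family,
                "macro_AUC": r.macro_auc,
                "p-value": r.p_value,
                **{
                    STATE_NAMES.get(s, str(s)): _state_column(r.per_class_auc, s)
                    for s in (0, 1, 2)
                },
            }
        )
    return pd.DataFrame(rows, columns=["kmer", "Model", "macro_AUC", "p-value", "H", "M", "S"])


def best_model_table(
    reports: Sequence[EvalReport],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Best classifier per dataset, gated on permutation significance.

    Among families with p-value < alpha, the highest macro AUC wins; ties
    break by family order (simpler families first). Datasets with no
    significant family report their best AUC flagged ``significant=False``.
    The globally best significant (dataset, family) pair is flagged ``best``.
    """
    if not reports:
        raise ValueError("no reports to tabulate")
    order = {f: i for i, f in enumerate(FAMILY_ORDER)}
    by_dataset: dict[str, list[EvalReport]] = {}
    for r in reports:
        by_dataset.setdefault(r.dataset_name, []).append(r)
    rows = []
    for dataset, items in by_dataset.items():
        significant = [r for r in items if r.p_value is not None and r.p_value < alpha]
        pool = significant or items
        chosen = sorted(pool, key=lambda r: (-r.macro_auc, order[r.family]))[0]
        rows.append(
            {
                "kmer": dataset,
                "Model": chosen.family,
                "macro_AUC": chosen.macro_auc,
                "p-value": chosen.p_value,
                **{
                    STATE_NAMES.get(s, str(s)): _state_column(chosen.per_class_auc, s)
                    for s in (0, 1, 2)
                },
                "significant": bool(significant),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["kmer", "Model", "macro_AUC", "p-value", "H", "M", "S", "significant"],
    )
    flagged = table[table["significant"]] if table["significant"].any() else table
    best_idx = flagged["macro_AUC"].idxmax()
    table["best"] = False
    table.loc[best_idx, "best"] = True
    return table


# ---------------------------------------------------------------------------
# feature importance and shared-motif intersection


def top_kmers(
    model: Pipeline,
    feature_space: FeatureSpace,
    top_n: int = 50,
) -> list[tuple[str, float]]:
    """Top-N concatemers by importance from a fitted pipeline.

    Tree families expose impurity importances and linear families
    coefficient magnitudes; families with neither (KNN, MLP) fall back to
    the in-pipeline ANOVA F statistic of the selected features.
    """
    clf = model.named_steps["clf"]
    if "select" in model.named_steps:
        selector = model.named_steps["select"]
        col_idx = np.flatnonzero(selector.mask_)
        f_stat = selector.selection_.f_stat[col_idx]
    else:
        col_idx = np.arange(feature_space.n_features)
        f_stat = None
    if hasattr(clf, "feature_importances_"):
        imp = np.asarray(clf.feature_importances_, dtype=float)
    elif hasattr(clf, "coef_"):
        imp = np.abs(np.atleast_2d(clf.coef_)).sum(axis=0).astype(float)
    elif f_stat is not None:
        imp = np.where(np.isfinite(f_stat), f_stat, 0.0)
    else:
        raise ValueError(
            "model exposes neither importances nor coefficients and has no "
            "selection step to fall back on"
        )
    order = np.argsort(-imp, kind="stable")[:top_n]
    return [(feature_space.columns[col_idx[i]], float(imp[i])) for i in order]


def shared_kmer_analysis(
    selected: Mapping[str, Sequence[tuple[str, float]] | Mapping[str, float]],
    top_n: int = 50,
) -> list[SharedKmerReport]:
    """Intersect the top-N important k-mers between every pair of subsets.

    ``selected`` maps subset name to its ranked (kmer, importance) pairs
    (or a kmer -> importance mapping). Shared k-mers are ordered by the sum
    of their ranks in the two subsets.
    """
    if len(selected) < 2:
        raise ValueError("shared-k-mer analysis needs >= 2 subsets")
    ranked: dict[str, list[tuple[str, float]]] = {}
    for subset, items in selected.items():
        pairs = list(items.items()) if isinstance(items, Mapping) else list(items)
        pairs.sort(key=lambda kv: (-kv[1], kv[0]))
        ranked[subset] = pairs[:top_n]
    reports = []
    subsets = sorted(ranked)
    for i, a in enumerate(subsets):
        for b in subsets[i + 1 :]:
            imp_a = dict(ranked[a])
            imp_b = dict(ranked[b])
            rank_a = {k: r for r, (k, _) in enumerate(ranked[a])}
            rank_b = {k: r for r, (k, _) in enumerate(ranked[b])}
            common = sorted(
                set(imp_a) & set(imp_b), key=lambda k: rank_a[k] + rank_b[k]
            )
            reports.append(
                SharedKmerReport(
                    subset_pair=(a, b),
                    shared=[(k, imp_a[k], imp_b[k]) for k in common],
                )
            )
    return reports


def shared_kmers_to_frame(reports: Sequence[SharedKmerReport]) -> pd.DataFrame:
    rows = [
        {
            "subset_a": r.subset_pair[0],
            "subset_b": r.subset_pair[1],
            "kmer": k,
            "importance_a": ia,
            "importance_b": ib,
        }
        for r in reports
        for k, ia, ib in r.shared
    ]
    return pd.DataFrame(
        rows, columns=["subset_a", "subset_b", "kmer", "importance_a", "importance_b"]
    )
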