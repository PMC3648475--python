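"""Learning-based validation of the climate-defined sets.

If ecotypic differentiation is real, classifiers trained on the measured
traits should recover the climate-based wet/dry membership.  The harness:
standardize the combined accession-level data (mean 0, SD 1, sample SD),
split 2/3 train / 1/3 test at random, fit three model families
(CART decision tree, random forest, RBF-kernel SVM), score the held-out
third, and repeat 10 times.

Metric kernels are implemented here: ROC-AUC via the midrank (Mann-Whitney)
formulation — equal to the trapezoidal area under the ROC and to the
probability that a random dry accession outscores a random wet one, with
ties counted half; confusion-matrix rates with the dry set as the positive
("trait-holding") class; and Cohen's kappa with chance agreement from the
marginal products.  AUC >= 0.7 is read as high discriminative performance
and kappa >= 0.4 as good agreement.

Variable importance: impurity (Gini) importance from the tree ensembles and
permutation importance (mean decrease in accuracy) — defined for the tree
families only, not for SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, DomainError, NotSupportedError

POSITIVE_LABEL = "dry"  # the "trait-holding" class for sensitivity/omission

METRIC_NAMES = (
    "auc",
    "omission_rate",
    "sensitivity",
    "specificity",
    "correct_classification_rate",
    "kappa",
)

FAMILIES = ("tree", "random_forest", "svm_rbf")


@dataclass(frozen=True)
class ClassifierSpec:
    """One model family plus its (overridable) hyperparameters.

    Defaults follow the conventions of the families' canonical
    implementations: random forest with 500 trees and sqrt(p) candidate
    predictors per node; RBF SVM with gamma = 1/p and cost C = 1; CART with
    cost-complexity pruning (ccp_alpha 0.01).
    """

    family: str
    hyperparameters: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown model family {self.family!r}; expected {FAMILIES}")


def default_model_specs(seed: int = 0) -> list[ClassifierSpec]:
    return [ClassifierSpec(family, seed=seed) for family in FAMILIES]


def build_model(spec: ClassifierSpec, n_features: int, random_state: int):
    """Instantiate the scikit-learn estimator behind a spec."""
    hp = dict(spec.hyperparameters)
    if spec.family == "tree":
        return DecisionTreeClassifier(
            ccp_alpha=hp.pop("ccp_alpha", 0.01), random_state=random_state, **hp
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(hp.pop("n_tree", 500)),
            max_features=hp.pop("m_try", "sqrt"),
            random_state=random_state,
            **hp,
        )
    if spec.family == "svm_rbf":
        return SVC(
            kernel="rbf",
            gamma=hp.pop("gamma", 1.0 / n_features),
            C=hp.pop("C", 1.0),
            random_state=random_state,
            **hp,
        )
    raise ConfigError(f"unknown model family {spec.family!r}")


@dataclass(frozen=True)
class EvalMetrics:
    """One run's test-set scores; omission_rate is 1 - sensitivity."""

    auc: float
    omission_rate: float
    sensitivity: float
    specificity: float
    correct_classification_rate: float
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class RunSummary:
    """Per-model aggregate over the repeated splits (mean, min, max)."""

    family: str
    per_run: list[EvalMetrics]
    n_failed: int = 0
    roc_points: list[pd.DataFrame] = field(default_factory=list)

    def _agg(self, fn) -> dict[str, float]:
        return {m: float(fn([getattr(r, m) for r in self.per_run])) for m in METRIC_NAMES}

    @property
    def mean(self) -> dict[str, float]:
        return self._agg(np.mean)

    @property
    def lower(self) -> dict[str, float]:
        return self._agg(np.min)

    @property
    def upper(self) -> dict[str, float]:
        return self._agg(np.max)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "n_runs": len(self.per_run),
            "n_failed": self.n_failed,
            "mean": self.mean,
            "lower": self.lower,
            "upper": self.upper,
            "per_run": [r.as_dict() for r in self.per_run],
        }


def standardize(traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center/scale every column to mean 0, SD 1 (sample SD, ddof=1).

    Computed over the combined data (both sets together).  Constant columns
    carry no information for the split and are dropped with a warning entry
    in the returned transform table.  Returns ``(standardized, params)``
    where ``params`` has one row per input column (mean, sd, kept flag).
    """
    if len(traits) < 2:
        raise DomainError("standardization needs at least 2 rows")
    num = traits.select_dtypes(include=[np.number])
    means = num.mean()
    sds = num.std(ddof=1)
    kept = sds > 0
    params = pd.DataFrame({"mean": means, "sd": sds, "kept": kept})
    out = (num.loc[:, kept] - means[kept]) / sds[kept]
    return out, params


def split_train_test(
    n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random 2/3 train / 1/3 test partition of ``range(n)``.

    ``|train| = round(2n/3)``; the partition is disjoint and exhaustive and
    a deterministic function of the seed.
    """
    if n < 3:
        raise DomainError("need at least 3 cases to split 2/3 - 1/3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.rint(2 * n / 3))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def roc_auc(scores: Sequence[float], labels: Sequence[str | bool]) -> float:
    """Area under the ROC curve via midranks.

    ``labels`` marks the positive (dry) class, either as booleans or as
    label strings compared to the positive label.  With ties handled by
    midranks this equals the trapezoidal ROC area and the pairwise-ordering
    probability P(score_pos > score_neg) + 0.5 P(tie).
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    pos = lab if lab.dtype == bool else lab == POSITIVE_LABEL
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError("AUC undefined: both classes must be present")
    from scipy.stats import rankdata

    r = rankdata(s)  # midranks
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve_points(scores: Sequence[float], labels: Sequence[str | bool]) -> pd.DataFrame:
    """ROC curve (fpr, tpr, threshold), one step per distinct score."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    pos = lab if lab.dtype == bool else lab == POSITIVE_LABEL
    order = np.argsort(-s, kind="mergesort")
    s, pos = s[order], pos[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(pos)[distinct]
    fps = np.cumsum(~pos)[distinct]
    return pd.DataFrame(
        {
            "threshold": np.r_[np.inf, s[distinct]],
            "fpr": np.r_[0.0, fps / max(int((~pos).sum()), 1)],
            "tpr": np.r_[0.0, tps / max(int(pos.sum()), 1)],
        }
    )


def confusion_metrics(
    predicted: Sequence[str], actual: Sequence[str], positive: str = POSITIVE_LABEL
) -> dict[str, float]:
    """Confusion-matrix rates and Cohen's kappa (AUC handled separately).

    Sensitivity = TP/(TP+FN) with respect to the positive (dry) class;
    omission rate = 1 - sensitivity; correct classification rate =
    (TP+TN)/N; kappa = (p_o - p_e)/(1 - p_e) with p_e from the marginal
    products, defined as 0 when p_e = 1 (constant prediction on a constant
    truth).
    """
    pred = np.asarray(predicted)
    act = np.asarray(actual)
    if pred.size == 0 or pred.shape != act.shape:
        raise DomainError("predicted/actual must be non-empty and equal-length")
    p = pred == positive
    a = act == positive
    tp = int((p & a).sum())
    fn = int((~p & a).sum())
    tn = int((~p & ~a).sum())
    fp = int((p & ~a).sum())
    n = tp + fn + tn + fp
    if tp + fn == 0 or tn + fp == 0:
        raise DomainError("both classes must be present in the actual labels")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ccr = (tp + tn) / n
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    kappa = 0.0 if p_e == 1.0 else (ccr - p_e) / (1.0 - p_e)
    return {
        "omission_rate": 1.0 - sens,
        "sensitivity": sens,
        "specificity": spec,
        "correct_classification_rate": ccr,
        "kappa": kappa,
    }


def _positive_scores(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous score for the positive class + thresholded prediction.

    Probability-producing models are thresholded at 0.5; margin-based
    models (SVM) use the signed decision value thresholded at 0.  AUC is
    rank-invariant to the choice.
    """
    classes = list(model.classes_)
    if hasattr(model, "predict_proba"):
        score = model.predict_proba(X)[:, classes.index(POSITIVE_LABEL)]
        pred = np.where(score >= 0.5, POSITIVE_LABEL, _other(classes))
    else:
        dec = model.decision_function(X)
        if classes[1] != POSITIVE_LABEL:
            dec = -dec
        score = dec
        pred = np.where(dec >= 0.0, POSITIVE_LABEL, _other(classes))
    return score, pred


def _other(classes: list[str]) -> str:
    return next(c for c in classes if c != POSITIVE_LABEL)


def run_harness(
    traits: pd.DataFrame,
    membership: pd.Series,
    models: Sequence[ClassifierSpec] | None = None,
    n_runs: int = 10,
    seed: int = 0,
    collect_roc: bool = False,
) -> dict[str, RunSummary]:
    """The repeated-split evaluation: standardize once, then ``n_runs``
    random 2/3-1/3 splits, fitting every model family on each train fold
    and scoring the held-out third.

    ``membership`` is a label series ("dry"/"wet") aligned to ``traits``
    rows.  Everything is a deterministic function of the master seed.
    """
    labels = np.asarray(membership)
    if len(set(labels)) < 2:
        raise DomainError("both sets must be represented in the membership labels")
    specs = list(models) if models is not None else default_model_specs(seed)
    X_df, _ = standardize(traits)
    X = X_df.to_numpy()
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)

    summaries = {s.family: RunSummary(family=s.family, per_run=[]) for s in specs}
    for run_seed in run_seeds:
        train, test = split_train_test(len(labels), int(run_seed))
        for spec in specs:
            model = build_model(spec, X.shape[1], random_state=int(run_seed))
            try:
                model.fit(X[train], labels[train])
                score, pred = _positive_scores(model, X[test])
                cm = confusion_metrics(pred, labels[test])
                metrics = EvalMetrics(auc=roc_auc(score, labels[test]), **cm)
            except Exception:
                summaries[spec.family].n_failed += 1
                continue
            summaries[spec.family].per_run.append(metrics)
            if collect_roc:
                pts = roc_curve_points(score, labels[test])
                pts.insert(0, "run", len(summaries[spec.family].per_run))
                summaries[spec.family].roc_points.append(pts)
    for fam, s in summaries.items():
        if not s.per_run:
            raise DomainError(f"every run failed for model family {fam}")
    return summaries


def variable_importance(
    traits: pd.DataFrame,
    membership: pd.Series,
    families: Sequence[str] = ("tree", "random_forest"),
    seed: int = 0,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Variable-importance table from the tree-based families.

    Columns: ``tree_importance`` (CART impurity importance),
    ``mean_decrease_gini`` (random-forest impurity importance: total Gini
    decrease attributed to splits on the variable), and
    ``mean_decrease_accuracy`` (permutation importance of the fitted
    forest).  Ranks (1 = most important) are assigned per column; the
    headline ``rank`` follows mean_decrease_gini.  SVM has no intrinsic
    importance and raises :class:`NotSupportedError`.
    """
    for fam in families:
        if fam == "svm_rbf":
            raise NotSupportedError("variable importance is undefined for the SVM family")
        if fam not in FAMILIES:
            raise ConfigError(f"unknown model family {fam!r}")
    labels = np.asarray(membership)
    X_df, _ = standardize(traits)
    X = X_df.to_numpy()
    out = pd.DataFrame(index=X_df.columns)

    if "tree" in families:
        tree = build_model(ClassifierSpec("tree"), X.shape[1], random_state=seed)
        tree.fit(X, labels)
        out["tree_importance"] = tree.feature_importances_
    if "random_forest" in families:
        rf = build_model(ClassifierSpec("random_forest"), X.shape[1], random_state=seed)
        rf.fit(X, labels)
        out["mean_decrease_gini"] = rf.feature_importances_
        perm = permutation_importance(
            rf, X, labels, scoring="accuracy", n_repeats=n_repeats, random_state=seed
        )
        # floor at 0: negative permutation scores are sampling noise
        out["mean_decrease_accuracy"] = np.maximum(perm.importances_mean, 0.0)

    for col in list(out.columns):
        out[f"rank_{col}"] = out[col].rank(ascending=False, method="first").astype(int)
    if "mean_decrease_gini" in out.columns:
        out["rank"] = out["rank_mean_decrease_gini"]
    elif "tree_importance" in out.columns:
        out["rank"] = out["rank_tree_importance"]
    return out.sort_values("rank")


def repeated_importance(
    traits: pd.DataFrame,
    membership: pd.Series,
    n_runs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Random-forest impurity importance across repeated 2/3 train splits.

    Returns a runs x variables table; used to ask how stably a variable
    leads the ranking.
    """
    labels = np.asarray(membership)
    X_df, _ = standardize(traits)
    X = X_df.to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for run_seed in rng.integers(0, 2**31 - 1, size=n_runs):
        train, _ = split_train_test(len(labels), int(run_seed))
        rf = build_model(ClassifierSpec("random_forest"), X.shape[1], random_state=int(run_seed))
        rf.fit(X[train], labels[train])
        rows.append(rf.feature_importances_)
    return pd.DataFrame(rows, columns=X_df.columns)
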