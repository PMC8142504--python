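"""Subtype classifier: Cox-screened DEGs, a random forest with the study's
hyperparameters (mtry=2, 500 trees), tenfold cross-validated variable-count
selection, ROC/AUC, and cross-cohort prediction with rank harmonization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .io import ClinicalTable, ExpressionMatrix, SubtypeAssignment, log2cpm
from .survival import univariate_cox_screen


@dataclass
class ClassifierSpec:
    """A trained subtype classifier and its selection protocol record."""

    selected_genes: list[str]             # genes in the final model, importance order
    mtry: int
    ntree: int
    seed: int
    cv_error_curve: pd.Series             # n_variables -> mean CV error
    model: RandomForestClassifier
    classes: list[str]
    training_medians: pd.Series           # per-gene median rank-unit value
    candidate_genes: list[str] = field(default_factory=list)


def select_classifier_genes(
    deg_table: pd.DataFrame,
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    p: float = 0.05,
    endpoint: str = "os",
) -> list[str]:
    """DEGs whose univariate Cox p-value on overall survival is < ``p``."""
    degs = deg_table.index[deg_table["is_deg"]].tolist()
    if not degs:
        raise ValueError("no DEGs to screen; relax the DEG thresholds")
    surv = clinical.survival(endpoint)
    common = [s for s in expr.sample_ids if s in surv.index]
    vals = log2cpm(expr.restrict_samples(common), genes=degs)
    fits = univariate_cox_screen(vals, surv.loc[common, "time"],
                                 surv.loc[common, "event"])
    kept = fits.index[fits["p"] < p].tolist()
    if not kept:
        raise ValueError(
            "no DEGs pass the survival screen; consider raising the p threshold"
        )
    return kept


def rank_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene within-cohort rank normalization to [0, 1].

    Makes an RNA-seq-trained model applicable to array cohorts: each
    gene's values are replaced by (rank-1)/(n-1) across the cohort.
    """
    n = values.shape[1]
    if n == 1:
        return values * 0 + 0.5
    ranks = values.rank(axis=1, method="average")
    return (ranks - 1.0) / (n - 1.0)


def _features(expr: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    """Samples x genes feature frame on the rank-normalized scale."""
    vals = rank_normalize(log2cpm(expr, genes=genes))
    return vals.T


def train_and_cv(
    expr: ExpressionMatrix,
    labels: SubtypeAssignment | pd.Series,
    genes: list[str],
    mtry: int = 2,
    ntree: int = 500,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    subset_sizes=None,
) -> ClassifierSpec:
    """Train the subtype random forest with variable-count selection.

    Genes are ranked by mean impurity-decrease importance from a forest on
    all candidate genes; cross-validated error is evaluated on nested
    importance-ranked subsets (all sizes 1..G unless ``subset_sizes``
    restricts the sweep), averaged over ``repeats`` repetitions of
    stratified ``folds``-fold CV; the final forest is refit on the subset
    with minimum mean error (ties -> fewer genes).
    """
    y = labels.labels if isinstance(labels, SubtypeAssignment) else pd.Series(labels)
    X = _features(expr, genes)
    y = y.loc[X.index].astype(str)
    if len(X) < 20:
        raise ValueError("need at least 20 samples to train the classifier")
    if y.nunique() < 2:
        raise ValueError("both classes must be present")
    mtry = min(mtry, len(genes))

    ranker = RandomForestClassifier(
        n_estimators=ntree, max_features=mtry, random_state=seed
    ).fit(X.to_numpy(), y.to_numpy())
    order = np.argsort(-ranker.feature_importances_, kind="stable")
    ranked_genes = [X.columns[i] for i in order]

    sizes = list(subset_sizes) if subset_sizes is not None else list(
        range(1, len(ranked_genes) + 1))
    sizes = sorted({min(s, len(ranked_genes)) for s in sizes})
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=seed + 1)
    Xv = X[ranked_genes].to_numpy()
    yv = y.to_numpy()
    errors = {s: [] for s in sizes}
    for train_idx, test_idx in cv.split(Xv, yv):
        if len(np.unique(yv[train_idx])) < 2:
            raise ValueError("a class is absent from a training fold")
        for s in sizes:
            clf = RandomForestClassifier(
                n_estimators=ntree, max_features=min(mtry, s), random_state=seed
            ).fit(Xv[train_idx][:, :s], yv[train_idx])
            pred = clf.predict(Xv[test_idx][:, :s])
            errors[s].append(np.mean(pred != yv[test_idx]))
    curve = pd.Series({s: float(np.mean(errors[s])) for s in sizes},
                      name="cv_error").sort_index()
    best_size = int(curve.index[np.argmin(curve.to_numpy())])  # ties -> fewer genes
    final_genes = ranked_genes[:best_size]
    model = RandomForestClassifier(
        n_estimators=ntree, max_features=min(mtry, best_size), random_state=seed
    ).fit(X[final_genes].to_numpy(), yv)
    medians = X[final_genes].median(axis=0)
    return ClassifierSpec(
        selected_genes=final_genes,
        mtry=mtry,
        ntree=ntree,
        seed=seed,
        cv_error_curve=curve,
        model=model,
        classes=sorted(y.unique()),
        training_medians=medians,
        candidate_genes=ranked_genes,
    )


def roc_auc(scores, binary_labels) -> dict:
    """Empirical ROC curve and trapezoidal AUC.

    Equals (concordant pairs + half the tied pairs) / all pairs.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("need both classes present")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    # group tied thresholds
    tps = np.cumsum(yy)
    fps = np.cumsum(1 - yy)
    last_of_tie = np.r_[np.diff(s) != 0, True]
    tpr = np.r_[0.0, tps[last_of_tie] / n_pos]
    fpr = np.r_[0.0, fps[last_of_tie] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return {"auc": auc, "fpr": fpr, "tpr": tpr}


def predict_subtypes(
    spec: ClassifierSpec,
    expr_new: ExpressionMatrix,
    reference: SubtypeAssignment | None = None,
) -> dict:
    """Predict subtype labels for a new cohort.

    Genes missing from the new cohort are imputed at the training-set
    median (with a warning); an error is raised when more than half the
    model genes are absent. Returns majority-vote labels, per-class vote
    fractions, and (when ``reference`` is given) the concordance with a
    reference assignment.
    """
    present = [g for g in spec.selected_genes if g in expr_new.values.index]
    missing = [g for g in spec.selected_genes if g not in expr_new.values.index]
    if len(missing) > len(spec.selected_genes) / 2:
        raise ValueError(f"{len(missing)}/{len(spec.selected_genes)} model genes "
                         "missing from the new cohort")
    X = _features(expr_new, present)
    for g in missing:
        warnings.warn(f"gene {g} missing: imputed at training median", stacklevel=2)
        X[g] = spec.training_medians[g]
    X = X[spec.selected_genes]
    votes = spec.model.predict_proba(X.to_numpy())
    labels = pd.Series(
        [spec.model.classes_[i] for i in votes.argmax(axis=1)],
        index=X.index, name="subtype",
    )
    vote_df = pd.DataFrame(votes, index=X.index, columns=spec.model.classes_)
    out = {"labels": labels, "votes": vote_df}
    if reference is not None:
        common = [s for s in labels.index if s in reference.labels.index]
        agree = (labels.loc[common] == reference.labels.loc[common]).mean()
        out["concordance"] = float(agree)
    return out


class SubtypeClassifier:
    """scikit-learn-style wrapper around the forest training protocol."""

    def __init__(self, mtry=2, ntree=500, folds=10, repeats=10, seed=0,
                 subset_sizes=None):
        self.mtry = mtry
        self.ntree = ntree
        self.folds = folds
        self.repeats = repeats
        self.seed = seed
        self.subset_sizes = subset_sizes

    def get_params(self, deep=True):
        return {
            "mtry": self.mtry, "ntree": self.ntree, "folds": self.folds,
            "repeats": self.repeats, "seed": self.seed,
            "subset_sizes": self.subset_sizes,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key}")
            setattr(self, key, value)
        return self

    def fit(self, expr: ExpressionMatrix, y, genes=None):
        genes = genes or list(expr.values.index)
        self.spec_ = train_and_cv(
            expr, y, genes, mtry=self.mtry, ntree=self.ntree, folds=self.folds,
            repeats=self.repeats, seed=self.seed, subset_sizes=self.subset_sizes,
        )
        self.selected_genes_ = self.spec_.selected_genes
        self.cv_error_curve_ = self.spec_.cv_error_curve
        return self

    def predict(self, expr_new: ExpressionMatrix):
        return predict_subtypes(self.spec_, expr_new)["labels"]

    def predict_proba(self, expr_new: ExpressionMatrix):
        return predict_subtypes(self.spec_, expr_new)["votes"]
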