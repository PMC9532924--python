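"""Responder-prediction model: feature assembly and nested-CV linear SVM.

A binary linear support-vector machine separates responders (>= 50 %
seizure reduction, the positive class) from non-responders using up to 43
features: 25 encoded clinical covariates and the 18 global
phase-synchronization features. Feature selection — either a Fisher-score
filter or recursive feature elimination (RFE) — and the SVM cost C are
chosen by 5-fold cross-validation inside each training split of a
stratified 10-fold outer loop, so the reported accuracy, precision and
ROC/AUC are leakage-free estimates. Standardization statistics are
likewise learned on each training split only.

"Coefficients" reported for recurrently selected features are the linear
SVM weights in standardized feature space, aggregated (mean +/- SD) over
the outer folds in which the feature was selected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE
from sklearn.metrics import confusion_matrix, precision_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .recording import sync_feature_names

ETIOLOGIES = ("structural", "genetic", "autoimmune", "unknown")
SEIZURE_TYPES = ("generalized", "focal", "spasms", "multiple")
SYNDROMES = ("infantile_spasms", "LGS", "EOEE", "unclassified")
MRI_FINDINGS = ("local", "multifocal", "negative")

#: Fixed order of the 25 encoded clinical columns.
CLINICAL_COLUMNS: tuple[str, ...] = (
    "bmi", "diastolic_pressure", "pulse_pressure", "age_implantation",
    "epilepsy_duration", "age_onset", "prior_surgery", "seizure_frequency",
    *(f"etiology_{e}" for e in ETIOLOGIES),
    *(f"seizure_type_{t}" for t in SEIZURE_TYPES),
    *(f"syndrome_{s}" for s in SYNDROMES),
    *(f"mri_{m}" for m in MRI_FINDINGS),
    "n_asm_historical", "n_asm_baseline",
)

DEFAULT_C_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_K_GRID: tuple[int, ...] = (5, 10, 15, 20, 30, 43)


@dataclass(frozen=True)
class ClinicalRecord:
    """Baseline clinical covariates of one subject.

    ``gender`` and ``benzodiazepine_use`` are carried for the descriptive
    group comparison but are not part of the 25-column model encoding.
    ``seizure_types`` is a non-exclusive set (a child may have several
    predominant types), hence its indicator block is multi-hot.
    """

    bmi: float
    diastolic_pressure: float
    pulse_pressure: float
    age_implantation: float
    epilepsy_duration: float
    age_onset: float
    prior_surgery: bool
    seizure_frequency: float
    etiology: str
    seizure_types: frozenset[str]
    syndrome: str
    mri: str
    n_asm_historical: int
    n_asm_baseline: int
    gender: str = "male"
    benzodiazepine_use: bool = False

    def __post_init__(self) -> None:
        if self.etiology not in ETIOLOGIES:
            raise ValueError(f"unknown etiology {self.etiology!r}")
        if self.syndrome not in SYNDROMES:
            raise ValueError(f"unknown syndrome {self.syndrome!r}")
        if self.mri not in MRI_FINDINGS:
            raise ValueError(f"unknown MRI finding {self.mri!r}")
        unknown = set(self.seizure_types) - set(SEIZURE_TYPES)
        if unknown:
            raise ValueError(f"unknown seizure types {sorted(unknown)}")
        if not self.seizure_types:
            raise ValueError("at least one seizure type is required")
        for name in ("bmi", "age_implantation", "epilepsy_duration", "age_onset",
                     "seizure_frequency"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_asm_historical < 0 or self.n_asm_baseline < 0:
            raise ValueError("ASM counts must be >= 0")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "bmi", "diastolic_pressure", "pulse_pressure", "age_implantation",
            "epilepsy_duration", "age_onset", "prior_surgery", "seizure_frequency",
            "etiology", "syndrome", "mri", "n_asm_historical", "n_asm_baseline",
            "gender", "benzodiazepine_use")}
        d["seizure_types"] = "|".join(sorted(self.seizure_types))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClinicalRecord":
        d = dict(d)
        d["seizure_types"] = frozenset(str(d["seizure_types"]).split("|"))
        for b in ("prior_surgery", "benzodiazepine_use"):
            v = d[b]
            d[b] = v if isinstance(v, (bool, np.bool_)) else str(v).lower() in ("true", "1")
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


def encode_clinical(record: ClinicalRecord) -> np.ndarray:
    """Encode a clinical record as the fixed 25-column numeric vector."""
    vec = [
        record.bmi, record.diastolic_pressure, record.pulse_pressure,
        record.age_implantation, record.epilepsy_duration, record.age_onset,
        float(record.prior_surgery), record.seizure_frequency,
        *(float(record.etiology == e) for e in ETIOLOGIES),
        *(float(t in record.seizure_types) for t in SEIZURE_TYPES),
        *(float(record.syndrome == s) for s in SYNDROMES),
        *(float(record.mri == m) for m in MRI_FINDINGS),
        float(record.n_asm_historical), float(record.n_asm_baseline),
    ]
    out = np.array(vec, dtype=float)
    assert out.shape == (len(CLINICAL_COLUMNS),)
    return out


@dataclass
class FeatureMatrix:
    """Subjects x features design matrix with binary responder labels."""

    X: pd.DataFrame
    y: np.ndarray  # 1 = responder (positive class)

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if len(self.y) != len(self.X):
            raise ValueError("label/subject count mismatch")


def assemble_matrix(
    clinical: dict[str, ClinicalRecord] | None,
    sync: dict[str, dict[str, float]] | None,
    labels: dict[str, bool],
    mode: str = "integrated",
) -> FeatureMatrix:
    """Stack clinical and/or synchronization features into a model input.

    ``mode`` is one of ``integrated`` (43 columns), ``clinical`` (25) or
    ``sync`` (18). Keys of all mappings are subject ids and must agree.
    """
    if mode not in ("integrated", "clinical", "sync"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = sorted(labels)
    if len(set(ids)) != len(labels):
        raise ValueError("duplicate subject ids")
    blocks: list[pd.DataFrame] = []
    if mode in ("integrated", "clinical"):
        if clinical is None or set(clinical) != set(ids):
            raise ValueError("clinical records missing or subject sets mismatch")
        blocks.append(pd.DataFrame(
            [encode_clinical(clinical[i]) for i in ids],
            index=ids, columns=list(CLINICAL_COLUMNS)))
    if mode in ("integrated", "sync"):
        names = sync_feature_names()
        if sync is None or set(sync) != set(ids):
            raise ValueError("sync features missing or subject sets mismatch")
        blocks.append(pd.DataFrame(
            [[sync[i][n] for n in names] for i in ids], index=ids, columns=names))
    X = pd.concat(blocks, axis=1)
    y = np.array([int(labels[i]) for i in ids])
    return FeatureMatrix(X=X, y=y)


def f_score_rank(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-class Fisher-criterion F-score per feature, ranked descending.

    score_j = ((m+_j - m_j)^2 + (m-_j - m_j)^2) /
              (s+_j^2 + s-_j^2)        (unbiased within-class variances)

    Constant features (zero denominator) score 0. Returns
    ``(order, scores)`` where ``order`` is a stable descending sort with
    ties broken by column index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("f_score_rank requires exactly two classes present")
    pos, neg = X[y == classes[1]], X[y == classes[0]]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 subjects per class for within-class variance")
    m, mp, mn = X.mean(axis=0), pos.mean(axis=0), neg.mean(axis=0)
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    scores = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    order = np.argsort(-scores, kind="stable")
    return order, scores


def rfe_select(X: np.ndarray, y: np.ndarray, n_keep: int, C: float = 1.0) -> np.ndarray:
    """Recursive feature elimination with a linear SVM, one feature per step."""
    X = np.asarray(X, dtype=float)
    if n_keep < 1 or n_keep > X.shape[1]:
        raise ValueError(f"n_keep must be in [1, {X.shape[1]}]")
    if len(np.unique(y)) != 2:
        raise ValueError("rfe_select requires both classes present")
    rfe = RFE(SVC(kernel="linear", C=C), n_features_to_select=n_keep, step=1)
    rfe.fit(X, y)
    return np.nonzero(rfe.support_)[0]


def _select(selector: str, X: np.ndarray, y: np.ndarray, k: int, C: float) -> np.ndarray:
    k = min(k, X.shape[1])
    if selector == "f_score":
        order, _ = f_score_rank(X, y)
        return np.sort(order[:k])
    if selector == "rfe":
        return rfe_select(X, y, k, C)
    raise ValueError(f"unknown selector {selector!r}")


def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (other - mu) / sd, mu, sd


@dataclass
class ModelReport:
    """Pooled outer-fold performance of the nested-CV SVM."""

    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    decision_scores: np.ndarray
    fold_assignment: np.ndarray
    confusion: np.ndarray  # rows true [NR, R], cols predicted [NR, R]
    accuracy: float
    precision: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    selected_per_fold: list[list[str]]
    chosen_params: list[dict]
    coefficient_summary: pd.DataFrame
    seed: int
    config: dict = field(default_factory=dict)


def _inner_cv_choose(
    X: np.ndarray, y: np.ndarray, selector: str,
    c_grid: Sequence[float], k_grid: Sequence[int],
    inner_k: int, rng_seed: int,
) -> tuple[float, int]:
    """Pick (C, n_features) by mean inner-CV accuracy.

    Ties prefer fewer features, then smaller C (simplicity first).
    """
    inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=rng_seed)
    best = None
    for k in sorted(set(min(k, X.shape[1]) for k in k_grid)):
        for C in sorted(c_grid):
            accs = []
            for tr, va in inner.split(X, y):
                Xtr, Xva, _, _ = _standardize(X[tr], X[va])
                cols = _select(selector, Xtr, y[tr], k, C)
                clf = SVC(kernel="linear", C=C)
                clf.fit(Xtr[:, cols], y[tr])
                accs.append(clf.score(Xva[:, cols], y[va]))
            mean_acc = float(np.mean(accs))
            key = (mean_acc, -k, -C)
            if best is None or key > best[0]:
                best = (key, C, k)
    assert best is not None
    return best[1], best[2]


def nested_cv(
    fm: FeatureMatrix,
    selector: str = "f_score",
    outer_k: int = 10,
    inner_k: int = 5,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    seed: int = 0,
    min_select_fraction: float = 0.5,
) -> ModelReport:
    """Stratified nested cross-validation of the linear SVM.

    Scaling, feature selection and the (C, n_features) choice are fit on
    each outer-training split only; outer-test predictions and decision
    scores are pooled for the confusion matrix, accuracy, precision and
    ROC/AUC. Deterministic given ``seed``.
    """
    X = fm.X.to_numpy(dtype=float)
    y = fm.y
    names = list(fm.X.columns)
    if len(y) < outer_k:
        raise ValueError("fewer subjects than outer folds")
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    n = len(y)
    y_pred = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    fold_of = np.empty(n, dtype=int)
    selected_per_fold: list[list[str]] = []
    chosen: list[dict] = []
    fold_weights: list[dict[str, float]] = []
    for f, (tr, te) in enumerate(outer.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"outer fold {f}: a class is missing from training data")
        C, k = _inner_cv_choose(X[tr], y[tr], selector, c_grid, k_grid, inner_k,
                                rng_seed=seed * 1000 + f)
        Xtr, Xte, _, _ = _standardize(X[tr], X[te])
        cols = _select(selector, Xtr, y[tr], k, C)
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xtr[:, cols], y[tr])
        y_pred[te] = clf.predict(Xte[:, cols])
        scores[te] = clf.decision_function(Xte[:, cols])
        fold_of[te] = f
        sel_names = [names[c] for c in cols]
        selected_per_fold.append(sel_names)
        chosen.append({"C": C, "n_features": int(k)})
        fold_weights.append(dict(zip(sel_names, clf.coef_.ravel())))

    conf = confusion_matrix(y, y_pred, labels=[0, 1])
    acc = float((y_pred == y).mean())
    prec = float(precision_score(y, y_pred, pos_label=1, zero_division=0))
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))

    counts: dict[str, int] = {}
    for sel in selected_per_fold:
        for s in sel:
            counts[s] = counts.get(s, 0) + 1
    rows = []
    for name, cnt in counts.items():
        if cnt / outer_k >= min_select_fraction:
            w = [fw[name] for fw in fold_weights if name in fw]
            rows.append({"feature": name, "n_folds": cnt,
                         "coef_mean": float(np.mean(w)),
                         "coef_sd": float(np.std(w, ddof=1)) if len(w) > 1 else 0.0})
    coef = pd.DataFrame(rows, columns=["feature", "n_folds", "coef_mean", "coef_sd"])
    if len(coef):
        coef = coef.sort_values("coef_mean", ascending=False, ignore_index=True)

    return ModelReport(
        subject_ids=list(fm.X.index),
        y_true=y.copy(), y_pred=y_pred, decision_scores=scores,
        fold_assignment=fold_of, confusion=conf, accuracy=acc, precision=prec,
        roc_fpr=fpr, roc_tpr=tpr, auc=auc,
        selected_per_fold=selected_per_fold, chosen_params=chosen,
        coefficient_summary=coef, seed=seed,
        config={"selector": selector, "outer_k": outer_k, "inner_k": inner_k,
                "c_grid": list(c_grid), "k_grid": list(k_grid),
                "min_select_fraction": min_select_fraction},
    )


@dataclass
class FittedModel:
    """A final scale -> select -> fit pipeline, JSON-serializable."""

    feature_names: list[str]
    mu: np.ndarray
    sd: np.ndarray
    selected: np.ndarray
    weights: np.ndarray
    intercept: float
    C: float
    selector: str

    def predict(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        if list(X.columns) != self.feature_names:
            raise ValueError("external matrix columns do not match the fitted model")
        Z = (X.to_numpy(dtype=float) - self.mu) / self.sd
        s = Z[:, self.selected] @ self.weights + self.intercept
        return (s > 0).astype(int), s

    def to_json(self) -> str:
        return json.dumps({
            "schema": 1, "feature_names": self.feature_names,
            "mu": self.mu.tolist(), "sd": self.sd.tolist(),
            "selected": self.selected.tolist(), "weights": self.weights.tolist(),
            "intercept": self.intercept, "C": self.C, "selector": self.selector,
        })

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"], mu=np.array(d["mu"]),
            sd=np.array(d["sd"]), selected=np.array(d["selected"], dtype=int),
            weights=np.array(d["weights"]), intercept=float(d["intercept"]),
            C=float(d["C"]), selector=d["selector"],
        )


def fit_final(
    fm: FeatureMatrix,
    selector: str = "f_score",
    inner_k: int = 5,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    seed: int = 0,
) -> FittedModel:
    """Fit one final pipeline on all discovery data with inner-CV-chosen settings."""
    X = fm.X.to_numpy(dtype=float)
    y = fm.y
    C, k = _inner_cv_choose(X, y, selector, c_grid, k_grid, inner_k, rng_seed=seed)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    cols = _select(selector, Z, y, k, C)
    clf = SVC(kernel="linear", C=C)
    clf.fit(Z[:, cols], y)
    return FittedModel(
        feature_names=list(fm.X.columns), mu=mu, sd=sd, selected=cols,
        weights=clf.coef_.ravel(), intercept=float(clf.intercept_[0]),
        C=C, selector=selector,
    )


def fit_final_and_predict(
    fm_train: FeatureMatrix,
    X_external: pd.DataFrame,
    y_external: np.ndarray | None = None,
    **fit_kwargs,
) -> tuple[FittedModel, np.ndarray, float | None]:
    """Fit on all discovery data, predict an external cohort.

    Returns the fitted model, external predictions, and — when external
    labels are supplied — the external accuracy.
    """
    model = fit_final(fm_train, **fit_kwargs)
    pred, _ = model.predict(X_external)
    acc = float((pred == np.asarray(y_external)).mean()) if y_external is not None else None
    return model, pred, acc
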