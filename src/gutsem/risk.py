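"""Imbalanced-class logistic risk estimation on latent factor scores.

The depression cohorts this pipeline targets are heavily imbalanced
(roughly 1 case per 7-11 controls), so the logistic layer is trained on
SMOTE-balanced data inside stratified cross-validation folds — synthetic
minority samples are interpolated only within each training partition, never
into held-out data — and summarised by the pooled held-out ROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .sem import MeasurementModel


def smote(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    ratio: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling.

    New minority points are drawn as x_i + u (x_nn - x_i) with u ~ U(0, 1)
    and x_nn one of the k nearest minority neighbours of x_i (Euclidean
    distance on internally standardized features; the interpolation itself
    happens in the original feature space). The minority class is grown to
    ``ratio`` times the majority count; majority rows are untouched and the
    original rows are returned first, verbatim.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels).astype(int)
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE needs exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class needs at least two samples")
    n_new = int(round(ratio * n_maj)) - n_min
    if n_new <= 0:
        return x.copy(), y.copy()
    if k > n_min - 1:
        warnings.warn(
            f"k={k} exceeds minority size - 1; reduced to {n_min - 1}",
            RuntimeWarning,
            stacklevel=2,
        )
        k = n_min - 1
    x_min = x[y == minority]
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min / sd)
    neigh = nn.kneighbors(x_min / sd, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    base = rng.integers(n_min, size=n_new)
    pick = neigh[base, rng.integers(k, size=n_new)]
    u = rng.uniform(size=(n_new, 1))
    synth = x_min[base] + u * (x_min[pick] - x_min[base])
    x_out = np.vstack([x, synth])
    y_out = np.concatenate([y, np.full(n_new, minority)])
    return x_out, y_out


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))


def fit_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    l2: float = 1e-6,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """Ridge-stabilised logistic regression by iteratively reweighted LS.

    Returns the coefficient vector (intercept first). The tiny default L2
    penalty (not applied to the intercept) keeps coefficients finite on
    separable data while leaving well-posed fits essentially unpenalised.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to fit")
    design = np.column_stack([np.ones(len(y)), x])
    pen = l2 * np.eye(design.shape[1])
    pen[0, 0] = 0.0
    beta = np.zeros(design.shape[1])
    for _ in range(maxiter):
        mu = _sigmoid(design @ beta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        hess = design.T @ (design * w[:, None]) + pen
        grad = design.T @ (y - mu) - pen @ beta
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta
    raise RuntimeError(f"IRLS did not converge in {maxiter} iterations")


@dataclass
class RocResult:
    """ROC curve points and trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve over sorted unique thresholds and its trapezoid AUC.

    The trapezoid AUC equals the Mann-Whitney concordance probability
    #(case > control) + 0.5 #(ties) over all case/control pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


@dataclass
class RiskResults:
    """Deployable logistic risk model with its cross-validation summary."""

    feature_names: list[str]
    intercept: float
    coef: np.ndarray
    folds: int
    seed: int
    smote_k: int
    smote_ratio: float
    cv_predictions: np.ndarray
    cv_auc_pooled: float
    fold_aucs: list[float]
    auc_resubstitution: float
    roc: RocResult = field(repr=False)

    def predict(self, features: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Probability of the positive class for each row of ``features``."""
        if isinstance(features, pd.DataFrame):
            features = features[self.feature_names].to_numpy(dtype=float)
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x.reshape(-1, len(self.coef))
        return _sigmoid(self.intercept + x @ self.coef)

    def summary(self) -> str:
        terms = ", ".join(
            f"{n}: {c:+.3f}" for n, c in zip(self.feature_names, self.coef)
        )
        return (
            "Logistic depression-risk model (SMOTE-balanced, "
            f"{self.folds}-fold stratified CV)\n"
            f"  intercept = {self.intercept:+.3f}; {terms}\n"
            f"  pooled held-out AUC = {self.cv_auc_pooled:.3f} "
            f"(per-fold mean {np.mean(self.fold_aucs):.3f}); "
            f"resubstitution AUC = {self.auc_resubstitution:.3f}"
        )

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "folds": self.folds,
            "seed": self.seed,
            "smote_k": self.smote_k,
            "smote_ratio": self.smote_ratio,
            "cv_auc_pooled": self.cv_auc_pooled,
            "fold_aucs": list(self.fold_aucs),
            "auc_resubstitution": self.auc_resubstitution,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskResults":
        return cls(
            feature_names=list(d["feature_names"]),
            intercept=float(d["intercept"]),
            coef=np.asarray(d["coef"], dtype=float),
            folds=int(d["folds"]),
            seed=int(d["seed"]),
            smote_k=int(d["smote_k"]),
            smote_ratio=float(d["smote_ratio"]),
            cv_predictions=np.asarray(d.get("cv_predictions", []), dtype=float),
            cv_auc_pooled=float(d["cv_auc_pooled"]),
            fold_aucs=[float(a) for a in d["fold_aucs"]],
            auc_resubstitution=float(d["auc_resubstitution"]),
            roc=RocResult(np.array([]), np.array([]), np.array([]), float(d["cv_auc_pooled"])),
        )


class LogisticRiskModel:
    """Cross-validated logistic risk model on latent scores, statsmodels-style.

    Parameters
    ----------
    features : DataFrame or ndarray
        Explanatory variables — latent factor scores and/or standardized CLR
        of direct-observed taxa.
    labels : array-like of {0, 1}
        Case (1) / control (0) indicator.
    """

    def __init__(self, features, labels, feature_names: list[str] | None = None):
        if isinstance(features, pd.DataFrame):
            feature_names = feature_names or [str(c) for c in features.columns]
            features = features.to_numpy(dtype=float)
        features = np.asarray(features, dtype=float)
        if features.ndim == 1:
            features = features[:, None]
        self.exog = features
        self.endog = np.asarray(labels).astype(int)
        self.feature_names = feature_names or [
            f"x{i + 1}" for i in range(self.exog.shape[1])
        ]

    def fit(
        self,
        folds: int = 10,
        seed: int = 0,
        smote_k: int = 5,
        smote_ratio: float = 1.0,
        l2: float = 1e-6,
    ) -> RiskResults:
        """Stratified CV with in-fold SMOTE, then a full-data refit.

        Held-out probabilities are pooled across folds into the headline ROC;
        the deployable coefficients come from refitting on all data after
        SMOTE balancing.
        """
        x, y = self.exog, self.endog
        counts = np.bincount(y, minlength=2)
        if counts.min() < folds:
            raise ValueError(
                f"smallest class has {counts.min()} samples, fewer than "
                f"{folds} folds; reduce the number of folds"
            )
        ss = np.random.SeedSequence(seed)
        fold_seeds = ss.spawn(folds + 1)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        preds = np.empty(len(y))
        fold_aucs: list[float] = []
        for (train, test), child in zip(skf.split(x, y), fold_seeds[:folds]):
            xb, yb = smote(x[train], y[train], k=smote_k, ratio=smote_ratio, seed=child)
            beta = fit_logistic(xb, yb, l2=l2)
            preds[test] = _sigmoid(beta[0] + x[test] @ beta[1:])
            if len(np.unique(y[test])) == 2:
                fold_aucs.append(roc_auc(preds[test], y[test]).auc)
        pooled = roc_auc(preds, y)
        xb, yb = smote(x, y, k=smote_k, ratio=smote_ratio, seed=fold_seeds[folds])
        beta = fit_logistic(xb, yb, l2=l2)
        resub = roc_auc(_sigmoid(beta[0] + x @ beta[1:]), y).auc
        return RiskResults(
            feature_names=self.feature_names,
            intercept=float(beta[0]),
            coef=beta[1:],
            folds=folds,
            seed=seed,
            smote_k=smote_k,
            smote_ratio=smote_ratio,
            cv_predictions=preds,
            cv_auc_pooled=pooled.auc,
            fold_aucs=fold_aucs,
            auc_resubstitution=resub,
            roc=pooled,
        )


def cv_risk_model(
    features,
    labels,
    folds: int = 10,
    seed: int = 0,
    smote_k: int = 5,
    smote_ratio: float = 1.0,
) -> tuple[RiskResults, np.ndarray]:
    """Functional wrapper around :class:`LogisticRiskModel`."""
    res = LogisticRiskModel(features, labels).fit(
        folds=folds, seed=seed, smote_k=smote_k, smote_ratio=smote_ratio
    )
    return res, res.cv_predictions


def estimate_risk(
    risk: RiskResults, measurement: MeasurementModel, clr: pd.DataFrame
) -> pd.Series:
    """Score new samples: standardize -> factor scores -> logistic probability.

    Only the taxon columns named by the measurement model are consulted; any
    outcome column present is ignored, so scoring is depression-blinded.
    """
    scores = measurement.factor_scores(clr)
    missing = [f for f in risk.feature_names if f not in scores.columns]
    if missing:
        raise ValueError(f"measurement model does not produce features: {missing}")
    probs = risk.predict(scores[risk.feature_names])
    return pd.Series(probs, index=clr.index, name="depression_risk")
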