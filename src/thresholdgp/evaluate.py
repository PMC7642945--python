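"""Prediction and cross-validated accuracy for the fitted threshold model.

Predictions are modal categories under the fitted cumulative-probit
probabilities.  Accuracy is the proportion of cases correctly classified
(PCCC), evaluated by k-fold cross-validation at the record level with a
bootstrap standard error per fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

from .ecm import FitResult, OrdinalDataset, ThresholdState, fit_mapt
from .priors import PriorSpec

__all__ = [
    "CVResult",
    "category_probabilities",
    "predict_classes",
    "pccc",
    "bootstrap_se",
    "kfold_cv",
]


@dataclass
class CVResult:
    per_fold_pccc: list[float]
    per_fold_se: list[float]
    seed: int
    k: int

    @property
    def mean_pccc(self) -> float:
        return float(np.mean(self.per_fold_pccc))

    @property
    def mean_se(self) -> float:
        return float(np.mean(self.per_fold_se))

    def to_dict(self) -> dict:
        return {
            "per_fold_pccc": list(self.per_fold_pccc),
            "per_fold_se": list(self.per_fold_se),
            "mean_pccc": self.mean_pccc,
            "mean_se": self.mean_se,
            "seed": self.seed,
            "k": self.k,
        }


def category_probabilities(eta, thr: ThresholdState) -> np.ndarray:
    """P(y = c | eta) = Phi(gamma_c + eta) - Phi(gamma_{c-1} + eta), per record.

    Returns an (n, C) array (or (C,) for scalar eta); rows are non-negative
    and sum to one by the telescoping of the normal CDF.
    """
    gamma = thr.gamma
    if np.any(np.diff(gamma) <= 0):
        raise ValueError("cut-points must be strictly increasing")
    eta_arr = np.atleast_1d(np.asarray(eta, dtype=float))
    edges = np.concatenate(([-np.inf], gamma, [np.inf]))
    cdf = stats.norm.cdf(edges[None, :] + eta_arr[:, None])
    cdf[:, 0] = 0.0
    cdf[:, -1] = 1.0
    probs = np.diff(cdf, axis=1)
    probs = np.clip(probs, 0.0, None)
    if np.isscalar(eta) or np.asarray(eta).ndim == 0:
        return probs[0]
    return probs


def predict_classes(etas, thr: ThresholdState) -> np.ndarray:
    """Modal category per record; ties go to the lowest category index."""
    probs = np.atleast_2d(category_probabilities(etas, thr))
    return np.argmax(probs, axis=1) + 1  # argmax takes the first maximum


def pccc(observed, predicted) -> float:
    """Proportion of cases correctly classified."""
    observed = np.asarray(observed)
    predicted = np.asarray(predicted)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if observed.size == 0:
        raise ValueError("empty input")
    return float(np.mean(observed == predicted))


def bootstrap_se(observed, predicted, B: int = 500,
                 seed: int | None = None) -> float:
    """Bootstrap standard error of the PCCC.

    Resamples (observed, predicted) pairs with replacement B times and
    returns the standard deviation of the resampled PCCC values.
    """
    observed = np.asarray(observed)
    predicted = np.asarray(predicted)
    n = observed.size
    if n == 0:
        raise ValueError("empty input")
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    hits = (observed == predicted).astype(float)
    idx = rng.integers(0, n, size=(B, n))
    reps = hits[idx].mean(axis=1)
    return float(np.std(reps, ddof=1))


def kfold_cv(data: OrdinalDataset, prior: PriorSpec, k: int = 5,
             seed: int = 0, bootstrap_B: int = 500,
             tol: float = 1e-8, max_iter: int = 1000) -> CVResult:
    """Record-level k-fold cross-validation of classification accuracy.

    Records are partitioned at random into k folds of near-equal size; for
    each fold the model is fitted on the remaining records and the held-out
    fold is classified.  A line may therefore be in training for some of its
    environments and in testing for others, mimicking sparse multi-environment
    trials.  Single replication.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_pccc: list[float] = []
    fold_se: list[float] = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(data.X), start=1):
        y_train = data.y[train_idx]
        present = np.bincount(y_train, minlength=data.C + 1)[1:]
        if np.any(present == 0):
            miss = [c + 1 for c in range(data.C) if present[c] == 0]
            raise ValueError(
                f"training split of fold {fold} lacks categories {miss}")
        train = OrdinalDataset(y=y_train, X=data.X[train_idx], C=data.C,
                               penalized=data.penalized)
        fit = fit_mapt(train, prior, tol=tol, max_iter=max_iter)
        eta_test = data.X[test_idx] @ fit.coefficients.beta
        pred = predict_classes(eta_test, fit.thresholds)
        obs = data.y[test_idx]
        fold_pccc.append(pccc(obs, pred))
        fold_se.append(bootstrap_se(obs, pred, B=bootstrap_B,
                                    seed=seed * 1000 + fold))
    return CVResult(per_fold_pccc=fold_pccc, per_fold_se=fold_se,
                    seed=seed, k=k)
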