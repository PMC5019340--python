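"""Customized training: per-test-sample local lasso models.

For a single test sample, its pixels are clustered jointly with the
training pixels (k-means on the standardized union).  Each cluster that
contains test pixels gets its own lasso, fitted to the training pixels
assigned to that cluster (with its own patient-grouped CV for the penalty),
and the cluster's test pixels are predicted by that local model.  Clusters
whose local training set lacks ``min_train_per_class`` pixels of any tissue
class fall back to the global model, which prevents degenerate one-class
fits.  With one cluster the procedure reduces exactly to the global model.

The payoff is on mixed-histology samples under batch effects: a local model
inherits the class balance and spectral neighborhood of its cluster, so a
stroma-dominated test sample is judged against stroma-dominated training
data instead of the glands-dominated global pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .model import LassoFit, MultinomialLassoClassifier, PixelPrediction, _as_values


@dataclass
class CustomizedConfig:
    """Settings for the customized-training procedure.

    n_clusters: number of joint k-means clusters (G).
    min_train_per_class: minimum local training pixels of every class for a
        cluster to get its own model; below it the global model is used.
    seed: k-means seed (k-means++ initialization, ``n_init`` restarts, best
        inertia kept -- deterministic given the seed).
    n_lambdas / lambda_min_ratio / max_cv_pixels_per_group / tol: penalty-path
        and CV settings for the local fits (same meaning as in the global
        classifier).
    """

    n_clusters: int = 3
    min_train_per_class: int = 30
    seed: int = 0
    n_init: int = 10
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4
    max_cv_pixels_per_group: int | None = None
    tol: float = 1e-5
    refit_tol: float = 1e-5
    cv_max_iter: int = 400

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


def cluster_joint(
    train_features, test_features, n_clusters: int, seed: int, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """K-means on the standardized union of training and test pixels.

    Returns cluster assignments for the training and test sets.  The union
    is standardized feature-wise before clustering so high-abundance
    channels do not dominate the distances.
    """
    Xtr, _, _ = _as_values(train_features)
    Xte, _, _ = _as_values(test_features)
    if Xtr.shape[1] != Xte.shape[1]:
        raise ValueError("training and test pixels must share the feature space")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > Xte.shape[0]:
        raise ValueError("more clusters than test pixels")
    if n_clusters == 1:
        return np.zeros(len(Xtr), dtype=int), np.zeros(len(Xte), dtype=int)
    union = np.vstack([Xtr, Xte]).astype(np.float32)
    mean = union.mean(axis=0)
    scale = union.std(axis=0)
    scale[scale == 0] = 1.0
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    assign = km.fit_predict((union - mean) / scale)
    return assign[: len(Xtr)], assign[len(Xtr):]


@dataclass
class CustomizedResult:
    """Merged prediction plus the per-cluster models behind it.

    Every test pixel is predicted exactly once, by the model of its
    cluster.  ``cluster_models`` maps cluster id -> its LassoFit (the
    global fit where the fallback applied; see ``used_global``).
    """

    prediction: PixelPrediction
    test_assignments: np.ndarray
    train_assignments: np.ndarray
    cluster_models: dict[int, LassoFit]
    used_global: dict[int, bool]
    global_fit: LassoFit

    def weight_tables(self) -> dict[int, pd.DataFrame]:
        """Per-cluster signed feature-weight tables."""
        return {cid: fit.weight_table() for cid, fit in self.cluster_models.items()}


class CustomizedTraining:
    """Customized-training model over a fixed training cohort.

    Parameters mirror :class:`MultinomialLassoClassifier`; ``global_fit``
    may be supplied to reuse an already cross-validated global model,
    otherwise one is fitted by patient-grouped CV on construction.
    """

    def __init__(self, train_features, train_labels, train_groups,
                 config: CustomizedConfig | None = None,
                 global_fit: LassoFit | None = None):
        self.config = config or CustomizedConfig()
        self.train_features = train_features
        Xtr, _, _ = _as_values(train_features)
        self.Xtr = Xtr
        self.labels = np.asarray(train_labels, dtype=object)
        self.groups = np.asarray(train_groups, dtype=object)
        from .io import CLASSES

        if set(np.unique(self.labels)) != set(CLASSES):
            raise ValueError("training must cover all three tissue classes")
        self.global_model = MultinomialLassoClassifier(
            train_features, train_labels, groups=train_groups
        )
        if global_fit is None:
            cv = self.global_model.fit_cv(
                n_lambdas=self.config.n_lambdas,
                lambda_min_ratio=self.config.lambda_min_ratio,
                max_pixels_per_group=self.config.max_cv_pixels_per_group,
                tol=self.config.tol,
                max_iter=self.config.cv_max_iter,
            )
            global_fit = cv.fit_
        self.global_fit = global_fit

    def fit_predict(self, test_features) -> CustomizedResult:
        """Cluster one test sample with the training pool and predict it."""
        cfg = self.config
        Xte, _, te_pixels = _as_values(test_features)
        if cfg.n_clusters == 1:
            pred = self.global_fit.predict(test_features)
            n_tr, n_te = len(self.Xtr), len(Xte)
            return CustomizedResult(
                prediction=pred,
                test_assignments=np.zeros(n_te, dtype=int),
                train_assignments=np.zeros(n_tr, dtype=int),
                cluster_models={0: self.global_fit},
                used_global={0: True},
                global_fit=self.global_fit,
            )
        tr_assign, te_assign = cluster_joint(
            self.Xtr, Xte, cfg.n_clusters, cfg.seed, cfg.n_init
        )
        if not np.isin(tr_assign, np.unique(te_assign)).any():
            warnings.warn("no training pixels share a cluster with the test sample; "
                          "using the global model throughout")
        classes = self.global_model.classes
        proba = np.empty((len(Xte), len(classes)))
        cluster_models: dict[int, LassoFit] = {}
        used_global: dict[int, bool] = {}
        for cid in np.unique(te_assign):
            te_sel = te_assign == cid
            tr_sel = tr_assign == cid
            y_loc = self.labels[tr_sel]
            counts = {c: int((y_loc == c).sum()) for c in classes}
            if min(counts.values(), default=0) < cfg.min_train_per_class:
                fit = self.global_fit
                used_global[cid] = True
            else:
                fit = self._fit_local(tr_sel)
                used_global[cid] = False
            cluster_models[int(cid)] = fit
            proba[te_sel] = fit.predict(Xte[te_sel]).probabilities
        return CustomizedResult(
            prediction=PixelPrediction(proba, classes, te_pixels),
            test_assignments=te_assign,
            train_assignments=tr_assign,
            cluster_models=cluster_models,
            used_global=used_global,
            global_fit=self.global_fit,
        )

    def _fit_local(self, tr_sel: np.ndarray) -> LassoFit:
        cfg = self.config
        local = MultinomialLassoClassifier(
            self.Xtr[tr_sel], self.labels[tr_sel],
            groups=self.groups[tr_sel],
            classes=self.global_model.classes,
        )
        n_patients = len(pd.unique(self.groups[tr_sel]))
        if n_patients >= 2:
            cv = local.fit_cv(
                n_lambdas=cfg.n_lambdas,
                lambda_min_ratio=cfg.lambda_min_ratio,
                max_pixels_per_group=cfg.max_cv_pixels_per_group,
                tol=cfg.tol,
                refit_tol=cfg.refit_tol,
                max_iter=cfg.cv_max_iter,
            )
            return cv.fit_
        # single-patient cluster: no grouped CV possible; reuse the global
        # penalty on the local data
        return local.fit(min(self.global_fit.lam, local.lambda_max), tol=cfg.tol)
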