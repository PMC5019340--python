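"""L1-penalized multinomial logistic classification of MSI pixels.

The central object is :class:`MultinomialLassoClassifier`, a model built
from a feature matrix and per-pixel class labels (optionally with patient
identifiers for grouped cross-validation).  Fitting returns results objects:

* ``fit(lam)``       -> :class:`LassoFit` -- weights, intercepts, prediction,
  the signed feature-weight table, and a ``summary()``.
* ``fit_path()``     -> :class:`LassoPath` -- warm-started fits on a
  log-spaced penalty grid from ``lambda_max`` downward.
* ``fit_cv()``       -> :class:`CVResult` -- leave-one-patient-out
  cross-validation over the path, the chosen penalty (fewest misclassified
  held-out pixels, ties to the larger penalty), and the model refit on all
  training pixels at that penalty.

Features are standardized (zero mean, unit variance) inside the solver and
weights are reported on the standardized scale, making them dimensionless
and comparable across m/z; the standardization is stored on the results so
it can be inverted.  Sign semantics: an ion whose abundance characterizes a
class gets a positive weight for that class; an ion whose low abundance or
absence is informative gets a negative weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _solver
from .io import CLASSES
from .preprocess import FeatureMatrix


@dataclass
class PixelPrediction:
    """Per-pixel class probabilities and argmax labels.

    Probabilities are softmax outputs (non-negative, summing to 1 per
    pixel); the predicted class is the highest-probability one, ties broken
    by class order (cancer < glands < stroma).
    """

    probabilities: np.ndarray
    classes: tuple
    pixels: pd.DataFrame | None = None

    @property
    def labels(self) -> np.ndarray:
        idx = self.probabilities.argmax(axis=1)  # argmax takes first max: class order
        return np.asarray(self.classes, dtype=object)[idx]

    @property
    def n_pixels(self) -> int:
        return self.probabilities.shape[0]

    def class_fraction(self, cls: str) -> float:
        return float((self.labels == cls).mean())


def _as_values(features) -> tuple[np.ndarray, np.ndarray | None, pd.DataFrame | None]:
    if isinstance(features, FeatureMatrix):
        return features.values, features.mz, features.pixels
    X = np.asarray(features, dtype=float)
    return X, None, None


class MultinomialLassoClassifier:
    """Multiclass logistic regression with an L1 penalty on pixel features.

    Parameters
    ----------
    features : FeatureMatrix or array (n_pixels, n_features)
        Binned intensities.
    labels : array of class names, length n_pixels
        At least two distinct classes must be present.
    groups : array of patient ids, optional
        Required for ``fit_cv`` (each patient forms one CV fold).
    classes : ordered class tuple
        Defaults to the classes present in ``labels`` in the canonical
        tissue order, falling back to sorted order for other label sets.
    """

    def __init__(self, features, labels, groups=None, classes=None):
        X, mz, pixels = _as_values(features)
        if not np.isfinite(X).all():
            raise ValueError("features must be finite")
        labels = np.asarray(labels, dtype=object)
        if len(labels) != X.shape[0]:
            raise ValueError("one label per pixel required")
        present = set(labels)
        if len(present) < 2:
            raise ValueError("degenerate fit: fewer than two classes present")
        if classes is None:
            canon = [c for c in CLASSES if c in present]
            extra = sorted(present - set(CLASSES))
            classes = tuple(canon + extra)
        elif not present <= set(classes):
            raise ValueError("labels outside the declared class set")
        self.X = X
        self.labels = labels
        self.classes = tuple(classes)
        self.groups = None if groups is None else np.asarray(groups, dtype=object)
        if self.groups is not None and len(self.groups) != X.shape[0]:
            raise ValueError("one group per pixel required")
        self.mz = mz
        self.pixels = pixels
        self.Y = _solver.one_hot(labels, self.classes)
        self.mean_, self.scale_ = _solver.standardization(X)

    # -- penalties ---------------------------------------------------------

    @property
    def lambda_max(self) -> float:
        """Smallest penalty at which all weights are exactly zero."""
        return _solver.lambda_max(self.X, self.Y, self.mean_, self.scale_)

    def lambda_grid(self, n_lambdas: int = 100, lambda_min_ratio: float = 1e-4):
        """Log-spaced penalty grid from ``lambda_max`` downward."""
        if n_lambdas < 2:
            raise ValueError("n_lambdas must be >= 2")
        lmax = self.lambda_max
        return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)

    # -- fitting -----------------------------------------------------------

    def fit(self, lam: float, tol: float = 1e-7, warm_start=None, **kw) -> "LassoFit":
        """Fit at one penalty value to the stated KKT tolerance."""
        W0 = b0 = None
        lam_prev = None
        if warm_start is not None:
            W0, b0 = warm_start.weights, warm_start.intercepts
            lam_prev = warm_start.lam
        W, b = _solver.fit_l1_multinomial(
            self.X, self.Y, lam, self.mean_, self.scale_,
            W0=W0, b0=b0, tol=tol, lam_prev=lam_prev, **kw
        )
        return LassoFit(model=self, lam=float(lam), weights=W, intercepts=b)

    def fit_path(
        self,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-4,
        lambdas=None,
        tol: float = 1e-7,
        max_iter: int = 20000,
    ) -> "LassoPath":
        """Warm-started fits along a descending penalty grid.

        The first grid point is ``lambda_max``, where the fit has all-zero
        weights; the active set then grows (up to solver tolerance) as the
        penalty decreases.
        """
        if lambdas is None:
            lambdas = self.lambda_grid(n_lambdas, lambda_min_ratio)
        lambdas = np.sort(np.asarray(lambdas, float))[::-1]
        fits = []
        prev = None
        for lam in lambdas:
            prev = self.fit(lam, tol=tol, warm_start=prev, max_iter=max_iter)
            fits.append(prev)
        return LassoPath(model=self, fits=fits)

    def fit_cv(
        self,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-4,
        lambdas=None,
        tol: float = 1e-5,
        max_pixels_per_group: int | None = None,
        seed: int = 0,
        refit_tol: float = 1e-7,
        max_iter: int = 2000,
        refit_max_iter: int = 5000,
    ) -> "CVResult":
        """Leave-one-patient-out cross-validation for the penalty.

        Each fold holds out exactly one patient; for each penalty on the
        grid the misclassified held-out pixels are totalled over folds and
        the penalty with the fewest total errors is chosen (ties go to the
        larger penalty).  The returned result carries the model refit on all
        pixels at the chosen penalty.

        ``max_pixels_per_group`` optionally subsamples each patient's pixels
        (seeded) for the CV search only; the final refit always uses every
        pixel.
        """
        if self.groups is None:
            raise ValueError("fit_cv requires patient groups")
        if lambdas is None:
            lambdas = self.lambda_grid(n_lambdas, lambda_min_ratio)
        lambdas = np.sort(np.asarray(lambdas, float))[::-1]

        idx_all = np.arange(len(self.labels))
        if max_pixels_per_group is not None:
            rng = np.random.default_rng(seed)
            keep = []
            for g in pd.unique(self.groups):
                gi = idx_all[self.groups == g]
                if gi.size > max_pixels_per_group:
                    gi = rng.choice(gi, size=max_pixels_per_group, replace=False)
                keep.append(gi)
            idx_all = np.sort(np.concatenate(keep))
        Xcv, ycv, gcv = self.X[idx_all], self.labels[idx_all], self.groups[idx_all]

        patients = list(pd.unique(gcv))
        usable = [p for p in patients if (gcv == p).sum() > 0]
        if len(usable) < 2:
            raise ValueError("cross-validation requires at least two patients")
        fold_errors = np.zeros((len(usable), len(lambdas)))
        fold_sizes = np.zeros(len(usable))
        for fi, pat in enumerate(usable):
            test = gcv == pat
            train = ~test
            if len(set(ycv[train])) < 2:
                warnings.warn(f"fold {pat}: fewer than two classes in training; skipped")
                continue
            sub = MultinomialLassoClassifier(
                Xcv[train], ycv[train], classes=self.classes
            )
            path = sub.fit_path(lambdas=lambdas, tol=tol, max_iter=max_iter)
            fold_sizes[fi] = test.sum()
            for li, f in enumerate(path.fits):
                pred = f.predict(Xcv[test]).labels
                fold_errors[fi, li] = (pred != ycv[test]).sum()
        total = fold_errors.sum(axis=0)
        best = int(np.flatnonzero(total == total.min())[0])  # grid descends: first = larger lam
        chosen = float(lambdas[best])
        refit = self.fit(chosen, tol=refit_tol, max_iter=refit_max_iter)
        return CVResult(
            model=self,
            lambdas=np.asarray(lambdas),
            fold_errors=fold_errors,
            fold_patients=list(usable),
            fold_sizes=fold_sizes,
            chosen_lambda=chosen,
            fit_=refit,
        )


@dataclass
class LassoFit:
    """Results of one penalized fit.

    ``weights`` (features x classes, standardized scale) is sparse in
    content; ``intercepts`` are centered to sum to zero.  The feature-weight
    table lists only features with at least one nonzero class weight.
    """

    model: MultinomialLassoClassifier
    lam: float
    weights: np.ndarray
    intercepts: np.ndarray

    # -- prediction --------------------------------------------------------

    def predict(self, features) -> PixelPrediction:
        """Softmax class probabilities and argmax labels for new pixels."""
        X, _, pixels = _as_values(features)
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"feature count {X.shape[1]} does not match model "
                f"({self.weights.shape[0]})"
            )
        from scipy.special import softmax

        Z = _solver._scores(X, self.weights, self.intercepts,
                            self.model.mean_, self.model.scale_)
        return PixelPrediction(softmax(Z, axis=1), self.model.classes, pixels)

    # -- diagnostics -------------------------------------------------------

    @property
    def nonzero_count(self) -> int:
        """Number of features with any nonzero class weight."""
        return int((np.abs(self.weights).sum(axis=1) > 0).sum())

    def objective_value(self) -> float:
        m = self.model
        return _solver.objective(
            m.X, m.Y, self.weights, self.intercepts, self.lam, m.mean_, m.scale_
        )

    def kkt_violation(self) -> float:
        m = self.model
        GW, _, _ = _solver._grad(m.X, m.Y, self.weights, self.intercepts,
                                 m.mean_, m.scale_)
        return _solver.kkt_violation(GW, self.weights, self.lam)

    def weight_table(self) -> pd.DataFrame:
        """Signed weights of the selected features, sorted by m/z.

        Rows appear only for features with at least one nonzero class
        weight; features are labeled by bin-center m/z (one decimal) when
        the model was built from a FeatureMatrix, else by feature index.
        """
        nz = np.abs(self.weights).sum(axis=1) > 0
        idx = np.nonzero(nz)[0]
        if self.model.mz is not None:
            label = np.round(self.model.mz[idx], 1)
        else:
            label = idx
        cols = {"mz": label}
        for k, cls in enumerate(self.model.classes):
            cols[cls] = self.weights[idx, k]
        return pd.DataFrame(cols)

    def summary(self) -> str:
        m = self.model
        counts = pd.Series(m.labels).value_counts()
        lines = [
            "L1-penalized multinomial logistic fit",
            "=" * 48,
            f"pixels:           {len(m.labels)}",
            f"features:         {m.X.shape[1]}",
            f"classes:          {', '.join(m.classes)}"
            f"  (n = {', '.join(str(counts.get(c, 0)) for c in m.classes)})",
            f"lambda:           {self.lam:.6g}",
            f"selected features: {self.nonzero_count}",
            f"objective:        {self.objective_value():.6g}",
            f"max KKT violation: {self.kkt_violation():.2e}",
            "",
            "intercepts: "
            + ", ".join(f"{c}={v:+.4f}" for c, v in zip(m.classes, self.intercepts)),
        ]
        tbl = self.weight_table()
        if len(tbl):
            lines += ["", "feature weights (standardized scale):",
                      tbl.to_string(index=False, float_format=lambda v: f"{v:+.3f}" if v else "")]
        return "\n".join(lines)


@dataclass
class LassoPath:
    """Warm-started fits along a descending penalty grid."""

    model: MultinomialLassoClassifier
    fits: list[LassoFit]

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([f.lam for f in self.fits])

    def nonzero_counts(self) -> np.ndarray:
        return np.array([f.nonzero_count for f in self.fits])


@dataclass
class CVResult:
    """Leave-one-patient-out cross-validation summary.

    ``fold_errors[f, l]`` counts misclassified held-out pixels for fold
    ``f`` at penalty ``l``; ``fit_`` is the final model refit on all
    training pixels at ``chosen_lambda``.
    """

    model: MultinomialLassoClassifier
    lambdas: np.ndarray
    fold_errors: np.ndarray
    fold_patients: list
    fold_sizes: np.ndarray
    chosen_lambda: float
    fit_: LassoFit

    @property
    def n_folds(self) -> int:
        return len(self.fold_patients)

    @property
    def total_errors(self) -> np.ndarray:
        return self.fold_errors.sum(axis=0)

    def error_rate(self) -> np.ndarray:
        """Total CV misclassification rate per penalty (pixel-weighted)."""
        return self.total_errors / self.fold_sizes.sum()

    def per_patient_error_rate(self) -> np.ndarray:
        """Mean over folds of each patient's error rate (patient-weighted)."""
        with np.errstate(invalid="ignore"):
            rates = self.fold_errors / self.fold_sizes[:, None]
        return np.nanmean(rates, axis=0)

    def se_error_rate(self) -> np.ndarray:
        """Standard error over folds of the per-fold error rates."""
        with np.errstate(invalid="ignore"):
            rates = self.fold_errors / self.fold_sizes[:, None]
        return np.nanstd(rates, axis=0, ddof=1) / np.sqrt(self.n_folds)

    def summary(self) -> str:
        er = self.error_rate()
        best = int(np.argmin(np.abs(self.lambdas - self.chosen_lambda)))
        lines = [
            "Leave-one-patient-out cross-validation",
            "=" * 48,
            f"folds (patients):  {self.n_folds}",
            f"pixels in CV:      {int(self.fold_sizes.sum())}",
            f"penalty grid:      {len(self.lambdas)} values "
            f"[{self.lambdas.min():.3g}, {self.lambdas.max():.3g}]",
            f"chosen lambda:     {self.chosen_lambda:.6g}",
            f"CV error at choice: {er[best]:.4f} "
            f"(+/- {self.se_error_rate()[best]:.4f} over folds)",
            f"selected features: {self.fit_.nonzero_count}",
        ]
        return "\n".join(lines)
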