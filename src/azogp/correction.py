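"""Data-driven correction of physics-based wavelength predictions.

TD-DFT transition wavelengths carry systematic errors (e.g. a roughly
constant red/blue shift for a given functional). A sparse linear model of
the residual r = experimental - computed, fit on fragprint features with an
L1 penalty (Lasso, default multiplier 0.1), is added back to the computed
values. Evaluation is leave-one-out: each fold fits the residual model on
the remaining pairs and corrects the held-out prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso

from .evaluation import EvalReport, metric_suite


@dataclass
class ResidualModel:
    coefficients: np.ndarray
    intercept: float
    l1_multiplier: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    n_fp_bits: int | None = None

    @property
    def n_features(self) -> int:
        return len(self.coefficients)

    def predict_residual(self, features) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.n_features:
            raise ValueError(
                f"feature-config mismatch: model expects {self.n_features} "
                f"features, got {features.shape[1]}"
            )
        Z = (features - self.feature_mean) / self.feature_scale
        return Z @ self.coefficients + self.intercept


def _standardisation(features: np.ndarray, n_fp_bits: int | None):
    """Column mean/scale for the penalised fit. The count block (columns
    from ``n_fp_bits`` on) is z-scored because L1 shrinkage is
    scale-sensitive; binary fingerprint bits are left as-is. With
    ``n_fp_bits=None`` every column is standardised. Zero-variance columns
    keep unit scale."""
    mean = np.zeros(features.shape[1])
    scale = np.ones(features.shape[1])
    start = 0 if n_fp_bits is None else int(n_fp_bits)
    block = features[:, start:]
    m = block.mean(axis=0)
    s = block.std(axis=0)
    s[s == 0.0] = 1.0
    mean[start:] = m
    scale[start:] = s
    return mean, scale


def fit_residual_model(features, computed_nm, experimental_nm,
                       l1_multiplier: float = 0.1,
                       n_fp_bits: int | None = None) -> ResidualModel:
    """Lasso fit of the residual (experimental - computed) on features."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    computed = np.asarray(computed_nm, dtype=float).ravel()
    experimental = np.asarray(experimental_nm, dtype=float).ravel()
    if not (features.shape[0] == len(computed) == len(experimental)):
        raise ValueError("features, computed and experimental must align")
    if len(computed) < 2:
        raise ValueError("need at least 2 paired observations")
    if l1_multiplier <= 0:
        raise ValueError("l1_multiplier must be > 0")
    residual = experimental - computed
    mean, scale = _standardisation(features, n_fp_bits)
    Z = (features - mean) / scale
    if np.ptp(residual) == 0.0:
        # constant target: closed form — all coefficients shrink to zero
        coef = np.zeros(features.shape[1])
        intercept = float(residual[0])
    else:
        lasso = Lasso(alpha=l1_multiplier, fit_intercept=True,
                      max_iter=10_000, tol=1e-6)
        lasso.fit(Z, residual)
        coef = np.asarray(lasso.coef_, dtype=float)
        intercept = float(lasso.intercept_)
    return ResidualModel(coefficients=coef, intercept=intercept,
                         l1_multiplier=l1_multiplier, feature_mean=mean,
                         feature_scale=scale, n_fp_bits=n_fp_bits)


def apply_correction(model: ResidualModel, features, computed_nm
                     ) -> np.ndarray:
    """corrected = computed + predicted residual."""
    computed = np.asarray(computed_nm, dtype=float).ravel()
    return computed + model.predict_residual(features)


def loo_corrected_eval(features, computed_nm, experimental_nm,
                       l1_multiplier: float = 0.1,
                       n_fp_bits: int | None = None
                       ) -> tuple[EvalReport, EvalReport]:
    """Leave-one-out evaluation of the correction.

    Returns (uncorrected, corrected) reports; per fold the residual model
    is fit on the n-1 remaining pairs and applied to the held-out pair.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    computed = np.asarray(computed_nm, dtype=float).ravel()
    experimental = np.asarray(experimental_nm, dtype=float).ravel()
    n = len(computed)
    if n < 3:
        raise ValueError("need at least 3 pairs for LOO")
    corrected = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_residual_model(features[keep], computed[keep],
                                   experimental[keep],
                                   l1_multiplier=l1_multiplier,
                                   n_fp_bits=n_fp_bits)
        corrected[i] = apply_correction(model, features[i:i + 1],
                                        computed[i:i + 1])[0]
    uncorrected_report = metric_suite(computed.tolist(),
                                      experimental.tolist())
    corrected_report = metric_suite(corrected.tolist(), experimental.tolist())
    return uncorrected_report, corrected_report
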