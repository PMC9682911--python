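"""Benchmarking harness: metrics, repeated random splits, leave-one-out
validation, confidence-error curves, and paired model comparison.

Model factories
---------------
The benchmark drivers are model-agnostic. A ``model_factory`` is a callable

    model_factory(X_train, y_train, seed) -> predict_fn

where ``predict_fn(X_test)`` returns predicted values (an extra variance
output, if present, is ignored by the drivers here).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class EvalReport:
    mae: float
    signed_me: float
    rmse: float
    stderr_mae: float
    n: int
    per_item_errors: list[float] = field(default_factory=list)
    n_dropped: int = 0


def metric_suite(predictions, truths) -> EvalReport:
    """MAE, mean signed error (prediction - truth), RMSE and the standard
    error of the absolute errors. Pairs with an absent truth are dropped
    and counted in ``n_dropped``."""
    predictions = list(predictions)
    truths = list(truths)
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must have equal length")
    errors = []
    dropped = 0
    for p, t in zip(predictions, truths):
        if t is None or (isinstance(t, float) and math.isnan(t)):
            dropped += 1
            continue
        errors.append(float(p) - float(t))
    if not errors:
        raise ValueError("no valid prediction/truth pairs")
    err = np.asarray(errors)
    abs_err = np.abs(err)
    return EvalReport(
        mae=float(abs_err.mean()),
        signed_me=float(err.mean()),
        rmse=float(np.sqrt((err**2).mean())),
        stderr_mae=float(abs_err.std(ddof=1) / np.sqrt(len(err)))
        if len(err) > 1 else 0.0,
        n=len(err),
        per_item_errors=err.tolist(),
        n_dropped=dropped,
    )


def split_indices(n: int, test_fraction: float, seed: int, split_id: int):
    """Counter-based split scheme: split ``split_id`` under ``seed`` is the
    same for every model, enabling paired comparisons and extensible runs."""
    rng = np.random.default_rng([seed, split_id])
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    return perm[n_test:], perm[:n_test]


def random_split_benchmark(X, y, model_factory, n_splits: int = 20,
                           test_fraction: float = 0.2, seed: int = 0
                           ) -> list[EvalReport]:
    """Repeated random train/test evaluation (default 20 splits, 80/20)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 10:
        raise ValueError("need at least 10 labelled molecules")
    reports = []
    for k in range(n_splits):
        tr, te = split_indices(len(y), test_fraction, seed, k)
        predict = model_factory(X[tr], y[tr], seed)
        preds = np.asarray(predict(X[te]), dtype=float).ravel()
        reports.append(metric_suite(preds.tolist(), y[te].tolist()))
    return reports


def loo_benchmark(X, y, model_factory, ids=None, extra=None, seed: int = 0
                  ) -> EvalReport:
    """Leave-one-out validation: test on a single molecule, train on the
    others plus an optional extra training pool.

    ``ids`` (e.g. canonical SMILES) guard against leakage: any extra-pool
    entry sharing the held-out molecule's id is removed for that fold.
    ``extra`` is a triple (X_extra, y_extra, ids_extra); ids_extra may be
    None when no guard is needed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 labelled molecules for LOO")
    if extra is not None:
        X_e, y_e, ids_e = extra
        X_e = np.atleast_2d(np.asarray(X_e, dtype=float))
        y_e = np.asarray(y_e, dtype=float).ravel()
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        X_tr, y_tr = X[keep], y[keep]
        if extra is not None:
            if ids is not None and ids_e is not None:
                held = ids[i]
                mask = np.asarray([e != held for e in ids_e])
            else:
                mask = np.ones(len(y_e), dtype=bool)
            X_tr = np.vstack([X_tr, X_e[mask]])
            y_tr = np.concatenate([y_tr, y_e[mask]])
        predict = model_factory(X_tr, y_tr, seed)
        preds[i] = float(np.asarray(predict(X[i:i + 1])).ravel()[0])
    return metric_suite(preds.tolist(), y.tolist())


@dataclass
class ConfidenceCurve:
    retained_fractions: list[float]
    mae_at_fraction: list[float]


DEFAULT_GRID = tuple(round(0.05 * k, 2) for k in range(1, 21))


def confidence_error_curve(predictions, variances, truths, grid=DEFAULT_GRID
                           ) -> ConfidenceCurve:
    """MAE over the most-confident (lowest predictive variance) fraction of
    predictions, for each retained fraction in the grid. A well-calibrated
    model yields a curve that decreases as the retained fraction shrinks."""
    predictions = np.asarray(predictions, dtype=float).ravel()
    variances = np.asarray(variances, dtype=float).ravel()
    truths = np.asarray(truths, dtype=float).ravel()
    if predictions.size == 0:
        raise ValueError("empty input")
    if not (len(predictions) == len(variances) == len(truths)):
        raise ValueError("length mismatch")
    if np.any(variances < 0):
        raise ValueError("variances must be non-negative")
    order = np.argsort(variances, kind="stable")  # ascending variance
    abs_err = np.abs(predictions - truths)[order]
    n = len(abs_err)
    fracs, maes = [], []
    for f in grid:
        k = min(n, max(1, math.ceil(f * n)))
        fracs.append(float(f))
        maes.append(float(abs_err[:k].mean()))
    return ConfidenceCurve(retained_fractions=fracs, mae_at_fraction=maes)


def wilcoxon_paired(errors_a, errors_b, zero_method: str = "wilcox"):
    """Two-sided Wilcoxon signed-rank test on paired per-split errors.

    Exact null distribution for n <= 25 (no ties/zeros), normal
    approximation with continuity correction otherwise. Zero differences
    are discarded by default (classic Wilcoxon); pass ``zero_method="pratt"``
    for the Pratt variant.
    """
    a = np.asarray(errors_a, dtype=float).ravel()
    b = np.asarray(errors_b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; degenerate test")
        return 0.0, 1.0
    nz = d[d != 0]
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not has_ties
                         and zero_method == "wilcox") else "approx"
    res = stats.wilcoxon(a, b, zero_method=zero_method, correction=True,
                         alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
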