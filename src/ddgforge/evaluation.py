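"""Benchmark statistics for stability predictors.

The standard report for a mutant benchmark: Pearson R, the slope and
intercept of the linear fit of experimental against predicted ddG, and the
root-mean-square error of the raw predictions.  Version-to-version
comparisons use a two-sided Wilcoxon signed-rank test on paired absolute
errors.  Practical accuracy is summarized two ways: the accuracy-vs-error
curve (fraction of mutants whose experimental ddG lies within prediction
+/- a tolerance) and the ROC AUC for classifying the sign of the
experimental change using the predicted ddG as score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

WILCOXON_EXACT_MAX_N = 25


@dataclass
class BenchmarkResult:
    R: float        # Pearson correlation
    S: float        # slope of the linear fit
    I: float        # intercept, kcal/mol
    RMSE: float     # kcal/mol
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.R <= 1.0 + 1e-12:
            raise ValueError("Pearson R outside [-1, 1]")
        if self.RMSE < 0 or self.n < 2:
            raise ValueError("invalid benchmark result")


def regression_stats(pred, exp, orientation: str = "exp_on_pred",
                     ) -> BenchmarkResult:
    """Linear-fit benchmark metrics.

    By default experimental ddG is regressed on predicted ddG (the reported
    slope/intercept convention); ``orientation='pred_on_exp'`` flips the
    axes.  RMSE is always the root mean squared prediction error
    rms(pred - exp), independent of the fit orientation.
    """
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1:
        raise ValueError("pred and exp must be equal-length 1-D arrays")
    if len(pred) < 2:
        raise ValueError("need at least 2 points")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(exp))):
        raise ValueError("non-finite values in input")
    x, y = (pred, exp) if orientation == "exp_on_pred" else (exp, pred)
    if np.var(x) == 0:
        raise ValueError("zero variance in regressor")
    fit = stats.linregress(x, y)
    rmse = float(np.sqrt(np.mean((pred - exp) ** 2)))
    return BenchmarkResult(R=float(fit.rvalue), S=float(fit.slope),
                           I=float(fit.intercept), RMSE=rmse, n=len(pred))


def paired_wilcoxon(err_a, err_b) -> float:
    """Two-sided signed-rank p-value on paired absolute errors.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 non-zero pairs and the continuity-corrected normal
    approximation above that.
    """
    err_a = np.asarray(err_a, dtype=float)
    err_b = np.asarray(err_b, dtype=float)
    if err_a.shape != err_b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = err_a - err_b
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    method = "exact" if len(nonzero) <= WILCOXON_EXACT_MAX_N else "approx"
    res = stats.wilcoxon(err_a, err_b, zero_method="wilcox",
                         alternative="two-sided", correction=True,
                         method=method)
    return float(res.pvalue)


def accuracy_curve(pred, exp, error_grid) -> list[tuple[float, float]]:
    """Accuracy at each error tolerance: fraction with |pred - exp| <= e."""
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if len(pred) == 0:
        raise ValueError("empty input")
    if pred.shape != exp.shape:
        raise ValueError("pred and exp must have equal length")
    residual = np.abs(pred - exp)
    return [(float(e), float(np.mean(residual <= e))) for e in error_grid]


def error_for_accuracy(pred, exp, level: float, error_grid) -> float | None:
    """Smallest grid tolerance reaching the requested accuracy level."""
    for e, acc in accuracy_curve(pred, exp, error_grid):
        if acc >= level:
            return e
    return None


def sign_auc(pred, exp) -> float:
    """ROC AUC for predicting sign(exp) (destabilizing positive) from pred."""
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    labels = (exp > 0).astype(int)
    if labels.min() == labels.max():
        raise ValueError("experimental values must contain both signs")
    return float(roc_auc_score(labels, pred))
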