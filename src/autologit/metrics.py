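"""Model evaluation: AUC (Mann-Whitney rank form) and AIC comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .exceptions import ValidationError
from .models import FitResult

__all__ = ["auc_roc", "ModelComparison", "compare_models"]


def auc_roc(scores, outcome) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney U) formulation.

    Ties are handled with midranks, which makes the statistic identical to
    trapezoidal integration of the empirical ROC curve.  Equals the
    probability that a random case outranks a random control.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(outcome, dtype=float).ravel()
    if s.shape[0] != y.shape[0]:
        raise ValidationError("scores and outcome have different lengths")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError("outcome must be binary 0/1")
    n1 = int(y.sum())
    n0 = y.shape[0] - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC undefined: outcome has a single class")
    r = rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class ModelComparison:
    """AIC/AUC comparison of two fits on the same cohort; lower AIC wins."""

    label_a: str
    label_b: str
    aic_a: float
    aic_b: float
    auc_a: float
    auc_b: float
    delta_aic: float  # aic_b - aic_a
    delta_auc: float  # auc_b - auc_a
    preferred: str | None  # label of the lower-AIC model; None on a tie
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compare_models(
    fit_a: FitResult,
    fit_b: FitResult,
    label_a: str = "logistic",
    label_b: str = "autologistic",
) -> ModelComparison:
    """Compare two converged fits of the same outcome on the same n."""
    if fit_a.n != fit_b.n:
        raise ValidationError(
            f"cannot compare models fitted on different sample sizes "
            f"({fit_a.n} vs {fit_b.n})"
        )
    if not (fit_a.converged and fit_b.converged):
        raise ValidationError("both fits must have converged for comparison")
    auc_a = auc_roc(fit_a.fitted, fit_a.y)
    auc_b = auc_roc(fit_b.fitted, fit_b.y)
    delta_aic = fit_b.aic - fit_a.aic
    if abs(delta_aic) < 1e-9:
        preferred = None
    else:
        preferred = label_b if delta_aic < 0 else label_a
    return ModelComparison(
        label_a=label_a,
        label_b=label_b,
        aic_a=fit_a.aic,
        aic_b=fit_b.aic,
        auc_a=auc_a,
        auc_b=auc_b,
        delta_aic=delta_aic,
        delta_auc=auc_b - auc_a,
        preferred=preferred,
        n=fit_a.n,
    )
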