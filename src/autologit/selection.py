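"""Two-stage variable selection: univariate screen at P < 0.25.

Each candidate is fitted alone (with intercept) against the outcome.  A
single-df term keeps its Wald p-value; a multi-level categorical term is
judged by the likelihood-ratio test of the whole term against the
intercept-only model.  Candidates with p below the threshold enter the
final multiple model, in their original order.  A candidate whose fit fails
(separation, no variation, ...) is excluded with a warning, never fatally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AutologitError, ValidationError
from .models import Covariate, DesignSpec, LogisticGLM, fit_logistic

__all__ = ["ScreenResult", "univariate_screen"]


@dataclass
class ScreenResult:
    """Selected covariates plus the per-candidate screening table."""

    selected: list[Covariate]
    table: pd.DataFrame  # candidate, p_value, test, selected, note
    threshold: float

    @property
    def selected_names(self) -> list[str]:
        return [c.name for c in self.selected]


def _as_covariate(c, cohort: pd.DataFrame) -> Covariate:
    if isinstance(c, Covariate):
        return c
    s = cohort[c]
    if pd.api.types.is_numeric_dtype(s) and s.dropna().nunique() > 2:
        return Covariate(c, "continuous")
    if s.dropna().nunique() <= 2:
        return Covariate(c, "binary")
    return Covariate(c, "categorical")


def univariate_screen(
    candidates,
    cohort: pd.DataFrame,
    outcome: str = "death",
    threshold: float = 0.25,
) -> ScreenResult:
    """Screen candidates one at a time; retain those with p < threshold."""
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    rows = []
    selected: list[Covariate] = []
    for cand in candidates:
        cov = _as_covariate(cand, cohort)
        try:
            design = DesignSpec([cov], outcome=outcome)
            X, y, _ = design.build(cohort)
            fit = LogisticGLM(outcome_name=outcome).fit(X, y)
            if not fit.converged_:
                raise AutologitError("fit did not converge")
            if X.shape[1] == 1:
                p = float(fit.result_.table["p"].iloc[1])
                test = "wald"
            else:
                # likelihood-ratio test of the whole multi-level term
                null = LogisticGLM(outcome_name=outcome).fit(
                    pd.DataFrame(index=X.index), y
                )
                lr = 2.0 * (fit.loglik_ - null.loglik_)
                p = float(stats.chi2.sf(lr, df=X.shape[1]))
                test = "lr"
            keep = p < threshold
            note = ""
        except AutologitError as err:
            warnings.warn(
                f"candidate {cov.name!r} excluded from screening: {err}",
                stacklevel=2,
            )
            p, test, keep, note = np.nan, "failed", False, str(err)
        if keep:
            selected.append(cov)
        rows.append(
            {
                "candidate": cov.name,
                "p_value": p,
                "test": test,
                "selected": keep,
                "note": note,
            }
        )
    return ScreenResult(
        selected=selected, table=pd.DataFrame(rows), threshold=threshold
    )
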