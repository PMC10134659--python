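"""Descriptive (Table-1-style) cohort summaries stratified by outcome.

Continuous variables are summarised as mean +- SD (or median (IQR)) and
compared between outcome strata with the independent two-sample t-test;
categorical variables are summarised as n (%) per level and compared with
the Pearson chi-square test.  Percentages are computed on the non-missing
rows of each variable (complete-case per variable) and rounded to one
decimal only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = ["VariableSpec", "DescriptiveTable", "descriptive_table"]


@dataclass(frozen=True)
class VariableSpec:
    name: str
    kind: str  # "continuous" | "categorical"
    style: str = "mean_sd"  # "mean_sd" | "median_iqr" (continuous only)


def _default_spec(cohort: pd.DataFrame, outcome: str) -> list[VariableSpec]:
    skip = {outcome, "unit_id", "x", "y"}
    out = []
    for col in cohort.columns:
        if col in skip:
            continue
        s = cohort[col]
        if pd.api.types.is_numeric_dtype(s) and s.dropna().nunique() > 2:
            style = "median_iqr" if col == "los" else "mean_sd"
            out.append(VariableSpec(col, "continuous", style))
        else:
            out.append(VariableSpec(col, "categorical"))
    return out


@dataclass
class DescriptiveTable:
    """Tidy numeric summary plus a Table-1-style formatted view."""

    data: pd.DataFrame
    outcome: str
    n_total: int
    n_event: int
    n_nonevent: int

    def formatted(self) -> pd.DataFrame:
        """Presentation view: counts with one-decimal percentages."""
        rows = []
        for _, r in self.data.iterrows():
            if r["kind"] == "categorical":
                fmt = {
                    g: f"{int(r[f'{g}_n'])} ({r[f'{g}_pct']:.1f})"
                    for g in ("overall", "event", "nonevent")
                }
            elif r["style"] == "median_iqr":
                fmt = {
                    g: f"{r[f'{g}_median']:.1f} ({r[f'{g}_iqr']:.1f})"
                    for g in ("overall", "event", "nonevent")
                }
            else:
                fmt = {
                    g: f"{r[f'{g}_mean']:.1f} ± {r[f'{g}_sd']:.1f}"
                    for g in ("overall", "event", "nonevent")
                }
            rows.append(
                {
                    "variable": r["variable"],
                    "level": r["level"],
                    "overall": fmt["overall"],
                    "death_yes": fmt["event"],
                    "death_no": fmt["nonevent"],
                    "p_value": "" if np.isnan(r["p_value"]) else f"{r['p_value']:.3g}",
                    "test": r["test"],
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _cont_row(var: VariableSpec, s, y, groups):
    row = {"variable": var.name, "level": "", "kind": "continuous", "style": var.style}
    for g, mask in groups.items():
        v = s[mask].dropna().astype(float)
        row[f"{g}_n"] = len(v)
        row[f"{g}_mean"] = v.mean() if len(v) else np.nan
        row[f"{g}_sd"] = v.std(ddof=1) if len(v) > 1 else np.nan
        row[f"{g}_median"] = v.median() if len(v) else np.nan
        row[f"{g}_iqr"] = (
            v.quantile(0.75) - v.quantile(0.25) if len(v) else np.nan
        )
    a = s[groups["event"]].dropna().astype(float)
    b = s[groups["nonevent"]].dropna().astype(float)
    if len(a) > 1 and len(b) > 1:
        _, p = stats.ttest_ind(a, b, equal_var=True)
        row["p_value"], row["test"] = p, "t-test"
    else:
        row["p_value"], row["test"] = np.nan, "not applicable"
    return [row]


def _cat_rows(var: VariableSpec, s, y, groups):
    s = s.astype("object")
    levels = [lv for lv in pd.unique(s.dropna())]
    tab = pd.crosstab(s, y)
    if tab.shape[0] >= 2 and tab.shape[1] >= 2 and (tab.sum(axis=0) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        p_val, test = p, "chi-square"
    else:
        p_val, test = np.nan, "not applicable"
    rows = []
    denom = {g: s[mask].notna().sum() for g, mask in groups.items()}
    for k, lv in enumerate(levels):
        row = {
            "variable": var.name,
            "level": str(lv),
            "kind": "categorical",
            "style": "",
        }
        for g, mask in groups.items():
            n = int(((s == lv) & mask).sum())
            row[f"{g}_n"] = n
            row[f"{g}_pct"] = 100.0 * n / denom[g] if denom[g] else np.nan
        row["p_value"] = p_val if k == 0 else np.nan
        row["test"] = test if k == 0 else ""
        rows.append(row)
    return rows


def descriptive_table(
    cohort: pd.DataFrame,
    spec: list[VariableSpec] | None = None,
    outcome: str = "death",
) -> DescriptiveTable:
    """Overall and outcome-stratified summaries with t / chi-square tests."""
    if outcome not in cohort.columns:
        raise ValidationError(f"outcome column {outcome!r} not in cohort")
    y = pd.to_numeric(cohort[outcome], errors="coerce")
    if not y.dropna().isin([0, 1]).all():
        raise ValidationError(f"outcome {outcome!r} must be binary 0/1")
    if spec is None:
        spec = _default_spec(cohort, outcome)
    groups = {
        "overall": y.notna(),
        "event": y == 1,
        "nonevent": y == 0,
    }
    rows = []
    for var in spec:
        if var.name not in cohort.columns:
            raise ValidationError(f"variable {var.name!r} not in cohort")
        s = cohort[var.name]
        if var.kind == "continuous":
            rows += _cont_row(var, s, y, groups)
        elif var.kind == "categorical":
            rows += _cat_rows(var, s, y, groups)
        else:
            raise ValidationError(f"unknown variable kind {var.kind!r}")
    return DescriptiveTable(
        data=pd.DataFrame(rows),
        outcome=outcome,
        n_total=int(y.notna().sum()),
        n_event=int((y == 1).sum()),
        n_nonevent=int((y == 0).sum()),
    )
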