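"""Logistic and auto-logistic regression by maximum (pseudo)likelihood.

The auto-logistic model for a binary outcome Y_i at location i is

    Y_i ~ Binomial(p_i)
    logit(p_i) = b0 + b1 X_1i + ... + bk X_ki + gamma * autocov_i

where autocov_i is the inverse-distance-weighted average of the neighbours'
outcomes (see :mod:`autologit.spatial`).  Estimation plugs the *observed*
outcomes into the autocovariate and maximises the resulting ordinary
logistic likelihood — the maximum-pseudolikelihood estimator of the
autologistic Markov random field.  Reported standard errors for gamma are
therefore pseudolikelihood-based and approximate; they are flagged as such
in the model card.

Fitting is iteratively reweighted least squares (Fisher scoring) with
step-halving; convergence when max |score| < 1e-8 or the relative
log-likelihood change < 1e-10.  Odds ratios and 95% CIs are Wald on the
log-odds scale, exp-transformed.

Estimators follow the scikit-learn protocol (``fit``, ``predict_proba``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so
they compose with sklearn pipelines; the module-level ``fit_logistic`` /
``fit_autologistic`` functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats
from sklearn.base import BaseEstimator

from .exceptions import ConvergenceError, SingularDesignError, ValidationError
from .spatial import DistanceBandWeights, autocovariate

__all__ = [
    "Covariate",
    "DesignSpec",
    "FitResult",
    "LogisticGLM",
    "AutoLogistic",
    "fit_logistic",
    "fit_autologistic",
]

AUTOCOV_TERM = "autocovariate"


# ---------------------------------------------------------------------------
# design specification


@dataclass(frozen=True)
class Covariate:
    """One model term: a cohort column with its declared type.

    kind is ``continuous``, ``binary`` (0/1, boolean, or two-level with a
    reference) or ``categorical`` (dummy-coded against ``reference``).
    """

    name: str
    kind: str = "continuous"
    reference: str | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValidationError(f"unknown covariate kind {self.kind!r}")


@dataclass
class DesignSpec:
    """Outcome plus covariate terms; builds the numeric design matrix."""

    covariates: list[Covariate]
    outcome: str = "death"
    include_autocovariate: bool = False

    def build(self, cohort: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, pd.Index]:
        """Return (X without intercept, y, retained row index).

        Rows with missing values in any modelled column are dropped
        (complete-case) with a warning stating the count.
        """
        if self.outcome not in cohort.columns:
            raise ValidationError(f"outcome column {self.outcome!r} not in cohort")
        used = [self.outcome] + [c.name for c in self.covariates]
        for name in used:
            if name not in cohort.columns:
                raise ValidationError(f"column {name!r} not in cohort")
        sub = cohort[used]
        keep = sub.notna().all(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            warnings.warn(
                f"complete-case analysis: dropped {n_drop} row(s) with missing "
                "values in modelled columns",
                stacklevel=2,
            )
        sub = sub.loc[keep]

        y = _validate_binary_outcome(sub[self.outcome], self.outcome)
        cols: dict[str, np.ndarray] = {}
        for cov in self.covariates:
            s = sub[cov.name]
            if cov.kind == "continuous":
                vals = pd.to_numeric(s, errors="coerce").to_numpy(float)
                if not np.all(np.isfinite(vals)):
                    raise ValidationError(f"non-numeric values in {cov.name!r}")
                cols[cov.name] = vals
            else:
                cols.update(_encode_levels(s, cov))
        X = pd.DataFrame(cols, index=sub.index)
        return X, y, sub.index


def _validate_binary_outcome(s: pd.Series, name: str) -> np.ndarray:
    y = pd.to_numeric(s, errors="coerce").to_numpy(float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError(f"outcome {name!r} must be binary 0/1")
    if y.sum() == 0:
        raise ValidationError(f"outcome {name!r} has no events (all 0)")
    if y.sum() == len(y):
        raise ValidationError(f"outcome {name!r} has no non-events (all 1)")
    return y


def _encode_levels(s: pd.Series, cov: Covariate) -> dict[str, np.ndarray]:
    if cov.kind == "binary" and s.dropna().isin([0, 1, True, False]).all():
        return {cov.name: s.astype(float).to_numpy()}
    levels = pd.unique(s.astype(str))
    ref = cov.reference
    if ref is None:
        # default reference: most frequent observed level
        ref = s.astype(str).value_counts().idxmax()
    if str(ref) not in set(levels):
        raise ValidationError(
            f"reference level {ref!r} of {cov.name!r} not among observed "
            f"levels {sorted(levels)}"
        )
    others = [lv for lv in sorted(levels) if lv != str(ref)]
    if cov.kind == "binary" and len(levels) > 2:
        raise ValidationError(f"{cov.name!r} declared binary but has levels {levels}")
    return {
        f"{cov.name}_{lv}": (s.astype(str) == lv).to_numpy(float) for lv in others
    }


# ---------------------------------------------------------------------------
# fit container


@dataclass
class FitResult:
    """Fitted-model container: tidy coefficient table + model-level stats.

    ``table`` has one row per term (index) with columns estimate, se, z, p,
    OR, ci_low, ci_high.  AIC = 2k - 2 logLik.
    """

    table: pd.DataFrame
    loglik: float
    aic: float
    n: int
    n_params: int
    converged: bool
    n_iter: int
    fitted: np.ndarray
    y: np.ndarray
    outcome: str = "death"
    diverging_term: str | None = None
    row_index: pd.Index | None = None
    has_autocovariate: bool = False

    @property
    def params(self) -> pd.Series:
        return self.table["estimate"]

    def to_csv(self, path) -> None:
        """Tidy export: term, estimate, se, z, p, OR, ci_low, ci_high."""
        out = self.table.reset_index(names="term")
        out.to_csv(path, index=False)

    def model_card(self, **extra) -> dict:
        card = {
            "outcome": self.outcome,
            "n": int(self.n),
            "n_params": int(self.n_params),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "has_autocovariate": bool(self.has_autocovariate),
        }
        if self.has_autocovariate:
            card["gamma_se_note"] = (
                "gamma SE is pseudolikelihood-based (autocovariate built from "
                "observed outcomes) and approximate"
            )
        if self.diverging_term:
            card["diverging_term"] = self.diverging_term
        card.update(extra)
        return card


# ---------------------------------------------------------------------------
# IRLS core


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1+e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise SingularDesignError(
            f"design matrix is singular; collinear column(s): {bad}"
        )


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    max_iter: int = 50,
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-10,
    ridge: float = 0.0,
):
    """IRLS / Fisher scoring with step-halving.

    Returns (beta, cov, loglik, converged, n_iter, diverging_term).
    """
    _check_rank(X, names)
    n, p = X.shape
    beta = np.zeros(p)
    ll = _loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = special.expit(eta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol_score:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        xtwx = (X * w[:, None]).T @ X
        if ridge > 0:
            xtwx = xtwx + ridge * np.eye(p)
        try:
            delta = linalg.solve(xtwx, score, assume_a="pos")
        except linalg.LinAlgError as err:  # pragma: no cover - rank pre-checked
            raise SingularDesignError(
                f"weighted normal equations singular: {err}"
            ) from err
        step = 1.0
        ll_new = _loglik(X, y, beta + delta)
        while ll_new < ll - 1e-12 and step > 1e-8:
            step *= 0.5
            ll_new = _loglik(X, y, beta + step * delta)
        beta = beta + step * delta
        if abs(ll_new - ll) < tol_loglik * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    eta = X @ beta
    mu = special.expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    xtwx = (X * w[:, None]).T @ X
    if ridge > 0:
        xtwx = xtwx + ridge * np.eye(p)
    cov = linalg.inv(xtwx)
    ll = _loglik(X, y, beta)

    # (near-)complete separation: the likelihood plateaus while coefficients
    # drift to +/- infinity, so both the score and the log-likelihood change
    # can look converged; detect via the standardised coefficient magnitude
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    std_beta = np.abs(beta) * scale
    separated = bool(np.max(std_beta) > 15.0)
    if separated:
        converged = False
    diverging = None
    if not converged:
        diverging = names[int(np.argmax(std_beta))]
    return beta, cov, ll, converged, it, diverging


# ---------------------------------------------------------------------------
# estimators


class LogisticGLM(BaseEstimator):
    """Binary logistic regression fitted by IRLS, reporting odds ratios.

    Parameters
    ----------
    add_intercept : bool
        Prepend a constant column (default True).
    max_iter, tol_score, tol_loglik : IRLS controls.
    ridge : float
        Optional tiny L2 jitter for near-separated designs (default 0, i.e.
        plain maximum likelihood).

    Fitted attributes: ``coef_``, ``se_``, ``feature_names_``, ``loglik_``,
    ``aic_``, ``converged_``, ``result_`` (a :class:`FitResult`).
    """

    def __init__(
        self,
        add_intercept: bool = True,
        max_iter: int = 50,
        tol_score: float = 1e-8,
        tol_loglik: float = 1e-10,
        ridge: float = 0.0,
        outcome_name: str = "death",
    ):
        self.add_intercept = add_intercept
        self.max_iter = max_iter
        self.tol_score = tol_score
        self.tol_loglik = tol_loglik
        self.ridge = ridge
        self.outcome_name = outcome_name

    # -- helpers ----------------------------------------------------------
    def _design(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            mat = X.to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            if mat.ndim == 1:
                mat = mat[:, None]
            names = [f"x{j}" for j in range(mat.shape[1])]
        if not np.all(np.isfinite(mat)):
            raise ValidationError("design matrix contains missing/non-finite values")
        if self.add_intercept:
            mat = np.column_stack([np.ones(mat.shape[0]), mat])
            names = ["intercept"] + names
        return mat, names

    def fit(self, X, y):
        y = _validate_binary_outcome(pd.Series(np.asarray(y).ravel()), self.outcome_name)
        mat, names = self._design(X)
        if mat.shape[0] != y.shape[0]:
            raise ValidationError("X and y have different lengths")
        beta, cov, ll, converged, n_iter, diverging = _irls(
            mat,
            y,
            names,
            max_iter=self.max_iter,
            tol_score=self.tol_score,
            tol_loglik=self.tol_loglik,
            ridge=self.ridge,
        )
        se = np.sqrt(np.diag(cov))
        zval = beta / se
        pval = 2.0 * stats.norm.sf(np.abs(zval))
        with np.errstate(over="ignore"):  # diverged terms legitimately -> inf
            table = pd.DataFrame(
                {
                    "estimate": beta,
                    "se": se,
                    "z": zval,
                    "p": pval,
                    "OR": np.exp(beta),
                    "ci_low": np.exp(beta - 1.959963984540054 * se),
                    "ci_high": np.exp(beta + 1.959963984540054 * se),
                },
                index=pd.Index(names, name="term"),
            )
        fitted = special.expit(mat @ beta)
        k = mat.shape[1]
        self.coef_ = beta
        self.cov_ = cov
        self.se_ = se
        self.feature_names_ = names
        self.loglik_ = ll
        self.aic_ = 2.0 * k - 2.0 * ll
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.fitted_ = fitted
        self.classes_ = np.array([0.0, 1.0])
        self.result_ = FitResult(
            table=table,
            loglik=ll,
            aic=self.aic_,
            n=int(mat.shape[0]),
            n_params=k,
            converged=converged,
            n_iter=n_iter,
            fitted=fitted,
            y=y,
            outcome=self.outcome_name,
            diverging_term=diverging,
            row_index=X.index if isinstance(X, pd.DataFrame) else None,
        )
        if not converged:
            warnings.warn(
                f"IRLS did not converge in {self.max_iter} iterations; "
                f"term {diverging!r} appears to diverge (possible complete "
                "separation)",
                stacklevel=2,
            )
        return self

    def predict_proba(self, X) -> np.ndarray:
        mat, _ = self._design(X)
        p1 = special.expit(mat @ self.coef_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(float)


class AutoLogistic(LogisticGLM):
    """Auto-logistic regression: logistic GLM plus the autocovariate term.

    ``X`` passed to :meth:`fit` must contain the coordinate columns named in
    ``coord_cols`` (projected metres); they are removed from the design and
    used to build distance-band weights, unless prebuilt ``weights`` are
    supplied.  The autocovariate of the observed outcome is appended as the
    final design column and its coefficient is gamma
    (``gamma_`` after fitting).
    """

    def __init__(
        self,
        radius: float | None = None,
        coord_cols: tuple[str, str] = ("x", "y"),
        weights: DistanceBandWeights | None = None,
        isolated_fallback: str | float = "prevalence",
        add_intercept: bool = True,
        max_iter: int = 50,
        tol_score: float = 1e-8,
        tol_loglik: float = 1e-10,
        ridge: float = 0.0,
        outcome_name: str = "death",
    ):
        super().__init__(
            add_intercept=add_intercept,
            max_iter=max_iter,
            tol_score=tol_score,
            tol_loglik=tol_loglik,
            ridge=ridge,
            outcome_name=outcome_name,
        )
        self.radius = radius
        self.coord_cols = coord_cols
        self.weights = weights
        self.isolated_fallback = isolated_fallback

    def fit(self, X, y):
        from .spatial import build_weights  # local import to avoid cycle noise

        y_arr = np.asarray(y, dtype=float).ravel()
        if self.weights is not None:
            w = self.weights
            if isinstance(X, pd.DataFrame):
                Xd = X.drop(columns=list(self.coord_cols), errors="ignore")
            else:
                Xd = X
        else:
            if not isinstance(X, pd.DataFrame):
                raise ValidationError(
                    "AutoLogistic needs a DataFrame with coordinate columns "
                    f"{self.coord_cols} or prebuilt weights"
                )
            missing = set(self.coord_cols) - set(X.columns)
            if missing:
                raise ValidationError(f"coordinate column(s) {sorted(missing)} missing")
            w = build_weights(X[list(self.coord_cols)].rename(
                columns=dict(zip(self.coord_cols, ("x", "y")))
            ), self.radius)
            Xd = X.drop(columns=list(self.coord_cols))
        if w.n != len(y_arr):
            raise ValidationError("weights and outcome describe different units")
        ac = autocovariate(w, y_arr, self.isolated_fallback)
        if np.ptp(ac) == 0:
            raise SingularDesignError(
                f"{AUTOCOV_TERM} is constant across units (no variation in "
                "neighbour outcomes); the auto-logistic design is singular"
            )
        if isinstance(Xd, pd.DataFrame):
            Xaug = Xd.copy()
            Xaug[AUTOCOV_TERM] = ac
        else:
            Xaug = pd.DataFrame(
                np.column_stack([np.asarray(Xd, dtype=float), ac]),
                columns=[f"x{j}" for j in range(np.atleast_2d(Xd).shape[1])]
                + [AUTOCOV_TERM],
            )
        super().fit(Xaug, y_arr)
        self.weights_ = w
        self.autocovariate_ = ac
        self.gamma_ = float(self.result_.table.loc[AUTOCOV_TERM, "estimate"])
        self.result_.has_autocovariate = True
        return self

    def predict_proba(self, X, autocov=None) -> np.ndarray:
        """Predict with an explicit autocovariate vector (in-sample default)."""
        if isinstance(X, pd.DataFrame):
            X = X.drop(columns=list(self.coord_cols), errors="ignore")
        if autocov is None:
            autocov = self.autocovariate_
        if isinstance(X, pd.DataFrame):
            X = X.copy()
            X[AUTOCOV_TERM] = np.asarray(autocov, dtype=float)
        else:
            X = np.column_stack([np.asarray(X, dtype=float), autocov])
        return LogisticGLM.predict_proba(self, X)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_logistic(design: DesignSpec, cohort: pd.DataFrame, **kwargs) -> FitResult:
    """Fit an ordinary multiple logistic regression per the design spec."""
    X, y, idx = design.build(cohort)
    est = LogisticGLM(outcome_name=design.outcome, **kwargs).fit(X, y)
    est.result_.row_index = idx
    return est.result_


def fit_autologistic(
    design: DesignSpec,
    cohort: pd.DataFrame,
    weights: DistanceBandWeights,
    isolated_fallback: str | float = "prevalence",
    **kwargs,
) -> FitResult:
    """Fit the auto-logistic model (pseudolikelihood) with prebuilt weights.

    The weights must be built on the same units as the cohort (complete-case
    row dropping is not allowed here, because the autocovariate couples every
    unit to its neighbours).
    """
    X, y, idx = design.build(cohort)
    if len(idx) != weights.n:
        raise ValidationError(
            f"weights cover {weights.n} units but the complete-case design "
            f"has {len(idx)} rows; rebuild weights on the modelled rows"
        )
    est = AutoLogistic(
        weights=weights,
        isolated_fallback=isolated_fallback,
        outcome_name=design.outcome,
        **kwargs,
    ).fit(X, y)
    est.result_.row_index = idx
    return est.result_
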