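"""Genotype–phenotype association statistics.

Covers the statistics used for the survival-assay cohorts: Fisher's exact
test on 2×2 tables, Woolf odds ratios with the Haldane–Anscombe
continuity correction, binomial logistic GLMs fitted by IRLS, χ²
likelihood-ratio tests against an intercept-only null, and backward
stepwise model reduction under the Bayesian Information Criterion.

Conventions
-----------
* The Haldane–Anscombe correction adds 0.5 to *every* cell whenever
  requested, not only when a zero is present; this is the convention of
  the classic epidemiological estimator and reproduces published values
  exactly.
* Complete separation is detected by |β| > 15 on the logit scale; the
  fit is returned with ``separation=True`` and the astronomically large
  odds ratio left untouched rather than clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

SEPARATION_BETA = 15.0


@dataclass
class ContingencyTable2x2:
    """Rows = exposure groups, columns = (alive, dead)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("contingency cells must be non-negative")
        if sum(cells) == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class GlmFit:
    """A fitted binomial GLM with the summaries downstream code consumes."""

    params: pd.Series
    bse: pd.Series
    odds_ratios: pd.DataFrame     # columns: OR, ci_low, ci_high, p
    deviance: float
    null_deviance: float
    bic: float
    llf: float
    n: int
    df_model: int
    converged: bool
    separation: bool
    terms: list[str] = field(default_factory=list)


def _coerce_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    return ContingencyTable2x2(*(int(x) for x in arr.ravel()))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p: sum of margin-fixed tables with
    hypergeometric probability ≤ that of the observed table."""
    t = _coerce_table(table)
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("Fisher test undefined with an empty margin")
    _, p = scipy.stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def woolf_or(table, correction: bool = True) -> tuple[float, float, float]:
    """Woolf odds ratio with optional Haldane–Anscombe correction.

    Returns (OR, ci_low, ci_high) with a 95% Wald interval on the log
    scale.  Without the correction a zero cell yields an infinite or
    zero OR; that is signalled by returning ``inf``/``0.0`` with
    infinite CI bounds rather than raising.
    """
    t = _coerce_table(table)
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0.0:
        orr = np.inf if (b == 0 or c == 0) else 0.0
        return float(orr), 0.0, np.inf
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(orr) - 1.96 * se))
    hi = float(np.exp(np.log(orr) + 1.96 * se))
    return float(orr), lo, hi


def fit_binomial_glm(
    y: np.ndarray,
    X: pd.DataFrame,
    add_intercept: bool = True,
) -> GlmFit:
    """Fit a logistic-link binomial GLM by IRLS.

    Parameters
    ----------
    y : binary response vector (1 = alive/resistant).
    X : design frame; categorical columns should already be dummy-coded
        (see :func:`build_design`).
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    X = pd.DataFrame(X).astype(float)
    if add_intercept and "Intercept" not in X.columns:
        X = X.copy()
        X.insert(0, "Intercept", 1.0)
    if len(y) < X.shape[1]:
        raise ValueError("more parameters than observations")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-10)
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial())
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null_res = null.fit()
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    separation = bool((params.drop("Intercept", errors="ignore").abs()
                       > SEPARATION_BETA).any())
    rows = {}
    with np.errstate(over="ignore"):
        for term in X.columns:
            if term == "Intercept":
                continue
            beta, se = params[term], bse[term]
            rows[term] = {
                "OR": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.96 * se)),
                "ci_high": float(np.exp(beta + 1.96 * se)),
                "p": float(res.pvalues[term]),
            }
    return GlmFit(
        params=params,
        bse=bse,
        odds_ratios=pd.DataFrame(rows).T,
        deviance=float(res.deviance),
        null_deviance=float(null_res.deviance),
        bic=float(-2 * res.llf + X.shape[1] * np.log(len(y))),
        llf=float(res.llf),
        n=len(y),
        df_model=X.shape[1] - 1,
        converged=bool(res.converged),
        separation=separation,
        terms=[c for c in X.columns if c != "Intercept"],
    )


def lr_test_vs_null(fit: GlmFit) -> float:
    """χ² likelihood-ratio p-value of a fit against the intercept-only null."""
    stat = fit.null_deviance - fit.deviance
    df = fit.df_model
    if df == 0:
        return 1.0
    if stat < 0:
        stat = 0.0
    return float(scipy.stats.chi2.sf(stat, df))


def build_design(
    predictors: pd.DataFrame,
    categorical: tuple[str, ...] = (),
    reference: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Dummy-code categorical columns (reference level dropped) and keep
    continuous columns as floats; column order follows the input frame."""
    reference = reference or {}
    out = {}
    for col in predictors.columns:
        if col in categorical:
            values = predictors[col].astype(str)
            levels = sorted(values.unique())
            ref = reference.get(col, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {col!r}")
            for lev in levels:
                if lev == ref:
                    continue
                out[f"{col}[{lev}]"] = (values == lev).astype(float).to_numpy()
        else:
            out[col] = predictors[col].astype(float).to_numpy()
    return pd.DataFrame(out, index=predictors.index)


def stepwise_bic(y: np.ndarray, X: pd.DataFrame) -> GlmFit:
    """Backward elimination under BIC.

    Starting from the full design, repeatedly drop the single column
    whose removal most decreases the BIC, until no removal decreases
    it.  Ties are broken by column order (the earlier column wins), so
    the procedure is deterministic.  Duplicated (perfectly collinear)
    columns are resolved naturally: dropping one of them never hurts
    the likelihood, so exactly one survives.
    """
    X = pd.DataFrame(X)
    current = list(X.columns)
    best_fit = fit_binomial_glm(y, X[current])
    while current:
        candidates = []
        for col in current:
            reduced = [c for c in current if c != col]
            fit = fit_binomial_glm(y, X[reduced]) if reduced else fit_binomial_glm(
                y, pd.DataFrame(index=X.index)
            )
            candidates.append((fit.bic, col, fit))
        best_bic, best_col, fit = min(
            candidates, key=lambda t: (t[0], current.index(t[1]))
        )
        if best_bic < best_fit.bic - 1e-12:
            current.remove(best_col)
            best_fit = fit
        else:
            break
    return best_fit
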