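"""Ordinary least squares fitting with explicit term bookkeeping.

All regression in this package ("generalized linear model" in the Gaussian
identity-link sense, i.e. OLS) goes through :func:`fit_linear_model`, which
wraps :mod:`statsmodels` and keeps track of which design columns belong to
which model term.  That bookkeeping is what makes contribution-by-deletion
variance decomposition and nested-model F tests possible without re-parsing
formulas.

Categorical terms are expanded to reference-level dummies (first level in
sorted order is the reference), contributing ``k - 1`` columns for ``k``
observed levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import DesignError, SingularDesignError


@dataclass(frozen=True)
class Term:
    """One model term: a column of the data table plus its type."""

    name: str
    categorical: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"C({self.name})" if self.categorical else self.name


@dataclass
class ModelFit:
    """A fitted OLS model with adjusted-r2 bookkeeping.

    ``adj_r2`` is the "percentage of variance explained" convention on the
    fraction scale: ``1 - (1 - r2) (n - 1) / (n - p_terms - 1)``; ``model_p``
    the overall F-test against the intercept-only model.  ``term_pvalues``
    carries per-term Wald tests (t test for a 1-column term, partial F test
    for a multi-column categorical term) as supplementary output.
    """

    response: str
    terms: tuple[Term, ...]
    coefficients: pd.Series
    r2: float
    adj_r2: float
    model_p: float
    n: int
    p_terms: int
    n_dropped: int
    term_pvalues: dict[str, float]
    bse: pd.Series
    term_columns: dict[str, list[str]]


def build_design(table: pd.DataFrame, terms: list[Term]) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Intercept + dummy-encoded design matrix and term -> column map."""
    X = pd.DataFrame(index=table.index)
    X["Intercept"] = 1.0
    term_columns: dict[str, list[str]] = {}
    for t in terms:
        if t.name not in table.columns:
            raise DesignError(f"term {t.name!r} not found in table")
        col = table[t.name]
        if t.categorical:
            levels = sorted(pd.unique(col.dropna()), key=str)
            dummy_cols = []
            for lev in levels[1:]:
                cname = f"{t.name}[{lev}]"
                X[cname] = (col == lev).astype(float)
                dummy_cols.append(cname)
            term_columns[t.name] = dummy_cols  # may be empty for 1 level
        else:
            X[t.name] = pd.to_numeric(col)
            term_columns[t.name] = [t.name]
    return X, term_columns


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns linearly dependent on earlier ones (pivoted QR)."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return []
    # greedy: keep a column if it increases the rank of the kept set
    kept: list[int] = []
    aliased: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased


def fit_linear_model(table: pd.DataFrame, response: str, terms: list[Term]) -> ModelFit:
    """Fit ``response ~ terms`` by OLS.

    Rows with missing values in the response or any used column are dropped
    (and counted in ``n_dropped``).  Raises :class:`SingularDesignError`
    naming the aliased columns on rank-deficient designs — e.g. a patient
    identifier combined with a covariate constant within patients — and
    :class:`DesignError` when fewer than ``p_terms + 2`` rows remain.
    """
    if response not in table.columns:
        raise DesignError(f"response {response!r} not found in table")
    used = list(dict.fromkeys([response] + [t.name for t in terms]))
    sub = table[used].dropna()
    n_dropped = len(table) - len(sub)
    X, term_columns = build_design(sub, terms)
    y = pd.to_numeric(sub[response]).astype(float)
    p_terms = sum(len(cols) for cols in term_columns.values())
    n = len(sub)
    if n <= p_terms + 1:
        raise DesignError(
            f"{n} complete rows cannot support {p_terms} predictors plus intercept"
        )
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise SingularDesignError(_aliased_columns(Xv, list(X.columns)))

    res = sm.OLS(y.to_numpy(), Xv).fit()
    coefficients = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)

    if p_terms == 0:
        r2, adj_r2, model_p = 0.0, 0.0, float("nan")
    else:
        r2 = float(res.rsquared)
        adj_r2 = float(res.rsquared_adj)
        model_p = float(res.f_pvalue)

    term_pvalues: dict[str, float] = {}
    for t in terms:
        cols = term_columns[t.name]
        if not cols:
            term_pvalues[t.name] = float("nan")
        elif len(cols) == 1:
            term_pvalues[t.name] = float(res.pvalues[X.columns.get_loc(cols[0])])
        else:
            idx = [X.columns.get_loc(c) for c in cols]
            R = np.zeros((len(idx), Xv.shape[1]))
            for i, j in enumerate(idx):
                R[i, j] = 1.0
            term_pvalues[t.name] = float(res.f_test(R).pvalue)

    return ModelFit(
        response=response,
        terms=tuple(terms),
        coefficients=coefficients,
        r2=r2,
        adj_r2=adj_r2,
        model_p=model_p,
        n=n,
        p_terms=p_terms,
        n_dropped=n_dropped,
        term_pvalues=term_pvalues,
        bse=bse,
        term_columns=term_columns,
    )


def nested_f_test(full: ModelFit, reduced: ModelFit, table: pd.DataFrame) -> float:
    """P-value of the F test comparing two nested OLS fits.

    Both fits must have been produced from the same rows of ``table``; the
    reduced model's terms must be a subset of the full model's.
    """
    if not set(t.name for t in reduced.terms) <= set(t.name for t in full.terms):
        raise DesignError("reduced model terms are not a subset of the full model")
    if full.n != reduced.n:
        raise DesignError("nested F test requires identical observations")
    df_num = full.p_terms - reduced.p_terms
    if df_num <= 0:
        raise DesignError("full model adds no parameters over the reduced model")
    df_den = full.n - full.p_terms - 1
    # F from r2 difference: valid because both models include the intercept
    num = (full.r2 - reduced.r2) / df_num
    den = (1.0 - full.r2) / df_den
    if den <= 0:
        return 0.0
    f = num / den
    return float(scipy.stats.f.sf(f, df_num, df_den))
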