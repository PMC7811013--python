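"""Cross-sectional covariate-adjusted association analyses.

Operates on one scan per patient (the first available).  Implements:

* explained variance by age and gender: adjusted r2 of
  ``trait ~ age + gender + protocol`` minus that of ``trait ~ protocol``;
* cross-tissue MTR correlation: ``trait_a ~ trait_b + age + gender +
  protocol`` with the full-model adjusted r2 and the t-test p-value for the
  other tissue's trait — 6 such tests (median and peak height over the three
  tissue-class pairs);
* the clinical/demographic/genetic association scan: each of the 10 traits
  against each typed predictor, always adjusting for age, gender and MRI
  protocol (minus the predictor itself when it is one of those);
* Bonferroni thresholds (``alpha / n_tests``), with the cross-sectional
  family of 10 x 10 + 6 = 106 tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import DesignError, DomainError
from .image_traits import TRAIT_NAMES
from .models import ModelFit, Term, fit_linear_model, nested_f_test

logger = logging.getLogger(__name__)

#: The 6 cross-tissue tests: median and peak height over the three pairs.
CROSS_TISSUE_PAIRS = tuple(
    (f"{a}_mtr_{kind}", f"{b}_mtr_{kind}")
    for kind in ("median", "peak_height")
    for a, b in (("lesion", "nawm"), ("lesion", "nagm"), ("nawm", "nagm"))
)

#: The cross-sectional test family: 10 traits x 10 predictors + 6 cross-tissue.
CROSS_SECTIONAL_N_TESTS = 106


@dataclass
class AssociationResult:
    """One covariate-adjusted association test."""

    trait: str
    predictor: str
    beta: float
    se: float
    p: float
    adj_r2_full: float
    adj_r2_baseline: float
    delta_adj_r2: float
    n: int

    def to_row(self) -> dict:
        return dict(self.__dict__)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance cutoff ``alpha / n_tests``."""
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise DomainError("n_tests must be >= 1")
    return alpha / n_tests


def _covariate_terms(table: pd.DataFrame, exclude: str | None = None) -> list[Term]:
    terms = [Term("age"), Term("gender", categorical=True), Term("protocol_id", categorical=True)]
    return [t for t in terms if t.name != exclude]


def first_scans(scans: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """One row per patient (the earliest scan) joined with patient covariates."""
    first = scans.sort_values(["patient_id", "time_days"]).drop_duplicates("patient_id", keep="first")
    cols = [c for c in patients.columns if c not in first.columns or c == "patient_id"]
    return first.merge(patients[cols], on="patient_id", validate="one_to_one")


def explained_variance_by_age_gender(table: pd.DataFrame, trait: str) -> AssociationResult:
    """Fraction of trait variance attributable to age and gender jointly.

    ``delta_adj_r2`` is adj r2 of the full model (age + gender + protocol)
    minus adj r2 of the protocol-only baseline; the p-value is the nested F
    test for adding age and gender.  A single-protocol table degrades the
    baseline to intercept-only (allowed; logged).
    """
    sub = table[[trait, "age", "gender", "protocol_id"]].dropna()
    if sub["protocol_id"].nunique() < 2:
        logger.info("single protocol level: baseline for %s is intercept-only", trait)
    full = fit_linear_model(sub, trait, _covariate_terms(sub))
    baseline = fit_linear_model(sub, trait, [Term("protocol_id", categorical=True)])
    p = nested_f_test(full, baseline, sub)
    return AssociationResult(
        trait=trait,
        predictor="age+gender",
        beta=float("nan"),
        se=float("nan"),
        p=p,
        adj_r2_full=full.adj_r2,
        adj_r2_baseline=baseline.adj_r2,
        delta_adj_r2=full.adj_r2 - baseline.adj_r2,
        n=full.n,
    )


def cross_tissue_correlation(table: pd.DataFrame, trait_a: str, trait_b: str) -> AssociationResult:
    """Covariate-adjusted regression of one tissue's MTR trait on another's.

    Fits ``trait_a ~ trait_b + age + gender + protocol`` and reports the
    full-model adjusted r2 together with the t-test p-value for ``trait_b``;
    the baseline (covariates-only) adjusted r2 isolates the cross-tissue
    increment.
    """
    cols = list(dict.fromkeys([trait_a, trait_b, "age", "gender", "protocol_id"]))
    sub = table[cols].dropna()
    covs = _covariate_terms(sub)
    if len(sub) < len(covs) + 3:
        raise DesignError(f"too few complete rows ({len(sub)}) for cross-tissue regression")
    full = fit_linear_model(sub, trait_a, [Term(trait_b)] + covs)
    baseline = fit_linear_model(sub, trait_a, covs)
    return AssociationResult(
        trait=trait_a,
        predictor=trait_b,
        beta=float(full.coefficients[trait_b]),
        se=float(full.bse[trait_b]),
        p=full.term_pvalues[trait_b],
        adj_r2_full=full.adj_r2,
        adj_r2_baseline=baseline.adj_r2,
        delta_adj_r2=full.adj_r2 - baseline.adj_r2,
        n=full.n,
    )


#: Default typing of the clinical/demographic predictors.
DEFAULT_CLINICAL_PREDICTORS = (
    Term("gender", categorical=True),
    Term("age"),
    Term("disease_duration"),
    Term("ocb_status", categorical=True),
    Term("igg_index"),
    Term("msss"),
    Term("treatment_status", categorical=True),
)


def clinical_association_scan(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    predictors: list[Term] | None = None,
    alpha: float = 0.05,
    n_tests_family: int | None = None,
) -> pd.DataFrame:
    """Scan every trait against every typed predictor.

    Each test fits ``trait ~ predictor + covariates`` where the covariates
    are age, gender and MRI protocol minus the predictor itself.  Constant
    predictors are skipped (counted untested), all-missing columns skipped
    with a log entry.  The Bonferroni cutoff uses ``n_tests_family``
    (default: the 106-test cross-sectional family).
    """
    traits = traits or [t for t in TRAIT_NAMES if t in table.columns]
    predictors = list(predictors) if predictors is not None else [
        t for t in DEFAULT_CLINICAL_PREDICTORS if t.name in table.columns
    ]
    cutoff = bonferroni_threshold(alpha, n_tests_family or CROSS_SECTIONAL_N_TESTS)
    rows = []
    for pred in predictors:
        col = table[pred.name]
        if col.dropna().empty:
            logger.info("predictor %s all missing: skipped", pred.name)
            continue
        if col.dropna().nunique() < 2:
            for trait in traits:
                rows.append({"trait": trait, "predictor": pred.name, "tested": False,
                             "beta": float("nan"), "se": float("nan"), "p": float("nan"),
                             "adj_r2_full": float("nan"), "adj_r2_baseline": float("nan"),
                             "delta_adj_r2": float("nan"), "n": 0,
                             "significant": False, "threshold": cutoff})
            continue
        covs = _covariate_terms(table, exclude=pred.name)
        for trait in traits:
            cols = list({trait, pred.name, *(c.name for c in covs)})
            sub = table[cols].dropna()
            full = fit_linear_model(sub, trait, [pred] + covs)
            baseline = fit_linear_model(sub, trait, covs)
            p = full.term_pvalues[pred.name]
            single_col = len(full.term_columns[pred.name]) == 1
            beta = float(full.coefficients[full.term_columns[pred.name][0]]) if single_col else float("nan")
            se = float(full.bse[full.term_columns[pred.name][0]]) if single_col else float("nan")
            rows.append({"trait": trait, "predictor": pred.name, "tested": True,
                         "beta": beta, "se": se, "p": p,
                         "adj_r2_full": full.adj_r2, "adj_r2_baseline": baseline.adj_r2,
                         "delta_adj_r2": full.adj_r2 - baseline.adj_r2, "n": full.n,
                         "significant": bool(p <= cutoff), "threshold": cutoff})
    return pd.DataFrame(rows)


def cross_sectional_report(
    scans: pd.DataFrame,
    patients: pd.DataFrame,
    extra_predictors: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Full cross-sectional analysis on the first scan per patient.

    ``extra_predictors`` (e.g. the three PRS columns, indexed by patient id)
    are appended as continuous predictors.  Returns the age/gender
    explained-variance table, the 6-row cross-tissue table, and the
    clinical/genetic association scan.
    """
    table = first_scans(scans, patients)
    predictors = [t for t in DEFAULT_CLINICAL_PREDICTORS if t.name in table.columns]
    if extra_predictors is not None:
        table = table.merge(extra_predictors, left_on="patient_id", right_index=True, how="left")
        predictors += [Term(c) for c in extra_predictors.columns]

    age_gender = pd.DataFrame([
        explained_variance_by_age_gender(table, t).to_row()
        for t in TRAIT_NAMES if t in table.columns
    ])
    cross_tissue = pd.DataFrame([
        cross_tissue_correlation(table, a, b).to_row()
        for a, b in CROSS_TISSUE_PAIRS
        if a in table.columns and b in table.columns
    ])
    scan = clinical_association_scan(table, predictors=predictors, alpha=alpha)
    return {"age_gender": age_gender, "cross_tissue": cross_tissue, "clinical_scan": scan}
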