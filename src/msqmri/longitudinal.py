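"""Inter- vs intra-patient variance decomposition of longitudinal traits.

Two fixed-effect OLS models are fitted per MRI trait:

* the generic model ``trait ~ patient_id + time_days`` — the patient
  identifier absorbs everything that differs between patients at inclusion,
  the days-since-first-scan term the within-patient drift;
* the clinical model ``trait ~ age + gender + disease_duration +
  time_days`` — can known patient-level covariates replace the identifier?

The contribution of each generic-model term is measured by deletion:
adjusted r2 of the full model minus adjusted r2 of the model without that
term; relative shares normalize the (non-negative parts of the) two raw
contributions to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DesignError
from .image_traits import TRAIT_NAMES
from .models import ModelFit, Term, fit_linear_model

GENERIC_TERMS = (Term("patient_id", categorical=True), Term("time_days"))
CLINICAL_TERMS = (
    Term("age"),
    Term("gender", categorical=True),
    Term("disease_duration"),
    Term("time_days"),
)

#: Family-wise threshold for this cohort: alpha = 0.05 over 10 traits x 2 models.
LONGITUDINAL_N_TESTS = 20


@dataclass
class VarianceDecomposition:
    """Adjusted-r2 accounting of the generic model for one trait.

    ``contributions`` holds the raw deletion differences (may be negative);
    ``relative_shares`` the percent split over the positive parts, summing
    to 100 whenever at least one contribution is positive.
    """

    trait: str
    full_adj_r2: float
    model_p: float
    contributions: dict[str, float]
    relative_shares: dict[str, float]
    n: int


def _deletion_shares(contributions: dict[str, float]) -> dict[str, float]:
    floored = {k: max(v, 0.0) for k, v in contributions.items()}
    total = sum(floored.values())
    if total <= 0:
        return {k: float("nan") for k in contributions}
    return {k: 100.0 * v / total for k, v in floored.items()}


def decompose_generic_model(table: pd.DataFrame, trait: str) -> VarianceDecomposition:
    """Contribution-by-deletion decomposition of the generic model.

    Requires at least two patients with two or more scans and time coded in
    days since each patient's first scan.  Patients with a single scan are
    retained (they inform the intercepts only).
    """
    sub = table[["patient_id", "time_days", trait]].dropna()
    scans_per = sub.groupby("patient_id").size()
    if (scans_per >= 2).sum() < 2:
        raise DesignError("need >= 2 scans for >= 2 patients to separate patient and time")
    if sub.groupby("patient_id")["time_days"].nunique().max() < 2:
        raise DesignError("time term undefined: no patient has scans at distinct times")

    full = fit_linear_model(sub, trait, list(GENERIC_TERMS))
    without_patient = fit_linear_model(sub, trait, [Term("time_days")])
    without_time = fit_linear_model(sub, trait, [Term("patient_id", categorical=True)])
    contributions = {
        "patient_id": full.adj_r2 - without_patient.adj_r2,
        "time_days": full.adj_r2 - without_time.adj_r2,
    }
    return VarianceDecomposition(
        trait=trait,
        full_adj_r2=full.adj_r2,
        model_p=full.model_p,
        contributions=contributions,
        relative_shares=_deletion_shares(contributions),
        n=full.n,
    )


def fit_clinical_model(table: pd.DataFrame, trait: str) -> ModelFit:
    """OLS fit of ``trait ~ age + gender + disease_duration + time_days``."""
    return fit_linear_model(table, trait, list(CLINICAL_TERMS))


def longitudinal_report(
    scans: pd.DataFrame,
    patients: pd.DataFrame,
    traits: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-trait decomposition table (generic + clinical models side by side).

    Joins patient-level covariates onto the scan table, then reports for each
    trait the generic-model adjusted r2 and overall F p-value, the
    patient/time relative shares, and the clinical-model adjusted r2 and
    p-value, with the Bonferroni threshold alpha / 20 applied to both model
    p-values.
    """
    from .cross_sectional import bonferroni_threshold

    traits = traits or [t for t in TRAIT_NAMES if t in scans.columns]
    cov_cols = ["patient_id", "age", "gender", "disease_duration"]
    merged = scans.merge(patients[cov_cols], on="patient_id", validate="many_to_one")
    cutoff = bonferroni_threshold(alpha, LONGITUDINAL_N_TESTS)
    rows = []
    for trait in traits:
        dec = decompose_generic_model(merged, trait)
        clin = fit_clinical_model(merged, trait)
        rows.append({
            "trait": trait,
            "generic_adj_r2": dec.full_adj_r2,
            "generic_p": dec.model_p,
            "generic_significant": dec.model_p <= cutoff,
            "patient_share_pct": dec.relative_shares["patient_id"],
            "time_share_pct": dec.relative_shares["time_days"],
            "patient_contribution": dec.contributions["patient_id"],
            "time_contribution": dec.contributions["time_days"],
            "clinical_adj_r2": clin.adj_r2,
            "clinical_p": clin.model_p,
            "clinical_significant": clin.model_p <= cutoff,
            "n_scans": dec.n,
            "bonferroni_threshold": cutoff,
        })
    return pd.DataFrame(rows)
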