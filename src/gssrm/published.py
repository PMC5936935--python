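"""Published summaries from the motivating field study.

The model was developed for the inter-household support networks of a
community of indigenous Nicaraguan horticulturalists (108 interviewed
adults in 32 households; directed nominations elicited by the roster
method).  The raw data live in supplementary archives, but the printed
posterior summaries and descriptive statistics are useful on their own:
worked examples recompute the reported variance partition coefficients
and reciprocity correlations from them, and counterfactual predictions
can be evaluated at the reported covariate means.

All values are posterior means (model tables) or sample summaries
(descriptive table) exactly as printed, on the analysis scale: wealth
and distance are natural logs, average inter-household relatedness is
log-transformed and centred at its sample mean of -3.86, and age, BMI
and skin colour are z-scored over the roster.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "MODEL0_VARIANCES",
    "MODEL1_VARIANCES",
    "MODEL5_COEFFICIENTS",
    "STUDY_SCENARIO_DEFAULTS",
    "STUDY_COUNTS",
    "study_scenario_design",
]

#: Posterior-mean variances of the conventional social relations model
#: (individual giving/receiving effects and the symmetric dyad effect).
MODEL0_VARIANCES: dict[str, float] = {
    "var_a1": 0.81,
    "var_b1": 1.17,
    "var_u": 1.52,
}

#: Posterior-mean variances of the full group-structured model without
#: covariates (the second "empty" model).
MODEL1_VARIANCES: dict[str, float] = {
    "var_a2": 0.30,
    "var_b2": 0.14,
    "var_a1": 0.88,
    "var_b1": 1.92,
    "var_c": 0.47,
    "var_d": 0.89,
    "var_h": 1.78,
    "var_u": 0.36,
}

#: Posterior-mean fixed effects of the infidelity model (model 5),
#: keyed by design-column name.
MODEL5_COEFFICIENTS: dict[str, float] = {
    "intercept": -0.90,
    "male_i": -0.43,
    "male_j": -0.58,
    "male_i_x_male_j": 0.55,
    "age_i": 0.81,
    "age2_i": -0.23,
    "age_j": 0.06,
    "age2_j": 0.09,
    "bmi_i": 0.02,
    "bmi_j": -0.15,
    "bmi_i_x_bmi_j": -0.01,
    "skin_i": -0.08,
    "skin_j": -0.12,
    "skin_i_x_skin_j": -0.02,
    "godparent": 1.02,
    "wealth_k": 0.02,
    "wealth_l": 0.01,
    "distance": -0.23,
    "relatedness": 7.21,
    "affinal_r": 3.27,
    "avg_relatedness": 0.69,
    "infidelity": -2.13,
}

#: Covariate-holding defaults on the study's analysis scale: indicator
#: columns at the reference level, continuous main effects at their
#: reported sample means (0 for z-scored variables), quadratic columns
#: at the sample mean of the squared z-score (~1), product columns at
#: the product of the held main effects.
STUDY_SCENARIO_DEFAULTS: dict[str, float] = {
    "intercept": 1.0,
    "male_i": 0.0,
    "male_j": 0.0,
    "male_i_x_male_j": 0.0,
    "age_i": 0.0,
    "age2_i": 1.0,
    "age_j": 0.0,
    "age2_j": 1.0,
    "bmi_i": 0.0,
    "bmi_j": 0.0,
    "bmi_i_x_bmi_j": 0.0,
    "skin_i": 0.0,
    "skin_j": 0.0,
    "skin_i_x_skin_j": 0.0,
    "godparent": 0.0,
    "wealth_k": -0.92,
    "wealth_l": -0.92,
    "distance": 5.78,
    "relatedness": 0.05,
    "affinal_r": 0.06,
    "avg_relatedness": -3.74 - (-3.86),
    "infidelity": 0.0,
}

def study_scenario_design(model_id: int = 5):
    """Scenario-only design on the study's covariate scale.

    Carries no dyad rows — just the column set and the published
    covariate-holding defaults — so counterfactual probabilities can be
    evaluated against reported coefficients without the raw data.
    """
    from .covariates import MODEL_COLUMNS, DesignMatrix

    columns = MODEL_COLUMNS[model_id]
    defaults = {}
    for col in columns:
        if col in STUDY_SCENARIO_DEFAULTS:
            defaults[col] = STUDY_SCENARIO_DEFAULTS[col]
        elif "_x_" in col:
            factors = col.split("_x_")
            value = 1.0
            for f in factors:
                value *= STUDY_SCENARIO_DEFAULTS[f]
            defaults[col] = value
        else:
            raise ValueError(f"no published default for column {col!r}")
    return DesignMatrix(
        model_id=model_id,
        table=pd.DataFrame(columns=columns),
        columns=columns,
        metadata={"scale": "published study"},
        defaults=defaults,
    )


#: Sample sizes of the study community.
STUDY_COUNTS: dict[str, int] = {
    "individuals": 108,
    "households": 32,
    "individual_dyads": 5602,
    "household_dyads": 496,
}
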