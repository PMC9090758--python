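"""Conventional behavioral statistics: mixed-effects models of the raw data.

Log response times (trial level), accuracy and omission counts (subject
by condition) are analysed with linear mixed models carrying fixed
condition, group and interaction effects and a random intercept per
subject, fitted by REML through statsmodels.  Effects are summarised as
Wald F statistics; denominator degrees of freedom use the containment
approximation (observations minus fixed-effect columns minus subjects),
which is recorded in the output metadata.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps


def _wald_terms(result, data, outcome):
    """F tests for condition, group and interaction from a MixedLM fit."""
    params = result.fe_params
    cov = result.cov_params().loc[params.index, params.index]
    n_obs = result.model.nobs
    n_groups = result.model.n_groups
    df_den = max(int(n_obs - len(params) - n_groups), 1)
    rows = []
    for effect, key in (("condition", "C(condition)["),
                        ("group", "C(group)["),
                        ("condition:group", ":")):
        if effect == "condition:group":
            idx = [i for i, n in enumerate(params.index) if ":" in n]
        else:
            idx = [i for i, n in enumerate(params.index)
                   if n.startswith(key) and ":" not in n]
        q = len(idx)
        C = np.zeros((q, len(params)))
        for r, i in enumerate(idx):
            C[r, i] = 1.0
        cb = C @ params.to_numpy()
        V = C @ cov.to_numpy() @ C.T
        F = float(cb @ np.linalg.solve(V, cb) / q)
        p = float(sps.f.sf(F, q, df_den))
        rows.append({"outcome": outcome, "effect": effect, "F": F,
                     "df_num": q, "df_den": df_den, "p": p})
    return rows


def behavioral_stats(trials: pd.DataFrame) -> pd.DataFrame:
    """Mixed-model tests of condition/group effects on behavior.

    Returns one row per outcome (logRT, accuracy, omissions) and effect
    (condition, group, interaction) with F, dfs and p.  RT analysis uses
    the natural log of non-omitted trials; accuracy and omissions are
    aggregated per subject and condition.  Subjects with only omissions
    are dropped with a warning.
    """
    required = {"subject_id", "group", "condition", "response", "rt"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    if trials["group"].nunique() < 2 or trials["condition"].nunique() < 2:
        raise ValueError("need at least 2 groups and 2 conditions")

    rows = []
    resp = trials["response"].astype(str)
    valid = trials[resp != "omission"].copy()
    all_om = set(trials["subject_id"].unique()) - set(valid["subject_id"].unique())
    if all_om:
        warnings.warn(f"excluding all-omission subjects: {sorted(all_om)}")
    valid["logrt"] = np.log(valid["rt"].astype(float))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = smf.mixedlm("logrt ~ C(condition) * C(group)", valid,
                        groups=valid["subject_id"]).fit(reml=True)
    rows += _wald_terms(m, valid, "logRT")

    agg = trials.assign(omit=(resp == "omission").to_numpy()).groupby(
        ["subject_id", "group", "condition"], as_index=False).agg(
        accuracy=("correct", "mean"), omissions=("omit", "sum"))
    for outcome in ("accuracy", "omissions"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = smf.mixedlm(f"{outcome} ~ C(condition) * C(group)", agg,
                            groups=agg["subject_id"]).fit(reml=True)
        rows += _wald_terms(m, agg, outcome)
    out = pd.DataFrame(rows)
    out.attrs["df_method"] = "containment (Wald F)"
    return out


def condition_rt_means(trials: pd.DataFrame) -> pd.Series:
    """Mean RT per condition over non-omitted trials (for ordering checks)."""
    resp = trials["response"].astype(str)
    valid = trials[resp != "omission"]
    return valid.groupby("condition")["rt"].mean()
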