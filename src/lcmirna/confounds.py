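"""Demographic comparisons and confound correlations.

Group comparisons use the pooled-variance Student t test with
df = n1 + n2 - 2 (Welch's correction is deliberately not applied: with
tissue-bank cohorts of 9-11 subjects the pooled form is the conventional
report, and both forms agree to ~0.01 here).  Confound screens correlate
each assay's expression with age, postmortem interval and brain pH via
the Pearson product-moment correlation, within each group; sex effects
reuse the two-sample t per assay.

Direction language: on the Ct scale lower values mean *higher*
expression; outputs state direction on the expression scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CtMatrix, SampleInfo, samples_to_frame

__all__ = [
    "GroupComparison",
    "two_sample_t",
    "group_summary",
    "confound_correlations",
    "sex_effect",
]

COVARIATES = ("age", "pmi", "ph")


@dataclass(frozen=True)
class GroupComparison:
    """Pooled-variance two-sample t comparison of one variable."""

    variable: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.df != self.n1 + self.n2 - 2:
            raise ValueError("df must equal n1 + n2 - 2")


def two_sample_t(
    x: Sequence[float], y: Sequence[float], variable: str = ""
) -> GroupComparison:
    """Pooled-variance Student t; df = n1 + n2 - 2, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("two_sample_t requires n >= 2 per group")
    sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
        len(x) + len(y) - 2
    )
    if sp2 == 0:
        if x.mean() == y.mean():
            t, p = 0.0, 1.0
        else:
            raise ValueError("zero pooled variance with unequal means")
    else:
        t, p = stats.ttest_ind(x, y, equal_var=True)
    return GroupComparison(
        variable=variable,
        mean1=float(x.mean()),
        sd1=float(x.std(ddof=1)),
        n1=len(x),
        mean2=float(y.mean()),
        sd2=float(y.std(ddof=1)),
        n2=len(y),
        t=float(t),
        df=len(x) + len(y) - 2,
        p=float(p),
    )


def group_summary(samples: Sequence[SampleInfo]) -> pd.DataFrame:
    """Mean +/- sample SD (n-1 denominator) per group for each covariate.

    Returns a DataFrame indexed by (group, variable) with columns
    ``mean``, ``sd``, ``n``.
    """
    meta = samples_to_frame(samples)
    rows = []
    for g, sub in meta.groupby("group"):
        for var in ("age", "pmi", "ph", "rin"):
            vals = sub[var].astype(float)
            rows.append(
                {
                    "group": g,
                    "variable": var,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)),
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(rows).set_index(["group", "variable"])


def demographic_comparisons(samples: Sequence[SampleInfo]) -> list[GroupComparison]:
    """Control-vs-case pooled t for age, PMI, pH and RIN."""
    meta = samples_to_frame(samples)
    ctrl = meta[meta["group"] == "control"]
    case = meta[meta["group"] == "case"]
    return [
        two_sample_t(ctrl[v].astype(float), case[v].astype(float), variable=v)
        for v in ("age", "pmi", "ph", "rin")
    ]


def confound_correlations(
    expr: CtMatrix,
    samples: Sequence[SampleInfo],
    per_group: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r of each assay with age/PMI/pH, per group.

    Returns a tidy DataFrame (assay_id, covariate, group, r, p,
    significant); rows with a zero-variance covariate are skipped with a
    warning.  Correlations are computed on detectable cells only.
    """
    meta = samples_to_frame(samples)
    if per_group:
        groups = {g: list(sub.index) for g, sub in meta.groupby("group")}
    else:
        groups = {"all": list(meta.index)}
    masked = expr.values.where(expr.detect_mask)
    rows = []
    for g, members in groups.items():
        members = [s for s in members if s in masked.index]
        sub_meta = meta.loc[members]
        for cov in COVARIATES:
            covariate = sub_meta[cov].astype(float)
            if covariate.nunique() <= 1:
                warnings.warn(
                    f"zero-variance covariate {cov!r} in group {g!r}; skipped",
                    stacklevel=2,
                )
                continue
            for assay in masked.columns:
                y = masked.loc[members, assay]
                okk = y.notna()
                if okk.sum() < 3 or y[okk].nunique() <= 1:
                    continue
                r, p = stats.pearsonr(covariate[okk], y[okk])
                rows.append(
                    {
                        "assay_id": assay,
                        "covariate": cov,
                        "group": g,
                        "r": float(r),
                        "p": float(p),
                        "significant": bool(p <= alpha),
                    }
                )
    return pd.DataFrame(
        rows, columns=["assay_id", "covariate", "group", "r", "p", "significant"]
    )


def sex_effect(
    expr: CtMatrix, samples: Sequence[SampleInfo], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-assay two-sample t between female and male subjects.

    Direction is reported on the *expression* scale: a lower mean Ct in
    females means higher expression in females.  Assays where either sex
    has fewer than 2 detectable values are skipped with a warning.
    """
    meta = samples_to_frame(samples)
    females = [s for s in expr.samples if meta.at[s, "sex"] == "F"]
    males = [s for s in expr.samples if meta.at[s, "sex"] == "M"]
    if not females or not males:
        raise ValueError("both sexes must be present")
    masked = expr.values.where(expr.detect_mask)
    rows, skipped = [], []
    for assay in masked.columns:
        f = masked.loc[females, assay].dropna()
        m = masked.loc[males, assay].dropna()
        if len(f) < 2 or len(m) < 2:
            skipped.append(assay)
            continue
        if f.var(ddof=1) == 0 and m.var(ddof=1) == 0 and f.mean() != m.mean():
            skipped.append(assay)
            continue
        cmp = two_sample_t(f, m, variable=assay)
        rows.append(
            {
                "assay_id": assay,
                "t": cmp.t,
                "df": cmp.df,
                "p": cmp.p,
                # lower Ct = higher expression
                "higher_expression_in": "F" if cmp.mean1 < cmp.mean2 else ("M" if cmp.mean1 > cmp.mean2 else "="),
                "significant": bool(cmp.p <= alpha),
            }
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} assays skipped in sex_effect (insufficient data)",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows, columns=["assay_id", "t", "df", "p", "higher_expression_in", "significant"]
    )
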