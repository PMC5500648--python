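"""Demographic balance checks between comparison groups.

Before comparing two groups' connectomes we verify the groups are matched
on age (two-sample t-test) and sex (chi-squared on the 2 x 2 sex-by-group
table), so that a connectivity difference cannot be a demographic artifact.
Education years are reported descriptively only: in the cohort designs this
package targets, education is controlled upstream by the group definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import Cohort

__all__ = ["BalanceReport", "age_balance", "sex_balance", "balance_report"]


@dataclass(frozen=True)
class BalanceReport:
    comparison: tuple[str, str]
    age_t: float
    age_p: float
    sex_chi2: float
    sex_p: float
    n_per_group: tuple[int, int]
    education_mean: tuple[float, float]


def _group_frame(cohort: Cohort, group: str) -> pd.DataFrame:
    sub = cohort.table[cohort.table["group"] == group]
    if len(sub) < 2:
        raise ValidationError(f"group {group!r} absent or has fewer than 2 subjects")
    return sub


def age_balance(
    cohort: Cohort, group_a: str, group_b: str, welch: bool = False
) -> tuple[float, float]:
    """Two-sample t-test on age; pooled-variance by default, Welch by flag."""
    ages_a = _group_frame(cohort, group_a)["age"].to_numpy(dtype=float)
    ages_b = _group_frame(cohort, group_b)["age"].to_numpy(dtype=float)
    t, p = stats.ttest_ind(ages_a, ages_b, equal_var=not welch)
    return float(t), float(p)


def sex_balance(
    cohort: Cohort, group_a: str, group_b: str, yates: bool = False
) -> tuple[float, float]:
    """Chi-squared test on the 2 x 2 sex-by-group contingency table."""
    sub_a = _group_frame(cohort, group_a)
    sub_b = _group_frame(cohort, group_b)
    sexes = sorted(set(sub_a["sex"]) | set(sub_b["sex"]))
    if len(sexes) < 2:
        raise ValidationError(
            f"degenerate sex table comparing {group_a!r} vs {group_b!r}: "
            f"only category {sexes} present"
        )
    table = np.array(
        [
            [int((sub["sex"] == s).sum()) for s in sexes]
            for sub in (sub_a, sub_b)
        ]
    )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def balance_report(
    cohort: Cohort,
    group_a: str,
    group_b: str,
    welch: bool = False,
    yates: bool = False,
) -> BalanceReport:
    """Full balance battery for one two-group comparison."""
    t, age_p = age_balance(cohort, group_a, group_b, welch=welch)
    chi2, sex_p = sex_balance(cohort, group_a, group_b, yates=yates)
    sub_a = _group_frame(cohort, group_a)
    sub_b = _group_frame(cohort, group_b)
    return BalanceReport(
        comparison=(group_a, group_b),
        age_t=t,
        age_p=age_p,
        sex_chi2=chi2,
        sex_p=sex_p,
        n_per_group=(len(sub_a), len(sub_b)),
        education_mean=(
            float(sub_a["education_years"].mean()),
            float(sub_b["education_years"].mean()),
        ),
    )
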