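"""Group-level cohort comparisons.

All comparisons are pooled-variance two-sample Student t tests, two-sided —
including the one on the binary high-grade indicator, mirroring how such
cohort tables are usually reported (a chi-square or Fisher test would be the
orthodox choice for a binary outcome; the t test on the 0/1 indicator is
kept deliberately and documented as a caveat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "student_t", "grade_association", "marker_summary",
           "comparisons_table"]


@dataclass
class GroupComparison:
    variable: str
    group: int
    mean_group: float
    mean_rest: float
    t: float
    df: int
    p: float
    n_group: int
    n_rest: int
    status: str = "ok"


def student_t(values, labels, group: int, variable: str = "value") -> GroupComparison:
    """Pooled-variance two-sample Student t of one group against the rest.

    t = (m1 - m2) / (s_p * sqrt(1/n1 + 1/n2)) with s_p^2 the pooled variance
    and df = n1 + n2 - 2; the two-sided p comes from the exact t
    distribution.  Zero pooled variance yields t = 0, p = 1 for equal means
    and p = 0 (with a warning) otherwise.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    a = values[labels == group]
    b = values[labels != group]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both sides need >= 2 samples")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in comparison")
    n1, n2 = len(a), len(b)
    m1, m2 = a.mean(), b.mean()
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    dof = n1 + n2 - 2
    if sp2 == 0:
        if m1 == m2:
            t, p = 0.0, 1.0
        else:
            warnings.warn(f"{variable}: zero pooled variance with unequal means")
            t = np.inf if m1 > m2 else -np.inf
            p = 0.0
    else:
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * float(sps.t.sf(abs(t), dof))
    return GroupComparison(
        variable=variable, group=group, mean_group=float(m1), mean_rest=float(m2),
        t=float(t), df=dof, p=float(p), n_group=n1, n_rest=n2,
    )


def grade_association(
    metadata: pd.DataFrame, labels, group: int
) -> GroupComparison:
    """High-grade (WHO grade >= 2) membership of one group vs the rest,
    tested as a Student t on the 0/1 indicator."""
    grades = metadata["who_grade"].to_numpy()
    if not np.isin(grades, [1, 2, 3]).all():
        raise ValueError("who_grade must be 1, 2 or 3")
    indicator = (grades >= 2).astype(float)
    return student_t(indicator, labels, group, variable="high_grade")


def marker_summary(
    tpm_matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    labels,
    markers: list[str],
    group: int,
) -> pd.DataFrame:
    """Proliferation read-out of the designated group: one comparison per
    marker gene (per-sample TPM) plus one for the mitotic index.

    Markers absent from the expression index produce an ``absent`` row
    rather than an error.
    """
    rows = []
    for m in markers:
        if m not in tpm_matrix.index:
            rows.append(GroupComparison(m, group, np.nan, np.nan, np.nan, 0,
                                        np.nan, 0, 0, status="absent"))
            continue
        rows.append(student_t(tpm_matrix.loc[m].to_numpy(), labels, group,
                              variable=m))
    rows.append(
        student_t(metadata["mitotic_index"].to_numpy(), labels, group,
                  variable="mitotic_index")
    )
    return comparisons_table(rows)


def comparisons_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": c.variable, "group": c.group,
                "mean_group": c.mean_group, "mean_rest": c.mean_rest,
                "t": c.t, "df": c.df, "p": c.p,
                "n_group": c.n_group, "n_rest": c.n_rest, "status": c.status,
            }
            for c in comparisons
        ]
    )
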