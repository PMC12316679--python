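"""Group-level statistics on per-subject ROI summaries.

Mirrors the study design: univariable linear regression of each
vessel-architecture measure on group (0 = control, 1 = patient),
multivariable models adding age and sex (0 = female, 1 = male), an
optional group x age interaction, exploratory cardiovascular covariates,
paired t-tests NAWM vs WMH within patients, and independent t-tests on the
subject-wise voxel-VSI IQR.  No multiple-testing correction is applied
(two-sided p < 0.05), matching the source analysis; this is a documented
limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class RegressionResult:
    """One regression term: estimate, normal-theory 95% CI and p-value."""

    term: str
    beta: float
    ci95_low: float
    ci95_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci95_low <= self.beta <= self.ci95_high):
            raise ValueError("CI does not bracket the estimate")


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns via QR pivoting
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        bad = [X.columns[i] for i in np.where(diag <= tol)[0]]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {arr.shape[1]}); "
            f"collinear terms: {bad or list(X.columns)}"
        )


def ols_fit(y, design: pd.DataFrame, add_intercept: bool = True):
    """Ordinary least squares of ``y`` on the named design columns.

    Two-sided p-values and 95% CIs come from the t distribution with
    n - k degrees of freedom.  Returns a list of
    :class:`RegressionResult`, intercept first.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(design).astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than design terms")
    _check_full_rank(X)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    return [
        RegressionResult(
            term="intercept" if t == "const" else str(t),
            beta=float(res.params[t]),
            ci95_low=float(ci.loc[t, 0]),
            ci95_high=float(ci.loc[t, 1]),
            p_value=float(res.pvalues[t]),
        )
        for t in X.columns
    ]


def interaction_model(
    y, group, age, sex, center_age: bool = True
) -> list[RegressionResult]:
    """Group + age + sex model with a group x age interaction term.

    Age is mean-centered before forming the product (default) so the group
    main effect stays interpretable at the mean age.
    """
    group = np.asarray(group, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    age_c = age - age.mean() if center_age else age
    design = pd.DataFrame(
        {
            "group": group,
            "age": age_c,
            "sex": sex,
            "group_x_age": group * age_c,
        }
    )
    return ols_fit(y, design)


def paired_ttest(a, b) -> tuple[float, int, float]:
    """Two-sided paired t-test; raises on zero difference variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    diff = a - b
    if np.var(diff, ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    t, p = sps.ttest_rel(a, b)
    return float(t), a.size - 1, float(p)


def independent_ttest(
    a, b, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def percent_contrast(reference: float, value: float) -> float:
    """Percentage change of ``value`` relative to ``reference``.

    E.g. group means Q = 0.29 in lesions vs 0.39 in normal-appearing
    white matter give -25.6% (a ~26% reduction).
    """
    if reference == 0:
        raise ValueError("reference mean is zero")
    return 100.0 * (value - reference) / reference


def contrast_report(
    means: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    """Percent contrasts for a dict metric -> (reference mean, other mean)."""
    rows = [
        {
            "metric": m,
            "reference": ref,
            "value": val,
            "percent_change": percent_contrast(ref, val),
        }
        for m, (ref, val) in means.items()
    ]
    return pd.DataFrame(rows)


def regression_table(
    results: dict[str, list[RegressionResult]]
) -> pd.DataFrame:
    """Long-format table (outcome, term, beta, 95% CI, p)."""
    rows = []
    for outcome, terms in results.items():
        for r in terms:
            rows.append(
                {
                    "outcome": outcome,
                    "term": r.term,
                    "beta": r.beta,
                    "ci95_low": r.ci95_low,
                    "ci95_high": r.ci95_high,
                    "p_value": r.p_value,
                }
            )
    return pd.DataFrame(rows)


def format_regression_report(table: pd.DataFrame) -> str:
    """Human-readable report: one line per term, beta (95% CI), p."""
    lines = []
    for outcome, grp in table.groupby("outcome", sort=False):
        lines.append(f"## {outcome}")
        for _, r in grp.iterrows():
            lines.append(
                f"  {r['term']:<14s} {r['beta']: .3f} "
                f"({r['ci95_low']: .3f} to {r['ci95_high']: .3f})  "
                f"p={r['p_value']:.4f}"
            )
    return "\n".join(lines)
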