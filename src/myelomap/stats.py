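"""Cohort-level statistics: outcome scoring, group and location comparisons,
correlations with Bonferroni control, and intra-rater reliability.

Conventions fixed here because the study design leaves them open:

- ICC is the two-way mixed, absolute-agreement, single-measure form ICC(A,1).
- The partial Spearman correlation is the Pearson correlation of the
  residuals from rank-regressions of x and y on the covariate ranks, with
  degrees of freedom reduced by the number of covariates.
- The mixed-design repeated-measures ANOVA applies the Greenhouse-Geisser
  correction when sphericity is rejected; Shapiro-Wilk normality is checked
  per cell and a violation warns rather than aborts.
- Missing data are handled complete-case per test, with the n used reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "ma_percent",
    "nonmotor_psom",
    "bonferroni",
    "mixed_anova",
    "correlate",
    "icc_intra_rater",
    "group_compare",
]


@dataclass
class StatResult:
    """One inferential result: a named estimate with its p-value and n."""

    test: str
    estimate: float
    p_value: float
    n: int
    p_adjusted: float | None = None
    details: dict = field(default_factory=dict)


def ma_percent(points_achieved: int, total_points: int = 122) -> float:
    """Melbourne Assessment percentage: achieved / possible * 100."""
    if total_points <= 0:
        raise ValueError("total_points must be positive")
    if not 0 <= points_achieved <= total_points:
        raise ValueError("points_achieved must lie in [0, total_points]")
    return 100.0 * points_achieved / total_points


def nonmotor_psom(
    lang_prod: float, lang_comp: float, cogbeh: float
) -> tuple[float, str]:
    """Non-motor PSOM: sum of the two language subscores and the
    cognitive/behavioural subscore (each 0-2), dichotomized as poor iff the
    total strictly exceeds 1."""
    for name, v in (
        ("lang_prod", lang_prod),
        ("lang_comp", lang_comp),
        ("cogbeh", cogbeh),
    ):
        if not 0.0 <= v <= 2.0:
            raise ValueError(f"{name} must lie in [0, 2]")
    score = lang_prod + lang_comp + cogbeh
    return score, ("poor" if score > 1.0 else "good")


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p), m defaulting to the family size."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m is None else m
    logger.info("Bonferroni family size m=%d", m)
    return np.minimum(1.0, m * p)


def _complete_cases(*arrays):
    arrs = [np.asarray(a, dtype=float) for a in arrays]
    mask = np.all(np.isfinite(np.column_stack(arrs)), axis=1)
    return [a[mask] for a in arrs]


def group_compare(values_a, values_b, labels=("a", "b")) -> StatResult:
    """Two-sample t-test on independent groups (Welch when a group variance
    degenerates), with the mean difference and its 95% CI."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    diff = float(a.mean() - b.mean())
    if var_a == 0 and var_b == 0:
        # identical-within groups: no sampling variability to test against
        p = 1.0 if diff == 0 else 0.0
        return StatResult(
            "t-test", diff, p, len(a) + len(b),
            details={"t": 0.0 if diff == 0 else np.inf, "ci": (diff, diff)},
        )
    equal_var = not (var_a == 0 or var_b == 0)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    ci = res.confidence_interval(0.95)
    return StatResult(
        "t-test" if equal_var else "welch-t",
        diff,
        float(res.pvalue),
        len(a) + len(b),
        details={"t": float(res.statistic), "ci": (float(ci.low), float(ci.high))},
    )


def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a)


def correlate(x, y, method: str = "pearson", covariates=None) -> StatResult:
    """Pearson or Spearman correlation, optionally partial on covariates.

    The partial variant correlates the residuals of regressions of x and y on
    the covariates (rank-transformed first for Spearman), testing with
    n - 2 - k degrees of freedom.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    covs = [] if covariates is None else list(covariates)
    arrays = _complete_cases(x, y, *covs)
    x_, y_, covs_ = arrays[0], arrays[1], arrays[2:]
    n = len(x_)
    k = len(covs_)
    if n < 3 + k:
        raise ValueError("need at least 3 complete paired cases beyond covariates")
    if x_.std() == 0 or y_.std() == 0:
        raise ValueError("zero variance in x or y")

    if not covs_:
        if method == "pearson":
            r, p = sps.pearsonr(x_, y_)
        else:
            r, p = sps.spearmanr(x_, y_)
        return StatResult(f"{method}-r", float(r), float(p), n)

    if method == "spearman":
        x_, y_ = _rank(x_), _rank(y_)
        covs_ = [_rank(c) for c in covs_]
    design = np.column_stack([np.ones(n)] + covs_)
    rx = x_ - design @ np.linalg.lstsq(design, x_, rcond=None)[0]
    ry = y_ - design @ np.linalg.lstsq(design, y_, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero residual variance after covariate adjustment")
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 2 - k
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(dof / max(1.0 - r**2, 1e-300))
    p = float(2 * sps.t.sf(abs(t), dof))
    return StatResult(f"partial-{method}-r", r, p, n, details={"dof": dof})


def icc_intra_rater(scores_run1, scores_run2) -> StatResult:
    """Intra-rater reliability: two-way mixed, absolute-agreement,
    single-measure intraclass correlation ICC(A,1) between two scoring runs."""
    r1, r2 = _complete_cases(scores_run1, scores_run2)
    n = len(r1)
    if n < 3:
        raise ValueError("ICC requires at least 3 paired measurements")
    if np.array_equal(r1, r2):
        return StatResult("icc(A,1)", 1.0, 0.0, n)
    long = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["run1", "run2"], n),
            "score": np.concatenate([r1, r2]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc = pg.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
    row = icc.loc["ICC(A,1)"]
    ci_col = "CI95%" if "CI95%" in icc.columns else "CI95"
    return StatResult(
        "icc(A,1)", float(row["ICC"]), float(row["pval"]), n,
        details={"ci95": tuple(row[ci_col])},
    )


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "location",
    subject: str = "subject",
    between: str | None = "group",
) -> list[StatResult]:
    """Mixed-design repeated-measures ANOVA over region location, with a
    between-subject group factor when present.

    Falls back to a one-way repeated-measures ANOVA when only one group level
    exists.  Pairwise location contrasts are Bonferroni-adjusted.  Normality
    is screened per (group, location) cell with Shapiro-Wilk and violations
    are logged as warnings.
    """
    data = table.dropna(subset=[dv]).copy()
    if data.empty:
        raise ValueError("empty table")
    cells = [within] if between is None else [between, within]
    for key, cell in data.groupby(cells, observed=True):
        vals = cell[dv].to_numpy(float)
        if len(vals) < 2:
            raise ValueError(f"cell {key} has fewer than 2 observations")
        if np.ptp(vals) == 0:
            raise ValueError(f"cell {key} is degenerate (all values identical)")
        if 3 <= len(vals) <= 5000:
            w, p_sw = sps.shapiro(vals)
            if p_sw < 0.05:
                logger.warning(
                    "normality questionable in cell %s (Shapiro W=%.3f, p=%.3g)",
                    key, w, p_sw,
                )

    n_between = data[between].nunique() if between is not None else 1
    results: list[StatResult] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if between is not None and n_between >= 2:
            aov = pg.mixed_anova(
                data=data, dv=dv, within=within, subject=subject,
                between=between, correction="auto",
            )
            for _, row in aov.iterrows():
                results.append(
                    StatResult(
                        f"mixed-anova:{row['Source']}",
                        float(row["F"]),
                        float(_anova_p(row, aov.columns)),
                        int(data[subject].nunique()),
                        details={"df1": row["DF1"], "df2": row["DF2"]},
                    )
                )
        else:
            aov = pg.rm_anova(
                data=data, dv=dv, within=within, subject=subject, correction="auto",
            )
            row = aov.iloc[0]
            results.append(
                StatResult(
                    f"rm-anova:{within}",
                    float(row["F"]),
                    float(_anova_p(row, aov.columns)),
                    int(data[subject].nunique()),
                    details={"ddof1": row["ddof1"], "ddof2": row["ddof2"]},
                )
            )
        pw = pg.pairwise_tests(
            data=data, dv=dv, within=within, subject=subject,
            padjust="bonf",
        )
    p_unc_col = _first_col(pw.columns, "p_unc", "p-unc")
    p_corr_col = _first_col(pw.columns, "p_corr", "p-corr") or p_unc_col
    for _, row in pw.iterrows():
        if row["Contrast"] != within:
            continue
        results.append(
            StatResult(
                f"contrast:{row['A']}-vs-{row['B']}",
                float(row["T"]),
                float(row[p_unc_col]),
                int(data[subject].nunique()),
                p_adjusted=float(row[p_corr_col]),
            )
        )
    return results


def _first_col(columns, *names) -> str | None:
    for name in names:
        if name in columns:
            return name
    return None


def _anova_p(row, columns) -> float:
    """Greenhouse-Geisser-corrected p when pingouin reports one (sphericity
    rejected), else the uncorrected p."""
    gg = _first_col(columns, "p_GG_corr", "p-GG-corr")
    if gg is not None and np.isfinite(row[gg]):
        return row[gg]
    return row[_first_col(columns, "p_unc", "p-unc")]
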