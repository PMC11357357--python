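"""Module-labelled change scores and longitudinal group contrasts.

Change scores are differences of a measure between consecutive 3-month
timepoints, labelled by the module the subject's cohort trained over that
interval.  Contrasts are Wald tests on the module indicator in a linear
model with age and sex covariates and, when subjects contribute multiple
intervals, a random intercept per subject.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth import INTERVALS, RETEST, module_schedule

__all__ = [
    "build_change_records",
    "ContrastResult",
    "fit_contrast",
    "cohens_d",
    "correct_multiplicity",
    "associate_change",
]

logger = logging.getLogger(__name__)


def build_change_records(
    measures: pd.DataFrame,
    subjects: pd.DataFrame,
    intervals=INTERVALS,
) -> pd.DataFrame:
    """Difference scores over consecutive intervals, labelled by module.

    ``measures`` is long: ``subject_id, timepoint, measure, value``.
    ``subjects`` carries ``subject_id, cohort, age, sex``.  A record is
    emitted only when both interval endpoints are present; intervals where a
    cohort has no scheduled activity produce no record.
    """
    meta = subjects.set_index("subject_id")
    wide = measures.pivot_table(
        index=["subject_id", "measure"], columns="timepoint", values="value",
        aggfunc="first",
    )
    rows = []
    for (sid, measure), vals in wide.iterrows():
        cohort = meta.loc[sid, "cohort"]
        for ta, tb in intervals:
            module = module_schedule(cohort, (ta, tb))
            if module is None:
                continue
            va, vb = vals.get(ta, np.nan), vals.get(tb, np.nan)
            if np.isnan(va) or np.isnan(vb):
                logger.debug("no %s change for %s over (%s,%s): missing endpoint",
                             measure, sid, ta, tb)
                continue
            rows.append((sid, cohort, module, ta, tb, measure,
                         float(vb - va), float(meta.loc[sid, "age"]),
                         meta.loc[sid, "sex"]))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "cohort", "module", "interval_start",
                 "interval_end", "measure", "delta", "age", "sex"],
    )


@dataclass
class ContrastResult:
    contrast: str
    t: float
    p: float
    d: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    model: str
    q: float | None = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "contrast": self.contrast, "t": self.t, "p": self.p, "q": self.q,
            "d": self.d, "n_a": self.n_a, "n_b": self.n_b,
            "mean_a": self.mean_a, "mean_b": self.mean_b,
            "sd_a": self.sd_a, "sd_b": self.sd_b,
            "ci_a": list(self.ci_a), "ci_b": list(self.ci_b),
            "model": self.model,
        }


def _mixed_wald(y: np.ndarray, X: np.ndarray, groups: np.ndarray, col: int = 1):
    """Wald (coef, se, t) for one column of a mixed model with random intercept.

    Columns and the response are standardized internally for numerical
    stability (the t statistic is invariant); the coefficient is returned on
    the original scale.
    """
    import statsmodels.api as sm

    sy = y.std() or 1.0
    scales = np.ones(X.shape[1])
    for j in range(1, X.shape[1]):
        s = X[:, j].std()
        scales[j] = s if s > 0 else 1.0
    Xs = X / scales
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y / sy, Xs, groups=groups)
        try:
            fit = model.fit(reml=True, method="lbfgs")
            if not np.isfinite(fit.bse_fe[col]):
                raise ValueError("non-finite SE")
        except (np.linalg.LinAlgError, ValueError):
            fit = model.fit(reml=True, method="powell")
        coef = float(fit.fe_params[col]) * sy / scales[col]
        se = float(fit.bse_fe[col]) * sy / scales[col]
    if not (np.isfinite(coef) and np.isfinite(se) and se > 0):
        raise ValueError("mixed model produced a non-finite Wald statistic")
    return coef, se, coef / se


def _arm_descriptives(deltas: np.ndarray):
    n = len(deltas)
    m = float(deltas.mean())
    sd = float(deltas.std(ddof=1)) if n > 1 else float("nan")
    if n > 1 and np.isfinite(sd):
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        ci = (m - half, m + half)
    else:
        ci = (float("nan"), float("nan"))
    return n, m, sd, ci


def fit_contrast(
    records: pd.DataFrame,
    arm_a: str,
    arm_b: str,
    covariates: tuple[str, ...] = ("age", "sex"),
    contrast_name: str | None = None,
) -> ContrastResult:
    """Wald t for arm_a vs arm_b on change scores.

    Fits ``delta ~ arm + covariates`` with a random intercept per subject
    when any subject contributes more than one record; otherwise ordinary
    least squares (which without covariates reproduces the classical pooled
    two-sample t exactly).  Positive t means arm_a > arm_b.  Two-sided p
    from a t distribution with residual degrees of freedom.
    """
    import statsmodels.api as sm

    df = records[records["module"].isin([arm_a, arm_b])].copy()
    na, nb = (df["module"] == arm_a).sum(), (df["module"] == arm_b).sum()
    if na < 2 or nb < 2:
        raise ValueError(f"need >= 2 records per arm, got {na}/{nb}")
    df["arm"] = (df["module"] == arm_a).astype(float)

    X = [np.ones(len(df)), df["arm"].to_numpy(float)]
    names = ["const", "arm"]
    for cov in covariates:
        v = df[cov]
        if v.dtype == object:
            v = (v == sorted(v.unique())[0]).astype(float)
        X.append(v.to_numpy(float))
        names.append(cov)
    X = np.column_stack(X)
    y = df["delta"].to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")

    repeated = df["subject_id"].duplicated().any()
    if repeated:
        coef, se, _ = _mixed_wald(y, X, df["subject_id"].to_numpy())
        dof = len(df) - X.shape[1]
        desc = "mixedlm"
    else:
        fit = sm.OLS(y, X).fit()
        coef, se = fit.params[1], fit.bse[1]
        dof = fit.df_resid
        desc = "ols"
    tval = float(coef / se)
    p = float(2 * stats.t.sf(abs(tval), dof))

    da = df.loc[df["arm"] == 1, "delta"].to_numpy()
    db = df.loc[df["arm"] == 0, "delta"].to_numpy()
    n_a, m_a, sd_a, ci_a = _arm_descriptives(da)
    n_b, m_b, sd_b, ci_b = _arm_descriptives(db)
    design = "within" if repeated else "between"
    d = cohens_d(tval, n_a, n_b, design=design)
    return ContrastResult(
        contrast=contrast_name or f"{arm_a} vs {arm_b}",
        t=tval, p=p, d=d, n_a=n_a, n_b=n_b,
        mean_a=m_a, mean_b=m_b, sd_a=sd_a, sd_b=sd_b,
        ci_a=ci_a, ci_b=ci_b, model=desc,
    )


def cohens_d(t: float, n1: int, n2: int | None = None,
             design: str = "between") -> float:
    """Effect size from a t statistic.

    between: d = t * sqrt(1/n1 + 1/n2); within/one-sample: d = t / sqrt(n1),
    with n1 the number of paired subjects.
    """
    if n1 <= 0 or (design == "between" and (n2 is None or n2 <= 0)):
        raise ValueError("sample sizes must be positive")
    if design == "between":
        return float(t * np.sqrt(1.0 / n1 + 1.0 / n2))
    if design in ("within", "one-sample"):
        return float(t / np.sqrt(n1))
    raise ValueError(f"unknown design: {design!r}")


def correct_multiplicity(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values or Bonferroni-adjusted p."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method != "bh":
        raise ValueError(f"unknown method: {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def associate_change(
    brain: pd.DataFrame,
    cortisol: pd.DataFrame,
    brain_measure: str,
    cortisol_measure: str,
    modules: list[str] | None = None,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> ContrastResult:
    """Regress a brain change score on a cortisol change score.

    Both inputs are change-record tables; rows are paired on
    (subject_id, interval_start).  With a single-module filter an OLS fit is
    used; pooled over modules a random subject intercept is added.  The
    returned ``t`` carries the sign of the cortisol coefficient.
    """
    import statsmodels.api as sm

    b = brain[brain["measure"] == brain_measure]
    c = cortisol[cortisol["measure"] == cortisol_measure]
    if modules is not None:
        b = b[b["module"].isin(modules)]
    merged = b.merge(
        c[["subject_id", "interval_start", "delta"]],
        on=["subject_id", "interval_start"],
        suffixes=("", "_cort"),
    ).dropna(subset=["delta", "delta_cort"])
    n = len(merged)
    if n < len(covariates) + 2:
        raise ValueError(f"too few paired records: n={n}")
    if merged["delta_cort"].nunique() <= 1:
        raise ValueError("cortisol change score has zero variance")

    X = [np.ones(n), merged["delta_cort"].to_numpy(float)]
    for cov in covariates:
        v = merged[cov]
        if v.dtype == object:
            v = (v == sorted(v.unique())[0]).astype(float)
        X.append(v.to_numpy(float))
    X = np.column_stack(X)
    y = merged["delta"].to_numpy(float)

    repeated = merged["subject_id"].duplicated().any()
    if repeated:
        coef, se, _ = _mixed_wald(y, X, merged["subject_id"].to_numpy())
        dof = n - X.shape[1]
        desc = "mixedlm"
    else:
        fit = sm.OLS(y, X).fit()
        coef, se = fit.params[1], fit.bse[1]
        dof = fit.df_resid
        desc = "ols"
    tval = float(coef / se)
    p = float(2 * stats.t.sf(abs(tval), dof))
    dvals = merged["delta"].to_numpy()
    n_a, m_a, sd_a, ci_a = _arm_descriptives(dvals)
    return ContrastResult(
        contrast=f"{brain_measure} ~ {cortisol_measure}"
                 + (f" [{'+'.join(modules)}]" if modules else " [pooled]"),
        t=tval, p=p, d=float("nan"), n_a=n_a, n_b=0,
        mean_a=m_a, mean_b=float("nan"), sd_a=sd_a, sd_b=float("nan"),
        ci_a=ci_a, ci_b=(float("nan"), float("nan")), model=desc,
        extra={"slope": float(coef), "sign": int(np.sign(coef))},
    )
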