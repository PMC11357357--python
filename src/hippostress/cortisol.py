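"""Diurnal saliva cortisol cleaning and summary indices, plus hair change scores.

The cleaning order is fixed: natural-log transform, winsorization at a
mean +/- k*SD boundary computed across the full sample (per sampling occasion
by default), averaging of the two sampling days, then index computation.

Indices on the log scale:

* CAR   — awakening-to-peak change score, peak chosen among the 30- and
          60-min samples; if the awakening sample exceeds both, the 30-min
          sample operationalizes an inverse CAR.
* slope — change score from awakening to the final (600-min) sample.
* AUCg  — trapezoidal area with respect to ground over the awakening, 240,
          360, 480 and 600-min samples; the 30/60-min samples never enter.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

__all__ = [
    "AUCG_OFFSETS",
    "log_transform",
    "winsorize_3sd",
    "average_days",
    "compute_car",
    "compute_slope",
    "compute_aucg",
    "diurnal_indices",
    "hair_change",
]

logger = logging.getLogger(__name__)

AUCG_OFFSETS = (0, 240, 360, 480, 600)
CAR_OFFSETS = (0, 30, 60)


def log_transform(saliva: pd.DataFrame, value_col: str = "nmol_l") -> pd.DataFrame:
    """Natural-log transform raw concentrations into a ``log_value`` column.

    Non-positive concentrations are outside the domain of the log; the rows
    are flagged invalid, excluded, and counted in a warning.
    """
    out = saliva.copy()
    vals = out[value_col].astype(float)
    bad = ~(vals > 0) & vals.notna()
    if bad.any():
        logger.warning("excluding %d non-positive concentration(s)", int(bad.sum()))
        out = out.loc[~bad].copy()
        vals = vals.loc[~bad]
    out["log_value"] = np.log(vals)
    return out


def winsorize_3sd(values, k: float = 3.0) -> np.ndarray:
    """Clip values beyond mean +/- k*SD of the input vector to the boundary.

    Mean and SD are computed in a single pass with outliers included; missing
    values propagate unchanged.  Requires at least 3 non-missing values.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 3:
        raise ValueError("winsorize_3sd requires >= 3 non-missing values")
    m = v[finite].mean()
    sd = v[finite].std(ddof=1)
    lo, hi = m - k * sd, m + k * sd
    out = v.copy()
    out[finite] = np.clip(v[finite], lo, hi)
    return out


def average_days(profile: pd.DataFrame, value_col: str = "log_value") -> pd.Series:
    """Mean per occasion over available days for one subject-timepoint.

    Occasions present on a single day use that day's value; occasions missing
    on both days stay missing.  Returns a series indexed by ``offset_min``.
    """
    return profile.groupby("offset_min")[value_col].mean()


def _get(series: pd.Series, offset: int) -> float:
    v = series.get(offset, np.nan)
    return float(v) if v is not None else math.nan


def compute_car(series: pd.Series) -> float:
    """Awakening response from a day-averaged 7-occasion series.

    nan when the awakening sample is missing, when neither post-awakening
    sample is available, or when the inverse-CAR rule needs a missing
    30-min sample.
    """
    s0 = _get(series, 0)
    s30 = _get(series, 30)
    s60 = _get(series, 60)
    if math.isnan(s0) or (math.isnan(s30) and math.isnan(s60)):
        return math.nan
    peak = np.nanmax([s30, s60])
    if s0 >= peak:
        # peak at awakening: inverse CAR via the 30-min sample
        return s30 - s0 if not math.isnan(s30) else math.nan
    return float(peak - s0)


def compute_slope(series: pd.Series) -> float:
    """Awakening-to-600-min change score (negative = diurnal decline)."""
    s0 = _get(series, 0)
    s600 = _get(series, 600)
    if math.isnan(s0) or math.isnan(s600):
        return math.nan
    return s600 - s0


def compute_aucg(series: pd.Series, offsets=AUCG_OFFSETS) -> float:
    """Trapezoidal area under the diurnal curve with respect to ground.

    All included occasions must be present: the trapezoid weights depend on
    the time gaps, so no interpolation is attempted.
    """
    t = np.asarray(offsets, dtype=float)
    y = np.array([_get(series, int(o)) for o in offsets])
    if np.isnan(y).any():
        return math.nan
    return float(np.trapezoid(y, t))


def diurnal_indices(
    saliva: pd.DataFrame,
    winsorize: bool = True,
    sd_limit: float = 3.0,
    per_occasion: bool = True,
    use_actual_times: bool = False,
) -> pd.DataFrame:
    """Full cleaning + index pipeline over a long saliva table.

    Expects columns ``subject_id, timepoint, day, offset_min, nmol_l`` (and
    ``actual_min`` when ``use_actual_times``).  Winsorization boundaries are
    estimated across the full sample, per designed occasion by default or
    pooled over all samples otherwise.  Returns one row per
    subject-timepoint with ``car, slope, aucg`` and per-index sample counts.
    """
    cols = ["subject_id", "timepoint", "car", "slope", "aucg",
            "n_car", "n_slope", "n_aucg"]
    if saliva.empty:
        return pd.DataFrame(columns=cols)
    df = log_transform(saliva)
    if winsorize and len(df) >= 3:
        if per_occasion:
            df["log_value"] = df.groupby("offset_min")["log_value"].transform(
                lambda v: winsorize_3sd(v, k=sd_limit)
            )
        else:
            df["log_value"] = winsorize_3sd(df["log_value"].to_numpy(), k=sd_limit)

    if use_actual_times:
        return _indices_slow(df, cols)

    # day averaging then vectorized index computation over all profiles
    wide = (
        df.groupby(["subject_id", "timepoint", "offset_min"])["log_value"]
        .mean()
        .unstack("offset_min")
    )
    for off in (0, 30, 60, 240, 360, 480, 600):
        if off not in wide.columns:
            wide[off] = np.nan
    s = {off: wide[off].to_numpy(float) for off in wide.columns}

    with np.errstate(invalid="ignore"):
        peak = np.fmax(s[30], s[60])
        car = np.where(s[0] >= peak, s[30] - s[0], peak - s[0])
    car = np.where(np.isnan(s[0]) | np.isnan(peak), np.nan, car)
    slope = s[600] - s[0]
    # trapezoid weights for the 0/240/360/480/600-min grid
    weights = np.diff(AUCG_OFFSETS, prepend=AUCG_OFFSETS[0],
                      append=AUCG_OFFSETS[-1])
    weights = (weights[:-1] + weights[1:]) / 2.0
    Y = np.column_stack([s[o] for o in AUCG_OFFSETS])
    aucg = Y @ weights
    aucg[np.isnan(Y).any(axis=1)] = np.nan

    out = pd.DataFrame({
        "car": car, "slope": slope, "aucg": aucg,
        "n_car": sum(~np.isnan(s[o]) for o in CAR_OFFSETS),
        "n_slope": sum(~np.isnan(s[o]) for o in (0, 600)),
        "n_aucg": sum(~np.isnan(s[o]) for o in AUCG_OFFSETS),
    }, index=wide.index).reset_index()
    n_missing = int(np.isnan(aucg).sum())
    if n_missing:
        logger.debug("AUCg undefined for %d profile(s)", n_missing)
    return out[cols]


def _indices_slow(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Per-profile path used when trapezoids run over actual sampling times."""
    rows = []
    for (sid, tp), grp in df.groupby(["subject_id", "timepoint"], sort=True):
        series = average_days(grp)
        times = grp.groupby("offset_min")["actual_min"].mean()
        car = compute_car(series)
        slope = compute_slope(series)
        if not any(math.isnan(_get(series, o)) for o in AUCG_OFFSETS):
            t = np.array([times[o] for o in AUCG_OFFSETS], dtype=float)
            y = np.array([_get(series, o) for o in AUCG_OFFSETS])
            aucg = float(np.trapezoid(y, t))
        else:
            aucg = math.nan
        present = set(series.dropna().index)
        rows.append((
            sid, tp, car, slope, aucg,
            len(present & set(CAR_OFFSETS)),
            len(present & {0, 600}),
            len(present & set(AUCG_OFFSETS)),
        ))
    return pd.DataFrame(rows, columns=cols)


def hair_change(hair: pd.DataFrame, log: bool = True) -> pd.DataFrame:
    """Per-interval change in hair steroid accumulation.

    Segments are labelled by the timepoint at which the strand was taken;
    the change over interval (Ta, Tb) is segment(Tb) - segment(Ta), with a
    natural-log transform first by default.  Returns columns
    ``subject_id, interval_start, interval_end, d_cortisol, d_cortisone``.
    """
    rows = []
    value_cols = ["cortisol_pg_mg", "cortisone_pg_mg"]
    for sid, grp in hair.groupby("subject_id", sort=True):
        grp = grp.set_index("segment")
        segs = [s for s in sorted(grp.index)]
        for a, b in zip(segs[:-1], segs[1:]):
            va = grp.loc[a, value_cols].astype(float)
            vb = grp.loc[b, value_cols].astype(float)
            if log:
                if (va <= 0).any() or (vb <= 0).any():
                    logger.warning("non-positive hair value for %s, skipping", sid)
                    continue
                va, vb = np.log(va), np.log(vb)
            rows.append((sid, a, b,
                         float(vb.iloc[0] - va.iloc[0]),
                         float(vb.iloc[1] - va.iloc[1])))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "interval_start", "interval_end",
                 "d_cortisol", "d_cortisone"],
    )
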