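"""Group-level inference across days.

Each impact day is compared to baseline region by region with a paired
one-tailed contrast (the planned pairwise comparison of a
repeated-measures design; the omnibus within-subject F is computed and
logged but does not gate anything). Missing sessions are filled by mean
imputation over observed subjects. Multiplicity is controlled with a
dual gate: raw one-tailed p < alpha AND Benjamini-Hochberg significance
at FDR q over the whole contrast family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionDayMatrix",
    "matrix_from_records",
    "mean_impute",
    "paired_one_tailed",
    "region_day_vs_baseline",
    "bh_fdr",
    "volume_affected_by_day",
    "significance_stars",
]

BASELINE = "baseline"


@dataclass
class RegionDayMatrix:
    """subject x day x region slopes (%/s) with an explicit missing mask."""

    slopes: np.ndarray
    missing: np.ndarray
    subjects: list[str]
    days: list[str]
    region_ids: list[int]

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.slopes.shape != self.missing.shape:
            raise ValueError("slopes and missing mask must share shape")
        if self.slopes.shape != (len(self.subjects), len(self.days), len(self.region_ids)):
            raise ValueError("shape must be (subjects, days, regions)")
        if BASELINE not in self.days:
            raise ValueError("baseline day column required")
        b = self.days.index(BASELINE)
        if self.missing[:, b, :].any():
            raise ValueError("baseline must be observed for every subject")

    def day_index(self, day: str) -> int:
        return self.days.index(day)


def matrix_from_records(df: pd.DataFrame) -> RegionDayMatrix:
    """Build the matrix from long-format per-session region tables.

    Expects columns ``subject_id``, ``day_label``, ``region``,
    ``slope_pct_per_s``. (subject, day) pairs absent from the table are
    marked missing.
    """
    subjects = sorted(df["subject_id"].unique())
    days = [d for d in ["baseline", "hit1", "hit2", "hit3"] if d in set(df["day_label"])]
    extra = sorted(set(df["day_label"]) - set(days))
    days = days + extra
    regions = sorted(df["region"].unique())
    slopes = np.full((len(subjects), len(days), len(regions)), np.nan)
    missing = np.ones_like(slopes, dtype=bool)
    pos = {
        (s, d, r): (i, j, k)
        for i, s in enumerate(subjects)
        for j, d in enumerate(days)
        for k, r in enumerate(regions)
    }
    for rec in df.itertuples():
        i, j, k = pos[(rec.subject_id, rec.day_label, rec.region)]
        slopes[i, j, k] = rec.slope_pct_per_s
        missing[i, j, k] = False
    return RegionDayMatrix(slopes, missing, subjects, days, [int(r) for r in regions])


def mean_impute(matrix: RegionDayMatrix) -> RegionDayMatrix:
    """Replace missing entries by the (day, region) mean over observed.

    The missing mask is preserved for audit; a (day, region) column
    with no observed subject at all is an error.
    """
    slopes = matrix.slopes.copy()
    for j, day in enumerate(matrix.days):
        for k, rid in enumerate(matrix.region_ids):
            miss = matrix.missing[:, j, k]
            if not miss.any():
                continue
            if miss.all():
                raise ValueError(f"no observed subject for day={day!r} region={rid}")
            slopes[miss, j, k] = slopes[~miss, j, k].mean()
    return RegionDayMatrix(
        slopes, matrix.missing.copy(), list(matrix.subjects),
        list(matrix.days), list(matrix.region_ids),
    )


def paired_one_tailed(day_values: np.ndarray, baseline_values: np.ndarray) -> tuple[float, float, float, bool]:
    """Paired one-tailed t test, H1: day > baseline.

    Returns (mean difference, t, one-tailed p, degenerate flag). With
    zero variance of the differences the p value is set by sign
    convention (0 all positive, 1 all negative, 0.5 all zero) and the
    result is flagged degenerate.
    """
    diffs = np.asarray(day_values, dtype=float) - np.asarray(baseline_values, dtype=float)
    n = len(diffs)
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    effect = float(diffs.mean())
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.all(diffs > 0):
            return effect, float("inf"), 0.0, True
        if np.all(diffs < 0):
            return effect, float("-inf"), 1.0, True
        return effect, 0.0, 0.5, True
    res = stats.ttest_rel(day_values, baseline_values, alternative="greater")
    return effect, float(res.statistic), float(res.pvalue), False


def _rm_anova_f(data: np.ndarray) -> tuple[float, float]:
    """Classic one-way within-subject F over days (logged only)."""
    n_sub, n_day = data.shape
    grand = data.mean()
    ss_day = n_sub * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_sub = n_day * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_day - ss_sub
    df_day = n_day - 1
    df_err = (n_sub - 1) * (n_day - 1)
    if ss_err <= 0 or df_err == 0:
        return float("inf"), 0.0
    f = (ss_day / df_day) / (ss_err / df_err)
    return float(f), float(stats.f.sf(f, df_day, df_err))


def region_day_vs_baseline(
    matrix: RegionDayMatrix,
    q: float = 0.1,
    alpha_gate: float = 0.05,
    impute: bool = True,
) -> pd.DataFrame:
    """Per-(region, day) paired contrasts vs baseline with the BH gate.

    Returns one row per region and non-baseline day with columns
    ``region``, ``day_label``, ``effect`` (mean slope difference,
    %/s), ``t``, ``p_one_tailed``, ``degenerate``, ``q_significant``,
    plus the logged per-region rmANOVA ``f_omnibus``/``p_omnibus``.
    """
    if len(matrix.subjects) < 3:
        raise ValueError("need at least 3 subjects")
    m = mean_impute(matrix) if impute else matrix
    b = m.day_index(BASELINE)
    rows = []
    for k, rid in enumerate(m.region_ids):
        f_omni, p_omni = _rm_anova_f(m.slopes[:, :, k])
        for j, day in enumerate(m.days):
            if day == BASELINE:
                continue
            effect, t, p, degen = paired_one_tailed(m.slopes[:, j, k], m.slopes[:, b, k])
            rows.append({
                "region": rid,
                "day_label": day,
                "effect": effect,
                "t": t,
                "p_one_tailed": p,
                "degenerate": degen,
                "f_omnibus": f_omni,
                "p_omnibus": p_omni,
            })
    df = pd.DataFrame(rows)
    df["q_significant"] = bh_fdr(df["p_one_tailed"].to_numpy(), q=q, alpha_gate=alpha_gate)
    return df


def bh_fdr(p_values, q: float = 0.1, alpha_gate: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up at rate ``q`` with a raw-p gate.

    A hypothesis is flagged iff it is BH-significant at FDR ``q`` over
    the whole family AND its raw p is below ``alpha_gate`` (the dual
    condition). Set ``alpha_gate=1`` for plain BH.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    passing = ranked <= (np.arange(1, m + 1) * q / m)
    flags = np.zeros(m, dtype=bool)
    if passing.any():
        k_max = int(np.nonzero(passing)[0].max())
        flags[order[: k_max + 1]] = True
    return flags & (p < alpha_gate)


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def volume_affected_by_day(
    records: pd.DataFrame,
    q: float = 0.1,
    alpha_gate: float = 0.05,
) -> pd.DataFrame:
    """Day-wise comparison of percent-brain-volume-affected vs baseline.

    ``records`` is long format with columns ``subject_id``,
    ``day_label``, ``percent_of_brain``. Missing (subject, day) cells
    are mean-imputed. Returns per non-baseline day: mean, sd, paired
    one-tailed p, BH-gated significance flag and star annotation; the
    baseline row carries only the descriptive statistics.
    """
    wide = records.pivot_table(
        index="subject_id", columns="day_label", values="percent_of_brain",
        dropna=False,
    )
    if BASELINE not in wide.columns:
        raise ValueError("baseline records required")
    if wide[BASELINE].isna().any():
        raise ValueError("baseline must be observed for every subject")
    if len(wide) < 3:
        raise ValueError("need at least 3 subjects")
    wide = wide.apply(lambda col: col.fillna(col.mean()))
    ordered = [d for d in ["baseline", "hit1", "hit2", "hit3"] if d in wide.columns]
    ordered += [d for d in wide.columns if d not in ordered]

    rows = []
    tests = []
    for day in ordered:
        row = {
            "day_label": day,
            "mean_percent": float(wide[day].mean()),
            "sd_percent": float(wide[day].std(ddof=1)),
        }
        if day != BASELINE:
            effect, t, p, degen = paired_one_tailed(
                wide[day].to_numpy(), wide[BASELINE].to_numpy()
            )
            row.update(effect=effect, t=t, p_one_tailed=p, degenerate=degen)
            tests.append(row)
        else:
            row.update(effect=0.0, t=np.nan, p_one_tailed=np.nan, degenerate=False)
        rows.append(row)
    df = pd.DataFrame(rows)
    test_mask = df["day_label"] != BASELINE
    flags = bh_fdr(df.loc[test_mask, "p_one_tailed"].to_numpy(), q=q, alpha_gate=alpha_gate)
    df["significant"] = False
    df.loc[test_mask, "significant"] = flags
    df["stars"] = [
        significance_stars(p) if sig else ""
        for p, sig in zip(df["p_one_tailed"], df["significant"])
    ]
    return df
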