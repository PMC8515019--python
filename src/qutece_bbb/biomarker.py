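"""Apparent-CBV time series, leak slopes, and per-subject inference.

The biomarker is the slope of apparent CBV over the seven post-contrast
scans, expressed as percent change of apparent CBV per second.
Per-voxel apparent CBV is the linear mixing quotient against per-scan
pure-blood and pure-tissue reference intensities; the default analysis
unit is the atlas region (voxel-then-average), with voxelwise maps
available for display. Per-subject significance uses a one-tailed
linear regression with Bonferroni control over the tested family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import AtlasLabels
from .preprocess import ScanSession
from .signal_model import CompartmentSignals, apparent_cbv

__all__ = [
    "CbvSeries",
    "SlopeResult",
    "VolumeAffected",
    "compartment_refs",
    "region_cbv_series",
    "cbv_slope",
    "quantify_session",
    "subject_leak_map",
    "percent_volume_affected",
    "voxel_slope_map",
]


@dataclass
class CbvSeries:
    """Apparent-CBV values over the post-contrast scans for one unit."""

    values: np.ndarray
    timestamps: np.ndarray
    scope: str = "region"  # or "voxel"
    unit_id: int | tuple = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.values.shape != self.timestamps.shape:
            raise ValueError("values and timestamps must have equal length")
        # "region-absent" is an explicit marker series and may be NaN
        if self.scope != "region-absent" and not np.all(np.isfinite(self.values)):
            raise ValueError("CBV series must be finite")


@dataclass
class SlopeResult:
    """One-tailed OLS slope of a CBV series.

    ``slope_pct_per_s`` is the raw slope normalized by the fitted
    intercept (apparent CBV at t = 0) times 100; if the intercept is
    not positive the series mean is used instead and ``normalization``
    records the fallback.
    """

    slope_pct_per_s: float
    slope_raw: float
    intercept: float
    t_statistic: float
    p_one_tailed: float
    normalization: str = "intercept"


@dataclass
class VolumeAffected:
    subject_id: str
    day_label: str
    percent_of_brain: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_of_brain <= 100.0:
            raise ValueError("percent_of_brain must lie in [0, 100]")


def compartment_refs(session: ScanSession, atlas: AtlasLabels) -> list[CompartmentSignals]:
    """Per-post-scan reference intensities from the designated masks.

    Blood reference = mean over the pure-blood pool label, evaluated on
    each post-contrast volume separately so blood-pool clearance is
    tracked. The tissue reference label is agent-free by construction,
    so its intensity is pooled over all post-contrast scans: a per-scan
    tissue reference would inject a common-mode noise trend into every
    region's CBV series and inflate the slope statistics.
    """
    if atlas.blood_mask is None or atlas.tissue_mask is None:
        raise ValueError("atlas must provide blood and tissue reference masks")
    tissue_pooled = float(
        np.mean([vol[atlas.tissue_mask].mean() for vol in session.post_volumes])
    )
    refs = []
    for vol, t in zip(session.post_volumes, session.post_times):
        refs.append(
            CompartmentSignals(
                blood_intensity=float(vol[atlas.blood_mask].mean()),
                tissue_intensity=tissue_pooled,
                timestamp=float(t),
            )
        )
    return refs


def region_cbv_series(
    session: ScanSession,
    atlas: AtlasLabels,
    refs: list[CompartmentSignals] | None = None,
) -> dict[int, CbvSeries]:
    """Apparent-CBV series per atlas region (voxel CBV, then average).

    Regions present in the table but empty on the grid are returned
    with an all-NaN marker series rather than silently dropped.
    """
    refs = refs if refs is not None else compartment_refs(session, atlas)
    if len(refs) != len(session.post_volumes):
        raise ValueError("need one reference pair per post-contrast scan")
    out: dict[int, CbvSeries] = {}
    times = session.post_times
    labels = atlas.labels
    region_masks = {rid: labels == rid for rid in atlas.region_ids}
    cbv_stack = [apparent_cbv(vol, ref) for vol, ref in zip(session.post_volumes, refs)]
    for rid, mask in region_masks.items():
        if not mask.any():
            out[int(rid)] = CbvSeries(
                values=np.full(len(times), np.nan),
                timestamps=times,
                scope="region-absent",
                unit_id=int(rid),
            )
            continue
        values = np.asarray([float(c[mask].mean()) for c in cbv_stack])
        out[int(rid)] = CbvSeries(values=values, timestamps=times, scope="region",
                                  unit_id=int(rid))
    return out


def cbv_slope(series: CbvSeries, normalization: str = "intercept") -> SlopeResult:
    """One-tailed OLS slope of apparent CBV on time, in %/s.

    H1: slope > 0 (contrast agent accumulating in tissue); p from the
    t distribution with n - 2 degrees of freedom. A perfectly linear
    series has zero residual and its p is clamped to 0 (increasing),
    1 (decreasing) or 0.5 (constant).
    """
    t = series.timestamps
    y = series.values
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if np.ptp(t) == 0:
        raise ValueError("zero time variance")
    res = stats.linregress(t, y)
    slope, intercept, stderr = res.slope, res.intercept, res.stderr
    if stderr == 0 or not np.isfinite(stderr):
        t_stat = np.inf * np.sign(slope) if slope != 0 else 0.0
        p_one = 0.0 if slope > 0 else (1.0 if slope < 0 else 0.5)
    else:
        t_stat = slope / stderr
        p_one = float(stats.t.sf(t_stat, df=len(t) - 2))
    denom = intercept
    used = normalization
    if normalization == "mean" or denom <= 0:
        denom = float(np.mean(y))
        used = "mean"
    if denom == 0:
        raise ValueError("cannot normalize slope: zero intercept and mean")
    return SlopeResult(
        slope_pct_per_s=float(slope / denom * 100.0),
        slope_raw=float(slope),
        intercept=float(intercept),
        t_statistic=float(t_stat),
        p_one_tailed=p_one,
        normalization=used,
    )


def quantify_session(
    session: ScanSession,
    atlas: AtlasLabels,
    alpha: float = 0.1,
    correction: str = "bonferroni",
    normalization: str = "intercept",
) -> pd.DataFrame:
    """Region table for one session: slope, t, one-tailed p, flags.

    Columns: region, name, hemisphere, n_voxels, slope_pct_per_s, t,
    p_one_tailed, significant, family_size. Significance is one-tailed
    p <= alpha / family (Bonferroni over the regions tested).
    """
    series = region_cbv_series(session, atlas)
    rows = []
    for rid, s in series.items():
        n_vox = int((atlas.labels == rid).sum())
        row = {
            "subject_id": session.subject_id,
            "day_label": session.day_label,
            "region": rid,
            "name": str(atlas.table.loc[atlas.table["id"] == rid, "name"].iloc[0]),
            "hemisphere": atlas.hemisphere_of(rid),
            "n_voxels": n_vox,
        }
        if s.scope == "region-absent":
            row.update(slope_pct_per_s=np.nan, t=np.nan, p_one_tailed=np.nan,
                       absent=True)
        else:
            fit = cbv_slope(s, normalization=normalization)
            row.update(
                slope_pct_per_s=fit.slope_pct_per_s,
                t=fit.t_statistic,
                p_one_tailed=fit.p_one_tailed,
                absent=False,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    return subject_leak_map(df, alpha=alpha, correction=correction)


def subject_leak_map(
    df: pd.DataFrame,
    alpha: float = 0.1,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Flag significant units after family-wise correction.

    Family = all tested (non-absent) units in the table. Slope values
    of non-significant units are masked to NaN in ``slope_masked`` for
    display parity (only significant slopes are shown on leak maps).
    """
    tested = ~df["p_one_tailed"].isna()
    family = int(tested.sum())
    if family == 0:
        raise ValueError("empty test family")
    if correction == "bonferroni":
        threshold = alpha / family
    elif correction == "none":
        threshold = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    df = df.copy()
    df["family_size"] = family
    df["significant"] = tested & (df["p_one_tailed"] <= threshold)
    df["slope_masked"] = df["slope_pct_per_s"].where(df["significant"])
    return df


def percent_volume_affected(leak_map: pd.DataFrame, atlas: AtlasLabels) -> VolumeAffected:
    """Percent of brain voxels belonging to significant regions."""
    total = int(atlas.brain_mask.sum())
    if total == 0:
        raise ValueError("empty brain mask")
    sig_regions = leak_map.loc[leak_map["significant"], "region"]
    affected = int(np.isin(atlas.labels, list(sig_regions)).sum())
    return VolumeAffected(
        subject_id=str(leak_map["subject_id"].iloc[0]),
        day_label=str(leak_map["day_label"].iloc[0]),
        percent_of_brain=100.0 * affected / total,
    )


def voxel_slope_map(
    session: ScanSession,
    atlas: AtlasLabels,
    alpha: float = 0.1,
    correction: str = "bonferroni",
    normalization: str = "intercept",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelwise slope/p maps within the brain (display parity).

    Returns (slope %/s, one-tailed p, significance mask); Bonferroni
    family = number of brain voxels. Vectorized closed-form OLS.
    """
    refs = compartment_refs(session, atlas)
    mask = atlas.brain_mask
    times = session.post_times
    y = np.stack(
        [apparent_cbv(vol, ref)[mask] for vol, ref in zip(session.post_volumes, refs)]
    )  # (n_scans, n_voxels)
    n = len(times)
    tc = times - times.mean()
    sxx = float((tc**2).sum())
    slope = (tc[:, None] * y).sum(axis=0) / sxx
    intercept = y.mean(axis=0) - slope * times.mean()
    resid = y - (intercept[None, :] + slope[None, :] * times[:, None])
    se = np.sqrt((resid**2).sum(axis=0) / (n - 2) / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, slope / se, np.sign(slope) * np.inf)
    p = stats.t.sf(t_stat, df=n - 2)
    denom = np.where(intercept > 0, intercept, y.mean(axis=0))
    slope_pct = slope / denom * 100.0

    family = int(mask.sum())
    thr = alpha / family if correction == "bonferroni" else alpha
    sig = p <= thr

    out_slope = np.full(mask.shape, np.nan)
    out_p = np.full(mask.shape, np.nan)
    out_sig = np.zeros(mask.shape, dtype=bool)
    out_slope[mask] = slope_pct
    out_p[mask] = p
    out_sig[mask] = sig
    return out_slope, out_p, out_sig
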