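"""ROI aggregation with the study's hemisphere rule, outlier filtering,
composite regions, CSF masking and the normalized group-difference map.

The hemisphere rule: control values average both hemispheres; patient values
use only the hemisphere contralateral to the clinically affected body side
(right-affected -> left hemisphere and vice versa), since that hemisphere
drives the affected side.

All tabular interfaces are pandas DataFrames in "region-table" form: one row
per (subject_id, region, hemisphere) with the ROI-mean metric in percent, the
contributing voxel count, and exclusion flags.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import COMPOSITES, RIGHT_OFFSET, REGION_CODES

REGION_TABLE_COLUMNS = ("subject_id", "region", "hemisphere", "value_pct",
                        "n_voxels", "excluded", "reason")


def extract_roi_means(metric_map: np.ndarray, label_volume: np.ndarray,
                      regions: Sequence[str], qc_mask: np.ndarray | None = None,
                      subject_id: str = "") -> pd.DataFrame:
    """Per-hemisphere ROI means of a voxel map.

    Only voxels passing ``qc_mask`` (e.g. converged fits) contribute.  A
    region label absent from the volume (or fully QC-excluded) yields a row
    with ``n_voxels = 0`` and an error flag instead of raising.
    """
    metric = np.asarray(metric_map, dtype=float)
    labels = np.asarray(label_volume)
    if metric.shape != labels.shape:
        raise ValueError("metric map and label volume shapes differ")
    if qc_mask is None:
        qc_mask = np.isfinite(metric)
    else:
        qc_mask = np.asarray(qc_mask, dtype=bool) & np.isfinite(metric)

    rows = []
    for region in regions:
        base = REGION_CODES[region]
        for hemisphere, code in (("left", base), ("right", base + RIGHT_OFFSET)):
            sel = (labels == code) & qc_mask
            n = int(sel.sum())
            rows.append({
                "subject_id": subject_id, "region": region,
                "hemisphere": hemisphere,
                "value_pct": float(metric[sel].mean()) if n else np.nan,
                "n_voxels": n,
                "excluded": n == 0,
                "reason": "" if n else "label absent or fully QC-excluded",
            })
    return pd.DataFrame(rows, columns=list(REGION_TABLE_COLUMNS))


def hemisphere_select(table: pd.DataFrame, group: str, affected_side: str) -> pd.DataFrame:
    """Collapse left/right rows to 'combined' rows for one subject.

    Controls: voxel-count-weighted mean of both hemispheres.  Patients: the
    hemisphere contralateral to the affected side, exactly.
    """
    if group == "PwPD" and affected_side not in ("left", "right"):
        raise ValueError("patient requires an affected side of 'left' or 'right'")
    out = []
    for region, sub in table.groupby("region", sort=False):
        left = sub[sub.hemisphere == "left"].iloc[0]
        right = sub[sub.hemisphere == "right"].iloc[0]
        if group == "HC":
            n = left.n_voxels + right.n_voxels
            value = np.nan if n == 0 else (
                (left.value_pct * left.n_voxels if left.n_voxels else 0.0)
                + (right.value_pct * right.n_voxels if right.n_voxels else 0.0)) / n
            row = dict(subject_id=left.subject_id, region=region,
                       hemisphere="combined", value_pct=value, n_voxels=int(n),
                       excluded=n == 0, reason="" if n else "both hemispheres empty")
        else:
            chosen = left if affected_side == "right" else right
            row = dict(subject_id=chosen.subject_id, region=region,
                       hemisphere="combined", value_pct=chosen.value_pct,
                       n_voxels=int(chosen.n_voxels), excluded=bool(chosen.excluded),
                       reason=chosen.reason)
        out.append(row)
    return pd.DataFrame(out, columns=list(REGION_TABLE_COLUMNS))


def remove_outliers(values: np.ndarray, fence_multiplier: float = 1.5,
                    min_cell: int = 4) -> tuple:
    """Tukey-fence filter for one region x group cell of subject-level values.

    Returns (kept_values, keep_mask, fences).  Cells smaller than
    ``min_cell`` are returned unfiltered with a warning.  The fences always
    contain the interquartile box, so filtering can never empty a cell.
    """
    v = np.asarray(values, dtype=float)
    if v.size < min_cell:
        warnings.warn(f"cell of size {v.size} < {min_cell}: outlier filter skipped")
        return v, np.ones(v.size, dtype=bool), (-np.inf, np.inf)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - fence_multiplier * iqr, q3 + fence_multiplier * iqr
    keep = (v >= lo) & (v <= hi)
    return v[keep], keep, (float(lo), float(hi))


def filter_region_table(table: pd.DataFrame, groups: Mapping[str, str],
                        fence_multiplier: float = 1.5) -> pd.DataFrame:
    """Apply the Tukey rule per (region, group) across subjects on combined
    rows.  Exclusion applies to that region only, never the whole subject;
    flagged rows carry the fence values in ``reason``."""
    table = table.copy()
    table["_group"] = table["subject_id"].map(groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for (region, group), sub in table.groupby(["region", "_group"]):
            usable = sub[~sub.excluded & sub.value_pct.notna()]
            if len(usable) == 0:
                continue
            _, keep, (lo, hi) = remove_outliers(usable.value_pct.to_numpy(),
                                                fence_multiplier)
            out_idx = usable.index[~keep]
            table.loc[out_idx, "excluded"] = True
            table.loc[out_idx, "reason"] = f"outlier (fences [{lo:.4g}, {hi:.4g}])"
    return table.drop(columns="_group")


def composite_value(table: pd.DataFrame, members: Sequence[str]) -> tuple:
    """Voxel-count-weighted mean over member regions (= union-ROI mean).

    Returns (value, n_voxels, partial) where ``partial`` is True if any
    member row is missing or excluded.
    """
    sub = table[table.region.isin(members)]
    present = sub[~sub.excluded & sub.value_pct.notna()]
    partial = (len(sub) < len(members)) or (len(present) < len(sub))
    n = int(present.n_voxels.sum())
    value = float((present.value_pct * present.n_voxels).sum() / n) if n else np.nan
    return value, n, partial


def add_composites(table: pd.DataFrame,
                   composites: Mapping[str, Sequence[str]] = COMPOSITES) -> pd.DataFrame:
    """Append composite-region rows (hemisphere 'combined') per subject."""
    rows = []
    for sid, sub in table.groupby("subject_id", sort=False):
        for name, members in composites.items():
            value, n, partial = composite_value(sub, members)
            rows.append(dict(subject_id=sid, region=name, hemisphere="combined",
                             value_pct=value, n_voxels=n, excluded=n == 0,
                             reason="partial" if partial else ""))
    return pd.concat([table, pd.DataFrame(rows)], ignore_index=True)


def csf_mask(t1w_intensity: np.ndarray, threshold_fraction: float = 0.25) -> np.ndarray:
    """CSF by intensity thresholding: voxels strictly below
    threshold_fraction x robust-max (99th percentile) of the structural
    channel."""
    t1w = np.asarray(t1w_intensity, dtype=float)
    if not np.all(np.isfinite(t1w)):
        raise ValueError("structural intensities must be finite")
    robust_max = float(np.percentile(t1w, 99))
    return t1w < threshold_fraction * robust_max


def difference_map(hc_maps: Sequence[np.ndarray],
                   pwpd_maps_sides: Sequence[tuple],
                   csf: np.ndarray | None = None) -> np.ndarray:
    """Normalized group-average difference map, mean(HC) - mean(PwPD),
    rescaled to [0, 1] over non-missing voxels.

    The patient average pools the hemisphere contralateral to each affected
    side: maps of left-affected patients are mirrored along the first axis so
    their right hemisphere lands on the left-hemisphere template; the pooled
    left-template mean is then reflected to fill both hemispheres.  Higher
    output values mark greater patient signal reduction.  CSF voxels are set
    to NaN.  A constant difference (identical groups) returns all zeros with
    a warning.
    """
    if not len(hc_maps) or not len(pwpd_maps_sides):
        raise ValueError("need at least one subject per group")
    hc_mean = np.mean([np.asarray(m, dtype=float) for m in hc_maps], axis=0)

    pooled = []
    for m, side in pwpd_maps_sides:
        m = np.asarray(m, dtype=float)
        if side == "left":
            m = m[::-1, :, :]       # right hemisphere -> left template
        elif side != "right":
            raise ValueError("patient affected side must be 'left' or 'right'")
        pooled.append(m)
    pd_template = np.mean(pooled, axis=0)
    nx = pd_template.shape[0]
    half = nx // 2
    pd_mean = pd_template.copy()
    pd_mean[nx - half:] = pd_template[:half][::-1]   # reflect left template

    d = hc_mean - pd_mean
    if csf is not None:
        d = np.where(np.asarray(csf, dtype=bool), np.nan, d)
    finite = np.isfinite(d)
    if not finite.any():
        raise ValueError("difference map has no usable voxels")
    lo, hi = np.nanmin(d), np.nanmax(d)
    if hi == lo:
        warnings.warn("constant difference map; returning zeros")
        return np.where(finite, 0.0, np.nan)
    return np.where(finite, (d - lo) / (hi - lo), np.nan)
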