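"""Activation overlap and fingertip-specificity quantification.

Covers thresholded activation masks, exactly-k overlap counts and threshold
sweeps, the adjacent-pair overlap ratio (intersection over the arithmetic
mean of the two activation counts -- numerically identical to the Dice
coefficient), anterior/posterior ROI splitting, ROI-averaged response
tables, and cross-subject normalization.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "activation_masks",
    "overlap_count_map",
    "overlap_proportions_by_threshold",
    "overlap_ratio",
    "overlap_table",
    "split_rois",
    "roi_average_betas",
    "normalize_across_subjects",
]

ADJACENT_PAIRS = [(1, 2), (2, 3), (3, 4), (4, 5)]


def activation_masks(stat, alpha: float = 0.05,
                     correction: str = "fwe") -> dict[int, np.ndarray]:
    """Binary significance masks per finger at adjusted-p < alpha."""
    if correction == "fwe":
        p_adj = stat.p_fwe
    elif correction == "fdr":
        p_adj = stat.p_fdr
    else:
        raise ValueError("correction must be 'fwe' or 'fdr'")
    if p_adj is None:
        raise ValueError(f"{correction}-adjusted p-values not present")
    vol = stat.analysis_volume
    masks = {}
    for finger, p in p_adj.items():
        m = p < alpha
        if vol is not None:
            m = m & vol
        masks[finger] = m
    return masks


def overlap_count_map(masks: dict[int, np.ndarray]) -> np.ndarray:
    """Per-voxel count of fingers whose mask includes the voxel (0..5)."""
    stack = np.stack([masks[f] for f in sorted(masks)], axis=0)
    return stack.sum(axis=0).astype(int)


def overlap_proportions_by_threshold(stat, roi_voxels: np.ndarray,
                                     z_grid) -> pd.DataFrame:
    """Exactly-k voxel fractions among active ROI voxels per Z threshold.

    Thresholds apply to the FDR-derived Z maps: a finger is "active" at a
    voxel when ``z_fdr > z``.  At each threshold the fractions over
    k = 1..5 are computed among ROI voxels active for at least one finger
    (so they sum to 1 wherever any voxel survives).  Columns: z, k,
    fraction, n_active.
    """
    if stat.z_fdr is None:
        raise ValueError("z_fdr maps required")
    if not roi_voxels.any():
        return pd.DataFrame(columns=["z", "k", "fraction", "n_active"])
    rows = []
    zmaps = np.stack([stat.z_fdr[f] for f in sorted(stat.z_fdr)], axis=0)
    zmaps = zmaps[:, roi_voxels]
    for z in np.asarray(z_grid, dtype=float):
        counts = (zmaps > z).sum(axis=0)
        active = counts >= 1
        n_active = int(active.sum())
        for k in range(1, 6):
            frac = float((counts[active] == k).mean()) if n_active else np.nan
            rows.append({"z": z, "k": k, "fraction": frac, "n_active": n_active})
    return pd.DataFrame(rows)


def overlap_ratio(mask_a: np.ndarray, mask_b: np.ndarray,
                  within: np.ndarray) -> float:
    """|A & B| / mean(|A|, |B|) inside ``within``; 0 when both are empty."""
    a = mask_a & within
    b = mask_b & within
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        logger.info("overlap_ratio: both masks empty inside region")
        return 0.0
    return float((a & b).sum()) / ((na + nb) / 2.0)


def overlap_table(masks: dict[int, np.ndarray],
                  regions: dict[str, np.ndarray],
                  as_percent: bool = True) -> pd.DataFrame:
    """Adjacent-pair overlap ratios per region, with an across-pair average row.

    Rows: D1&D2 .. D4&D5 plus 'Average' (arithmetic mean of the pair rows,
    recomputed, never stored independently).
    """
    scale = 100.0 if as_percent else 1.0
    data = {}
    for name, region in regions.items():
        col = [scale * overlap_ratio(masks[a], masks[b], region)
               for a, b in ADJACENT_PAIRS]
        data[name] = col
    index = [f"D{a}&D{b}" for a, b in ADJACENT_PAIRS]
    table = pd.DataFrame(data, index=index)
    table.loc["Average"] = table.loc[index].mean(axis=0)
    return table


def split_rois(rois, boundary_labels: np.ndarray,
               anterior_code: int = 1, posterior_code: int = 2):
    """Partition each whole ROI into anterior and posterior compartments.

    ``boundary_labels`` assigns every ROI voxel to one side; unlabeled ROI
    voxels raise.  Returns a flat list of compartment ROIs (counts preserved:
    |anterior| + |posterior| = |whole| per finger).
    """
    out = []
    for roi in rois:
        inside = roi.voxels
        lab = boundary_labels[inside]
        if np.any((lab != anterior_code) & (lab != posterior_code)):
            raise ValueError(f"finger {roi.finger}: unlabeled ROI voxels")
        ant = inside & (boundary_labels == anterior_code)
        post = inside & (boundary_labels == posterior_code)
        out.append(replace(roi, voxels=ant, compartment="anterior"))
        out.append(replace(roi, voxels=post, compartment="posterior"))
    return out


def roi_average_betas(fit, rois) -> pd.DataFrame:
    """Mean magnitude beta per (ROI, stimulated finger).

    Returns a tidy frame with columns roi_finger, compartment,
    stimulated_finger, mean_beta; empty compartments yield NaN (logged).
    """
    rows = []
    for roi in rois:
        sel = roi.voxels & fit.valid
        empty = not sel.any()
        if empty:
            logger.info("finger %d (%s): empty ROI, missing values",
                        roi.finger, roi.compartment)
        for stim in range(1, 6):
            val = (float(np.nanmean(fit.coef(stim, "magnitude")[sel]))
                   if not empty else np.nan)
            rows.append({"roi_finger": roi.finger,
                         "compartment": roi.compartment,
                         "stimulated_finger": stim,
                         "mean_beta": val})
    return pd.DataFrame(rows)


def normalize_across_subjects(tables: list[pd.DataFrame],
                              value_col: str = "mean_beta") -> list[pd.DataFrame]:
    """Scale each subject by (group mean of per-subject maxima) / own maximum.

    Preserves within-subject rank order; single subjects are unchanged.
    """
    maxima = []
    for tbl in tables:
        mx = float(np.nanmax(tbl[value_col].to_numpy()))
        if not mx > 0:
            raise ValueError("non-positive subject maximum")
        maxima.append(mx)
    group_max = float(np.mean(maxima))
    out = []
    for tbl, mx in zip(tables, maxima):
        t = tbl.copy()
        t[value_col + "_normalized"] = t[value_col] * (group_max / mx)
        out.append(t)
    return out
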