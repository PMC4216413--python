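"""Subject-report tables: HRF timing, ROI sizes, ROI distances, overlap ratios.

Average rows are always recomputed from the table rows, never stored
independently.  Rounding conventions match the published report layout:
latencies to one decimal, voxel-count averages rounded down to a whole
voxel, volumes to whole cubic centimeters.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "voxel_volume_ul",
    "analyzed_volume_cm3",
    "timing_table",
    "roi_size_table",
    "distance_table",
    "overlap_ratio_table",
    "add_average_row",
]


def voxel_volume_ul(voxel_size_mm=1.5) -> float:
    """Volume of one voxel in microliters (1 mm^3 == 1 ul)."""
    sizes = np.broadcast_to(voxel_size_mm, (3,)).astype(float)
    return float(np.prod(sizes))


def analyzed_volume_cm3(n_voxels: float, voxel_size_mm=1.5,
                        round_to_int: bool = True) -> float:
    """Total volume of ``n_voxels`` voxels in cubic centimeters."""
    vol = n_voxels * voxel_volume_ul(voxel_size_mm) / 1000.0
    return float(round(vol)) if round_to_int else vol


def add_average_row(table: pd.DataFrame, label: str = "Average",
                    ndigits: int | None = None,
                    floor_cols=()) -> pd.DataFrame:
    """Append an arithmetic-mean row; optional per-column floor to integer."""
    out = table.copy()
    avg = table.mean(axis=0)
    if ndigits is not None:
        avg = avg.round(ndigits)
    for col in floor_cols:
        avg[col] = math.floor(table[col].mean())
    out.loc[label] = avg
    return out


def timing_table(positive_peaks_s, negative_peaks_s,
                 voxels_analyzed) -> pd.DataFrame:
    """Per-subject HRF peak latencies and analyzed-voxel counts.

    Average row: latencies rounded to one decimal; the voxel-count average
    is rounded down to the nearest whole voxel.
    """
    n = len(positive_peaks_s)
    table = pd.DataFrame({
        "positive_peak_s": np.asarray(positive_peaks_s, dtype=float),
        "negative_peak_s": np.asarray(negative_peaks_s, dtype=float),
        "voxels_analyzed": np.asarray(voxels_analyzed, dtype=float),
    }, index=[f"Subject {i + 1}" for i in range(n)])
    return add_average_row(table, ndigits=1, floor_cols=["voxels_analyzed"])


def roi_size_table(counts_per_subject) -> pd.DataFrame:
    """ROI voxel counts (subjects x fingers) with a rounded average row."""
    fingers = ["Thumb", "Index", "Middle", "Ring", "Little"]
    table = pd.DataFrame(np.asarray(counts_per_subject, dtype=float),
                         columns=fingers,
                         index=[f"Subject {i + 1}"
                                for i in range(len(counts_per_subject))])
    return add_average_row(table, ndigits=0)


def distance_table(anterior_mm: np.ndarray,
                   posterior_mm: np.ndarray) -> pd.DataFrame:
    """Pairwise ROI center distances: anterior upper triangle, posterior lower.

    Both inputs are symmetric 5x5 matrices (mm).
    """
    labels = [f"D{i}" for i in range(1, 6)]
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i in range(5):
        for j in range(5):
            if i < j:
                out.iloc[i, j] = anterior_mm[i, j]
            elif i > j:
                out.iloc[i, j] = posterior_mm[i, j]
    return out


def overlap_ratio_table(pair_values: dict[str, list[float]],
                        ndigits: int | None = 1) -> pd.DataFrame:
    """Adjacent-pair overlap ratios per region with the across-pair average.

    ``pair_values`` maps region name -> four values ordered D1&D2..D4&D5.
    The average row is the arithmetic mean of the four pair rows, rounded to
    ``ndigits`` (None keeps full precision).
    """
    index = ["D1&D2", "D2&D3", "D3&D4", "D4&D5"]
    table = pd.DataFrame(pair_values, index=index)
    avg = table.mean(axis=0)
    if ndigits is not None:
        avg = avg.round(ndigits)
    out = table.copy()
    out.loc["Average"] = avg
    return out
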