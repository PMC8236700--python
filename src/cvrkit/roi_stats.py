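"""Tissue masks, voxel-exclusion rules and ROI summaries of CVR metrics.

Metric maps are summarized over gray matter within each vascular
territory (cerebellum, anterior / middle / posterior cerebral artery) and
over all white matter.  Before averaging, voxels with mCVR above
0.7 %/mmHg are removed from every metric's average (they are dominated by
sinovenous structures, not parenchyma), and voxels with negative ssCVR
are additionally removed from TAU averages, where the time constant no
longer indexes the speed of vasodilation (steal physiology).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CvrkitError

__all__ = [
    "DEFAULT_TERRITORY_NAMES",
    "MCVR_SINOVENOUS_THRESHOLD",
    "make_tissue_masks",
    "exclusion_filter",
    "territory_means",
    "cohort_summary",
]

DEFAULT_TERRITORY_NAMES = {1: "CER", 2: "ACA", 3: "MCA", 4: "PCA"}
MCVR_SINOVENOUS_THRESHOLD = 0.7  # %/mmHg
METRICS = ("mcvr", "sscvr", "tau", "td")


def make_tissue_masks(
    prob_maps: np.ndarray, threshold: float = 0.7
) -> dict[str, np.ndarray]:
    """Binary GM/WM/CSF masks by strict thresholding of probability maps.

    ``prob_maps`` is an (X, Y, Z, 3) stack; a voxel enters a class mask
    when its probability is strictly above the threshold (default 0.7).
    """
    prob_maps = np.asarray(prob_maps, dtype=float)
    if not 0 <= threshold < 1:
        raise CvrkitError("threshold must be in [0, 1)")
    return {name: prob_maps[..., i] > threshold
            for i, name in enumerate(("gm", "wm", "csf"))}


def exclusion_filter(
    maps: dict[str, np.ndarray],
    metric: str,
    mcvr_threshold: float = MCVR_SINOVENOUS_THRESHOLD,
) -> np.ndarray:
    """Boolean volume of voxels retained for the given metric's averages.

    Removes mCVR > threshold voxels for every metric; additionally removes
    negative-ssCVR voxels when the metric is TAU.  Values exactly at the
    mCVR threshold are retained (the cut is strictly "above").  Non-finite
    metric values are always excluded.
    """
    metric = metric.lower()
    if metric not in METRICS:
        raise CvrkitError(f"unknown metric {metric!r}")
    if "mcvr" not in maps:
        raise CvrkitError("exclusion filter needs the mCVR map")
    mcvr = np.asarray(maps["mcvr"], dtype=float)
    keep = np.isfinite(mcvr) & ~(mcvr > mcvr_threshold)
    if metric == "tau":
        if "sscvr" not in maps:
            raise CvrkitError("TAU exclusion needs the ssCVR map")
        sscvr = np.asarray(maps["sscvr"], dtype=float)
        keep &= np.isfinite(sscvr) & ~(sscvr < 0)
    target = np.asarray(maps[metric], dtype=float)
    return keep & np.isfinite(target)


def territory_means(
    maps: dict[str, np.ndarray],
    tissue_masks: dict[str, np.ndarray],
    territories: np.ndarray,
    territory_names: dict[int, str] | None = None,
    correction: str = "NN",
    mcvr_threshold: float = MCVR_SINOVENOUS_THRESHOLD,
) -> pd.DataFrame:
    """Mean +/- sd of each metric over GM per territory and over all WM.

    Returns a long-format table with one row per (territory, metric,
    correction); empty cells are reported with count 0 and NaN statistics.
    """
    territory_names = territory_names or DEFAULT_TERRITORY_NAMES
    territories = np.asarray(territories)
    rois = {name: tissue_masks["gm"] & (territories == label)
            for label, name in sorted(territory_names.items())}
    rois["WM"] = np.asarray(tissue_masks["wm"], dtype=bool)

    rows = []
    for metric in METRICS:
        if metric not in maps:
            continue
        keep = exclusion_filter(maps, metric, mcvr_threshold)
        vol = np.asarray(maps[metric], dtype=float)
        for roi_name, roi in rois.items():
            sel = vol[roi & keep]
            rows.append({
                "territory": roi_name,
                "metric": metric,
                "correction": correction,
                "mean": float(sel.mean()) if sel.size else np.nan,
                "sd": float(sel.std(ddof=0)) if sel.size else np.nan,
                "n_voxels": int(sel.size),
            })
    return pd.DataFrame(rows)


def cohort_summary(subject_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Across-subject mean +/- sd of the per-subject ROI means.

    The cohort mean is the mean of per-subject means and the sd is taken
    across subjects (not across pooled voxels), matching how normative
    tables are conventionally reported.
    """
    if not subject_tables:
        raise CvrkitError("no subject tables supplied")
    stacked = pd.concat(
        [t.assign(subject=i) for i, t in enumerate(subject_tables)], ignore_index=True
    )
    grouped = stacked.groupby(["territory", "metric", "correction"], sort=False)
    out = grouped.agg(
        mean=("mean", "mean"),
        sd=("mean", lambda s: float(np.std(s, ddof=0))),
        n_subjects=("mean", "size"),
    ).reset_index()
    return out
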