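"""Segmentation and per-cell fluorescence quantification.

Per-cell measurements follow the confocal analysis convention: total
fluorescence in a cell is counted and normalized to the cell area (mean
fluorescence, AFU).  The membrane-bound component is obtained by
subtraction — the intracellular level (estimated on the cell mask eroded by
the ring width) is extrapolated to the full cell and removed from the total;
the remainder is normalized to the membrane (ring) area.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import disk, erosion
from skimage.segmentation import watershed

from ._errors import FormatError

#: Fewer cells than this per condition/experiment triggers a warning.
MIN_CELLS_PER_CONDITION = 10


def read_stack(path: str) -> tuple[np.ndarray, dict]:
    """Read a grayscale TIFF stack as a ``(n_pages, H, W)`` array.

    Single-page files come back with a leading axis of length 1.  RGB or
    otherwise non-grayscale files raise :class:`FormatError`.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            photometric = tif.pages[0].photometric
            arr = tif.asarray()
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not read TIFF {path}: {exc}") from exc
    if photometric not in (
        tifffile.PHOTOMETRIC.MINISBLACK,
        tifffile.PHOTOMETRIC.MINISWHITE,
    ):
        raise FormatError(f"{path} is not grayscale (photometric={photometric!r})")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path} has unexpected shape {arr.shape}")
    meta = {"dtype": str(arr.dtype), "n_pages": arr.shape[0], "path": path}
    return arr, meta


def segment_cells(
    frame: np.ndarray,
    min_area: int = 120,
    max_area: int | None = None,
    smooth_sigma: float = 1.0,
    split_touching: bool = False,
) -> np.ndarray:
    """Segment cells in a single intensity frame.

    Gaussian smoothing, Otsu global threshold, hole filling, area filtering,
    and optionally a distance-transform watershed to split touching cells.
    Returns an int32 label image (0 = background).  An all-background frame
    yields zero labels rather than an error.
    """
    frame = np.asarray(frame, dtype=np.float64)
    smoothed = gaussian(frame, sigma=smooth_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return np.zeros(frame.shape, dtype=np.int32)
    thresh = threshold_otsu(smoothed)
    mask = smoothed > thresh
    # A threshold that selects most of the frame means there is no real
    # foreground/background structure (e.g. pure noise or uniform signal).
    if mask.mean() > 0.5:
        return np.zeros(frame.shape, dtype=np.int32)
    mask = ndi.binary_fill_holes(mask)
    labels, _ = ndi.label(mask)
    if split_touching and labels.max() > 0:
        distance = ndi.distance_transform_edt(mask)
        smooth_dist = gaussian(distance, sigma=2.0, preserve_range=True)
        peaks = smooth_dist == ndi.maximum_filter(smooth_dist, size=9)
        markers, _ = ndi.label(peaks & mask)
        labels = watershed(-distance, markers, mask=mask)
    # area filter, then compact relabeling
    sizes = np.bincount(labels.ravel())
    bad = sizes < min_area
    if max_area is not None:
        bad |= sizes > max_area
    bad[0] = True
    keep = np.flatnonzero(~bad)
    remap = np.zeros(len(sizes), dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labels]


def quantify(
    frame: np.ndarray,
    labels: np.ndarray,
    ring_width_px: int = 3,
    background: float | None = None,
    exclude_edge: bool = True,
) -> pd.DataFrame:
    """Per-cell fluorescence measurements for one frame.

    Background defaults to the median of non-cell pixels and is subtracted
    per pixel.  For each cell: ``mean_fluor`` is background-corrected total
    divided by cell area (floored at 0); the interior level is estimated on
    the mask eroded by ``ring_width_px`` and ``surface_mean`` is the excess
    total over that level divided by the membrane (ring) area.  Cells whose
    interior erodes away are flagged ``too_small`` (surface metrics NaN);
    edge-touching cells are flagged and dropped unless ``exclude_edge`` is
    False.
    """
    if ring_width_px < 1:
        raise ValueError("ring_width_px must be >= 1")
    frame = np.asarray(frame, dtype=np.float64)
    labels = np.asarray(labels)
    if background is None:
        bg_pixels = frame[labels == 0]
        background = float(np.median(bg_pixels)) if bg_pixels.size else 0.0
    corrected = frame - background

    selem = disk(ring_width_px)
    h, w = labels.shape
    rows = []
    for label, slc in enumerate(ndi.find_objects(labels), start=1):
        if slc is None:
            continue
        pad = ring_width_px + 1
        rs = slice(max(0, slc[0].start - pad), min(h, slc[0].stop + pad))
        cs = slice(max(0, slc[1].start - pad), min(w, slc[1].stop + pad))
        mask = labels[rs, cs] == label
        vals = corrected[rs, cs]
        cell_area = int(mask.sum())
        total = float(vals[mask].sum())
        touches_edge = (
            slc[0].start == 0 or slc[1].start == 0 or slc[0].stop == h or slc[1].stop == w
        )
        interior = erosion(mask, selem)
        interior_area = int(interior.sum())
        membrane_area = cell_area - interior_area
        too_small = interior_area == 0
        if too_small:
            interior_mean = np.nan
            interior_fluor = np.nan
            surface_mean = np.nan
        else:
            interior_mean = float(vals[interior].mean())
            # interior level extrapolated to the whole cell footprint
            interior_fluor = interior_mean * cell_area
            surface_mean = (total - interior_fluor) / membrane_area
        rows.append(
            {
                "cell_label": label,
                "cell_area": cell_area,
                "membrane_area": membrane_area,
                "total_fluor": total,
                "interior_fluor": interior_fluor,
                "mean_fluor": max(0.0, total / cell_area),
                "interior_mean": interior_mean,
                "surface_mean": surface_mean,
                "background": background,
                "touches_edge": touches_edge,
                "too_small": too_small,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "cell_label",
            "cell_area",
            "membrane_area",
            "total_fluor",
            "interior_fluor",
            "mean_fluor",
            "interior_mean",
            "surface_mean",
            "background",
            "touches_edge",
            "too_small",
        ],
    )
    if exclude_edge and len(df):
        df = df[~df["touches_edge"]].reset_index(drop=True)
    return df


def quantify_stack(
    stack: np.ndarray,
    ring_width_px: int = 3,
    min_area: int = 120,
    max_area: int | None = None,
    exclude_edge: bool = True,
) -> pd.DataFrame:
    """Segment and quantify every page of a stack; adds a ``page`` column."""
    frames = []
    for page, frame in enumerate(stack):
        labels = segment_cells(frame, min_area=min_area, max_area=max_area)
        df = quantify(
            frame, labels, ring_width_px=ring_width_px, exclude_edge=exclude_edge
        )
        df.insert(0, "page", page)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def aggregate(
    measurements: pd.DataFrame,
    manifest: pd.DataFrame,
    value_cols: tuple = ("mean_fluor", "interior_mean", "surface_mean"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition-level statistics from per-cell measurements.

    ``measurements`` must carry a ``stack_path`` column joining it to the
    manifest.  Returns ``(per_experiment, per_condition)``: cell counts,
    means, and SD per (condition, experiment), then mean of experiment means
    with SEM across experiments.  Warns when a condition/experiment has
    fewer than 10 cells.
    """
    missing = set(measurements["stack_path"]) - set(manifest["stack_path"])
    if missing:
        raise KeyError(f"measurements reference stacks absent from manifest: {sorted(missing)[:3]}")
    merged = measurements.merge(manifest, on="stack_path", how="left")

    per_exp_rows = []
    for (cid, exp), grp in merged.groupby(["condition_id", "experiment_id"], sort=True):
        row = {"condition_id": cid, "experiment_id": exp, "n_cells": len(grp)}
        if len(grp) < MIN_CELLS_PER_CONDITION:
            warnings.warn(
                f"condition {cid} experiment {exp} has only {len(grp)} cells "
                f"(< {MIN_CELLS_PER_CONDITION})",
                stacklevel=2,
            )
        for col in value_cols:
            vals = grp[col].dropna()
            row[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        per_exp_rows.append(row)
    per_experiment = pd.DataFrame(per_exp_rows)

    per_cond_rows = []
    for cid, grp in per_experiment.groupby("condition_id", sort=True):
        row = {"condition_id": cid, "n_experiments": len(grp), "n_cells": int(grp["n_cells"].sum())}
        for col in value_cols:
            means = grp[f"{col}_mean"].dropna()
            row[f"{col}_mean"] = means.mean() if len(means) else np.nan
            row[f"{col}_sem"] = (
                means.std(ddof=1) / np.sqrt(len(means)) if len(means) > 1 else 0.0
            )
        per_cond_rows.append(row)
    per_condition = pd.DataFrame(per_cond_rows)
    return per_experiment, per_condition


def label_iou(pred: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Intersection-over-union of each ground-truth cell with its best match.

    Returns one row per truth label with the best-matching predicted label
    and the IoU (0 when nothing overlaps).
    """
    rows = []
    for t in np.unique(truth[truth > 0]):
        tmask = truth == t
        overlapping = np.unique(pred[tmask])
        overlapping = overlapping[overlapping > 0]
        best_iou, best_label = 0.0, 0
        for p in overlapping:
            pmask = pred == p
            inter = np.logical_and(tmask, pmask).sum()
            union = np.logical_or(tmask, pmask).sum()
            iou = inter / union
            if iou > best_iou:
                best_iou, best_label = iou, int(p)
        rows.append({"truth_label": int(t), "pred_label": best_label, "iou": best_iou})
    return pd.DataFrame(rows, columns=["truth_label", "pred_label", "iou"])
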