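"""Synthetic imaging scenes: cell placement and ground-truth masks.

Cells are ellipses with random semi-axes and orientation, placed without
overlap and fully inside the frame.  Each cell is split into a fixed-width
membrane ring (outer shell) and an interior; the two partitions are disjoint
and exhaustive.  Every cell carries a multiplicative expression factor
(lognormal, mean 1) modelling cell-to-cell scatter in transporter surface
density — the reason the assay quantifies single cells rather than fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk, erosion

from .._errors import ConfigurationError, PlacementError


@dataclass(frozen=True)
class ScenePlan:
    """Geometry and layout of one synthetic field of view."""

    image_width: int = 384
    image_height: int = 384
    pixel_size_um: float = 0.5
    n_cells: int = 30
    #: (min, max) ellipse semi-axes in micrometers.
    cell_axes_um: tuple = (3.5, 6.5)
    membrane_ring_width_um: float = 1.5
    background_level: float = 20.0
    #: Cell-intrinsic fluorescence (AFU) independent of substrate handling;
    #: keeps cells segmentable even at full transport inhibition.
    cell_autofluorescence: float = 15.0
    #: Lognormal sigma of the per-cell expression factor (mean normalized to 1).
    expression_sigma: float = 0.15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_width < 16 or self.image_height < 16:
            raise ConfigurationError("frame must be at least 16x16 pixels")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        lo, hi = self.cell_axes_um
        if not 0 < lo <= hi:
            raise ConfigurationError("cell_axes_um must satisfy 0 < min <= max")
        if self.membrane_ring_width_um <= 0:
            raise ConfigurationError("membrane ring width must be positive")
        if self.background_level < 0 or self.cell_autofluorescence < 0:
            raise ConfigurationError("background and autofluorescence must be >= 0")
        if self.expression_sigma < 0:
            raise ConfigurationError("expression_sigma must be >= 0")

    @property
    def ring_width_px(self) -> int:
        return max(1, round(self.membrane_ring_width_um / self.pixel_size_um))


@dataclass
class GroundTruth:
    """Label masks and per-cell geometry of one synthetic scene.

    ``labels`` assigns every pixel to at most one cell (0 = background);
    ``interior_labels`` and ``ring_labels`` partition each cell exactly.
    """

    plan: ScenePlan
    labels: np.ndarray
    interior_labels: np.ndarray
    ring_labels: np.ndarray
    cells: pd.DataFrame  # label, cy, cx, a_px, b_px, theta, areas, expression_factor

    @property
    def n_cells(self) -> int:
        return len(self.cells)


#: Minimum clear gap (px) between placed cells so blur cannot merge them.
_MIN_GAP_PX = 4
#: Clear margin (px) kept between any cell and the frame edge.
_EDGE_MARGIN_PX = 3
#: Placement attempts per cell before giving up.
_MAX_TRIES = 500


def build_scene(plan: ScenePlan) -> GroundTruth:
    """Place ``plan.n_cells`` non-overlapping elliptical cells in the frame.

    Deterministic for a given plan (including ``rng_seed``).  Raises
    :class:`PlacementError` when the frame cannot accommodate the requested
    number of cells after bounded retries.
    """
    rng = np.random.default_rng(plan.rng_seed)
    h, w = plan.image_height, plan.image_width
    lo_px = plan.cell_axes_um[0] / plan.pixel_size_um
    hi_px = plan.cell_axes_um[1] / plan.pixel_size_um

    labels = np.zeros((h, w), dtype=np.int32)
    interior_labels = np.zeros_like(labels)
    ring_labels = np.zeros_like(labels)
    placed: list[tuple[float, float, float]] = []  # (cy, cx, bounding radius)
    rows = []
    selem = disk(plan.ring_width_px)

    for label in range(1, plan.n_cells + 1):
        for _ in range(_MAX_TRIES):
            a = rng.uniform(lo_px, hi_px)
            b = rng.uniform(lo_px, hi_px)
            theta = rng.uniform(0.0, np.pi)
            r = max(a, b)
            margin = r + _EDGE_MARGIN_PX
            if 2 * margin >= min(h, w):
                continue
            cy = rng.uniform(margin, h - 1 - margin)
            cx = rng.uniform(margin, w - 1 - margin)
            if all(
                np.hypot(cy - py, cx - px) > r + pr + _MIN_GAP_PX for py, px, pr in placed
            ):
                break
        else:
            raise PlacementError(
                f"could not place cell {label}/{plan.n_cells} in a "
                f"{w}x{h} frame after {_MAX_TRIES} attempts"
            )
        placed.append((cy, cx, r))

        rr, cc = draw_ellipse(cy, cx, a, b, rotation=theta, shape=(h, w))
        labels[rr, cc] = label
        # interior = erosion of the cell mask by the ring width, on a crop
        r0, r1 = rr.min(), rr.max() + 1
        c0, c1 = cc.min(), cc.max() + 1
        pad = plan.ring_width_px + 1
        r0p, c0p = max(0, r0 - pad), max(0, c0 - pad)
        crop = labels[r0p : r1 + pad, c0p : c1 + pad] == label
        interior = erosion(crop, selem)
        ring = crop & ~interior
        sub_i = interior_labels[r0p : r1 + pad, c0p : c1 + pad]
        sub_r = ring_labels[r0p : r1 + pad, c0p : c1 + pad]
        sub_i[interior] = label
        sub_r[ring] = label

        rows.append(
            {
                "label": label,
                "cy": cy,
                "cx": cx,
                "a_px": a,
                "b_px": b,
                "theta": theta,
                "area_px": int(crop.sum()),
                "interior_area_px": int(interior.sum()),
                "ring_area_px": int(ring.sum()),
            }
        )

    cells = pd.DataFrame(
        rows,
        columns=[
            "label",
            "cy",
            "cx",
            "a_px",
            "b_px",
            "theta",
            "area_px",
            "interior_area_px",
            "ring_area_px",
        ],
    )
    if plan.n_cells > 0 and plan.expression_sigma > 0:
        factors = rng.lognormal(0.0, plan.expression_sigma, size=plan.n_cells)
        factors /= np.exp(plan.expression_sigma**2 / 2.0)  # mean-1 normalization
    else:
        factors = np.ones(plan.n_cells)
    cells["expression_factor"] = factors

    return GroundTruth(
        plan=plan,
        labels=labels,
        interior_labels=interior_labels,
        ring_labels=ring_labels,
        cells=cells,
    )
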