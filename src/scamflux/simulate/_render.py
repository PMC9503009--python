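"""Rendering of synthetic stacks and whole experiment directories.

The noise chain per page is: Poisson shot noise on photon-scaled intensities,
additive Gaussian read noise, then a Gaussian blur standing in for the point
spread function.  Images are written as multi-page 16-bit grayscale TIFFs;
AFU values are converted to counts with a fixed ``intensity_scale`` recorded
in the manifest so analysis can convert back.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .._errors import ConfigurationError, IntensityOverflowError
from ..conditions import ConditionSpec
from ._mechanism import MechanismParams, signal_components
from ._scene import GroundTruth, ScenePlan, build_scene

#: Counts per AFU when quantizing to uint16.
DEFAULT_INTENSITY_SCALE = 20.0
_U16_MAX = 65535


@dataclass(frozen=True)
class NoiseParams:
    """Acquisition noise settings.

    ``poisson_scale`` is the photon count corresponding to 1 AFU (None
    disables shot noise); ``read_sigma`` is Gaussian read noise in AFU;
    ``psf_sigma`` the blur kernel width in pixels.  The default blur is the
    lateral resolution of a high-NA confocal (sigma ~0.2 um) expressed at
    the default 0.5 um/pixel sampling.
    """

    psf_sigma: float = 0.4
    read_sigma: float = 2.0
    poisson_scale: float | None = 5.0

    def __post_init__(self) -> None:
        if self.psf_sigma < 0 or self.read_sigma < 0:
            raise ConfigurationError("noise sigmas must be >= 0")
        if self.poisson_scale is not None and self.poisson_scale <= 0:
            raise ConfigurationError("poisson_scale must be positive or None")


NOISE_FREE = NoiseParams(psf_sigma=0.0, read_sigma=0.0, poisson_scale=None)


def render_stack(
    scene: GroundTruth,
    cond: ConditionSpec,
    mech: MechanismParams,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    n_pages: int = 1,
    intensity_scale: float = DEFAULT_INTENSITY_SCALE,
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Render one condition on one scene.

    Returns ``(stack, cell_truth, condition_truth)`` where ``stack`` is a
    ``(n_pages, H, W)`` uint16 array, ``cell_truth`` the per-cell true means
    (AFU, background excluded) and ``condition_truth`` the mechanistic
    decomposition of the condition.  Pages share the scene but carry
    independent noise.
    """
    if n_pages < 1:
        raise ConfigurationError("n_pages must be >= 1")
    comp = signal_components(cond, mech)
    plan = scene.plan

    # Noise-free intensity field in AFU.  Interior signal fills the whole
    # cell (ring included); the membrane component rides on top of the ring.
    field = np.full(
        (plan.image_height, plan.image_width), plan.background_level, dtype=np.float64
    )
    expr = np.ones(scene.n_cells + 1)
    if scene.n_cells:
        expr[scene.cells["label"].to_numpy()] = scene.cells["expression_factor"].to_numpy()

    cell_mask = scene.labels > 0
    interior_level = (
        plan.cell_autofluorescence
        + comp.interior_specific * expr[scene.labels]
        + comp.interior_nonspecific
    )
    field[cell_mask] += interior_level[cell_mask]
    ring_mask = scene.ring_labels > 0
    membrane_level = comp.membrane_specific * expr[scene.ring_labels] + comp.membrane_nonspecific
    field[ring_mask] += membrane_level[ring_mask]

    if field.max() * intensity_scale > _U16_MAX:
        raise IntensityOverflowError(
            f"noise-free intensity {field.max():.1f} AFU overflows uint16 at "
            f"scale {intensity_scale}"
        )

    rng = np.random.default_rng(seed)
    pages = np.empty((n_pages, *field.shape), dtype=np.uint16)
    clipped = 0
    for p in range(n_pages):
        img = field
        if noise.poisson_scale is not None:
            img = rng.poisson(img * noise.poisson_scale) / noise.poisson_scale
        if noise.read_sigma > 0:
            img = img + rng.normal(0.0, noise.read_sigma, size=img.shape)
        if noise.psf_sigma > 0:
            img = gaussian_filter(img, noise.psf_sigma)
        counts = np.rint(img * intensity_scale)
        clipped += int((counts > _U16_MAX).sum())
        pages[p] = np.clip(counts, 0, _U16_MAX).astype(np.uint16)
    clipped_frac = clipped / pages.size
    if clipped_frac > 1e-3:
        raise IntensityOverflowError(
            f"{clipped_frac:.2%} of pixels clipped at intensity scale {intensity_scale}"
        )

    cell_truth = scene.cells.copy()
    cell_truth["true_interior_mean"] = (
        plan.cell_autofluorescence
        + comp.interior_specific * cell_truth["expression_factor"]
        + comp.interior_nonspecific
    )
    cell_truth["true_membrane_mean"] = (
        comp.membrane_specific * cell_truth["expression_factor"] + comp.membrane_nonspecific
    )

    condition_truth = {
        "condition_id": cond.condition_id(),
        "experiment_id": cond.experiment_id,
        "replicate_id": cond.replicate_id,
        "interior_specific": comp.interior_specific,
        "interior_nonspecific": comp.interior_nonspecific,
        "membrane_specific": comp.membrane_specific,
        "membrane_nonspecific": comp.membrane_nonspecific,
        "unmodified_fraction": comp.unmodified_fraction,
        "k_eff": comp.k_eff,
        "clipped_frac": clipped_frac,
    }
    return pages, cell_truth, condition_truth


def write_stack(path: str, stack: np.ndarray) -> None:
    """Write a (pages, H, W) array as a multi-page grayscale TIFF."""
    tifffile.imwrite(path, stack, photometric="minisblack")


def generate_experiment(
    design: list[ConditionSpec],
    mech: MechanismParams,
    plan: ScenePlan,
    out_dir: str,
    seed: int = 0,
    noise: NoiseParams = NoiseParams(),
    n_pages: int = 1,
    intensity_scale: float = DEFAULT_INTENSITY_SCALE,
) -> pd.DataFrame:
    """Render every condition of a design into ``out_dir``.

    Writes one TIFF stack per condition/experiment/replicate, a manifest CSV
    (one row per stack), and per-cell / per-condition ground-truth CSVs.
    A fresh scene (new field of cells) is drawn for each stack; all
    randomness derives from ``seed``.
    """
    if not design:
        raise ConfigurationError("experiment design is empty")
    keys = [c.stack_key() for c in design]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ConfigurationError(f"duplicate condition/replicate keys: {dupes[:3]}")

    os.makedirs(out_dir, exist_ok=True)
    children = np.random.SeedSequence(seed).spawn(len(design))
    manifest_rows = []
    cell_truths = []
    cond_truths = []
    for i, (cond, child) in enumerate(zip(design, children)):
        scene_seed, noise_seed = (int(s) for s in child.generate_state(2) % (2**31))
        scene = build_scene(
            ScenePlan(**{**plan.__dict__, "rng_seed": scene_seed})
        )
        stack, cell_truth, cond_truth = render_stack(
            scene,
            cond,
            mech,
            noise=noise,
            seed=noise_seed,
            n_pages=n_pages,
            intensity_scale=intensity_scale,
        )
        fname = f"stack_{i:04d}.tif"
        write_stack(os.path.join(out_dir, fname), stack)

        row = cond.to_manifest_row(fname)
        row["intensity_scale"] = intensity_scale
        manifest_rows.append(row)
        cell_truth.insert(0, "stack_path", fname)
        cell_truths.append(cell_truth)
        cond_truth["stack_path"] = fname
        cond_truths.append(cond_truth)

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    pd.concat(cell_truths, ignore_index=True).to_csv(
        os.path.join(out_dir, "truth_cells.csv"), index=False
    )
    pd.DataFrame(cond_truths).to_csv(
        os.path.join(out_dir, "truth_conditions.csv"), index=False
    )
    return manifest
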