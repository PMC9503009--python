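"""Image reading, segmentation, per-cell quantification, aggregation."""

import numpy as np
import pandas as pd
import pytest
import tifffile

from scamflux import ConditionSpec, FormatError, ScenePlan
from scamflux import imaging
from scamflux.simulate import (
    DEFAULT_INTENSITY_SCALE,
    NOISE_FREE,
    build_scene,
    render_stack,
    write_stack,
)

SCALE = DEFAULT_INTENSITY_SCALE


class TestReadStack:
    def test_round_trip_is_bit_exact(self, tmp_path, mech, small_scene, app_condition):
        stack, _, _ = render_stack(small_scene, app_condition, mech, seed=0, n_pages=2)
        path = tmp_path / "s.tif"
        write_stack(str(path), stack)
        back, meta = imaging.read_stack(str(path))
        assert np.array_equal(back, stack)
        assert meta["n_pages"] == 2
        assert meta["dtype"] == "uint16"

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FormatError):
            imaging.read_stack(str(tmp_path / "nope.tif"))

    def test_rgb_file_rejected(self, tmp_path):
        rgb = np.zeros((32, 32, 3), dtype=np.uint8)
        path = tmp_path / "rgb.tif"
        tifffile.imwrite(str(path), rgb, photometric="rgb")
        with pytest.raises(FormatError, match="grayscale"):
            imaging.read_stack(str(path))

    def test_single_page_gets_leading_axis(self, tmp_path):
        path = tmp_path / "one.tif"
        tifffile.imwrite(str(path), np.zeros((16, 16), dtype=np.uint16))
        arr, meta = imaging.read_stack(str(path))
        assert arr.shape == (1, 16, 16)


class TestSegmentation:
    def test_noise_free_frame_recovers_exact_masks(self, mech, small_scene, app_condition):
        stack, _, _ = render_stack(small_scene, app_condition, mech, noise=NOISE_FREE, seed=0)
        frame = stack[0].astype(np.float64) / SCALE
        labels = imaging.segment_cells(frame, smooth_sigma=0.0)
        assert labels.max() == small_scene.n_cells
        iou = imaging.label_iou(labels, small_scene.labels)
        assert (iou["iou"] == 1.0).all()

    def test_uniform_frame_yields_no_labels(self):
        assert imaging.segment_cells(np.full((64, 64), 20.0)).max() == 0

    def test_pure_noise_frame_yields_no_cells(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(20.0, 2.0, size=(128, 128))
        assert imaging.segment_cells(frame).max() == 0

    def test_default_noise_thirty_cells(self, mech, default_scene, app_condition):
        stack, _, _ = render_stack(default_scene, app_condition, mech, seed=5)
        labels = imaging.segment_cells(stack[0].astype(np.float64) / SCALE)
        assert labels.max() == default_scene.n_cells
        iou = imaging.label_iou(labels, default_scene.labels)
        assert (iou["iou"] >= 0.8).all()


class TestQuantify:
    def test_uniform_cell_mean_is_intensity_minus_background(self):
        frame = np.full((40, 40), 5.0)
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[10:25, 10:25] = 1
        frame[labels == 1] = 17.0
        df = imaging.quantify(frame, labels, ring_width_px=2)
        assert len(df) == 1
        assert df.loc[0, "mean_fluor"] == pytest.approx(12.0)
        assert df.loc[0, "background"] == pytest.approx(5.0)

    def test_decomposition_conserves_total_signal(self, mech, default_scene):
        cond = ConditionSpec(substrate="ASP+", substrate_conc_uM=10.0, digitonin_ug_ml=25.0)
        stack, _, _ = render_stack(default_scene, cond, mech, seed=4)
        df = imaging.quantify(stack[0].astype(np.float64) / SCALE, default_scene.labels,
                              ring_width_px=3)
        ok = ~df["too_small"]
        recomposed = df.loc[ok, "interior_fluor"] + df.loc[ok, "surface_mean"] * df.loc[
            ok, "membrane_area"
        ]
        assert np.allclose(recomposed, df.loc[ok, "total_fluor"], rtol=1e-9)
        assert (df["cell_area"] > df["membrane_area"]).all()
        assert (df["membrane_area"] > 0).all()

    def test_membrane_only_cells_recover_surface_density(self, mech, default_scene):
        """Noise-free, truth-mask quantification reproduces the generator's
        membrane signal: the digitonin + ASP+ geometry of a binding assay."""
        cond = ConditionSpec(substrate="ASP+", substrate_conc_uM=10.0, digitonin_ug_ml=25.0)
        stack, truth, _ = render_stack(default_scene, cond, mech, noise=NOISE_FREE, seed=0)
        df = imaging.quantify(
            stack[0].astype(np.float64) / SCALE, default_scene.labels,
            ring_width_px=default_scene.plan.ring_width_px,
        )
        merged = df.merge(truth, left_on="cell_label", right_on="label")
        rel = (merged["surface_mean"] - merged["true_membrane_mean"]) / merged[
            "true_membrane_mean"
        ]
        assert np.abs(rel).max() < 0.02
        # interior carries only autofluorescence + residual nonspecific signal
        assert (merged["interior_mean"] < 0.35 * merged["true_interior_mean"].max() + 20).all()

    def test_noise_free_quantification_matches_truth_table(self, noise_free_app_stack, default_scene):
        stack, truth, _ = noise_free_app_stack
        df = imaging.quantify(
            stack[0].astype(np.float64) / SCALE, default_scene.labels,
            ring_width_px=default_scene.plan.ring_width_px,
        )
        merged = df.merge(truth, left_on="cell_label", right_on="label")
        quantum = 0.5 / SCALE
        assert np.allclose(merged["mean_fluor"], merged["true_interior_mean"], atol=2 * quantum)

    def test_noisy_cell_means_match_model_prediction(self, mech, default_scene, app_condition):
        stack, _, cond_truth = render_stack(default_scene, app_condition, mech, seed=21)
        frame = stack[0].astype(np.float64) / SCALE
        labels = imaging.segment_cells(frame)
        df = imaging.quantify(frame, labels)
        predicted = (
            default_scene.plan.cell_autofluorescence
            + cond_truth["interior_specific"]
            + cond_truth["interior_nonspecific"]
        )
        assert df["mean_fluor"].mean() == pytest.approx(predicted, rel=0.05)

    def test_cell_too_small_for_ring_is_flagged(self):
        frame = np.full((30, 30), 5.0)
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[14:17, 14:17] = 1  # 3x3 cell, erodes away at ring width 3
        df = imaging.quantify(frame, labels, ring_width_px=3)
        assert df.loc[0, "too_small"]
        assert np.isnan(df.loc[0, "surface_mean"])

    def test_edge_touching_cells_excluded_by_default(self):
        frame = np.full((40, 40), 5.0)
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[0:10, 5:15] = 1
        labels[20:32, 20:32] = 2
        assert len(imaging.quantify(frame, labels)) == 1
        assert len(imaging.quantify(frame, labels, exclude_edge=False)) == 2


class TestAggregate:
    @staticmethod
    def _tables(values_by_exp):
        cells, manifest = [], []
        for exp, vals in values_by_exp.items():
            stack = f"stack_{exp}.tif"
            manifest.append({"stack_path": stack, "condition_id": "c1", "experiment_id": exp})
            for v in vals:
                cells.append(
                    {"stack_path": stack, "mean_fluor": v, "interior_mean": v, "surface_mean": v}
                )
        return pd.DataFrame(cells), pd.DataFrame(manifest)

    def test_constant_cells_have_zero_sd(self):
        cells, manifest = self._tables({1: [7.0] * 12})
        per_exp, per_cond = imaging.aggregate(cells, manifest)
        assert per_exp.loc[0, "mean_fluor_mean"] == 7.0
        assert per_exp.loc[0, "mean_fluor_sd"] == 0.0

    def test_sem_across_three_experiments(self):
        cells, manifest = self._tables({1: [1.0] * 10, 2: [2.0] * 10, 3: [3.0] * 10})
        _, per_cond = imaging.aggregate(cells, manifest)
        sem = np.std([1.0, 2.0, 3.0], ddof=1) / np.sqrt(3)
        assert per_cond.loc[0, "mean_fluor_mean"] == pytest.approx(2.0)
        assert per_cond.loc[0, "mean_fluor_sem"] == pytest.approx(sem)

    def test_low_cell_count_warns(self):
        cells, manifest = self._tables({1: [1.0] * 9})
        with pytest.warns(UserWarning, match="only 9 cells"):
            imaging.aggregate(cells, manifest)

    def test_unknown_stack_raises(self):
        cells, manifest = self._tables({1: [1.0] * 10})
        cells.loc[0, "stack_path"] = "other.tif"
        with pytest.raises(KeyError):
            imaging.aggregate(cells, manifest)
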