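"""End-to-end orchestration: simulate -> quantify -> fit -> compare.

``run_pipeline`` drives the full analysis for one preset design: synthetic
stacks are rendered, every frame segmented and quantified, per-cell
measurements aggregated per condition and experiment, the nonspecific
(fluoxetine-blocked) component subtracted, and the preset's analysis run
(Michaelis-Menten kinetics, inhibition-ladder rate constants,
fixed-concentration protection, ion panels, digitonin panel).  All outputs
are plain CSV; every random draw derives from the single master seed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import accessibility, compare, imaging, kinetics
from ._errors import ConfigurationError, ScamfluxError
from .conditions import pathway_of
from .presets import get_preset
from .simulate import (
    DEFAULT_INTENSITY_SCALE,
    MechanismParams,
    NoiseParams,
    ScenePlan,
    generate_experiment,
)

logger = logging.getLogger("scamflux")

_COND_ATTRS = [
    "condition_id",
    "mutant",
    "substrate",
    "substrate_conc_uM",
    "mts_reagent",
    "mts_conc_M",
    "mts_time_s",
    "ligand",
    "ligand_conc_uM",
    "ion_medium",
    "digitonin_ug_ml",
    "uptake_blocked",
]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    preset: str = "fig3"
    out_dir: str = "scamflux_out"
    seed: int = 0
    n_experiments: int = 3
    plan: ScenePlan = field(default_factory=ScenePlan)
    mech: MechanismParams = field(default_factory=MechanismParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    n_pages: int = 1
    intensity_scale: float = DEFAULT_INTENSITY_SCALE
    ring_width_px: int | None = None  # None -> the scene plan's ring width
    min_area: int = 120
    max_area: int | None = None
    fit_model: str = "exponential"
    alpha: float = 0.05
    min_fold: float = 1.1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "plan" in d and isinstance(d["plan"], dict):
            plan = dict(d["plan"])
            if "cell_axes_um" in plan:
                plan["cell_axes_um"] = tuple(plan["cell_axes_um"])
            d["plan"] = ScenePlan(**plan)
        if "mech" in d and isinstance(d["mech"], dict):
            mech = dict(d["mech"])
            if "k_base" in mech and isinstance(mech["k_base"], dict):
                mech["k_base"] = {
                    tuple(k.split(":")) if isinstance(k, str) else tuple(k): v
                    for k, v in mech["k_base"].items()
                }
            if "digitonin_access_completeness" in mech:
                mech["digitonin_access_completeness"] = tuple(
                    tuple(p) for p in mech["digitonin_access_completeness"]
                )
            d["mech"] = MechanismParams(**mech)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseParams(**d["noise"])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        d = self.to_dict()
        # YAML cannot key mappings by tuples
        d["mech"]["k_base"] = {":".join(k): v for k, v in d["mech"]["k_base"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    """Bundle of the tables produced by one pipeline run."""

    config: PipelineConfig
    manifest: pd.DataFrame
    cells: pd.DataFrame
    per_experiment: pd.DataFrame
    per_condition: pd.DataFrame
    specific: pd.DataFrame
    fits: pd.DataFrame | None = None
    comparisons: list = field(default_factory=list)
    comparison_table: pd.DataFrame | None = None
    conformation_calls: pd.DataFrame | None = None
    kinetics_summaries: dict = field(default_factory=dict)
    ion_uptake: pd.DataFrame | None = None
    ion_panels: dict = field(default_factory=dict)
    digitonin_table: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# stage helpers


def _metric_col(row) -> str:
    """Assay readout per condition: ASP+ binding in permeabilized cells is
    read on the membrane; ASP+ uptake in intact cells on the interior (its
    surface-bound component would otherwise contaminate the transport
    signal); APP+ accumulates only intracellularly, so whole-cell mean
    fluorescence is used directly."""
    if row["substrate"] == "ASP+":
        return "surface_mean_mean" if row["digitonin_ug_ml"] > 0 else "interior_mean_mean"
    return "mean_fluor_mean"


def _quantify_all(manifest: pd.DataFrame, sim_dir: str, cfg: PipelineConfig) -> pd.DataFrame:
    # Default erosion is 2 px deeper than the true ring: segmentation masks
    # sit slightly outside the cell boundary (threshold + blur), and a deeper
    # interior estimate keeps membrane signal from bleeding into it.
    ring = cfg.ring_width_px if cfg.ring_width_px is not None else cfg.plan.ring_width_px + 2
    frames = []
    for _, row in manifest.iterrows():
        stack, _meta = imaging.read_stack(os.path.join(sim_dir, row["stack_path"]))
        df = imaging.quantify_stack(
            stack.astype(np.float64) / row["intensity_scale"],
            ring_width_px=ring,
            min_area=cfg.min_area,
            max_area=cfg.max_area,
        )
        df.insert(0, "stack_path", row["stack_path"])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def simulate_measurements(
    design,
    mech: MechanismParams,
    plan: ScenePlan,
    seed: int = 0,
    noise: NoiseParams = NoiseParams(),
    n_pages: int = 1,
    ring_width_px: int | None = None,
    min_area: int = 120,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a design and quantify it fully in memory (no files written).

    Returns ``(per_experiment, manifest)`` exactly as the disk-based stages
    would, which makes repeated parameter-recovery simulations cheap.  Every
    stack gets a fresh scene; all randomness derives from ``seed``.
    """
    from .simulate._render import render_stack
    from .simulate._scene import build_scene

    if not design:
        raise ConfigurationError("experiment design is empty")
    ring = ring_width_px if ring_width_px is not None else plan.ring_width_px + 2
    children = np.random.SeedSequence(seed).spawn(len(design))
    manifest_rows = []
    frames = []
    for i, (cond, child) in enumerate(zip(design, children)):
        scene_seed, noise_seed = (int(s) for s in child.generate_state(2) % (2**31))
        scene = build_scene(ScenePlan(**{**plan.__dict__, "rng_seed": scene_seed}))
        stack, _, _ = render_stack(
            scene, cond, mech, noise=noise, seed=noise_seed, n_pages=n_pages,
            intensity_scale=DEFAULT_INTENSITY_SCALE,
        )
        name = f"stack_{i:04d}"
        row = cond.to_manifest_row(name)
        row["intensity_scale"] = DEFAULT_INTENSITY_SCALE
        manifest_rows.append(row)
        df = imaging.quantify_stack(
            stack.astype(np.float64) / DEFAULT_INTENSITY_SCALE,
            ring_width_px=ring,
            min_area=min_area,
        )
        df.insert(0, "stack_path", name)
        frames.append(df)
    manifest = pd.DataFrame(manifest_rows)
    cells = pd.concat(frames, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_exp, _ = imaging.aggregate(cells, manifest)
    return per_exp, manifest


def specific_activities(per_exp: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Blocked-subtracted activity per (condition, experiment).

    The nonspecific reference for a measurement is the fluoxetine-blocked
    stack matched on construct, substrate, substrate concentration,
    digitonin level, and experiment.
    """
    attrs = manifest[_COND_ATTRS].drop_duplicates("condition_id")
    df = per_exp.merge(attrs, on="condition_id", how="left")
    key_cols = ["mutant", "substrate", "substrate_conc_uM", "digitonin_ug_ml", "experiment_id"]

    blocked = {}
    for _, row in df[df["uptake_blocked"]].iterrows():
        blocked[tuple(row[k] for k in key_cols)] = row[_metric_col(row)]

    rows = []
    for _, row in df[~df["uptake_blocked"]].iterrows():
        key = tuple(row[k] for k in key_cols)
        ns = blocked.get(key)
        if ns is None:
            warnings.warn(f"no blocked reference for {row['condition_id']}", stacklevel=2)
            ns = 0.0
        raw = row[_metric_col(row)]
        out = {k: row[k] for k in _COND_ATTRS if k != "uptake_blocked"}
        out["experiment_id"] = row["experiment_id"]
        out["n_cells"] = row["n_cells"]
        out["raw_activity"] = raw
        out["nonspecific"] = ns
        out["activity"] = max(0.0, raw - ns)
        rows.append(out)
    return pd.DataFrame(rows)


def _zero_activity(spec: pd.DataFrame, mutant, substrate, digitonin, exp) -> float:
    """Specific activity of the zero-reagent, no-ligand reference."""
    sel = spec[
        (spec["mutant"] == mutant)
        & (spec["substrate"] == substrate)
        & (spec["digitonin_ug_ml"] == digitonin)
        & (spec["experiment_id"] == exp)
        & (spec["mts_reagent"] == "none")
        & (spec["ligand"] == "none")
    ]
    if sel.empty:
        raise ConfigurationError(
            f"no zero-reagent reference for {mutant}/{substrate} "
            f"(digitonin {digitonin}, experiment {exp})"
        )
    return float(sel["activity"].mean())


def _group_label(ligand: str, medium: str) -> str:
    return medium if ligand == "none" and medium != "NaCl" else ligand


# ---------------------------------------------------------------------------
# analyses


def _analyze_mm(result: PipelineResult, cfg: PipelineConfig) -> None:
    spec = result.specific
    base = spec[(spec["mts_reagent"] == "none")]
    for (mutant, substrate), grp in base[base["ion_medium"] == "NaCl"].groupby(
        ["mutant", "substrate"]
    ):
        series = grp.rename(columns={"substrate_conc_uM": "conc", "activity": "value"})[
            ["conc", "experiment_id", "value"]
        ]
        if series.groupby("experiment_id")["conc"].nunique().min() < 4:
            continue
        summary = kinetics.fit_mm_experiments(series)
        result.kinetics_summaries[(mutant, substrate)] = summary
        logger.info(
            "MM fit %s/%s: Km=%.3f +/- %.3f uM, Vmax=%.2f +/- %.2f AFU",
            mutant, substrate, summary.Km, summary.Km_sem, summary.Vmax, summary.Vmax_sem,
        )

    # ion requirement panel at the standard substrate concentrations
    panels = []
    for substrate, grp in base.groupby("substrate"):
        std_conc = {"APP+": 2.0, "ASP+": 10.0}[substrate]
        sel = grp[grp["substrate_conc_uM"] == std_conc]
        means = sel.groupby("ion_medium")["activity"].mean().to_dict()
        if "NaCl" in means and len(means) > 1:
            tab = kinetics.ion_panel(means)
            tab.insert(0, "substrate", substrate)
            panels.append(tab)
    if panels:
        result.ion_uptake = pd.concat(panels, ignore_index=True)


def ladder_fits(spec: pd.DataFrame, model: str = "exponential") -> pd.DataFrame:
    """Fit every MTS concentration ladder in the specific-activity table."""
    treated = spec[spec["mts_reagent"] != "none"]
    frames = []
    group_cols = ["mutant", "substrate", "mts_reagent", "ligand", "ion_medium", "digitonin_ug_ml"]
    for key, grp in treated.groupby(group_cols, sort=True):
        mutant, substrate, reagent, ligand, medium, dig = key
        if grp["mts_conc_M"].nunique() < 3:
            continue  # fixed-concentration conditions are analyzed elsewhere
        fits = []
        for exp, sub in grp.groupby("experiment_id"):
            zero = _zero_activity(spec, mutant, substrate, dig, exp)
            conc = np.concatenate([[0.0], sub["mts_conc_M"].to_numpy()])
            act = np.concatenate([[zero], sub["activity"].to_numpy()])
            t = float(sub["mts_time_s"].iloc[0])
            fits.append(
                accessibility.fit_inhibition(
                    conc, act, t, model=model, experiment_id=exp
                )
            )
        frame = accessibility.fits_to_frame(
            fits,
            mutant=mutant,
            substrate=substrate,
            mts_reagent=reagent,
            ligand=ligand,
            ion_medium=medium,
            digitonin_ug_ml=dig,
            pathway=pathway_of(mutant),
        )
        frames.append(frame)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def _compare_ladders(result: PipelineResult, cfg: PipelineConfig) -> None:
    fits = result.fits
    if fits is None or fits.empty:
        return
    usable = fits[fits["converged"] & ~fits["below_detection"]]
    comparisons = []
    for (mutant, reagent, dig), grp in usable.groupby(
        ["mutant", "mts_reagent", "digitonin_ug_ml"], sort=True
    ):
        ctrl = grp[(grp["ligand"] == "none") & (grp["ion_medium"] == "NaCl")]
        if ctrl.empty:
            continue
        k_ctrl = dict(zip(ctrl["experiment_id"], ctrl["k"]))
        for (ligand, medium), sub in grp.groupby(["ligand", "ion_medium"], sort=True):
            if ligand == "none" and medium == "NaCl":
                continue
            k_cond = dict(zip(sub["experiment_id"], sub["k"]))
            try:
                comparisons.append(
                    compare.compare_conditions(
                        k_cond,
                        k_ctrl,
                        alpha=cfg.alpha,
                        min_fold=cfg.min_fold,
                        condition=_group_label(ligand, medium),
                        control="none",
                        pathway=pathway_of(mutant),
                        mutant=mutant,
                    )
                )
            except ConfigurationError as exc:
                logger.warning("comparison skipped for %s/%s: %s", mutant, ligand, exc)
    result.comparisons = comparisons
    result.comparison_table = _comparison_frame(comparisons)
    _call_conformations(result, cfg)


def _comparison_frame(comparisons) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": c.pathway,
                "mutant": c.mutant,
                "condition": c.condition,
                "control": c.control,
                "fold": c.fold,
                "p_value": c.p_value,
                "direction": c.direction,
                "n_pairs": c.n_pairs,
            }
            for c in comparisons
        ]
    )


def _call_conformations(result: PipelineResult, cfg: PipelineConfig) -> None:
    """Pair extracellular and cytoplasmic comparisons with the same label."""
    ex = {c.condition: c for c in result.comparisons if c.pathway == "extracellular"}
    cy = {c.condition: c for c in result.comparisons if c.pathway == "cytoplasmic"}
    rows = []
    for label in sorted(set(ex) & set(cy)):
        call = compare.call_conformation(ex[label], cy[label])
        rows.append(
            {
                "condition": label,
                "extracellular_direction": call.extracellular_direction,
                "extracellular_fold": call.extracellular_fold,
                "cytoplasmic_direction": call.cytoplasmic_direction,
                "cytoplasmic_fold": call.cytoplasmic_fold,
                "call": call.call,
            }
        )
    if rows:
        result.conformation_calls = pd.DataFrame(rows)


def _fixed_conc_rates(spec: pd.DataFrame) -> pd.DataFrame:
    """Back-calculated per-experiment rate constants for every
    fixed-concentration MTS condition."""
    treated = spec[spec["mts_reagent"] != "none"]
    rows = []
    for _, row in treated.iterrows():
        zero = _zero_activity(
            spec, row["mutant"], row["substrate"], row["digitonin_ug_ml"], row["experiment_id"]
        )
        frac = row["activity"] / zero if zero > 0 else math.nan
        k = accessibility.rate_from_remaining_fraction(
            frac, row["mts_conc_M"], row["mts_time_s"]
        )
        rows.append(
            {
                "mutant": row["mutant"],
                "pathway": pathway_of(row["mutant"]),
                "mts_reagent": row["mts_reagent"],
                "mts_conc_M": row["mts_conc_M"],
                "ligand": row["ligand"],
                "ion_medium": row["ion_medium"],
                "digitonin_ug_ml": row["digitonin_ug_ml"],
                "experiment_id": row["experiment_id"],
                "remaining_fraction": frac,
                "k": k,
            }
        )
    return pd.DataFrame(rows)


def _analyze_fixed_concentration(result: PipelineResult, cfg: PipelineConfig) -> None:
    rates = _fixed_conc_rates(result.specific)
    result.fits = rates
    comparisons = []
    for mutant, grp in rates.groupby("mutant", sort=True):
        ctrl = grp[(grp["ligand"] == "none") & (grp["ion_medium"] == "NaCl")]
        if ctrl.empty:
            continue
        k_ctrl = dict(zip(ctrl["experiment_id"], ctrl["k"]))
        for (ligand, medium), sub in grp.groupby(["ligand", "ion_medium"], sort=True):
            if ligand == "none" and medium == "NaCl":
                continue
            comparisons.append(
                compare.compare_conditions(
                    dict(zip(sub["experiment_id"], sub["k"])),
                    k_ctrl,
                    alpha=cfg.alpha,
                    min_fold=cfg.min_fold,
                    condition=_group_label(ligand, medium),
                    control="none",
                    pathway=pathway_of(mutant),
                    mutant=mutant,
                )
            )
    result.comparisons = comparisons
    result.comparison_table = _comparison_frame(comparisons)
    _call_conformations(result, cfg)


def _analyze_ion_panel(result: PipelineResult, cfg: PipelineConfig) -> None:
    rates = _fixed_conc_rates(result.specific)
    result.fits = rates
    comparisons = []
    for mutant, grp in rates.groupby("mutant", sort=True):
        pathway = pathway_of(mutant)
        k_by_medium = {
            medium: dict(zip(sub["experiment_id"], sub["k"]))
            for medium, sub in grp.groupby("ion_medium")
        }
        panel = compare.ion_panel_analysis(
            k_by_medium, pathway, alpha=cfg.alpha, min_fold=cfg.min_fold, mutant=mutant
        )
        result.ion_panels[mutant] = panel
        comparisons.extend(panel.comparisons)
    result.comparisons = comparisons
    result.comparison_table = pd.concat(
        [p.table.assign(pathway=p.pathway, mutant=m) for m, p in result.ion_panels.items()],
        ignore_index=True,
    )
    # conformational reading of each medium against the ion-free baseline
    ex_panel = next((p for p in result.ion_panels.values() if p.pathway == "extracellular"), None)
    cy_panel = next((p for p in result.ion_panels.values() if p.pathway == "cytoplasmic"), None)
    if ex_panel and cy_panel:
        ex = {c.condition: c for c in ex_panel.comparisons if c.control == "NMDG-gluconate"}
        cy = {c.condition: c for c in cy_panel.comparisons if c.control == "NMDG-gluconate"}
        rows = []
        for medium in sorted(set(ex) & set(cy)):
            call = compare.call_conformation(ex[medium], cy[medium])
            rows.append(
                {
                    "condition": medium,
                    "extracellular_direction": call.extracellular_direction,
                    "extracellular_fold": call.extracellular_fold,
                    "cytoplasmic_direction": call.cytoplasmic_direction,
                    "cytoplasmic_fold": call.cytoplasmic_fold,
                    "call": call.call,
                }
            )
        result.conformation_calls = pd.DataFrame(rows)


def _analyze_digitonin(result: PipelineResult, cfg: PipelineConfig) -> None:
    spec = result.specific
    base = spec[(spec["mts_reagent"] == "none") & (spec["mutant"] == "WT")]
    # total-fluorescence retention is judged on whole-cell mean fluorescence,
    # independent of which metric the binding/uptake assays use
    attrs = result.manifest[_COND_ATTRS].drop_duplicates("condition_id")
    per_exp = result.per_experiment.merge(attrs, on="condition_id", how="left")
    totals = per_exp[
        (per_exp["mts_reagent"] == "none")
        & (per_exp["mutant"] == "WT")
        & ~per_exp["uptake_blocked"]
    ]
    rows = []
    for (substrate, dig), grp in base.groupby(["substrate", "digitonin_ug_ml"], sort=True):
        tot = totals[
            (totals["substrate"] == substrate) & (totals["digitonin_ug_ml"] == dig)
        ]["mean_fluor_mean"].mean()
        rows.append(
            {
                "substrate": substrate,
                "digitonin_ug_ml": dig,
                "specific_activity": grp["activity"].mean(),
                "total_mean_fluor": tot,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        for substrate, grp in table.groupby("substrate"):
            ref = grp.loc[grp["digitonin_ug_ml"] == 0.0, "total_mean_fluor"]
            if len(ref):
                table.loc[grp.index, "retention_vs_untreated"] = (
                    grp["total_mean_fluor"] / float(ref.iloc[0])
                )
    result.digitonin_table = table
    result.fits = ladder_fits(spec, cfg.fit_model)
    _compare_ladders(result, cfg)


_ANALYSES = {
    "mm_kinetics": _analyze_mm,
    "fixed_concentration": _analyze_fixed_concentration,
    "ion_panel": _analyze_ion_panel,
    "digitonin_panel": _analyze_digitonin,
}


# ---------------------------------------------------------------------------
# driver


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline for one configuration; write all outputs."""
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "log.txt")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
        design, analysis = get_preset(config.preset, config.n_experiments)
        logger.info("preset %s: %d stacks, analysis %s", config.preset, len(design), analysis)

        sim_dir = os.path.join(config.out_dir, "stacks")
        manifest = generate_experiment(
            design,
            config.mech,
            config.plan,
            sim_dir,
            seed=config.seed,
            noise=config.noise,
            n_pages=config.n_pages,
            intensity_scale=config.intensity_scale,
        )
        cells = _quantify_all(manifest, sim_dir, config)
        per_exp, per_cond = imaging.aggregate(cells, manifest)
        specific = specific_activities(per_exp, manifest)

        result = PipelineResult(
            config=config,
            manifest=manifest,
            cells=cells,
            per_experiment=per_exp,
            per_condition=per_cond,
            specific=specific,
        )
        if analysis == "inhibition_ladder":
            result.fits = ladder_fits(specific, config.fit_model)
            _compare_ladders(result, config)
        else:
            _ANALYSES[analysis](result, config)

        _write_outputs(result)
        return result
    except ScamfluxError:
        logger.exception("pipeline failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_outputs(result: PipelineResult) -> None:
    out = result.config.out_dir
    result.cells.to_csv(os.path.join(out, "cells.csv"), index=False)
    result.per_experiment.to_csv(os.path.join(out, "per_experiment.csv"), index=False)
    result.per_condition.to_csv(os.path.join(out, "per_condition.csv"), index=False)
    result.specific.to_csv(os.path.join(out, "specific_activity.csv"), index=False)
    if result.fits is not None and len(result.fits):
        result.fits.to_csv(os.path.join(out, "fits.csv"), index=False)
    if result.comparison_table is not None and len(result.comparison_table):
        result.comparison_table.to_csv(os.path.join(out, "comparisons.csv"), index=False)
    if result.conformation_calls is not None:
        result.conformation_calls.to_csv(
            os.path.join(out, "conformation_calls.csv"), index=False
        )
    if result.kinetics_summaries:
        rows = [
            {
                "mutant": mutant,
                "substrate": substrate,
                "Km_uM": s.Km,
                "Km_sem": s.Km_sem,
                "Vmax_AFU": s.Vmax,
                "Vmax_sem": s.Vmax_sem,
                "n_experiments": s.n_experiments,
            }
            for (mutant, substrate), s in sorted(result.kinetics_summaries.items())
        ]
        pd.DataFrame(rows).to_csv(os.path.join(out, "kinetics_fits.csv"), index=False)
    if result.ion_uptake is not None:
        result.ion_uptake.to_csv(os.path.join(out, "ion_uptake.csv"), index=False)
    if result.digitonin_table is not None:
        result.digitonin_table.to_csv(os.path.join(out, "digitonin_panel.csv"), index=False)
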