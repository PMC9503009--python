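"""Bundled experiment designs mirroring the study's assay panels.

Each preset returns the list of conditions to simulate plus the analysis the
pipeline should run on the quantified stacks.  Naming follows the figure
panels of the study design: substrate kinetics and ion requirements
(``fig1``), MTSET concentration ladders on the extracellular cysteines
(``fig3``), ligand effects by ladder (``fig4``) and by fixed-concentration
protection (``fig5``), digitonin permeabilization (``fig6``), cytoplasmic
MTSEA ladders (``fig7``), ion panels (``fig8``), and vilazodone on both
pathways (``fig9``).
"""

from __future__ import annotations

import numpy as np

from ._errors import ConfigurationError
from .conditions import ConditionSpec

#: MTSET concentration ladder, 0.1 uM - 1 mM (8 points, log-spaced).
MTSET_LADDER_M = tuple(float(c) for c in 10 ** np.linspace(-7, -3, 8))
#: MTSET ladder used in ligand experiments, 1 uM - 1 mM.
MTSET_LIGAND_LADDER_M = tuple(float(c) for c in 10 ** np.linspace(-6, -3, 8))
#: MTSEA ladder, 1 uM - 5 mM.
MTSEA_LADDER_M = tuple(float(c) for c in 10 ** np.linspace(-6, np.log10(5e-3), 8))

#: Substrate concentration series for Michaelis-Menten fits (uM).
APP_CONC_SERIES_UM = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
ASP_CONC_SERIES_UM = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)

#: Fixed MTSET concentrations near the control IC50 (M).
FIXED_MTSET_M = {"Y107C/C109A": 1e-5, "S404C/C109A": 2e-6}
#: Fixed MTSEA concentration for the cytoplasmic ion panel (M).
FIXED_MTSEA_M = 1.2e-4

MTSET_TIME_S = 900.0
MTSEA_TIME_S = 300.0
DIGITONIN_REF = 25.0

PRESETS = {}


def _register(name):
    def deco(fn):
        PRESETS[name] = fn
        return fn

    return deco


def get_preset(name: str, n_experiments: int = 3) -> tuple[list[ConditionSpec], str]:
    """Return ``(design, analysis)`` for a named preset."""
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name](n_experiments)


def _uptake_refs(mutant, substrate, conc, exp, digitonin=0.0):
    """Zero-MTS reference stack and its fluoxetine-blocked partner."""
    base = ConditionSpec(
        substrate=substrate,
        substrate_conc_uM=conc,
        mutant=mutant,
        digitonin_ug_ml=digitonin,
        experiment_id=exp,
    )
    return [base, base.blocked_partner()]


def _ladder(mutant, reagent, concs, t_exposure, exp, ligand="none", medium="NaCl",
            substrate="APP+", sub_conc=2.0, digitonin=0.0):
    lig_conc = 0.0 if ligand == "none" else 10.0
    return [
        ConditionSpec(
            substrate=substrate,
            substrate_conc_uM=sub_conc,
            mts_reagent=reagent,
            mts_conc_M=c,
            mts_time_s=t_exposure,
            ligand=ligand,
            ligand_conc_uM=lig_conc,
            ion_medium=medium,
            digitonin_ug_ml=digitonin,
            mutant=mutant,
            experiment_id=exp,
        )
        for c in concs
    ]


@_register("fig1")
def fig1_design(n_experiments=3):
    """Substrate kinetics (total + blocked series) and the four-media ion panel."""
    design = []
    for exp in range(1, n_experiments + 1):
        for substrate, series in (("APP+", APP_CONC_SERIES_UM), ("ASP+", ASP_CONC_SERIES_UM)):
            for conc in series:
                design += _uptake_refs("WT", substrate, conc, exp)
        # the NaCl reference of the ion panel is the matching point of the
        # kinetics series above (APP+ 2 uM / ASP+ 10 uM in NaCl)
        for medium in ("NMDG-gluconate", "NMDG-Cl", "Na-isethionate"):
            for substrate, conc in (("APP+", 2.0), ("ASP+", 10.0)):
                base = ConditionSpec(
                    substrate=substrate,
                    substrate_conc_uM=conc,
                    ion_medium=medium,
                    mutant="WT",
                    experiment_id=exp,
                )
                design += [base, base.blocked_partner()]
    return design, "mm_kinetics"


@_register("fig3")
def fig3_design(n_experiments=3):
    """MTSET ladders on C109A, Y107C/C109A, S404C/C109A (APP+ readout)."""
    design = []
    for exp in range(1, n_experiments + 1):
        for mutant in ("C109A", "Y107C/C109A", "S404C/C109A"):
            design += _uptake_refs(mutant, "APP+", 2.0, exp)
            design += _ladder(mutant, "MTSET", MTSET_LADDER_M, MTSET_TIME_S, exp)
    return design, "inhibition_ladder"


@_register("fig3-recovery")
def fig3_recovery_design(n_experiments=3):
    """The Y107C/C109A arm of the fig3 design, used for parameter-recovery
    simulations (same ladder, cells, and replicate structure)."""
    design = []
    for exp in range(1, n_experiments + 1):
        design += _uptake_refs("Y107C/C109A", "APP+", 2.0, exp)
        design += _ladder("Y107C/C109A", "MTSET", MTSET_LADDER_M, MTSET_TIME_S, exp)
    return design, "inhibition_ladder"


@_register("fig4")
def fig4_design(n_experiments=3):
    """Ligand effects on the Y107C/C109A MTSET inhibition curve."""
    design = []
    for exp in range(1, n_experiments + 1):
        design += _uptake_refs("Y107C/C109A", "APP+", 2.0, exp)
        for ligand in ("none", "fluoxetine", "citalopram", "5-HT"):
            design += _ladder(
                "Y107C/C109A", "MTSET", MTSET_LIGAND_LADDER_M, MTSET_TIME_S, exp, ligand=ligand
            )
    return design, "inhibition_ladder"


@_register("fig5")
def fig5_design(n_experiments=3):
    """Fixed-concentration MTSET protection assay on both extracellular mutants."""
    ligands = ("none", "fluoxetine", "paroxetine", "citalopram", "imipramine",
               "5-HT", "5-HTP", "Trp")
    design = []
    for exp in range(1, n_experiments + 1):
        for mutant, conc in FIXED_MTSET_M.items():
            design += _uptake_refs(mutant, "APP+", 2.0, exp)
            for ligand in ligands:
                design += _ladder(
                    mutant, "MTSET", (conc,), MTSET_TIME_S, exp, ligand=ligand
                )
    return design, "fixed_concentration"


@_register("fig6")
def fig6_design(n_experiments=3):
    """Digitonin panel plus MTSEA ladders on S277C/X5C and the X5C background."""
    design = []
    for exp in range(1, n_experiments + 1):
        for dig in (0.0, 10.0, 15.0, 25.0, 50.0, 100.0):
            for substrate, conc in (("APP+", 2.0), ("ASP+", 10.0)):
                design += _uptake_refs("WT", substrate, conc, exp, digitonin=dig)
        for mutant in ("S277C/X5C", "X5C"):
            design += _uptake_refs(mutant, "ASP+", 10.0, exp, digitonin=DIGITONIN_REF)
            design += _ladder(
                mutant, "MTSEA", MTSEA_LADDER_M, MTSEA_TIME_S, exp,
                substrate="ASP+", sub_conc=10.0, digitonin=DIGITONIN_REF,
            )
    return design, "digitonin_panel"


@_register("fig7")
def fig7_design(n_experiments=3):
    """Ligand effects on cytoplasmic MTSEA inhibition of ASP+ binding."""
    design = []
    for exp in range(1, n_experiments + 1):
        design += _uptake_refs("S277C/X5C", "ASP+", 10.0, exp, digitonin=DIGITONIN_REF)
        for ligand in ("none", "fluoxetine", "citalopram", "5-HT"):
            design += _ladder(
                "S277C/X5C", "MTSEA", MTSEA_LADDER_M, MTSEA_TIME_S, exp,
                ligand=ligand, substrate="ASP+", sub_conc=10.0, digitonin=DIGITONIN_REF,
            )
    return design, "inhibition_ladder"


@_register("fig8")
def fig8_design(n_experiments=3):
    """Fixed-concentration ion panels on both pathways."""
    media = ("NMDG-gluconate", "NMDG-Cl", "Na-isethionate", "NaCl", "NaCl+5-HT")
    design = []
    for exp in range(1, n_experiments + 1):
        design += _uptake_refs("Y107C/C109A", "APP+", 2.0, exp)
        for medium in media:
            design += _ladder(
                "Y107C/C109A", "MTSET", (FIXED_MTSET_M["Y107C/C109A"],), MTSET_TIME_S,
                exp, medium=medium,
            )
        design += _uptake_refs("S277C/X5C", "ASP+", 10.0, exp, digitonin=DIGITONIN_REF)
        for medium in media:
            design += _ladder(
                "S277C/X5C", "MTSEA", (FIXED_MTSEA_M,), MTSEA_TIME_S, exp,
                medium=medium, substrate="ASP+", sub_conc=10.0, digitonin=DIGITONIN_REF,
            )
    return design, "ion_panel"


@_register("fig9")
def fig9_design(n_experiments=3):
    """Vilazodone on both pathways (full concentration ladders)."""
    design = []
    for exp in range(1, n_experiments + 1):
        design += _uptake_refs("Y107C/C109A", "APP+", 2.0, exp)
        for ligand in ("none", "vilazodone"):
            design += _ladder(
                "Y107C/C109A", "MTSET", MTSET_LIGAND_LADDER_M, MTSET_TIME_S, exp,
                ligand=ligand,
            )
        design += _uptake_refs("S277C/X5C", "ASP+", 10.0, exp, digitonin=DIGITONIN_REF)
        for ligand in ("none", "vilazodone"):
            design += _ladder(
                "S277C/X5C", "MTSEA", MTSEA_LADDER_M, MTSEA_TIME_S, exp,
                ligand=ligand, substrate="ASP+", sub_conc=10.0, digitonin=DIGITONIN_REF,
            )
    return design, "inhibition_ladder"
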