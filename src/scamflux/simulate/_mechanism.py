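"""Mechanistic signal model for fluorescent-substrate assays.

The model composes four pieces:

1. **Transport** — specific substrate accumulation over the 5-min uptake
   window follows Michaelis-Menten initial-rate kinetics,
   ``v = Vmax * S / (Km + S)``, expressed directly in arbitrary fluorescence
   units (AFU) accumulated over the standard window.  Transport requires the
   simultaneous presence of Na+ and Cl- (NaCl-based media only).
2. **Surface binding** (ASP+ only) — a saturable membrane-bound component,
   ``b = Bmax * S / (Kd + S)``, which survives digitonin permeabilization.
3. **Cysteine modification** — pre-treatment with an MTS reagent at
   concentration ``c`` for time ``t`` leaves an unmodified transporter
   fraction ``floor + (1 - floor) * exp(-k_eff * c * t)`` (pseudo-first-order
   kinetics in reagent concentration).  ``k_eff`` is the construct's base
   rate constant times condition-dependent fold factors (ligands, ions).
   For cytoplasm-facing cysteines the modifiable fraction is additionally
   capped by how completely digitonin has permeabilized the membrane.
4. **Digitonin** — suppresses uptake steeply with concentration while
   largely sparing surface binding.

Nonspecific (fluoxetine-insensitive) components share the saturable
concentration dependence of their specific counterparts so that the
blockable fraction of the signal is concentration-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .._errors import ConfigurationError
from ..conditions import (
    ConditionSpec,
    CYTOPLASMIC_MUTANTS,
    TRANSPORT_MEDIA,
    pathway_of,
)

# Per-construct Michaelis-Menten parameters (Km in uM, Vmax in AFU) for both
# substrates; constructs not listed fall back to WT values.
DEFAULT_MUTANT_KINETICS = {
    "WT": {"Km_app": 2.63, "Vmax_app": 30.5, "Km_asp": 8.52, "Vmax_asp": 75.8},
    "Y107C/C109A": {"Km_app": 2.39, "Vmax_app": 39.4, "Km_asp": 9.32, "Vmax_asp": 59.9},
    "S404C/C109A": {"Km_app": 2.07, "Vmax_app": 34.9, "Km_asp": 8.87, "Vmax_asp": 53.2},
    "S277C/X5C": {"Km_app": 1.99, "Vmax_app": 26.5, "Km_asp": 9.66, "Vmax_asp": 40.2},
}

# Base modification rate constants (M^-1 s^-1) per (construct, reagent) in the
# standard NaCl assay buffer.  The two extracellular MTSET values follow from
# the measured half-maximal concentrations (0.011 mM and 0.0025 mM at 15 min)
# via k = ln2 / (t * c50); the cytoplasmic MTSEA values are measured directly.
DEFAULT_K_BASE = {
    ("Y107C/C109A", "MTSET"): 70.0,
    ("S404C/C109A", "MTSET"): 308.0,
    ("S277C/X5C", "MTSEA"): 11.97,
    ("X5C", "MTSEA"): 0.05,
    # MTSET cannot reach the cytoplasmic pathway even in permeabilized cells,
    # and the cysteine-less backgrounds are unreactive.
    ("S277C/X5C", "MTSET"): 0.0,
    ("X5C", "MTSET"): 0.0,
    ("C109A", "MTSET"): 0.0,
    ("C109A", "MTSEA"): 0.0,
    ("WT", "MTSET"): 0.0,
    ("WT", "MTSEA"): 0.0,
}

# Ligand-induced fold changes on k_eff, relative to the no-ligand control in
# the same medium.  Antidepressants open the extracellular pathway (folds
# 1.7-2.2) and close the cytoplasmic one; substrate 5-HT does the opposite;
# the 5-HT precursors are inert; vilazodone acts like the antidepressants
# despite binding an allosteric site.
DEFAULT_LIGAND_FOLD = {
    "extracellular": {
        "none": 1.0,
        "fluoxetine": 2.0,
        "paroxetine": 2.2,
        "citalopram": 1.8,
        "imipramine": 1.7,
        "5-HT": 0.5,
        "5-HTP": 1.0,
        "Trp": 1.0,
        "vilazodone": 1.8,
    },
    "cytoplasmic": {
        "none": 1.0,
        "fluoxetine": 0.5,
        "paroxetine": 0.5,
        "citalopram": 0.33,
        "imipramine": 0.5,
        "5-HT": 2.0,
        "5-HTP": 1.0,
        "Trp": 1.0,
        "vilazodone": 0.5,
    },
}

# Ion-composition fold changes on k_eff, normalized to the NaCl assay buffer
# (in which the base rate constants are defined).  Relative to the
# NMDG-gluconate (ion-free) baseline these reproduce the qualitative pattern:
# Na+ alone opens the extracellular pathway (1.3/0.714 ~ 1.8x) and closes the
# cytoplasmic one; adding Cl- partially reverses the Na+ effect; adding both
# Cl- and 5-HT reverses it past baseline.
DEFAULT_ION_FOLD = {
    "extracellular": {
        "NaCl": 1.0,
        "Na-isethionate": 1.3,
        "NMDG-gluconate": 5.0 / 7.0,
        "NMDG-Cl": 5.0 / 7.0,
        "NaCl+5-HT": 0.5,
    },
    "cytoplasmic": {
        "NaCl": 1.0,
        "Na-isethionate": 0.714,
        "NMDG-gluconate": 1.43,
        "NMDG-Cl": 1.43,
        "NaCl+5-HT": 2.0,
    },
}

# Fraction of cytoplasm-facing cysteine rendered modifiable as a function of
# digitonin concentration (ug/mL): piecewise-linear breakpoints.
DEFAULT_ACCESS_COMPLETENESS = ((0.0, 0.0), (10.0, 0.4), (15.0, 0.5), (25.0, 1.0))


@dataclass
class SignalComponents:
    """Decomposed per-cell mean signal (AFU) predicted for one condition."""

    interior_specific: float
    interior_nonspecific: float
    membrane_specific: float
    membrane_nonspecific: float
    unmodified_fraction: float
    k_eff: float

    @property
    def interior_mean(self) -> float:
        return self.interior_specific + self.interior_nonspecific

    @property
    def membrane_mean(self) -> float:
        return self.membrane_specific + self.membrane_nonspecific


@dataclass
class MechanismParams:
    """Ground-truth parameters of the synthetic assay mechanism.

    Concentrations are uM unless noted; rate constants M^-1 s^-1; signals AFU.
    """

    mutant_kinetics: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MUTANT_KINETICS.items()}
    )
    #: ASP+ surface binding: dissociation constant (uM) and capacity (AFU).
    Kd_bind_asp: float = 5.0
    Bmax_asp: float = 110.0
    #: Nonspecific signal amplitude as a fraction of the specific Vmax/Bmax.
    #: 0.05/0.95 makes 95% of interior signal fluoxetine-blockable (APP+);
    #: the binding fraction makes 84% of total ASP+ signal blockable at the
    #: standard 10 uM ASP+.
    nonspecific_uptake_frac: float = 0.05 / 0.95
    nonspecific_bind_frac: float = 0.2674
    k_base: dict = field(default_factory=lambda: dict(DEFAULT_K_BASE))
    ligand_fold: dict = field(
        default_factory=lambda: {p: dict(m) for p, m in DEFAULT_LIGAND_FOLD.items()}
    )
    ion_fold: dict = field(
        default_factory=lambda: {p: dict(m) for p, m in DEFAULT_ION_FOLD.items()}
    )
    #: Intrinsically unmodifiable activity fraction (0 = full modification).
    residual_modifiable_floor: float = 0.0
    #: Digitonin suppression of uptake: Hill-type with IC50 (ug/mL) and slope.
    digitonin_uptake_ic50: float = 9.0
    digitonin_uptake_hill: float = 3.0
    #: Fraction of surface binding retained at the reference 25 ug/mL.
    digitonin_bind_retention: float = 0.9
    digitonin_access_completeness: tuple = DEFAULT_ACCESS_COMPLETENESS
    #: Standard incubation windows (s).
    exposure_time_mtset: float = 900.0
    exposure_time_mtsea: float = 300.0
    uptake_time_s: float = 300.0

    def __post_init__(self) -> None:
        for name in ("Kd_bind_asp", "Bmax_asp", "digitonin_uptake_ic50", "uptake_time_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in (
            "nonspecific_uptake_frac",
            "nonspecific_bind_frac",
            "residual_modifiable_floor",
            "digitonin_bind_retention",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for mut, params in self.mutant_kinetics.items():
            for key, v in params.items():
                if v <= 0:
                    raise ConfigurationError(f"{mut} {key} must be strictly positive")
        for key, v in self.k_base.items():
            if v < 0:
                raise ConfigurationError(f"k_base{key} must be >= 0")
        concs = [c for c, _ in self.digitonin_access_completeness]
        fracs = [f for _, f in self.digitonin_access_completeness]
        if sorted(concs) != list(concs) or any(not 0 <= f <= 1 for f in fracs):
            raise ConfigurationError("invalid digitonin access-completeness table")

    # -- parameter lookups ------------------------------------------------

    def mm_params(self, mutant: str, substrate: str) -> tuple[float, float]:
        """Return (Km uM, Vmax AFU) for a construct/substrate pair."""
        params = self.mutant_kinetics.get(mutant, self.mutant_kinetics["WT"])
        if substrate == "APP+":
            return params["Km_app"], params["Vmax_app"]
        return params["Km_asp"], params["Vmax_asp"]

    def default_exposure_time(self, reagent: str) -> float:
        return {"MTSET": self.exposure_time_mtset, "MTSEA": self.exposure_time_mtsea}.get(
            reagent, 0.0
        )

    def access_completeness(self, digitonin_ug_ml: float) -> float:
        """Modifiable fraction of a cytoplasm-facing cysteine at a given
        digitonin concentration (piecewise-linear, clamped to [0, 1])."""
        xs = np.array([c for c, _ in self.digitonin_access_completeness])
        ys = np.array([f for _, f in self.digitonin_access_completeness])
        return float(np.clip(np.interp(digitonin_ug_ml, xs, ys), 0.0, 1.0))

    def digitonin_uptake_factor(self, digitonin_ug_ml: float) -> float:
        if digitonin_ug_ml <= 0:
            return 1.0
        ratio = digitonin_ug_ml / self.digitonin_uptake_ic50
        return 1.0 / (1.0 + ratio**self.digitonin_uptake_hill)

    def digitonin_bind_factor(self, digitonin_ug_ml: float) -> float:
        """Surface-binding retention; mild linear loss anchored at the
        reference 25 ug/mL retention, floored at 0.5 for high doses."""
        if digitonin_ug_ml <= 0:
            return 1.0
        loss = (1.0 - self.digitonin_bind_retention) * digitonin_ug_ml / 25.0
        return max(0.5, 1.0 - loss)

    def k_eff(self, cond: ConditionSpec) -> float:
        """Effective modification rate constant for a condition (M^-1 s^-1)."""
        if cond.mts_reagent == "none":
            return 0.0
        base = self.k_base.get((cond.mutant, cond.mts_reagent), 0.0)
        pathway = pathway_of(cond.mutant)
        if pathway == "none" or base == 0.0:
            return 0.0
        try:
            lig = self.ligand_fold[pathway][cond.ligand]
            ion = self.ion_fold[pathway][cond.ion_medium]
        except KeyError as exc:  # pragma: no cover - guarded by ConditionSpec
            raise ConfigurationError(f"no fold factor for {exc}") from exc
        return base * lig * ion

    def accessibility_fold(self, cond: ConditionSpec) -> float:
        """Condition multiplier on the base rate constant (k_eff / k_base)."""
        base = self.k_base.get((cond.mutant, cond.mts_reagent), 0.0)
        if base == 0.0:
            return 1.0
        return self.k_eff(cond) / base

    def unmodified_fraction(self, cond: ConditionSpec) -> float:
        """Transporter fraction left active after the MTS pre-treatment."""
        if cond.mts_reagent == "none" or cond.mts_conc_M == 0.0:
            return 1.0
        completeness = 1.0
        if cond.mutant in CYTOPLASMIC_MUTANTS:
            completeness = self.access_completeness(cond.digitonin_ug_ml)
        modifiable = completeness * (1.0 - self.residual_modifiable_floor)
        k = self.k_eff(cond)
        decay = math.exp(-k * cond.mts_conc_M * cond.mts_time_s)
        return (1.0 - modifiable) + modifiable * decay


def signal_components(cond: ConditionSpec, mech: MechanismParams) -> SignalComponents:
    """Predict the decomposed per-cell mean signal for one condition."""
    S = cond.substrate_conc_uM
    Km, Vmax = mech.mm_params(cond.mutant, cond.substrate)
    unmod = mech.unmodified_fraction(cond)
    time_scale = mech.uptake_time_s / 300.0

    # Medium during the accumulation measurement: accessibility protocols wash
    # cells back into the standard NaCl buffer after the MTS step, so the
    # condition's ion_medium gates uptake only when there was no MTS step.
    uptake_medium = cond.ion_medium if cond.mts_reagent == "none" else "NaCl"
    ion_gate = 1.0 if uptake_medium in TRANSPORT_MEDIA else 0.0
    dig_up = mech.digitonin_uptake_factor(cond.digitonin_ug_ml)
    blocked = 0.0 if cond.uptake_blocked else 1.0

    sat = S / (Km + S) if S > 0 else 0.0
    interior_specific = Vmax * sat * ion_gate * dig_up * unmod * blocked * time_scale
    interior_nonspecific = mech.nonspecific_uptake_frac * Vmax * sat * dig_up * time_scale

    membrane_specific = 0.0
    membrane_nonspecific = 0.0
    if cond.substrate == "ASP+":
        bsat = S / (mech.Kd_bind_asp + S) if S > 0 else 0.0
        dig_bind = mech.digitonin_bind_factor(cond.digitonin_ug_ml)
        membrane_specific = mech.Bmax_asp * bsat * dig_bind * unmod * blocked
        membrane_nonspecific = mech.nonspecific_bind_frac * mech.Bmax_asp * bsat

    return SignalComponents(
        interior_specific=interior_specific,
        interior_nonspecific=interior_nonspecific,
        membrane_specific=membrane_specific,
        membrane_nonspecific=membrane_nonspecific,
        unmodified_fraction=unmod,
        k_eff=mech.k_eff(cond),
    )


def signal_model(cond: ConditionSpec, mech: MechanismParams) -> tuple[float, float]:
    """Per-cell (interior mean, membrane mean) in AFU for one condition."""
    comp = signal_components(cond, mech)
    return comp.interior_mean, comp.membrane_mean
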