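"""Assay-condition vocabulary and the :class:`ConditionSpec` record.

A condition describes one imaging stack: which transporter construct is
expressed, which fluorescent substrate is applied and at what concentration,
whether the cells were pre-treated with a methanethiosulfonate (MTS) reagent
and/or a conformational ligand, the ion composition of the incubation medium,
and the digitonin concentration used to permeabilize the membrane.

Two subtleties of the wet protocol are encoded explicitly:

* ``ligand`` is present only during the MTS exposure and is washed out before
  the substrate accumulation is measured; it changes cysteine reactivity but
  not the uptake measurement itself.
* ``uptake_blocked`` means 10 uM fluoxetine is present *during* the
  accumulation/binding measurement.  Such stacks define the nonspecific
  component that is subtracted from matched total-signal stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from ._errors import ConfigurationError

SUBSTRATES = ("APP+", "ASP+")
MTS_REAGENTS = ("none", "MTSET", "MTSEA")
LIGANDS = (
    "none",
    "fluoxetine",
    "paroxetine",
    "citalopram",
    "imipramine",
    "5-HT",
    "5-HTP",
    "Trp",
    "vilazodone",
)
#: All media are 150 mM; mutually exclusive alternatives for the MTS/uptake buffer.
ION_MEDIA = ("NMDG-gluconate", "NMDG-Cl", "Na-isethionate", "NaCl", "NaCl+5-HT")
MUTANTS = ("WT", "C109A", "Y107C/C109A", "S404C/C109A", "S277C/X5C", "X5C")

#: Constructs whose reporter cysteine faces the extracellular pathway.
EXTRACELLULAR_MUTANTS = ("Y107C/C109A", "S404C/C109A")
#: Constructs whose reporter cysteine faces the cytoplasmic pathway.
CYTOPLASMIC_MUTANTS = ("S277C/X5C", "X5C")

#: Media that contain both Na+ and Cl-, the requirement for specific transport.
TRANSPORT_MEDIA = ("NaCl", "NaCl+5-HT")

#: Default MTS exposure times (s): 15 min for MTSET, 5 min for MTSEA.
DEFAULT_MTS_TIME_S = {"MTSET": 900.0, "MTSEA": 300.0}

#: Standard substrate concentrations (uM) used in accumulation measurements.
STANDARD_SUBSTRATE_CONC_UM = {"APP+": 2.0, "ASP+": 10.0}


def pathway_of(mutant: str) -> str:
    """Return which permeation pathway a construct's reporter cysteine probes."""
    if mutant in EXTRACELLULAR_MUTANTS:
        return "extracellular"
    if mutant in CYTOPLASMIC_MUTANTS:
        return "cytoplasmic"
    return "none"


@dataclass(frozen=True)
class ConditionSpec:
    """Full description of one assay condition (one image stack)."""

    substrate: str = "APP+"
    substrate_conc_uM: float = 2.0
    mts_reagent: str = "none"
    mts_conc_M: float = 0.0
    mts_time_s: float = 0.0
    ligand: str = "none"
    ligand_conc_uM: float = 0.0
    ion_medium: str = "NaCl"
    digitonin_ug_ml: float = 0.0
    mutant: str = "WT"
    uptake_blocked: bool = False
    experiment_id: int = 1
    replicate_id: int = 1

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES:
            raise ConfigurationError(f"unknown substrate {self.substrate!r}")
        if self.mts_reagent not in MTS_REAGENTS:
            raise ConfigurationError(f"unknown MTS reagent {self.mts_reagent!r}")
        if self.ligand not in LIGANDS:
            raise ConfigurationError(f"unknown ligand {self.ligand!r}")
        if self.ion_medium not in ION_MEDIA:
            raise ConfigurationError(f"unknown ion medium {self.ion_medium!r}")
        if self.mutant not in MUTANTS:
            raise ConfigurationError(f"unknown mutant {self.mutant!r}")
        if self.substrate_conc_uM < 0:
            raise ConfigurationError("substrate concentration must be >= 0")
        if self.mts_conc_M < 0 or self.mts_time_s < 0:
            raise ConfigurationError("MTS concentration and time must be >= 0")
        if self.digitonin_ug_ml < 0:
            raise ConfigurationError("digitonin concentration must be >= 0")
        # zero concentration and 'none' reagent must agree
        if (self.mts_reagent == "none") != (self.mts_conc_M == 0.0):
            raise ConfigurationError(
                "mts_conc_M must be 0 iff mts_reagent is 'none' "
                f"(got {self.mts_reagent!r} at {self.mts_conc_M} M)"
            )
        if self.mts_reagent != "none" and self.mts_time_s <= 0:
            raise ConfigurationError("MTS exposure requires mts_time_s > 0")
        if (self.ligand == "none") != (self.ligand_conc_uM == 0.0):
            raise ConfigurationError("ligand_conc_uM must be 0 iff ligand is 'none'")

    @property
    def pathway(self) -> str:
        return pathway_of(self.mutant)

    def condition_id(self) -> str:
        """Stable identifier of the condition, excluding replicate structure."""
        parts = [
            self.mutant,
            f"{self.substrate}@{self.substrate_conc_uM:g}uM",
            f"{self.mts_reagent}@{self.mts_conc_M:g}M" if self.mts_reagent != "none" else "noMTS",
            f"{self.ligand}@{self.ligand_conc_uM:g}uM" if self.ligand != "none" else "noligand",
            self.ion_medium,
            f"dig{self.digitonin_ug_ml:g}",
        ]
        if self.uptake_blocked:
            parts.append("blocked")
        return "|".join(parts)

    def stack_key(self) -> tuple:
        """Unique key of one stack within an experiment design."""
        return (self.condition_id(), self.experiment_id, self.replicate_id)

    def with_(self, **changes) -> "ConditionSpec":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **changes)

    def blocked_partner(self) -> "ConditionSpec":
        """The matched nonspecific-measurement condition (fluoxetine present
        during uptake, no MTS pre-treatment, no conformational ligand)."""
        return self.with_(
            mts_reagent="none",
            mts_conc_M=0.0,
            mts_time_s=0.0,
            ligand="none",
            ligand_conc_uM=0.0,
            uptake_blocked=True,
        )

    def to_manifest_row(self, stack_path: str) -> dict:
        return {
            "stack_path": stack_path,
            "mutant": self.mutant,
            "substrate": self.substrate,
            "substrate_conc_uM": self.substrate_conc_uM,
            "mts_reagent": self.mts_reagent,
            "mts_conc_M": self.mts_conc_M,
            "mts_time_s": self.mts_time_s,
            "ligand": self.ligand,
            "ligand_conc_uM": self.ligand_conc_uM,
            "ion_medium": self.ion_medium,
            "digitonin_ug_ml": self.digitonin_ug_ml,
            "experiment_id": self.experiment_id,
            "replicate_id": self.replicate_id,
            "uptake_blocked": self.uptake_blocked,
            "condition_id": self.condition_id(),
        }

    @classmethod
    def from_manifest_row(cls, row) -> "ConditionSpec":
        return cls(
            substrate=row["substrate"],
            substrate_conc_uM=float(row["substrate_conc_uM"]),
            mts_reagent=row["mts_reagent"],
            mts_conc_M=float(row["mts_conc_M"]),
            mts_time_s=float(row["mts_time_s"]),
            ligand=row["ligand"],
            ligand_conc_uM=float(row["ligand_conc_uM"]),
            ion_medium=row["ion_medium"],
            digitonin_ug_ml=float(row["digitonin_ug_ml"]),
            mutant=row["mutant"],
            uptake_blocked=bool(row["uptake_blocked"]),
            experiment_id=int(row["experiment_id"]),
            replicate_id=int(row["replicate_id"]),
        )
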