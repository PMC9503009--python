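"""Condition comparisons and conformational-effect classification.

Rate constants measured under a test condition are compared with the matched
control by pairing per-experiment values (Student's paired t-test) and
summarizing the fold-change as the geometric mean of per-experiment ratios,
so swapping condition and control exactly inverts the fold.  Opposite
accessibility changes of the extracellular reporter cysteines (Cys107,
Cys404) and the cytoplasmic reporter (Cys277) diagnose the direction of the
alternating-access conformational equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigurationError

#: Media compared in the ion panel, in presentation order.
ION_PANEL_MEDIA = ("NMDG-gluconate", "NMDG-Cl", "Na-isethionate", "NaCl", "NaCl+5-HT")


def fold_change(k_condition: float, k_control: float) -> float:
    """Ratio of two rate constants, k_condition / k_control."""
    if k_control <= 0:
        raise ConfigurationError("control rate constant must be positive")
    return k_condition / k_control


@dataclass
class ComparisonResult:
    """Rate-constant comparison between one condition and its control."""

    condition: str
    control: str
    fold: float  # geometric mean of per-experiment ratios
    per_experiment_folds: dict
    p_value: float
    direction: str  # 'increased' | 'decreased' | 'unchanged'
    pathway: str = ""
    mutant: str = ""
    alpha: float = 0.05
    n_pairs: int = 0


def compare_conditions(
    k_condition: Mapping[int, float],
    k_control: Mapping[int, float],
    alpha: float = 0.05,
    min_fold: float = 1.1,
    condition: str = "condition",
    control: str = "control",
    pathway: str = "",
    mutant: str = "",
) -> ComparisonResult:
    """Paired comparison of per-experiment rate constants.

    Both mappings are keyed by experiment id; at least two paired
    experiments are required.  Direction is 'unchanged' unless the paired
    t-test is significant at ``alpha`` *and* the fold-change differs from 1
    by at least ``min_fold``.
    """
    common = sorted(set(k_condition) & set(k_control))
    if set(k_condition) != set(k_control):
        raise ConfigurationError(
            f"unpaired experiment ids: {sorted(set(k_condition) ^ set(k_control))}"
        )
    if len(common) < 2:
        raise ConfigurationError("need >= 2 paired experiments")
    a = np.array([k_condition[e] for e in common], dtype=float)
    b = np.array([k_control[e] for e in common], dtype=float)
    if (a <= 0).any() or (b <= 0).any():
        raise ConfigurationError("rate constants must be positive for comparison")
    ratios = a / b
    fold = float(np.exp(np.mean(np.log(ratios))))
    if np.allclose(a, b):
        p = 1.0
    else:
        p = float(stats.ttest_rel(a, b).pvalue)
    if p < alpha and abs(math.log(fold)) >= math.log(min_fold):
        direction = "increased" if fold > 1 else "decreased"
    else:
        direction = "unchanged"
    return ComparisonResult(
        condition=condition,
        control=control,
        fold=fold,
        per_experiment_folds={e: float(r) for e, r in zip(common, ratios)},
        p_value=p,
        direction=direction,
        pathway=pathway,
        mutant=mutant,
        alpha=alpha,
        n_pairs=len(common),
    )


def holm_adjust(results: list[ComparisonResult]) -> list[float]:
    """Holm step-down adjusted p-values for a family of comparisons."""
    ps = np.array([r.p_value for r in results])
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


@dataclass
class ConformationCall:
    """Joint interpretation of extracellular and cytoplasmic reactivity shifts."""

    extracellular_direction: str
    cytoplasmic_direction: str
    call: str
    extracellular_fold: float = math.nan
    cytoplasmic_fold: float = math.nan


def call_conformation(
    extracellular: ComparisonResult,
    cytoplasmic: ComparisonResult,
    full_shift_extracellular_fold: float = 0.55,
    full_shift_cytoplasmic_fold: float = 1.8,
) -> ConformationCall:
    """Classify the conformational effect of a condition.

    * extracellular up & cytoplasmic down -> outward-open stabilized
      (the antidepressant / vilazodone signature);
    * extracellular down & cytoplasmic up -> inward-open shifted, reported
      as 'partial/intermediate' when the folds do not reach the full-shift
      thresholds (the Cl- signature);
    * both unchanged -> no change; anything else -> discordant.
    """
    if extracellular.control != cytoplasmic.control:
        raise ConfigurationError(
            "extracellular and cytoplasmic comparisons use different controls "
            f"({extracellular.control!r} vs {cytoplasmic.control!r})"
        )
    ex, cy = extracellular.direction, cytoplasmic.direction
    if ex == "increased" and cy == "decreased":
        call = "outward-open stabilized"
    elif ex == "decreased" and cy == "increased":
        full = (
            extracellular.fold <= full_shift_extracellular_fold
            and cytoplasmic.fold >= full_shift_cytoplasmic_fold
        )
        call = "inward-open shifted" if full else "partial/intermediate"
    elif ex == "unchanged" and cy == "unchanged":
        call = "no change"
    else:
        call = "discordant"
    return ConformationCall(
        extracellular_direction=ex,
        cytoplasmic_direction=cy,
        call=call,
        extracellular_fold=extracellular.fold,
        cytoplasmic_fold=cytoplasmic.fold,
    )


@dataclass
class IonPanelAnalysis:
    """Ordered ion-composition contrasts for one pathway."""

    pathway: str
    comparisons: list = field(default_factory=list)
    table: pd.DataFrame | None = None
    #: True when NaCl sits between Na-isethionate and NaCl+5-HT: Cl- (with
    #: Na+) partially shifts reactivity toward the substrate-bound direction.
    cl_signature: bool = False


def ion_panel_analysis(
    k_by_medium: Mapping[str, Mapping[int, float]],
    pathway: str,
    alpha: float = 0.05,
    min_fold: float = 1.1,
    mutant: str = "",
) -> IonPanelAnalysis:
    """Reproduce the ion-panel contrasts for one pathway.

    ``k_by_medium`` maps each of the five media to per-experiment rate
    constants.  Contrasts: every medium vs the NMDG-gluconate baseline,
    NaCl vs Na-isethionate, and NaCl+5-HT vs NaCl.
    """
    missing = [m for m in ION_PANEL_MEDIA if m not in k_by_medium]
    if missing:
        raise ConfigurationError(f"ion panel missing media: {missing}")

    contrasts = [(m, "NMDG-gluconate") for m in ION_PANEL_MEDIA if m != "NMDG-gluconate"]
    contrasts += [("NaCl", "Na-isethionate"), ("NaCl+5-HT", "NaCl")]
    comparisons = [
        compare_conditions(
            k_by_medium[cond],
            k_by_medium[ctrl],
            alpha=alpha,
            min_fold=min_fold,
            condition=cond,
            control=ctrl,
            pathway=pathway,
            mutant=mutant,
        )
        for cond, ctrl in contrasts
    ]
    table = pd.DataFrame(
        {
            "condition": [c.condition for c in comparisons],
            "control": [c.control for c in comparisons],
            "fold": [c.fold for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "direction": [c.direction for c in comparisons],
        }
    )

    by = {(c.condition, c.control): c for c in comparisons}
    nacl_vs_na = by[("NaCl", "Na-isethionate")]
    sht_vs_nacl = by[("NaCl+5-HT", "NaCl")]
    # Cl- moves reactivity from the Na+-alone level toward (but not past)
    # the fully substrate-shifted level: the NaCl point sits between the
    # Na-isethionate and NaCl+5-HT levels (both steps change k the same
    # way) and the overall shift is significant.
    monotone = (nacl_vs_na.fold - 1.0) * (sht_vs_nacl.fold - 1.0) > 0
    cl_signature = bool(monotone and sht_vs_nacl.direction != "unchanged")
    return IonPanelAnalysis(
        pathway=pathway, comparisons=comparisons, table=table, cl_signature=cl_signature
    )
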