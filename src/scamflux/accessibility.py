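"""MTS concentration-inhibition fitting and rate-constant conversion.

The core statistic of the assay: after exposing cells to an MTS reagent at
concentration ``c`` for a fixed time ``t``, the surviving transport (or
binding) activity follows pseudo-first-order modification kinetics,

    A(c) = floor + (A0 - floor) * exp(-k * c * t),

so the reagent concentration ``c50`` that halves the modifiable activity
satisfies ``k * c50 * t = ln 2``.  Equivalently, at the half-maximal
concentration the modification half-time equals the exposure time, making
``ln 2 / t`` the first-order rate constant there; dividing by ``c50`` gives
the pseudo-first-order (concentration-normalized) rate constant

    k = (ln 2 / t) / c50        [M^-1 s^-1].

Two curve models are provided: the mechanistic exponential fit (default,
estimates ``k`` directly) and an empirical asymmetric logistic fit in log10
concentration whose half-activity crossing is reported as ``c50``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from ._errors import ConfigurationError

#: Below this maximal observed inhibition, no rate constant is estimated;
#: only an upper detection bound is reported.
DETECTION_INHIBITION_FRAC = 0.2
#: A terminal plateau above this fraction of A0 triggers a free-floor fit.
FLOOR_DETECTION_FRAC = 0.1


@dataclass
class InhibitionFit:
    """Concentration-inhibition fit for one activity series."""

    A0: float  # unmodified-activity plateau (AFU)
    floor: float  # residual-activity plateau (AFU)
    c50: float  # half-maximal reagent concentration (M)
    k: float  # pseudo-first-order rate constant (M^-1 s^-1)
    k_se: float
    t_exposure: float  # s
    model: str  # 'exponential' or 'logistic'
    below_detection: bool = False
    detection_bound: float = math.nan  # M^-1 s^-1, upper bound when undetectable
    converged: bool = True
    n_points: int = 0
    experiment_id: int | None = None

    @property
    def floor_fraction(self) -> float:
        return self.floor / self.A0 if self.A0 else math.nan


def first_order_rate(t_exposure: float) -> float:
    """First-order rate constant (s^-1) at the half-maximal concentration:
    the modification half-time there equals the exposure time, so the rate
    is ln(2)/t.  For the standard 15-min exposure this is 7.7e-4 s^-1."""
    if t_exposure <= 0:
        raise ConfigurationError("exposure time must be positive")
    return math.log(2.0) / t_exposure

def rate_constant_from_c50(c50: float, t_exposure: float) -> float:
    """Convert a half-maximal reagent concentration into the
    pseudo-first-order modification rate constant k = ln2/(t * c50)."""
    if c50 <= 0:
        raise ConfigurationError("c50 must be positive")
    return first_order_rate(t_exposure) / c50


def detection_bound(c_max: float, t_exposure: float) -> float:
    """Smallest rate constant resolvable at the highest tested concentration."""
    return rate_constant_from_c50(c_max, t_exposure)


def _fit_exponential(conc, activity, t, fit_floor):
    A0_0 = float(np.mean(activity[conc == 0])) if (conc == 0).any() else float(activity.max())
    c_pos = conc[conc > 0]
    # initial k from the concentration nearest half-activity
    half = A0_0 / 2.0
    idx = int(np.argmin(np.abs(activity - half)))
    c_half = conc[idx] if conc[idx] > 0 else float(np.median(c_pos))
    k0 = math.log(2.0) / (max(c_half, c_pos.min() / 10) * t)

    if fit_floor:
        f = lambda c, A0, k, floor: floor + (A0 - floor) * np.exp(-k * c * t)
        p0 = (A0_0, k0, float(activity.min()))
        bounds = ((0, 1e-12, 0), (np.inf, np.inf, np.inf))
    else:
        f = lambda c, A0, k: A0 * np.exp(-k * c * t)
        p0 = (A0_0, k0)
        bounds = ((0, 1e-12), (np.inf, np.inf))
    popt, pcov = curve_fit(f, conc, activity, p0=p0, bounds=bounds, maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    A0, k = float(popt[0]), float(popt[1])
    floor = float(popt[2]) if fit_floor else 0.0
    return A0, k, float(perr[1]), floor


def _fit_logistic(conc, activity, t):
    """Empirical dose-inhibition fit: an asymmetric (five-parameter)
    logistic in log10 concentration, with the zero-concentration activity
    anchoring the top plateau.  First-order inhibition curves are asymmetric
    on a log-concentration axis, so a symmetric midpoint would land ~10%
    off; the half-maximal concentration is therefore read off the fitted
    curve where it crosses halfway between the plateaus."""
    zero_mask = conc == 0
    top = float(np.mean(activity[zero_mask])) if zero_mask.any() else float(activity.max())
    c_pos = conc[~zero_mask]
    a_pos = activity[~zero_mask]
    logc = np.log10(c_pos)

    def f(x, bottom, logc50, hill, asym):
        return bottom + (top - bottom) / (1.0 + 10 ** (hill * (x - logc50))) ** asym

    p0 = (max(float(a_pos.min()), 0.0), float(np.median(logc)), 1.0, 1.0)
    bounds = ((0.0, logc.min() - 4, 0.1, 0.05), (top, logc.max() + 4, 10.0, 20.0))
    popt, pcov = curve_fit(f, logc, a_pos, p0=p0, bounds=bounds, maxfev=40000)
    perr = np.sqrt(np.diag(pcov))
    bottom = float(popt[0])
    half = bottom + (top - bottom) / 2.0
    lo, hi = logc.min() - 4, logc.max() + 4
    try:
        x50 = brentq(lambda x: f(x, *popt) - half, lo, hi)
    except ValueError:  # no sign change in range; fall back to the midpoint
        x50 = float(popt[1])
    c50 = 10.0**x50
    k = rate_constant_from_c50(c50, t)
    # delta-method SE on k from the midpoint-parameter SE
    k_se = k * math.log(10.0) * float(perr[1])
    return top, bottom, float(c50), k, k_se


def fit_inhibition(
    conc: np.ndarray,
    activity: np.ndarray,
    t_exposure: float,
    model: str = "exponential",
    experiment_id: int | None = None,
) -> InhibitionFit:
    """Fit one concentration-inhibition series.

    ``conc`` in molar (must include 0 and at least 4 distinct values);
    ``activity`` in AFU (specific activity, nonspecific already removed).
    When the maximal observed inhibition is below 20%, no fit is attempted
    and the result reports only an upper detection bound on ``k``.  A
    residual plateau above 10% of A0 switches the exponential model to a
    free-floor fit.
    """
    conc = np.asarray(conc, dtype=np.float64)
    activity = np.asarray(activity, dtype=np.float64)
    if t_exposure <= 0:
        raise ConfigurationError("t_exposure must be positive")
    if len(np.unique(conc)) < 4:
        raise ConfigurationError("need >= 4 reagent concentrations")
    if not (conc == 0).any():
        raise ConfigurationError("series must include the zero-reagent control")
    if model not in ("exponential", "logistic"):
        raise ConfigurationError(f"unknown model {model!r}")

    order = np.argsort(conc)
    conc, activity = conc[order], activity[order]
    A0_obs = float(np.mean(activity[conc == 0]))
    c_max = float(conc.max())

    # terminal plateau: mean activity at the two highest concentrations
    tail = float(np.mean(activity[-2:]))
    max_inhibition = 1.0 - min(activity.min(), tail) / A0_obs if A0_obs > 0 else 0.0
    if max_inhibition < DETECTION_INHIBITION_FRAC:
        return InhibitionFit(
            A0=A0_obs,
            floor=A0_obs,
            c50=math.inf,
            k=math.nan,
            k_se=math.nan,
            t_exposure=t_exposure,
            model=model,
            below_detection=True,
            detection_bound=detection_bound(c_max, t_exposure),
            n_points=len(conc),
            experiment_id=experiment_id,
        )

    fit_floor = tail > FLOOR_DETECTION_FRAC * A0_obs
    try:
        if model == "exponential":
            A0, k, k_se, floor = _fit_exponential(conc, activity, t_exposure, fit_floor)
            # the modifiable fraction halves at c50 regardless of the floor
            c50 = math.log(2.0) / (k * t_exposure)
        else:
            A0, floor, c50, k, k_se = _fit_logistic(conc, activity, t_exposure)
        converged = all(map(math.isfinite, (A0, k, c50)))
    except RuntimeError:
        warnings.warn("inhibition fit did not converge", stacklevel=2)
        A0, floor, c50, k, k_se, converged = A0_obs, 0.0, math.nan, math.nan, math.nan, False
    return InhibitionFit(
        A0=A0,
        floor=floor,
        c50=c50,
        k=k,
        k_se=k_se,
        t_exposure=t_exposure,
        model=model,
        detection_bound=detection_bound(c_max, t_exposure),
        converged=converged,
        n_points=len(conc),
        experiment_id=experiment_id,
    )


@dataclass
class ProtectionResult:
    """Fixed-concentration protection/enhancement readout."""

    frac_ctrl: float  # remaining activity with MTS alone, relative to A0
    frac_ligand: float  # remaining activity with MTS + ligand, relative to A0
    k_fold: float  # implied k_ligand / k_ctrl under exponential kinetics
    full_protection: bool = False
    capped: bool = False


def fixed_concentration_protection(
    activity_mts: float,
    activity_mts_plus_ligand: float,
    activity_untreated: float,
) -> ProtectionResult:
    """Fold-change in modification rate from a single-concentration assay.

    With MTS applied at a fixed concentration (ideally near the control
    IC50), remaining activity fractions translate into a rate-constant
    fold via the exponential model:
    ``k_lig / k_ctrl = ln(A_lig / A0) / ln(A_ctrl / A0)``.
    """
    A0 = activity_untreated
    if A0 <= 0:
        raise ConfigurationError("untreated activity must be positive")
    frac_ctrl = activity_mts / A0
    frac_lig = activity_mts_plus_ligand / A0
    if not 0.3 <= frac_ctrl <= 0.7:
        warnings.warn(
            f"MTS-alone condition is not near half-inhibition (remaining "
            f"fraction {frac_ctrl:.2f}); fold estimate is less reliable",
            stacklevel=2,
        )
    capped = False
    if frac_lig >= 1.0:
        # ligand fully protected the cysteine: no detectable modification
        return ProtectionResult(frac_ctrl, frac_lig, 0.0, full_protection=True)
    if frac_lig <= 0.0:
        frac_lig = 1e-6
        capped = True
    if frac_ctrl >= 1.0 or frac_ctrl <= 0.0:
        raise ConfigurationError(
            f"control remaining fraction {frac_ctrl:.3f} outside (0, 1); "
            "cannot back-calculate a rate fold"
        )
    fold = math.log(frac_lig) / math.log(frac_ctrl)
    return ProtectionResult(frac_ctrl, frac_lig, fold, capped=capped)


def rate_from_remaining_fraction(
    frac_remaining: float, conc: float, t_exposure: float
) -> float:
    """Back-calculate k (M^-1 s^-1) from remaining specific activity after a
    fixed-concentration exposure: k = -ln(f) / (c * t)."""
    if conc <= 0 or t_exposure <= 0:
        raise ConfigurationError("concentration and time must be positive")
    f = min(max(frac_remaining, 1e-6), 1.0)
    return -math.log(f) / (conc * t_exposure)


def fits_to_frame(fits: list[InhibitionFit], **extra) -> pd.DataFrame:
    """Tabulate a list of fits (one row each) with optional constant columns."""
    rows = []
    for f in fits:
        row = {
            "experiment_id": f.experiment_id,
            "A0": f.A0,
            "floor": f.floor,
            "c50_M": f.c50,
            "k": f.k,
            "k_se": f.k_se,
            "t_exposure_s": f.t_exposure,
            "model": f.model,
            "below_detection": f.below_detection,
            "detection_bound": f.detection_bound,
            "converged": f.converged,
            "n_points": f.n_points,
        }
        row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)
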