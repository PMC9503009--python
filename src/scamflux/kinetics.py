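"""Transport kinetics: nonspecific subtraction, Michaelis-Menten fits, and
ion-requirement panels.

Specific uptake is defined operationally as total accumulation minus the
accumulation measured with 10 uM fluoxetine present (the nonspecific,
transporter-independent component).  Michaelis-Menten parameters are fitted
per experiment on the specific values and aggregated across experiments as
mean +/- SEM of the per-experiment fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._errors import ConfigurationError


@dataclass
class MMFit:
    """Michaelis-Menten fit result for one specific-uptake series."""

    Km: float  # uM
    Km_se: float
    Vmax: float  # AFU
    Vmax_se: float
    n_points: int
    residual_rms: float
    converged: bool = True
    #: Km beyond the tested concentration range makes the fit unreliable.
    unreliable: bool = False
    experiment_id: int | None = None


@dataclass
class MMSummary:
    """Cross-experiment aggregation of per-experiment fits (mean +/- SEM)."""

    Km: float
    Km_sem: float
    Vmax: float
    Vmax_sem: float
    n_experiments: int
    fits: list = field(default_factory=list)


def michaelis_menten(S, Vmax, Km):
    return Vmax * S / (Km + S)


def subtract_nonspecific(
    total: pd.DataFrame, blocked: pd.DataFrame, value_col: str = "value"
) -> pd.DataFrame:
    """Concentration-wise specific signal: total minus fluoxetine-blocked.

    Both tables need ``conc`` and ``value_col`` columns on identical
    concentration grids (no interpolation is attempted).  Negative
    differences are floored at zero with a warning.
    """
    t = total.sort_values("conc").reset_index(drop=True)
    b = blocked.sort_values("conc").reset_index(drop=True)
    if len(t) != len(b) or not np.allclose(t["conc"], b["conc"]):
        raise ConfigurationError(
            "total and blocked series are on different concentration grids"
        )
    specific = t[value_col].to_numpy() - b[value_col].to_numpy()
    if (specific < 0).any():
        warnings.warn(
            "negative specific signal floored at 0 "
            f"({int((specific < 0).sum())} of {len(specific)} points)",
            stacklevel=2,
        )
        specific = np.maximum(specific, 0.0)
    return pd.DataFrame({"conc": t["conc"].to_numpy(), value_col: specific})


def fit_mm(
    conc: np.ndarray, v: np.ndarray, experiment_id: int | None = None
) -> MMFit:
    """Least-squares Michaelis-Menten fit of a specific-uptake series.

    Requires at least 4 distinct concentrations.  Standard errors come from
    the fit covariance; the result is flagged unreliable when Km exceeds the
    highest tested concentration.
    """
    conc = np.asarray(conc, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if len(np.unique(conc)) < 4:
        raise ConfigurationError("need >= 4 distinct substrate concentrations")
    if conc.min() < 0:
        raise ConfigurationError("concentrations must be >= 0")
    vmax0 = max(v.max(), 1e-9)
    half = vmax0 / 2.0
    km0 = float(conc[np.argmin(np.abs(v - half))]) or float(np.median(conc[conc > 0]))
    try:
        popt, pcov = curve_fit(
            michaelis_menten,
            conc,
            v,
            p0=(vmax0, km0),
            bounds=((0.0, 1e-12), (np.inf, np.inf)),
            maxfev=10000,
        )
        perr = np.sqrt(np.diag(pcov))
        converged = np.all(np.isfinite(popt))
    except RuntimeError:
        popt, perr, converged = (np.nan, np.nan), (np.nan, np.nan), False
    vmax, km = popt
    resid = v - michaelis_menten(conc, vmax, km) if converged else np.full_like(v, np.nan)
    return MMFit(
        Km=float(km),
        Km_se=float(perr[1]),
        Vmax=float(vmax),
        Vmax_se=float(perr[0]),
        n_points=len(conc),
        residual_rms=float(np.sqrt(np.nanmean(resid**2))),
        converged=bool(converged),
        unreliable=bool(converged and km > conc.max()),
        experiment_id=experiment_id,
    )


def fit_mm_experiments(series: pd.DataFrame, value_col: str = "value") -> MMSummary:
    """Fit each experiment separately and aggregate as mean +/- SEM.

    ``series`` has columns ``conc``, ``experiment_id`` and ``value_col``.
    """
    fits = [
        fit_mm(grp["conc"].to_numpy(), grp[value_col].to_numpy(), experiment_id=exp)
        for exp, grp in series.groupby("experiment_id")
    ]
    kms = np.array([f.Km for f in fits if f.converged])
    vmaxs = np.array([f.Vmax for f in fits if f.converged])
    n = len(kms)
    if n == 0:
        raise ConfigurationError("no experiment produced a converged fit")
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return MMSummary(
        Km=float(kms.mean()),
        Km_sem=sem(kms),
        Vmax=float(vmaxs.mean()),
        Vmax_sem=sem(vmaxs),
        n_experiments=n,
        fits=fits,
    )


def ion_panel(condition_means: dict) -> pd.DataFrame:
    """Specific uptake by ion medium, normalized to the NaCl reference.

    ``condition_means`` maps medium name to mean specific uptake (AFU).
    """
    if "NaCl" not in condition_means:
        raise ConfigurationError("ion panel requires a NaCl reference medium")
    ref = condition_means["NaCl"]
    if ref <= 0:
        raise ConfigurationError("degenerate NaCl reference (specific uptake <= 0)")
    rows = [
        {"ion_medium": medium, "specific_uptake": val, "relative_uptake": val / ref}
        for medium, val in condition_means.items()
    ]
    return pd.DataFrame(rows, columns=["ion_medium", "specific_uptake", "relative_uptake"])
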