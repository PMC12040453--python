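"""Surviving fractions and cohort-effect ratio analyses.

Two notions of survival are provided: the classical linear-quadratic (LQ)
curve ``S = exp(-αD - βD²)``, and the compartmental estimate obtained by
switching off all proliferation (``kd = k0 = 0``) so that the initial C0
cells simply partition between the terminal compartments.  In that
construction the fraction of initial cells that end up well-repaired is

    S(t) = λr/(λu+λr) · (1 - exp(-(λu+λr)(t-Ta))),   t >= Ta

with the limit ``S = λr/(λu+λr)`` as t → ∞.

The cohort effect — inhibition of the regrowth of repaired cells by
co-irradiated dying/senescent cells — is quantified by the ratio
``Cr/(Cs+CD)`` and by the normalized occupancies of the three terminal
compartments at the experiment endpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams, Trajectory

__all__ = [
    "LQParams",
    "SurvivalSummary",
    "CohortRatios",
    "lq_survival",
    "surviving_fraction_curve",
    "surviving_fraction_limit",
    "cohort_ratios",
    "survival_summary",
]


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic sensitivity parameters (alpha in Gy⁻¹, beta in Gy⁻²)."""

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")


@dataclass(frozen=True)
class SurvivalSummary:
    dose: float
    S_mean: float  # fraction in [0, 1]
    S_sd: float
    density_subset: str  # "all C0" | "2 highest C0"

    @property
    def S_mean_percent(self) -> float:
        return 100.0 * self.S_mean

    @property
    def S_sd_percent(self) -> float:
        return 100.0 * self.S_sd


@dataclass(frozen=True)
class CohortRatios:
    """Terminal-compartment ratios at a fixed end time."""

    ratio_Cr_over_CsCD: float  # may be +inf when Cs+CD = 0
    frac_Cr: float
    frac_Cs: float
    frac_CD: float
    undamaged: bool = False  # True when Cs+CD = 0 (ratio is the +inf sentinel)


def lq_survival(lq: LQParams, D: float):
    """LQ surviving fraction ``exp(-alpha D - beta D²)``; D in Gy."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("dose must be >= 0")
    out = np.exp(-lq.alpha * D - lq.beta * D * D)
    return float(out) if out.ndim == 0 else out


def surviving_fraction_curve(params: ModelParams, t) -> float:
    """Time-resolved compartmental surviving fraction (no-proliferation limit).

    Implemented directly from the closed form, independently of the ODE
    integrator (which the tests use as a cross-check).
    """
    lam = params.lambda_u + params.lambda_r
    if lam <= 0:
        raise ValueError("lambda_u + lambda_r must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < params.Ta):
        raise ValueError("surviving fraction is defined for t >= Ta")
    S = params.lambda_r / lam * (1.0 - np.exp(-lam * (t - params.Ta)))
    return float(S) if S.ndim == 0 else S


def surviving_fraction_limit(params: ModelParams) -> float:
    """Asymptotic surviving fraction ``λr/(λu+λr)``."""
    lam = params.lambda_u + params.lambda_r
    if lam <= 0:
        raise ValueError("lambda_u + lambda_r must be > 0")
    return params.lambda_r / lam


def cohort_ratios(traj: Trajectory, t_end: float = 144.0) -> CohortRatios:
    """Terminal-compartment ratios of a simulated trajectory at ``t_end``."""
    if t_end < traj.times[0] or t_end > traj.times[-1]:
        raise ValueError(f"t_end={t_end} outside trajectory span")
    i = int(np.argmin(np.abs(traj.times - t_end)))
    Cr, Cs, CD = float(traj.Cr[i]), float(traj.Cs[i]), float(traj.CD[i])
    total = Cr + Cs + CD
    if total == 0:
        raise ValueError("Cr + Cs + CD = 0: terminal ratios undefined")
    unrepaired = Cs + CD
    if unrepaired == 0:
        return CohortRatios(math.inf, 1.0, 0.0, 0.0, undamaged=True)
    return CohortRatios(Cr / unrepaired, Cr / total, Cs / total, CD / total)


def survival_summary(fit_results, C0s=None, n_highest: int = 2) -> pd.DataFrame:
    """Aggregate per-curve asymptotic surviving fractions into a dose table.

    For each dose the fraction λr/(λu+λr) is computed per fitted curve, then
    averaged (mean ± sd across curves) over all seeding densities and over the
    ``n_highest`` highest ones.  ``C0s`` (parallel to ``fit_results``) orders
    the curves by seeding density; without it the input order is taken as
    lowest→highest.  Control (0 Gy) fits are skipped.  Returns a tidy frame
    with percentages, one row per (dose, subset).
    """
    if C0s is None:
        C0s = list(range(len(list(fit_results))))
    rows = []
    by_dose: dict[float, list] = {}
    for r, c0 in zip(fit_results, C0s):
        if r.params.dose == 0:
            continue
        by_dose.setdefault(float(r.params.dose), []).append((c0, r))
    for dose in sorted(by_dose):
        results = [r for _, r in sorted(by_dose[dose], key=lambda p: p[0])]
        S = np.array([surviving_fraction_limit(r.params) for r in results])
        subsets = {"all C0": S}
        if len(S) > n_highest:
            subsets[f"{n_highest} highest C0"] = S[-n_highest:]
        for label, vals in subsets.items():
            rows.append(
                {
                    "dose_Gy": dose,
                    "subset": label,
                    "S_mean_percent": 100.0 * float(np.mean(vals)),
                    "S_sd_percent": 100.0 * float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
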