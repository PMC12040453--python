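"""Two-phase compartmental model of a cell population's response to irradiation.

The population dynamics are split at ``t = Ta`` (the duration of the
*repairing phase*) into two regimes:

Phase 1 (``0 <= t <= Ta``) — a single undifferentiated population whose
proliferation coefficient ramps linearly from 0 to the damaged growth rate
``kd``::

    dC/dt = (kd/Ta) * t * C * (1 - C/Cmax)

Phase 2 (``t > Ta``, the *regrow-or-die phase*) — the whole population is
placed in the damaged compartment ``Cd`` and partitions into well-repaired
(``Cr``), misrepaired (``Cu``), senescent (``Cs``) and dead (``CD``) cells::

    dCd/dt = -(lambda_u + lambda_r) Cd + kd Cd (1 - C/Cmax)
    dCr/dt = k0 Cr (1 - C/Cmax) + lambda_r Cd
    dCu/dt = lambda_u Cd - gamma Cu
    dCs/dt = lambda_s Cu
    dCD/dt = lambda_D Cu

with the structural relations ``kd = lambda_u + lambda_r - gamma`` and
``lambda_D = gamma - lambda_s`` (the misrepair clearing rate ``delta`` is
pinned to ``gamma``).  Dead cells detach from the plate, so the observed
density is ``C = Cd + Cr + Cu + Cs`` (``CD`` excluded).

Densities are in cells/µm², times in hours, rates in h⁻¹.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "ModelParams",
    "CompartmentState",
    "Trajectory",
    "simulate",
    "analytic_no_logistic",
    "observed_density",
    "RTOL",
    "ATOL",
]

RTOL = 1e-8
ATOL = 1e-12


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to meet its tolerances."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the irradiation-response model.

    The derived rates ``kd`` (damaged-cell growth rate) and ``lambda_D``
    (death rate out of the misrepaired compartment) are properties, so the
    structural relations can never be violated by construction.

    Parameters
    ----------
    k0 : normal growth rate of well-repaired cells, h⁻¹.
    gamma : characteristic rate of the damaged/misrepaired kinetics, h⁻¹.
    lambda_u : misrepair (Cd→Cu) rate, h⁻¹.
    lambda_r : repair (Cd→Cr) rate, h⁻¹.
    lambda_s : senescence (Cu→Cs) rate, h⁻¹; must not exceed ``delta``.
    Ta : duration of the repairing phase, h.
    Cmax : carrying capacity, cells/µm².
    dose : radiation dose in Gy; metadata label only, never enters the ODEs.
    delta : clearing rate of Cu, h⁻¹; ``None`` pins it to ``gamma`` (the
        simplification used throughout the fitting pipeline).
    """

    k0: float = 0.045
    gamma: float = 0.06
    lambda_u: float = 0.0
    lambda_r: float = 0.105
    lambda_s: float = 0.0
    Ta: float = 0.0
    Cmax: float = 2.4e-3
    dose: float = 0.0
    delta: float | None = None

    @property
    def delta_eff(self) -> float:
        return self.gamma if self.delta is None else self.delta

    @property
    def kd(self) -> float:
        """Damaged-cell growth rate, ``lambda_u + lambda_r - gamma``."""
        return self.lambda_u + self.lambda_r - self.gamma

    @property
    def lambda_D(self) -> float:
        """Death rate out of Cu, ``delta - lambda_s`` (= ``gamma - lambda_s``)."""
        return self.delta_eff - self.lambda_s

    def validate(
        self,
        require_delta_pinned: bool = False,
        strict_dose_zero: bool = True,
    ) -> "ModelParams":
        """Check invariants, returning self so calls can be chained.

        ``strict_dose_zero=False`` skips the dose-0 ⟹ (Ta=0, λu=0)
        implication; the fitting pipeline uses this when deliberately fitting
        the irradiation model to control data as a continuity check.
        """
        for name in ("k0", "gamma", "lambda_u", "lambda_r", "lambda_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.Ta < 0:
            raise ValueError(f"Ta must be >= 0, got {self.Ta}")
        if self.Cmax <= 0:
            raise ValueError(f"Cmax must be > 0, got {self.Cmax}")
        if self.lambda_D < -1e-15:
            raise ValueError(
                f"lambda_s={self.lambda_s} exceeds delta={self.delta_eff}: lambda_D must be >= 0"
            )
        if strict_dose_zero and self.dose == 0 and (self.Ta != 0 or self.lambda_u != 0):
            raise ValueError("dose 0 requires Ta = 0 and lambda_u = 0")
        if require_delta_pinned and self.delta is not None and self.delta != self.gamma:
            raise ValueError("pipeline code requires delta pinned to gamma")
        return self


@dataclass(frozen=True)
class CompartmentState:
    """Densities (cells/µm²) of the five phase-2 compartments."""

    Cd: float
    Cr: float
    Cu: float
    Cs: float
    CD: float

    def as_array(self) -> np.ndarray:
        return np.array([self.Cd, self.Cr, self.Cu, self.Cs, self.CD], dtype=float)


def observed_density(state: CompartmentState) -> float:
    """Observed (attached) cell density: ``Cd + Cr + Cu + Cs``, dead cells excluded."""
    arr = np.asarray([state.Cd, state.Cr, state.Cu, state.Cs, state.CD], dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"negative compartment density in {state}")
    return float(arr[:4].sum())


@dataclass(frozen=True)
class Trajectory:
    """Simulated compartment densities on a time grid.

    During phase 1 (``t <= Ta``) the single undifferentiated population is
    reported in the ``Cd`` column with the other compartments at zero; at
    ``t = Ta`` it is handed over unchanged as the phase-2 initial condition,
    so the observed density is continuous across the phase boundary.
    """

    times: np.ndarray
    Cd: np.ndarray
    Cr: np.ndarray
    Cu: np.ndarray
    Cs: np.ndarray
    CD: np.ndarray
    params: ModelParams
    C0: float

    @property
    def observed(self) -> np.ndarray:
        """Observed density C = Cd + Cr + Cu + Cs at each grid time."""
        return self.Cd + self.Cr + self.Cu + self.Cs

    def state_at(self, i: int) -> CompartmentState:
        return CompartmentState(
            float(self.Cd[i]), float(self.Cr[i]), float(self.Cu[i]),
            float(self.Cs[i]), float(self.CD[i]),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times,
                "Cd": self.Cd,
                "Cr": self.Cr,
                "Cu": self.Cu,
                "Cs": self.Cs,
                "CD": self.CD,
                "C_observed": self.observed,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _phase1_density(params: ModelParams, C0: float, t: np.ndarray, logistic: bool) -> np.ndarray:
    """Exact phase-1 solution.

    The ramped equation is separable: with pseudo-time ``u = t²/(2 Ta)`` it is
    plain exponential/logistic growth at rate ``kd``, hence
    ``C = C0·exp(kd u)`` (no logistic) or the logistic sigmoid in ``u``.
    """
    t = np.asarray(t, dtype=float)
    if params.Ta == 0:
        return np.full(t.shape, C0, dtype=float)
    u = t * t / (2.0 * params.Ta)
    if not logistic:
        return C0 * np.exp(params.kd * u)
    Cmax = params.Cmax
    # logistic solution in u; written to stay stable for kd*u large of either sign
    return Cmax / (1.0 + (Cmax / C0 - 1.0) * np.exp(-params.kd * u))


def _rhs(y, t, k0, gamma, lu, lr, ls, lD, kd, Cmax, logistic):
    Cd, Cr, Cu, Cs, CD = y
    C = Cd + Cr + Cu + Cs
    g = 1.0 - C / Cmax if logistic else 1.0
    return (
        -(lu + lr) * Cd + kd * Cd * g,
        k0 * Cr * g + lr * Cd,
        lu * Cd - gamma * Cu,
        ls * Cu,
        lD * Cu,
    )


def simulate(
    params: ModelParams,
    C0: float,
    t_grid: np.ndarray,
    logistic: bool = True,
) -> Trajectory:
    """Integrate the two-phase model on ``t_grid`` (hours, starting at 0).

    Phase 1 uses the exact closed-form ramped-growth solution; phase 2 is
    integrated with LSODA (Adams/BDF with automatic stiffness switching) at
    rtol 1e-8 / atol 1e-12.  With ``logistic=False`` every ``1 - C/Cmax``
    factor is replaced by 1.  ``Ta >= max(t_grid)`` is valid (pure phase 1).
    """
    params.validate(strict_dose_zero=False)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if t_grid[0] != 0:
        raise ValueError("t_grid must start at 0 (time of irradiation)")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if C0 <= 0:
        raise ValueError("C0 must be > 0")

    n = len(t_grid)
    Ta = params.Ta
    pre = t_grid <= Ta

    Cd = np.zeros(n)
    Cr = np.zeros(n)
    Cu = np.zeros(n)
    Cs = np.zeros(n)
    CD = np.zeros(n)
    Cd[pre] = _phase1_density(params, C0, t_grid[pre], logistic)

    t_post = t_grid[~pre]
    if len(t_post):
        CTa = float(_phase1_density(params, C0, np.array([Ta]), logistic)[0])
        y0 = np.array([CTa, 0.0, 0.0, 0.0, 0.0])
        t_solve = np.concatenate(([Ta], t_post))
        args = (
            params.k0, params.gamma, params.lambda_u, params.lambda_r,
            params.lambda_s, params.lambda_D, params.kd, params.Cmax, logistic,
        )
        y, info = odeint(
            _rhs, y0, t_solve, args=args, rtol=RTOL, atol=ATOL,
            full_output=True, printmessg=False, mxstep=10000,
        )
        if info["message"] != "Integration successful." or not np.all(np.isfinite(y)):
            raise IntegrationError(f"LSODA failed: {info['message']}")
        y = y[1:]
        if np.any(y < -1e3 * ATOL):
            warnings.warn(
                f"integrator produced negative densities (min {y.min():.3e}); clipped to 0",
                RuntimeWarning,
                stacklevel=2,
            )
        y = np.clip(y, 0.0, None)
        Cd[~pre], Cr[~pre], Cu[~pre], Cs[~pre], CD[~pre] = y.T

    return Trajectory(t_grid, Cd, Cr, Cu, Cs, CD, params, float(C0))


def analytic_no_logistic(params: ModelParams, C0: float, t) -> CompartmentState:
    """Closed-form phase-2 solution in the low-density limit (no logistic terms).

    Valid for ``t >= Ta`` with ``delta`` pinned to ``gamma``.  With
    ``tau = t - Ta`` and ``CTa = C0 exp(kd Ta / 2)``::

        Cd = CTa exp(-gamma tau)
        Cu = lambda_u CTa tau exp(-gamma tau)          (resonant case delta=gamma)
        Cr = lambda_r CTa (exp(k0 tau) - exp(-gamma tau)) / (k0 + gamma)
        Cs = (lambda_s lambda_u CTa / gamma²) [1 - (1 + gamma tau) exp(-gamma tau)]
        CD = same as Cs with lambda_D in place of lambda_s

    Each expression is validated against the ODE right-hand sides by the
    oracle-equivalence tests.  Accepts a scalar or array ``t``; components are
    returned with matching shape.
    """
    params.validate(require_delta_pinned=True, strict_dose_zero=False)
    t = np.asarray(t, dtype=float)
    if np.any(t < params.Ta):
        raise ValueError("analytic solution requires t >= Ta")
    if params.k0 + params.gamma == 0:
        raise ZeroDivisionError("k0 + gamma = 0: degenerate denominator")
    g = params.gamma
    tau = t - params.Ta
    CTa = C0 * math.exp(params.kd * params.Ta / 2.0)
    decay = np.exp(-g * tau)
    Cd = CTa * decay
    Cu = params.lambda_u * CTa * tau * decay
    Cr = params.lambda_r * CTa * (np.exp(params.k0 * tau) - decay) / (params.k0 + g)
    if g > 0:
        ramp = (1.0 - (1.0 + g * tau) * decay) / (g * g)
    else:  # gamma = 0: Cu ramps linearly, integral is tau²/2
        ramp = tau * tau / 2.0
    Cs = params.lambda_s * params.lambda_u * CTa * ramp
    CD = params.lambda_D * params.lambda_u * CTa * ramp

    def _cast(x):
        return float(x) if x.ndim == 0 else x

    return CompartmentState(*(_cast(np.asarray(v)) for v in (Cd, Cr, Cu, Cs, CD)))
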