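"""Estimation pipeline: reduced-χ² objective, bounded multi-start fitting,
profile likelihoods, and the procedures that fix Ta, γ, k0 and Cmax.

Each response curve (one dose, one seeding density) is fitted separately.
The free parameters default to the transfer rates (λs, λu, λr); the growth
rate k0, the characteristic rate γ, the carrying capacity Cmax and the
repairing-phase duration Ta are fixed beforehand from dedicated estimators.
Data points above the confluence threshold CT are excluded from the
objective, because crowding-induced death is outside the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import savgol_filter

from .model import IntegrationError, ModelParams, simulate

__all__ = [
    "TimeCourse",
    "FitResult",
    "ProfileLikelihood",
    "chi2_reduced",
    "fit",
    "estimate_Ta",
    "estimate_gamma_from_peak",
    "profile_likelihood",
    "fit_exponential_control",
    "read_timecourses",
    "write_timecourses",
    "CONFLUENCE_THRESHOLD",
    "DEFAULT_FIXED",
    "DEFAULT_BOUNDS",
    "TA_BY_DOSE",
]

#: density above which crowding effects confound the radiation response
CONFLUENCE_THRESHOLD = 1.3e-3  # cells/µm²

#: parameters fixed before the per-curve fits (h⁻¹ except Cmax in cells/µm²)
DEFAULT_FIXED = {"k0": 0.045, "gamma": 0.06, "Cmax": 2.4e-3}

#: repairing-phase duration per dose, from the derivative-maximum estimator
TA_BY_DOSE = {0.0: 0.0, 5.0: 16.0, 10.0: 18.0, 15.0: 21.0}

#: box bounds for free parameters
DEFAULT_BOUNDS = {
    "lambda_u": (0.0, 0.2),
    "lambda_r": (0.0, 0.2),
    "lambda_s": (0.0, 0.06),
    "Cmax": (1e-4, 1e-2),
    "gamma": (1e-6, 0.2),
    "k0": (0.0, 0.2),
}

_DEFAULT_FREE = ("lambda_s", "lambda_u", "lambda_r")


@dataclass(frozen=True)
class TimeCourse:
    """Observed mean-density series for one (dose, seeding density) condition."""

    dose: float
    seeding_index: int
    C0: float
    times: np.ndarray
    mean_density: np.ndarray
    sd_density: np.ndarray
    n_replicates: int = 3

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.mean_density, dtype=float)
        s = np.asarray(self.sd_density, dtype=float)
        if not (len(t) == len(m) == len(s)):
            raise ValueError("times, mean_density and sd_density must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(m < 0):
            raise ValueError("mean_density must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "mean_density", m)
        object.__setattr__(self, "sd_density", s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_Gy": self.dose,
                "seeding_index": self.seeding_index,
                "C0_cells_per_um2": self.C0,
                "time_h": self.times,
                "mean_density": self.mean_density,
                "sd_density": self.sd_density,
                "n_replicates": self.n_replicates,
            }
        )


def write_timecourses(curves, path) -> None:
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(path, index=False)


def read_timecourses(path) -> list[TimeCourse]:
    df = pd.read_csv(path)
    curves = []
    for (dose, idx), g in df.groupby(["dose_Gy", "seeding_index"], sort=True):
        g = g.sort_values("time_h")
        curves.append(
            TimeCourse(
                dose=float(dose),
                seeding_index=int(idx),
                C0=float(g["C0_cells_per_um2"].iloc[0]),
                times=g["time_h"].to_numpy(),
                mean_density=g["mean_density"].to_numpy(),
                sd_density=g["sd_density"].to_numpy(),
                n_replicates=int(g["n_replicates"].iloc[0]),
            )
        )
    return curves


@dataclass(frozen=True)
class FitResult:
    """Best multi-start fit with its provenance."""

    params: ModelParams
    chi2_nu: float
    free_names: tuple
    free_values: np.ndarray
    bounds: dict
    n_starts: int
    seed: int
    objective_evals: int
    start_objectives: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = {
            "dose_Gy": self.params.dose,
            "chi2_nu": float(self.chi2_nu),
            "free_names": list(self.free_names),
            "free_values": [float(v) for v in self.free_values],
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "n_starts": int(self.n_starts),
            "seed": int(self.seed),
            "objective_evals": int(self.objective_evals),
            "params": {
                "k0": self.params.k0,
                "gamma": self.params.gamma,
                "lambda_u": self.params.lambda_u,
                "lambda_r": self.params.lambda_r,
                "lambda_s": self.params.lambda_s,
                "Ta": self.params.Ta,
                "Cmax": self.params.Cmax,
                "kd": self.params.kd,
                "lambda_D": self.params.lambda_D,
            },
        }
        return d


@dataclass(frozen=True)
class ProfileLikelihood:
    """Minimized χ²ν as one parameter is scanned over a grid."""

    param_name: str
    grid: np.ndarray
    chi2_nu_min: np.ndarray
    errors: list = field(default_factory=list)

    @property
    def argmin(self) -> float:
        return float(self.grid[int(np.nanargmin(self.chi2_nu_min))])


def _safe_sd(sd: np.ndarray, mean: np.ndarray | None = None) -> np.ndarray:
    """Replace non-positive σ by usable weights.

    Isolated zero σ (identical replicates) are replaced by the smallest
    positive σ in the curve.  If every σ is zero (noiseless data), weights
    proportional to the density (1 % of the mean) are used instead so the
    objective keeps a meaningful scale for the optimizer.
    """
    sd = np.asarray(sd, dtype=float).copy()
    bad = sd <= 0
    if bad.any():
        pos = sd[~bad]
        if len(pos):
            fill = pos.min()
            warnings.warn(
                f"{bad.sum()} data points have σ<=0; replaced by {fill:.3g}",
                RuntimeWarning,
                stacklevel=3,
            )
            sd[bad] = fill
        else:
            warnings.warn(
                "all σ are zero; weighting by 1% of the mean density",
                RuntimeWarning,
                stacklevel=3,
            )
            if mean is None:
                sd[:] = 1.0
            else:
                mean = np.asarray(mean, dtype=float)
                scale = mean.max() if mean.max() > 0 else 1.0
                sd = 0.01 * np.maximum(mean, 1e-6 * scale)
    return sd


def _truncation_mask(data: TimeCourse, CT: float) -> np.ndarray:
    return data.mean_density <= CT


def _model_density(params: ModelParams, C0: float, times: np.ndarray, logistic: bool) -> np.ndarray:
    """Observed model density at the data times (prepending t=0 if absent)."""
    if times[0] == 0:
        return simulate(params, C0, times, logistic=logistic).observed
    grid = np.concatenate(([0.0], times))
    return simulate(params, C0, grid, logistic=logistic).observed[1:]


def chi2_reduced(
    data: TimeCourse,
    params: ModelParams,
    free_names=_DEFAULT_FREE,
    CT: float = CONFLUENCE_THRESHOLD,
    logistic: bool = True,
) -> float:
    """Reduced chi-square of the model against one curve.

    ``(1/(n-k)) Σ [(Cdata - Cmod)/σ]²`` over the points at or below the
    confluence threshold CT, where k = number of free parameters.
    """
    mask = _truncation_mask(data, CT)
    n = int(mask.sum())
    k = len(free_names)
    if n <= k:
        raise ValueError(f"n={n} usable points <= k={k} free parameters")
    sd = _safe_sd(data.sd_density, data.mean_density)[mask]
    model = _model_density(params, data.C0, data.times[mask], logistic)
    resid = (data.mean_density[mask] - model) / sd
    return float(resid @ resid / (n - k))


def _assemble(base: dict, free_names, x) -> ModelParams:
    kw = dict(base)
    kw.update(zip(free_names, x))
    return ModelParams(**kw)


def fit(
    data: TimeCourse,
    free_names=_DEFAULT_FREE,
    fixed: dict | None = None,
    bounds: dict | None = None,
    n_starts: int = 10_000,
    seed: int = 0,
    logistic: bool = True,
    CT: float = CONFLUENCE_THRESHOLD,
    fast: bool = True,
    sd_floor_frac: float = 0.0,
) -> FitResult:
    """Bounded multi-start minimization of the reduced chi-square.

    ``n_starts`` initial points are drawn uniformly within the bounds and each
    is refined with L-BFGS-B; the lowest-χ²ν refinement wins.  Deterministic
    given ``seed``.  ``fixed`` overrides the default fixed parameters
    (k0, γ, Cmax, and Ta looked up per dose).  ``fast=True`` evaluates the
    model through the compiled RK4 path (same dynamics, validated against the
    LSODA reference); ``fast=False`` goes through :func:`radpop.simulate`.

    ``data`` may also be a list of curves of the same dose; the free
    parameters are then shared across the curves (each keeps its own C0) and
    the objective is the pooled reduced chi-square.

    ``sd_floor_frac`` floors each σ at that fraction of the mean density.
    With few replicates the empirical σ is heavy-tailed in 1/σ² and a
    handful of underestimated error bars can dominate the objective; a floor
    at the detection-error scale (~0.06, which the reported error bars do
    not include) regularizes profile likelihoods.
    """
    curves = list(data) if isinstance(data, (list, tuple)) else [data]
    if len({c.dose for c in curves}) != 1:
        raise ValueError("joint fits require curves of a single dose")
    lead = curves[0]

    free_names = tuple(free_names)
    base = dict(DEFAULT_FIXED)
    base["Ta"] = TA_BY_DOSE.get(float(lead.dose), 0.0)
    if fixed:
        base.update(fixed)
    base["dose"] = float(lead.dose)
    for name in free_names:
        base.pop(name, None)

    gamma = base.get("gamma", DEFAULT_FIXED["gamma"])
    bnds = {}
    for name in free_names:
        lo, hi = (bounds or {}).get(name, DEFAULT_BOUNDS[name])
        if name == "lambda_s" and "gamma" not in free_names:
            hi = min(hi, gamma)  # keeps lambda_D = gamma - lambda_s >= 0
        bnds[name] = (lo, hi)

    k = len(free_names)
    sets = []
    n_tot = 0
    for c in curves:
        mask = _truncation_mask(c, CT)
        n_tot += int(mask.sum())
        sd = _safe_sd(c.sd_density, c.mean_density)
        if sd_floor_frac > 0:
            sd = np.maximum(sd, sd_floor_frac * c.mean_density)
        sets.append((c.C0, c.times[mask], c.mean_density[mask], sd[mask]))
    if n_tot <= k:
        raise ValueError(
            f"n={n_tot} usable points after CT truncation <= k={k} free parameters"
        )
    ndof = n_tot - k

    evals = [0]
    if fast:
        from ._fastode import fast_observed as _observed
    else:

        def _observed(params, C0, times, logistic):
            return _model_density(params, C0, times, logistic)

    def objective(x):
        evals[0] += 1
        try:
            params = _assemble(base, free_names, x)
            total = 0.0
            for C0, times, y, sd in sets:
                resid = (y - _observed(params, C0, times, logistic)) / sd
                total += resid @ resid
        except (IntegrationError, ValueError, OverflowError, FloatingPointError):
            return 1e30
        v = total / ndof
        return v if np.isfinite(v) else 1e30

    rng = np.random.default_rng(seed)
    lo = np.array([bnds[nm][0] for nm in free_names])
    hi = np.array([bnds[nm][1] for nm in free_names])
    starts = rng.uniform(lo, hi, size=(n_starts, k))

    start_obj = np.empty(n_starts)
    best_x, best_f = None, np.inf
    failures = []
    opt_bounds = list(zip(lo, hi))
    for i, x0 in enumerate(starts):
        start_obj[i] = objective(x0)
        res = minimize(objective, x0, method="L-BFGS-B", bounds=opt_bounds)
        if not np.isfinite(res.fun) or res.fun >= 1e29:
            failures.append(f"start {i}: {res.message}")
            continue
        if res.fun < best_f:
            best_f, best_x = float(res.fun), np.clip(res.x, lo, hi)
    if best_x is None:
        raise RuntimeError("all starts failed: " + "; ".join(failures[:5]))

    params = _assemble(base, free_names, best_x)
    return FitResult(
        params=params,
        chi2_nu=best_f,
        free_names=free_names,
        free_values=best_x,
        bounds=bnds,
        n_starts=n_starts,
        seed=seed,
        objective_evals=evals[0],
        start_objectives=start_obj,
    )


def _common_grid(curves) -> np.ndarray:
    t0 = curves[0].times
    for c in curves[1:]:
        if len(c.times) != len(t0) or not np.allclose(c.times, t0):
            lo = max(c.times[0] for c in curves)
            hi = min(c.times[-1] for c in curves)
            step = np.median(np.diff(t0))
            return np.arange(lo, hi + step / 2, step)
    return t0


def estimate_Ta(
    curves,
    window: int = 15,
    polyorder: int = 3,
    CT: float = CONFLUENCE_THRESHOLD,
) -> float:
    """Estimate the repairing-phase duration from the derivative maximum.

    Each curve is normalized by its C0 and interpolated onto a common grid;
    the curves are averaged, differentiated with central finite differences,
    smoothed with a Savitzky–Golay filter, and the time of the maximum of the
    smoothed derivative — restricted to the pre-confluence window — is
    returned.  A maximum sitting on the window boundary triggers a warning
    (unreliable estimate).  At dose 0 the repairing phase vanishes by
    definition (Ta = 0); this estimator is meant for irradiated curves.
    """
    if not curves:
        raise ValueError("need at least one curve")
    grid = _common_grid(curves)
    norm = np.mean(
        [np.interp(grid, c.times, c.mean_density / c.C0) for c in curves], axis=0
    )
    # pre-confluence prefix: stop where any curve first exceeds CT
    n_ok = len(grid)
    for c in curves:
        above = np.where(np.interp(grid, c.times, c.mean_density) > CT)[0]
        if len(above):
            n_ok = min(n_ok, int(above[0]))
    if n_ok < 3:
        raise ValueError("fewer than 3 pre-confluence points; cannot estimate Ta")
    deriv = np.gradient(norm, grid)
    win = min(window, n_ok if n_ok % 2 else n_ok - 1)
    smooth = savgol_filter(deriv[:n_ok], win, min(polyorder, win - 1))
    i = int(np.argmax(smooth))
    if i in (0, n_ok - 1):
        warnings.warn(
            "derivative maximum at the pre-confluence window boundary; "
            "Ta estimate is unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(grid[i])


def estimate_gamma_from_peak(
    curve: TimeCourse,
    Ta: float,
    window: int = 15,
    polyorder: int = 3,
) -> float:
    """Estimate γ from the time of the density maximum, ``γ = 1/(Tmax - Ta)``.

    In the low-density limit the observed density peaks at Tmax = Ta + 1/γ
    (alongside the misrepaired compartment Cu).  The *first* interior maximum
    of the smoothed curve is used: at late times the regrowth of repaired
    cells can climb past the damage-driven peak, which is not the feature the
    estimator targets.
    """
    from scipy.signal import find_peaks

    y = curve.mean_density
    win = min(window, len(y) if len(y) % 2 else len(y) - 1)
    smooth = savgol_filter(y, win, min(polyorder, win - 1)) if win > polyorder else y
    span = float(smooth.max() - smooth.min())
    peaks, _ = find_peaks(smooth, prominence=0.05 * span if span > 0 else None)
    i = int(peaks[0]) if len(peaks) else int(np.argmax(smooth))
    Tmax = float(curve.times[i])
    if Tmax <= Ta:
        raise ValueError(f"density maximum at {Tmax} h is not after Ta={Ta} h")
    return 1.0 / (Tmax - Ta)


def profile_likelihood(
    data: TimeCourse,
    param_name: str,
    grid,
    n_starts_per_point: int = 100,
    seed: int = 0,
    free_names=None,
    **fit_kwargs,
) -> ProfileLikelihood:
    """Scan one parameter over a grid, refitting the others at each value."""
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    if free_names is None:
        free_names = tuple(nm for nm in _DEFAULT_FREE if nm != param_name)
    chi2 = np.full(len(grid), np.nan)
    errors = []
    base_fixed = dict(fit_kwargs.pop("fixed", None) or {})
    for i, g in enumerate(grid):
        fixed = dict(base_fixed)
        fixed[param_name] = float(g)
        child = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        try:
            res = fit(
                data,
                free_names=free_names,
                fixed=fixed,
                n_starts=n_starts_per_point,
                seed=child,
                **fit_kwargs,
            )
            chi2[i] = res.chi2_nu
        except (RuntimeError, ValueError) as exc:  # annotated, not fatal
            errors.append((i, str(exc)))
    return ProfileLikelihood(param_name, grid, chi2, errors)


def fit_exponential_control(curves, k0_bounds=(0.0, 1.0)) -> float:
    """Mean exponential growth rate of control (0 Gy) curves.

    Each curve is fitted with ``C(t) = C0 exp(k0 t)``; C0 is fixed to the
    first observation and k0 is the single free parameter with large bounds.
    Returns the mean fitted k0 across seeding densities.
    """
    if not curves:
        raise ValueError("need at least one control curve")
    rates = []
    for c in curves:
        if np.any(c.mean_density <= 0):
            raise ValueError("non-positive densities in control curve")
        C0 = float(c.mean_density[0])
        t = c.times - c.times[0]
        y = c.mean_density

        def sse(k):
            r = y - C0 * np.exp(k * t)
            return float(r @ r)

        # log-linear slope as the starting point for the bounded 1-D fit
        k_init = float(np.polyfit(t, np.log(y / C0), 1)[0])
        res = minimize(
            lambda v: sse(v[0]),
            [np.clip(k_init, *k0_bounds)],
            method="L-BFGS-B",
            bounds=[k0_bounds],
        )
        rates.append(float(res.x[0]))
    return float(np.mean(rates))
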