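"""Synthetic data emulating the irradiation time-lapse experiment.

Two generators are provided:

* :func:`generate_timecourses` — replicate growth curves with the design of
  the experiment: doses {0, 5, 10, 15} Gy, six seeding densities in a
  doubling series, a 1.5 h sampling step up to 144 h, three replicates and
  15–20 % relative noise on the density.
* :func:`generate_nuclei_image` — fluorescence-like rasters of Gaussian
  nuclei (with a low-intensity tail) over a smooth mesh-scale background
  plus read noise, with the ground-truth centers attached.

The per-dose ground-truth parameter sets (:func:`default_ground_truth`) are
constructed to reproduce the headline observables of the experiment — the
fixed rates k0 = 0.045 h⁻¹, γ = 0.06 h⁻¹, Cmax = 2.4×10⁻³ cells/µm², the
dose-dependent repair durations Ta, the common observed-density maximum
near 35 h at high dose, and asymptotic surviving fractions of the order
reported per dose.  They are plausible regime representatives, not fits to
any particular dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fitting import TimeCourse
from .imaging import NucleiImage
from .model import ModelParams, simulate

__all__ = [
    "ExperimentDesign",
    "NucleiImage",
    "default_ground_truth",
    "generate_timecourses",
    "generate_nuclei_image",
]

#: area of one well of a 6-well plate, µm² (9.6 cm²); converts cells/well to cells/µm²
WELL_AREA_UM2 = 9.6e8

#: seeding series 1.1e4 .. 3.52e5 cells/well, each double the previous
DEFAULT_SEEDING_DENSITIES = tuple(1.1e4 * 2**i / WELL_AREA_UM2 for i in range(6))


@dataclass(frozen=True)
class ExperimentDesign:
    """Study design of the time-lapse irradiation experiment."""

    doses: tuple = (0.0, 5.0, 10.0, 15.0)
    seeding_densities: tuple = DEFAULT_SEEDING_DENSITIES  # cells/µm², lowest→highest
    t_step: float = 1.5  # h
    t_max: float = 144.0  # h
    n_replicates: int = 3
    noise_cv: float = 0.15  # relative sd of a single replicate
    seed: int = 0

    def validate(self) -> "ExperimentDesign":
        if len(self.doses) == 0:
            raise ValueError("dose list must be non-empty")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")
        if self.t_step <= 0 or self.t_max <= 0:
            raise ValueError("t_step and t_max must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        dens = np.asarray(self.seeding_densities, dtype=float)
        if np.any(dens <= 0) or np.any(np.diff(dens) <= 0):
            raise ValueError("seeding densities must be positive and increasing")
        if len(dens) > 1 and not np.allclose(dens[1:] / dens[:-1], 2.0, rtol=1e-6):
            raise ValueError("seeding densities must form a doubling series")
        return self

    @property
    def t_grid(self) -> np.ndarray:
        return np.arange(0.0, self.t_max + self.t_step / 2, self.t_step)


def default_ground_truth() -> dict:
    """Per-dose generating parameters (see module docstring for rationale).

    * 0 Gy — no repairing phase, no misrepair; λr = k0 + γ keeps kd = k0, and
      the control population grows exponentially (its densities stay well
      below the control carrying capacity).
    * 5 Gy — comparable repair/misrepair (S∞ ≈ 0.39); growth is
      logistic-limited so the curve saturates near Cmax.
    * 10 and 15 Gy — misrepair dominates (S∞ ≈ 6.5×10⁻³ and 1.8×10⁻⁴), with
      λs placing the observed-density maximum near Ta + 1/γ ≈ 35 h.
    """
    return {
        0.0: ModelParams(dose=0.0, Ta=0.0, lambda_u=0.0, lambda_r=0.105, lambda_s=0.0),
        5.0: ModelParams(dose=5.0, Ta=16.0, lambda_u=0.055, lambda_r=0.0352, lambda_s=0.03),
        10.0: ModelParams(dose=10.0, Ta=18.0, lambda_u=0.12, lambda_r=7.85e-4, lambda_s=0.03),
        15.0: ModelParams(dose=15.0, Ta=21.0, lambda_u=0.12, lambda_r=2.16e-5, lambda_s=0.025),
    }


def generate_timecourses(
    design: ExperimentDesign,
    truth: dict | None = None,
    noise_model: str = "lognormal",
) -> list[TimeCourse]:
    """Simulate noisy replicate growth curves for every (dose, seeding) pair.

    The noiseless trajectory is perturbed per replicate and per time point by
    multiplicative lognormal factors with unit mean and coefficient of
    variation ``design.noise_cv`` (``noise_model="gaussian"`` switches to
    additive Gaussian noise of the same relative scale); the replicate mean
    and sample sd are reported.  Control (0 Gy) curves are generated without
    the logistic factor (exponential growth); irradiated ones with it.
    Deterministic given ``design.seed``.
    """
    design.validate()
    if noise_model not in ("lognormal", "gaussian"):
        raise ValueError(f"unknown noise_model {noise_model!r}")
    truth = dict(default_ground_truth(), **(truth or {}))
    t = design.t_grid
    cv = design.noise_cv
    sig = math.sqrt(math.log1p(cv * cv)) if cv > 0 else 0.0
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(len(design.doses) * len(design.seeding_densities))
    curves = []
    for i_d, dose in enumerate(design.doses):
        params = truth[float(dose)]
        for i_s, C0 in enumerate(design.seeding_densities):
            rng = np.random.default_rng(children[i_d * len(design.seeding_densities) + i_s])
            clean = simulate(params, C0, t, logistic=(dose > 0)).observed
            if cv > 0:
                if noise_model == "lognormal":
                    factors = np.exp(
                        rng.normal(-sig * sig / 2, sig, size=(design.n_replicates, len(t)))
                    )
                    reps = clean[None, :] * factors
                else:
                    reps = clean[None, :] * (
                        1.0 + rng.normal(0.0, cv, size=(design.n_replicates, len(t)))
                    )
                reps = np.clip(reps, 0.0, None)
                mean = reps.mean(axis=0)
                sd = reps.std(axis=0, ddof=1) if design.n_replicates > 1 else np.zeros(len(t))
            else:
                mean = clean.copy()
                sd = np.zeros(len(t))
            curves.append(
                TimeCourse(
                    dose=float(dose),
                    seeding_index=i_s + 1,
                    C0=float(C0),
                    times=t.copy(),
                    mean_density=mean,
                    sd_density=sd,
                    n_replicates=design.n_replicates,
                )
            )
    return curves


def _sample_centers(rng, n, shape, min_sep, margin):
    """Uniform centers with a minimum-separation rejection rule."""
    centers = np.empty((0, 2))
    attempts = 0
    while len(centers) < n and attempts < 200 * max(n, 1):
        c = rng.uniform([margin, margin], [shape[0] - margin, shape[1] - margin])
        if min_sep > 0 and len(centers):
            if np.min(np.hypot(*(centers - c).T)) < min_sep:
                attempts += 1
                continue
        centers = np.vstack([centers, c])
        attempts += 1
    if len(centers) < n:
        raise ValueError(
            f"could only place {len(centers)}/{n} nuclei with min_separation={min_sep}"
        )
    return centers


def generate_nuclei_image(
    n_nuclei: int,
    shape: tuple = (1040, 1408),
    psf_sigma_px: float = 3.0,
    intensity_range: tuple = (3.0, 30.0),
    background_level: float = 100.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    min_separation_px: float = 9.0,
    edge_margin_px: float = 4.0,
) -> NucleiImage:
    """Synthetic fluorescence image: smooth background + Gaussian nuclei + noise.

    Nucleus amplitudes are drawn log-uniformly in ``intensity_range`` (units
    of ``noise_sd``), producing the dim low-fluorescence tail seen in real
    frames; per-nucleus widths jitter ±15 % around ``psf_sigma_px``.  The
    background varies smoothly on a mesh scale around ``background_level``.
    Deterministic given ``seed``.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    rng = np.random.default_rng(seed)

    # smooth large-scale background: low-res multiplicative field, upsampled
    coarse = rng.uniform(0.97, 1.03, size=(6, 8))
    zoom = (shape[0] / coarse.shape[0], shape[1] / coarse.shape[1])
    img = background_level * ndimage.zoom(coarse, zoom, order=3, grid_mode=True, mode="nearest")
    img = img[: shape[0], : shape[1]].astype(float)

    centers = (
        _sample_centers(rng, n_nuclei, shape, min_separation_px, edge_margin_px)
        if n_nuclei
        else np.empty((0, 2))
    )
    lo, hi = intensity_range
    amps = noise_sd * np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_nuclei))
    sigmas = psf_sigma_px * rng.uniform(0.85, 1.15, size=n_nuclei)

    for (r, c), a, s in zip(centers, amps, sigmas):
        w = int(math.ceil(4 * s))
        r0, r1 = max(0, int(r) - w), min(shape[0], int(r) + w + 1)
        c0, c1 = max(0, int(c) - w), min(shape[1], int(c) + w + 1)
        rr = np.arange(r0, r1)[:, None] - r
        cc = np.arange(c0, c1)[None, :] - c
        img[r0:r1, c0:c1] += a * np.exp(-(rr * rr + cc * cc) / (2 * s * s))

    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    return NucleiImage(pixels=img, ground_truth=centers)
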