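"""Synthetic data: PET tumor phantoms with known hotspot geometry, and
simulated cohorts with a protective hotspot-to-perimeter effect.

Phantoms are spheres or axis-aligned ellipsoids filled with a smooth unimodal
uptake field that peaks at a planted hotspot, optionally blurred by a
Gaussian point-spread function and perturbed by Gaussian noise. The interior
uptake never drops below half the peak, so the entire planted shape survives
a 40% relative threshold and the analytic ground truth is comparable to the
segmented geometry (up to blur and voxelization).

For a sphere with the hotspot planted at normalized offset ``d`` from the
center, the continuum ground truth is ``NHOC = d`` and ``NHOP = 1 - d``.
Ellipsoid truths are computed from the continuum shape (point-to-ellipsoid
distance via 1D root finding), not assumed spherical.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import expit

from .errors import InvalidArgumentError
from .image_core import PETVolume

__all__ = [
    "PhantomTruth",
    "make_phantom",
    "simulate_cohort",
    "ellipsoid_surface_distance",
    "COHORT_CSV_COLUMNS",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

COHORT_CSV_COLUMNS = (
    "patient_id",
    "nhop_max",
    "nhoc_max",
    "suv_max",
    "mtv_ml",
    "tlg",
    "recurrence",
    "dfs_months",
    "event",
)


@dataclass(frozen=True)
class PhantomTruth:
    """Generator parameters plus analytic ground-truth geometry.

    ``true_nhoc``/``true_nhop`` are filled in by :func:`make_phantom`.
    """

    shape_kind: str = "sphere"  # "sphere" | "ellipsoid"
    radii_mm: tuple[float, float, float] = (21.0, 21.0, 21.0)
    hotspot_offset_frac: float = 0.0
    psf_fwhm_mm: float = 0.0
    noise_sd_suv: float = 0.0
    peak_suv: float = 10.0
    background_suv: float = 0.0
    bump_sigma_mm: Optional[float] = None  # default: 0.25 * min radius
    seed: int = 0
    true_nhoc: Optional[float] = None
    true_nhop: Optional[float] = None

    def __post_init__(self) -> None:
        if self.shape_kind not in ("sphere", "ellipsoid"):
            raise InvalidArgumentError(f"unknown shape kind {self.shape_kind!r}")
        radii = tuple(float(r) for r in self.radii_mm)
        if len(radii) != 3 or any(r <= 0 for r in radii):
            raise InvalidArgumentError("radii must be three positive lengths")
        if self.shape_kind == "sphere" and len(set(radii)) != 1:
            raise InvalidArgumentError("sphere phantom requires equal radii")
        if not (0.0 <= self.hotspot_offset_frac < 1.0):
            raise InvalidArgumentError("hotspot offset must lie in [0, 1)")
        if self.psf_fwhm_mm < 0 or self.noise_sd_suv < 0:
            raise InvalidArgumentError("blur and noise parameters must be >= 0")
        if not self.peak_suv > 0:
            raise InvalidArgumentError("peak SUV must be positive")
        if not (0.0 <= self.background_suv < 0.4 * self.peak_suv):
            raise InvalidArgumentError(
                "background SUV must be below 40% of the peak so the lesion is "
                "separable at the default threshold"
            )
        if self.bump_sigma_mm is not None and self.bump_sigma_mm <= 0:
            raise InvalidArgumentError("bump sigma must be positive")
        object.__setattr__(self, "radii_mm", radii)

    @property
    def r_equiv_mm(self) -> float:
        """Radius of the sphere with the ellipsoid's volume: (rx ry rz)^(1/3)."""
        rx, ry, rz = self.radii_mm
        return (rx * ry * rz) ** (1.0 / 3.0)

    def to_json_dict(self) -> dict[str, object]:
        return dataclasses.asdict(self)


def ellipsoid_surface_distance(
    point_mm: np.ndarray, radii_mm: tuple[float, float, float]
) -> float:
    """Distance from an interior point to the surface of a centered ellipsoid.

    Solves the first-order condition of the closest-point problem: the
    nearest surface point is ``y_i = r_i^2 p_i / (r_i^2 + t)`` for the root
    ``t`` of ``sum_i (r_i p_i / (r_i^2 + t))^2 = 1`` in ``(-min r_i^2, 0]``.
    Components with ``p_i = 0`` admit degenerate off-axis candidates at
    ``t = -r_j^2``; all candidates are enumerated and the minimum is taken.
    """
    p = np.asarray(point_mm, dtype=np.float64)
    r = np.asarray(radii_mm, dtype=np.float64)
    if np.sum((p / r) ** 2) >= 1.0:
        raise InvalidArgumentError("point must lie strictly inside the ellipsoid")

    candidates: list[float] = []
    nonzero = np.abs(p) > 1e-12 * r.max()
    if not nonzero.any():
        return float(r.min())

    def g(t: float) -> float:
        return float(np.sum((r[nonzero] * p[nonzero] / (r[nonzero] ** 2 + t)) ** 2) - 1.0)

    lo = -float((r[nonzero] ** 2).min())
    eps = 1e-12 * r.max() ** 2
    a, b = lo + eps, 0.0
    # g -> +inf at lo+, g(0) < 0 for interior points: a unique root in between.
    while g(a) < 0:  # guard against eps overshooting the pole
        eps *= 0.5
        a = lo + eps
    t_root = optimize.brentq(g, a, b, xtol=1e-14, rtol=1e-15)
    y = np.where(nonzero, r**2 * p / (r**2 + t_root), 0.0)
    candidates.append(float(np.linalg.norm(y - p)))

    for j in np.nonzero(~nonzero)[0]:
        # Off-axis candidate: nearest point leaves the subspace {x_j = 0}.
        denom = r**2 - r[j] ** 2
        ok = nonzero & (np.abs(denom) > 1e-12 * r.max() ** 2)
        if not np.array_equal(ok, nonzero):
            continue
        h = 1.0 - float(np.sum((r[ok] * p[ok] / denom[ok]) ** 2))
        if h < 0:
            continue
        y = np.zeros(3)
        y[ok] = (r[ok] ** 2 * p[ok]) / denom[ok]
        y[j] = r[j] * math.sqrt(h)
        candidates.append(float(np.linalg.norm(y - p)))

    return min(candidates)


def _ground_truth(truth: PhantomTruth) -> tuple[float, float]:
    d = truth.hotspot_offset_frac
    if truth.shape_kind == "sphere":
        return d, 1.0 - d
    r_eq = truth.r_equiv_mm
    offset = np.array([d * truth.radii_mm[0], 0.0, 0.0])
    nhoc = float(np.linalg.norm(offset)) / r_eq
    nhop = ellipsoid_surface_distance(offset, truth.radii_mm) / r_eq
    return nhoc, nhop


def make_phantom(
    truth: PhantomTruth, grid_spacing_mm: float = 3.0
) -> tuple[PETVolume, PhantomTruth]:
    """Rasterize a phantom volume; returns it with ground-truth fields filled.

    The hotspot is planted along the +x principal axis at
    ``hotspot_offset_frac`` of the x radius from the center. Uptake inside
    the lesion is a plateau at ``0.5 * peak_suv`` plus a Gaussian bump of
    scale ``bump_sigma_mm`` peaking at ``peak_suv`` at the hotspot, so uptake
    decreases outward and never drops below half the peak inside the lesion.
    Deterministic given ``truth.seed``.
    """
    spacing = float(grid_spacing_mm)
    if spacing <= 0:
        raise InvalidArgumentError("grid spacing must be positive")
    if min(truth.radii_mm) < 4.0 * spacing:
        raise InvalidArgumentError(
            f"radii {truth.radii_mm} too small for spacing {spacing} "
            "(need radius >= 4 voxels)"
        )

    margin = max(3.0 * spacing, 2.0 * truth.psf_fwhm_mm)
    half_counts = [int(math.ceil((r + margin) / spacing)) for r in truth.radii_mm]
    shape = tuple(2 * h + 1 for h in half_counts)
    center = np.array([h * spacing for h in half_counts])

    axes = [np.arange(n) * spacing - c for n, c in zip(shape, center)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    rx, ry, rz = truth.radii_mm
    inside = (gx / rx) ** 2 + (gy / ry) ** 2 + (gz / rz) ** 2 <= 1.0

    hotspot_mm = np.array([truth.hotspot_offset_frac * rx, 0.0, 0.0])
    dist_to_hot = np.sqrt(
        (gx - hotspot_mm[0]) ** 2 + (gy - hotspot_mm[1]) ** 2 + (gz - hotspot_mm[2]) ** 2
    )
    # Plateau at half the peak plus a sharp Gaussian bump at the hotspot: the
    # whole lesion clears a 40% relative threshold, while the uptake maximum
    # stays pinned at the planted location under mild blur and noise.
    sigma_bump = truth.bump_sigma_mm or 0.18 * min(truth.radii_mm)
    lesion = 0.5 * truth.peak_suv * (1.0 + np.exp(-0.5 * (dist_to_hot / sigma_bump) ** 2))
    values = np.where(inside, lesion, truth.background_suv)

    if truth.psf_fwhm_mm > 0:
        sigma_vox = truth.psf_fwhm_mm * _FWHM_TO_SIGMA / spacing
        values = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="nearest")
    if truth.noise_sd_suv > 0:
        rng = np.random.default_rng(truth.seed)
        values = values + rng.normal(0.0, truth.noise_sd_suv, size=values.shape)
    values = np.clip(values, 0.0, None)

    nhoc, nhop = _ground_truth(truth)
    resolved = dataclasses.replace(truth, true_nhoc=nhoc, true_nhop=nhop)
    return PETVolume(values, (spacing, spacing, spacing)), resolved


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

# Marginal location/scale used to map latent standard normals onto plausible
# metric scales (means/SDs of the same order as routine clinical cohorts).
_MARGINALS = {
    "nhop_max": ("clipped_normal", 0.34, 0.23),
    "nhoc_max": ("clipped_normal", 0.55, 0.28),
    "suv_max": ("lognormal", 6.54, 4.62),
    "mtv_ml": ("lognormal", 5.43, 10.61),
    "tlg": ("lognormal", 25.68, 76.45),
}


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def simulate_cohort(
    n: int,
    *,
    beta_nhop: float = -1.2,
    beta_suv: float = 0.5,
    intercept: float = -1.5,
    baseline_hazard: float = 0.02,
    hr_nhop: float = 0.4,
    censor_months: float = 96.0,
    binormal_delta: Optional[float] = None,
    prevalence: float = 0.2,
    correlation: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-patient cohort table.

    Metric columns are generated from correlated latent standard normals
    (exchangeable correlation ``correlation``) pushed through log-normal /
    clipped-normal marginals. Two outcome designs:

    * default (logistic): ``recurrence ~ Bernoulli(expit(intercept
      + beta_nhop * z_nhop + beta_suv * z_suv))`` on the standardized latent
      scores, so ``beta_nhop < 0`` makes a high hotspot-to-perimeter distance
      protective;
    * binormal (``binormal_delta`` given): ``recurrence ~
      Bernoulli(prevalence)`` and the latent nhop score of recurrent patients
      is shifted down by ``binormal_delta``, so the theoretical AUC of nhop
      is ``Phi(delta / sqrt 2)``.

    Recurrent patients draw an exponential event time with hazard
    ``baseline_hazard * hr_nhop ** z_nhop``, administratively censored at
    ``censor_months``; non-recurrent patients are censored there. Hence
    ``event == 1`` implies ``recurrence == 1``. Deterministic given ``seed``.
    """
    if n < 10:
        raise InvalidArgumentError("cohort size must be at least 10")
    params = [beta_nhop, beta_suv, intercept, baseline_hazard, hr_nhop, censor_months]
    if not all(np.isfinite(params)):
        raise InvalidArgumentError("effect parameters must be finite")
    if baseline_hazard <= 0:
        raise InvalidArgumentError("baseline hazard must be positive")
    if not (0.0 <= correlation < 1.0):
        raise InvalidArgumentError("correlation must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    names = list(_MARGINALS)
    k = len(names)
    cov = np.full((k, k), correlation)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    latent = dict(zip(names, z.T))

    if binormal_delta is None:
        lin = intercept + beta_nhop * latent["nhop_max"] + beta_suv * latent["suv_max"]
        recurrence = (rng.random(n) < expit(lin)).astype(int)
    else:
        if not np.isfinite(binormal_delta):
            raise InvalidArgumentError("binormal separation must be finite")
        recurrence = (rng.random(n) < prevalence).astype(int)
        latent["nhop_max"] = latent["nhop_max"] - binormal_delta * recurrence

    columns: dict[str, np.ndarray] = {}
    for name in names:
        kind, a, b = _MARGINALS[name]
        if kind == "lognormal":
            mu, sigma = _lognormal_params(a, b)
            columns[name] = np.exp(mu + sigma * latent[name])
        else:
            columns[name] = np.clip(a + b * latent[name], 0.005, None)

    z_nhop = latent["nhop_max"]
    hazard = baseline_hazard * np.power(hr_nhop, z_nhop)
    event_time = rng.exponential(1.0 / hazard)
    dfs = np.where(recurrence == 1, np.minimum(event_time, censor_months), censor_months)
    event = ((recurrence == 1) & (event_time <= censor_months)).astype(int)

    table = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "nhop_max": columns["nhop_max"],
            "nhoc_max": columns["nhoc_max"],
            "suv_max": columns["suv_max"],
            "mtv_ml": columns["mtv_ml"],
            "tlg": columns["tlg"],
            "recurrence": recurrence,
            "dfs_months": dfs,
            "event": event,
        }
    )
    return table
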