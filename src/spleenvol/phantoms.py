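"""Synthetic spleen phantoms with exact analytic volumes, and cohort generation.

The spleen varies hugely in size, shape and position between individuals, and
no public dataset accompanies the kind of retrospective volumetry study this
package emulates.  Everything downstream (segmentation, Cavalieri volume,
coefficient of error, morphometry, cohort regression) is therefore validated
against voxelized 3-D phantoms whose true volume is known in closed form or
from a high-resolution numerical quadrature, and against a gender-stratified
synthetic cohort whose volume/length distributions match published summary
statistics (male 223.5 ± 122.9 cm³, 10 ± 2.3 cm; female 170.27 ± 89.25 cm³,
8.7 ± 2.1 cm; 110 male, 235 female).

All lengths are centimetres, areas cm², volumes cm³.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import root
from scipy.spatial.transform import Rotation
from scipy.special import gamma
from scipy.stats import truncnorm

from .imaging_io import ImageSeries, SegmentationMask

logger = logging.getLogger(__name__)

SHAPE_KINDS = ("ellipsoid", "superellipsoid", "bumpy_ellipsoid")

INSIDE_VALUE = 1000.0  # phantom tissue intensity; background is 0


@dataclass(frozen=True)
class PhantomSpec:
    """An analytic 3-D shape standing in for a spleen.

    ``semi_axes`` are the (a, b, c) semi-axes in cm along the shape's local
    x/y/z axes.  ``exponent`` is the superellipsoid exponent p in
    |x/a|^p + |y/b|^p + |z/c|^p <= 1 (p = 2 reduces to the ellipsoid).
    ``bump_amplitude`` modulates the radial extent of a bumpy ellipsoid by
    1 + amplitude * sin(3θ)cos(2φ); it vanishes at the poles so the
    craniocaudal extent stays 2c.  ``rotation`` is intrinsic x-y-z Euler
    angles in radians.
    """

    shape_kind: str = "ellipsoid"
    semi_axes: tuple[float, float, float] = (3.0, 3.0, 5.0)
    exponent: float = 2.0
    bump_amplitude: float = 0.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "semi_axes", tuple(float(v) for v in self.semi_axes))
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))
        object.__setattr__(self, "rotation", tuple(float(v) for v in self.rotation))
        if self.shape_kind not in SHAPE_KINDS:
            raise ValueError(f"unsupported shape_kind {self.shape_kind!r}; one of {SHAPE_KINDS}")
        if len(self.semi_axes) != 3 or any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be three positive lengths (cm)")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")
        if not 0.0 <= self.bump_amplitude <= 0.3:
            raise ValueError("bump_amplitude must lie in [0, 0.3]")

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation).as_matrix()

    def half_extents(self) -> np.ndarray:
        """Conservative world-frame half-extents (cm) along x, y, z.

        Every supported shape lies inside the local box
        [-a, a]x[-b, b]x[-c, c] scaled by (1 + bump_amplitude), so the
        rotated bounding half-extent along world axis i is
        sum_j |R_ij| * box_j.
        """
        box = np.asarray(self.semi_axes) * (1.0 + self.bump_amplitude)
        return np.abs(self.rotation_matrix) @ box

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership test for world-frame points (N, 3) in cm."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        local = (pts - np.asarray(self.center)) @ self.rotation_matrix  # R^T p
        n = local / np.asarray(self.semi_axes)
        if self.shape_kind == "ellipsoid":
            return np.einsum("ij,ij->i", n, n) <= 1.0
        if self.shape_kind == "superellipsoid":
            p = self.exponent
            return np.sum(np.abs(n) ** p, axis=1) <= 1.0
        # bumpy ellipsoid: radial bound 1 + amp*sin(3θ)cos(2φ) in normalized space
        m = np.sqrt(np.einsum("ij,ij->i", n, n))
        inside = np.ones(len(n), dtype=bool)
        nz = m > 0
        u = n[nz] / m[nz, None]
        theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
        phi = np.arctan2(u[:, 1], u[:, 0])
        bound = 1.0 + self.bump_amplitude * np.sin(3.0 * theta) * np.cos(2.0 * phi)
        inside[nz] = m[nz] <= bound
        return inside


@dataclass(frozen=True)
class VoxelizationConfig:
    """MRI-like sampling geometry for rasterizing a phantom.

    Defaults emulate a typical abdominal acquisition: 1.5 x 1.5 mm in-plane
    pixels and 8 mm center-to-center slice spacing (6 mm slice thickness plus
    2 mm inter-slice gap).  ``slice_offset`` is the distance (cm) of the first
    slice plane from the lower grid edge; ``None`` draws it uniformly on
    [0, d) — the random start the Cavalieri estimator requires.
    """

    pixel_spacing: tuple[float, float] = (0.15, 0.15)  # (dx, dy) cm
    slice_thickness: float = 0.6
    slice_gap: float = 0.2
    slice_offset: Optional[float] = None
    grid_margin: float = 0.5
    grid_half_extents: Optional[tuple[float, float, float]] = None
    noise_sd: float = 0.0  # additive Gaussian intensity noise (image units)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixel_spacing", tuple(float(v) for v in self.pixel_spacing))
        dx, dy = self.pixel_spacing
        if dx <= 0 or dy <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")
        if self.slice_gap < 0:
            raise ValueError("slice_gap must be non-negative")
        if self.slice_offset is not None and not 0.0 <= self.slice_offset < self.d:
            raise ValueError("slice_offset must lie in [0, d)")
        if self.grid_margin < 0:
            raise ValueError("grid_margin must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def d(self) -> float:
        """Center-to-center slice spacing (cm): thickness + gap."""
        return self.slice_thickness + self.slice_gap


# ---------------------------------------------------------------------------
# analytic volumes


def analytic_volume(spec: PhantomSpec) -> float:
    """True volume (cm³) of a phantom.

    Closed form for the ellipsoid (4/3·π·a·b·c) and the superellipsoid
    (8abc·Γ(1+1/p)³/Γ(1+3/p)); the bumpy ellipsoid uses a cached
    Gauss–Legendre × trapezoid spherical quadrature with >10⁶ sample points
    (accurate to well below 1e-10 relative for these smooth radii).
    """
    a, b, c = spec.semi_axes
    return a * b * c * unit_volume_factor(spec.shape_kind, spec.exponent, spec.bump_amplitude)


@lru_cache(maxsize=None)
def unit_volume_factor(shape_kind: str, exponent: float, bump_amplitude: float) -> float:
    """Volume of the unit-semi-axis shape; analytic volume = a·b·c times this."""
    if shape_kind == "ellipsoid":
        return 4.0 * math.pi / 3.0
    if shape_kind == "superellipsoid":
        p = exponent
        return 8.0 * gamma(1.0 + 1.0 / p) ** 3 / gamma(1.0 + 3.0 / p)
    if shape_kind == "bumpy_ellipsoid":
        return _bumpy_unit_volume(bump_amplitude)
    raise ValueError(f"unsupported shape_kind {shape_kind!r}")


def _bumpy_unit_volume(amp: float, n_theta: int = 1024, n_phi: int = 1024) -> float:
    # V = (1/3) ∮ r(θ,φ)³ dΩ over the unit sphere, r = 1 + amp·sin(3θ)cos(2φ)
    t, w = leggauss(n_theta)  # nodes in cosθ on [-1, 1]
    theta = np.arccos(t)[:, None]
    phi = np.linspace(0.0, 2.0 * math.pi, n_phi, endpoint=False)[None, :]
    r = 1.0 + amp * np.sin(3.0 * theta) * np.cos(2.0 * phi)
    inner = (r**3).mean(axis=1) * 2.0 * math.pi  # periodic trapezoid in φ
    return float((w * inner).sum() / 3.0)


# ---------------------------------------------------------------------------
# voxelization


def voxelize(
    spec: PhantomSpec, cfg: VoxelizationConfig, subject_id: str = "phantom"
) -> tuple[ImageSeries, SegmentationMask, float]:
    """Rasterize a phantom onto an MRI-like grid.

    Returns the two-level intensity series (inside 1000, background 0, plus
    optional Gaussian noise), the ground-truth binary mask (voxel inside iff
    its *center* satisfies the shape inequality), and the analytic volume.
    Slice planes sit at z = z_lo + offset + k·d; the uniform random offset
    makes repeated voxelizations a systematic random sample along the axis.
    """
    rng = np.random.default_rng(cfg.seed)
    dx, dy = cfg.pixel_spacing
    d = cfg.d
    half = spec.half_extents() + cfg.grid_margin
    if cfg.grid_half_extents is not None:
        grid_half = np.asarray(cfg.grid_half_extents, dtype=float)
        if np.any(half > grid_half + 1e-12):
            raise ValueError(
                f"phantom (half-extents {tuple(np.round(half, 3))} cm incl. margin) "
                f"exceeds grid half-extents {tuple(grid_half)} cm"
            )
        half = grid_half
    cx, cy, cz = spec.center

    offset = cfg.slice_offset
    if offset is None:
        offset = float(rng.uniform(0.0, d))

    nx = max(1, math.ceil(2.0 * half[0] / dx))
    ny = max(1, math.ceil(2.0 * half[1] / dy))
    xs = cx + (np.arange(nx) - (nx - 1) / 2.0) * dx
    ys = cy + (np.arange(ny) - (ny - 1) / 2.0) * dy
    z_lo, z_hi = cz - half[2], cz + half[2]
    zs = z_lo + offset + d * np.arange(max(1, math.floor((z_hi - z_lo - offset) / d) + 1))

    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    mask = spec.contains(pts).reshape(len(zs), ny, nx)

    intensity = np.where(mask, INSIDE_VALUE, 0.0)
    if cfg.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, cfg.noise_sd, size=intensity.shape)
    pixels = np.clip(np.rint(intensity), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    series = ImageSeries(
        pixels=pixels,
        dx=dx,
        dy=dy,
        slice_thickness=cfg.slice_thickness,
        slice_gap=cfg.slice_gap,
        subject_id=subject_id,
        z_positions=zs.copy(),
        provenance="synthetic phantom",
    )
    return series, SegmentationMask(data=mask, label="spleen"), analytic_volume(spec)


# ---------------------------------------------------------------------------
# cohort generation

SEXES = ("male", "female")

# Single-slice predictor study conditions: mean, SD, and latent correlation
# with spleen volume.  Means are the cohort-level published values; SDs are
# the published per-variable standard errors scaled by sqrt(345); the
# correlations encode the study's qualitative finding that only the abdomen
# transverse diameter carries a (weak) volume signal.
PREDICTOR_DEFAULTS: dict[str, tuple[float, float, float]] = {
    "age": (51.658, 16.271, 0.0),
    "l1_ap": (2.5773, 0.3232, 0.05),
    "l1_tv": (3.2275, 0.3802, 0.05),
    "l1_area": (7.6177, 1.6565, 0.05),
    "abd_ap": (20.9712, 3.2642, 0.05),
    "abd_tv": (30.0002, 3.9383, 0.30),
    "abd_circumference": (99.0719, 14.3625, 0.05),
    "canal_area": (3.0757, 0.5565, 0.05),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the gender-stratified synthetic cohort.

    Volume and length are sex-conditional truncated-at-zero normals whose
    *truncated* mean/SD equal the configured values, coupled through a latent
    Gaussian with correlation ``volume_length_corr``.  Each subject gets a
    phantom whose analytic volume equals the drawn volume and whose long
    (craniocaudal) axis equals the drawn length, with the two short semi-axes
    equal and solved from the shape's volume formula.
    """

    n_male: int = 110
    n_female: int = 235
    volume_mean_by_sex: dict[str, float] = field(
        default_factory=lambda: {"male": 223.5, "female": 170.27}
    )
    volume_sd_by_sex: dict[str, float] = field(
        default_factory=lambda: {"male": 122.9, "female": 89.25}
    )
    length_mean_by_sex: dict[str, float] = field(
        default_factory=lambda: {"male": 10.0, "female": 8.7}
    )
    length_sd_by_sex: dict[str, float] = field(
        default_factory=lambda: {"male": 2.3, "female": 2.1}
    )
    volume_length_corr: float = 0.80
    predictor_means: dict[str, float] = field(
        default_factory=lambda: {k: v[0] for k, v in PREDICTOR_DEFAULTS.items()}
    )
    predictor_sds: dict[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in PREDICTOR_DEFAULTS.items()}
    )
    predictor_volume_corr: dict[str, float] = field(
        default_factory=lambda: {k: v[2] for k, v in PREDICTOR_DEFAULTS.items()}
    )
    shape_weights: dict[str, float] = field(
        default_factory=lambda: {"ellipsoid": 0.5, "superellipsoid": 0.5}
    )
    exponent: float = 2.5
    bump_amplitude: float = 0.0
    n_raters: int = 2
    rater_cv: float = 0.02  # per-rater observation CV on single-slice predictors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("cohort counts must be non-negative")
        for dct in (self.volume_sd_by_sex, self.length_sd_by_sex, self.predictor_sds):
            if any(v < 0 for v in dct.values()):
                raise ValueError("standard deviations must be non-negative")
        if not -1.0 < self.volume_length_corr < 1.0:
            raise ValueError("volume_length_corr must lie in (-1, 1)")
        if set(self.shape_weights) - set(SHAPE_KINDS):
            raise ValueError(f"shape_weights keys must be among {SHAPE_KINDS}")
        if self.n_raters < 1:
            raise ValueError("n_raters must be >= 1")


@dataclass
class CohortSubject:
    """Ground truth for one synthetic subject plus its phantom."""

    subject_id: str
    sex: str
    spec: PhantomSpec
    true_volume: float
    true_length: float
    predictors: dict[str, float]
    voxel_seed: int
    n_resampled: int = 0

    @property
    def age(self) -> float:
        return self.predictors["age"]


@lru_cache(maxsize=None)
def truncated_normal_parent(mean: float, sd: float) -> tuple[float, float]:
    """Parent (μ, σ) of a zero-truncated normal with given truncated mean/SD."""
    if sd == 0:
        return float(mean), 0.0
    if mean <= 0:
        raise ValueError("target mean of a zero-truncated normal must be positive")

    def equations(params: np.ndarray) -> list[float]:
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        m, v = truncnorm.stats(-mu / sigma, np.inf, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = root(equations, x0=np.array([mean, math.log(sd)]), tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"truncated-normal moment matching failed for mean={mean}, sd={sd}")
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def _solve_axes(volume: float, length: float, kind: str, exponent: float, amp: float):
    """Short semi-axis a (= b) for a phantom of given volume and long axis 2c."""
    c = length / 2.0
    k = unit_volume_factor(kind, exponent, amp)
    a = math.sqrt(volume / (k * c))
    feasible = a * (1.0 + amp) <= c  # long axis must really be the longest extent
    return a, c, feasible


def generate_cohort(cfg: CohortConfig) -> list[CohortSubject]:
    """Draw a reproducible gender-stratified cohort with phantom ground truth.

    Volumes, lengths and predictors are strictly positive (zero-truncation by
    rejection on the latent draws).  Infeasible volume/length pairs — a length
    too short to be the phantom's longest extent — are resampled and counted
    in ``n_resampled``.
    """
    rng = np.random.default_rng(cfg.seed)
    kinds = sorted(cfg.shape_weights)
    weights = np.array([cfg.shape_weights[k] for k in kinds], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("shape_weights must have positive total weight")
    weights = weights / weights.sum()
    rho = cfg.volume_length_corr

    subjects: list[CohortSubject] = []
    counts = {"male": cfg.n_male, "female": cfg.n_female}
    idx = 0
    for sex in SEXES:
        mu_v, sig_v = truncated_normal_parent(
            cfg.volume_mean_by_sex[sex], cfg.volume_sd_by_sex[sex]
        )
        mu_l, sig_l = truncated_normal_parent(
            cfg.length_mean_by_sex[sex], cfg.length_sd_by_sex[sex]
        )
        for _ in range(counts[sex]):
            idx += 1
            kind = kinds[int(rng.choice(len(kinds), p=weights))]
            exponent = cfg.exponent if kind == "superellipsoid" else 2.0
            amp = cfg.bump_amplitude if kind == "bumpy_ellipsoid" else 0.0
            n_resampled = 0
            for _attempt in range(10_000):
                z_v = rng.standard_normal()
                z_l = rho * z_v + math.sqrt(1.0 - rho * rho) * rng.standard_normal()
                vol = mu_v + sig_v * z_v
                length = mu_l + sig_l * z_l
                if vol > 0 and length > 0:
                    a, c, ok = _solve_axes(vol, length, kind, exponent, amp)
                    if ok:
                        break
                n_resampled += 1
            else:
                raise RuntimeError(f"could not draw a feasible subject for sex={sex}")
            if n_resampled:
                logger.debug("subject %d: resampled %d infeasible draws", idx, n_resampled)

            predictors: dict[str, float] = {}
            for name, mean in cfg.predictor_means.items():
                sd = cfg.predictor_sds[name]
                r = cfg.predictor_volume_corr.get(name, 0.0)
                for _attempt in range(10_000):
                    z = r * z_v + math.sqrt(1.0 - r * r) * rng.standard_normal()
                    value = mean + sd * z
                    if value > 0:
                        break
                else:
                    raise RuntimeError(f"could not draw positive predictor {name}")
                predictors[name] = value

            spec = PhantomSpec(
                shape_kind=kind,
                semi_axes=(a, a, c),
                exponent=exponent,
                bump_amplitude=amp,
            )
            subjects.append(
                CohortSubject(
                    subject_id=f"S{idx:04d}",
                    sex=sex,
                    spec=spec,
                    true_volume=vol,
                    true_length=length,
                    predictors=predictors,
                    voxel_seed=int(rng.integers(0, 2**31 - 1)),
                    n_resampled=n_resampled,
                )
            )
    return subjects


def cohort_truth_table(subjects: list[CohortSubject]):
    """Ground-truth table (one row per subject) as a pandas DataFrame."""
    import pandas as pd

    if not subjects:
        cols = [
            "subject_id", "sex", "true_volume_cm3", "true_length_cm", "shape_kind",
            "semi_axis_short_cm", "semi_axis_long_cm", "voxel_seed", "n_resampled",
        ] + [f"true_{k}" for k in PREDICTOR_DEFAULTS]
        return pd.DataFrame(columns=cols)
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "sex": s.sex,
            "true_volume_cm3": s.true_volume,
            "true_length_cm": s.true_length,
            "shape_kind": s.spec.shape_kind,
            "semi_axis_short_cm": s.spec.semi_axes[0],
            "semi_axis_long_cm": s.spec.semi_axes[2],
            "voxel_seed": s.voxel_seed,
            "n_resampled": s.n_resampled,
        }
        row.update({f"true_{k}": v for k, v in s.predictors.items()})
        rows.append(row)
    return pd.DataFrame(rows)
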