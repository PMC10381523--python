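"""Synthetic inputs with known ground truth for every pipeline stage.

The study's raw per-sample data are not published, so verification relies
on generated inputs whose true structure is known exactly:

- small-n predictor tables with a prescribed linear model y = Xβ + ε
  (Gaussian noise on the response), optionally rank-deficient through
  latent factors — exercises the regression engine's coefficient recovery;
- full study tables with valid compositions (drawn on the 100 % simplex)
  and ordered roughness triples — exercises the dataset schema and IO;
- quasi-circular granule silhouettes whose boundary is a base circle plus
  low-order waviness plus a sinusoidal roughness term with closed-form
  Pa = 2A/π and Pq = A/√2 — exercises binarization, envelope tracing and
  the roughness parameters;
- mask pairs hitting an exact target area fraction — exercises the
  macroporosity counter.

All draws go through ``numpy.random.default_rng`` (PCG64) under the spec's
seed; identical specs give identical artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import (
    BiomaterialRecord,
    Composition,
    StudyTable,
    SummaryStat,
    COMPOSITION_FIELDS,
)
from .image_quant import CalibratedImage

__all__ = [
    "SyntheticError",
    "TableGenSpec",
    "GranuleGenSpec",
    "GranuleImage",
    "gen_table",
    "gen_study_table",
    "gen_granule_image",
    "gen_mask_pair",
    "RNG_ALGORITHM",
]

RNG_ALGORITHM = "numpy.random.PCG64"


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class TableGenSpec:
    """Recipe for a predictor table with known linear structure.

    ``predictor_ranges`` defaults to (0, 100) per column — the wt% and
    percent scales of the study's predictors. ``latent_rank`` < p draws the
    columns from that many latent factors, emulating the collinearity of
    coupled physico-chemical properties.
    """

    seed: int
    n: int
    p: int
    true_coefficients: tuple[float, ...]
    noise_sd: float = 0.0
    latent_rank: int | None = None
    predictor_ranges: tuple[tuple[float, float], ...] | None = None
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise SyntheticError("n must be ≥ 4")
        if self.p < 1:
            raise SyntheticError("p must be ≥ 1")
        if len(self.true_coefficients) != self.p:
            raise SyntheticError("true_coefficients must have length p")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be ≥ 0")
        r = self.p if self.latent_rank is None else self.latent_rank
        if not (1 <= r <= self.p):
            raise SyntheticError("latent_rank must be in [1, p]")
        ranges = self.predictor_ranges or tuple((0.0, 100.0) for _ in range(self.p))
        if len(ranges) != self.p or any(hi <= lo for lo, hi in ranges):
            raise SyntheticError("predictor_ranges must be p non-empty intervals")
        object.__setattr__(self, "predictor_ranges", tuple((float(a), float(b)) for a, b in ranges))
        object.__setattr__(self, "true_coefficients", tuple(float(c) for c in self.true_coefficients))


def gen_table(spec: TableGenSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (X, y, β): X uniform in its ranges, y = β0 + Xβ + N(0, σ²)."""
    rng = np.random.default_rng(spec.seed)
    r = spec.p if spec.latent_rank is None else spec.latent_rank
    if r == spec.p:
        U = rng.uniform(size=(spec.n, spec.p))
    else:
        Z = rng.uniform(size=(spec.n, r))
        M = rng.uniform(0.2, 1.0, size=(r, spec.p))
        U = Z @ M
        span = U.max(axis=0) - U.min(axis=0)
        span[span == 0] = 1.0
        U = (U - U.min(axis=0)) / span
    lo = np.array([a for a, _ in spec.predictor_ranges])
    hi = np.array([b for _, b in spec.predictor_ranges])
    X = lo + U * (hi - lo)
    beta = np.array(spec.true_coefficients)
    y = spec.intercept + X @ beta
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n)
    return X, y, beta


_SYNTH_PREDICTORS = ("caco3_wt", "ti_wt", "macroporosity")


#: Dirichlet concentration for synthetic compositions: apatite-dominated
#: grafts with minor carbonate/collagen/water/titanium phases, so the linear
#: BMC model stays inside [0, 100] and avoids censoring bias.
_COMPOSITION_ALPHA = (8.0, 3.0, 0.8, 1.5, 1.2, 0.8)


def gen_study_table(
    seed: int,
    n: int = 8,
    true_coefficients: Sequence[float] = (1.5, -0.3, -0.35),
    intercept: float = 50.0,
    noise_sd: float = 2.0,
) -> tuple[StudyTable, np.ndarray]:
    """A schema-valid synthetic study table with a known BMC model.

    Compositions are drawn on the 100 % simplex (apatite-dominated),
    roughness triples respect Pa ≤ Pq ≤ Pt, and the 6-month BMC mean
    follows a linear model over (caco3_wt, ti_wt, macroporosity) with
    Gaussian noise, clipped to [0, 100] as a last resort. Returns the table
    and the true coefficient vector.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(true_coefficients, dtype=float)
    if beta.shape != (3,):
        raise SyntheticError("gen_study_table uses exactly 3 true coefficients")
    records = []
    for i in range(n):
        w = rng.dirichlet(_COMPOSITION_ALPHA) * 100.0
        comp = Composition(**dict(zip(COMPOSITION_FIELDS, w)))
        mp = float(rng.uniform(10.0, 75.0))
        pa = float(rng.uniform(0.3, 1.5))
        pq = pa * float(rng.uniform(1.05, 1.3))
        pt = pq * float(rng.uniform(2.0, 5.0))
        x = np.array([comp.caco3_wt, comp.ti_wt, mp])
        bmc = float(np.clip(intercept + x @ beta + rng.normal(0.0, noise_sd), 0.0, 100.0))
        ra = float(rng.uniform(40.0, 100.0))
        records.append(
            BiomaterialRecord(
                name=f"synthetic-{i:02d}",
                composition=comp,
                origin="synthetic",
                particle_size_um=(250.0, 1000.0),
                macroporosity=SummaryStat(mp, float(rng.uniform(1.0, 8.0)), 6),
                pa=SummaryStat(pa, 0.05, 3),
                pt=SummaryStat(pt, 0.5, 3),
                pq=SummaryStat(pq, 0.08, 3),
                bmc_6mo=SummaryStat(bmc, float(rng.uniform(3.0, 15.0)), 6),
                regenerated_area_6mo=SummaryStat(ra, float(rng.uniform(3.0, 15.0)), 6),
            )
        )
    return StudyTable(tuple(records)), beta


@dataclass(frozen=True)
class GranuleGenSpec:
    """Recipe for a quasi-circular granule silhouette.

    The boundary radius is ``base_radius_um`` plus an order-2 waviness term
    of amplitude ``waviness_amplitude_um`` plus a sinusoidal roughness term
    of amplitude ``roughness_amplitude_um`` whose wavelength (measured
    along the circumference) is snapped to an integer number of periods to
    keep the boundary continuous.
    """

    seed: int
    image_size: int = 480
    pixel_size_um: float = 0.25
    base_radius_um: float = 45.0
    roughness_amplitude_um: float = 1.2
    roughness_wavelength_um: float = 8.0
    waviness_amplitude_um: float = 0.0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise SyntheticError("image_size must be ≥ 16 pixels")
        if self.pixel_size_um <= 0 or self.base_radius_um <= 0:
            raise SyntheticError("pixel size and base radius must be positive")
        if self.roughness_amplitude_um < 0 or self.waviness_amplitude_um < 0:
            raise SyntheticError("amplitudes must be ≥ 0")
        if self.roughness_wavelength_um <= 2 * self.pixel_size_um:
            raise SyntheticError("roughness wavelength must exceed 2 pixels (resolvable)")
        reach = self.base_radius_um + self.roughness_amplitude_um + self.waviness_amplitude_um
        if 2 * reach >= self.image_size * self.pixel_size_um:
            raise SyntheticError(
                f"granule (diameter ≤ {2 * reach:g} µm) exceeds the "
                f"{self.image_size * self.pixel_size_um:g} µm frame"
            )


@dataclass(frozen=True)
class GranuleImage:
    """A rendered granule with its exact boundary and analytic roughness."""

    image: CalibratedImage
    boundary_theta: np.ndarray = field(repr=False)
    boundary_radius_um: np.ndarray = field(repr=False)
    analytic_pa_um: float
    analytic_pq_um: float
    effective_wavelength_um: float
    metadata: dict


def gen_granule_image(spec: GranuleGenSpec, n_boundary: int = 4096) -> GranuleImage:
    """Render a granule silhouette with known boundary roughness.

    Material pixels take gray level 200 on a background of 20 (8-bit), so
    Otsu binarization is exact. The analytic Pa = 2A/π and Pq = A/√2 of the
    sinusoidal roughness term are attached as ground truth; random phases
    are the only stochastic element.
    """
    rng = np.random.default_rng(spec.seed)
    m = max(1, round(2 * math.pi * spec.base_radius_um / spec.roughness_wavelength_um))
    lam_eff = 2 * math.pi * spec.base_radius_um / m
    phase_r = float(rng.uniform(0, 2 * math.pi))
    phase_w = float(rng.uniform(0, 2 * math.pi))

    def radius(theta: np.ndarray) -> np.ndarray:
        return (
            spec.base_radius_um
            + spec.waviness_amplitude_um * np.sin(2 * theta + phase_w)
            + spec.roughness_amplitude_um * np.sin(m * theta + phase_r)
        )

    S = spec.image_size
    u = spec.pixel_size_um
    c = (S - 1) / 2.0
    yy, xx = np.mgrid[0:S, 0:S]
    dx = (xx - c) * u
    dy = (c - yy) * u  # row 0 is the image top
    theta = np.arctan2(dy, dx)
    mask = np.hypot(dx, dy) <= radius(theta)
    pixels = np.where(mask, 200, 20).astype(np.uint8)

    th = np.linspace(-math.pi, math.pi, n_boundary, endpoint=False)
    A = spec.roughness_amplitude_um
    return GranuleImage(
        image=CalibratedImage(pixels=pixels, pixel_size_um=u),
        boundary_theta=th,
        boundary_radius_um=radius(th),
        analytic_pa_um=2 * A / math.pi,
        analytic_pq_um=A / math.sqrt(2),
        effective_wavelength_um=lam_eff,
        metadata={
            "rng": RNG_ALGORITHM,
            "seed": spec.seed,
            "harmonic_order": m,
            "phase_roughness": phase_r,
            "phase_waviness": phase_w,
        },
    )


def gen_mask_pair(
    seed: int,
    zone_shape: tuple[int, int] = (100, 100),
    target_macroporosity: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A full zonal mask and a colonized subset hitting a target percentage.

    The colonized mask has exactly round(target/100 · area) pixels, drawn
    uniformly without replacement, so the recovered area fraction matches
    the target to within half a pixel's worth of percent.
    """
    if not (0.0 <= target_macroporosity <= 100.0):
        raise SyntheticError(f"target {target_macroporosity!r} outside [0, 100]")
    h, w = zone_shape
    if h < 1 or w < 1:
        raise SyntheticError("zone must be at least 1×1")
    rng = np.random.default_rng(seed)
    total = np.ones((h, w), dtype=bool)
    area = h * w
    k = round(target_macroporosity / 100.0 * area)
    flat = np.zeros(area, dtype=bool)
    flat[rng.choice(area, size=k, replace=False)] = True
    return total, flat.reshape(h, w)
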