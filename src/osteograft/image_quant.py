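"""Profile roughness and macroporosity from binarized micrographs.

Granular bone substitutes are too wavy for stylus or laser profilometry, so
surface roughness is taken from electron micrographs instead: the image is
binarized, the outer envelope of the material is traced column by column
(a stylus-like first-hit profile), referenced to its mean plane, and the
unfiltered primary-profile parameters are computed:

    Pa = (1/n) Σ |y_i|            arithmetical mean deviation
    Pq = sqrt((1/n) Σ y_i²)       root-mean-square deviation
    Pt = Pp − Pv                  total height (max peak − max valley)

Macroporosity is an area fraction: the percentage of a zonal mask occupied
by cell-colonized space (soft tissue and marrow), pores above ~100 µm and
interparticle voids included by construction of the masks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "ImageQuantError",
    "DegenerateMaskError",
    "ShortEvaluationWarning",
    "CalibratedImage",
    "Profile",
    "RoughnessParams",
    "RoughnessSettings",
    "ImageSetResult",
    "binarize",
    "extract_profile",
    "roughness_params",
    "roughness_of_image_set",
    "macroporosity",
    "macroporosity_of_set",
]

#: Minimum lateral extent over which roughness parameters are trusted (µm).
DEFAULT_MIN_EVAL_LENGTH_UM = 40.0


class ImageQuantError(ValueError):
    """Base class for image-quantification failures."""


class DegenerateMaskError(ImageQuantError):
    """Binarization produced an all-material or all-background mask."""


class ShortEvaluationWarning(UserWarning):
    """The profile's evaluation length is below the configured minimum."""


@dataclass(frozen=True)
class CalibratedImage:
    """A grayscale image with isotropic pixel size in µm (row 0 = top)."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ImageQuantError("image must be 2-D and at least 2×2 pixels")
        if not (self.pixel_size_um > 0):
            raise ImageQuantError(f"pixel_size_um must be > 0, got {self.pixel_size_um!r}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "pixel_size_um", float(self.pixel_size_um))


@dataclass(frozen=True)
class Profile:
    """A calibrated 1-D surface-height sequence referenced to its mean plane.

    Heights are in µm, positive outward from the material; ``gap_flag`` is
    set when scan columns without material were dropped.
    """

    heights: np.ndarray
    spacing_um: float
    gap_flag: bool = False

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 1 or h.size < 2:
            raise ImageQuantError("profile needs at least 2 points")
        if not (self.spacing_um > 0):
            raise ImageQuantError("profile spacing must be > 0")
        if abs(h.mean()) > 1e-9 * max(1.0, float(np.abs(h).max())):
            raise ImageQuantError("profile heights must be mean-centered")
        object.__setattr__(self, "heights", h)

    @property
    def n_points(self) -> int:
        return int(self.heights.size)

    @property
    def evaluation_length_um(self) -> float:
        return (self.n_points - 1) * self.spacing_um


@dataclass(frozen=True)
class RoughnessParams:
    """Primary-profile parameters for one evaluation length (all µm)."""

    pa: float
    pq: float
    pt: float
    pp: float
    pv: float


@dataclass(frozen=True)
class RoughnessSettings:
    """Pipeline settings for image-set roughness analysis."""

    method: str = "otsu"
    threshold: float | None = None
    direction: str = "top"
    detrend: str = "none"
    min_eval_length_um: float = DEFAULT_MIN_EVAL_LENGTH_UM


@dataclass(frozen=True)
class ImageSetResult:
    """Per-image parameters plus mean ± SD aggregate over an image set."""

    per_image: tuple[RoughnessParams | None, ...]
    errors: tuple[str | None, ...]
    mean: RoughnessParams
    sd: RoughnessParams | None


def binarize(image: CalibratedImage, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Threshold a calibrated grayscale image into a material mask.

    ``otsu`` picks the threshold that separates the bimodal gray-level
    histogram; ``fixed`` uses the supplied gray level. Material is the
    brighter phase (backscatter contrast: mineral > resin).
    """
    px = np.asarray(image.pixels, dtype=float)
    if method == "otsu":
        if px.min() == px.max():
            raise DegenerateMaskError("constant image cannot be thresholded")
        thr = threshold_otsu(px)
    elif method == "fixed":
        if threshold is None:
            raise ImageQuantError("fixed method requires a threshold")
        thr = float(threshold)
    else:
        raise ImageQuantError(f"unknown binarization method {method!r}")
    mask = px > thr
    frac = mask.mean()
    if frac in (0.0, 1.0):
        raise DegenerateMaskError(
            f"degenerate mask: material fraction {frac:.0%} at threshold {thr}"
        )
    return mask


_DIRECTIONS = ("top", "bottom", "left", "right")


def extract_profile(
    mask: np.ndarray,
    pixel_size_um: float,
    direction: str = "top",
    detrend: str = "none",
) -> Profile:
    """Trace the outer material envelope seen from one image edge.

    For each scan column (or row, for lateral directions) the distance from
    the scan edge to the first material pixel is recorded — the profile a
    stylus approaching from that edge would feel. Surface-opening pores
    deeper than the first hit are invisible by construction. Columns without
    material are dropped and flagged. Heights are converted to µm with the
    outward-positive sign convention and referenced to the mean plane.

    ``detrend`` removes nominal form before referencing:

    - ``"none"``   — mean-plane subtraction only (default);
    - ``"linear"`` — least-squares line removal (tilt);
    - ``"circle"`` — least-squares circular-arc removal, for granule
      silhouettes whose nominal form is a circle.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ImageQuantError("mask must be 2-D")
    if not (pixel_size_um > 0):
        raise ImageQuantError("pixel_size_um must be > 0")
    if direction not in _DIRECTIONS:
        raise ImageQuantError(f"direction must be one of {_DIRECTIONS}")
    if detrend not in ("none", "linear", "circle"):
        raise ImageQuantError(f"unknown detrend mode {detrend!r}")

    if direction == "bottom":
        mask = mask[::-1, :]
    elif direction == "left":
        mask = mask.T
    elif direction == "right":
        mask = mask[:, ::-1].T
    # now always scanning from the top edge downwards
    has_material = mask.any(axis=0)
    gap = not bool(has_material.all())
    if has_material.sum() < 2:
        raise ImageQuantError("fewer than 2 scan columns contain material")
    depths = np.argmax(mask, axis=0).astype(float)[has_material]
    x = np.flatnonzero(has_material).astype(float) * pixel_size_um
    y = -depths * pixel_size_um  # outward (toward scan edge) is positive
    x = x - x.mean()
    y = y - y.mean()
    if detrend == "linear":
        y = y - np.polyval(np.polyfit(x, y, 1), x)
    elif detrend == "circle":
        y = _remove_circular_form(x, y)
    y = y - y.mean()
    return Profile(heights=y, spacing_um=float(pixel_size_um), gap_flag=gap)


def _remove_circular_form(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Subtract the least-squares circle (Kåsa fit) from an envelope profile."""
    A = np.column_stack([x, y, np.ones_like(x)])
    b = -(x**2 + y**2)
    try:
        (d, e, f), *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - lstsq rarely fails
        raise ImageQuantError(f"circular form fit failed: {exc}") from exc
    cx, cy = -d / 2.0, -e / 2.0
    r2 = cx * cx + cy * cy - f
    if r2 <= 0:
        raise ImageQuantError("circular form fit degenerate (non-positive radius)")
    return np.hypot(x - cx, y - cy) - math.sqrt(r2)


def roughness_params(
    profile: Profile,
    min_eval_length_um: float = DEFAULT_MIN_EVAL_LENGTH_UM,
) -> RoughnessParams:
    """Compute Pa, Pq, Pt (with Pp, Pv) from a mean-referenced profile.

    Issues :class:`ShortEvaluationWarning` when the evaluation length is
    below ``min_eval_length_um`` — a quality flag, not a failure.
    """
    y = profile.heights
    if profile.evaluation_length_um < min_eval_length_um:
        warnings.warn(
            f"evaluation length {profile.evaluation_length_um:.1f} µm below the "
            f"{min_eval_length_um:g} µm minimum",
            ShortEvaluationWarning,
            stacklevel=2,
        )
    pp = float(y.max())
    pv = float(y.min())
    return RoughnessParams(
        pa=float(np.mean(np.abs(y))),
        pq=float(np.sqrt(np.mean(y**2))),
        pt=pp - pv,
        pp=pp,
        pv=pv,
    )


def roughness_of_image_set(
    images: Sequence[CalibratedImage],
    settings: RoughnessSettings = RoughnessSettings(),
) -> ImageSetResult:
    """Binarize, trace and parametrize each image; aggregate mean ± SD.

    Per-image failures are collected (with the parameters slot left empty)
    and only fatal if every image fails. SD uses the n−1 denominator and is
    absent for a single usable image.
    """
    images = list(images)
    if not images:
        raise ImageQuantError("at least one image is required")
    per: list[RoughnessParams | None] = []
    errs: list[str | None] = []
    for img in images:
        try:
            mask = binarize(img, method=settings.method, threshold=settings.threshold)
            prof = extract_profile(
                mask, img.pixel_size_um, direction=settings.direction,
                detrend=settings.detrend,
            )
            per.append(roughness_params(prof, settings.min_eval_length_um))
            errs.append(None)
        except ImageQuantError as exc:
            per.append(None)
            errs.append(str(exc))
    ok = [p for p in per if p is not None]
    if not ok:
        raise ImageQuantError(f"all {len(images)} images failed: {errs}")
    stack = np.array([[p.pa, p.pq, p.pt, p.pp, p.pv] for p in ok])
    mean = RoughnessParams(*(float(v) for v in stack.mean(axis=0)))
    sd = None
    if len(ok) > 1:
        sd = RoughnessParams(*(float(v) for v in stack.std(axis=0, ddof=1)))
    return ImageSetResult(per_image=tuple(per), errors=tuple(errs), mean=mean, sd=sd)


def macroporosity(total_zone: np.ndarray, colonized: np.ndarray) -> float:
    """Colonized-area fraction of a zonal mask, in percent.

    ``colonized`` must be a subset of ``total_zone``; the result is
    100 · |colonized| / |total_zone| ∈ [0, 100].
    """
    total_zone = np.asarray(total_zone).astype(bool)
    colonized = np.asarray(colonized).astype(bool)
    if total_zone.shape != colonized.shape:
        raise ImageQuantError(
            f"mask shapes differ: {total_zone.shape} vs {colonized.shape}"
        )
    area = int(total_zone.sum())
    if area == 0:
        raise ImageQuantError("total zone is empty")
    if bool(np.any(colonized & ~total_zone)):
        raise ImageQuantError("colonized pixels outside the total zone")
    return 100.0 * float(colonized.sum()) / area


def macroporosity_of_set(
    pairs: Iterable[tuple[np.ndarray, np.ndarray]],
) -> tuple[float, float | None]:
    """Mean ± SD macroporosity over (total_zone, colonized) mask pairs."""
    values = [macroporosity(t, c) for t, c in pairs]
    if not values:
        raise ImageQuantError("at least one mask pair is required")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else None
    return mean, sd
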