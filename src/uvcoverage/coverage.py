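"""Baseline-calibrated segmentation of UV photographs into covered/uncovered.

On a UV-reflectance photograph, a UV-absorbing product (sunscreen or SPF
moisturiser) darkens the skin it covers.  Each participant supplies a
bare-skin *baseline* image from which a personal intensity threshold is
calibrated (``mu - k*sigma`` over the face region); pixels of the
post-application image darker than the threshold are classed *covered*.
Per-region percent-missed metrics and the binary medial-canthus outcome
are computed from the resulting binary coverage map.

Per-participant calibration, rather than one global threshold, is what
makes the segmentation robust across skin tones (Fitzpatrick types I-IV
have very different baseline intensities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import color, morphology

__all__ = [
    "UVImage",
    "ThresholdCalibration",
    "CoverageMap",
    "CoverageReport",
    "read_image",
    "write_mask_png",
    "calibrate_threshold",
    "working_channel",
    "segment_coverage",
    "percent_missed",
    "classify_medial_canthus",
    "mean_region_intensity",
    "darkness_change",
    "baseline_contamination_flag",
]


@dataclass
class UVImage:
    """A UV-camera photograph with acquisition metadata.

    ``pixels`` is ``(H, W)`` grayscale or ``(H, W, 3)`` RGB, 8-bit range
    [0, 255].  ``condition`` is one of ``baseline``, ``sunscreen``,
    ``moisturiser``.
    """

    pixels: np.ndarray
    channel_mode: str = "gray"
    participant: str = ""
    visit: int = 0
    condition: str = "baseline"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            self.channel_mode = "gray"
        elif px.ndim == 3 and px.shape[2] == 3:
            self.channel_mode = "rgb"
        else:
            raise ValueError(f"unsupported image shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")
        self.pixels = px

    @property
    def dims(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def read_image(path: str | Path, **meta) -> UVImage:
    """Load a PNG/TIFF image as a :class:`UVImage` (8-bit gray or RGB)."""
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA"):
            arr = np.asarray(im.convert("RGB"))
        else:
            arr = np.asarray(im.convert("L"))
    return UVImage(arr.astype(np.uint8), **meta)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a 0/255 grayscale PNG."""
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)


@dataclass(frozen=True)
class ThresholdCalibration:
    """Per-participant covered/uncovered decision threshold.

    ``threshold = max(mu_base - k * sigma_base, floor)`` where ``mu_base``
    and ``sigma_base`` are taken over the baseline face pixels.  With the
    default ``k = 3`` the expected false-covered rate on bare skin with
    Gaussian noise is the normal tail P(Z < -3) ~ 0.13%.
    """

    mu_base: float
    sigma_base: float
    k: float
    threshold: float
    floor: float
    source: str = ""


@dataclass
class CoverageMap:
    """Per-pixel binary classification: covered (True) / uncovered (False)."""

    mask: np.ndarray
    calibration: ThresholdCalibration
    source: str = ""


@dataclass
class CoverageReport:
    """Per-region percent-missed metrics for one participant-visit."""

    participant: str
    visit: int
    formulation: str
    percent_missed: dict[str, float] = field(default_factory=dict)
    canthus_outcome: dict[str, str] = field(default_factory=dict)
    darkness_change: float = float("nan")
    mu_base: float = float("nan")


def working_channel(img: UVImage, saturation_band: tuple[float, float] | None = None
                    ) -> np.ndarray:
    """Reduce an image to the single intensity channel used for thresholding.

    Grayscale images pass through unchanged.  RGB images are converted to
    HSV (standard hexcone transform) and the value channel is returned on
    the [0, 255] scale.  If ``saturation_band=(lo, hi)`` is given, pixels
    whose saturation falls outside the band are pushed to intensity 255 so
    the covered-iff-dark rule ignores them.
    """
    px = img.pixels
    if img.channel_mode == "gray":
        return px.astype(float)
    hsv = color.rgb2hsv(px.astype(float) / 255.0)
    value = hsv[:, :, 2] * 255.0
    if saturation_band is not None:
        lo, hi = saturation_band
        sat = hsv[:, :, 1]
        value = np.where((sat >= lo) & (sat <= hi), value, 255.0)
    return value


def calibrate_threshold(baseline: UVImage, face: np.ndarray,
                        k: float = 3.0, floor: float = 0.0) -> ThresholdCalibration:
    """Calibrate the covered/uncovered threshold from a bare-skin image."""
    if not np.any(face):
        raise ValueError("face mask is empty; cannot calibrate threshold")
    chan = working_channel(baseline)
    vals = chan[face]
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=0))
    threshold = max(mu - k * sigma, floor)
    return ThresholdCalibration(
        mu_base=mu, sigma_base=sigma, k=k, threshold=threshold, floor=floor,
        source=f"{baseline.participant}/visit{baseline.visit}",
    )


def baseline_contamination_flag(baseline: UVImage, face: np.ndarray,
                                provisional_threshold: float = 100.0,
                                max_fraction: float = 0.05) -> bool:
    """Flag a baseline image that appears to already carry product.

    Participants sometimes arrive wearing an SPF product; calibrating on
    such a baseline would mask real coverage.  Returns True when the
    fraction of face pixels below a provisional global threshold exceeds
    ``max_fraction`` — the run then requires an operator override.
    """
    chan = working_channel(baseline)
    frac = float((chan[face] < provisional_threshold).mean())
    return frac > max_fraction


def segment_coverage(img: UVImage, cal: ThresholdCalibration,
                     min_blob: int = 5, close_radius: int = 1,
                     saturation_band: tuple[float, float] | None = None
                     ) -> CoverageMap:
    """Binarize a post-application image into covered/uncovered pixels.

    A pixel is covered iff its working-channel intensity is strictly below
    the calibrated threshold.  Morphological closing (radius
    ``close_radius``) then fills pinhole gaps in the covered set, and
    covered components smaller than ``min_blob`` pixels are dropped as
    noise.  Either cleanup step is disabled by passing 0.
    """
    chan = working_channel(img, saturation_band=saturation_band)
    covered = chan < cal.threshold
    if close_radius > 0:
        covered = morphology.closing(covered, morphology.disk(close_radius))
    if min_blob > 0:
        # drop covered components strictly smaller than min_blob pixels
        covered = morphology.remove_small_objects(covered, max_size=min_blob - 1)
    return CoverageMap(mask=covered, calibration=cal,
                       source=f"{img.participant}/visit{img.visit}/{img.condition}")


def percent_missed(cov: CoverageMap, region: np.ndarray) -> float:
    """Percent of region pixels left uncovered: ``100 * uncovered / total``."""
    n = int(region.sum())
    if n == 0:
        raise ValueError("region mask is empty")
    uncovered = int((~cov.mask[region]).sum())
    return 100.0 * uncovered / n


def classify_medial_canthus(cov: CoverageMap, canthus: np.ndarray,
                            tau: float = 0.95) -> str:
    """Score a medial-canthus box as ``covered`` or ``missed``.

    ``covered`` iff the covered fraction within the box is >= ``tau``
    (boundary inclusive); the default 0.95 reads "fully covered" with a
    small tolerance for pixel noise.
    """
    n = int(canthus.sum())
    if n == 0:
        raise ValueError("canthus mask is empty")
    frac = float(cov.mask[canthus].mean())
    return "covered" if frac >= tau else "missed"


def mean_region_intensity(img: UVImage, region: np.ndarray) -> float:
    """Arithmetic mean of the working channel over a region."""
    if not np.any(region):
        raise ValueError("region mask is empty")
    return float(working_channel(img)[region].mean())


def darkness_change(baseline: UVImage, applied: UVImage,
                    face: np.ndarray) -> tuple[float, float]:
    """Mean face darkening after application, in grey levels.

    Returns ``(change, mu_base)`` where ``change`` = mean baseline face
    intensity minus mean applied face intensity (positive = darker after
    application) and ``mu_base`` is the baseline mean, reported as the
    skin-tone covariate.
    """
    if baseline.dims != applied.dims:
        raise ValueError(
            f"image dims differ: {baseline.dims} vs {applied.dims}"
        )
    mu_base = mean_region_intensity(baseline, face)
    mu_app = mean_region_intensity(applied, face)
    return mu_base - mu_app, mu_base
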