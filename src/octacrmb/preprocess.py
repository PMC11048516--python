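"""Angiogram loading, digital-vasculature-map extraction, ETDRS regions, binarization.

An en-face OCTA scan is handled as a :class:`DVMImage`: a square grayscale
raster with a physical scale (mm per pixel) and a fovea-center coordinate.
The ETDRS macular grid partitions the scan into a central 1-mm-diameter
fovea circle and the surrounding 1–3 mm parafoveal annulus; all downstream
perfusion and geometry metrics are reported over these regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from scipy.ndimage import gaussian_filter, uniform_filter


class GeometryError(ValueError):
    """Crop or scan geometry violates the square-scan contract."""


class DegenerateImageError(ValueError):
    """Image content cannot support the requested operation (e.g. constant)."""


class DegenerateSegmentationError(ValueError):
    """Binarization produced an empty or full vessel mask."""


@dataclass(frozen=True)
class DVMImage:
    """Digital vasculature map: normalized en-face angiogram with physical scale.

    Parameters
    ----------
    pixels
        2-D float array of intensities in [0, 1].
    width_mm, height_mm
        Physical extent of the scan (default 3 x 3 mm macular scan).
    center_rc
        Fovea center in 0-based (row, col) pixel coordinates. Defaults to
        the geometric image center, since the device centers the scan on
        the fovea.
    """

    pixels: np.ndarray
    width_mm: float = 3.0
    height_mm: float = 3.0
    center_rc: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise GeometryError(f"expected 2-D image, got shape {px.shape}")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("DVM intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)
        if self.center_rc is None:
            r, c = (px.shape[0] - 1) / 2.0, (px.shape[1] - 1) / 2.0
            object.__setattr__(self, "center_rc", (r, c))
        cr, cc = self.center_rc
        if not (0 <= cr < px.shape[0] and 0 <= cc < px.shape[1]):
            raise GeometryError(f"center_rc {self.center_rc} outside image bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_size_mm(self) -> float:
        """Physical size of one pixel (mm), from the scan width."""
        return self.width_mm / self.pixels.shape[1]


@dataclass(frozen=True)
class RegionMasks:
    """ETDRS fovea / parafovea masks aligned to a DVMImage."""

    fovea_mask: np.ndarray
    parafovea_mask: np.ndarray
    full_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.logical_and(self.fovea_mask, self.parafovea_mask).any():
            raise ValueError("fovea and parafovea masks overlap")


@dataclass(frozen=True)
class BinaryVesselMap:
    """Boolean vessel map plus the threshold provenance that produced it."""

    pixels: np.ndarray
    source: DVMImage
    threshold_used: float
    method: str = "global_otsu"

    def __post_init__(self) -> None:
        if self.pixels.shape != self.source.shape:
            raise GeometryError("binary map shape differs from source DVM")

    @property
    def vessel_fraction(self) -> float:
        return float(self.pixels.mean())


def load_angiogram(path: str) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG/TIFF as a float array (raw counts)."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) exports
        arr = arr[..., :3].mean(axis=-1)
    return np.asarray(arr, dtype=float)


def extract_dvm(
    report_image: np.ndarray,
    crop_box: tuple[int, int, int, int] | None = None,
    width_mm: float = 3.0,
    center_rc: tuple[float, float] | None = None,
) -> DVMImage:
    """Extract and min–max normalize the DVM from a device-report raster.

    Parameters
    ----------
    report_image
        Grayscale raster (any intensity range).
    crop_box
        ``(top, left, height, width)`` in pixel coordinates; the crop must be
        square within one pixel. ``None`` takes the full frame.
    width_mm
        Physical width the crop covers (3.0 for a 3 x 3 mm macular scan).
    center_rc
        Optional fovea-center override in crop coordinates; default is the
        crop center.
    """
    img = np.asarray(report_image, dtype=float)
    if img.ndim != 2:
        raise GeometryError("report image must be 2-D grayscale")
    if crop_box is None:
        crop_box = (0, 0, img.shape[0], img.shape[1])
    top, left, h, w = crop_box
    if top < 0 or left < 0 or top + h > img.shape[0] or left + w > img.shape[1]:
        raise GeometryError(f"crop_box {crop_box} exceeds raster {img.shape}")
    if abs(h - w) > 1:
        raise GeometryError(f"crop {h}x{w} is not square within 1 pixel")
    block = img[top : top + h, left : left + w]
    lo, hi = block.min(), block.max()
    if hi - lo <= 0:
        raise DegenerateImageError("constant-intensity crop: no vasculature signal")
    norm = (block - lo) / (hi - lo)
    return DVMImage(norm, width_mm=width_mm, height_mm=width_mm * h / w,
                    center_rc=center_rc)


def _radial_distance_mm(dvm: DVMImage) -> np.ndarray:
    rr, cc = np.indices(dvm.shape)
    cr, cc0 = dvm.center_rc
    return np.hypot(rr - cr, cc - cc0) * dvm.pixel_size_mm


def make_etdrs_masks(
    dvm: DVMImage, fovea_radius_mm: float = 0.5, parafovea_radius_mm: float = 1.5
) -> RegionMasks:
    """ETDRS regions: fovea = central 1-mm circle, parafovea = 1–3 mm annulus.

    Distances are Euclidean, in physical units from pixel centers.
    """
    if dvm.pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be positive")
    d = _radial_distance_mm(dvm)
    fovea = d < fovea_radius_mm
    parafovea = (d >= fovea_radius_mm) & (d < parafovea_radius_mm)
    return RegionMasks(fovea, parafovea, np.ones(dvm.shape, dtype=bool))


def binarize(
    dvm: DVMImage,
    method: str = "local_mean",
    local_window_mm: float = 0.2,
    local_offset_frac: float = 0.05,
    smooth_sigma_px: float = 0.5,
    min_object_px: int = 15,
) -> BinaryVesselMap:
    """Threshold a DVM into a vessel / background map.

    ``local_mean`` (default) lightly denoises the image (Gaussian,
    ``smooth_sigma_px``), then marks a pixel as vessel when it exceeds the
    mean intensity in a window of ``local_window_mm`` by an offset expressed
    as a fraction of the image intensity range; connected components below
    ``min_object_px`` are dropped as speckle. The positive offset keeps
    uniform background regions (where pixel ~ local mean) out of the mask;
    the local window makes the method robust to the slow intensity falloff
    and vignetting of OCTA exports, and the whole chain is invariant to
    affine intensity rescaling. ``global_otsu`` applies a single Otsu
    threshold to the raw image (no smoothing, no speckle removal).
    """
    px = dvm.pixels
    if px.max() - px.min() <= 0:
        raise DegenerateImageError("uniform image cannot be binarized")
    if method == "global_otsu":
        thr = float(threshold_otsu(px))
        mask = px > thr
    elif method == "local_mean":
        sm = gaussian_filter(px, smooth_sigma_px) if smooth_sigma_px > 0 else px
        win = max(3, int(round(local_window_mm / dvm.pixel_size_mm)) | 1)
        local = uniform_filter(sm, size=win, mode="reflect")
        offset = local_offset_frac * (px.max() - px.min())
        mask = sm > local + offset
        if min_object_px > 0:
            mask = remove_small_objects(mask, max_size=min_object_px - 1,
                                        connectivity=2)
        thr = float(np.mean(local) + offset)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    if not mask.any() or mask.all():
        raise DegenerateSegmentationError(
            f"{method} produced a {'full' if mask.all() else 'empty'} vessel mask "
            f"(threshold {thr:.4f}); check input contrast"
        )
    return BinaryVesselMap(mask, source=dvm, threshold_used=thr, method=method)
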