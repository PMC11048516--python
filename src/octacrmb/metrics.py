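"""The twelve computational retinal microvascular biomarkers (CRMBs).

Per eye, from a superficial (SCP) and deep (DCP) en-face angiogram pair:

========  ====================================================================
PDL       perfusion density of large vessels, parafovea (mean signal, [0,1])
PDCS      perfusion density of superficial capillaries, parafovea
PDCD      perfusion density of deep capillaries, parafovea
MVT       macular vessel tortuosity (length-weighted arc/chord, >= 1)
MVDiam    macular vessel diameter, µm (mean centerline caliber, large vessels)
MVDisp    macular vessel dispersion ([0,1]): degree to which parafoveal
          vessels deviate from radial (centripetal) orientation
FDS/FDD   box-counting fractal dimension of the binarized SCP / DCP
FAS/FAD   foveal avascular zone (FAZ) area, mm², SCP / DCP
FACS/FACD FAZ acircularity (perimeter over equal-area-circle perimeter, >= 1)
========  ====================================================================

The FAZ is demarcated by casting rays from the fovea center and connecting,
per direction, the vessel-positive pixel nearest the center into a closed
polygon. MVDisp measures centripetalism: for each skeleton pixel the local
tangent (PCA over a small neighborhood) is compared with the radial
direction; MVDisp is the mean of 1 - |cos θ| over the parafoveal skeleton,
0 when every vessel runs radially and -> 1 when all run tangentially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.spatial import cKDTree

from .preprocess import (
    BinaryVesselMap,
    DVMImage,
    RegionMasks,
    binarize,
    make_etdrs_masks,
)
from .separation import (
    LargeVesselMask,
    SkeletonMap,
    capillary_mask,
    delineate_large_vessels,
    skeletonize_map,
)

CRMB_NAMES = [
    "PDL", "PDCS", "PDCD", "MVT", "MVDiam", "MVDisp",
    "FDS", "FDD", "FAS", "FAD", "FACS", "FACD",
]


class UndefinedRegionError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


@dataclass
class CRMBRecord:
    """One eye's twelve biomarkers. Missing metrics are NaN."""

    PDL: float
    PDCS: float
    PDCD: float
    MVT: float
    MVDiam: float
    MVDisp: float
    FDS: float
    FDD: float
    FAS: float
    FAD: float
    FACS: float
    FACD: float
    provenance: dict = field(default_factory=dict, repr=False)

    def as_dict(self) -> dict[str, float]:
        d = asdict(self)
        d.pop("provenance")
        return d


@dataclass
class FAZPolygon:
    """Ray-cast FAZ demarcation: one vertex per cast ray, in angular order."""

    vertices: np.ndarray  # (n_rays, 2) float (row, col)
    area_mm2: float
    perimeter_mm: float
    acircularity: float
    open_rays: int = 0  # rays that hit the image border without a vessel


def perfusion_density(
    dvm: DVMImage, compartment_mask: np.ndarray, region_mask: np.ndarray
) -> float:
    """Mean signal intensity of a vascular compartment over a region.

    Sum of DVM intensities over compartment ∩ region, divided by the region
    pixel count — the grayscale (flow-weighted) perfusion density.
    """
    n_region = int(region_mask.sum())
    if n_region == 0:
        raise UndefinedRegionError("empty analysis region")
    sel = compartment_mask & region_mask
    return float(dvm.pixels[sel].sum() / n_region)


def box_counting_fd(binary: np.ndarray, box_sizes: list[int] | None = None) -> float:
    """Box-counting fractal dimension of a binary image.

    N(s) counts s x s grid boxes (grid anchored at the image origin)
    containing at least one foreground pixel; FD is the OLS slope of
    log N(s) against log(1/s). Default box sizes are dyadic from 2 to a
    quarter of the image side.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise DegenerateFitError("empty image has no box-counting dimension")
    n = max(binary.shape)
    if box_sizes is None:
        box_sizes = []
        s = 2
        while s <= n // 4:
            box_sizes.append(s)
            s *= 2
    if len(box_sizes) < 2:
        raise DegenerateFitError("need at least 2 box sizes")
    counts = []
    for s in box_sizes:
        nr = math.ceil(binary.shape[0] / s)
        nc = math.ceil(binary.shape[1] / s)
        padded = np.zeros((nr * s, nc * s), dtype=bool)
        padded[: binary.shape[0], : binary.shape[1]] = binary
        blocks = padded.reshape(nr, s, nc, s).any(axis=(1, 3))
        counts.append(int(blocks.sum()))
    counts = np.array(counts, dtype=float)
    if len(np.unique(counts)) < 2:
        raise DegenerateFitError("box counts do not vary across scales")
    slope = np.polyfit(np.log(1.0 / np.asarray(box_sizes, float)), np.log(counts), 1)[0]
    return float(slope)


def _polyline_length(points: np.ndarray, step: int = 7) -> float:
    """Arc length of a pixel polyline, chord-summed every `step` points.

    Sub-sampling suppresses the systematic overestimate of 8-connected
    chain-code length on smooth curves.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    idx = list(range(0, len(pts), step))
    if idx[-1] != len(pts) - 1:
        idx.append(len(pts) - 1)
    sub = pts[idx]
    return float(np.sqrt(((np.diff(sub, axis=0)) ** 2).sum(axis=1)).sum())


def _clip_segment_to_region(seg: np.ndarray, region_mask: np.ndarray) -> list[np.ndarray]:
    inside = region_mask[seg[:, 0], seg[:, 1]]
    runs, start = [], None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append(seg[start:i])
            start = None
    if start is not None:
        runs.append(seg[start:])
    return [r for r in runs if len(r) >= 2]


def vessel_tortuosity(
    skeleton: SkeletonMap,
    region_mask: np.ndarray | None = None,
    min_chord_px: float = 10.0,
) -> float:
    """Macular vessel tortuosity: length-weighted mean arc/chord ratio.

    Each skeleton segment (clipped to the region) contributes arc length
    divided by the Euclidean distance between its endpoints; segments with
    chord below ``min_chord_px`` are excluded as too short to define a
    direction. Returns NaN when no segment qualifies.
    """
    ratios, weights = [], []
    for seg in skeleton.segments:
        pieces = (
            [seg] if region_mask is None else _clip_segment_to_region(seg, region_mask)
        )
        for piece in pieces:
            chord = float(np.hypot(*(piece[-1] - piece[0]).astype(float)))
            if chord < min_chord_px:
                continue
            arc = _polyline_length(piece)
            ratios.append(max(arc / chord, 1.0))
            weights.append(arc)
    if not ratios:
        return float("nan")
    return float(np.average(ratios, weights=weights))


def mean_vessel_diameter(
    skeleton: SkeletonMap, region_mask: np.ndarray | None = None
) -> float:
    """Mean local caliber (µm) over skeleton pixels inside the region."""
    if skeleton.local_diameter_um is None:
        raise ValueError("skeleton carries no local diameters")
    sel = skeleton.pixels if region_mask is None else (skeleton.pixels & region_mask)
    vals = skeleton.local_diameter_um[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def vessel_dispersion(
    skeleton: SkeletonMap,
    center_rc: tuple[float, float],
    region_mask: np.ndarray | None = None,
    neighborhood_px: float = 5.0,
    min_pixels: int = 20,
) -> float:
    """Macular vessel dispersion: mean deviation from radial orientation.

    For each qualifying skeleton pixel the local tangent is the principal
    PCA axis of skeleton pixels within ``neighborhood_px``; θ is the acute
    angle between tangent and the ray joining the pixel to the fovea
    center. MVDisp = mean(1 - |cos θ|): 0 for perfectly radial
    (centripetal) vessels, -> 1 for purely tangential ones; an isotropic
    orientation field gives 1 - 2/π ≈ 0.363.
    """
    coords = np.column_stack(np.nonzero(skeleton.pixels))
    if region_mask is not None and coords.size:
        keep = region_mask[coords[:, 0], coords[:, 1]]
    else:
        keep = np.ones(len(coords), dtype=bool)
    if coords.size == 0 or keep.sum() < min_pixels:
        return float("nan")
    tree = cKDTree(coords)
    center = np.asarray(center_rc, dtype=float)
    vals = []
    neighbor_lists = tree.query_ball_point(coords[keep], r=neighborhood_px)
    for p, nbr_idx in zip(coords[keep].astype(float), neighbor_lists):
        if len(nbr_idx) < 3:
            continue
        nbrs = coords[nbr_idx].astype(float)
        centered = nbrs - nbrs.mean(axis=0)
        cov = centered.T @ centered
        w, v = np.linalg.eigh(cov)
        tangent = v[:, -1]
        radial = p - center
        nr = np.linalg.norm(radial)
        if nr < 1e-9:
            continue
        cos_theta = abs(float(tangent @ radial)) / nr
        vals.append(1.0 - min(cos_theta, 1.0))
    if len(vals) < min_pixels:
        return float("nan")
    return float(np.mean(vals))


def _ray_first_hit(
    mask: np.ndarray, center: np.ndarray, d: np.ndarray
) -> tuple[float, bool]:
    """Exact grid traversal (Amanatides–Woo DDA) from center along d.

    Visits every pixel the ray crosses, so thin diagonal vessels cannot be
    skipped. Returns (t, hit): the ray parameter at which the ray enters the
    first vessel-positive pixel, or the parameter at which it leaves the
    image when no vessel is met.
    """
    h, w = mask.shape
    # shift so pixel (i, j) covers [i, i+1) x [j, j+1)
    x, y = center[0] + 0.5, center[1] + 0.5
    i, j = int(math.floor(x)), int(math.floor(y))
    if mask[i, j]:
        return 0.0, True
    step_i = 1 if d[0] > 0 else -1
    step_j = 1 if d[1] > 0 else -1
    t_max_i = ((i + (step_i > 0)) - x) / d[0] if abs(d[0]) > 1e-12 else math.inf
    t_max_j = ((j + (step_j > 0)) - y) / d[1] if abs(d[1]) > 1e-12 else math.inf
    t_delta_i = abs(1.0 / d[0]) if abs(d[0]) > 1e-12 else math.inf
    t_delta_j = abs(1.0 / d[1]) if abs(d[1]) > 1e-12 else math.inf
    t = 0.0
    while True:
        if t_max_i < t_max_j:
            t, t_max_i, i = t_max_i, t_max_i + t_delta_i, i + step_i
        else:
            t, t_max_j, j = t_max_j, t_max_j + t_delta_j, j + step_j
        if not (0 <= i < h and 0 <= j < w):
            return t, False
        if mask[i, j]:
            return t, True


def demarcate_faz(
    binary: BinaryVesselMap,
    center_rc: tuple[float, float] | None = None,
    n_rays: int = 360,
    smooth_deg: float = 9.0,
) -> FAZPolygon:
    """Demarcate the foveal avascular zone by radial ray casting.

    From the fovea center, ``n_rays`` equally spaced rays traverse the pixel
    grid exactly (every crossed pixel is tested); the entry point into the
    first vessel-positive pixel on each ray fixes the boundary radius for
    that direction. The radius profile r(θ) is smoothed with a circular
    moving average of width ``smooth_deg`` — single-pixel radial jitter
    between adjacent rays otherwise inflates the perimeter (and hence
    acircularity) without representing real FAZ shape. The smoothed radii
    form the polygon: area via the shoelace formula, perimeter as the edge
    length sum, acircularity = perimeter / (2·sqrt(π·area)) (>= 1 by the
    isoperimetric inequality).

    Rays that reach the image border without meeting a vessel place their
    vertex at the border and are counted in ``open_rays``.
    """
    if n_rays < 36:
        raise ValueError("n_rays must be at least 36")
    mask = binary.pixels
    h, w = mask.shape
    center = np.asarray(
        binary.source.center_rc if center_rc is None else center_rc, dtype=float
    )
    if not (0 <= center[0] < h and 0 <= center[1] < w):
        raise ValueError("fovea center outside the image")
    angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    radii = np.empty(n_rays)
    open_rays = 0
    for i, ang in enumerate(angles):
        d = np.array([math.sin(ang), math.cos(ang)])
        t, hit = _ray_first_hit(mask, center, d)
        if not hit:
            open_rays += 1
        radii[i] = t
    win = int(round(n_rays * smooth_deg / 360.0)) | 1
    if smooth_deg > 0 and win >= 3:
        kernel = np.ones(win) / win
        padded = np.concatenate([radii[-(win // 2):], radii, radii[: win // 2]])
        radii = np.convolve(padded, kernel, mode="valid")
    verts = center + radii[:, None] * np.column_stack(
        [np.sin(angles), np.cos(angles)]
    )
    px_mm = binary.source.pixel_size_mm
    closed = np.vstack([verts, verts[:1]])
    x, y = closed[:, 1], closed[:, 0]
    area_px2 = 0.5 * abs(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1]))
    perim_px = float(np.sqrt((np.diff(closed, axis=0) ** 2).sum(axis=1)).sum())
    area = float(area_px2) * px_mm**2
    perim = perim_px * px_mm
    acirc = perim / (2.0 * math.sqrt(math.pi * area)) if area > 0 else float("inf")
    return FAZPolygon(verts, area, perim, acirc, open_rays)


def compute_crmbs(
    scp: DVMImage,
    dcp: DVMImage,
    threshold_method: str = "local_mean",
    intensity_threshold: float | None = None,
    diameter_threshold_um: float = 25.0,
    n_rays: int = 360,
    fd_box_sizes: list[int] | None = None,
) -> CRMBRecord:
    """Run the full biomarker pipeline on an aligned SCP/DCP pair.

    Binarizes both layers, separates SCP large vessels from capillaries,
    skeletonizes, and evaluates all twelve CRMBs: perfusion densities over
    the parafovea, fractal dimensions over the full scan, tortuosity and
    diameter on the large-vessel skeleton, dispersion on the full SCP
    skeleton within the parafovea, and FAZ area/acircularity per layer.
    """
    if scp.shape != dcp.shape:
        raise ValueError("SCP and DCP images must share geometry")
    regions = make_etdrs_masks(scp)
    parafovea = regions.parafovea_mask

    bin_s = binarize(scp, method=threshold_method)
    bin_d = binarize(dcp, method=threshold_method)
    large = delineate_large_vessels(
        scp, bin_s, intensity_threshold, diameter_threshold_um
    )
    cap_s = capillary_mask(bin_s, large)

    skel_large = skeletonize_map(large.pixels, bin_s)
    skel_all = skeletonize_map(bin_s.pixels, bin_s)

    faz_s = demarcate_faz(bin_s, n_rays=n_rays)
    faz_d = demarcate_faz(bin_d, n_rays=n_rays)

    rec = CRMBRecord(
        PDL=perfusion_density(scp, large.pixels, parafovea),
        PDCS=perfusion_density(scp, cap_s, parafovea),
        PDCD=perfusion_density(dcp, bin_d.pixels, parafovea),
        MVT=vessel_tortuosity(skel_large, parafovea),
        MVDiam=mean_vessel_diameter(skel_large, parafovea),
        MVDisp=vessel_dispersion(skel_all, scp.center_rc, parafovea),
        FDS=box_counting_fd(bin_s.pixels, fd_box_sizes),
        FDD=box_counting_fd(bin_d.pixels, fd_box_sizes),
        FAS=faz_s.area_mm2,
        FAD=faz_d.area_mm2,
        FACS=faz_s.acircularity,
        FACD=faz_d.acircularity,
    )
    rec.provenance = {
        "threshold_method": threshold_method,
        "scp_threshold": bin_s.threshold_used,
        "dcp_threshold": bin_d.threshold_used,
        "intensity_threshold": large.intensity_threshold,
        "diameter_threshold_um": large.diameter_threshold_um,
        "n_rays": n_rays,
        "faz_open_rays_scp": faz_s.open_rays,
        "faz_open_rays_dcp": faz_d.open_rays,
    }
    return rec
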