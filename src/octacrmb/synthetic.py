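"""Ground-truthed synthetic OCTA angiograms and cohorts.

Emulates the macroscopic structure of a 3 x 3 mm macular en-face angiogram:
a central avascular zone (rendered as an area-preserving ellipse of
controllable radius and eccentricity), a handful of smooth radially
oriented large vessels of controllable caliber (superficial layer only), an
isotropic-to-oriented capillary mesh built from short strokes until a
target vessel-area fraction is reached, and additive Gaussian intensity
noise. Every sample carries the truth masks and parameters that produced
it, so segmentation and biomarker recovery can be scored exactly.

Cohort generation draws per-subject parameters from group-specific
distributions: the vein-occlusion (RVO) group gets a rarefied capillary
mesh, narrower and more meandering large vessels, a larger and more
eccentric avascular zone, and more tangentially oriented capillaries.
Visual acuity is generated from a stated linear model on the true
parameters — plumbing for recovery tests, not a claim about biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line
from skimage.morphology import disk
from scipy.ndimage import binary_dilation

from .preprocess import DVMImage
from .metrics import compute_crmbs, CRMB_NAMES


@dataclass(frozen=True)
class SyntheticParams:
    """Generative parameters for one SCP/DCP angiogram pair."""

    faz_radius_mm: float = 0.25       # equal-area radius of the avascular zone
    faz_eccentricity: float = 0.2     # 0 = circle; area is preserved
    faz_irregularity: float = 0.04    # rel. amplitude of low-order boundary lobes
    n_large_vessels: int = 5
    large_vessel_width_um: float = 50.0
    large_vessel_intensity: float = 0.95
    capillary_density: float = 0.40   # target vessel-area fraction
    capillary_width_um: float = 10.0
    capillary_intensity: float = 0.65
    tangential_fraction: float = 0.30  # share of non-radial capillary strokes
    vessel_wobble_mm: float = 0.04     # lateral meander amplitude of large vessels
    noise_sigma: float = 0.05
    background: float = 0.12
    dcp_faz_scale: float = 1.1         # deep-layer FAZ is typically larger
    image_px: int = 304
    width_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.faz_eccentricity < 1:
            raise ValueError("faz_eccentricity must lie in [0, 1)")
        if self.faz_radius_mm >= self.width_mm / 2:
            raise ValueError("faz_radius_mm must be below half the scan width")
        if self.capillary_density > 0.9:
            raise ValueError("capillary_density above 0.9 is unreachable")
        if self.large_vessel_width_um <= 0 or self.capillary_width_um <= 0:
            raise ValueError("vessel widths must be positive")


@dataclass
class SyntheticSample:
    scp: DVMImage
    dcp: DVMImage
    truth_scp_mask: np.ndarray
    truth_dcp_mask: np.ndarray
    truth_large_vessel_mask: np.ndarray
    params: SyntheticParams


def _faz_modes(rng: np.random.Generator, irregularity: float) -> np.ndarray:
    """Fourier coefficients (modes 3..6, cos/sin) of the boundary lobes."""
    if irregularity <= 0:
        return np.zeros((4, 2))
    return rng.normal(0.0, irregularity / 2.0, size=(4, 2))


def _faz_rho(theta: np.ndarray, modes: np.ndarray) -> np.ndarray:
    """Relative boundary radius 1 + lobe modulation at elliptical angle theta."""
    rho = np.ones_like(theta)
    for i, k in enumerate(range(3, 7)):
        rho += modes[i, 0] * np.cos(k * theta) + modes[i, 1] * np.sin(k * theta)
    return np.clip(rho, 0.3, 2.0)


def _faz_ellipse_mask(
    n: int, center: float, r_px: float, ecc: float, angle: float,
    modes: np.ndarray | None = None,
) -> np.ndarray:
    """Area-preserving ellipse (semi-axes r/(1-e²)^¼ and r·(1-e²)^¼) with
    optional low-order radial lobes shared with the terminal ring."""
    q = (1.0 - ecc**2) ** 0.25
    a, b = r_px / q, r_px * q
    rr, cc = np.indices((n, n)).astype(float)
    dr, dc = rr - center, cc - center
    u = dr * math.cos(angle) + dc * math.sin(angle)
    v = -dr * math.sin(angle) + dc * math.cos(angle)
    s = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    if modes is None or not modes.any():
        return s <= 1.0
    theta = np.arctan2(v / b, u / a)
    return s <= _faz_rho(theta, modes)


def _width_radius_px(width_um: float, um_per_px: float) -> int:
    return max(0, int(round((width_um / um_per_px - 1) / 2)))


def _draw_polyline(mask: np.ndarray, pts: np.ndarray) -> None:
    n = mask.shape[0]
    pts = np.clip(np.round(pts).astype(int), 0, n - 1)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True


def _terminal_ring(p: SyntheticParams, faz: np.ndarray, center: float,
                   r_px: float, ecc: float, angle: float,
                   modes: np.ndarray | None = None) -> np.ndarray:
    """Terminal capillary ring hugging the avascular-zone boundary.

    The perifoveal terminal arcade is the anatomical structure that bounds
    the FAZ; rendering it keeps ray-cast demarcation from leaking through
    gaps in the stroke mesh.
    """
    n = p.image_px
    um_per_px = p.width_mm / n * 1000.0
    q = (1.0 - ecc**2) ** 0.25
    a, b = r_px / q, r_px * q
    ts = np.linspace(0, 2 * math.pi, max(64, int(8 * r_px)))
    rho = _faz_rho(ts, modes) if modes is not None and modes.any() else 1.0
    u, v = rho * a * np.cos(ts), rho * b * np.sin(ts)
    rr = center + u * math.cos(angle) - v * math.sin(angle)
    cc = center + u * math.sin(angle) + v * math.cos(angle)
    ring = np.zeros((n, n), dtype=bool)
    _draw_polyline(ring, np.column_stack([rr, cc]))
    r = _width_radius_px(p.capillary_width_um, um_per_px)
    if r > 0:
        ring = binary_dilation(ring, structure=disk(r))
    return ring & ~faz


def _render_large_vessels(p: SyntheticParams, rng: np.random.Generator,
                          faz: np.ndarray) -> np.ndarray:
    n = p.image_px
    center = (n - 1) / 2.0
    px_mm = p.width_mm / n
    um_per_px = px_mm * 1000.0
    wobble_px = p.vessel_wobble_mm / px_mm
    thin = np.zeros((n, n), dtype=bool)
    base = rng.uniform(0, 2 * math.pi)
    for k in range(p.n_large_vessels):
        ang = base + 2 * math.pi * k / max(p.n_large_vessels, 1) + rng.normal(0, 0.15)
        d = np.array([math.sin(ang), math.cos(ang)])
        perp = np.array([d[1], -d[0]])
        t0 = p.faz_radius_mm / px_mm * 0.9
        t1 = n  # run past the border; clipped when drawn
        ts = np.linspace(t0, t1, 80)
        phase = rng.uniform(0, 2 * math.pi)
        lam = rng.uniform(0.3, 0.5) * n
        lateral = wobble_px * np.sin(2 * math.pi * ts / lam + phase)
        pts = center + ts[:, None] * d + lateral[:, None] * perp
        inside = (pts >= 0).all(axis=1) & (pts < n).all(axis=1)
        if inside.sum() >= 2:
            _draw_polyline(thin, pts[inside])
    r = _width_radius_px(p.large_vessel_width_um, um_per_px)
    wide = binary_dilation(thin, structure=disk(r)) if r > 0 else thin
    return wide & ~faz


def _render_capillaries(p: SyntheticParams, rng: np.random.Generator,
                        faz: np.ndarray, occupied: np.ndarray,
                        target_extra: float) -> np.ndarray:
    """Add oriented short strokes until total vessel fraction reaches target."""
    n = p.image_px
    center = (n - 1) / 2.0
    px_mm = p.width_mm / n
    um_per_px = px_mm * 1000.0
    r = _width_radius_px(p.capillary_width_um, um_per_px)
    struct = disk(r) if r > 0 else None
    cap = np.zeros((n, n), dtype=bool)
    target_px = target_extra * n * n
    stroke_len_px = (0.25 / px_mm)
    max_strokes = 60000
    batch = np.zeros((n, n), dtype=bool)
    for i in range(max_strokes):
        cr, cc = rng.uniform(0, n - 1, size=2)
        radial_ang = math.atan2(cr - center, cc - center)
        if rng.uniform() < p.tangential_fraction:
            ang = radial_ang + math.pi / 2
        else:
            ang = radial_ang
        ang += rng.normal(0, 0.25)
        length = stroke_len_px * rng.uniform(0.6, 1.4)
        d = np.array([math.sin(ang), math.cos(ang)])
        p0 = np.array([cr, cc]) - d * length / 2
        p1 = np.array([cr, cc]) + d * length / 2
        pts = np.clip(np.vstack([p0, p1]), 0, n - 1)
        _draw_polyline(batch, pts)
        if i % 200 == 199:
            grown = binary_dilation(batch, structure=struct) if struct is not None else batch
            cap |= grown & ~faz
            batch[:] = False
            if ((cap | occupied) & ~faz).sum() >= target_px:
                break
    if batch.any():
        grown = binary_dilation(batch, structure=struct) if struct is not None else batch
        cap |= grown & ~faz
    return cap


def _compose(p: SyntheticParams, rng: np.random.Generator,
             large: np.ndarray, cap: np.ndarray) -> np.ndarray:
    img = np.full((p.image_px, p.image_px), p.background)
    img[cap] = p.capillary_intensity
    img[large] = p.large_vessel_intensity
    img += rng.normal(0.0, p.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_sample(params: SyntheticParams) -> SyntheticSample:
    """Render one reproducible SCP/DCP pair with truth masks."""
    p = params
    n = p.image_px
    center = (n - 1) / 2.0
    px_mm = p.width_mm / n
    rng = np.random.default_rng(p.seed)
    ang_s = rng.uniform(0, math.pi)
    modes_s = _faz_modes(rng, p.faz_irregularity)
    faz_s = _faz_ellipse_mask(n, center, p.faz_radius_mm / px_mm,
                              p.faz_eccentricity, ang_s, modes_s)
    large = (
        _render_large_vessels(p, rng, faz_s)
        if p.n_large_vessels > 0
        else np.zeros((n, n), dtype=bool)
    )
    cap_s = (
        _render_capillaries(p, rng, faz_s, large, p.capillary_density)
        | _terminal_ring(p, faz_s, center, p.faz_radius_mm / px_mm,
                         p.faz_eccentricity, ang_s, modes_s)
        if p.capillary_density > 0
        else np.zeros((n, n), dtype=bool)
    )
    scp_mask = large | cap_s
    scp_img = _compose(p, rng, large, cap_s)

    ang_d = rng.uniform(0, math.pi)
    modes_d = _faz_modes(rng, p.faz_irregularity)
    faz_d = _faz_ellipse_mask(n, center, p.faz_radius_mm * p.dcp_faz_scale / px_mm,
                              p.faz_eccentricity, ang_d, modes_d)
    empty = np.zeros((n, n), dtype=bool)
    cap_d = (
        _render_capillaries(p, rng, faz_d, empty, p.capillary_density)
        | _terminal_ring(p, faz_d, center, p.faz_radius_mm * p.dcp_faz_scale / px_mm,
                         p.faz_eccentricity, ang_d, modes_d)
        if p.capillary_density > 0
        else empty
    )
    dcp_img = _compose(p, rng, empty, cap_d)

    return SyntheticSample(
        scp=DVMImage(scp_img, width_mm=p.width_mm),
        dcp=DVMImage(dcp_img, width_mm=p.width_mm),
        truth_scp_mask=scp_mask,
        truth_dcp_mask=cap_d,
        truth_large_vessel_mask=large,
        params=p,
    )


@dataclass(frozen=True)
class GroupEffect:
    """Additive shifts applied to the RVO group's generative parameters.

    Defaults encode the qualitative group differences expected in vein
    occlusion: rarefied capillaries, narrower and more meandering large
    vessels, a larger and more irregular avascular zone, and loss of radial
    capillary organization.
    """

    faz_radius_mm: float = 0.10
    faz_eccentricity: float = 0.25
    faz_irregularity: float = 0.15
    large_vessel_width_um: float = -10.0
    capillary_density: float = -0.10
    tangential_fraction: float = 0.30
    vessel_wobble_mm: float = 0.05

    @classmethod
    def none(cls) -> "GroupEffect":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


# BCVA generative model (decimal acuity): intercept + capillary + FAZ terms
BCVA_COEF = {"intercept": 0.20, "capillary_density": 2.2, "faz_radius_mm": -1.5,
             "noise_sd": 0.06}

_COMORBIDITY_P = {
    # (normal, RVO) prevalence used when sampling covariates
    "diabetes": (0.02, 0.05),
    "hypertension": (0.05, 0.35),
    "hyperlipidaemia": (0.03, 0.14),
    "atherosclerosis": (0.03, 0.26),
}


def _draw_params(rng: np.random.Generator, effect: GroupEffect | None,
                 image_px: int, seed: int) -> SyntheticParams:
    e = effect or GroupEffect.none()
    return SyntheticParams(
        faz_radius_mm=float(np.clip(rng.normal(0.25 + e.faz_radius_mm, 0.025), 0.12, 0.6)),
        faz_eccentricity=float(np.clip(rng.normal(0.2 + e.faz_eccentricity, 0.05), 0.0, 0.85)),
        faz_irregularity=float(np.clip(rng.normal(0.04 + e.faz_irregularity, 0.01), 0.0, 0.3)),
        n_large_vessels=5,
        large_vessel_width_um=float(np.clip(rng.normal(50.0 + e.large_vessel_width_um, 3.0), 20.0, 90.0)),
        capillary_density=float(np.clip(rng.normal(0.40 + e.capillary_density, 0.025), 0.08, 0.6)),
        tangential_fraction=float(np.clip(rng.normal(0.30 + e.tangential_fraction, 0.05), 0.0, 1.0)),
        vessel_wobble_mm=float(np.clip(rng.normal(0.04 + e.vessel_wobble_mm, 0.008), 0.0, 0.2)),
        image_px=image_px,
        seed=seed,
    )


def generate_cohort(
    n_normal: int,
    n_rvo: int,
    effect: GroupEffect | None = None,
    seed: int = 0,
    image_px: int = 304,
    extract: bool = True,
    keep_images: bool = False,
    **crmb_kwargs,
):
    """Simulate a two-group cohort and (optionally) extract CRMBs per eye.

    Returns a per-subject DataFrame with group label, clinical covariates, a
    BCVA generated from a linear model on the true parameters, the true
    generative parameters (``true_*`` columns), and — when ``extract`` is
    true — the twelve extracted biomarkers. With ``keep_images`` the
    rendered :class:`SyntheticSample` list is returned alongside.
    """
    if n_normal < 2 or n_rvo < 2:
        raise ValueError("need at least 2 subjects per group")
    effect = GroupEffect() if effect is None else effect
    master = np.random.default_rng(seed)
    rows, samples = [], []
    for i in range(n_normal + n_rvo):
        is_rvo = i >= n_normal
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        p = _draw_params(rng, effect if is_rvo else None, image_px,
                         seed=int(rng.integers(0, 2**31 - 1)))
        bcva = (
            BCVA_COEF["intercept"]
            + BCVA_COEF["capillary_density"] * p.capillary_density
            + BCVA_COEF["faz_radius_mm"] * p.faz_radius_mm
            + rng.normal(0, BCVA_COEF["noise_sd"])
        )
        row = {
            "id": f"S{i:03d}",
            "group": "RVO" if is_rvo else "normal",
            "eye": "right" if rng.uniform() < 0.5 else "left",
            "age": float(np.clip(rng.normal(55 if is_rvo else 45, 14), 18, 90)),
            "sex": "men" if rng.uniform() < 0.5 else "women",
            "bcva_initial": float(np.clip(bcva, 0.05, 1.5)),
        }
        for name, (p0, p1) in _COMORBIDITY_P.items():
            row[name] = bool(rng.uniform() < (p1 if is_rvo else p0))
        for k, v in asdict(p).items():
            if k not in ("image_px", "seed", "width_mm"):
                row[f"true_{k}"] = v
        if extract:
            sample = generate_sample(p)
            rec = compute_crmbs(sample.scp, sample.dcp, **crmb_kwargs)
            row.update(rec.as_dict())
            if keep_images:
                samples.append(sample)
        rows.append(row)
    df = pd.DataFrame(rows)
    if keep_images:
        return df, samples
    return df
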