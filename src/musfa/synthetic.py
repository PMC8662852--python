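"""Synthetic calibrated B-mode muscle phantoms and study cohorts.

Clinical hamstring images cannot be redistributed, so this module generates
stand-ins with known ground truth:

* fully developed speckle — a complex white scatterer field convolved with a
  separable point-spread function (Gaussian-modulated cosine axially,
  Gaussian laterally), envelope-detected and log-compressed to 8 bits;
* quasi-periodic hyperechoic banding emulating the perimysial pattern of
  longitudinal muscle images, as a raised-cosine multiplicative grating at a
  controllable spacing (~1.0–1.5 mm in healthy muscle);
* focal injury: inside an "edema" polygon the banding is attenuated and
  its spacing widened (fluid pushing fascicle bundles apart) while
  broadband noise is elevated — the two mechanisms by which acute strain
  injury lowers Mmax% and PSFR;
* whole cohorts whose per-athlete region parameters are drawn around
  configurable group means/SDs, with a small pilot grid calibrating the
  band amplitude needed to land a requested Mmax%.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import CalibrationError, ConfigurationError, ValidationError
from .image_io import BModeImage, PolygonROI, polygon_mask, write_roi_file
from .sfa_core import SFAConfig, analyze_roi

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "SyntheticTruth",
    "CohortImage",
    "TABLE_TARGETS",
    "speckle_envelope",
    "simulate_speckle",
    "add_fascicular_bands",
    "make_phantom",
    "sample_region_pairs",
    "draw_cohort_targets",
    "amplitude_for_mmax",
    "render_cohort",
    "generate_cohort",
]

# Display mapping constants: intensities are 20*log10(envelope/RMS) shifted by
# +35 dB and scaled so that a 60 dB dynamic range spans 0..255. RMS
# normalisation keeps mean brightness stable across image sizes and seeds.
_DYNAMIC_RANGE_DB = 60.0
_DB_SHIFT = 35.0

#: Default cohort calibration targets: group means (SD) of PSFR (cycles/mm)
#: and Mmax% (%) for the injured and adjacent regions of the involved limb,
#: and the pooled contralateral values.
TABLE_TARGETS: dict[tuple[str, str], tuple[float, float]] = {
    ("injured", "psfr"): (0.77, 0.24),
    ("adjacent", "psfr"): (0.89, 0.25),
    ("injured", "mmax"): (1.41, 0.43),
    ("adjacent", "mmax"): (2.28, 0.50),
    ("contralateral", "psfr"): (0.875, 0.22),
    ("contralateral", "mmax"): (2.41, 0.62),
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic B-mode frame.

    ``band_spacing_mm`` is the perimysial period: the expected PSFR of the
    healthy texture is ``1/band_spacing_mm``. Inside ``edema_polygon`` the
    band amplitude is multiplied by ``edema_attenuation``, the spacing is
    replaced by ``edema_band_spacing_mm`` (when set) and Gaussian noise of
    scale ``edema_noise_sigma`` is added, emulating focal injury.
    """

    shape_mm: tuple[float, float] = (40.0, 56.0)
    pixel_mm: float = 0.1
    band_spacing_mm: float = 1.15
    band_amplitude: float = 0.1
    band_angle_deg: float = 0.0
    noise_sigma: float = 6.0
    edema_polygon: PolygonROI | None = None
    edema_attenuation: float = 0.35
    edema_band_spacing_mm: float | None = None
    edema_noise_sigma: float = 12.0
    seed: int = 0
    # point-spread function of the simulated system (high-resolution linear
    # array: speckle cells of roughly one pixel)
    psf_sigma_axial_mm: float = 0.08
    psf_sigma_lateral_mm: float = 0.12
    psf_carrier_cpmm: float = 2.5
    # post-processing blur applied by scan conversion / display smoothing;
    # attenuates high-frequency noise far above the perimysial band
    display_smoothing_mm: float = 0.10

    def __post_init__(self) -> None:
        if self.pixel_mm <= 0:
            raise ValidationError("pixel_mm must be positive")
        if self.band_spacing_mm <= 2 * self.pixel_mm:
            raise ValidationError("band_spacing_mm must exceed 2*pixel_mm (resolvable)")
        if not 0.0 <= self.band_amplitude <= 1.0:
            raise ValidationError("band_amplitude must lie in [0, 1]")
        if self.noise_sigma < 0 or self.edema_noise_sigma < 0:
            raise ValidationError("noise scales must be >= 0")

    @property
    def shape_px(self) -> tuple[int, int]:
        return (
            int(round(self.shape_mm[0] / self.pixel_mm)),
            int(round(self.shape_mm[1] / self.pixel_mm)),
        )


def _psf(spec: PhantomSpec) -> np.ndarray:
    """Separable PSF sampled at the pixel pitch, truncated at 3 sigma."""
    p = spec.pixel_mm
    n_ax = max(1, int(np.ceil(3 * spec.psf_sigma_axial_mm / p)))
    n_lat = max(1, int(np.ceil(3 * spec.psf_sigma_lateral_mm / p)))
    rows, cols = spec.shape_px
    if 2 * n_ax + 1 > rows or 2 * n_lat + 1 > cols:
        raise ConfigurationError("PSF support is wider than the image")
    z = np.arange(-n_ax, n_ax + 1) * p
    x = np.arange(-n_lat, n_lat + 1) * p
    h_ax = np.exp(-0.5 * (z / spec.psf_sigma_axial_mm) ** 2) * np.cos(
        2 * np.pi * spec.psf_carrier_cpmm * z
    )
    h_lat = np.exp(-0.5 * (x / spec.psf_sigma_lateral_mm) ** 2)
    return np.outer(h_ax, h_lat)


def speckle_envelope(spec: PhantomSpec) -> np.ndarray:
    """Pre-log speckle envelope (Rayleigh-distributed for this model).

    A complex circular-Gaussian scatterer field convolved with the PSF stays
    complex Gaussian, so its modulus is exactly Rayleigh — the fully
    developed speckle regime.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape_px
    scat = rng.standard_normal((rows, cols)) + 1j * rng.standard_normal((rows, cols))
    fld = signal.fftconvolve(scat, _psf(spec), mode="same")
    return np.abs(fld)


def _log_compress(env: np.ndarray) -> np.ndarray:
    rms = float(np.sqrt(np.mean(env**2)))
    db = 20.0 * np.log10(np.maximum(env / rms, 1e-6))
    return np.clip(255.0 * (db + _DB_SHIFT) / _DYNAMIC_RANGE_DB, 0.0, 255.0)


def _unit_noise(
    rng: np.random.Generator, shape: tuple[int, int], smooth_px: float
) -> np.ndarray:
    """Unit-variance Gaussian noise, low-passed like the display chain."""
    from scipy import ndimage

    n = rng.standard_normal(shape)
    if smooth_px > 0:
        n = ndimage.gaussian_filter(n, smooth_px)
        n /= n.std()
    return n


def simulate_speckle(spec: PhantomSpec) -> BModeImage:
    """Log-compressed speckle background with optional additive noise.

    The additive noise and the compressed image both pass through the
    display-smoothing blur, as a scan converter would apply it."""
    from scipy import ndimage

    img = _log_compress(speckle_envelope(spec))
    smooth_px = spec.display_smoothing_mm / spec.pixel_mm
    if spec.noise_sigma > 0:
        rng = np.random.default_rng((spec.seed, 101))
        img = img + spec.noise_sigma * _unit_noise(rng, img.shape, smooth_px)
    if smooth_px > 0:
        img = ndimage.gaussian_filter(img, smooth_px)
    img = np.clip(img, 0.0, 255.0)
    return BModeImage(
        img, spec.pixel_mm, spec.pixel_mm, image_id=f"phantom-{spec.seed}", bit_max=255.0
    )


def add_fascicular_bands(img: BModeImage, spec: PhantomSpec) -> BModeImage:
    """Overlay the multiplicative raised-cosine perimysial grating.

    Intensity is multiplied by ``1 + A * g`` where ``g`` is a raised cosine
    in ``[0, 1]`` at spatial frequency ``1/band_spacing_mm`` oriented
    ``band_angle_deg`` from horizontal — hyperechoic bands brighten, never
    darken. Inside the edema polygon the amplitude, spacing and noise floor
    switch to the injured values.
    """
    rows, cols = img.shape
    p = img.spacing_axial
    z = np.arange(rows)[:, None] * p
    x = np.arange(cols)[None, :] * p
    th = np.radians(spec.band_angle_deg)
    coord = z * np.cos(th) + x * np.sin(th)

    def grating(spacing: float) -> np.ndarray:
        return 0.5 * (1.0 + np.cos(2 * np.pi * coord / spacing))

    out = img.pixels * (1.0 + spec.band_amplitude * grating(spec.band_spacing_mm))
    if spec.edema_polygon is not None:
        mask = polygon_mask(img.shape, spec.edema_polygon)
        a_in = spec.band_amplitude * spec.edema_attenuation
        sp_in = spec.edema_band_spacing_mm or spec.band_spacing_mm
        inner = img.pixels * (1.0 + a_in * grating(sp_in))
        if spec.edema_noise_sigma > 0:
            rng = np.random.default_rng((spec.seed, 202))
            smooth_px = spec.display_smoothing_mm / spec.pixel_mm
            inner = inner + spec.edema_noise_sigma * _unit_noise(rng, img.shape, smooth_px)
        out[mask] = inner[mask]
    out = np.clip(out, 0.0, img.bit_max)
    return BModeImage(out, img.spacing_axial, img.spacing_lateral, img.image_id, img.bit_max)


def make_phantom(spec: PhantomSpec) -> BModeImage:
    """Speckle background plus fascicular banding in one call."""
    return add_fascicular_bands(simulate_speckle(spec), spec)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Design of a synthetic study cohort.

    Per athlete the generator renders an involved-limb image at time of
    injury (attenuated, widened bands plus edema noise inside the injured
    polygon; healthy banding in the adjacent region), a contralateral image
    with mirrored ROIs and uniform healthy texture, and — for a separate
    return-to-sport group of ``n_rts`` athletes — an involved-limb image
    whose injured-region parameters have recovered toward the adjacent ones
    by ``healed_fraction`` (1.0 = fully healed).

    ``region_means`` maps ``(region, parameter)`` to ``(mean, sd)`` targets
    used to draw per-athlete true parameter values; ``rho`` is the
    within-athlete correlation between the injured and adjacent draws
    (regions of one image share machine settings and anatomy).
    """

    n_athletes: int = 11
    n_rts: int = 9
    region_means: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE_TARGETS)
    )
    healed_fraction: float = 1.0
    rho: float = 0.5
    pixel_mm: float = 0.1
    image_shape_mm: tuple[float, float] = (40.0, 56.0)
    noise_sigma: float = 6.0
    edema_noise_sigma: float = 12.0
    band_angle_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_athletes < 2:
            raise ValidationError("n_athletes must be >= 2")
        if any(sd < 0 for _, sd in self.region_means.values()):
            raise ValidationError("region SDs must be >= 0")
        nyq = 0.5 / self.pixel_mm
        for (region, param), (mean, _) in self.region_means.items():
            if param == "psfr" and mean >= nyq:
                raise CalibrationError(
                    f"target PSFR {mean} for region '{region}' is at or above "
                    f"Nyquist {nyq} cycles/mm"
                )


@dataclass
class SyntheticTruth:
    """Ground truth for one generated image, the oracle for recovery tests."""

    image_id: str
    band_spacing_mm: dict[str, float]
    expected_psfr: dict[str, float]
    band_amplitude: dict[str, float]
    target_mmax: dict[str, float]
    noise_sigma: float
    edema_noise_sigma: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class CohortImage:
    """One rendered study observation: image + its ROIs + generator truth."""

    athlete_id: str
    limb: str  # involved | contralateral
    timepoint: str  # TOI | RTS
    image: BModeImage
    rois: list[PolygonROI]
    truth: SyntheticTruth


def sample_region_pairs(
    rng: np.random.Generator,
    mean_sd_a: tuple[float, float],
    mean_sd_b: tuple[float, float],
    rho: float,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n correlated (a, b) pairs from a bivariate normal."""
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    a = mean_sd_a[0] + mean_sd_a[1] * z1
    b = mean_sd_b[0] + mean_sd_b[1] * (rho * z1 + np.sqrt(1 - rho**2) * z2)
    return a, b


def _floor_compensated_mean(mean: float, sd: float, floor: float) -> float:
    """Mean to draw from so that E[max(draw, floor)] equals ``mean``.

    The generator cannot realise an Mmax% below the speckle noise floor;
    drawing around the raw target would bias the realised group mean
    upward, so the drawing mean is shifted down to cancel the truncation.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    if sd <= 0 or floor <= mean - 4 * sd:
        return mean

    def emax(m: float) -> float:
        a = (floor - m) / sd
        return floor * norm.cdf(a) + m * norm.sf(a) + sd * norm.pdf(a)

    lo = mean - 6 * sd
    if emax(lo) > mean:  # floor itself is above the target mean
        return lo
    return float(brentq(lambda m: emax(m) - mean, lo, mean + sd))


def draw_cohort_targets(
    spec: CohortSpec, rng: np.random.Generator, n: int
) -> pd.DataFrame:
    """Per-athlete true (psfr, mmax) targets for injured and adjacent regions.

    Draws are clipped to the physically renderable range: PSFR into
    ``[0.3, 0.9*Nyquist]`` cycles/mm, Mmax% to positive values. Mmax% means
    are floor-compensated against the pilot noise floor of each region's
    rendering condition.
    """
    nyq = 0.5 / spec.pixel_mm
    m = spec.region_means
    psfr_inj, psfr_adj = sample_region_pairs(
        rng, m[("injured", "psfr")], m[("adjacent", "psfr")], spec.rho, n
    )
    floor_adj = _mmax_pilot(round(spec.pixel_mm, 6), round(spec.noise_sigma, 6),
                            0.0, 1.15)[1][0]
    floor_inj = _mmax_pilot(round(spec.pixel_mm, 6), round(spec.noise_sigma, 6),
                            round(spec.edema_noise_sigma, 6), 1.15)[1][0]
    mi_mean, mi_sd = m[("injured", "mmax")]
    ma_mean, ma_sd = m[("adjacent", "mmax")]
    mmax_inj, mmax_adj = sample_region_pairs(
        rng,
        (_floor_compensated_mean(mi_mean, mi_sd, floor_inj), mi_sd),
        (_floor_compensated_mean(ma_mean, ma_sd, floor_adj), ma_sd),
        spec.rho,
        n,
    )
    df = pd.DataFrame(
        {
            "psfr_injured": np.clip(psfr_inj, 0.3, 0.9 * nyq),
            "psfr_adjacent": np.clip(psfr_adj, 0.3, 0.9 * nyq),
            "mmax_injured": np.clip(mmax_inj, 0.05, None),
            "mmax_adjacent": np.clip(mmax_adj, 0.05, None),
        }
    )
    return df


# -- amplitude calibration ---------------------------------------------------

_PILOT_AMPS = (0.0, 0.02, 0.05, 0.09, 0.15, 0.25, 0.4, 0.6)
_PILOT_SPACINGS = (1.0, 1.15, 1.3, 1.45, 1.6)


def _nearest_pilot_spacing(spacing_mm: float) -> float:
    """Snap a band spacing to the pilot grid (measured Mmax% varies with the
    band frequency through the noise spectrum under the peak)."""
    return min(_PILOT_SPACINGS, key=lambda s: abs(s - spacing_mm))


@lru_cache(maxsize=16)
def _mmax_pilot(
    pixel_mm: float,
    noise_sigma: float,
    edema_noise_sigma: float,
    band_spacing_mm: float,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Map band amplitude -> measured ROI-mean Mmax% on a small pilot phantom.

    When ``edema_noise_sigma > 0`` the pilot renders the ROI *inside* an
    edema polygon (attenuation 1, elevated noise) so the calibration sees
    exactly the injured-region rendering path. Averaged over two seeds; made
    monotone so it can be inverted by linear interpolation.
    """
    cfg = SFAConfig(stride_px=8)
    side_mm = 15.0
    n = int(round(side_mm / pixel_mm))
    lo, hi = 24, n - 24
    roi = PolygonROI(
        [(lo, lo), (lo, hi), (hi, hi), (hi, lo)], label="adjacent", image_id="pilot"
    )
    edema = None
    if edema_noise_sigma > 0:
        edema = PolygonROI(
            [(0, 0), (0, n - 1), (n - 1, n - 1), (n - 1, 0)],
            label="injured", image_id="pilot",
        )
    means = []
    for amp in _PILOT_AMPS:
        vals = []
        for seed in (90001, 90002):
            spec = PhantomSpec(
                shape_mm=(side_mm, side_mm),
                pixel_mm=pixel_mm,
                band_spacing_mm=band_spacing_mm,
                band_amplitude=amp,
                noise_sigma=noise_sigma,
                edema_polygon=edema,
                edema_attenuation=1.0,
                edema_noise_sigma=edema_noise_sigma,
                seed=seed,
            )
            vals.append(analyze_roi(make_phantom(spec), roi, cfg).mean_mmax_pct)
        means.append(float(np.mean(vals)))
    mono = tuple(np.maximum.accumulate(means).tolist())
    return _PILOT_AMPS, mono


def amplitude_for_mmax(
    target_mmax: float,
    pixel_mm: float = 0.1,
    noise_sigma: float = 6.0,
    edema_noise_sigma: float = 0.0,
    band_spacing_mm: float = 1.15,
) -> float:
    """Band amplitude whose measured Mmax% is ~target, by pilot inversion."""
    amps, mmaxes = _mmax_pilot(round(pixel_mm, 6), round(noise_sigma, 6),
                               round(edema_noise_sigma, 6), round(band_spacing_mm, 6))
    if target_mmax > mmaxes[-1]:
        raise CalibrationError(
            f"target Mmax% {target_mmax:.2f} exceeds the generator's reachable "
            f"maximum {mmaxes[-1]:.2f} at amplitude {amps[-1]}"
        )
    return float(np.interp(target_mmax, mmaxes, amps))


# -- image assembly ----------------------------------------------------------


def _roi_rects(
    shape_px: tuple[int, int], mirrored: bool
) -> tuple[PolygonROI, PolygonROI]:
    """Side-by-side rectangular injured/adjacent ROIs, non-overlapping.

    On large frames the ROIs span a muscle-like 16 mm of depth; on small
    frames they expand so a 6.5 mm kernel still fits."""
    h, w = shape_px
    r0, r1 = int(0.25 * h), int(0.65 * h)
    if r1 - r0 < 100:
        r0, r1 = int(0.10 * h), int(0.85 * h)
    labels = ("mirrored_injury", "mirrored_adjacent") if mirrored else ("injured", "adjacent")
    inj = PolygonROI(
        [(r0, int(0.10 * w)), (r0, int(0.42 * w)), (r1, int(0.42 * w)), (r1, int(0.10 * w))],
        label=labels[0],
    )
    adj = PolygonROI(
        [(r0, int(0.52 * w)), (r0, int(0.84 * w)), (r1, int(0.84 * w)), (r1, int(0.52 * w))],
        label=labels[1],
    )
    return inj, adj


def render_involved_image(
    spec: CohortSpec,
    targets: pd.Series,
    athlete_id: str,
    timepoint: str,
    seed: int,
) -> CohortImage:
    """Involved-limb image: healthy bands in the adjacent region, attenuated
    widened bands plus edema noise inside the injured polygon.

    At RTS the injured-region parameters are moved toward the adjacent ones
    by ``healed_fraction`` and the edema noise shrinks proportionally.
    """
    h = spec.healed_fraction if timepoint == "RTS" else 0.0
    psfr_adj = float(targets["psfr_adjacent"])
    mmax_adj = float(targets["mmax_adjacent"])
    psfr_inj = psfr_adj + (1 - h) * (float(targets["psfr_injured"]) - psfr_adj)
    mmax_inj = mmax_adj + (1 - h) * (float(targets["mmax_injured"]) - mmax_adj)
    edema_noise = (1 - h) * spec.edema_noise_sigma

    a_adj = amplitude_for_mmax(
        mmax_adj, spec.pixel_mm, spec.noise_sigma,
        band_spacing_mm=_nearest_pilot_spacing(1.0 / psfr_adj),
    )
    a_inj = amplitude_for_mmax(
        mmax_inj, spec.pixel_mm, spec.noise_sigma, edema_noise,
        band_spacing_mm=_nearest_pilot_spacing(1.0 / psfr_inj),
    )
    a_adj = max(a_adj, 1e-6)

    shape_px = (
        int(round(spec.image_shape_mm[0] / spec.pixel_mm)),
        int(round(spec.image_shape_mm[1] / spec.pixel_mm)),
    )
    image_id = f"{athlete_id}_involved_{timepoint}"
    inj_roi, adj_roi = _roi_rects(shape_px, mirrored=False)
    inj_roi.image_id = adj_roi.image_id = image_id

    phantom = PhantomSpec(
        shape_mm=spec.image_shape_mm,
        pixel_mm=spec.pixel_mm,
        band_spacing_mm=1.0 / psfr_adj,
        band_amplitude=min(a_adj, 1.0),
        band_angle_deg=spec.band_angle_deg,
        noise_sigma=spec.noise_sigma,
        edema_polygon=inj_roi,
        edema_attenuation=min(a_inj / a_adj, 1.0 / max(a_adj, 1e-9)),
        edema_band_spacing_mm=1.0 / psfr_inj,
        edema_noise_sigma=edema_noise,
        seed=seed,
    )
    img = make_phantom(phantom)
    img.image_id = image_id
    truth = SyntheticTruth(
        image_id=image_id,
        band_spacing_mm={"injured": 1.0 / psfr_inj, "adjacent": 1.0 / psfr_adj},
        expected_psfr={"injured": psfr_inj, "adjacent": psfr_adj},
        band_amplitude={"injured": a_inj, "adjacent": a_adj},
        target_mmax={"injured": mmax_inj, "adjacent": mmax_adj},
        noise_sigma=spec.noise_sigma,
        edema_noise_sigma=edema_noise,
        seed=seed,
    )
    return CohortImage(athlete_id, "involved", timepoint, img, [inj_roi, adj_roi], truth)


def render_contralateral_image(
    spec: CohortSpec, psfr: float, mmax: float, athlete_id: str, seed: int
) -> CohortImage:
    """Contralateral image: uniform healthy texture, mirrored ROI labels.

    No injury polygon exists in the truth, by construction — the two
    mirrored regions sample the same process (the study's control)."""
    a = amplitude_for_mmax(
        mmax, spec.pixel_mm, spec.noise_sigma,
        band_spacing_mm=_nearest_pilot_spacing(1.0 / psfr),
    )
    shape_px = (
        int(round(spec.image_shape_mm[0] / spec.pixel_mm)),
        int(round(spec.image_shape_mm[1] / spec.pixel_mm)),
    )
    image_id = f"{athlete_id}_contralateral_TOI"
    m_inj, m_adj = _roi_rects(shape_px, mirrored=True)
    m_inj.image_id = m_adj.image_id = image_id
    phantom = PhantomSpec(
        shape_mm=spec.image_shape_mm,
        pixel_mm=spec.pixel_mm,
        band_spacing_mm=1.0 / psfr,
        band_amplitude=min(a, 1.0),
        band_angle_deg=spec.band_angle_deg,
        noise_sigma=spec.noise_sigma,
        seed=seed,
    )
    img = make_phantom(phantom)
    img.image_id = image_id
    truth = SyntheticTruth(
        image_id=image_id,
        band_spacing_mm={"mirrored_injury": 1.0 / psfr, "mirrored_adjacent": 1.0 / psfr},
        expected_psfr={"mirrored_injury": psfr, "mirrored_adjacent": psfr},
        band_amplitude={"mirrored_injury": a, "mirrored_adjacent": a},
        target_mmax={"mirrored_injury": mmax, "mirrored_adjacent": mmax},
        noise_sigma=spec.noise_sigma,
        edema_noise_sigma=0.0,
        seed=seed,
    )
    return CohortImage(athlete_id, "contralateral", "TOI", img, [m_inj, m_adj], truth)


def render_cohort(spec: CohortSpec) -> list[CohortImage]:
    """Render the full cohort in memory, deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    toi_targets = draw_cohort_targets(spec, rng, spec.n_athletes)
    contra_psfr = spec.region_means[("contralateral", "psfr")]
    contra_mmax = spec.region_means[("contralateral", "mmax")]
    nyq = 0.5 / spec.pixel_mm
    c_psfr = np.clip(
        contra_psfr[0] + contra_psfr[1] * rng.standard_normal(spec.n_athletes),
        0.3, 0.9 * nyq,
    )
    c_mmax = np.clip(
        contra_mmax[0] + contra_mmax[1] * rng.standard_normal(spec.n_athletes),
        0.05, None,
    )
    rts_targets = draw_cohort_targets(spec, rng, spec.n_rts) if spec.n_rts else None
    seeds = rng.integers(0, 2**31 - 1, size=2 * spec.n_athletes + spec.n_rts)

    out: list[CohortImage] = []
    s = 0
    for i in range(spec.n_athletes):
        aid = f"ath{i + 1:02d}"
        out.append(render_involved_image(spec, toi_targets.iloc[i], aid, "TOI", int(seeds[s])))
        s += 1
        out.append(
            render_contralateral_image(
                spec, float(c_psfr[i]), float(c_mmax[i]), aid, int(seeds[s])
            )
        )
        s += 1
    if rts_targets is not None:
        for i in range(spec.n_rts):
            aid = f"rts{i + 1:02d}"
            out.append(
                render_involved_image(spec, rts_targets.iloc[i], aid, "RTS", int(seeds[s]))
            )
            s += 1
    return out


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Render a cohort and write PNG images, ROI JSONs, truth JSONs and the
    study manifest CSV under ``out_dir``. Returns the manifest table (paths
    relative to ``out_dir``)."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "rois").mkdir(exist_ok=True)
    (out_dir / "truth").mkdir(exist_ok=True)
    rows = []
    for ci in render_cohort(spec):
        stem = ci.truth.image_id
        img_path = f"images/{stem}.png"
        roi_path = f"rois/{stem}.json"
        truth_path = f"truth/{stem}.json"
        iio.imwrite(out_dir / img_path, np.round(ci.image.pixels).astype(np.uint8))
        write_roi_file(ci.rois, out_dir / roi_path)
        (out_dir / truth_path).write_text(ci.truth.to_json() + "\n")
        rows.append(
            {
                "athlete_id": ci.athlete_id,
                "limb": ci.limb,
                "timepoint": ci.timepoint,
                "image_path": img_path,
                "spacing_axial": spec.pixel_mm,
                "spacing_lateral": spec.pixel_mm,
                "roi_path": roi_path,
                "truth_path": truth_path,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
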