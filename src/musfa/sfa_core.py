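"""Spatial frequency analysis (SFA) of B-mode speckle texture.

The method slides a square kernel — defined in physical units so that it is
comparable across imaging depths — over every position fully inside a
polygonal ROI, zero-pads each kernel into a larger FFT grid to refine the
frequency sampling, takes the 2-D magnitude spectrum, suppresses low spatial
frequencies with a radially symmetric high-pass, and reads off two
parameters per kernel:

* **PSFR** (peak spatial frequency radius): the radial distance, in
  cycles/mm, from the spectral origin to the maximum-magnitude bin. A more
  compact fascicular banding pattern gives a higher PSFR.
* **Mmax%**: the peak magnitude as a percentage of the overall image
  brightness (the unfiltered DC magnitude). It measures how strongly the
  dominant banded pattern stands out from the background.

Both parameters are averaged over all kernels in the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ROITooSmallError, ValidationError
from .image_io import BModeImage, PolygonROI, polygon_mask

__all__ = [
    "SFAConfig",
    "KernelResult",
    "ROIResult",
    "kernel_px",
    "enumerate_kernels",
    "kernel_spectrum",
    "highpass_gain",
    "highpass_filter",
    "extract_peak",
    "mmax_percent",
    "analyze_roi",
]

_FFT_CHUNK = 128  # kernels per batched FFT call; bounds peak memory


@dataclass(frozen=True)
class SFAConfig:
    """Tunable parameters of the spectral pipeline.

    kernel_mm
        Physical side of the square analysis kernel (mm).
    pad_n
        Zero-padded FFT size per axis (power of two >= kernel in pixels).
        Frequency resolution is ``1/(pad_n * pixel_mm)`` cycles/mm.
    stride_px
        Step between kernel origins in pixels; 1 analyzes every placement.
    hp_cutoff
        −3 dB cutoff of the radial Butterworth high-pass, cycles/mm.
    hp_order
        Butterworth order; larger = sharper roll-off.
    subtract_mean
        Subtract the kernel mean before zero-padding. Without it the DC
        term leaks through the padded window as a slowly decaying sidelobe
        skirt that can exceed genuine band peaks on bright log-compressed
        images. The DC bin of the returned spectrum always carries the true
        overall brightness (the plain intensity sum), so Mmax% is unaffected.
    axial_sector_deg
        Optional half-angle (degrees from the axial frequency axis)
        restricting the peak search to near-axial frequencies; ``None``
        searches the full non-redundant half-plane.
    """

    kernel_mm: float = 6.5
    pad_n: int = 128
    stride_px: int = 1
    hp_cutoff: float = 0.25
    hp_order: int = 2
    subtract_mean: bool = True
    axial_sector_deg: float | None = None

    def __post_init__(self) -> None:
        if self.kernel_mm <= 0:
            raise ConfigurationError("kernel_mm must be positive")
        if self.pad_n < 8 or (self.pad_n & (self.pad_n - 1)) != 0:
            raise ConfigurationError("pad_n must be a power of two >= 8")
        if self.stride_px < 1:
            raise ConfigurationError("stride_px must be >= 1")
        if self.hp_cutoff < 0:
            raise ConfigurationError("hp_cutoff must be >= 0")
        if self.hp_order < 1:
            raise ConfigurationError("hp_order must be >= 1")


@dataclass
class KernelResult:
    """Per-kernel spectral readout.

    ``psfr`` is NaN and ``no_peak`` True when the filtered spectrum is
    identically zero (e.g. an all-constant kernel); such kernels are
    excluded from ROI averages.
    """

    origin: tuple[int, int]
    psfr: float
    mmax_pct: float
    peak_bin: tuple[int, int]
    peak_mag: float
    dc_mag: float
    no_peak: bool = False


@dataclass
class ROIResult:
    """ROI-level summary: arithmetic means over kernels with a valid peak."""

    mean_psfr: float
    mean_mmax_pct: float
    n_kernels: int
    n_no_peak: int
    kernels: list[KernelResult]
    config_used: SFAConfig
    unreliable: bool = False


def kernel_px(img: BModeImage, cfg: SFAConfig) -> int:
    """Kernel side in pixels: the physical kernel size over the pixel pitch."""
    if not img.is_isotropic:
        raise ValidationError("kernel_px requires an isotropic image; resample first")
    k = int(round(cfg.kernel_mm / img.spacing_axial))
    if k < 8:
        raise ConfigurationError(
            f"kernel of {cfg.kernel_mm} mm is only {k} px at "
            f"{img.spacing_axial} mm/px; need >= 8"
        )
    if k > cfg.pad_n:
        raise ConfigurationError(
            f"kernel of {k} px exceeds FFT pad size {cfg.pad_n}"
        )
    if k > min(img.shape):
        raise ConfigurationError(f"kernel of {k} px exceeds image {img.shape}")
    return k


def enumerate_kernels(
    img: BModeImage, roi: PolygonROI, cfg: SFAConfig
) -> list[tuple[int, int]]:
    """Top-left origins of every kernel placement fully inside the polygon.

    A placement is admitted only when all ``k x k`` pixel centers it covers
    lie inside (or on the boundary of) the ROI, so tissue outside the drawn
    region never leaks into a spectrum. Origins are returned on the stride
    grid in row-major order.
    """
    k = kernel_px(img, cfg)
    mask = polygon_mask(img.shape, roi)
    n_r, n_c = img.shape
    if n_r < k or n_c < k:
        raise ROITooSmallError(
            f"image {img.shape} smaller than kernel {k} px"
        )
    # integral image: window sum == k*k  <=>  every center inside
    integral = np.zeros((n_r + 1, n_c + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)
    win = (
        integral[k:, k:] - integral[:-k, k:] - integral[k:, :-k] + integral[:-k, :-k]
    )
    valid = win == k * k
    rows = np.arange(0, n_r - k + 1, cfg.stride_px)
    cols = np.arange(0, n_c - k + 1, cfg.stride_px)
    sub = valid[np.ix_(rows, cols)]
    rr, cc = np.nonzero(sub)
    origins = [(int(rows[i]), int(cols[j])) for i, j in zip(rr, cc)]
    if not origins:
        raise ROITooSmallError(
            f"ROI '{roi.label}' on '{roi.image_id}' is too small for a "
            f"{k}-px kernel"
        )
    return origins


def kernel_spectrum(
    kernel: np.ndarray, cfg: SFAConfig, pixel_mm: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zero-padded 2-D magnitude spectrum of one kernel.

    The kernel (mean-subtracted when ``cfg.subtract_mean``, see
    :class:`SFAConfig`) is placed in the top-left corner of a
    ``pad_n x pad_n`` zero array and transformed without windowing. The DC
    bin of the returned magnitude always equals the plain intensity sum —
    the overall image brightness needed by Mmax%. Returns ``(magnitude,
    f_axial, f_lateral)`` with DC at index ``[0, 0]`` and frequency axes in
    cycles/mm (numpy ``fftfreq`` layout).
    """
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.ndim != 2 or kernel.shape[0] != kernel.shape[1]:
        raise ValidationError(f"kernel must be square, got {kernel.shape}")
    k = kernel.shape[0]
    if k > cfg.pad_n:
        raise ConfigurationError(f"kernel side {k} exceeds pad_n {cfg.pad_n}")
    padded = np.zeros((cfg.pad_n, cfg.pad_n))
    padded[:k, :k] = kernel - kernel.mean() if cfg.subtract_mean else kernel
    mag = np.abs(np.fft.fft2(padded))
    mag[0, 0] = abs(float(kernel.sum()))
    freqs = np.fft.fftfreq(cfg.pad_n, d=pixel_mm)
    return mag, freqs.copy(), freqs.copy()


def highpass_gain(
    f_axial: np.ndarray, f_lateral: np.ndarray, cfg: SFAConfig
) -> np.ndarray:
    """Radially symmetric Butterworth high-pass gain on the FFT grid.

    ``H(f) = 1 / sqrt(1 + (fc/f)^(2*order))`` with ``H(fc) = 1/sqrt(2)``
    (−3 dB) exactly and ``H(0) = 0``.
    """
    nyq = float(np.max(np.abs(f_axial)))
    if cfg.hp_cutoff >= nyq:
        raise ConfigurationError(
            f"hp_cutoff {cfg.hp_cutoff} cycles/mm >= Nyquist {nyq}"
        )
    fr = np.hypot(f_axial[:, None], f_lateral[None, :])
    gain = np.zeros_like(fr)
    nz = fr > 0
    if cfg.hp_cutoff == 0:
        gain[nz] = 1.0
    else:
        gain[nz] = 1.0 / np.sqrt(1.0 + (cfg.hp_cutoff / fr[nz]) ** (2 * cfg.hp_order))
    return gain


def highpass_filter(
    spectrum: np.ndarray,
    f_axial: np.ndarray,
    f_lateral: np.ndarray,
    cfg: SFAConfig,
) -> np.ndarray:
    """Apply the Butterworth high-pass to a magnitude spectrum.

    The caller must keep the unfiltered DC magnitude separately: Mmax%
    normalises the filtered peak by the *unfiltered* overall brightness.
    """
    if spectrum.shape != (len(f_axial), len(f_lateral)):
        raise ValidationError("spectrum shape does not match frequency axes")
    return spectrum * highpass_gain(f_axial, f_lateral, cfg)


def _halfplane_order(
    f_axial: np.ndarray, f_lateral: np.ndarray, cfg: SFAConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices of the non-redundant half-plane sorted by (radius, row, col).

    A real image has a conjugate-symmetric spectrum; searching both half
    planes would create systematic ties. The half-plane keeps bins with
    positive axial frequency plus the positive-lateral half of the zero-axial
    row. Bins beyond the (radial) Nyquist frequency are excluded so the
    reported radius is always physically resolvable, and the sort order makes
    a plain argmax break ties toward the lower radius, then row-major.
    """
    fa = f_axial[:, None] * np.ones_like(f_lateral)[None, :]
    fl = np.ones_like(f_axial)[:, None] * f_lateral[None, :]
    half = (fa > 0) | ((fa == 0) & (fl > 0))
    radius = np.hypot(fa, fl)
    nyq = float(np.max(np.abs(f_axial)))
    half &= radius <= nyq
    if cfg.axial_sector_deg is not None:
        with np.errstate(invalid="ignore"):
            ang = np.degrees(np.arctan2(np.abs(fl), np.abs(fa)))
        half &= ang <= cfg.axial_sector_deg
    rows, cols = np.nonzero(half)
    order = np.lexsort((cols, rows, radius[rows, cols]))
    return rows[order], cols[order], radius[rows, cols][order]


def extract_peak(
    filtered: np.ndarray,
    f_axial: np.ndarray,
    f_lateral: np.ndarray,
    cfg: SFAConfig | None = None,
) -> tuple[tuple[int, int], float, float] | None:
    """Locate the spectral peak and its radial frequency.

    Returns ``((row_bin, col_bin), peak_magnitude, psfr)`` or ``None`` when
    the filtered spectrum is identically zero over the search region
    ("no peak"). Ties break toward the lower radius, then row-major order.
    """
    cfg = cfg or SFAConfig()
    rows, cols, radii = _halfplane_order(f_axial, f_lateral, cfg)
    vals = filtered[rows, cols]
    i = int(np.argmax(vals))  # first occurrence == lowest (radius, row, col)
    if vals[i] <= 0:
        return None
    return (int(rows[i]), int(cols[i])), float(vals[i]), float(radii[i])


def mmax_percent(peak_mag: float, dc_mag: float) -> float:
    """Peak magnitude as a percentage of overall image brightness (DC).

    Dimensionless and invariant to uniform gain. ``NaN`` (flagged "no
    signal") when both magnitudes are zero.
    """
    if dc_mag == 0:
        if peak_mag == 0:
            return float("nan")
        raise ValidationError("Mmax% undefined: zero DC with a nonzero peak")
    return 100.0 * peak_mag / dc_mag


def analyze_roi(img: BModeImage, roi: PolygonROI, cfg: SFAConfig | None = None) -> ROIResult:
    """Run the full per-kernel pipeline over an ROI and average.

    Kernels whose filtered spectrum is identically zero are excluded from
    the means (they carry no frequency information); if more than half of
    the placements are excluded the result is flagged ``unreliable``.
    Deterministic for fixed inputs and configuration.
    """
    cfg = cfg or SFAConfig()
    if not img.is_isotropic:
        raise ValidationError("analyze_roi requires an isotropic image; resample first")
    k = kernel_px(img, cfg)
    origins = enumerate_kernels(img, roi, cfg)
    pixel_mm = img.spacing_axial

    freqs = np.fft.fftfreq(cfg.pad_n, d=pixel_mm)
    gain = highpass_gain(freqs, freqs, cfg)
    rows, cols, radii = _halfplane_order(freqs, freqs, cfg)
    # real-input FFT computes only lateral frequencies >= 0; conjugate
    # symmetry maps every half-plane bin onto that grid
    n = cfg.pad_n
    half_cols = n // 2 + 1
    r_rows = np.where(cols < half_cols, rows, (n - rows) % n)
    r_cols = np.where(cols < half_cols, cols, n - cols)
    gsel = gain[rows, cols][None, :]

    kernels: list[KernelResult] = []
    buf = np.zeros((min(_FFT_CHUNK, len(origins)), cfg.pad_n, cfg.pad_n))
    for start in range(0, len(origins), _FFT_CHUNK):
        chunk = origins[start : start + _FFT_CHUNK]
        m = len(chunk)
        buf[:m] = 0.0
        dc = np.empty(m)
        for i, (r, c) in enumerate(chunk):
            block = img.pixels[r : r + k, c : c + k]
            dc[i] = abs(float(block.sum()))
            buf[i, :k, :k] = block - block.mean() if cfg.subtract_mean else block
        mags = np.abs(np.fft.rfft2(buf[:m], axes=(-2, -1)))
        vals = mags[:, r_rows, r_cols] * gsel
        idx = np.argmax(vals, axis=1)
        pk = vals[np.arange(m), idx]
        for i, (r, c) in enumerate(chunk):
            if pk[i] <= 0:
                kernels.append(
                    KernelResult((r, c), float("nan"), float("nan"), (-1, -1), 0.0,
                                 float(dc[i]), no_peak=True)
                )
                continue
            j = int(idx[i])
            kernels.append(
                KernelResult(
                    origin=(r, c),
                    psfr=float(radii[j]),
                    mmax_pct=mmax_percent(float(pk[i]), float(dc[i])),
                    peak_bin=(int(rows[j]), int(cols[j])),
                    peak_mag=float(pk[i]),
                    dc_mag=float(dc[i]),
                )
            )

    valid = [kr for kr in kernels if not kr.no_peak]
    n_no_peak = len(kernels) - len(valid)
    if not valid:
        return ROIResult(float("nan"), float("nan"), 0, n_no_peak, kernels, cfg, True)
    mean_psfr = float(np.mean([kr.psfr for kr in valid]))
    mean_mmax = float(np.mean([kr.mmax_pct for kr in valid]))
    unreliable = n_no_peak > len(kernels) / 2
    return ROIResult(mean_psfr, mean_mmax, len(valid), n_no_peak, kernels, cfg, unreliable)
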