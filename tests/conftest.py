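import numpy as np
import pytest

from musfa import BModeImage, PolygonROI, SFAConfig


@pytest.fixture
def rect_roi():
    """Axis-aligned rectangle covering rows/cols [lo, hi] inclusive."""

    def make(lo_r, lo_c, hi_r, hi_c, label="adjacent", image_id="img"):
        return PolygonROI(
            [(lo_r, lo_c), (lo_r, hi_c), (hi_r, hi_c), (hi_r, lo_c)],
            label=label,
            image_id=image_id,
        )

    return make


@pytest.fixture
def cosine_image():
    """Vertical cosine pattern (banding along the axial direction)."""

    def make(shape=(100, 100), period_mm=1.25, pixel_mm=0.1, mean=100.0, amp=50.0):
        z = np.arange(shape[0])[:, None] * pixel_mm
        pix = mean + amp * np.cos(2 * np.pi * z / period_mm) * np.ones((1, shape[1]))
        return BModeImage(pix, pixel_mm, pixel_mm, "cosine")

    return make


@pytest.fixture
def fast_cfg():
    return SFAConfig(stride_px=4)


def naive_dft_magnitude(kernel, pad_n, subtract_mean=True):
    """Direct double-loop DFT of the zero-padded kernel (test oracle).

    Independent of the FFT path: evaluates the DFT sum bin by bin from its
    definition. The DC bin is overridden with the plain intensity sum, the
    convention used throughout the spectral pipeline.
    """
    kernel = np.asarray(kernel, dtype=float)
    k = kernel.shape[0]
    padded = np.zeros((pad_n, pad_n))
    padded[:k, :k] = kernel - kernel.mean() if subtract_mean else kernel
    mag = np.empty((pad_n, pad_n))
    rows = np.arange(pad_n)
    wr = np.exp(-2j * np.pi * np.outer(rows, rows) / pad_n)
    for u in range(pad_n):
        for v in range(pad_n):
            mag[u, v] = abs(np.sum(padded * np.outer(wr[u], wr[v])))
    mag[0, 0] = abs(kernel.sum())
    return mag
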