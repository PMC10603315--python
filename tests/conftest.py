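import numpy as np
import pytest

from chemoguide import DeviceGeometry


@pytest.fixture
def geometry():
    """Device centered in a 512 px field at 4 um/px (2048 um field of view)."""
    return DeviceGeometry(center_px=(256, 256), inner_radius_um=100.0, pixel_size_um=4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


# ---------------------------------------------------------------------------
# independent brute-force oracle for the structure tensor: analytic
# Gaussian-derivative kernels + explicit nested-loop separable correlation
# with edge-duplicating reflective padding.  No scipy.ndimage involved.


def gaussian_kernel1d(sigma: float, order: int, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=float)
    phi = np.exp(-0.5 * x * x / sigma**2)
    phi /= phi.sum()
    if order == 0:
        return phi
    return -x / sigma**2 * phi


def _correlate2d_sep(img: np.ndarray, k_row: np.ndarray, k_col: np.ndarray) -> np.ndarray:
    rr, rc = len(k_row) // 2, len(k_col) // 2
    pad = np.pad(img, ((rr, rr), (rc, rc)), mode="symmetric")
    h, w = img.shape
    krr, kcc = k_row[::-1], k_col[::-1]
    tmp = np.zeros((h, pad.shape[1]))
    for i in range(h):
        for j in range(pad.shape[1]):
            acc = 0.0
            for k in range(len(k_row)):
                acc += krr[k] * pad[i + k, j]
            tmp[i, j] = acc
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for k in range(len(k_col)):
                acc += kcc[k] * tmp[i, j + k]
            out[i, j] = acc
    return out


def naive_structure_tensor(img: np.ndarray, gradient_sigma: float, window_sigma: float):
    """Reference tensor computation by direct convolution loops (no FFT)."""
    rg = int(4.0 * gradient_sigma + 0.5)
    rw = int(4.0 * window_sigma + 0.5)
    g0 = gaussian_kernel1d(gradient_sigma, 0, rg)
    g1 = gaussian_kernel1d(gradient_sigma, 1, rg)
    w0 = gaussian_kernel1d(window_sigma, 0, rw)
    ix = _correlate2d_sep(img, g0, g1)
    iy = -_correlate2d_sep(img, g1, g0)  # y-up sign convention
    jxx = _correlate2d_sep(ix * ix, w0, w0)
    jxy = _correlate2d_sep(ix * iy, w0, w0)
    jyy = _correlate2d_sep(iy * iy, w0, w0)
    return jxx, jxy, jyy
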