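"""Embedded colorimetric constants.

Everything here is a package constant evaluated once at import time — no
runtime download, no external data file.

The CIE 1931 2° color-matching functions are generated from the multi-lobe
piecewise-Gaussian analytic representation of Wyman, Sloan & Shirley (2013),
which reproduces the standard observer to within about one percent over the
visible range.  The x̄ representation dips a few 1e-4 below zero near 501 nm
and is clipped at zero to keep the functions non-negative.
"""

from __future__ import annotations

import numpy as np

#: 1 nm wavelength grid, 380–780 nm inclusive (401 points).
WAVELENGTHS: np.ndarray = np.arange(380.0, 781.0, 1.0)
N_BANDS: int = WAVELENGTHS.size  # 401


def _lobe(lam: np.ndarray, mu: float, s_left: float, s_right: float) -> np.ndarray:
    """Piecewise Gaussian lobe with distinct left/right widths."""
    s = np.where(lam < mu, s_left, s_right)
    return np.exp(-0.5 * ((lam - mu) / s) ** 2)


def _cmf_tables(lam: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xbar = (
        1.056 * _lobe(lam, 599.8, 37.9, 31.0)
        + 0.362 * _lobe(lam, 442.0, 16.0, 26.7)
        - 0.065 * _lobe(lam, 501.1, 20.4, 26.2)
    )
    ybar = 0.821 * _lobe(lam, 568.8, 46.9, 40.5) + 0.286 * _lobe(lam, 530.9, 16.3, 31.1)
    zbar = 1.217 * _lobe(lam, 437.0, 11.8, 36.0) + 0.681 * _lobe(lam, 459.0, 26.0, 13.8)
    return np.clip(xbar, 0.0, None), ybar, zbar


XBAR, YBAR, ZBAR = _cmf_tables(WAVELENGTHS)
for _a in (XBAR, YBAR, ZBAR):
    _a.setflags(write=False)
WAVELENGTHS.setflags(write=False)

#: sRGB (IEC 61966-2-1) linear-RGB → XYZ matrix for the D65 white point,
#: at the classical published precision; row sums × 100 give the sRGB white
#: (95.047, 100.000, 108.883).
SRGB_TO_XYZ: np.ndarray = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
SRGB_TO_XYZ.setflags(write=False)

#: Bradford cone-response matrix used for chromatic adaptation.
BRADFORD: np.ndarray = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)
BRADFORD.setflags(write=False)

#: Reference whites on the Y = 100 luminance scale.
D65_WHITE: tuple[float, float, float] = (95.047, 100.000, 108.883)
EQUAL_ENERGY_WHITE: tuple[float, float, float] = (100.0, 100.0, 100.0)

#: sRGB transfer-function constants.
SRGB_LINEAR_THRESHOLD = 0.04045
SRGB_LINEAR_SLOPE = 12.92
SRGB_OFFSET = 0.055
SRGB_GAMMA = 2.4
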