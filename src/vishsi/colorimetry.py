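"""Spectra ↔ tristimulus conversions and the sRGB → XYZ chain.

The conversion chain implemented here is the front end of the visible-band
hyperspectral pipeline: encoded sRGB values are gamma-decoded to linear RGB,
mapped to CIE XYZ through the standard sRGB primaries matrix, and optionally
chromatically adapted from the D65 white of the sRGB space to the measured
white of the actual light source.  On the spectrometer side, an illuminant
spectrum S(λ) and a reflectance spectrum R(λ) are integrated against the CIE
1931 2° color-matching functions to give XYZ with the perfect-reflector
luminance normalised to Y = 100:

    k = 100 / Σ S(λ) ȳ(λ)
    X = k Σ S(λ) R(λ) x̄(λ)      (and likewise Y, Z)

Quadrature is the rectangle rule on the 1 nm grid; the Δλ factor cancels in
k, so the tristimulus values are step-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._cie import (
    BRADFORD,
    D65_WHITE,
    EQUAL_ENERGY_WHITE,
    N_BANDS,
    SRGB_GAMMA,
    SRGB_LINEAR_SLOPE,
    SRGB_LINEAR_THRESHOLD,
    SRGB_OFFSET,
    SRGB_TO_XYZ,
    WAVELENGTHS,
    XBAR,
    YBAR,
    ZBAR,
)

__all__ = [
    "WAVELENGTHS",
    "SpectralCurve",
    "CMFSet",
    "WhitePoint",
    "CIE_1931_2DEG",
    "D65",
    "EQUAL_ENERGY",
    "gamma_decode",
    "gamma_encode",
    "linear_rgb_to_xyz",
    "adaptation_matrix",
    "spectrum_to_xyz",
    "read_spectrum_csv",
    "write_spectrum_csv",
]


class DegenerateIlluminantError(ValueError):
    """The illuminant has no overlap with the luminance matching function."""


@dataclass(frozen=True)
class SpectralCurve:
    """A spectrum sampled on the 380–780 nm, 1 nm grid (401 points).

    ``kind`` distinguishes unitless reflectance (bounded to [0, 1]) from
    radiance/illuminant power in arbitrary units.
    """

    values: np.ndarray
    kind: Literal["reflectance", "radiance"] = "reflectance"
    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTHS, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        w = np.asarray(self.wavelengths, dtype=float)
        if v.shape != (N_BANDS,) or w.shape != (N_BANDS,):
            raise ValueError(f"spectral curves have {N_BANDS} samples, got {v.shape}")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectral values must be finite")
        if self.kind == "reflectance" and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("reflectance must lie in [0, 1]")

    def __mul__(self, other: "SpectralCurve | float") -> "SpectralCurve":
        ov = other.values if isinstance(other, SpectralCurve) else float(other)
        return SpectralCurve(self.values * ov, kind="radiance")

    @classmethod
    def flat(cls, value: float = 1.0, kind: str = "reflectance") -> "SpectralCurve":
        return cls(np.full(N_BANDS, float(value)), kind=kind)  # type: ignore[arg-type]


@dataclass(frozen=True)
class CMFSet:
    """A set of three color-matching functions on the standard grid."""

    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def as_matrix(self) -> np.ndarray:
        """3×401 stacked matching functions."""
        return np.stack([self.xbar, self.ybar, self.zbar])

    def to_frame(self) -> pd.DataFrame:
        """Export the embedded constants for audit."""
        return pd.DataFrame(
            {
                "wavelength_nm": WAVELENGTHS,
                "xbar": self.xbar,
                "ybar": self.ybar,
                "zbar": self.zbar,
            }
        )


#: The embedded CIE 1931 2° standard observer.
CIE_1931_2DEG = CMFSet(XBAR, YBAR, ZBAR)


@dataclass(frozen=True)
class WhitePoint:
    """Reference white tristimulus values, Y normalised to 100."""

    X: float
    Y: float
    Z: float
    role: Literal["standard-D65", "measured-source", "other"] = "other"

    def __post_init__(self) -> None:
        if min(self.X, self.Y, self.Z) <= 0:
            raise ValueError("white point components must be positive")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z])


D65 = WhitePoint(*D65_WHITE, role="standard-D65")
EQUAL_ENERGY = WhitePoint(*EQUAL_ENERGY_WHITE)


def gamma_decode(c):
    """Invert the sRGB transfer function: encoded channel → linear channel.

    Accepts scalars or arrays in [0, 1].  Below the 0.04045 threshold the
    function is linear (c / 12.92); above it, ((c + 0.055) / 1.055) ** 2.4.
    """
    arr = np.asarray(c, dtype=float)
    if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
        raise ValueError("encoded sRGB values must lie in [0, 1]")
    arr = np.clip(arr, 0.0, 1.0)
    out = np.where(
        arr <= SRGB_LINEAR_THRESHOLD,
        arr / SRGB_LINEAR_SLOPE,
        ((arr + SRGB_OFFSET) / (1 + SRGB_OFFSET)) ** SRGB_GAMMA,
    )
    return out if out.ndim else float(out)


def gamma_encode(c):
    """Forward sRGB transfer function: linear channel → encoded channel."""
    arr = np.asarray(c, dtype=float)
    if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
        raise ValueError("linear values must lie in [0, 1]")
    arr = np.clip(arr, 0.0, 1.0)
    thr = SRGB_LINEAR_THRESHOLD / SRGB_LINEAR_SLOPE
    out = np.where(
        arr <= thr,
        arr * SRGB_LINEAR_SLOPE,
        (1 + SRGB_OFFSET) * arr ** (1 / SRGB_GAMMA) - SRGB_OFFSET,
    )
    return out if out.ndim else float(out)


def linear_rgb_to_xyz(rgb, adaptation: np.ndarray | None = None) -> np.ndarray:
    """Map linear RGB in [0, 1] to XYZ on the 0–100 luminance scale.

    XYZ = M_A · T · rgb · 100, with T the standard sRGB(D65) primaries
    matrix and M_A an optional chromatic-adaptation matrix (identity by
    default).  ``rgb`` may be a single triplet or an (..., 3) array.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("expected RGB triplets on the last axis")
    m = SRGB_TO_XYZ if adaptation is None else np.asarray(adaptation) @ SRGB_TO_XYZ
    return rgb @ m.T * 100.0


def adaptation_matrix(source_white: WhitePoint, dest_white: WhitePoint) -> np.ndarray:
    """Bradford chromatic-adaptation matrix mapping one white onto another.

    Von Kries scaling in the Bradford cone space: the returned 3×3 matrix
    maps ``source_white`` exactly onto ``dest_white``.
    """
    cones_src = BRADFORD @ source_white.xyz
    cones_dst = BRADFORD @ dest_white.xyz
    if np.any(cones_src == 0):
        raise ValueError("degenerate source white in cone space")
    scale = np.diag(cones_dst / cones_src)
    return np.linalg.solve(BRADFORD, scale @ BRADFORD)


def spectrum_to_xyz(
    illuminant: SpectralCurve,
    reflectance: SpectralCurve,
    cmf: CMFSet = CIE_1931_2DEG,
) -> np.ndarray:
    """Tristimulus values of a reflectance under an illuminant.

    Normalised so a perfect reflector (R ≡ 1) has Y = 100 under any
    illuminant with non-zero ȳ overlap.
    """
    s = illuminant.values
    denom = float(np.sum(s * cmf.ybar))
    if denom <= 0:
        raise DegenerateIlluminantError("illuminant has no overlap with ybar")
    k = 100.0 / denom
    sr = s * reflectance.values
    return k * np.array(
        [np.sum(sr * cmf.xbar), np.sum(sr * cmf.ybar), np.sum(sr * cmf.zbar)]
    )


def spectra_to_xyz_matrix(
    illuminant: SpectralCurve,
    reflectances: np.ndarray,
    cmf: CMFSet = CIE_1931_2DEG,
) -> np.ndarray:
    """Vectorised form of :func:`spectrum_to_xyz` for an (n, 401) array."""
    s = illuminant.values
    denom = float(np.sum(s * cmf.ybar))
    if denom <= 0:
        raise DegenerateIlluminantError("illuminant has no overlap with ybar")
    k = 100.0 / denom
    weighted = cmf.as_matrix() * s  # 3×401
    return k * np.asarray(reflectances) @ weighted.T


def read_spectrum_csv(path, kind: str = "reflectance") -> SpectralCurve:
    """Read a two-column ``wavelength_nm,value`` CSV (header required)."""
    df = pd.read_csv(path)
    if not {"wavelength_nm", "value"}.issubset(df.columns):
        raise ValueError("spectrum CSV needs columns wavelength_nm,value")
    w = df["wavelength_nm"].to_numpy(dtype=float)
    if w.shape != WAVELENGTHS.shape or not np.allclose(w, WAVELENGTHS):
        raise ValueError("spectrum CSV must be on the 380–780 nm 1 nm grid")
    return SpectralCurve(df["value"].to_numpy(dtype=float), kind=kind)  # type: ignore[arg-type]


def write_spectrum_csv(curve: SpectralCurve, path) -> None:
    pd.DataFrame({"wavelength_nm": curve.wavelengths, "value": curve.values}).to_csv(
        path, index=False
    )
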