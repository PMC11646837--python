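"""Per-pixel spectral reconstruction, band-window analysis, and simulated
narrow-band imaging.

A fitted :class:`~vishsi.calibration.ConversionModel` is applied to every
pixel of an encoded RGB image: gamma decode → sRGB→XYZ (with optional
chromatic adaptation) → XYZ correction → PCA-score regression → 401-band
reflectance.  Pixels whose reconstruction is non-finite, or whose clipped
band fraction exceeds a threshold, are masked as failed transformations; a
frame with more than 20% masked pixels is flagged as failed.

Simulated NBI integrates the cube against two Gaussian passbands (default
centres 415 and 540 nm, 30 nm FWHM).  The 415 nm response — dominated by
superficial capillary absorption — drives the blue and green display
channels; the 540 nm response drives red.  The rendered image is min–max
normalised per image and sRGB-encoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._cie import N_BANDS, WAVELENGTHS
from .calibration import ConversionModel, expand_features, apply_correction
from .colorimetry import gamma_decode, gamma_encode, linear_rgb_to_xyz

__all__ = [
    "BandWindow",
    "NBIBandSpec",
    "HyperspectralCube",
    "convert_image",
    "band_slice",
    "region_spectrum",
    "simulate_nbi",
    "save_cube_envi",
    "load_cube_envi",
    "save_cube_npz",
    "load_cube_npz",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BandWindow:
    """Inclusive wavelength window, e.g. the 415–540 nm analysis band."""

    low_nm: float = 415.0
    high_nm: float = 540.0

    def __post_init__(self) -> None:
        if not (380.0 <= self.low_nm < self.high_nm <= 780.0):
            raise ValueError("window must satisfy 380 ≤ low < high ≤ 780")

    def indices(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.where((wavelengths >= self.low_nm) & (wavelengths <= self.high_nm))[0]


@dataclass(frozen=True)
class NBIBandSpec:
    """Two Gaussian passbands plus a display-channel mapping.

    ``mapping`` assigns each display channel (R, G, B) to passband index 0
    or 1; the default sends the first (415 nm) band to blue and green and
    the second (540 nm) band to red, mimicking narrow-band endoscope
    rendering.
    """

    centers_nm: tuple[float, float] = (415.0, 540.0)
    fwhm_nm: tuple[float, float] = (30.0, 30.0)
    mapping: tuple[int, int, int] = (1, 0, 0)  # display R,G,B ← passband index

    def __post_init__(self) -> None:
        for c in self.centers_nm:
            if not 380.0 <= c <= 780.0:
                raise ValueError("passband centre outside the grid")
        if min(self.fwhm_nm) <= 0:
            raise ValueError("FWHM must be positive")
        if any(m not in (0, 1) for m in self.mapping):
            raise ValueError("mapping entries must be 0 or 1")

    def weights(self, wavelengths: np.ndarray) -> np.ndarray:
        """2×n normalised Gaussian passband weights."""
        rows = []
        for c, fwhm in zip(self.centers_nm, self.fwhm_nm):
            sigma = fwhm * _FWHM_TO_SIGMA
            w = np.exp(-0.5 * ((wavelengths - c) / sigma) ** 2)
            rows.append(w / w.sum())
        return np.stack(rows)


@dataclass(frozen=True)
class HyperspectralCube:
    """H×W×bands reflectance image with a validity mask and provenance."""

    data: np.ndarray
    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTHS, repr=False)
    mask: np.ndarray | None = None  # True where the pixel is valid
    modality: str = "WLI"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != self.wavelengths.size:
            raise ValueError("cube shape must be H×W×n_bands matching the grid")
        if self.mask is not None and self.mask.shape != self.data.shape[:2]:
            raise ValueError("mask shape must match the image plane")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_masked(self) -> int:
        return 0 if self.mask is None else int((~self.mask).sum())

    @property
    def failed(self) -> bool:
        """A frame is a failed transformation when >20% of pixels are masked."""
        h, w, _ = self.data.shape
        return self.n_masked > 0.2 * h * w


def convert_image(
    image: np.ndarray,
    model: ConversionModel,
    adaptation: np.ndarray | None = None,
    clip_fraction_threshold: float = 0.5,
) -> HyperspectralCube:
    """Convert an encoded-RGB raster to a 401-band reflectance cube.

    ``image`` is H×W×3, either uint8 (0–255) or float in [0, 1], holding
    gamma-encoded sRGB.  Pixels whose reconstruction is non-finite or whose
    clipped band fraction exceeds ``clip_fraction_threshold`` are masked and
    counted in the cube provenance.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H×W×3 RGB image")
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    else:
        img = img.astype(float)
        if img.min() < -1e-9 or img.max() > 1 + 1e-9:
            raise ValueError("float images must be normalised to [0, 1]")
    h, w, _ = img.shape
    flat = img.reshape(-1, 3)
    xyz = linear_rgb_to_xyz(gamma_decode(flat), adaptation=adaptation)
    corrected = apply_correction(model.correction, xyz)
    feats = expand_features(corrected, model.score_expansion)
    scores = feats @ model.M.T
    spectra = model.basis.reconstruct(scores)
    finite = np.all(np.isfinite(spectra), axis=1)
    clipped_frac = np.mean((spectra < 0) | (spectra > 1), axis=1)
    valid = finite & (clipped_frac <= clip_fraction_threshold)
    if model.clip_reflectance:
        spectra = np.clip(spectra, 0.0, 1.0)
    spectra[~finite] = 0.0
    cube = HyperspectralCube(
        data=spectra.reshape(h, w, N_BANDS),
        mask=valid.reshape(h, w),
        modality=model.modality,
        provenance={
            "n_masked": int((~valid).sum()),
            "n_nonfinite": int((~finite).sum()),
            "clip_fraction_threshold": clip_fraction_threshold,
        },
    )
    return cube


def band_slice(cube: HyperspectralCube, window: BandWindow) -> HyperspectralCube:
    """Restrict a cube to an inclusive wavelength window (values unchanged)."""
    idx = window.indices(cube.wavelengths)
    if idx.size == 0:
        raise ValueError("band window does not intersect the cube grid")
    wl = cube.wavelengths[idx].copy()
    return replace(cube, data=cube.data[:, :, idx], wavelengths=wl)


def region_spectrum(
    cube: HyperspectralCube, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-band mean and standard deviation over a pixel region.

    Invalid (masked-out) cube pixels are excluded; the region must contain
    at least one valid pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("region mask shape must match the image plane")
    if cube.mask is not None:
        mask = mask & cube.mask
    if not mask.any():
        raise ValueError("empty region")
    pix = cube.data[mask]
    return pix.mean(axis=0), pix.std(axis=0)


def simulate_nbi(cube: HyperspectralCube, spec: NBIBandSpec = NBIBandSpec()) -> np.ndarray:
    """Render a simulated narrow-band image from a reflectance cube.

    Integrates each pixel spectrum against the two Gaussian passbands,
    maps the responses to display channels per ``spec.mapping``, min–max
    normalises over the whole image (joint across channels, preserving the
    channel ratios), gamma-encodes and returns a uint8 H×W×3 image.
    """
    w = spec.weights(cube.wavelengths)  # 2×n
    if np.any(w.sum(axis=1) <= 0):
        raise ValueError("degenerate passband")
    responses = cube.data @ w.T  # H×W×2
    img = responses[:, :, list(spec.mapping)]  # H×W×3
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        norm = np.full_like(img, 0.5)
    else:
        norm = (img - lo) / (hi - lo)
    encoded = gamma_encode(norm)
    return (np.round(encoded * 255)).astype(np.uint8)


# -- cube I/O --------------------------------------------------------------
# ENVI: plain-text .hdr companion + raw float32 BSQ binary.

def save_cube_envi(cube: HyperspectralCube, path) -> None:
    path = Path(path)
    raw = path.with_suffix(".img")
    h, w, b = cube.shape
    header = [
        "ENVI",
        "description = {vishsi reflectance cube}",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {b}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = {" + ", ".join(f"{x:g}" for x in cube.wavelengths) + "}",
    ]
    path.with_suffix(".hdr").write_text("\n".join(header) + "\n")
    np.ascontiguousarray(cube.data.transpose(2, 0, 1), dtype="<f4").tofile(raw)


def load_cube_envi(path, modality: str = "WLI") -> HyperspectralCube:
    path = Path(path)
    text = path.with_suffix(".hdr").read_text()
    fields: dict[str, str] = {}
    buf = text.replace("\n", " ")
    for key in ("samples", "lines", "bands", "interleave", "data type"):
        token = key + " ="
        if token not in buf:
            raise ValueError(f"missing ENVI header field: {key}")
        fields[key] = buf.split(token)[1].strip().split(" ")[0]
    if fields["interleave"].lower() != "bsq" or fields["data type"] != "4":
        raise ValueError("only float32 BSQ cubes are supported")
    w, h, b = int(fields["samples"]), int(fields["lines"]), int(fields["bands"])
    wl_str = buf.split("wavelength = {")[1].split("}")[0]
    wavelengths = np.array([float(x) for x in wl_str.split(",")])
    data = np.fromfile(path.with_suffix(".img"), dtype="<f4").reshape(b, h, w)
    return HyperspectralCube(
        data=data.transpose(1, 2, 0).astype(float),
        wavelengths=wavelengths,
        modality=modality,
    )


def save_cube_npz(cube: HyperspectralCube, path) -> None:
    np.savez_compressed(
        path,
        data=cube.data.astype(np.float32),
        wavelengths=cube.wavelengths,
        mask=cube.mask if cube.mask is not None else np.ones(cube.data.shape[:2], bool),
        modality=np.array(cube.modality),
    )


def load_cube_npz(path) -> HyperspectralCube:
    with np.load(path) as z:
        return HyperspectralCube(
            data=z["data"].astype(float),
            wavelengths=z["wavelengths"],
            mask=z["mask"],
            modality=str(z["modality"]),
        )
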