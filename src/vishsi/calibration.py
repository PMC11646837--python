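"""Color-checker calibration: correction matrix, spectral PCA basis, and the
XYZ → spectrum transformation matrix.

The calibration couples a trichromatic camera to a spectrometer through a
24-patch color checker.  Three fitted objects make up a conversion model:

* a **correction matrix** ``C`` (3×p) mapping a polynomial feature expansion
  of the camera-derived XYZ onto the spectrometer XYZ, fitted by least
  squares through the pseudoinverse, ``C = XYZ_spectrum · pinv(V)``;
* a **spectral basis** — mean-centred principal components of the 24
  measured reflectance spectra;
* a **transformation matrix** ``M`` (k×q) mapping a feature expansion of the
  corrected XYZ onto the PCA scores, again via the pseudoinverse.

Reconstruction of a spectrum from a camera XYZ triplet is then

    R̂(λ) = mean(λ) + B · M · v(C · v(XYZ))

with ``v(·)`` the monomial expansion and ``B`` the component matrix.  Both
regressions are affine (the expansions include a constant term), so the
whole reconstruction is affine in feature space.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import deltaE_ciede2000
from sklearn.decomposition import PCA

from ._cie import N_BANDS, WAVELENGTHS
from .colorimetry import CMFSet, CIE_1931_2DEG, SpectralCurve, WhitePoint, spectra_to_xyz_matrix

__all__ = [
    "ColorCheckerSet",
    "FeatureExpansion",
    "CorrectionModel",
    "SpectralBasis",
    "ConversionModel",
    "expand_features",
    "fit_correction",
    "apply_correction",
    "rmse",
    "fit_spectral_basis",
    "fit_transformation",
    "fit_conversion_model",
    "reconstruct_spectrum",
    "xyz_to_lab",
    "color_difference",
]

N_PATCHES = 24


@dataclass(frozen=True)
class ColorCheckerSet:
    """24 calibration patches: camera RGB, measured reflectance, measured XYZ.

    ``camera_rgb`` holds gamma-encoded values in [0, 1]; ``reflectances`` is
    a 24×401 array on the standard grid; ``spectrometer_xyz`` is 24×3 on the
    Y ≤ 100 scale.  Patch pairing is positional (row-major checker order)
    with explicit ids so a shuffled file is caught on read.
    """

    patch_ids: tuple
    camera_rgb: np.ndarray
    reflectances: np.ndarray
    spectrometer_xyz: np.ndarray

    def __post_init__(self) -> None:
        if len(self.patch_ids) != N_PATCHES:
            raise ValueError(f"expected {N_PATCHES} patches, got {len(self.patch_ids)}")
        if self.camera_rgb.shape != (N_PATCHES, 3):
            raise ValueError("camera_rgb must be 24×3")
        if self.reflectances.shape != (N_PATCHES, N_BANDS):
            raise ValueError(f"reflectances must be 24×{N_BANDS}")
        if self.spectrometer_xyz.shape != (N_PATCHES, 3):
            raise ValueError("spectrometer_xyz must be 24×3")
        r = self.reflectances
        if r.min() < -1e-9 or r.max() > 1 + 1e-9:
            raise ValueError("reflectances must lie in [0, 1]")


@dataclass(frozen=True)
class FeatureExpansion:
    """Ordered monomial expansion of (X, Y, Z) up to ``order``.

    Term order is deterministic: degree-1 terms X, Y, Z first, then for each
    higher degree the pure powers followed by the cross terms in
    lexicographic exponent order, and the constant term last.  Order 1 gives
    (X, Y, Z, 1); order 2 adds X², Y², Z², XY, XZ, YZ for 10 terms — small
    enough to be well determined by 24 patches.
    """

    order: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.order <= 3:
            raise ValueError("expansion order must be 1, 2 or 3")

    @property
    def exponents(self) -> list[tuple[int, int, int]]:
        terms: list[tuple[int, int, int]] = []
        for degree in range(1, self.order + 1):
            pure = [t for t in _monomials(degree) if max(t) == degree]
            cross = [t for t in _monomials(degree) if max(t) < degree]
            terms.extend(pure + cross)
        terms.append((0, 0, 0))
        return terms

    @property
    def n_terms(self) -> int:
        return len(self.exponents)


def _monomials(degree: int) -> list[tuple[int, int, int]]:
    out = []
    for i, j in itertools.product(range(degree, -1, -1), range(degree, -1, -1)):
        k = degree - i - j
        if k >= 0:
            out.append((i, j, k))
    return out


def expand_features(xyz, expansion: FeatureExpansion) -> np.ndarray:
    """Monomial feature vector(s) for XYZ triplet(s).

    Accepts a length-3 triplet or an (n, 3) array; returns length-p or
    (n, p) accordingly.
    """
    arr = np.atleast_2d(np.asarray(xyz, dtype=float))
    if arr.shape[-1] != 3 or not np.all(np.isfinite(arr)):
        raise ValueError("expected finite XYZ triplets")
    cols = [
        arr[:, 0] ** i * arr[:, 1] ** j * arr[:, 2] ** k
        for (i, j, k) in expansion.exponents
    ]
    out = np.stack(cols, axis=1)
    return out[0] if np.asarray(xyz).ndim == 1 else out


@dataclass(frozen=True)
class CorrectionModel:
    """Fitted XYZ correction: XYZ_correct = C · v(XYZ_camera)."""

    expansion: FeatureExpansion
    C: np.ndarray
    residual_rmse: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.C.shape != (3, self.expansion.n_terms):
            raise ValueError("C must be 3×p")
        if not np.all(np.isfinite(self.C)):
            raise ValueError("C must be finite")


def fit_correction(
    target_xyz: np.ndarray,
    camera_xyz: np.ndarray,
    expansion: FeatureExpansion = FeatureExpansion(),
) -> CorrectionModel:
    """Least-squares correction matrix via the pseudoinverse.

    ``C = target · pinv(V)`` with V the p×n matrix whose columns are the
    expanded camera XYZ features.  A rank-deficient V triggers a warning and
    yields the minimum-norm solution (pinv semantics).
    """
    target = np.asarray(target_xyz, dtype=float)
    cam = np.asarray(camera_xyz, dtype=float)
    if target.shape != cam.shape or target.shape[1] != 3:
        raise ValueError("target and camera XYZ must be matching n×3 arrays")
    V = expand_features(cam, expansion).T  # p×n
    if np.linalg.matrix_rank(V) < V.shape[0]:
        warnings.warn("rank-deficient feature matrix; using minimum-norm fit")
    C = target.T @ np.linalg.pinv(V)
    fitted = (C @ V).T
    per_patch = np.sqrt(np.mean((fitted - target) ** 2, axis=1))
    return CorrectionModel(expansion, C, residual_rmse=per_patch)


def apply_correction(model: CorrectionModel, xyz) -> np.ndarray:
    """Apply the fitted correction to triplet(s)."""
    feats = expand_features(xyz, model.expansion)
    return feats @ model.C.T


def rmse(a, b) -> float:
    """Root-mean-square difference of two equal-length vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass(frozen=True)
class SpectralBasis:
    """Mean-centred PCA basis of reflectance spectra."""

    mean: np.ndarray
    components: np.ndarray  # 401×k, orthonormal columns
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        gram = self.components.T @ self.components
        if np.abs(gram - np.eye(self.k)).max() > 1e-8:
            raise ValueError("components must be orthonormal")

    @property
    def k(self) -> int:
        return self.components.shape[1]

    def scores(self, spectra: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(spectra) - self.mean) @ self.components

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        return self.mean + np.atleast_2d(scores) @ self.components.T


def fit_spectral_basis(
    spectra: np.ndarray,
    k: int | None = None,
    variance_threshold: float = 0.999,
    max_k: int = 12,
) -> SpectralBasis:
    """PCA basis of a set of spectra.

    With ``k`` unset, the smallest number of components explaining at least
    ``variance_threshold`` of the variance is chosen, capped at ``max_k``.
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_BANDS:
        raise ValueError(f"spectra must be n×{N_BANDS}")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two spectra")
    max_rank = min(n - 1, N_BANDS)
    if k is not None and not 1 <= k <= max_rank:
        raise ValueError(f"k must be in [1, {max_rank}]")
    with np.errstate(invalid="ignore", divide="ignore"):  # zero-variance input
        pca = PCA(n_components=max_rank, svd_solver="full").fit(X)
    pca.explained_variance_ratio_ = np.nan_to_num(pca.explained_variance_ratio_)
    if k is None:
        evr = pca.explained_variance_ratio_
        cum = np.cumsum(evr)
        k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
        k = min(max(k, 1), max_k, max_rank)
    return SpectralBasis(
        mean=pca.mean_,
        components=pca.components_[:k].T,
        explained_variance_ratio=pca.explained_variance_ratio_[:k],
    )


@dataclass(frozen=True)
class ConversionModel:
    """Full camera-XYZ → reflectance-spectrum conversion model."""

    correction: CorrectionModel
    basis: SpectralBasis
    M: np.ndarray  # k×q
    score_expansion: FeatureExpansion
    band_window: tuple[float, float] = (380.0, 780.0)
    training_rmse: np.ndarray | None = None
    clip_reflectance: bool = True
    modality: str = "WLI"

    def __post_init__(self) -> None:
        if self.M.shape != (self.basis.k, self.score_expansion.n_terms):
            raise ValueError("M must be k×q")
        lo, hi = self.band_window
        if not (380.0 <= lo < hi <= 780.0):
            raise ValueError("band window must lie within 380–780 nm")

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "format": "vishsi-conversion-model",
            "version": 1,
            "modality": self.modality,
            "wavelength_nm": WAVELENGTHS.tolist(),
            "correction": {
                "order": self.correction.expansion.order,
                "C": self.correction.C.tolist(),
            },
            "basis": {
                "mean": self.basis.mean.tolist(),
                "components": self.basis.components.tolist(),
                "explained_variance_ratio": self.basis.explained_variance_ratio.tolist(),
            },
            "transformation": {
                "order": self.score_expansion.order,
                "M": self.M.tolist(),
            },
            "band_window": list(self.band_window),
            "clip_reflectance": self.clip_reflectance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ConversionModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "vishsi-conversion-model":
            raise ValueError("not a conversion-model file")
        corr = CorrectionModel(
            FeatureExpansion(payload["correction"]["order"]),
            np.array(payload["correction"]["C"]),
        )
        basis = SpectralBasis(
            mean=np.array(payload["basis"]["mean"]),
            components=np.array(payload["basis"]["components"]),
            explained_variance_ratio=np.array(
                payload["basis"]["explained_variance_ratio"]
            ),
        )
        return cls(
            correction=corr,
            basis=basis,
            M=np.array(payload["transformation"]["M"]),
            score_expansion=FeatureExpansion(payload["transformation"]["order"]),
            band_window=tuple(payload["band_window"]),
            clip_reflectance=payload["clip_reflectance"],
            modality=payload.get("modality", "WLI"),
        )


def fit_transformation(
    basis: SpectralBasis,
    corrected_xyz: np.ndarray,
    spectra: np.ndarray,
    expansion: FeatureExpansion = FeatureExpansion(),
    correction: CorrectionModel | None = None,
    band_window: tuple[float, float] = (380.0, 780.0),
    modality: str = "WLI",
) -> ConversionModel:
    """Fit the transformation matrix M from corrected XYZ to PCA scores.

    ``M = scores · pinv(V)`` with V the q×n expanded corrected-XYZ feature
    matrix.  The returned model records the per-patch RMSE between the
    simulated spectra (reconstructed through M) and the measured ones.
    """
    xyz = np.asarray(corrected_xyz, dtype=float)
    spectra = np.asarray(spectra, dtype=float)
    scores = basis.scores(spectra)  # n×k
    V = expand_features(xyz, expansion).T  # q×n
    if np.linalg.matrix_rank(V) < V.shape[0]:
        warnings.warn("rank-deficient feature matrix; using minimum-norm fit")
    M = scores.T @ np.linalg.pinv(V)  # k×q
    simulated = basis.reconstruct((M @ V).T)
    per_patch = np.sqrt(np.mean((simulated - spectra) ** 2, axis=1))
    if correction is None:
        correction = CorrectionModel(
            FeatureExpansion(1), np.hstack([np.eye(3), np.zeros((3, 1))])
        )
    return ConversionModel(
        correction=correction,
        basis=basis,
        M=M,
        score_expansion=expansion,
        band_window=band_window,
        training_rmse=per_patch,
        modality=modality,
    )


def fit_conversion_model(
    checker: ColorCheckerSet,
    camera_xyz: np.ndarray,
    illuminant: SpectralCurve | None = None,
    cmf: CMFSet = CIE_1931_2DEG,
    expansion: FeatureExpansion = FeatureExpansion(),
    k: int | None = None,
    xyz_target: str = "colorimetric",
    band_window: tuple[float, float] = (415.0, 540.0),
    modality: str = "WLI",
) -> ConversionModel:
    """End-to-end calibration from a color checker.

    ``xyz_target`` selects what the correction regresses onto: the
    illuminant-weighted colorimetric XYZ of the measured reflectances
    (``"colorimetric"``, requires ``illuminant``) or the spectrometer's own
    XYZ readings (``"spectrometer"``).
    """
    if xyz_target == "colorimetric":
        if illuminant is None:
            raise ValueError("colorimetric target requires an illuminant")
        target = spectra_to_xyz_matrix(illuminant, checker.reflectances, cmf)
    elif xyz_target == "spectrometer":
        target = checker.spectrometer_xyz
    else:
        raise ValueError("xyz_target must be 'colorimetric' or 'spectrometer'")
    correction = fit_correction(target, camera_xyz, expansion)
    corrected = apply_correction(correction, camera_xyz)
    basis = fit_spectral_basis(checker.reflectances, k=k)
    return fit_transformation(
        basis,
        corrected,
        checker.reflectances,
        expansion,
        correction=correction,
        band_window=band_window,
        modality=modality,
    )


def reconstruct_spectrum(model: ConversionModel, xyz, clip: bool | None = None):
    """Reconstruct reflectance spectrum(s) from camera XYZ triplet(s).

    Returns (spectra, clipped_fraction): clipping to [0, 1] is on by default
    (negative reflectance is unphysical) and the fraction of clipped bands
    per spectrum is reported alongside.
    """
    corrected = apply_correction(model.correction, xyz)
    feats = expand_features(corrected, model.score_expansion)
    scores = np.atleast_2d(feats) @ model.M.T
    spectra = model.basis.reconstruct(scores)
    do_clip = model.clip_reflectance if clip is None else clip
    clipped_frac = np.mean((spectra < 0) | (spectra > 1), axis=1)
    if do_clip:
        spectra = np.clip(spectra, 0.0, 1.0)
    if np.asarray(xyz).ndim == 1:
        return spectra[0], float(clipped_frac[0])
    return spectra, clipped_frac


# -- color difference -----------------------------------------------------

def xyz_to_lab(xyz, white: WhitePoint) -> np.ndarray:
    """CIE 1976 L*a*b* under an arbitrary reference white (Y scale 0–100)."""
    xyz = np.asarray(xyz, dtype=float)
    ratios = np.atleast_2d(xyz) / white.xyz

    def f(t):
        delta = 6.0 / 29.0
        return np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)

    fx, fy, fz = f(ratios[:, 0]), f(ratios[:, 1]), f(ratios[:, 2])
    lab = np.stack([116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)], axis=1)
    return lab[0] if xyz.ndim == 1 else lab


def color_difference(a, b, white: WhitePoint, method: str = "ciede2000") -> float:
    """Perceptual color difference between two XYZ triplets.

    ``method`` is ``"ciede2000"`` (default) or ``"cie76"`` (Euclidean ΔE*ab).
    """
    lab_a = xyz_to_lab(a, white)
    lab_b = xyz_to_lab(b, white)
    if method == "cie76":
        return float(np.linalg.norm(lab_a - lab_b))
    if method == "ciede2000":
        return float(deltaE_ciede2000(lab_a[np.newaxis, :], lab_b[np.newaxis, :])[0])
    raise ValueError("method must be 'ciede2000' or 'cie76'")
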