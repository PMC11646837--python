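"""Synthetic fixtures for every stage of the pipeline.

Generates color-checker calibration sets, illuminants, lesion scenes with
class-dependent tissue spectra, and frame-level detector outputs with
controlled error rates — everything needed to exercise calibration,
conversion, band analysis and evaluation without any external data.

Spectral construction.  All reflectances live in a shared smooth basis: a
fixed low baseline plus three broad Gaussian endmembers centred at 450, 550
and 650 nm.  Each checker patch and each tissue class is a positive mixture
of the three endmembers, so every generated spectrum is a 3-component
Gaussian mixture with three chromatic degrees of freedom.  Three degrees of
freedom is exactly what a trichromatic camera can measure, which makes the
noiseless calibration round trip exact — the closed-loop recovery tests
rest on this.  Mixing weights are bounded so spectra stay inside
[0.02, 0.95] by construction (no clipping, preserving linearity).

Tissue classes.  The three classes (normal, dysplasia, SCC) differ chiefly
in their 415–540 nm reflectivity — normal mucosa highest, carcinoma lowest,
emulating the increased superficial microvascular absorption of neoplastic
tissue in exactly the band the analysis window targets.

Camera.  Forward model: XYZ → linear sRGB → 3×3 channel mixing → optional
per-channel quadratic distortion → additive Gaussian noise → gamma encode.
All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._cie import N_BANDS, SRGB_TO_XYZ, WAVELENGTHS
from .calibration import ColorCheckerSet
from .colorimetry import SpectralCurve, gamma_encode, spectra_to_xyz_matrix
from .detection_eval import CLASSES, SEVERITY, BoundingBox, ConfusionMatrix3, FrameRecord

__all__ = [
    "ENDMEMBER_CENTERS",
    "endmembers",
    "SyntheticCameraModel",
    "TissueClassSpec",
    "default_tissue_specs",
    "LesionSpec",
    "SceneSpec",
    "SceneResult",
    "make_color_checker",
    "make_illuminant",
    "make_scene",
    "make_detections",
    "frames_from_confusion_matrix",
]

ENDMEMBER_CENTERS = (450.0, 550.0, 650.0)
_ENDMEMBER_WIDTHS = (55.0, 60.0, 65.0)
_BASELINE = 0.03
_MAX_WEIGHT = 0.55


def endmembers() -> np.ndarray:
    """3×401 smooth Gaussian endmember reflectance components."""
    rows = [
        np.exp(-0.5 * ((WAVELENGTHS - c) / s) ** 2)
        for c, s in zip(ENDMEMBER_CENTERS, _ENDMEMBER_WIDTHS)
    ]
    return np.stack(rows)


def _weights_to_spectra(weights: np.ndarray) -> np.ndarray:
    """(n, 3) mixing weights → (n, 401) reflectances in [0.02, 0.95]."""
    spectra = _BASELINE + np.atleast_2d(weights) @ endmembers()
    return np.clip(spectra, 0.02, 0.95)  # guard; inactive for bounded weights


@dataclass(frozen=True)
class SyntheticCameraModel:
    """Trichromatic camera forward model: gamma + matrix + noise.

    ``mixing`` is the 3×3 channel cross-talk matrix in linear RGB
    (invertible; default a mild departure from identity).  ``distortion``
    optionally adds a per-channel quadratic term a·c².  ``noise_sigma`` is
    the additive Gaussian noise s.d. in linear RGB, applied before gamma
    encoding.
    """

    mixing: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.95, 0.04, 0.01], [0.03, 0.94, 0.03], [0.02, 0.05, 0.93]]
        )
    )
    distortion: np.ndarray | None = None
    noise_sigma: float = 0.0
    apply_gamma: bool = True

    def __post_init__(self) -> None:
        m = np.asarray(self.mixing, dtype=float)
        if m.shape != (3, 3) or abs(np.linalg.det(m)) < 1e-9:
            raise ValueError("mixing matrix must be 3×3 and invertible")
        object.__setattr__(self, "mixing", m)
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")

    def render_xyz(self, xyz: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Scene XYZ (Y scale 0–100) → encoded RGB in [0, 1]."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        lin = (xyz / 100.0) @ np.linalg.inv(SRGB_TO_XYZ).T
        lin = lin @ self.mixing.T
        if self.distortion is not None:
            lin = lin + lin**2 * np.asarray(self.distortion)
        if self.noise_sigma > 0:
            if rng is None:
                raise ValueError("noisy rendering requires an RNG")
            lin = lin + rng.normal(0.0, self.noise_sigma, lin.shape)
        lin = np.clip(lin, 0.0, 1.0)
        return gamma_encode(lin) if self.apply_gamma else lin

    def render_reflectances(
        self,
        reflectances: np.ndarray,
        illuminant: SpectralCurve,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        xyz = spectra_to_xyz_matrix(illuminant, reflectances)
        return self.render_xyz(xyz, rng=rng)


def make_illuminant(kind: str = "broadband", seed: int = 0) -> SpectralCurve:
    """Synthetic illuminant spectrum.

    ``flat``: constant power.  ``broadband``: smooth strictly positive
    white-light-like curve.  ``dual-narrowband``: Gaussian lines at 415 and
    540 nm with 30 nm FWHM, emulating narrow-band endoscopic illumination.
    """
    rng = np.random.default_rng(seed)
    lam = WAVELENGTHS
    if kind == "flat":
        vals = np.ones(N_BANDS)
    elif kind == "broadband":
        amp = 0.4 + 0.2 * rng.random()
        center = 470 + 40 * rng.random()
        vals = 0.6 + amp * np.exp(-0.5 * ((lam - center) / 130.0) ** 2)
    elif kind == "dual-narrowband":
        sigma = 30.0 / (2 * np.sqrt(2 * np.log(2)))
        vals = np.exp(-0.5 * ((lam - 415.0) / sigma) ** 2) + np.exp(
            -0.5 * ((lam - 540.0) / sigma) ** 2
        )
    else:
        raise ValueError("kind must be flat, broadband or dual-narrowband")
    return SpectralCurve(vals, kind="radiance")


_CHECKER_IDS = tuple(f"patch_{i:02d}" for i in range(1, 25))


def make_color_checker(
    seed: int = 0,
    camera: SyntheticCameraModel | None = None,
    illuminant: SpectralCurve | None = None,
) -> tuple[ColorCheckerSet, SpectralCurve]:
    """24-patch synthetic color checker.

    Returns the checker (reflectances, spectrometer XYZ, rendered camera
    RGB) together with the illuminant used, so calibration can regress onto
    illuminant-weighted colorimetry.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    camera = camera or SyntheticCameraModel()
    illuminant = illuminant or make_illuminant("broadband", seed=seed)
    weights = rng.uniform(0.05, _MAX_WEIGHT, size=(24, 3))
    reflectances = _weights_to_spectra(weights)
    xyz = spectra_to_xyz_matrix(illuminant, reflectances)
    rgb = camera.render_xyz(xyz, rng=rng if camera.noise_sigma > 0 else None)
    checker = ColorCheckerSet(
        patch_ids=_CHECKER_IDS,
        camera_rgb=rgb,
        reflectances=reflectances,
        spectrometer_xyz=xyz,
    )
    return checker, illuminant


# -- tissue classes and scenes --------------------------------------------

@dataclass(frozen=True)
class TissueClassSpec:
    """Spectral description of one tissue class.

    ``weights`` are the endmember mixing weights of the class mean spectrum;
    ``weight_sigma`` is the within-class s.d. of per-pixel weight jitter.
    The default specs order mean 415–540 nm reflectivity
    normal > dysplasia > SCC.
    """

    name: str
    weights: tuple[float, float, float]
    weight_sigma: float = 0.015

    def __post_init__(self) -> None:
        if self.name not in CLASSES:
            raise ValueError(f"unknown tissue class {self.name!r}")
        if min(self.weights) < 0.02 or max(self.weights) > _MAX_WEIGHT + 0.03:
            raise ValueError("weights outside the in-gamut range")

    @property
    def mean_spectrum(self) -> np.ndarray:
        return _weights_to_spectra(np.asarray(self.weights))[0]

    def band_mean(self, low_nm: float = 415.0, high_nm: float = 540.0) -> float:
        sel = (WAVELENGTHS >= low_nm) & (WAVELENGTHS <= high_nm)
        return float(self.mean_spectrum[sel].mean())

    def sample_weights(self, n: int, rng: np.random.Generator) -> np.ndarray:
        w = np.asarray(self.weights) + rng.normal(0, self.weight_sigma, size=(n, 3))
        return np.clip(w, 0.02, _MAX_WEIGHT + 0.03)


def default_tissue_specs() -> dict[str, TissueClassSpec]:
    return {
        "normal": TissueClassSpec("normal", (0.50, 0.45, 0.20)),
        "dysplasia": TissueClassSpec("dysplasia", (0.30, 0.35, 0.30)),
        "scc": TissueClassSpec("scc", (0.12, 0.25, 0.40)),
    }


@dataclass(frozen=True)
class LesionSpec:
    """An elliptical lesion: class label plus centre/axes in pixels."""

    label: str
    cx: float
    cy: float
    rx: float
    ry: float

    def __post_init__(self) -> None:
        if self.label not in ("dysplasia", "scc"):
            raise ValueError("lesions are dysplasia or scc")
        if min(self.rx, self.ry) <= 0:
            raise ValueError("degenerate lesion")


@dataclass(frozen=True)
class SceneSpec:
    height: int = 48
    width: int = 64
    lesions: tuple[LesionSpec, ...] = ()
    background: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        for les in self.lesions:
            if not (0 <= les.cx < self.width and 0 <= les.cy < self.height):
                raise ValueError("lesion centre outside the frame")


@dataclass(frozen=True)
class SceneResult:
    image: np.ndarray  # H×W×3 uint8, encoded RGB
    boxes: tuple[BoundingBox, ...]
    class_map: np.ndarray  # H×W int, index into CLASSES
    reflectances: np.ndarray  # H×W×401 float32, ground-truth spectra


def make_scene(
    spec: SceneSpec,
    tissue: dict[str, TissueClassSpec] | None = None,
    camera: SyntheticCameraModel | None = None,
    illuminant: SpectralCurve | None = None,
) -> SceneResult:
    """Render a synthetic endoscopic-style frame.

    Elliptical lesions are painted onto a background class; where lesions
    overlap, the most severe class wins.  Each pixel draws a spectrum from
    its class distribution, XYZ follows from the illuminant-weighted
    colorimetry, and the camera renders encoded RGB.  A tight bounding box
    is emitted per lesion over the pixels it actually owns.
    """
    rng = np.random.default_rng(spec.seed)
    tissue = tissue or default_tissue_specs()
    camera = camera or SyntheticCameraModel()
    illuminant = illuminant or make_illuminant("broadband", seed=spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    class_map = np.full((h, w), CLASSES.index(spec.background), dtype=int)
    lesion_masks = []
    for les in spec.lesions:
        inside = ((xx - les.cx) / les.rx) ** 2 + ((yy - les.cy) / les.ry) ** 2 <= 1.0
        lesion_masks.append(inside)
        sev = SEVERITY[les.label]
        class_map = np.where(inside & (class_map < sev), sev, class_map)

    weights = np.zeros((h * w, 3))
    flat_map = class_map.ravel()
    for ci, cname in enumerate(CLASSES):
        sel = flat_map == ci
        if sel.any():
            weights[sel] = tissue[cname].sample_weights(int(sel.sum()), rng)
    reflectances = _weights_to_spectra(weights)
    xyz = spectra_to_xyz_matrix(illuminant, reflectances)
    rgb = camera.render_xyz(xyz, rng=rng if camera.noise_sigma > 0 else None)
    image = np.round(rgb.reshape(h, w, 3) * 255).astype(np.uint8)

    boxes = []
    for les, inside in zip(spec.lesions, lesion_masks):
        owned = inside & (class_map == SEVERITY[les.label])
        if not owned.any():
            continue  # fully overridden by a more severe overlapping lesion
        ys, xs = np.nonzero(owned)
        boxes.append(
            BoundingBox(
                label=les.label,
                x_min=float(xs.min()),
                y_min=float(ys.min()),
                x_max=float(xs.max() + 1),
                y_max=float(ys.max() + 1),
            )
        )
    return SceneResult(
        image=image,
        boxes=tuple(boxes),
        class_map=class_map,
        reflectances=reflectances.reshape(h, w, N_BANDS).astype(np.float32),
    )


# -- detector-output simulation -------------------------------------------

def _jittered_box(box: BoundingBox, label: str, rng: np.random.Generator) -> BoundingBox:
    """Perturb a truth box while keeping IoU ≥ 0.5 by construction.

    Shifts each edge by at most 8% of the box size, which bounds the IoU
    with the original box well above the 0.5 matching threshold.
    """
    bw, bh = box.x_max - box.x_min, box.y_max - box.y_min
    d = rng.uniform(-0.08, 0.08, size=4)
    return BoundingBox(
        label=label,
        x_min=box.x_min + d[0] * bw,
        y_min=box.y_min + d[1] * bh,
        x_max=box.x_max + d[2] * bw,
        y_max=box.y_max + d[3] * bh,
        confidence=float(rng.uniform(0.6, 0.99)),
    )


def make_detections(
    records,
    sensitivity: float = 0.85,
    class_confusion: dict[str, dict[str, float]] | None = None,
    false_positive_rate: float = 0.08,
    seed: int = 0,
    deterministic: bool = False,
    frame_size: tuple[int, int] = (480, 640),
) -> list[FrameRecord]:
    """Simulate detector outputs over truth-only frame records.

    Each neoplasm frame is detected with probability ``sensitivity`` (the
    emitted box keeps IoU ≥ 0.5 with the truth); a detected frame's class
    is drawn from ``class_confusion[true_class]`` (defaults to the correct
    class).  Normal frames receive a spurious detection with probability
    ``false_positive_rate``.  With ``deterministic=True``, per-class
    outcome counts are allocated exactly (largest-remainder rounding of the
    expected counts) instead of sampled, so fixtures reproduce target
    tables without sampling noise.
    """
    if not 0 <= sensitivity <= 1 or not 0 <= false_positive_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    class_confusion = class_confusion or {}
    records = list(records)
    h, w = frame_size

    def confusion_row(true_label: str) -> tuple[list[str], np.ndarray]:
        row = class_confusion.get(true_label, {true_label: 1.0})
        labels = list(row)
        probs = np.array([row[k] for k in labels], dtype=float)
        return labels, probs / probs.sum()

    # group frames by true class for deterministic allocation
    out: dict[str, FrameRecord] = {}
    by_class: dict[str, list[FrameRecord]] = {c: [] for c in CLASSES}
    for rec in records:
        labels = [b.label for b in rec.truths]
        true = max(labels, key=SEVERITY.__getitem__) if labels else "normal"
        by_class[true].append(rec)

    def allocate(n: int, probs: np.ndarray) -> np.ndarray:
        """Largest-remainder integer allocation of n slots to probs."""
        raw = probs * n
        base = np.floor(raw).astype(int)
        rem = n - base.sum()
        order = np.argsort(-(raw - base))
        base[order[:rem]] += 1
        return base

    for true_label, group in by_class.items():
        n = len(group)
        if n == 0:
            continue
        if true_label == "normal":
            if deterministic:
                n_fp = int(np.round(false_positive_rate * n))
                fp_flags = np.array([True] * n_fp + [False] * (n - n_fp))
            else:
                fp_flags = rng.random(n) < false_positive_rate
            for rec, is_fp in zip(group, fp_flags):
                preds = ()
                if is_fp:
                    bw, bh = rng.uniform(0.1, 0.3, 2) * (w, h)
                    x0 = rng.uniform(0, w - bw)
                    y0 = rng.uniform(0, h - bh)
                    label = rng.choice(["dysplasia", "scc"])
                    preds = (
                        BoundingBox(label, x0, y0, x0 + bw, y0 + bh,
                                    confidence=float(rng.uniform(0.5, 0.9))),
                    )
                out[rec.frame_id] = FrameRecord(
                    rec.frame_id, rec.truths, preds, rec.modality
                )
            continue
        labels, probs = confusion_row(true_label)
        # outcome alphabet: missed, or detected-as-label
        if deterministic:
            n_det = int(np.round(sensitivity * n))
            det_labels = np.concatenate(
                [np.repeat(labels, allocate(n_det, probs)), [""] * (n - n_det)]
            )
        else:
            detected = rng.random(n) < sensitivity
            det_labels = np.array(
                [rng.choice(labels, p=probs) if d else "" for d in detected]
            )
        for rec, lab in zip(group, det_labels):
            preds = ()
            if lab:
                target = max(rec.truths, key=lambda b: SEVERITY[b.label])
                preds = (_jittered_box(target, str(lab), rng),)
            out[rec.frame_id] = FrameRecord(rec.frame_id, rec.truths, preds, rec.modality)
    return [out[r.frame_id] for r in records]


def frames_from_confusion_matrix(
    cm: ConfusionMatrix3,
    seed: int = 0,
    frame_size: tuple[int, int] = (480, 640),
    modality: str = "WLI",
) -> list[FrameRecord]:
    """Emit frame records whose evaluation reproduces a confusion matrix
    exactly (deterministic count allocation, no sampling).

    For each (true, predicted) cell the stated number of frames is built:
    neoplasm truths get one ground-truth box; predicted-neoplasm outcomes
    get one matching (IoU ≥ 0.5) or, on normal frames, one spurious box.
    """
    rng = np.random.default_rng(seed)
    h, w = frame_size
    records: list[FrameRecord] = []
    counter = 0
    for i, true_label in enumerate(CLASSES):
        for j, pred_label in enumerate(CLASSES):
            for _ in range(int(cm.counts[i, j])):
                counter += 1
                fid = f"frame_{counter:05d}"
                truths: tuple[BoundingBox, ...] = ()
                preds: tuple[BoundingBox, ...] = ()
                if true_label != "normal":
                    bw, bh = rng.uniform(0.2, 0.4, 2) * (w, h)
                    x0 = rng.uniform(0, w - bw)
                    y0 = rng.uniform(0, h - bh)
                    tbox = BoundingBox(true_label, x0, y0, x0 + bw, y0 + bh)
                    truths = (tbox,)
                    if pred_label != "normal":
                        preds = (_jittered_box(tbox, pred_label, rng),)
                elif pred_label != "normal":
                    bw, bh = rng.uniform(0.1, 0.3, 2) * (w, h)
                    x0 = rng.uniform(0, w - bw)
                    y0 = rng.uniform(0, h - bh)
                    preds = (
                        BoundingBox(pred_label, x0, y0, x0 + bw, y0 + bh,
                                    confidence=float(rng.uniform(0.5, 0.9))),
                    )
                records.append(FrameRecord(fid, truths, preds, modality))
    return records
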