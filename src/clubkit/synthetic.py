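"""Synthetic fingertip-profile renderer with exact Lovibond-angle ground truth.

Every downstream stage (segmentation, orientation, landmark detection,
angle computation, grading, gating) is tested against images whose
geometry is known analytically.  The finger is modelled in millimetres in
a canonical pose (tip toward +x, dorsal side toward -y of a y-down raster)
as a capsule shaft with a circular tip bulb and a two-segment dorsal
polyline: shaft line A -> B (proximal nail fold) and nail plate B -> C.
The turn at B realises the requested Lovibond angle exactly *before*
rasterization, so the ground-truth landmarks and angle are free of pixel
error.  A pinhole camera (focal length in pixels) converts millimetres to
pixels at the requested capture distance.

The generator's defaults are the package's study conditions — they are not
tuned per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage.draw import polygon2mask

from .cfsa import SeverityGrade, SeverityThresholds, DEFAULT_THRESHOLDS, grade_severity
from .errors import ValidationError
from .landmarks import LandmarkTriplet
from .preprocess import CameraModel

__all__ = [
    "FingerProfileSpec",
    "SyntheticSample",
    "AugmentationParams",
    "render_finger_profile",
    "sample_dataset",
    "augment",
    "DEFAULT_ANGLE_RANGES",
    "DEFAULT_BULB_RANGES",
]

_BG = 0.15
_FG = 0.75
_MARGIN_MM = 3.5


@dataclass(frozen=True)
class FingerProfileSpec:
    """Parameters of one rendered profile.

    lovibond_angle_deg: profile angle at the nail fold, (90, 270).
    finger_width_mm:    shaft width seen in profile (default 16 mm).
    nail_length_mm:     visible nail-plate length from the fold (12 mm).
    tip_bulb_ratio:     fingertip bulb radius / shaft half-width, >= 1;
                        grows with clubbing severity.
    distance_cm:        simulated finger-to-camera distance on [1, 10];
                        sets pixels-per-mm through the camera model.
    brightness:         multiplicative factor on the finger intensity, [0,1].
    noise_sigma:        additive Gaussian noise std (intensity units, >=0).
    orientation_deg:    in-plane rotation applied to the whole scene.
    flip:               mirror the scene in x (other-hand view).
    seed:               RNG seed for the noise field.
    """

    lovibond_angle_deg: float
    finger_width_mm: float = 16.0
    nail_length_mm: float = 12.0
    tip_bulb_ratio: float = 1.15
    distance_cm: float = 5.0
    brightness: float = 1.0
    noise_sigma: float = 0.01
    orientation_deg: float = 0.0
    flip: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 90.0 < self.lovibond_angle_deg < 270.0:
            raise ValidationError("lovibond_angle_deg", "must lie in (90, 270)")
        for name in ("finger_width_mm", "nail_length_mm"):
            if not getattr(self, name) > 0:
                raise ValidationError(name, "must be strictly positive")
        if not self.tip_bulb_ratio >= 1.0:
            raise ValidationError("tip_bulb_ratio", "must be >= 1")
        if not 1.0 <= self.distance_cm <= 10.0:
            raise ValidationError("distance_cm", "must lie in [1, 10]")
        if not 0.0 <= self.brightness <= 1.0:
            raise ValidationError("brightness", "must lie in [0, 1]")
        if not self.noise_sigma >= 0:
            raise ValidationError("noise_sigma", "must be >= 0")


@dataclass
class SyntheticSample:
    """A rendered profile plus its exact ground truth."""

    image: np.ndarray                 # uint8 grayscale, HxW
    silhouette: np.ndarray            # bool, the true foreground raster
    truth_landmarks: LandmarkTriplet  # image pixel coordinates
    truth_angle_deg: float
    truth_grade: SeverityGrade
    bbox: tuple                       # (x0, y0, x1, y1), half-open
    distance_cm: float
    spec: FingerProfileSpec
    sub_seed: int = 0

    def to_sidecar(self) -> dict:
        return {
            "landmarks": self.truth_landmarks.to_dict(),
            "angle_deg": self.truth_angle_deg,
            "grade": str(self.truth_grade),
            "bbox": list(self.bbox),
            "distance_cm": self.distance_cm,
            "seed": self.spec.seed,
        }


@dataclass(frozen=True)
class AugmentationParams:
    """Training-time augmentation recipe: flip, brightness +/-20%, scale +/-10%."""

    flip_horizontal: bool = False
    brightness_delta: float = 0.0
    scale_factor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not -0.20 <= self.brightness_delta <= 0.20:
            raise ValidationError("brightness_delta", "must lie in [-0.20, 0.20]")
        if not 0.90 <= self.scale_factor <= 1.10:
            raise ValidationError("scale_factor", "must lie in [0.90, 1.10]")

    @staticmethod
    def sample(seed: int) -> "AugmentationParams":
        rng = np.random.default_rng(seed)
        return AugmentationParams(
            flip_horizontal=bool(rng.integers(2)),
            brightness_delta=float(rng.uniform(-0.20, 0.20)),
            scale_factor=float(rng.uniform(0.90, 1.10)),
            seed=seed,
        )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _profile_polygon_mm(spec: FingerProfileSpec):
    """Silhouette polygon and landmark triplet in canonical millimetres.

    Canonical pose: centreline y = 0, dorsal side y < 0, tip toward +x.
    Returns (polygon_vertices (N,2), landmarks (3,2)).
    """
    w = spec.finger_width_mm
    h = w / 2.0
    R = spec.tip_bulb_ratio * h
    L = spec.nail_length_mm
    x_bulb = 1.75 * w                       # bulb centre
    standoff = 0.25 * L
    xB = x_bulb - R - standoff
    B = np.array([xB, -h])
    tau = np.radians(180.0 - spec.lovibond_angle_deg)
    v_hat = np.array([np.cos(tau), np.sin(tau)])
    P = B + L * v_hat                       # nail-plate distal end
    A = B - np.array([0.35 * L, 0.0])       # nail matrix, on the fold line
    C = B + 0.5 * L * v_hat                 # nail plate landmark
    if A[0] <= 0.5:
        raise ValidationError(
            "tip_bulb_ratio", "geometry infeasible: bulb leaves no room for the shaft"
        )

    # palmar side: straight shaft line, a fillet arc blending into the bulb
    # (a bare line-circle junction would leave an anatomically wrong notch),
    # then the palmar arc of the bulb to the distal extreme
    r_f = 0.25 * w
    O = np.array([x_bulb, 0.0])
    dx = np.sqrt(max(0.0, (R + r_f) ** 2 - (h + r_f) ** 2))
    C_f = np.array([x_bulb - dx, h + r_f])      # fillet centre, in the notch
    L_t = np.array([x_bulb - dx, h])            # tangency on the shaft line
    to_f = C_f - O
    T_b = O + R * to_f / np.linalg.norm(to_f)   # tangency on the bulb circle
    phi_b = np.arctan2(T_b[1], T_b[0] - x_bulb)
    phis = np.linspace(0.0, phi_b, 40)[1:]
    arc_bulb = np.column_stack([x_bulb + R * np.cos(phis), R * np.sin(phis)])
    a2 = np.arctan2(T_b[1] - C_f[1], T_b[0] - C_f[0])
    fillet = np.linspace(a2, -np.pi / 2, 12)[1:]
    arc_fillet = np.column_stack(
        [C_f[0] + r_f * np.cos(fillet), C_f[1] + r_f * np.sin(fillet)]
    )

    verts = [
        [0.0, -h],          # proximal dorsal corner (flat cut)
        B.tolist(),
        P.tolist(),
        [x_bulb + R, 0.0],  # distal extreme
        *arc_bulb.tolist(),
        *arc_fillet.tolist(),
        L_t.tolist(),
        [0.0, h],           # proximal palmar corner
    ]
    poly = Polygon(verts)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
    verts = np.asarray(poly.exterior.coords)[:-1]
    return verts, np.vstack([A, B, C])


def _scene_transform(spec: FingerProfileSpec, verts_mm, marks_mm):
    """mm -> pixel coordinates with rotation, flip and margin translation."""
    cam = CameraModel()
    ppm = cam.pixels_per_mm(spec.distance_cm)
    verts = verts_mm * ppm
    marks = marks_mm * ppm
    centre = 0.5 * (verts.min(axis=0) + verts.max(axis=0))
    a = np.radians(spec.orientation_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    verts = (verts - centre) @ rot.T
    marks = (marks - centre) @ rot.T
    if spec.flip:
        verts[:, 0] *= -1
        marks[:, 0] *= -1
    margin = _MARGIN_MM * ppm
    shift = margin - verts.min(axis=0)
    verts += shift
    marks += shift
    size = np.ceil(verts.max(axis=0) + margin).astype(int)  # (W, H)
    return verts, marks, (int(size[1]), int(size[0]))


def _rasterize(verts_px: np.ndarray, shape, supersample: int) -> np.ndarray:
    """Anti-aliased coverage raster of the silhouette polygon on [0, 1]."""
    ss = supersample
    big = (shape[0] * ss, shape[1] * ss)
    poly_rc = (verts_px[:, ::-1] + 0.5) * ss - 0.5  # (x,y) -> (row,col), pixel centres
    m = polygon2mask(big, poly_rc)
    if ss == 1:
        return m.astype(float)
    return m.reshape(shape[0], ss, shape[1], ss).mean(axis=(1, 3))


def render_finger_profile(spec: FingerProfileSpec) -> SyntheticSample:
    """Render one profile image with exact landmark/angle/grade ground truth.

    Identical spec (including seed) gives a bit-identical sample.
    """
    verts_mm, marks_mm = _profile_polygon_mm(spec)
    verts, marks, shape = _scene_transform(spec, verts_mm, marks_mm)

    ppm = CameraModel().pixels_per_mm(spec.distance_cm)
    ss = 2 if ppm <= 40 else 1  # coarse images benefit most from anti-aliasing
    coverage = _rasterize(verts, shape, ss)

    fg = _FG * spec.brightness
    img = _BG + (fg - _BG) * coverage
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    image = np.round(img * 255.0).astype(np.uint8)

    silhouette = coverage >= 0.5
    x0, y0 = np.floor(verts.min(axis=0)).astype(int)
    x1, y1 = np.floor(verts.max(axis=0)).astype(int) + 1
    bbox = (int(x0), int(y0), int(x1), int(y1))

    return SyntheticSample(
        image=image,
        silhouette=silhouette,
        truth_landmarks=LandmarkTriplet.from_array(marks),
        truth_angle_deg=float(spec.lovibond_angle_deg),
        truth_grade=grade_severity(spec.lovibond_angle_deg),
        bbox=bbox,
        distance_cm=spec.distance_cm,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

# Study conditions: per-grade angle ranges keep a safety margin from the
# grade boundaries (ranges straddling a boundary are rejected), and bulb
# prominence grows with severity as it does clinically.
DEFAULT_ANGLE_RANGES = {
    "normal": (146.0, 159.5),
    "mild": (161.0, 178.0),
    "moderate": (179.3, 180.7),
    "severe": (182.0, 212.0),
}
DEFAULT_BULB_RANGES = {
    "normal": (1.0, 1.12),
    "mild": (1.1, 1.3),
    "moderate": (1.25, 1.45),
    "severe": (1.4, 1.8),
}


def _check_ranges(angle_ranges: dict, thresholds: SeverityThresholds) -> None:
    for grade, (lo, hi) in angle_ranges.items():
        eps = 1e-9
        g_lo = grade_severity(lo + eps, thresholds)
        g_hi = grade_severity(hi - eps, thresholds)
        if not (str(g_lo) == str(g_hi) == grade):
            raise ValidationError(
                "angle_ranges", f"range {lo}-{hi} straddles a boundary of '{grade}'"
            )


def sample_dataset(
    n: int,
    grade_mix=(0.25, 0.25, 0.25, 0.25),
    angle_ranges: dict = None,
    seed: int = 0,
    distance_range=(4.0, 7.0),
    noise_sigma: float = 0.01,
    thresholds: SeverityThresholds = DEFAULT_THRESHOLDS,
    render: bool = True,
):
    """Draw a deterministic cohort of synthetic samples.

    Grades are drawn from ``grade_mix`` (must sum to 1), angles uniformly
    within the sampled grade's range, distances uniformly in
    ``distance_range``.  Returns (samples, manifest DataFrame); with
    ``render=False`` the samples list is empty and only the manifest (id,
    angle, grade, distance, per-sample sub-seed) is produced.
    """
    mix = np.asarray(grade_mix, dtype=float)
    if mix.shape != (4,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValidationError("grade_mix", "must be 4 non-negative values summing to 1")
    ranges = dict(DEFAULT_ANGLE_RANGES if angle_ranges is None else angle_ranges)
    _check_ranges(ranges, thresholds)

    rng = np.random.default_rng(seed)
    grades = [str(g) for g in ["normal", "mild", "moderate", "severe"]]
    samples, rows = [], []
    for i in range(int(n)):
        gi = int(rng.choice(4, p=mix))
        grade = grades[gi]
        lo, hi = ranges[grade]
        angle = float(rng.uniform(lo, hi))
        dist = float(rng.uniform(*distance_range))
        blo, bhi = DEFAULT_BULB_RANGES[grade]
        bulb = float(rng.uniform(blo, bhi))
        orient = float(rng.uniform(-25.0, 25.0))
        flip = bool(rng.integers(2))
        bright = float(rng.uniform(0.85, 1.0))
        sub_seed = int(rng.integers(2**31))
        spec = FingerProfileSpec(
            lovibond_angle_deg=angle,
            tip_bulb_ratio=bulb,
            distance_cm=dist,
            brightness=bright,
            noise_sigma=noise_sigma,
            orientation_deg=orient,
            flip=flip,
            seed=sub_seed,
        )
        if render:
            s = render_finger_profile(spec)
            s.sub_seed = sub_seed
            samples.append(s)
        rows.append(
            {
                "id": f"sample_{i:05d}",
                "angle_deg": round(angle, 4),
                "grade": grade,
                "distance_cm": round(dist, 4),
                "seed": sub_seed,
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["id", "angle_deg", "grade", "distance_cm", "seed"]
    )
    return samples, manifest


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(sample: SyntheticSample, params: AugmentationParams) -> SyntheticSample:
    """Apply the augmentation recipe, keeping annotations consistent.

    Flip mirrors x (and the handedness); brightness shifts intensities with
    clipping; scaling zooms about the image centre (canvas size unchanged),
    so annotated coordinates transform as p' = c + s (p - c) with
    c = ((W-1)/2, (H-1)/2).  Angle and grade are unchanged throughout —
    the profile angle is mirror- and scale-invariant.
    """
    img = sample.image
    sil = sample.silhouette
    marks = sample.truth_landmarks.as_array()
    x0, y0, x1, y1 = sample.bbox
    H, W = img.shape

    if params.scale_factor != 1.0:
        s = params.scale_factor
        if s * min(H, W) < 16:
            raise ValidationError("scale_factor", "scaled image smaller than 16 px")
        c = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
        # output(o) = input(o/s + c - c/s), row/col order for ndimage
        mat = np.array([1.0 / s, 1.0 / s])
        off = (c - c / s)[::-1]
        img = ndi.affine_transform(
            img, mat, offset=off, order=1, mode="constant",
            cval=float(np.round(_BG * 255)), output=np.uint8,
        )
        sil = ndi.affine_transform(
            sil.astype(np.uint8), mat, offset=off, order=0, mode="constant", cval=0
        ).astype(bool)
        marks = c + s * (marks - c)
        corners = c + s * (np.array([[x0, y0], [x1, y1]]) - c)
        x0, y0 = np.floor(corners[0]).astype(int)
        x1, y1 = np.ceil(corners[1]).astype(int)
        x0, y0 = max(0, int(x0)), max(0, int(y0))
        x1, y1 = min(W, int(x1)), min(H, int(y1))

    if params.flip_horizontal:
        img = img[:, ::-1].copy()
        sil = sil[:, ::-1].copy()
        marks = marks.copy()
        marks[:, 0] = (W - 1) - marks[:, 0]
        x0, x1 = W - x1, W - x0

    if params.brightness_delta != 0.0:
        shift = params.brightness_delta * 255.0
        img = np.clip(img.astype(float) + shift, 0, 255).round().astype(np.uint8)

    return SyntheticSample(
        image=img,
        silhouette=sil,
        truth_landmarks=LandmarkTriplet.from_array(marks),
        truth_angle_deg=sample.truth_angle_deg,
        truth_grade=sample.truth_grade,
        bbox=(int(x0), int(y0), int(x1), int(y1)),
        distance_cm=sample.distance_cm,
        spec=sample.spec,
        sub_seed=sample.sub_seed,
    )
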