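"""Finger segmentation, canonical pose, distance estimation and capture gating.

The capture protocol assumes a single finger photographed in lateral profile.
Processing is deliberately classical: Otsu thresholding followed by
largest-connected-component selection is sufficient because the expected
inputs (synthetic renders, or real photographs against a plain background)
have a bimodal intensity histogram.  The segmentation entry point is a
pluggable seam — any callable returning a :class:`SegmentationMask` can
replace :func:`segment_finger` upstream of the rest of the cascade.

Coordinates are pixel units, origin at the top-left, x right, y down.
The *canonical frame* maps the fingertip direction onto +x and the dorsal
(nail) side onto -y, which gives the Lovibond turning angle a well-defined
sign: positive turns point toward the palmar side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import NoFingerError, OrientationError, ValidationError

__all__ = [
    "SegmentationMask",
    "CanonicalFrame",
    "CameraModel",
    "GateConfig",
    "GateDecision",
    "segment_finger",
    "normalize_orientation",
    "estimate_distance",
    "distance_from_width",
    "distance_from_area_fraction",
    "gate_capture",
    "shaft_width_px",
    "width_profile",
    "max_width_px",
    "bulb_diameter_px",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SegmentationMask:
    """Binary finger mask with summary shape statistics.

    ``principal_axis_deg`` is the major-axis direction from second-order
    central moments, in degrees, measured in image coordinates (x right,
    y down), on (-90, 90].  When the source intensity image and threshold
    are kept (``intensity``/``level``), boundary extraction traces the
    iso-intensity contour at the threshold, which is subpixel-accurate on
    anti-aliased edges; otherwise the binary mask boundary is used.
    """

    mask: np.ndarray
    area_fraction: float
    principal_axis_deg: float
    intensity: np.ndarray = None
    level: float = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass(frozen=True)
class CanonicalFrame:
    """Similarity transform into the canonical finger pose.

    ``apply`` maps image coordinates to canonical coordinates:

        p_can = F @ (R(rotation_deg) @ p) + translation

    where ``F = diag(1, -1)`` when ``flip_applied`` (a mirror is needed to
    bring the dorsal side to -y, i.e. the image shows the other hand's
    profile).  The transform is an exact similarity; round-trips are exact
    to floating-point precision.
    """

    rotation_deg: float
    translation: np.ndarray
    flip_applied: bool

    def _linear(self) -> np.ndarray:
        a = np.radians(self.rotation_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        if self.flip_applied:
            rot = np.diag([1.0, -1.0]) @ rot
        return rot

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N,2) or (2,) image coordinates into the canonical frame."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self._linear().T + np.asarray(self.translation, dtype=float)
        return out[0] if np.ndim(points) == 1 else out

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        """Map canonical coordinates back to image coordinates."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        lin = self._linear()
        out = (p - np.asarray(self.translation, dtype=float)) @ np.linalg.inv(lin).T
        return out[0] if np.ndim(points) == 1 else out

    @staticmethod
    def identity() -> "CanonicalFrame":
        return CanonicalFrame(0.0, np.zeros(2), False)


@dataclass(frozen=True)
class CameraModel:
    """Pinhole model used to convert finger pixel width into distance.

    ``focal_px`` is the focal length expressed in pixels;
    ``assumed_finger_width_mm`` is the population-typical width of the
    distal phalanx seen in profile (16 mm default).  Pixels-per-mm at
    distance d_cm is ``focal_px / (10 * d_cm)``.
    """

    focal_px: float = 1000.0
    assumed_finger_width_mm: float = 16.0

    def __post_init__(self):
        if not self.focal_px > 0:
            raise ValidationError("focal_px", "must be strictly positive")
        if not self.assumed_finger_width_mm > 0:
            raise ValidationError("assumed_finger_width_mm", "must be strictly positive")

    def pixels_per_mm(self, distance_cm: float) -> float:
        return self.focal_px / (10.0 * distance_cm)


@dataclass(frozen=True)
class GateConfig:
    """Accepted finger-to-camera distance band, closed on both ends."""

    min_cm: float = 4.0
    max_cm: float = 7.0

    def __post_init__(self):
        if not (0 < self.min_cm < self.max_cm):
            raise ValidationError("min_cm/max_cm", "need 0 < min_cm < max_cm")


@dataclass(frozen=True)
class GateDecision:
    status: str  # accept | too_close | too_far
    estimated_distance_cm: float

    @property
    def accepted(self) -> bool:
        return self.status == "accept"

    def to_dict(self) -> dict:
        return {"status": self.status, "distance_cm": round(self.estimated_distance_cm, 3)}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _as_float_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:  # RGB(A) -> luminance
        img = img[..., :3].mean(axis=2)
    if img.size == 0:
        raise ValidationError("image", "empty image")
    img = img.astype(float)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        img = img / 255.0
    if not np.all(np.isfinite(img)):
        raise ValidationError("image", "intensities must be finite")
    return img


def _principal_axis_deg(coords_xy: np.ndarray) -> tuple[float, float]:
    """Major-axis direction (deg) and axis-length ratio from central moments."""
    c = coords_xy - coords_xy.mean(axis=0)
    mu20 = np.mean(c[:, 0] ** 2)
    mu02 = np.mean(c[:, 1] ** 2)
    mu11 = np.mean(c[:, 0] * c[:, 1])
    phi = 0.5 * np.degrees(np.arctan2(2 * mu11, mu20 - mu02))
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    ev = np.sort(np.linalg.eigvalsh(cov))
    ratio = np.sqrt(ev[1] / ev[0]) if ev[0] > 0 else np.inf
    return float(phi), float(ratio)


def segment_finger(image: np.ndarray) -> SegmentationMask:
    """Segment the finger as the largest bright connected component.

    Otsu threshold -> largest connected component -> hole filling.  Raises
    :class:`NoFingerError` when the histogram is unimodal (e.g. an all-black
    frame) or no foreground pixel survives.
    """
    img = _as_float_image(image)
    try:
        thresh = threshold_otsu(img)
    except ValueError as exc:  # constant image
        raise NoFingerError("no finger detected: image has a single intensity") from exc
    fg = img > thresh
    if not fg.any():
        raise NoFingerError("no finger detected: empty foreground")
    labels, nlab = ndi.label(fg)
    if nlab > 1:
        sizes = ndi.sum_labels(fg, labels, index=np.arange(1, nlab + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndi.binary_fill_holes(fg)
    ys, xs = np.nonzero(fg)
    coords = np.column_stack([xs, ys]).astype(float)
    phi, _ = _principal_axis_deg(coords)
    # a lightly denoised copy keeps the iso-contour from wandering through
    # pixel noise while preserving subpixel edge localization
    smooth = ndi.gaussian_filter(img, 1.0)
    return SegmentationMask(
        mask=fg,
        area_fraction=float(fg.mean()),
        principal_axis_deg=phi,
        intensity=smooth,
        level=float(thresh),
    )


def _boundary_points(segmask) -> np.ndarray:
    """Longest closed silhouette boundary as (N,2) subpixel (x, y) points.

    Accepts a :class:`SegmentationMask` (preferring its iso-intensity
    contour, which is subpixel-accurate on anti-aliased edges) or a bare
    binary mask array.
    """
    if isinstance(segmask, SegmentationMask):
        if segmask.intensity is not None and segmask.level is not None:
            contours = measure.find_contours(segmask.intensity, segmask.level)
            if contours:
                longest = max(contours, key=len)
                return longest[:, ::-1].copy()
        mask = segmask.mask
    else:
        mask = np.asarray(segmask, dtype=bool)
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise NoFingerError("no finger detected: mask has no boundary")
    longest = max(contours, key=len)
    return longest[:, ::-1].copy()  # (row, col) -> (x, y)


def _rot(deg: float) -> np.ndarray:
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def _split_branches(boundary: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a closed boundary polyline into (upper, lower) branches.

    The two branches run between the extreme-x vertices, each ordered by
    walking the polyline (so they follow the true boundary even where it is
    locally non-monotonic in x); "upper" is the branch with the smaller
    mean y.  Both are returned proximal -> distal (increasing x overall).
    """
    pts = boundary
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    n = len(pts)
    imin = int(np.argmin(pts[:, 0]))
    imax = int(np.argmax(pts[:, 0]))
    if imin == imax:
        raise NoFingerError("degenerate boundary")
    idx1 = np.arange(imin, imin + (imax - imin) % n + 1) % n
    idx2 = np.arange(imax, imax + (imin - imax) % n + 1) % n
    b1, b2 = pts[idx1], pts[idx2][::-1]  # both min-x -> max-x
    if np.mean(b1[:, 1]) <= np.mean(b2[:, 1]):
        return b1, b2
    return b2, b1


def _turning_series(points: np.ndarray, window: int) -> np.ndarray:
    """Signed turning angle (deg) between back/forward chords of ``window`` pts."""
    n = len(points)
    if n < 3 * window:
        return np.zeros(0)
    p0 = points[: n - 2 * window]
    p1 = points[window: n - window]
    p2 = points[2 * window:]
    u = p1 - p0
    v = p2 - p1
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dot = u[:, 0] * v[:, 0] + u[:, 1] * v[:, 1]
    return np.degrees(np.arctan2(cross, dot))


def normalize_orientation(segmask: SegmentationMask, landmarks=None) -> CanonicalFrame:
    """Find the similarity transform to the canonical pose (tip +x, dorsal -y).

    The principal axis is rotated onto x; the tip is the axis end whose
    silhouette is narrower (fingertips taper, the proximal cut is flat);
    the dorsal side is the side of the axis holding the nail-fold notch
    when ``landmarks`` (a LandmarkTriplet) are given, otherwise the side
    whose boundary has the sharpest mid-contour corner (the nail fold and
    nail-tip corners live dorsally; the palmar boundary is smooth).
    """
    mask = segmask.mask
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise NoFingerError("no finger detected: empty mask")
    coords = np.column_stack([xs, ys]).astype(float)
    centroid = coords.mean(axis=0)
    phi, ratio = _principal_axis_deg(coords)
    if ratio < 1.2:
        raise OrientationError(
            f"orientation ambiguous: axis ratio {ratio:.2f} < 1.2"
        )

    boundary = _boundary_points(segmask)
    b1 = (boundary - centroid) @ _rot(-phi).T

    # tip = end with the smaller silhouette width over the outer 5% of length
    x1 = b1[:, 0]
    span = x1.max() - x1.min()
    strip = 0.05 * span
    widths = []
    for sel in (x1 <= x1.min() + strip, x1 >= x1.max() - strip):
        pts = b1[sel]
        widths.append(pts[:, 1].max() - pts[:, 1].min() if len(pts) else 0.0)
    if widths[1] > widths[0]:  # tip currently on the left: rotate 180 more
        phi = phi + 180.0
        b1 = (boundary - centroid) @ _rot(-phi).T

    # dorsal side
    if landmarks is not None:
        b_can = (np.array([landmarks.B.x, landmarks.B.y]) - centroid) @ _rot(-phi).T
        flip = b_can[1] > 0
    else:
        win = 7
        sharp = []
        x_lo = x1.min() + 0.20 * span
        x_hi = x1.min() + 0.85 * span
        for env in _split_branches(b1):
            t = _turning_series(env, win)
            # central x-band only: the proximal cut edge and the tip
            # extremity produce sharp corners on *both* sides and carry no
            # information, whereas the nail fold / nail-tip corners sit
            # mid-contour and exist only dorsally (the palmar boundary is
            # smooth)
            if len(t):
                xs = env[win: len(env) - win, 0]
                t = t[(xs >= x_lo) & (xs <= x_hi)]
            sharp.append(float(np.max(np.abs(t))) if len(t) else 0.0)
        flip = sharp[1] > sharp[0]

    rotation_deg = float(((-phi) + 180.0) % 360.0 - 180.0)
    frame = CanonicalFrame(rotation_deg, np.zeros(2), bool(flip))
    # translate so the centroid maps to the origin
    t = -frame.apply(centroid)
    return CanonicalFrame(rotation_deg, t, bool(flip))


def _branch_profiles(segmask: SegmentationMask):
    """Per-1-px-column medians of the upper and lower boundary branches.

    Coordinates are principal-axis aligned and centroid-centred; columns
    where either branch is absent are dropped.  Returns (x, upper_y, lower_y).
    """
    boundary = _boundary_points(segmask)
    centroid = boundary.mean(axis=0)
    b = (boundary - centroid) @ _rot(-segmask.principal_axis_deg).T
    upper, lower = _split_branches(b)
    lo = int(max(upper[:, 0].min(), lower[:, 0].min())) + 1
    hi = int(min(upper[:, 0].max(), lower[:, 0].max())) - 1
    if hi <= lo:
        raise ValidationError("mask", "too small to measure widths")

    def _bin_median(branch):
        bins = np.floor(branch[:, 0]).astype(int)
        order = np.argsort(bins, kind="stable")
        bins_s, y_s = bins[order], branch[order, 1]
        edges = np.searchsorted(bins_s, np.arange(lo, hi + 2))
        out = np.full(hi - lo + 1, np.nan)
        for i in range(hi - lo + 1):
            s, e = edges[i], edges[i + 1]
            if e > s:
                out[i] = np.median(y_s[s:e])
        return out

    u, l = _bin_median(upper), _bin_median(lower)
    keep = np.isfinite(u) & np.isfinite(l)
    x = np.arange(lo, hi + 1, dtype=float)
    return x[keep], u[keep], l[keep]


def width_profile(segmask: SegmentationMask) -> np.ndarray:
    """Cross-axis width (px) per 1-px column along the principal axis."""
    _, u, l = _branch_profiles(segmask)
    return l - u


def _stable_third(widths: np.ndarray) -> slice:
    """The third of the length whose widths have the smallest IQR (the shaft)."""
    third = len(widths) // 3
    best = None
    for start in (0, third, 2 * third):
        seg = widths[start: start + third]
        q75, q25 = np.percentile(seg, [75, 25])
        key = (q75 - q25, start)
        if best is None or key < best[0]:
            best = (key, slice(start, start + third))
    return best[1]


def max_width_px(segmask: SegmentationMask) -> float:
    """Largest cross-axis width (px) of the silhouette."""
    widths = width_profile(segmask)
    if not len(widths):
        raise ValidationError("mask", "too small to measure widths")
    return float(np.percentile(widths, 98))


def bulb_diameter_px(segmask: SegmentationMask, frame: "CanonicalFrame" = None) -> float:
    """Fingertip-bulb diameter (px), from the palmar bulge.

    The dorsal silhouette over the bulb is partly occluded by the nail, so
    the bulb is measured on the palmar side, where it forms a circular arc
    running into the finger's distal extreme: a least-squares circle is
    fitted to the distal portion of the lower boundary branch.  The fit is
    rotation-invariant, so residual principal-axis tilt does not bias it.
    ``frame`` (when available) fixes which end is the tip; without it the
    tip is taken as the end whose silhouette is narrower.
    """
    boundary = _boundary_points(segmask)
    if frame is not None:
        b = frame.apply(boundary)
    else:
        centroid = boundary.mean(axis=0)
        b = (boundary - centroid) @ _rot(-segmask.principal_axis_deg).T
        span = b[:, 0].max() - b[:, 0].min()
        strip = 0.05 * span
        wl = b[b[:, 0] <= b[:, 0].min() + strip, 1]
        wr = b[b[:, 0] >= b[:, 0].max() - strip, 1]
        if (wl.max() - wl.min()) < (wr.max() - wr.min()):
            b = -b  # tip was on the left: rotate 180 deg
    widths = width_profile(segmask)
    if not len(widths):
        raise ValidationError("mask", "too small to measure a bulb")
    r0 = float(np.max(widths)) / 2.0  # lower bound on the arc's x-extent
    span = b[:, 0].max() - b[:, 0].min()

    def _kasa(pts):
        # Kasa fit: x^2 + y^2 = 2 a x + 2 b y + c
        A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
        rhs = (pts**2).sum(axis=1)
        (a, b_, c), *_ = np.linalg.lstsq(A, rhs, rcond=None)
        r = float(np.sqrt(max(c + a * a + b_ * b_, 0.0)))
        rms = float(np.sqrt(np.mean((np.hypot(pts[:, 0] - a, pts[:, 1] - b_) - r) ** 2)))
        return r, rms

    if frame is not None:
        branches = [_split_branches(b)[1]]  # palmar branch is known
    else:
        branches = list(_split_branches(b))  # palmar side unknown: try both
    fits = []
    for br in branches:
        pts = br[br[:, 0] >= br[:, 0].max() - r0]
        if len(pts) >= 10:
            r, rms = _kasa(pts)
            if 0 < r <= 0.75 * span:  # a physical bulb, not a straight chord
                fits.append((rms, r))
    if not fits:
        raise ValidationError("mask", "too small to measure a bulb")
    return 2.0 * min(fits)[1]


def shaft_width_px(segmask: SegmentationMask) -> float:
    """Cross-axis width of the finger shaft in pixels.

    Widths are measured per 1-px column after rotating the boundary onto
    the principal axis; the shaft estimate is the median width within the
    most width-stable third of the finger's length (smallest IQR), which
    is insensitive to the bulbous tip and to the nail-plate taper.
    """
    widths = width_profile(segmask)
    if len(widths) < 9:
        raise ValidationError("mask", "too small to measure a shaft width")
    width = float(np.median(widths[_stable_third(widths)]))
    if width <= 0:
        raise ValidationError("mask", "zero-width mask")
    return width


def distance_from_width(finger_width_px: float, camera: CameraModel) -> float:
    """Pinhole distance (cm) from the measured finger width in pixels."""
    if not finger_width_px > 0:
        raise ValidationError("finger_width_px", "must be strictly positive")
    return camera.assumed_finger_width_mm * camera.focal_px / (finger_width_px * 10.0)


def estimate_distance(segmask: SegmentationMask, camera: CameraModel) -> float:
    """Estimate finger-to-camera distance (cm) from the mask's shaft width."""
    return distance_from_width(shaft_width_px(segmask), camera)


def distance_from_area_fraction(area_fraction: float, k: float) -> float:
    """Area-proportion calibration mode: d = k / sqrt(area_fraction).

    Provided for capture protocols calibrated on the proportion of the
    frame the finger fills rather than on its pixel width; ``k`` is the
    user-supplied calibration constant (cm at full-frame coverage).  The
    width-based pinhole estimate is the default because width is stable
    under partial cropping.
    """
    if not 0.0 < area_fraction <= 1.0:
        raise ValidationError("area_fraction", "must lie in (0, 1]")
    if not k > 0:
        raise ValidationError("k", "must be strictly positive")
    return k / float(np.sqrt(area_fraction))


def gate_capture(distance_cm: float, config: GateConfig = GateConfig()) -> GateDecision:
    """Apply the capture-distance gate (closed interval, accept on the bounds)."""
    if not (np.isfinite(distance_cm) and distance_cm > 0):
        raise ValidationError("distance_cm", "must be finite and positive")
    if distance_cm < config.min_cm:
        status = "too_close"
    elif distance_cm > config.max_cm:
        status = "too_far"
    else:
        status = "accept"
    return GateDecision(status=status, estimated_distance_cm=float(distance_cm))
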