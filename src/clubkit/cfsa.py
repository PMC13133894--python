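"""Lovibond-angle computation, severity grading and the assessment cascade.

The Lovibond (profile) angle is the angle at the nail base between the
line of the proximal nail fold (A -> B) and the line of the nail plate
(B -> C), viewed in lateral profile.  A healthy finger shows roughly 160
degrees; the angle grows as the nail base bulges with clubbing and exceeds
180 degrees (a reflex configuration) in severe disease.

The angle is computed as a *signed turning angle*: with the finger in the
canonical pose (tip toward +x, dorsal side up), let u = B - A and
v = C - B; tau is the signed angle from u to v, positive when the nail
plate dips toward the palmar side, and

    theta = 180 - tau.

This makes theta a proper reflex angle (> 180) when the plate rises
dorsally, which is what the "severe" grade requires, and reduces to 180
exactly for a collinear triplet.

Severity grades follow the clinical thresholds: normal for theta <= 160,
mild between 160 and 180, moderate at 180 (widened to a configurable
+/- epsilon band so the class has positive measure), severe above 180.
"""

from __future__ import annotations

import datetime as _dt
import enum
import functools
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ClubkitError, DegenerateTripletError, ValidationError
from .landmarks import (
    DetectorConfig,
    KeypointPrediction,
    LandmarkTriplet,
    detect_landmarks,
)
from .preprocess import (
    CameraModel,
    CanonicalFrame,
    GateConfig,
    GateDecision,
    estimate_distance,
    gate_capture,
    normalize_orientation,
    segment_finger,
)

__all__ = [
    "AngleMeasurement",
    "SeverityGrade",
    "SeverityThresholds",
    "AssessmentResult",
    "compute_lovibond_angle",
    "grade_severity",
    "classify_clubbing",
    "assess",
]


@functools.total_ordering
class SeverityGrade(enum.Enum):
    """Ordinal clubbing severity: normal < mild < moderate < severe."""

    NORMAL = "normal"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"

    @property
    def rank(self) -> int:
        return ["normal", "mild", "moderate", "severe"].index(self.value)

    def __lt__(self, other: "SeverityGrade") -> bool:
        return self.rank < other.rank

    def __str__(self) -> str:
        return self.value


GRADE_ORDER = [
    SeverityGrade.NORMAL,
    SeverityGrade.MILD,
    SeverityGrade.MODERATE,
    SeverityGrade.SEVERE,
]


@dataclass(frozen=True)
class AngleMeasurement:
    """Lovibond angle theta (deg, on (0, 360)) and signed turn tau = 180 - theta."""

    theta_deg: float
    turn_deg: float

    def __post_init__(self):
        if not np.isclose(self.theta_deg + self.turn_deg, 180.0, atol=1e-9):
            raise ValidationError("turn_deg", "theta_deg + turn_deg must equal 180")
        if not 0.0 < self.theta_deg < 360.0:
            raise ValidationError("theta_deg", "must lie in (0, 360)")

    @staticmethod
    def from_theta(theta_deg: float) -> "AngleMeasurement":
        return AngleMeasurement(float(theta_deg), 180.0 - float(theta_deg))


@dataclass(frozen=True)
class SeverityThresholds:
    """Grading thresholds in degrees.

    normal_max_deg: largest angle still called normal (boundary inclusive).
    reflex_deg: the straight-profile reference (180).
    moderate_band_deg: half-width epsilon of the moderate band around 180.
    """

    normal_max_deg: float = 160.0
    reflex_deg: float = 180.0
    moderate_band_deg: float = 1.0

    def __post_init__(self):
        if self.moderate_band_deg < 0:
            raise ValidationError("moderate_band_deg", "must be >= 0")
        if not self.normal_max_deg < self.reflex_deg - self.moderate_band_deg:
            raise ValidationError(
                "normal_max_deg", "must be below reflex_deg - moderate_band_deg"
            )


DEFAULT_THRESHOLDS = SeverityThresholds()


def compute_lovibond_angle(
    triplet: LandmarkTriplet, frame: Optional[CanonicalFrame] = None
) -> AngleMeasurement:
    """Lovibond angle of a landmark triplet.

    ``frame`` maps the triplet's image coordinates to the canonical pose;
    pass None when the points are already canonical (tip +x, dorsal -y).
    Because the frame carries any mirror flip, the angle is invariant to
    similarity transforms of the input, including reflections.
    """
    pts = triplet.as_array()
    if frame is not None:
        pts = frame.apply(pts)
    a, b, c = pts
    u = b - a
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateTripletError("coincident landmarks: zero-length segment")
    tau = np.degrees(np.arctan2(u[0] * v[1] - u[1] * v[0], float(u @ v)))
    theta = 180.0 - tau
    if not 0.0 < theta < 360.0:
        raise DegenerateTripletError("antiparallel landmark segments")
    return AngleMeasurement(theta_deg=float(theta), turn_deg=float(tau))


def grade_severity(
    theta_deg: float, thresholds: SeverityThresholds = DEFAULT_THRESHOLDS
) -> SeverityGrade:
    """Map a Lovibond angle to the four-level clinical grade.

    normal:   theta <= normal_max (160)
    mild:     normal_max < theta < 180 - eps
    moderate: |theta - 180| <= eps
    severe:   theta > 180 + eps
    """
    if not 0.0 < theta_deg < 360.0:
        raise ValidationError("theta_deg", "must lie in (0, 360)")
    t = thresholds
    if theta_deg <= t.normal_max_deg:
        return SeverityGrade.NORMAL
    if abs(theta_deg - t.reflex_deg) <= t.moderate_band_deg:
        return SeverityGrade.MODERATE
    if theta_deg < t.reflex_deg:
        return SeverityGrade.MILD
    return SeverityGrade.SEVERE


def classify_clubbing(angle: AngleMeasurement, cutoff_deg: float = 160.0) -> bool:
    """Binary clubbing-vs-normal decision; the 160 boundary counts as normal."""
    return angle.theta_deg > cutoff_deg


@dataclass
class AssessmentResult:
    """Outcome of the full cascade for one image.

    ``status`` is "ok" for a completed assessment, "rejected" when the
    capture gate refused the image (no grading is performed), or "failed"
    when a stage errored (the structured error names the stage).  For
    completed assessments the bypass rule holds: when no clubbing is
    detected the grade is normal and angle/landmarks are absent.
    """

    status: str
    gate: Optional[GateDecision] = None
    clubbing_detected: Optional[bool] = None
    angle: Optional[AngleMeasurement] = None
    grade: Optional[SeverityGrade] = None
    landmarks: Optional[KeypointPrediction] = None
    provenance: Optional[dict] = None
    error: Optional[dict] = None

    def to_record(self) -> dict:
        rec = {
            "status": self.status,
            "gate": self.gate.to_dict() if self.gate else None,
            "clubbing_detected": self.clubbing_detected,
            "angle_deg": round(self.angle.theta_deg, 3) if self.angle else None,
            "turn_deg": round(self.angle.turn_deg, 3) if self.angle else None,
            "grade": str(self.grade) if self.grade else None,
            "landmarks": self.landmarks.triplet.to_dict() if self.landmarks else None,
            "confidence": self.landmarks.confidence if self.landmarks else None,
            "detector_id": self.landmarks.detector_id if self.landmarks else None,
            "error": self.error,
        }
        rec.update(self.provenance or {})
        return rec


def assess(
    image: np.ndarray,
    *,
    camera: CameraModel = CameraModel(),
    gate: GateConfig = GateConfig(),
    thresholds: SeverityThresholds = DEFAULT_THRESHOLDS,
    detector: DetectorConfig = DetectorConfig(),
    detect_fn=None,
    cutoff_deg: float = 160.0,
    provenance: Optional[dict] = None,
) -> AssessmentResult:
    """Run the full cascade on one image.

    segment -> estimate distance -> gate -> orient -> landmarks -> angle ->
    binary classification -> severity grade.  Gate rejection short-circuits
    with status "rejected"; a normal binary decision bypasses grading and
    reports grade normal with angle and landmarks absent.  Stage errors are
    captured into a structured failure record, never raised.

    ``detect_fn`` overrides the landmark detector (same signature as
    :func:`clubkit.landmarks.detect_landmarks`).
    """
    prov = dict(provenance or {})
    prov.setdefault("timestamp", _dt.datetime.now(_dt.timezone.utc).isoformat())
    stage = "segment"
    try:
        mask = segment_finger(image)
        stage = "distance"
        dist = estimate_distance(mask, camera)
        decision = gate_capture(dist, gate)
        if not decision.accepted:
            return AssessmentResult(status="rejected", gate=decision, provenance=prov)
        stage = "orientation"
        frame = normalize_orientation(mask)
        stage = "landmarks"
        fn = detect_fn or detect_landmarks
        prediction = fn(mask, frame, detector)
        stage = "angle"
        angle = compute_lovibond_angle(prediction.triplet, frame)
        stage = "classify"
        detected = classify_clubbing(angle, cutoff_deg)
        if not detected:
            return AssessmentResult(
                status="ok",
                gate=decision,
                clubbing_detected=False,
                grade=SeverityGrade.NORMAL,
                provenance=prov,
            )
        stage = "grade"
        grade = grade_severity(angle.theta_deg, thresholds)
        return AssessmentResult(
            status="ok",
            gate=decision,
            clubbing_detected=True,
            angle=angle,
            grade=grade,
            landmarks=prediction,
            provenance=prov,
        )
    except ClubkitError as exc:
        return AssessmentResult(
            status="failed",
            provenance=prov,
            error={"stage": stage, "message": str(exc), "type": type(exc).__name__},
        )
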