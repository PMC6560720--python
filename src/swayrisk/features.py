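"""Balance parameters from silhouetted depth video.

Silhouette pixels are back-projected through the pinhole model into
camera-frame 3D points (x lateral, y vertical, z depth, metres).  The
person's centroid is the mean of those points; postural sway lives in the
horizontal (x, z) plane, since the camera faces the participant.  Three
scalars summarise one trial:

``centroid_variability``
    standard deviation of the horizontal centroid position,
    sqrt(var(x) + var(z)) — the RMS distance from the mean position;
``centroid_max_speed``
    maximum of the horizontal centroid speed (smoothed, central
    differences);
``max_dispersion``
    maximum over frames of the horizontal point-cloud elongation, the
    ratio of the larger to smaller eigenvalue of the 2x2 covariance of
    (x, z).  Grows when the arms are abducted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .depth_io import DepthFrame, DepthSequence
from .silhouette import DEFAULT_THRESHOLD_MM, SilhouetteMask, extract_all

__all__ = [
    "CentroidTrace",
    "BalanceParameters",
    "backproject",
    "compute_centroid",
    "centroid_trace",
    "centroid_variability",
    "centroid_max_speed",
    "body_dispersion",
    "extract_balance_parameters",
    "aggregate_trials",
    "DISPERSION_CAP",
    "DEFAULT_SMOOTH_WINDOW",
]

DISPERSION_CAP = 1e6
_DEGENERATE_EIGENVALUE = 1e-12  # m^2
DEFAULT_SMOOTH_WINDOW = 5


@dataclass(frozen=True)
class CentroidTrace:
    """Ordered per-frame 3D centroids (metres, camera frame)."""

    positions: np.ndarray  # (n, 3)
    frame_rate_hz: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(pos) < 1:
            raise ValueError("trace must contain at least one position")
        if not np.all(np.isfinite(pos)):
            raise ValueError("trace positions must be finite")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def horizontal(self) -> np.ndarray:
        """(n, 2) lateral/depth coordinates."""
        return self.positions[:, [0, 2]]


@dataclass(frozen=True)
class BalanceParameters:
    """The three per-trial balance scalars."""

    centroid_variability: float  # metres
    centroid_max_speed: float  # metres / second
    max_dispersion: float  # eigenvalue ratio, >= 1

    def __post_init__(self) -> None:
        vals = (self.centroid_variability, self.centroid_max_speed, self.max_dispersion)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("balance parameters must be finite")
        if self.centroid_variability < 0 or self.centroid_max_speed < 0:
            raise ValueError("centroid parameters must be non-negative")
        if self.max_dispersion < 1:
            raise ValueError("dispersion ratio is >= 1 by construction")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.centroid_variability, self.centroid_max_speed, self.max_dispersion)


def backproject(
    mask: SilhouetteMask,
    frame: DepthFrame,
    intrinsics: tuple[float, float, float, float],
    depth_scale_mm: float = 1.0,
) -> np.ndarray:
    """Pinhole back-projection of masked pixels to (n, 3) points in metres.

    x = (u - cx) d / fx, y = (v - cy) d / fy, z = d, with u the column and
    v the row index.  An empty mask yields an empty (0, 3) array.
    """
    fx, fy, cx, cy = intrinsics
    v, u = np.nonzero(mask.mask)
    if len(u) == 0:
        return np.empty((0, 3), dtype=float)
    d = frame.grid[v, u].astype(float) * depth_scale_mm / 1000.0
    return np.column_stack(((u - cx) * d / fx, (v - cy) * d / fy, d))


def compute_centroid(points: np.ndarray) -> np.ndarray | None:
    """Coordinate-wise mean of a point cloud; None for an empty cloud."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return None
    return pts.mean(axis=0)


def centroid_trace(seq: DepthSequence, masks: list[SilhouetteMask]) -> CentroidTrace:
    """Per-frame centroids with gap handling.

    Empty-mask frames become gaps; interior gaps are filled by linear
    interpolation between neighbouring centroids, leading and trailing
    gaps are dropped.
    """
    frames = seq.person_frames()
    if len(masks) != len(frames):
        raise ValueError("need exactly one mask per non-background frame")
    raw = np.full((len(frames), 3), np.nan)
    for i, (frame, mask) in enumerate(zip(frames, masks)):
        c = compute_centroid(backproject(mask, frame, seq.intrinsics, seq.depth_scale_mm))
        if c is not None:
            raw[i] = c
    present = ~np.isnan(raw[:, 0])
    if not present.any():
        raise ValueError("every frame has an empty mask; no centroid trace")
    first, last = np.flatnonzero(present)[[0, -1]]
    raw = raw[first : last + 1]
    present = present[first : last + 1]
    if not present.all():
        t = np.arange(len(raw))
        for k in range(3):
            raw[~present, k] = np.interp(t[~present], t[present], raw[present, k])
    return CentroidTrace(positions=raw, frame_rate_hz=seq.frame_rate_hz)


def centroid_variability(trace: CentroidTrace) -> float:
    """Standard deviation of the horizontal centroid position (metres).

    sqrt(var(x) + var(z)) with sample variance (divisor n-1).
    """
    if len(trace) < 2:
        raise ValueError("variability needs a trace of length >= 2")
    var = trace.horizontal.var(axis=0, ddof=1)
    return float(np.sqrt(var.sum()))


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges average over the available span."""
    if window == 1:
        return x
    half = window // 2
    csum = np.cumsum(np.concatenate(([0.0], x)))
    n = len(x)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def centroid_max_speed(trace: CentroidTrace, smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> float:
    """Maximum horizontal centroid speed (m/s).

    Horizontal coordinates are smoothed by a centered moving average of
    ``smooth_window`` frames (odd; 1 disables smoothing) — frame-to-frame
    centroid jitter otherwise dominates the maximum — then differentiated
    by central finite differences (one-sided at the ends, exact for
    linear signals) and scaled by the frame rate.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    if len(trace) < 2:
        raise ValueError("speed needs a trace of length >= 2")
    if len(trace) < smooth_window:
        raise ValueError("trace shorter than the smoothing window")
    xz = trace.horizontal
    smooth = np.column_stack([_moving_average(xz[:, k], smooth_window) for k in (0, 1)])
    vel = np.gradient(smooth, axis=0) * trace.frame_rate_hz
    speed = np.linalg.norm(vel, axis=1)
    return float(speed.max())


def body_dispersion(points: np.ndarray) -> float:
    """Horizontal elongation of a silhouette point cloud.

    Ratio lambda1/lambda2 (descending) of the eigenvalues of the 2x2
    covariance of the (x, z) coordinates.  When the cloud is degenerate
    (lambda2 <= 1e-12 m^2, e.g. collinear points) the ratio is capped at
    ``DISPERSION_CAP`` so the output stays bounded and sortable.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("dispersion needs at least 3 points")
    cov = np.cov(pts[:, 0], pts[:, 2], ddof=1)
    eig = np.linalg.eigvalsh(cov)  # ascending
    lam2, lam1 = float(eig[0]), float(eig[1])
    if lam2 <= _DEGENERATE_EIGENVALUE:
        return DISPERSION_CAP
    return min(lam1 / lam2, DISPERSION_CAP)


def extract_balance_parameters(
    seq: DepthSequence,
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> BalanceParameters:
    """Full per-trial pipeline: silhouettes -> centroid trace -> three scalars."""
    masks = extract_all(seq, threshold_mm=threshold_mm)
    trace = centroid_trace(seq, masks)
    dispersion = 1.0
    for frame, mask in zip(seq.person_frames(), masks):
        if mask.area >= 3:
            pts = backproject(mask, frame, seq.intrinsics, seq.depth_scale_mm)
            dispersion = max(dispersion, body_dispersion(pts))
    return BalanceParameters(
        centroid_variability=centroid_variability(trace),
        centroid_max_speed=centroid_max_speed(trace, smooth_window=smooth_window),
        max_dispersion=dispersion,
    )


def aggregate_trials(p1: BalanceParameters, p2: BalanceParameters) -> BalanceParameters:
    """Combine the two trials of a task by element-wise arithmetic mean."""
    a, b = np.array(p1.as_tuple()), np.array(p2.as_tuple())
    m = (a + b) / 2.0
    return BalanceParameters(*m)
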