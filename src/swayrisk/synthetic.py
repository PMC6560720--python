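"""Synthetic inputs: rendered depth sequences and feature-level cohorts.

Two levels of simulation make every pipeline stage testable without
recorded data:

* **Rendered level** — a swaying upright body in front of a flat
  background plane, imaged by a pinhole depth camera.  The sway is a
  sinusoid plus smoothed Gaussian velocity noise (closed-form standard
  deviation and peak speed, so the measured balance parameters can be
  checked analytically).  Intermittent arm abductions appear as
  horizontal protrusions, posture-break episodes as a widened stance.
  Ground-truth masks and the exact centroid path are exported alongside.

* **Feature level** — an 84-participant cohort (44 young + 40 elderly by
  default, mirroring the study design) whose balance parameters are
  drawn from log-normal distributions.  Young and non-at-risk elderly
  share a "better balance" distribution; at-risk elderly draw from a
  distribution shifted on selected tasks.  Effect sizes are specified in
  trial-level log-feature standard deviations; the clustering pipeline
  averages the two trials, which sharpens the participant-level
  separation by sqrt(2).  TUG, age and activity are drawn per group with
  the expected correlations (at-risk: slower TUG, lower activity, older).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .depth_io import (
    PARAMETER_NAMES,
    CohortTable,
    DepthFrame,
    DepthSequence,
    feature_column,
    write_cohort,
    write_depth_sequence,
)

__all__ = [
    "BalanceTask",
    "TASKS",
    "SwayProfile",
    "BodyModel",
    "CohortSpec",
    "SwayTrace",
    "RenderResult",
    "GeneratedCohort",
    "simulate_sway_trace",
    "render_depth_sequence",
    "generate_feature_cohort",
    "generate_study_fixture",
    "measured_log_effect_size",
    "profile_for_group",
    "DEFAULT_INTRINSICS",
    "DEFAULT_IMAGE_SHAPE",
]

DEFAULT_INTRINSICS = (365.456, 365.456, 256.0, 212.0)
DEFAULT_IMAGE_SHAPE = (424, 512)  # rows, cols


@dataclass(frozen=True)
class BalanceTask:
    """One standing balance task: stance, vision condition, duration."""

    number: int
    origin: str
    stance: str
    eyes: str
    duration_s: float


#: The eight-task catalogue (task 1 lasts two minutes, the rest one).
TASKS: tuple[BalanceTask, ...] = (
    BalanceTask(1, "Berg test, CTSIB", "Feet slightly apart", "open", 120.0),
    BalanceTask(2, "Berg test, CTSIB", "Feet slightly apart", "closed", 60.0),
    BalanceTask(3, "Berg and Tinetti test", "Narrow stance", "open", 60.0),
    BalanceTask(4, "Tinetti test", "Narrow stance", "closed", 60.0),
    BalanceTask(5, "Berg test", "On one leg", "open", 60.0),
    BalanceTask(6, "Berg test", "Tandem stance", "open", 60.0),
    BalanceTask(7, "CTSIB", "Two feet on foam pad", "open", 60.0),
    BalanceTask(8, "CTSIB", "Two feet on foam pad", "closed", 60.0),
)


@dataclass(frozen=True)
class SwayProfile:
    """Generating parameters for one participant's sway during a task."""

    lateral_amplitude: float = 0.01  # m
    ap_amplitude: float = 0.006  # m, antero-posterior (depth axis)
    sway_frequency: float = 0.5  # Hz
    velocity_noise_sd: float = 0.0  # m/s
    arm_event_rate: float = 0.0  # events / minute
    arm_event_duration: float = 2.0  # s
    posture_break_rate: float = 0.0  # events / minute
    posture_break_duration: float = 4.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "lateral_amplitude", "ap_amplitude", "sway_frequency",
            "velocity_noise_sd", "arm_event_rate", "arm_event_duration",
            "posture_break_rate", "posture_break_duration",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class BodyModel:
    """Upright body as a vertically elliptical silhouette with depth relief.

    The silhouette half-width varies elliptically with height (so the
    discrete mask edge crosses pixel boundaries at a different sway phase
    on every row, keeping the rendered centroid smooth), and the front
    surface bulges toward the camera by up to ``torso_half_depth``.
    """

    height: float = 1.70  # m
    torso_half_width: float = 0.22  # m
    torso_half_depth: float = 0.12  # m
    arm_length: float = 0.35  # m
    stand_distance: float = 2.0  # m, camera to body axis

    def __post_init__(self) -> None:
        for name in ("height", "torso_half_width", "torso_half_depth",
                     "arm_length", "stand_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SwayTrace:
    """Ground-truth horizontal trajectory with labeled event intervals."""

    positions: np.ndarray  # (n, 2): lateral x, antero-posterior z offsets (m)
    frame_rate_hz: float
    arm_events: tuple[tuple[int, int], ...] = ()  # [start, end) frame ranges
    posture_breaks: tuple[tuple[int, int], ...] = ()

    def __len__(self) -> int:
        return len(self.positions)


def simulate_sway_trace(
    profile: SwayProfile, duration_s: float, rate_hz: float = 30.0
) -> SwayTrace:
    """Sinusoid-plus-smoothed-noise sway trajectory with event intervals.

    Lateral sway is ``A sin(2 pi f t)``; antero-posterior sway is the same
    frequency in quadrature.  Velocity noise is white Gaussian, smoothed
    with a 2-frame-sigma Gaussian kernel and integrated.  Arm abductions
    and posture breaks arrive as Poisson events at their stated rates.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(profile.seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    omega = 2 * np.pi * profile.sway_frequency
    x = profile.lateral_amplitude * np.sin(omega * t)
    z = profile.ap_amplitude * np.sin(omega * t + np.pi / 2)
    if profile.velocity_noise_sd > 0:
        v = rng.normal(0.0, profile.velocity_noise_sd, size=(n, 2))
        v = ndimage.gaussian_filter1d(v, sigma=2.0, axis=0)
        drift = np.cumsum(v, axis=0) / rate_hz
        x = x + drift[:, 0]
        z = z + drift[:, 1]

    def _events(rate_per_min: float, duration: float) -> tuple[tuple[int, int], ...]:
        if rate_per_min <= 0:
            return ()
        count = rng.poisson(rate_per_min * duration_s / 60.0)
        spans = []
        for start_s in np.sort(rng.uniform(0.0, duration_s, size=count)):
            a = int(start_s * rate_hz)
            b = min(n, a + max(1, int(duration * rate_hz)))
            spans.append((a, b))
        return tuple(spans)

    return SwayTrace(
        positions=np.column_stack([x, z]),
        frame_rate_hz=rate_hz,
        arm_events=_events(profile.arm_event_rate, profile.arm_event_duration),
        posture_breaks=_events(profile.posture_break_rate, profile.posture_break_duration),
    )


@dataclass(frozen=True)
class RenderResult:
    """A rendered sequence plus its geometric ground truth."""

    sequence: DepthSequence
    truth_masks: list[np.ndarray]  # one bool grid per non-background frame
    truth_centroids: np.ndarray  # (n, 3) metres, camera frame
    trace: SwayTrace


def _in_spans(i: int, spans: Sequence[tuple[int, int]]) -> bool:
    return any(a <= i < b for a, b in spans)


def render_depth_sequence(
    trace: SwayTrace,
    body: BodyModel = BodyModel(),
    *,
    image_shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
    intrinsics: tuple[float, float, float, float] = DEFAULT_INTRINSICS,
    background_frames: int = 30,
    background_depth_m: float = 4.0,
    noise_sd_mm: float = 0.0,
    stance_widen_factor: float = 1.8,
    seed: int = 0,
) -> RenderResult:
    """Render a depth sequence of the swaying body over a background plane.

    The body is vertically centred on the optical axis; the shoulders sit
    a quarter body-height above centre and grow horizontal arm bars
    during arm events; posture breaks widen the below-centre silhouette
    by ``stance_widen_factor``.  Optional Gaussian depth noise (mm) is
    added before quantization to integer millimetres.
    """
    h, w = image_shape
    fx, fy, cx, cy = intrinsics
    rng = np.random.default_rng(seed)
    half_h = body.height / 2.0
    reach = body.torso_half_width * stance_widen_factor + body.arm_length
    max_off = float(np.abs(trace.positions[:, 0]).max(initial=0.0))
    z_min = body.stand_distance + float(trace.positions[:, 1].min(initial=0.0))
    if (body.torso_half_width + body.arm_length + max_off) > (w / 2) * z_min / fx:
        raise ValueError("body (with arms) does not fit the camera frame laterally")
    if half_h > (h / 2) * z_min / fy:
        raise ValueError("body does not fit the camera frame vertically")
    if background_depth_m <= body.stand_distance:
        raise ValueError("background plane must lie behind the body")

    u = np.arange(w)
    v = np.arange(h)
    bg_mm = background_depth_m * 1000.0

    def _quantize(depth_mm: np.ndarray) -> np.ndarray:
        if noise_sd_mm > 0:
            depth_mm = depth_mm + rng.normal(0.0, noise_sd_mm, size=depth_mm.shape)
        return np.clip(np.rint(depth_mm), 1, 65535).astype(np.uint16)

    frames: list[DepthFrame] = []
    for i in range(background_frames):
        frames.append(DepthFrame(grid=_quantize(np.full((h, w), bg_mm)), index=i))

    truth_masks: list[np.ndarray] = []
    truth_centroids = np.empty((len(trace), 3))
    for i in range(len(trace)):
        xc = float(trace.positions[i, 0])
        z0 = body.stand_distance + float(trace.positions[i, 1])
        # Depth relief varies with HEIGHT (chest fullest): each row's front
        # face is laterally flat, so lateral ray sampling is uniform and the
        # sampled centroid translates exactly with the body.  Solve the
        # ray-surface intersection y = (v - cy) d / fy per row.
        tan_u = (u - cx) / fx
        tan_v = (v - cy) / fy
        d_rows = np.full(h, z0)
        for _ in range(4):
            y_rows = tan_v * d_rows
            arg = np.clip(1.0 - (y_rows / half_h) ** 2, 0.0, 1.0)
            d_rows = z0 - body.torso_half_depth * np.sqrt(arg)
        y_rows = tan_v * d_rows
        # elliptical width profile over height
        width = body.torso_half_width * np.sqrt(
            np.clip(1.0 - (y_rows / half_h) ** 2, 0.0, 1.0)
        )
        width[np.abs(y_rows) > half_h] = -1.0  # outside the body: match nothing
        if _in_spans(i, trace.posture_breaks):
            legs = y_rows > 0.1 * half_h
            width[legs] *= stance_widen_factor
        dx = tan_u[None, :] * d_rows[:, None] - xc  # true lateral offset per pixel
        mask = np.abs(dx) <= width[:, None]
        if _in_spans(i, trace.arm_events):
            band = np.abs(y_rows - (-0.5 * half_h)) <= 0.06
            mask |= band[:, None] & (np.abs(dx) <= body.torso_half_width + body.arm_length)
        depth_rows_mm = d_rows * 1000.0
        depth_mm = np.where(mask, depth_rows_mm[:, None], bg_mm)

        # exact centroid from the un-quantized geometry
        n_row = mask.sum(axis=1)
        npts = int(n_row.sum())
        d_m = d_rows
        sx = float((d_m * (mask * tan_u[None, :]).sum(axis=1)).sum())
        sy = float((n_row * y_rows).sum())
        sz = float((n_row * d_m).sum())
        truth_centroids[i] = (sx / npts, sy / npts, sz / npts)
        truth_masks.append(mask)
        frames.append(DepthFrame(grid=_quantize(depth_mm), index=background_frames + i))

    seq = DepthSequence(
        frames=frames,
        frame_rate_hz=trace.frame_rate_hz,
        depth_scale_mm=1.0,
        intrinsics=intrinsics,
        background_frames=background_frames,
    )
    return RenderResult(
        sequence=seq, truth_masks=truth_masks, truth_centroids=truth_centroids, trace=trace
    )


# ---------------------------------------------------------------------------
# Feature-level cohorts
# ---------------------------------------------------------------------------


def _default_log_loc() -> dict[str, float]:
    # typical better-balance values: ~8 mm sway SD, ~5 cm/s peak speed,
    # dispersion ratio ~8
    return {
        "centroid_variability": float(np.log(0.008)),
        "centroid_max_speed": float(np.log(0.05)),
        "max_dispersion": float(np.log(8.0)),
    }


def _default_task_shift() -> dict[int, float]:
    return {8: 3.0}


@dataclass(frozen=True)
class CohortSpec:
    """Generating distributions for a feature-level cohort.

    Balance parameters are log-normal; ``task_shift_sd`` gives, per task,
    the at-risk group's upward shift in units of the trial-level
    log-feature standard deviation (``feature_log_scale``).  TUG,
    activity and age are (truncated) normal / uniform per group, with
    at-risk elderly slower on the TUG, less active and older.
    """

    n_young: int = 44
    n_elderly: int = 40
    fraction_elderly_at_risk: float = 0.5
    feature_log_loc: Mapping[str, float] = field(default_factory=_default_log_loc)
    feature_log_scale: float = 0.2
    task_shift_sd: Mapping[int, float] = field(default_factory=_default_task_shift)
    shifted_parameters: tuple[str, ...] = PARAMETER_NAMES
    young_age: tuple[float, float] = (21.0, 29.0)
    elderly_age: tuple[float, float] = (65.0, 80.0)
    at_risk_age: tuple[float, float] = (70.0, 85.0)
    young_tug: tuple[float, float] = (8.5, 0.8)  # mean, sd (s)
    elderly_tug: tuple[float, float] = (10.0, 1.1)
    at_risk_tug: tuple[float, float] = (12.5, 0.9)
    tug_trial_sd: float = 0.3  # within-participant trial scatter (s)
    young_activity: tuple[float, float] = (1500.0, 500.0)  # MET-min/week
    elderly_activity: tuple[float, float] = (1200.0, 400.0)
    at_risk_activity: tuple[float, float] = (400.0, 200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 0 or self.n_elderly < 0:
            raise ValueError("cohort counts must be non-negative")
        if not 0 <= self.fraction_elderly_at_risk <= 1:
            raise ValueError("fraction_elderly_at_risk must be in [0, 1]")
        if self.feature_log_scale <= 0:
            raise ValueError("feature_log_scale must be positive")

    def null_features(self) -> "CohortSpec":
        """No between-group feature structure (single feature distribution)."""
        return dataclasses.replace(self, task_shift_sd={})

    def null_correlates(self) -> "CohortSpec":
        """Feature structure intact, but all elderly share one TUG / age /
        activity distribution — the null for cluster-correlate tests."""
        return dataclasses.replace(
            self,
            at_risk_tug=self.elderly_tug,
            at_risk_age=self.elderly_age,
            at_risk_activity=self.elderly_activity,
        )


@dataclass(frozen=True)
class GeneratedCohort:
    """A synthetic cohort with its latent truth labels."""

    cohort: CohortTable
    at_risk_ids: frozenset[str]
    spec: CohortSpec


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > low:
            return float(v)
    raise ValueError(f"truncated normal ({mean}, {sd}) rarely exceeds {low}")


def generate_feature_cohort(spec: CohortSpec) -> GeneratedCohort:
    """Draw an 84-participant (by default) cohort at the feature level.

    Young and non-at-risk elderly draw every parameter from the baseline
    log-normal; at-risk elderly draw shifted values on the tasks listed in
    ``spec.task_shift_sd``.  Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_at_risk = int(round(spec.n_elderly * spec.fraction_elderly_at_risk))
    at_risk_idx = set(rng.choice(spec.n_elderly, size=n_at_risk, replace=False).tolist())

    rows = []
    at_risk_ids = set()
    participants = [("young", i) for i in range(spec.n_young)] + [
        ("elderly", i) for i in range(spec.n_elderly)
    ]
    for group, i in participants:
        pid = f"{'Y' if group == 'young' else 'E'}{i + 1:03d}"
        at_risk = group == "elderly" and i in at_risk_idx
        if at_risk:
            at_risk_ids.add(pid)
            age_rng, tug_d, act_d = spec.at_risk_age, spec.at_risk_tug, spec.at_risk_activity
        elif group == "elderly":
            age_rng, tug_d, act_d = spec.elderly_age, spec.elderly_tug, spec.elderly_activity
        else:
            age_rng, tug_d, act_d = spec.young_age, spec.young_tug, spec.young_activity
        row: dict[str, object] = {
            "id": pid,
            "group": group,
            "age": float(np.round(rng.uniform(*age_rng), 1)),
            "activity_met_min_week": max(0.0, float(np.round(rng.normal(*act_d), 1))),
        }
        base = _truncated_normal(rng, tug_d[0], tug_d[1], 0.5)
        for j in (1, 2, 3):
            row[f"tug_{j}"] = round(_truncated_normal(rng, base, spec.tug_trial_sd, 0.5), 3)
        for task in TASKS:
            shift = spec.task_shift_sd.get(task.number, 0.0) if at_risk else 0.0
            for trial in (1, 2):
                for param in PARAMETER_NAMES:
                    loc = spec.feature_log_loc[param]
                    if param in spec.shifted_parameters:
                        loc = loc + shift * spec.feature_log_scale
                    value = float(np.exp(rng.normal(loc, spec.feature_log_scale)))
                    row[feature_column(task.number, trial, param)] = value
        rows.append(row)
    cohort = CohortTable(pd.DataFrame(rows))
    return GeneratedCohort(cohort=cohort, at_risk_ids=frozenset(at_risk_ids), spec=spec)


def measured_log_effect_size(gen: GeneratedCohort, task: int, parameter: str) -> float:
    """Realized standardized between-group difference on trial-level
    log-features: (mean_at_risk - mean_rest) / pooled SD."""
    df = gen.cohort.table
    cols = [feature_column(task, trial, parameter) for trial in (1, 2)]
    values = np.log(df[cols].to_numpy(float))
    risk = df["id"].isin(gen.at_risk_ids).to_numpy()
    a = values[risk].ravel()
    b = values[~risk].ravel()
    pooled = np.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    )
    return float((a.mean() - b.mean()) / pooled)


def profile_for_group(at_risk: bool, seed: int = 0) -> SwayProfile:
    """Representative sway profiles for the two latent balance groups."""
    if at_risk:
        return SwayProfile(
            lateral_amplitude=0.022, ap_amplitude=0.012, sway_frequency=0.6,
            velocity_noise_sd=0.008, arm_event_rate=3.0, arm_event_duration=2.0,
            posture_break_rate=0.5, seed=seed,
        )
    return SwayProfile(
        lateral_amplitude=0.008, ap_amplitude=0.005, sway_frequency=0.45,
        velocity_noise_sd=0.003, arm_event_rate=0.3, arm_event_duration=1.5,
        posture_break_rate=0.0, seed=seed,
    )


def generate_study_fixture(
    spec: CohortSpec,
    out_dir: str | Path,
    render: bool = False,
    render_count: int = 2,
    render_task: int = 8,
    render_duration_s: float = 10.0,
) -> Path:
    """Write a complete on-disk study fixture.

    Always writes ``cohort.csv`` and a ``manifest.json`` (spec, seed,
    latent truth labels).  With ``render=True`` the first ``render_count``
    participants additionally get a rendered depth sequence of
    ``render_task`` under ``depth/<id>/task<k>_trial1/``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = generate_feature_cohort(spec)
    write_cohort(gen.cohort, out / "cohort.csv")
    manifest = {
        "seed": spec.seed,
        "spec": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(gen.spec).items()
        },
        "at_risk_ids": sorted(gen.at_risk_ids),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if render:
        rate = 30.0
        for k, pid in enumerate(gen.cohort.ids[:render_count]):
            profile = profile_for_group(pid in gen.at_risk_ids, seed=spec.seed * 1000 + k)
            trace = simulate_sway_trace(profile, duration_s=render_duration_s, rate_hz=rate)
            result = render_depth_sequence(trace)
            write_depth_sequence(
                result.sequence, out / "depth" / pid / f"task{render_task}_trial1"
            )
    return out
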