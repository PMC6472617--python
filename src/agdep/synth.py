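"""Synthetic study generator: rendered overhead trials and behavior.

Every fixture the pipeline consumes can be produced here with exact
ground truth: schematic overhead frames of a marmoset head (an ellipse
flanked by two bright ear-tuft disks on a dark floor), smooth
head-angle trajectories with scheduled threshold crossings and
occlusion windows, infrared-LED flash schedules carrying a session ID
code, and per-trial behavioral response tables drawn from a Gamma /
Bernoulli generative model with subject-nested-in-group random
intercepts.

Rendering is deliberately schematic rather than photorealistic: the
head-direction algorithm depends only on contrast and tuft geometry,
which schematic frames control exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stimuli
from .geometry import facing_vector, tuft_axis, wrap_angle

__all__ = [
    "DEFAULT_FRAME_SHAPE",
    "DEFAULT_LED_ROI",
    "HeadGeometry",
    "FlashSchedule",
    "Trajectory",
    "BehaviorSimSpec",
    "render_frame",
    "make_flash_schedule",
    "make_trajectory",
    "scan_turn_frames",
    "render_trial_video",
    "simulate_responses",
    "generate_full_study",
]

#: default fixture frame size (rows, cols); small to keep suites fast,
#: geometry scales through HeadGeometry
DEFAULT_FRAME_SHAPE = (120, 160)
#: (row_start, row_stop, col_start, col_stop) of the LED region of interest
DEFAULT_LED_ROI = (0, 8, 0, 8)

#: inner-repeat counts of the four trials in each test subclass of the
#: discrimination design
SUBCLASS_TRIAL_REPEATS = {
    "repetition": (1, 2, 4, 4),
    "variation": (3, 3, 5, 5),
    "missing_first": (1, 2, 3, 4),
    "missing_last": (1, 2, 3, 4),
}


@dataclass(frozen=True)
class HeadGeometry:
    """Schematic head: ellipse axes, tuft disks and intensity levels.

    The tuft intensity must exceed the head intensity, which must exceed
    the background -- the contrast assumption the tracker relies on
    (white ear tufts on a black-painted box floor).
    """

    head_major_px: float = 18.0  # semi-axis along the facing direction
    head_minor_px: float = 13.0
    tuft_radius_px: float = 4.0
    tuft_offset_px: float = 16.0
    background: float = 0.05
    head_intensity: float = 0.45
    tuft_intensity: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tuft_intensity > self.head_intensity > self.background):
            raise ValueError("need tuft intensity > head intensity > background")

    @property
    def extent_px(self) -> float:
        """Radius of the smallest circle containing head and tufts."""
        return max(self.head_major_px, self.tuft_offset_px + self.tuft_radius_px)


def render_frame(
    angle_deg: float,
    center_rc: tuple[float, float],
    geometry: HeadGeometry = HeadGeometry(),
    frame_shape: tuple[int, int] = DEFAULT_FRAME_SHAPE,
    noise_sd: float = 0.0,
    seed: int | None = None,
    occlude: str | None = None,
    led_on: bool = False,
    led_roi: tuple[int, int, int, int] = DEFAULT_LED_ROI,
) -> np.ndarray:
    """Render one overhead frame of a head facing ``angle_deg``.

    The head ellipse's major axis lies along the facing direction; the
    two tuft disks sit at +/- ``tuft_offset_px`` along the perpendicular
    inter-tuft axis.  ``occlude`` ("left"/"right", by image x of the
    tuft) hides one tuft, emulating a sideways head tilt.  ``led_on``
    saturates the LED region of interest.
    """
    h, w = frame_shape
    r0, c0 = center_rc
    ext = geometry.extent_px
    if r0 - ext < 0 or r0 + ext > h - 1 or c0 - ext < 0 or c0 + ext > w - 1:
        raise ValueError(
            f"head geometry (extent {ext:.1f} px at centre {center_rc}) exceeds "
            f"the {frame_shape} frame"
        )
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    dx = cols - c0
    dy = rows - r0
    v = facing_vector(angle_deg)  # (x, y)
    p = tuft_axis(angle_deg)
    u1 = dx * v[0] + dy * v[1]
    u2 = dx * p[0] + dy * p[1]
    frame = np.full(frame_shape, geometry.background)
    ellipse = (u1 / geometry.head_major_px) ** 2 + (
        u2 / geometry.head_minor_px
    ) ** 2 <= 1.0
    frame[ellipse] = geometry.head_intensity
    tuft_centres = [
        (c0 - geometry.tuft_offset_px * p[0], r0 - geometry.tuft_offset_px * p[1]),
        (c0 + geometry.tuft_offset_px * p[0], r0 + geometry.tuft_offset_px * p[1]),
    ]
    tuft_centres.sort(key=lambda xy: (xy[0], xy[1]))  # left (smaller x) first
    for side, (tx, ty) in zip(("left", "right"), tuft_centres):
        if occlude == side:
            continue
        disk = (cols - tx) ** 2 + (rows - ty) ** 2 <= geometry.tuft_radius_px**2
        frame[disk] = geometry.tuft_intensity
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frame = frame + rng.normal(0.0, noise_sd, frame.shape)
    if led_on:
        frame[led_roi[0] : led_roi[1], led_roi[2] : led_roi[3]] = (
            geometry.tuft_intensity
        )
    return frame


@dataclass(frozen=True)
class FlashSchedule:
    """Infrared-LED flash plan: an ID pulse train plus stimulus markers.

    The session ID is encoded MSB-first in ``id_bits`` consecutive time
    slots of ``slot_frames`` frames each; a 1-bit is a ``flash_frames``
    flash at the slot start.  After the ID window, single flashes mark
    stimulus onset and offset.
    """

    session_id: int
    id_bits: int = 5
    slot_frames: int = 10
    flash_frames: int = 4
    stimulus_on_frame: int = 100
    stimulus_off_frame: int = 250

    def __post_init__(self) -> None:
        if not 0 <= self.session_id < 2**self.id_bits:
            raise ValueError(
                f"session_id {self.session_id} does not fit in {self.id_bits} bits"
            )
        if self.stimulus_on_frame < self.id_bits * self.slot_frames:
            raise ValueError("stimulus onset flash overlaps the ID window")
        if self.stimulus_off_frame <= self.stimulus_on_frame:
            raise ValueError("stimulus offset must follow onset")

    def flash_intervals(self) -> list[tuple[int, int]]:
        """Half-open frame intervals during which the LED is lit."""
        intervals = []
        for k in range(self.id_bits):
            bit = (self.session_id >> (self.id_bits - 1 - k)) & 1
            if bit:
                start = k * self.slot_frames
                intervals.append((start, start + self.flash_frames))
        for f in (self.stimulus_on_frame, self.stimulus_off_frame):
            intervals.append((f, f + self.flash_frames))
        return intervals


def make_flash_schedule(
    session_id: int, stimulus_on_frame: int, stimulus_off_frame: int, **kwargs
) -> FlashSchedule:
    return FlashSchedule(
        session_id=session_id,
        stimulus_on_frame=stimulus_on_frame,
        stimulus_off_frame=stimulus_off_frame,
        **kwargs,
    )


def scan_turn_frames(
    angles_deg: np.ndarray, threshold_deg: float = 90.0
) -> list[int]:
    """Frames where |angle| crosses from below to at-or-above threshold.

    Direct scan over the ground-truth trajectory; used to derive turn
    schedules and as the oracle against tracker-side event detection.
    """
    a = np.abs(np.asarray(angles_deg, dtype=float))
    crossings = []
    armed = a[0] < threshold_deg
    for i in range(1, len(a)):
        if armed and a[i] >= threshold_deg:
            crossings.append(i)
            armed = False
        elif a[i] < threshold_deg:
            armed = True
    return crossings


@dataclass(frozen=True)
class Trajectory:
    """Ground-truth head-angle trajectory at a fixed frame rate."""

    angles_deg: np.ndarray
    fps: float
    occlusion_windows: tuple[tuple[int, int], ...] = ()
    turn_schedule: tuple[int, ...] = ()

    @property
    def n_frames(self) -> int:
        return len(self.angles_deg)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def make_trajectory(
    baseline_angle: float,
    turns: Sequence[tuple[float, float, float]],
    duration_s: float,
    occlusions: Sequence[tuple[int, int]] = (),
    fps: float = 100.0,
    threshold_deg: float = 90.0,
) -> Trajectory:
    """Build a smooth trajectory from a baseline angle and excursions.

    ``turns`` is an ordered list of ``(start_time_s, target_angle_deg,
    duration_s)``: from each start time the angle eases (raised cosine)
    from its current value to the target over the given duration and
    holds there.  Overlapping turns are rejected.  The turn schedule is
    derived by scanning the sampled trajectory for threshold crossings.
    """
    n = int(round(duration_s * fps))
    angles = np.full(n, float(baseline_angle))
    prev_end = -math.inf
    current = float(baseline_angle)
    for t0, target, dur in turns:
        if t0 < prev_end:
            raise ValueError("overlapping turns in trajectory specification")
        if dur <= 0:
            raise ValueError("turn duration must be positive")
        i0 = int(round(t0 * fps))
        i1 = min(int(round((t0 + dur) * fps)), n)
        if i0 >= n:
            raise ValueError("turn starts after trajectory end")
        ease = 0.5 * (1.0 - np.cos(np.pi * np.arange(i1 - i0) / max(i1 - i0, 1)))
        angles[i0:i1] = current + (target - current) * ease
        angles[i1:] = target
        current = float(target)
        prev_end = t0 + dur
    for s, e in occlusions:
        if not (0 <= s < e <= n):
            raise ValueError(f"occlusion window ({s}, {e}) outside trajectory")
    return Trajectory(
        angles_deg=angles,
        fps=fps,
        occlusion_windows=tuple((int(s), int(e)) for s, e in occlusions),
        turn_schedule=tuple(scan_turn_frames(angles, threshold_deg)),
    )


def render_trial_video(
    trajectory: Trajectory,
    geometry: HeadGeometry = HeadGeometry(),
    flash_schedule: FlashSchedule | None = None,
    center_rc: tuple[float, float] = (70.0, 80.0),
    frame_shape: tuple[int, int] = DEFAULT_FRAME_SHAPE,
    noise_sd: float = 0.0,
    seed: int = 0,
    led_roi: tuple[int, int, int, int] = DEFAULT_LED_ROI,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one trial as a frame stack plus a ground-truth table.

    One frame per trajectory sample (nominally 100 frames/s).  Occlusion
    windows hide the left tuft; flash intervals light the LED region.
    Returns ``(frames, ground_truth)`` where the table has per-frame
    time, true angle, occlusion and LED state.
    """
    n = trajectory.n_frames
    flash_frames: set[int] = set()
    if flash_schedule is not None:
        for s, e in flash_schedule.flash_intervals():
            if e > n:
                raise ValueError(f"flash interval ({s}, {e}) outside the {n}-frame trial")
            flash_frames.update(range(s, e))
    occluded = np.zeros(n, dtype=bool)
    for s, e in trajectory.occlusion_windows:
        occluded[s:e] = True
    frames = np.empty((n, *frame_shape))
    for i in range(n):
        frames[i] = render_frame(
            float(trajectory.angles_deg[i]),
            center_rc,
            geometry,
            frame_shape,
            noise_sd=noise_sd,
            seed=None if noise_sd == 0 else seed * 100003 + i,
            occlude="left" if occluded[i] else None,
            led_on=i in flash_frames,
            led_roi=led_roi,
        )
    truth = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) / trajectory.fps,
            "angle_deg": trajectory.angles_deg,
            "occluded": occluded,
            "led_on": [i in flash_frames for i in range(n)],
        }
    )
    return frames, truth


@dataclass(frozen=True)
class BehaviorSimSpec:
    """Generative model for the behavioral response tables.

    Mean head orientation is Gamma distributed with a log-linear mean:
    intercept + a multiplicative consistency effect applied to consistent
    trials of Test 1 only (the interaction structure the study design
    probes) + group and subject-within-group random intercepts.  The
    per-trial head-turn indicator is Bernoulli with the analogous logit
    structure, and latencies of turned trials are log-normal.
    """

    n_subjects: int = 8
    n_groups: int = 2
    baseline_orientation_deg: float = 40.0
    consistency_effect: float = 1.5  # multiplicative, on the Gamma mean
    turn_odds_ratio: float = 2.5  # on the turn-probability odds
    baseline_turn_prob: float = 0.45
    subject_sd: float = 0.25  # log / logit scale
    group_sd: float = 0.10
    gamma_shape: float = 6.0
    latency_log_mean: float = math.log(1.5)  # seconds
    latency_log_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subject_sd < 0 or self.group_sd < 0:
            raise ValueError("random-intercept SDs must be >= 0")
        if self.gamma_shape <= 0:
            raise ValueError("Gamma shape must be > 0")


def _design_frame(spec: BehaviorSimSpec, level: str) -> pd.DataFrame:
    """Full factorial design: subjects x tests x subclasses (x trials)."""
    rows = []
    per_group = spec.n_subjects // spec.n_groups
    for s in range(spec.n_subjects):
        group = s // per_group
        order = s % per_group % 3 + 1  # testing order within the group's day
        for test in (1, 2):
            for subclass, repeats in SUBCLASS_TRIAL_REPEATS.items():
                consistency = (
                    "consistent"
                    if subclass in ("repetition", "variation")
                    else "inconsistent"
                )
                base = {
                    "subject_id": f"S{s + 1}",
                    "group_id": f"G{group + 1}",
                    "test_type": test,
                    "subclass": subclass,
                    "consistency": consistency,
                    "subject_order": order,
                }
                if level == "trial":
                    for j, n_rep in enumerate(repeats):
                        rows.append({**base, "trial_slot": j, "n_repeats": n_rep})
                else:
                    rows.append({**base, "n_trials": len(repeats)})
    return pd.DataFrame(rows)


def simulate_responses(
    spec: BehaviorSimSpec = BehaviorSimSpec(), level: str = "subclass"
) -> pd.DataFrame:
    """Draw a behavioral response table from the generative model.

    ``level="subclass"`` yields one record per subject x test x subclass
    (the shape the discrimination GLMMs consume: 64 records for the full
    8-subject design, with the turn counts as ``turn_trials`` out of
    ``n_trials``); ``level="trial"`` yields one record per trial.
    Deterministic given ``spec.seed``.
    """
    if level not in ("subclass", "trial"):
        raise ValueError("level must be 'subclass' or 'trial'")
    rng = np.random.default_rng(spec.seed)
    design = _design_frame(spec, level)
    groups = sorted(design["group_id"].unique())
    subjects = sorted(design["subject_id"].unique(), key=lambda s: int(s[1:]))
    b_group = {g: rng.normal(0.0, spec.group_sd) for g in groups}
    b_subj = {s: rng.normal(0.0, spec.subject_sd) for s in subjects}

    effect_on = (
        (design["test_type"] == 1) & (design["consistency"] == "consistent")
    ).to_numpy()
    re_shift = (
        design["group_id"].map(b_group) + design["subject_id"].map(b_subj)
    ).to_numpy()
    log_mu = (
        math.log(spec.baseline_orientation_deg)
        + math.log(spec.consistency_effect) * effect_on
        + re_shift
    )
    mu = np.exp(log_mu)
    design["mean_orientation"] = rng.gamma(
        spec.gamma_shape, mu / spec.gamma_shape
    )
    design["max_rotation"] = np.minimum(
        design["mean_orientation"] * rng.uniform(1.2, 2.0, len(design)), 180.0
    )
    logit_p = (
        math.log(spec.baseline_turn_prob / (1.0 - spec.baseline_turn_prob))
        + math.log(spec.turn_odds_ratio) * effect_on
        + re_shift
    )
    p_turn = 1.0 / (1.0 + np.exp(-logit_p))
    if level == "trial":
        design["turned"] = rng.binomial(1, p_turn)
        lat = np.exp(rng.normal(spec.latency_log_mean, spec.latency_log_sd, len(design)))
        design["latency"] = np.where(design["turned"] == 1, lat, np.nan)
    else:
        design["turn_trials"] = rng.binomial(design["n_trials"], p_turn)
        lat = np.exp(rng.normal(spec.latency_log_mean, spec.latency_log_sd, len(design)))
        design["latency"] = np.where(design["turn_trials"] > 0, lat, np.nan)
    return design


def generate_full_study(
    master_seed: int,
    out_dir: str | Path | None = None,
    behavior: BehaviorSimSpec | None = None,
) -> dict:
    """Generate a complete synthetic study: stimuli, manifest, responses.

    Eight subjects in two groups, each tested in both grammars (Test 1:
    LH^nL consistent; Test 2: HL^nH consistent) with 16 trials per
    session -- 256 trial records in total, every subject with an
    individual stimulus set drawn from one shared tone inventory.
    Per-trial behavioral responses are drawn from ``behavior`` (defaults
    to ``BehaviorSimSpec`` seeded from ``master_seed``).

    Returns a dict with the tone ``inventory``, the 256-row trial
    ``manifest``, the trial-level ``responses`` table, and the
    familiarization ``tracks`` per group.  If ``out_dir`` is given the
    tables are written as CSV.
    """
    if behavior is None:
        behavior = BehaviorSimSpec(seed=master_seed)
    inventory = stimuli.sample_tone_inventory(master_seed)
    sim = simulate_responses(replace(behavior, seed=behavior.seed), level="trial")

    rows = []
    draws = {
        (r["subject_id"], r["test_type"], r["subclass"], r["trial_slot"]): r
        for r in sim.to_dict("records")
    }
    subjects = sorted(sim["subject_id"].unique(), key=lambda s: int(s[1:]))
    for subj in subjects:
        meta = sim[sim["subject_id"] == subj].iloc[0]
        for test in (1, 2):
            session = stimuli.generate_test_session(
                f"Test{test}", subj, inventory, master_seed
            )
            slot_counter: dict[str, int] = {}
            for trial in session:
                ts = trial.sequence.token_string
                slot = slot_counter.get(ts.subclass, 0)
                slot_counter[ts.subclass] = slot + 1
                resp = draws[(subj, test, ts.subclass, slot)]
                rows.append(
                    {
                        "subject_id": subj,
                        "group_id": meta["group_id"],
                        "test_type": test,
                        "trial_index": trial.trial_index,
                        "token_string": str(ts),
                        "subclass": ts.subclass,
                        "consistency": ts.consistency,
                        "n_repeats": ts.n_repeats,
                        "subject_order": meta["subject_order"],
                        "mean_orientation": resp["mean_orientation"],
                        "max_rotation": resp["max_rotation"],
                        "turned": resp["turned"],
                        "latency": resp["latency"],
                    }
                )
    manifest = pd.DataFrame(rows)
    tracks = {
        f"G{g + 1}": stimuli.compose_familiarization_track(
            stimuli.FAMILIARIZATION_COUNTS, inventory, seed=master_seed + g
        )
        for g in range(behavior.n_groups)
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(out / "manifest.csv", index=False)
        manifest.drop(columns=["token_string"]).to_csv(
            out / "responses.csv", index=False
        )
    return {
        "inventory": inventory,
        "manifest": manifest,
        "responses": manifest,
        "tracks": tracks,
    }
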