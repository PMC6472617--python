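"""Automated head-direction coding of overhead trial videos.

Three-step per-frame pipeline: (1) locate the head by normalized
cross-correlation against a template image, (2) threshold the bright
ear tufts inside the head region and take the two largest blob
centroids, (3) extrapolate the facing direction as the perpendicular
of the inter-tuft axis, resolving the intrinsic 180-degree ambiguity
by temporal continuity (seeded by the animal's known entry direction).

Frames where a tuft is occluded are marked invalid and later filled by
carrying the last valid angle forward; isolated 180-degree misflips
are corrected automatically and logged.  Head-turn events are coded
when the corrected absolute angle crosses the 90-degree threshold
within the response window, and per-trial summaries collect the four
response variables (mean orientation, maximum rotation, number of
turns, latency).

LED synchronization flashes are decoded from a brightness series of
the LED region: a leading pulse train carries the session ID and
subsequent single flashes mark stimulus onset and offset.

Angle convention: 0 deg = facing the front wall (feeding opening),
+/-180 deg = facing the loudspeaker; see :mod:`agdep.geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.feature import match_template
from skimage.measure import label, regionprops

from .geometry import axis_to_angle_candidates, circular_difference, wrap_angle

__all__ = [
    "HeadDetection",
    "TuftPair",
    "AngleSeries",
    "HeadTurnEvent",
    "TrialSummary",
    "SyncEvent",
    "SyncResult",
    "detect_head",
    "detect_tufts",
    "head_direction",
    "build_angle_series",
    "apply_corrections",
    "detect_turns",
    "summarize_trial",
    "detect_sync",
    "write_overlay_frames",
]

#: relative blob threshold: bright = above min + frac * (max - min) of the
#: head box, which makes detection invariant to overall brightness scaling
TUFT_THRESHOLD_FRAC = 0.75
#: minimum blob area (px) accepted as a tuft
MIN_TUFT_AREA = 3
#: a sample differing from both neighbours by 180 +/- this is a misflip
FLIP_TOLERANCE_DEG = 15.0


@dataclass(frozen=True)
class HeadDetection:
    found: bool
    center_rc: tuple[float, float] | None = None
    box: tuple[int, int, int, int] | None = None  # (r0, r1, c0, c1)
    score: float = 0.0


@dataclass(frozen=True)
class TuftPair:
    valid: bool
    left_centroid_rc: tuple[float, float] | None = None
    right_centroid_rc: tuple[float, float] | None = None


@dataclass
class AngleSeries:
    """Per-frame head direction with validity flags."""

    angles_deg: np.ndarray
    valid: np.ndarray
    fps: float
    initial_direction: float
    corrected: bool = False
    flipped_frames: tuple[int, ...] = ()
    carried_frames: tuple[int, ...] = ()

    @property
    def n_frames(self) -> int:
        return len(self.angles_deg)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def to_frame(self) -> pd.DataFrame:
        carried = np.zeros(self.n_frames, dtype=bool)
        carried[list(self.carried_frames)] = True
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": self.times_s,
                "angle_deg": self.angles_deg,
                "valid": self.valid,
                "corrected_flag": carried,
            }
        )


@dataclass(frozen=True)
class HeadTurnEvent:
    crossing_time_s: float  # from stimulus onset
    sign: int  # +90 or -90


@dataclass(frozen=True)
class TrialSummary:
    """The four response variables of one trial."""

    mean_orientation: float  # mean |angle| over the window, degrees
    max_rotation: float  # max |angle| over the window, degrees
    n_turns: int
    latency_s: float | None  # first crossing; None when no turn occurred


@dataclass(frozen=True)
class SyncEvent:
    frame_index: int
    kind: str  # id_code_bit | stimulus_on | stimulus_off


@dataclass(frozen=True)
class SyncResult:
    events: tuple[SyncEvent, ...]
    session_id: int | None
    incomplete: bool  # odd number of post-ID flashes


def detect_head(frame: np.ndarray, template: np.ndarray, score_threshold: float = 0.3) -> HeadDetection:
    """Locate the head by normalized cross-correlation with a template.

    Returns a no-detection result (``found=False``) for featureless
    frames or when the best correlation falls below ``score_threshold``;
    no-detection is a value, not an error.
    """
    if template.shape[0] > frame.shape[0] or template.shape[1] > frame.shape[1]:
        raise ValueError("template must be smaller than the frame")
    if float(np.std(frame)) < 1e-9:
        return HeadDetection(found=False)
    corr = match_template(frame.astype(float), template.astype(float), pad_input=True)
    peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
    score = float(corr[peak])
    if score < score_threshold:
        return HeadDetection(found=False, score=score)
    r, c = int(peak[0]), int(peak[1])
    th, tw = template.shape[:2]
    r0 = max(r - th // 2, 0)
    c0 = max(c - tw // 2, 0)
    r1 = min(r0 + th, frame.shape[0])
    c1 = min(c0 + tw, frame.shape[1])
    return HeadDetection(found=True, center_rc=(float(r), float(c)), box=(r0, r1, c0, c1), score=score)


def detect_tufts(frame: np.ndarray, head_box: tuple[int, int, int, int]) -> TuftPair:
    """Find the two bright ear-tuft blobs inside the head box.

    Pixels above a fixed fraction of the box's dynamic range are
    labelled; the centroids of the two largest components are returned,
    ordered left-to-right by image x (ties by y).  Fewer than two blobs
    (an occluded tuft) yields ``valid=False``.
    """
    r0, r1, c0, c1 = head_box
    patch = frame[r0:r1, c0:c1].astype(float)
    lo, hi = float(patch.min()), float(patch.max())
    if hi - lo < 1e-9:
        return TuftPair(valid=False)
    mask = patch > lo + TUFT_THRESHOLD_FRAC * (hi - lo)
    props = [p for p in regionprops(label(mask)) if p.area >= MIN_TUFT_AREA]
    if len(props) < 2:
        return TuftPair(valid=False)
    props.sort(key=lambda p: p.area, reverse=True)
    cents = [
        (p.centroid[0] + r0, p.centroid[1] + c0) for p in props[:2]
    ]  # (row, col) in frame coords
    cents.sort(key=lambda rc: (rc[1], rc[0]))
    return TuftPair(valid=True, left_centroid_rc=cents[0], right_centroid_rc=cents[1])


def head_direction(tufts: TuftPair, previous_angle: float) -> float:
    """Facing angle from a tuft pair, disambiguated by continuity.

    The facing direction is perpendicular to the inter-tuft axis; of
    the two perpendicular candidates (180 degrees apart) the one
    angularly closer to ``previous_angle`` is returned (the first frame
    uses the stored initial looking direction).
    """
    if not tufts.valid:
        raise ValueError("cannot compute a direction from an invalid tuft pair")
    (ly, lx), (ry, rx) = tufts.left_centroid_rc, tufts.right_centroid_rc
    axis_xy = np.array([rx - lx, ry - ly])
    cand_a, cand_b = axis_to_angle_candidates(axis_xy)
    if abs(circular_difference(cand_a, previous_angle)) <= abs(
        circular_difference(cand_b, previous_angle)
    ):
        return cand_a
    return cand_b


def build_angle_series(
    frames: Sequence[np.ndarray] | np.ndarray,
    template: np.ndarray,
    initial_direction: float,
    fps: float = 100.0,
    score_threshold: float = 0.3,
) -> AngleSeries:
    """Run the three-step coder over a frame stack.

    Frames without a head detection or with an occluded tuft are marked
    invalid (and not yet interpolated -- see :func:`apply_corrections`).
    Raises if no frame at all yields a detection.
    """
    n = len(frames)
    if n == 0:
        raise ValueError("empty frame stack")
    angles = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    previous = float(initial_direction)
    any_detection = False
    for i in range(n):
        det = detect_head(frames[i], template, score_threshold)
        if not det.found:
            continue
        any_detection = True
        tufts = detect_tufts(frames[i], det.box)
        if not tufts.valid:
            continue
        angle = head_direction(tufts, previous)
        angles[i] = angle
        valid[i] = True
        previous = angle
    if not any_detection:
        raise ValueError("head detection failed on every frame of the clip")
    return AngleSeries(
        angles_deg=angles, valid=valid, fps=fps, initial_direction=float(initial_direction)
    )


def apply_corrections(series: AngleSeries) -> AngleSeries:
    """Apply the two correction rules, yielding a fully valid series.

    Invalid frames (occluded tuft, missed detection) carry the last
    valid angle forward; leading invalid frames take the known entry
    direction.  Isolated samples differing from both temporal
    neighbours by 180 +/- ``FLIP_TOLERANCE_DEG`` degrees are flipped by
    180 degrees (the automated analogue of the manual back-of-head
    corrections); every flip is logged in ``flipped_frames``.
    Valid, unflipped samples are never altered.
    """
    if not series.valid.any():
        raise ValueError("cannot correct a series with no valid frame")
    angles = series.angles_deg.copy()
    carried = []
    last = series.initial_direction
    for i in range(len(angles)):
        if series.valid[i]:
            last = angles[i]
        else:
            angles[i] = last
            carried.append(i)
    flipped = []
    for i in range(1, len(angles) - 1):
        d_prev = circular_difference(angles[i], angles[i - 1])
        d_next = circular_difference(angles[i], angles[i + 1])
        if (
            abs(abs(d_prev) - 180.0) <= FLIP_TOLERANCE_DEG
            and abs(abs(d_next) - 180.0) <= FLIP_TOLERANCE_DEG
        ):
            angles[i] = wrap_angle(angles[i] + 180.0)
            flipped.append(i)
    return AngleSeries(
        angles_deg=angles,
        valid=np.ones(len(angles), dtype=bool),
        fps=series.fps,
        initial_direction=series.initial_direction,
        corrected=True,
        flipped_frames=tuple(flipped),
        carried_frames=tuple(carried),
    )


def _window_slice(series: AngleSeries, onset_time_s: float, window_s: float) -> np.ndarray:
    end = onset_time_s + window_s
    last_time = (series.n_frames - 1) / series.fps
    if onset_time_s < 0 or end > last_time + 1e-9:
        raise ValueError(
            f"response window [{onset_time_s}, {end}] s extends past the series "
            f"(last frame at {last_time:.2f} s)"
        )
    t = series.times_s
    return (t >= onset_time_s - 1e-9) & (t <= end + 1e-9)


def detect_turns(
    series: AngleSeries,
    onset_time_s: float,
    window_s: float = 5.0,
    threshold_deg: float = 90.0,
) -> list[HeadTurnEvent]:
    """Code head turns: |angle| crossings of the threshold in the window.

    One event per transition of the absolute angle from below to
    at-or-above the threshold; dropping back below re-arms detection.
    A trial already oriented past the threshold at onset contributes no
    event until the angle first re-enters the sub-threshold zone (a
    turn is a crossing, not a state).
    """
    mask = _window_slice(series, onset_time_s, window_s)
    idx = np.nonzero(mask)[0]
    a = np.abs(series.angles_deg[idx])
    events = []
    armed = a[0] < threshold_deg
    for k in range(len(idx)):
        if armed and a[k] >= threshold_deg:
            sign = 90 if series.angles_deg[idx[k]] > 0 else -90
            events.append(
                HeadTurnEvent(
                    crossing_time_s=idx[k] / series.fps - onset_time_s, sign=sign
                )
            )
            armed = False
        elif a[k] < threshold_deg:
            armed = True
    return events


def summarize_trial(
    series: AngleSeries,
    onset_time_s: float,
    window_s: float = 5.0,
    threshold_deg: float = 90.0,
) -> TrialSummary:
    """Compute the four response variables over the response window."""
    mask = _window_slice(series, onset_time_s, window_s)
    abs_angle = np.abs(series.angles_deg[mask])
    events = detect_turns(series, onset_time_s, window_s, threshold_deg)
    return TrialSummary(
        mean_orientation=float(abs_angle.mean()),
        max_rotation=float(abs_angle.max()),
        n_turns=len(events),
        latency_s=events[0].crossing_time_s if events else None,
    )


def write_overlay_frames(
    frames: Sequence[np.ndarray],
    series: AngleSeries,
    template: np.ndarray,
    out_dir,
    line_length_px: int = 30,
    score_threshold: float = 0.3,
) -> list:
    """Write review frames with the head-direction line drawn in.

    Mirrors the manual-revision output of the original coder: each
    frame gets a bright line from the head centre toward the computed
    point of visual attention.  Returns the written paths.
    """
    import imageio.v3 as iio
    from pathlib import Path
    from skimage.draw import line as skline

    from .geometry import facing_vector

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        img = np.asarray(frame, dtype=float).copy()
        det = detect_head(img, template, score_threshold)
        if det.found:
            v = facing_vector(float(series.angles_deg[i]))
            r0, c0 = det.center_rc
            r1 = int(round(r0 + line_length_px * v[1]))
            c1 = int(round(c0 + line_length_px * v[0]))
            rr, cc = skline(int(round(r0)), int(round(c0)), r1, c1)
            keep = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
            img[rr[keep], cc[keep]] = img.max()
        path = out / f"frame_{i:05d}.png"
        iio.imwrite(path, np.clip(img * 255, 0, 255).astype(np.uint8))
        paths.append(path)
    return paths


def detect_sync(
    brightness: np.ndarray,
    flash_threshold: float | None = None,
    id_bits: int = 5,
    slot_frames: int = 10,
) -> SyncResult:
    """Decode LED flashes from an LED-region brightness series.

    Flash onsets are rising edges of the thresholded series (default
    threshold: midway between the series minimum and maximum).  Onsets
    inside the leading ID window (``id_bits`` slots of ``slot_frames``
    frames) are pulse-train bits giving the session ID, MSB first;
    later flashes are labelled stimulus_on / stimulus_off alternately.
    An odd number of post-ID flashes flags the trial as incomplete.
    """
    b = np.asarray(brightness, dtype=float)
    if len(b) == 0 or float(b.max() - b.min()) < 1e-9:
        return SyncResult(events=(), session_id=None, incomplete=False)
    if flash_threshold is None:
        flash_threshold = 0.5 * (float(b.min()) + float(b.max()))
    lit = b > flash_threshold
    onsets = np.nonzero(lit & ~np.concatenate(([False], lit[:-1])))[0]
    if len(onsets) == 0:
        return SyncResult(events=(), session_id=None, incomplete=False)
    id_window = id_bits * slot_frames
    events: list[SyncEvent] = []
    session_id = 0
    saw_id_bit = False
    stim_flashes = []
    for f in onsets:
        if f < id_window:
            slot = int(f) // slot_frames
            session_id |= 1 << (id_bits - 1 - slot)
            saw_id_bit = True
            events.append(SyncEvent(frame_index=int(f), kind="id_code_bit"))
        else:
            stim_flashes.append(int(f))
    for j, f in enumerate(stim_flashes):
        kind = "stimulus_on" if j % 2 == 0 else "stimulus_off"
        events.append(SyncEvent(frame_index=f, kind=kind))
    return SyncResult(
        events=tuple(events),
        session_id=session_id if saw_id_bit else None,
        incomplete=len(stim_flashes) % 2 == 1,
    )
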