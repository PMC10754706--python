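"""Stimulus schedule generation, gaze-attendance coding, and inclusion rules.

The paradigm presents flickering images in four blocks that alternate
between two conditions — joint attention with communicative cues (JA) and
joint watching (JW).  Within a block each of the 15 images appears twice
in randomized order with no immediate repetitions; every third image is
preceded by a 3-s pre-phase.  Each image is preceded by a 1-s
attention-getter and a 0.5-0.8 s black-screen baseline gap and stays on
screen for 2 s.

Gaze coding marks an image as attended when the participant looked at the
screen from (at most) a short grace period after image onset — 500 ms,
i.e. 30 frames at 60 fps — continuously until image offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ScheduleError

CONDITIONS = ("JA", "JW")

IMAGE_DURATION_S = 2.0
GETTER_DURATION_S = 1.0
GAP_RANGE_S = (0.5, 0.8)
PRE_PHASE_DURATION_S = 3.0
PRE_PHASE_EVERY = 3

SCHEDULE_COLUMNS = ["time_s", "kind", "condition", "block", "image_id", "duration_s"]


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered timed events of one dyad's session.

    ``events`` is a DataFrame with columns ``time_s`` (onset, seconds),
    ``kind`` (pre_phase | attention_getter | baseline_gap | image),
    ``condition`` (JA | JW), ``block`` (1-based), ``image_id`` (1-based,
    0 for non-image events) and ``duration_s``.
    """

    events: pd.DataFrame
    image_duration_s: float = IMAGE_DURATION_S

    def __post_init__(self):
        missing = set(SCHEDULE_COLUMNS) - set(self.events.columns)
        if missing:
            raise ScheduleError(f"schedule missing columns: {sorted(missing)}")

    @property
    def images(self) -> pd.DataFrame:
        """Image events only, in presentation order (index reset)."""
        img = self.events[self.events["kind"] == "image"]
        return img.reset_index(drop=True)

    @property
    def n_images(self) -> int:
        return int((self.events["kind"] == "image").sum())

    @property
    def onsets(self) -> np.ndarray:
        return self.images["time_s"].to_numpy(dtype=float)

    @property
    def conditions(self) -> np.ndarray:
        return self.images["condition"].to_numpy()

    @property
    def end_time_s(self) -> float:
        last = self.events.iloc[-1]
        return float(last["time_s"] + last["duration_s"])

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StimulusSchedule":
        df = pd.read_csv(path)
        return cls(events=df[SCHEDULE_COLUMNS])


def _block_image_order(
    image_ids: np.ndarray, reps: int, rng: np.random.Generator, max_tries: int = 1000
) -> np.ndarray:
    """Random order with each id ``reps`` times and no consecutive repeats."""
    pool = np.repeat(image_ids, reps)
    if len(image_ids) < 2:
        raise ScheduleError(
            "no-consecutive-repetition constraint unsatisfiable with <2 images"
        )
    for _ in range(max_tries):
        order = rng.permutation(pool)
        if not np.any(order[1:] == order[:-1]):
            return order
    raise ScheduleError(
        f"could not draw a repetition-free image order in {max_tries} tries"
    )


def generate_schedule(
    n_images: int = 15,
    reps_per_block: int = 2,
    n_blocks: int = 4,
    first_condition: str = "JA",
    rng_seed: int | np.random.Generator = 0,
    start_time_s: float = 3.0,
) -> StimulusSchedule:
    """Generate a randomized block schedule.

    Blocks alternate conditions starting from ``first_condition``
    (counterbalancing parameter).  Image order within a block is drawn by
    rejection sampling until no image repeats back-to-back.
    """
    if n_images < 2:
        raise ScheduleError("need n_images >= 2")
    if reps_per_block < 1:
        raise ScheduleError("need reps_per_block >= 1")
    if n_blocks % 2 != 0 or n_blocks < 2:
        raise ScheduleError("n_blocks must be even and >= 2")
    if first_condition not in CONDITIONS:
        raise ScheduleError(f"unknown condition {first_condition!r}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    image_ids = np.arange(1, n_images + 1)
    other = "JW" if first_condition == "JA" else "JA"
    rows: list[tuple] = []
    t = float(start_time_s)
    for b in range(1, n_blocks + 1):
        cond = first_condition if b % 2 == 1 else other
        order = _block_image_order(image_ids, reps_per_block, rng)
        for i, img in enumerate(order):
            if i % PRE_PHASE_EVERY == 0:
                rows.append((t, "pre_phase", cond, b, 0, PRE_PHASE_DURATION_S))
                t += PRE_PHASE_DURATION_S
            rows.append((t, "attention_getter", cond, b, 0, GETTER_DURATION_S))
            t += GETTER_DURATION_S
            gap = float(rng.uniform(*GAP_RANGE_S))
            rows.append((t, "baseline_gap", cond, b, 0, gap))
            t += gap
            rows.append((t, "image", cond, b, int(img), IMAGE_DURATION_S))
            t += IMAGE_DURATION_S
    events = pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)
    return StimulusSchedule(events=events)


@dataclass(frozen=True)
class GazeTrack:
    """On-screen gaze intervals of one participant.

    ``intervals`` is an (n, 2) array of [start_s, end_s); intervals are
    sorted, non-overlapping, with non-negative duration.  ``frame_rate``
    supports frame arithmetic of the grace window (60 fps video coding).
    """

    role: str
    intervals: np.ndarray
    frame_rate: float = 60.0

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if np.any(iv[:, 1] < iv[:, 0]):
            raise ScheduleError("gaze interval with negative duration")
        if np.any(iv[1:, 0] < iv[:-1, 1] - 1e-9):
            raise ScheduleError("gaze intervals overlap or are unsorted")
        object.__setattr__(self, "intervals", iv)

    def grace_frames(self, grace_ms: float = 500.0) -> int:
        """Grace window expressed in video frames."""
        return int(round(grace_ms / 1000.0 * self.frame_rate))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "subject": self.role,
                "start_s": self.intervals[:, 0],
                "end_s": self.intervals[:, 1],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, role: str | None = None) -> "GazeTrack":
        df = pd.read_csv(path)
        if role is not None:
            df = df[df["subject"] == role]
        elif df["subject"].nunique() > 1:
            raise ScheduleError("gaze CSV holds several subjects; pass role=")
        r = role if role is not None else str(df["subject"].iloc[0])
        return cls(role=r, intervals=df[["start_s", "end_s"]].to_numpy())


def attendance_flags(
    gaze: GazeTrack,
    schedule: StimulusSchedule,
    grace_ms: float = 500.0,
) -> np.ndarray:
    """Per-image attendance flags from a gaze track.

    An image counts as attended when a single gaze interval starts no
    later than ``grace_ms`` after image onset and lasts continuously
    until image offset.
    """
    if grace_ms < 0:
        raise ScheduleError("grace_ms must be >= 0")
    onsets = schedule.onsets
    if onsets.size == 0:
        raise ScheduleError("schedule has no image events")
    iv = gaze.intervals
    offs = onsets + schedule.image_duration_s
    if iv.size == 0 or iv[:, 1].max() < onsets.min() or iv[:, 0].min() > offs.max():
        raise ScheduleError("gaze track and schedule time ranges are disjoint")
    grace_s = grace_ms / 1000.0
    eps = 1e-9
    flags = np.zeros(onsets.size, dtype=bool)
    for k, (on, off) in enumerate(zip(onsets, offs)):
        covers = (iv[:, 0] <= on + grace_s + eps) & (iv[:, 1] >= off - eps)
        flags[k] = bool(covers.any())
    return flags


def inclusion_decision(
    clean_epoch_counts: dict[str, int],
    min_epochs: int = 5,
    conditions: tuple[str, ...] = CONDITIONS,
) -> bool:
    """Participant inclusion: every condition needs >= ``min_epochs`` clean epochs."""
    if min_epochs < 1:
        raise ScheduleError("min_epochs must be >= 1")
    for cond in conditions:
        if cond not in clean_epoch_counts:
            raise ScheduleError(f"missing epoch count for condition {cond!r}")
        if clean_epoch_counts[cond] < 0:
            raise ScheduleError("epoch counts must be >= 0")
    return all(clean_epoch_counts[c] >= min_epochs for c in conditions)


@dataclass(frozen=True)
class AttendanceRateResult:
    mean_a: float
    mean_b: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def attendance_rate_test(
    flags_cond_a: list[np.ndarray],
    flags_cond_b: list[np.ndarray],
) -> AttendanceRateResult:
    """Dependent t-test on per-subject attendance proportions (A vs B).

    Each list element holds one subject's per-image boolean flags in one
    condition; subjects must line up across the two lists.
    """
    if len(flags_cond_a) != len(flags_cond_b):
        raise ScheduleError("conditions cover different subject sets")
    if len(flags_cond_a) < 2:
        raise ScheduleError("need at least 2 subjects")
    ra = np.array([np.mean(f) for f in flags_cond_a], dtype=float)
    rb = np.array([np.mean(f) for f in flags_cond_b], dtype=float)
    d = ra - rb
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        # zero-variance differences: t undefined; flag instead of dividing
        t = 0.0 if np.allclose(d.mean(), 0) else float(np.sign(d.mean()) * np.inf)
        p = 1.0 if t == 0.0 else 0.0
        return AttendanceRateResult(ra.mean(), rb.mean(), t, n - 1, p, degenerate=True)
    t, p = sps.ttest_rel(ra, rb)
    return AttendanceRateResult(ra.mean(), rb.mean(), float(t), n - 1, float(p))
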