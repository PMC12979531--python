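"""Stimulus-set enumeration and pseudorandomized session scheduling.

The experiment presents short videos (2.2-4 s) of a pigeon, or an abstract
control shape (a "greeble") animated with the same motion, performing one of
four behaviors (courtship, eating, flying, walking).  Four exemplar videos
exist per behavior, each with a sound-on and a sound-off version, plus four
auxiliary "two pigeon" videos.  The full set is therefore

    4 behaviors x 4 exemplars x 2 actors = 32 visually unique behavior videos
    + 4 two-pigeon videos               = 36 visually unique videos
    x 2 sound versions                  = 72 videos.

A session presents every video six times (three per monitor side), i.e. 432
trials, with the constraint that the same behavioral category never appears
more than three times in a row, and a random ~10% of trials rewarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BEHAVIORS = ("courtship", "eating", "flying", "walking")
TWO_PIGEON = "twoPigeon"
ACTORS = ("pigeon", "greeble")
ITI_SECONDS = 6.0
REWARD_SECONDS = 2.4
BIN_SECONDS = 0.2


class SchedulingError(RuntimeError):
    """Raised when no constraint-satisfying trial ordering is found."""


@dataclass(frozen=True)
class VideoSpec:
    """One video of the stimulus set.

    ``video`` identifies the visual content ignoring sound (a pigeon video
    and its greeble control are *different* visual content but share
    ``pair``, duration and event windows).
    """

    video_id: str           # unique, includes sound version
    pair: str               # behavior+exemplar key shared by pigeon/greeble
    behavior: str           # one of BEHAVIORS or "twoPigeon"
    exemplar: int           # 1-based
    actor: str              # "pigeon" | "greeble"
    sound: str              # "on" | "off"
    duration: float         # seconds
    event_windows: tuple = ()   # ((start_s, end_s, feature_tag), ...)

    @property
    def video(self) -> str:
        """Visually unique key (content without the sound dimension)."""
        return f"{self.pair}_{self.actor}"


@dataclass
class StimulusSet:
    videos: list[VideoSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.videos)

    @property
    def n_visually_unique(self) -> int:
        return len({v.video for v in self.videos})

    def by_id(self, video_id: str) -> VideoSpec:
        for v in self.videos:
            if v.video_id == video_id:
                return v
        raise KeyError(video_id)

    def unique_pairs(self, include_two_pigeon: bool = False) -> list[str]:
        """Behavior-exemplar keys that exist for both actors."""
        pairs = []
        for v in self.videos:
            if v.behavior == TWO_PIGEON and not include_two_pigeon:
                continue
            if v.pair not in pairs:
                pairs.append(v.pair)
        return pairs


_EVENT_TAGS = ("bowing", "wing_flap", "pecking", "head_bobbing", "walking_step")


def _draw_event_windows(rng: np.random.Generator, duration: float) -> tuple:
    """1-3 non-overlapping 200-600 ms windows inside the video interval."""
    n = int(rng.integers(1, 4))
    windows: list[tuple[float, float, str]] = []
    for _ in range(n):
        for _attempt in range(50):
            width = float(rng.uniform(0.2, 0.6))
            if width >= duration:
                continue
            start = float(rng.uniform(0.0, duration - width))
            end = start + width
            if all(end <= s or start >= e for s, e, _t in windows):
                tag = str(rng.choice(_EVENT_TAGS))
                windows.append((round(start, 3), round(end, 3), tag))
                break
    windows.sort()
    return tuple(windows)


def build_stimulus_set(
    n_behaviors: int = 4,
    n_exemplars: int = 4,
    include_two_pigeon: bool = True,
    duration_range: tuple[float, float] = (2.2, 4.0),
    seed: int = 0,
) -> StimulusSet:
    """Enumerate the full video set with per-video event windows.

    Pigeon videos and their greeble controls share duration and event
    windows; sound-on and sound-off versions are visually identical.
    Deterministic given ``seed``.
    """
    if not (1 <= n_behaviors <= len(BEHAVIORS)):
        raise ValueError(f"n_behaviors must be in [1, {len(BEHAVIORS)}]")
    if n_exemplars < 1:
        raise ValueError("n_exemplars must be >= 1")
    lo, hi = float(duration_range[0]), float(duration_range[1])
    if not (0.2 <= lo <= hi <= 60.0):
        raise ValueError("duration_range must satisfy 0.2 <= lo <= hi <= 60 s")

    rng = np.random.default_rng(seed)
    videos: list[VideoSpec] = []
    behaviors = list(BEHAVIORS[:n_behaviors])
    for behavior in behaviors:
        for ex in range(1, n_exemplars + 1):
            duration = round(float(rng.uniform(lo, hi)), 3)
            events = _draw_event_windows(rng, duration)
            pair = f"{behavior}{ex}"
            for actor in ACTORS:
                for sound in ("on", "off"):
                    videos.append(VideoSpec(
                        video_id=f"{pair}_{actor}_{sound}",
                        pair=pair, behavior=behavior, exemplar=ex,
                        actor=actor, sound=sound,
                        duration=duration, event_windows=events,
                    ))
    if include_two_pigeon:
        for ex in range(1, 5):
            duration = round(float(rng.uniform(lo, hi)), 3)
            events = _draw_event_windows(rng, duration)
            pair = f"{TWO_PIGEON}{ex}"
            for sound in ("on", "off"):
                videos.append(VideoSpec(
                    video_id=f"{pair}_pigeon_{sound}",
                    pair=pair, behavior=TWO_PIGEON, exemplar=ex,
                    actor="pigeon", sound=sound,
                    duration=duration, event_windows=events,
                ))
    return StimulusSet(videos=videos)


@dataclass(frozen=True)
class Trial:
    trial_index: int
    video_id: str
    monitor: str        # "left" | "right"
    reward: bool


@dataclass
class TrialSchedule:
    trials: list[Trial]
    iti_s: float = ITI_SECONDS
    reward_duration_s: float = REWARD_SECONDS

    def __len__(self) -> int:
        return len(self.trials)


def _max_run_length(categories: list[str]) -> int:
    best = run = 1
    for a, b in zip(categories, categories[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _category_run_ok(categories: list[str], max_consecutive: int) -> bool:
    return _max_run_length(categories) <= max_consecutive


def schedule_session(
    stimulus_set: StimulusSet,
    reps_per_video: int = 6,
    reward_fraction: float = 0.10,
    max_consecutive: int = 3,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> TrialSchedule:
    """Pseudorandomized session: every video ``reps_per_video`` times, half
    on each monitor, no behavioral category more than ``max_consecutive``
    times in a row.

    Ordering is found by rejection sampling with local repair: shuffle, then
    repeatedly swap a trial inside an over-long category run with a random
    position elsewhere.  Rewarded trials are exactly
    ``round(reward_fraction * n_trials)`` drawn without replacement.
    """
    if reps_per_video % 2 != 0:
        raise ValueError("reps_per_video must be even (split across monitors)")
    if not (0.0 <= reward_fraction <= 1.0):
        raise ValueError("reward_fraction must be in [0, 1]")
    if len(stimulus_set) == 0:
        raise ValueError("empty stimulus set")

    rng = np.random.default_rng(seed)
    video_ids = [v.video_id for v in stimulus_set.videos]
    behavior_of = {v.video_id: v.behavior for v in stimulus_set.videos}
    if len(set(behavior_of.values())) < 2:
        # a single category cannot be interleaved; the constraint is vacuous
        max_consecutive = float("inf")

    order = np.repeat(np.arange(len(video_ids)), reps_per_video)
    rng.shuffle(order)
    order = list(order)

    def categories() -> list[str]:
        return [behavior_of[video_ids[i]] for i in order]

    n = len(order)
    ok = False
    for _attempt in range(max_attempts):
        cats = categories()
        if _category_run_ok(cats, max_consecutive):
            ok = True
            break
        # locate first offending run and swap one member elsewhere
        run_start, run = 0, 1
        pos = None
        for i in range(1, n):
            if cats[i] == cats[i - 1]:
                run += 1
                if run > max_consecutive:
                    pos = i
                    break
            else:
                run = 1
        j = int(rng.integers(0, n))
        order[pos], order[j] = order[j], order[pos]
    if not ok:
        raise SchedulingError(
            f"no ordering with category run-length <= {max_consecutive} "
            f"found in {max_attempts} attempts")

    # monitor assignment: for each video, half of its occurrences left
    monitors = [""] * n
    positions: dict[int, list[int]] = {}
    for t, vid in enumerate(order):
        positions.setdefault(int(vid), []).append(t)
    for vid, pos_list in positions.items():
        half = len(pos_list) // 2
        left = rng.choice(len(pos_list), size=half, replace=False)
        left_set = {pos_list[i] for i in left}
        for t in pos_list:
            monitors[t] = "left" if t in left_set else "right"

    n_reward = int(round(reward_fraction * n))
    reward_idx = set(rng.choice(n, size=n_reward, replace=False).tolist()) if n_reward else set()

    trials = [
        Trial(trial_index=t, video_id=video_ids[i], monitor=monitors[t],
              reward=t in reward_idx)
        for t, i in enumerate(order)
    ]
    return TrialSchedule(trials=trials)
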