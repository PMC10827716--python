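"""Behavioral scoring: modified Neurological Severity Score (mNSS) and the
pasta handling task.

The mNSS is a composite 0-18 deficit scale (0 = no deficit, 18 = maximal
deficit) covering sensorimotor placing and proprioception, beam balance
(0-6, averaged over three repetitions), walking (0-3), limb flexion / head
turning on tail raise, three reflexes and seizure-like behavior (1 point
each).

The pasta handling task scores fine motor function while the animal eats a
thin pasta piece: time per pasta, per-forelimb grasp counts (ipsi/contra
relative to the stroke hemisphere), and nine binary atypical-handling
behaviors. A session presents at most five pasta pieces and stops early
after four valid trials; trials are invalid when the animal does not
perform or breaks the pasta (which changes task difficulty).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

# (field name, maximum score) for every mNSS item, in scoring-sheet order.
MNSS_ITEM_RANGES: tuple[tuple[str, float], ...] = (
    ("placing", 1),
    ("proprioception", 1),
    ("beam_balance", 6),
    ("walking", 3),
    ("raise_forelimb_flexion", 1),
    ("raise_hindlimb_flexion", 1),
    ("raise_head_turn", 1),
    ("reflex_corneal_absent", 1),
    ("reflex_pinna_absent", 1),
    ("reflex_startle_absent", 1),
    ("seizure_like", 1),
)

MNSS_MAX_TOTAL = 18  # sum of all item maxima

ATYPICAL_BEHAVIORS = (
    "hunched_posture",
    "angling_head_tilt",
    "paws_together_long",
    "paws_apart_short",
    "guide_grasp_switch",
    "mouth_pulling",
    # "failure to contact" split into three separate categories:
    "paw_supports_no_grip",
    "no_contact_while_eating",
    "no_contact_any_time",
)

TRIAL_STATUSES = ("valid", "no_performance", "pasta_break")


@dataclass
class MNSSItems:
    """Item-level mNSS scores for one animal at one timepoint.

    ``beam_balance`` is the mean of three repetitions and may therefore be
    fractional (multiples of 1/3); the raw repetition scores can be kept in
    ``beam_repetitions``. All other items are integers within their range.
    """

    placing: int = 0
    proprioception: int = 0
    beam_balance: float = 0.0
    walking: int = 0
    raise_forelimb_flexion: int = 0
    raise_hindlimb_flexion: int = 0
    raise_head_turn: int = 0
    reflex_corneal_absent: int = 0
    reflex_pinna_absent: int = 0
    reflex_startle_absent: int = 0
    seizure_like: int = 0
    beam_repetitions: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, hi in MNSS_ITEM_RANGES:
            v = getattr(self, name)
            if not (0 <= v <= hi):
                raise ValueError(f"mNSS item {name}={v} outside [0, {hi}]")
        if self.beam_repetitions is not None:
            if len(self.beam_repetitions) != 3 or any(
                    not (0 <= r <= 6) for r in self.beam_repetitions):
                raise ValueError("beam_repetitions must be three 0-6 scores")
            mean = sum(self.beam_repetitions) / 3.0
            if abs(mean - self.beam_balance) > 1e-9:
                raise ValueError("beam_balance != mean(beam_repetitions)")

    def raw_total(self) -> float:
        """Exact (possibly fractional) sum of all item scores."""
        return float(sum(getattr(self, name) for name, _ in MNSS_ITEM_RANGES))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def mnss_total(items: MNSSItems) -> int:
    """Total mNSS (0-18). The fractional beam-balance mean is carried at
    full precision into the sum; the total is rounded half-up for reporting.
    """
    items.validate()
    return _round_half_up(items.raw_total())


def mnss_relative_change(post_stroke: float, post_tdcs: float) -> float | None:
    """Relative mNSS change (post_stroke - post_tdcs) / post_stroke.

    Positive values mean improvement. Undefined (returns ``None``) when the
    post-stroke score is zero, since there is no deficit to recover from.
    """
    if post_stroke < 0 or post_tdcs < 0:
        raise ValueError("scores must be non-negative")
    if post_stroke == 0:
        return None
    return (post_stroke - post_tdcs) / post_stroke


@dataclass
class PastaTrial:
    """One pasta-piece performance.

    Grasp counts are per forelimb relative to the stroke hemisphere
    (``grasps_contra`` = affected limb). ``atypicals`` holds the nine
    binary atypical-behavior flags, keyed by :data:`ATYPICAL_BEHAVIORS`.
    """

    duration_s: float = 0.0
    grasps_ipsi: int = 0
    grasps_contra: int = 0
    atypicals: dict[str, bool] = field(default_factory=dict)
    status: str = "valid"

    def __post_init__(self) -> None:
        if self.status not in TRIAL_STATUSES:
            raise ValueError(f"status must be one of {TRIAL_STATUSES}")
        if self.grasps_ipsi < 0 or self.grasps_contra < 0:
            raise ValueError("grasp counts must be non-negative")
        if self.status == "valid" and self.duration_s <= 0:
            raise ValueError("valid trials need a positive duration")
        unknown = set(self.atypicals) - set(ATYPICAL_BEHAVIORS)
        if unknown:
            raise ValueError(f"unknown atypical flags: {sorted(unknown)}")


def validate_trial(trial: PastaTrial) -> tuple[bool, str | None]:
    """``(True, None)`` for a valid trial, else ``(False, reason)`` where
    reason is ``no_performance`` or ``pasta_break``."""
    if trial.status == "valid":
        return True, None
    return False, trial.status


def select_trials(session: Sequence[PastaTrial]) -> list[PastaTrial]:
    """Apply the session stop rules and return the valid trials.

    Trials are scanned in presentation order; the session ends after the
    fourth valid trial or the fifth presented piece, whichever comes first
    (so a fifth piece is never presented once four are valid). A session
    may not contain more than five presentations. An empty return value
    marks the animal as excluded from pasta analysis.
    """
    if len(session) > 5:
        raise ValueError("a session presents at most five pasta pieces")
    valid: list[PastaTrial] = []
    for trial in session:
        ok, _ = validate_trial(trial)
        if ok:
            valid.append(trial)
        if len(valid) == 4:
            break
    return valid


def atypical_count(trial: PastaTrial) -> int:
    """Number of atypical behaviors present (0-9) in a valid trial."""
    ok, reason = validate_trial(trial)
    if not ok:
        raise ValueError(f"atypicals are scored on valid trials only ({reason})")
    return sum(bool(trial.atypicals.get(name, False))
               for name in ATYPICAL_BEHAVIORS)


@dataclass(frozen=True)
class PastaMetrics:
    """Per-animal session summary: means over the valid trials."""

    n_valid: int
    time_per_pasta_s: float
    grasps_ipsi_per_pasta: float
    grasps_contra_per_pasta: float
    atypicals_per_pasta: float


def pasta_summary(valid_trials: Sequence[PastaTrial]) -> PastaMetrics:
    """Average single performances of one animal into session metrics.

    Raises on an empty list: an animal with no valid trial is excluded
    from pasta analysis, not averaged as zero.
    """
    if not valid_trials:
        raise ValueError("no valid trials: animal excluded from pasta analysis")
    for t in valid_trials:
        ok, reason = validate_trial(t)
        if not ok:
            raise ValueError(f"invalid trial ({reason}) in summary input")
    n = len(valid_trials)
    return PastaMetrics(
        n_valid=n,
        time_per_pasta_s=sum(t.duration_s for t in valid_trials) / n,
        grasps_ipsi_per_pasta=sum(t.grasps_ipsi for t in valid_trials) / n,
        grasps_contra_per_pasta=sum(t.grasps_contra for t in valid_trials) / n,
        atypicals_per_pasta=sum(atypical_count(t) for t in valid_trials) / n,
    )
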