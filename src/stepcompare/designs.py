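"""Comparison-target generation for the three daily social-comparison designs.

A *target profile* is a fictitious (or, in the team design, live) platform user
whose displayed daily step total sits at a controlled distance from the
comparer's own previous-day steps.  Distances are expressed as *nominal scales*
(fractions of the comparer's anchor steps, e.g. 0.9 = a downward target at 90%)
and a small multiplicative obfuscation noise of at most a few percent is
applied so users cannot reverse-engineer the scheme.

Three designs are built in:

* study 1 — a fixed option set each day: two upward targets (110%, 130%) and
  two downward targets (90%, 70%).
* study 2 — daily randomization among three option sets: downward-only
  (90/80/70/60%), mixed (90/80/110/120%) and upward-only (110/120/130/140%).
* study 3 — a three-entry leaderboard: the participant, a live teammate, and a
  platform-fabricated user placed 20% below the lower live total, between the
  two live totals, or 20% above the higher live total.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError, InvalidInputError

__all__ = [
    "StudyDesign",
    "TargetProfile",
    "ConditionAssignment",
    "Leaderboard",
    "LeaderboardEntry",
    "study_design",
    "load_design",
    "apply_noise",
    "generate_target_set",
    "assign_conditions",
    "generate_fabricated_steps",
    "build_leaderboard",
    "generate_username",
    "generate_detail_elements",
]

# Canonical condition sets.  The scale fractions are the study parameters, not
# tunables: changing them changes which study is being emulated.
STUDY1_CONDITIONS: dict[str, tuple[float, ...]] = {
    "fixed": (1.1, 1.3, 0.9, 0.7),
}
STUDY2_CONDITIONS: dict[str, tuple[float, ...]] = {
    "downward_only": (0.9, 0.8, 0.7, 0.6),
    "mixed": (0.9, 0.8, 1.1, 1.2),
    "upward_only": (1.1, 1.2, 1.3, 1.4),
}
STUDY3_PLACEMENTS: tuple[str, ...] = ("fab_below", "fab_between", "fab_above")

_FAB_BELOW_SCALE = 0.8  # of the lower live total
_FAB_ABOVE_SCALE = 1.2  # of the higher live total


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of one study design.

    ``scales_per_condition`` maps a condition label to the nominal scale
    fractions offered under that condition.  For the leaderboard design
    (study 3) the condition labels are fabricated-user placements and carry no
    scale list (empty tuples); fabricated totals are placed relative to the
    live teammates instead.
    """

    study_id: int
    scales_per_condition: Mapping[str, tuple[float, ...]]
    options_per_day: int
    noise_halfwidth: float = 0.02
    leaderboard: bool = False
    carry_forward_last_synced: bool = False
    assignment_mode: str = "blocked"  # or "iid"

    def __post_init__(self):
        if self.study_id not in (1, 2, 3):
            raise ConfigError(f"study_id must be 1, 2 or 3, got {self.study_id!r}")
        if not (0.0 <= self.noise_halfwidth <= 0.1):
            raise ConfigError(
                f"noise_halfwidth must lie in [0, 0.1], got {self.noise_halfwidth}"
            )
        for label, scales in self.scales_per_condition.items():
            if any(s <= 0 for s in scales):
                raise ConfigError(f"condition {label!r} has a non-positive scale")
        if self.assignment_mode not in ("blocked", "iid"):
            raise ConfigError(f"unknown assignment_mode {self.assignment_mode!r}")
        self._check_canonical()

    def _check_canonical(self):
        labels = set(self.scales_per_condition)
        if self.study_id == 1:
            if len(labels) != 1 or {
                frozenset(v) for v in self.scales_per_condition.values()
            } != {frozenset((0.7, 0.9, 1.1, 1.3))}:
                raise ConfigError(
                    "study 1 requires exactly one condition with scales "
                    "{0.7, 0.9, 1.1, 1.3}; got "
                    + ", ".join(sorted(labels))
                )
        elif self.study_id == 2:
            want = {k: frozenset(v) for k, v in STUDY2_CONDITIONS.items()}
            got = {k: frozenset(v) for k, v in self.scales_per_condition.items()}
            if got != want:
                bad = sorted(set(got) ^ set(want)) or sorted(
                    k for k in want if got.get(k) != want[k]
                )
                raise ConfigError(
                    "study 2 requires conditions downward_only/mixed/upward_only "
                    f"with their canonical scale sets; mismatch at: {', '.join(bad)}"
                )
        else:
            if labels != set(STUDY3_PLACEMENTS):
                bad = sorted(labels ^ set(STUDY3_PLACEMENTS))
                raise ConfigError(
                    "study 3 requires placement conditions "
                    f"fab_below/fab_between/fab_above; mismatch at: {', '.join(bad)}"
                )

    @property
    def condition_labels(self) -> tuple[str, ...]:
        return tuple(self.scales_per_condition)

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "conditions": {k: list(v) for k, v in self.scales_per_condition.items()},
            "options_per_day": self.options_per_day,
            "noise_halfwidth": self.noise_halfwidth,
            "leaderboard": self.leaderboard,
            "carry_forward_last_synced": self.carry_forward_last_synced,
            "assignment_mode": self.assignment_mode,
        }

    def without_noise(self) -> "StudyDesign":
        return replace(self, noise_halfwidth=0.0)


def study_design(study_id: int, **overrides) -> StudyDesign:
    """Return the canonical design for a study (1, 2 or 3)."""
    if study_id == 1:
        base = dict(
            study_id=1,
            scales_per_condition=STUDY1_CONDITIONS,
            options_per_day=4,
            leaderboard=False,
        )
    elif study_id == 2:
        base = dict(
            study_id=2,
            scales_per_condition=STUDY2_CONDITIONS,
            options_per_day=4,
            leaderboard=False,
        )
    elif study_id == 3:
        base = dict(
            study_id=3,
            scales_per_condition={p: () for p in STUDY3_PLACEMENTS},
            options_per_day=2,  # visible others besides the participant
            leaderboard=True,
        )
    else:
        raise ConfigError(f"study_id must be 1, 2 or 3, got {study_id!r}")
    base.update(overrides)
    return StudyDesign(**base)


def load_design(path: str | Path) -> StudyDesign:
    """Load a study design from a YAML or JSON config file.

    Expected keys: ``study_id``, ``conditions`` (label -> scale list; may be
    omitted to use the canonical set), ``noise_halfwidth``, ``options_per_day``,
    ``leaderboard`` and the optional behavioural flags.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict) or "study_id" not in raw:
        raise ConfigError(f"design config {path} is not a mapping with study_id")
    kwargs = {}
    if "conditions" in raw:
        kwargs["scales_per_condition"] = {
            str(k): tuple(v or ()) for k, v in raw["conditions"].items()
        }
    for key in (
        "options_per_day",
        "noise_halfwidth",
        "leaderboard",
        "carry_forward_last_synced",
        "assignment_mode",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    return study_design(int(raw["study_id"]), **kwargs)


@dataclass(frozen=True)
class TargetProfile:
    """One displayed comparison profile."""

    username: str
    displayed_steps: int
    direction: str  # "upward" | "downward" | "lateral"
    nominal_scale: float | None = None  # absent for live-teammate profiles
    fabricated: bool = True
    detail_elements: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.displayed_steps < 0:
            raise InvalidInputError("displayed_steps must be >= 0")
        if self.direction not in ("upward", "downward", "lateral"):
            raise InvalidInputError(f"unknown direction {self.direction!r}")

    def to_dict(self) -> dict:
        return {
            "username": self.username,
            "displayed_steps": self.displayed_steps,
            "direction": self.direction,
            "nominal_scale": self.nominal_scale,
            "fabricated": self.fabricated,
            "detail_elements": [list(e) for e in self.detail_elements],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TargetProfile":
        return cls(
            username=d["username"],
            displayed_steps=int(d["displayed_steps"]),
            direction=d["direction"],
            nominal_scale=d.get("nominal_scale"),
            fabricated=bool(d.get("fabricated", True)),
            detail_elements=tuple(
                (str(k), str(v)) for k, v in d.get("detail_elements", ())
            ),
        )


@dataclass(frozen=True)
class ConditionAssignment:
    participant_id: str
    day_index: int
    condition_label: str


@dataclass(frozen=True)
class LeaderboardEntry:
    username: str
    displayed_steps: int
    is_self: bool = False
    fabricated: bool = False


@dataclass(frozen=True)
class Leaderboard:
    """Ranked display of users by displayed step total, descending."""

    entries: tuple[LeaderboardEntry, ...]

    def __post_init__(self):
        if sum(e.is_self for e in self.entries) != 1:
            raise InvalidInputError("leaderboard must contain exactly one self entry")
        steps = [e.displayed_steps for e in self.entries]
        if steps != sorted(steps, reverse=True):
            raise InvalidInputError("leaderboard entries must descend by steps")

    @property
    def self_rank(self) -> int:
        """1-based rank of the participant's own entry."""
        return next(i for i, e in enumerate(self.entries, start=1) if e.is_self)

    def fabricated_rank(self) -> int | None:
        for i, e in enumerate(self.entries, start=1):
            if e.fabricated:
                return i
        return None


def direction_of(displayed_steps: int, anchor_steps: int) -> str:
    """Label a displayed total relative to the comparer's anchor steps."""
    if displayed_steps > anchor_steps:
        return "upward"
    if displayed_steps < anchor_steps:
        return "downward"
    return "lateral"


def apply_noise(
    nominal_steps: float, noise_halfwidth: float, rng: np.random.Generator
) -> int:
    """Obfuscate a nominal step total with multiplicative uniform noise.

    Returns ``round(nominal * (1 + u))`` with ``u ~ Uniform[-h, +h]`` (half-up
    rounding).  ``h = 0`` is the identity on integer input.
    """
    if nominal_steps < 0:
        raise InvalidInputError(f"nominal_steps must be >= 0, got {nominal_steps}")
    if not (0.0 <= noise_halfwidth <= 0.1):
        raise InvalidInputError(
            f"noise_halfwidth must lie in [0, 0.1], got {noise_halfwidth}"
        )
    u = rng.uniform(-noise_halfwidth, noise_halfwidth)
    return max(0, int(math.floor(nominal_steps * (1.0 + u) + 0.5)))


# --- cosmetic profile content -------------------------------------------------
# Small pools for usernames and detail-page fields.  Content is cosmetic: the
# telemetry layer measures *how many* fields a user opens, never which.

_CITIES = (
    "Philadelphia", "Camden", "Glassboro", "Trenton", "Wilmington",
    "Baltimore", "Pittsburgh", "Newark", "Allentown", "Atlantic City",
)
_PROFESSIONS = (
    "student", "barista", "nurse", "teacher", "retail associate",
    "line cook", "lab technician", "graphic designer", "accountant", "librarian",
)
_ACTIVITIES = (
    "walking", "running", "cycling", "swimming", "yoga",
    "basketball", "hiking", "dance", "weightlifting", "rock climbing",
)
_HOBBIES = (
    "photography", "cooking", "board games", "gardening", "painting",
    "video games", "reading", "birdwatching", "thrifting", "podcasts",
)
_EXERCISE_SPOTS = (
    "campus gym", "riverside trail", "city park", "home", "community pool",
    "rec center", "neighborhood streets", "track", "climbing gym", "basement",
)


def generate_username(rng: np.random.Generator) -> str:
    """Short handle in the platform's style, e.g. ``dmf25``."""
    letters = "".join(chr(rng.integers(97, 123)) for _ in range(3))
    digits = f"{rng.integers(0, 100):02d}"
    return letters + digits


def generate_detail_elements(
    rng: np.random.Generator,
) -> tuple[tuple[str, str], ...]:
    """Ordered labelled fields for a profile's full Details page.

    Covers the four blocks a Details page shows: demographics, physical
    appearance, exercise preferences and other personal information.
    """
    age = int(rng.integers(18, 40))
    sex = ("female", "male")[int(rng.integers(0, 2))]
    height = int(rng.integers(150, 196))
    weight = int(rng.integers(48, 110))
    pick = lambda pool: pool[int(rng.integers(0, len(pool)))]
    return (
        ("age", str(age)),
        ("sex", sex),
        ("profession", pick(_PROFESSIONS)),
        ("city", pick(_CITIES)),
        ("height_cm", str(height)),
        ("weight_kg", str(weight)),
        ("preferred_activity", pick(_ACTIVITIES)),
        ("second_activity", pick(_ACTIVITIES)),
        ("favorite_exercise_spot", pick(_EXERCISE_SPOTS)),
        ("hobby", pick(_HOBBIES)),
        ("second_hobby", pick(_HOBBIES)),
        ("weekly_active_days", str(int(rng.integers(1, 8)))),
    )


def _unique_usernames(n: int, rng: np.random.Generator, taken: set[str] | None = None) -> list[str]:
    taken = set(taken or ())
    names: list[str] = []
    while len(names) < n:
        name = generate_username(rng)
        if name not in taken:
            taken.add(name)
            names.append(name)
    return names


def generate_target_set(
    prev_day_steps: int,
    condition_label: str,
    design: StudyDesign,
    rng: np.random.Generator,
    with_details: bool = True,
) -> list[TargetProfile]:
    """Generate one day's comparison-target options for a scale-based design.

    One profile per nominal scale of the condition; each displayed total is the
    scaled anchor with obfuscation noise, and the direction label is set by
    comparison with the anchor itself (so a noisy 101% target near-certainly
    stays upward, and a zero-step anchor yields lateral profiles).
    """
    if prev_day_steps < 0:
        raise InvalidInputError("prev_day_steps must be >= 0")
    if condition_label not in design.scales_per_condition:
        raise ConfigError(
            f"unknown condition {condition_label!r} for study {design.study_id}; "
            f"expected one of: {', '.join(design.condition_labels)}"
        )
    scales = design.scales_per_condition[condition_label]
    if not scales:
        raise ConfigError(
            f"condition {condition_label!r} carries no scale list; "
            "leaderboard designs use generate_fabricated_steps instead"
        )
    usernames = _unique_usernames(len(scales), rng)
    profiles = []
    for scale, username in zip(scales, usernames):
        displayed = apply_noise(scale * prev_day_steps, design.noise_halfwidth, rng)
        profiles.append(
            TargetProfile(
                username=username,
                displayed_steps=displayed,
                direction=direction_of(displayed, prev_day_steps),
                nominal_scale=scale,
                fabricated=True,
                detail_elements=generate_detail_elements(rng) if with_details else (),
            )
        )
    return profiles


def assign_conditions(
    participant_id: str,
    n_days: int,
    design: StudyDesign,
    rng: np.random.Generator,
    mode: str | None = None,
) -> list[ConditionAssignment]:
    """Randomize a participant's daily condition schedule.

    The default ``blocked`` mode balances counts so each condition appears
    ``floor(n_days/k)`` or ``ceil(n_days/k)`` times (with the remainder spread
    at random), then shuffles the order; over a 9-day schedule with 3
    conditions every condition appears exactly 3 times, matching the equal
    marginal thirds observed empirically.  ``iid`` draws each day uniformly.
    """
    if n_days < 1:
        raise InvalidInputError("n_days must be >= 1")
    labels = list(design.condition_labels)
    mode = mode or design.assignment_mode
    if mode == "iid":
        seq = [labels[int(i)] for i in rng.integers(0, len(labels), size=n_days)]
    else:
        k = len(labels)
        base, extra = divmod(n_days, k)
        seq = labels * base
        if extra:
            seq += [labels[int(i)] for i in rng.choice(k, size=extra, replace=False)]
        order = rng.permutation(len(seq))
        seq = [seq[int(i)] for i in order]
    return [
        ConditionAssignment(participant_id, day, label)
        for day, label in enumerate(seq)
    ]


def generate_fabricated_steps(
    live_a_steps: int,
    live_b_steps: int,
    placement: str,
    rng: np.random.Generator,
    noise_halfwidth: float = 0.02,
) -> int:
    """Place the fabricated third user's step total relative to two live totals.

    ``fab_below`` sits 20% below the lower live total, ``fab_above`` 20% above
    the higher, ``fab_between`` at the midpoint; obfuscation noise is applied
    in all cases, and the between placement is clamped strictly inside the open
    interval when the live totals differ (it degrades to the shared value when
    they are equal).
    """
    if live_a_steps < 0 or live_b_steps < 0:
        raise InvalidInputError("live step totals must be >= 0")
    lo, hi = sorted((live_a_steps, live_b_steps))
    if placement == "fab_below":
        return apply_noise(_FAB_BELOW_SCALE * lo, noise_halfwidth, rng)
    if placement == "fab_above":
        return apply_noise(_FAB_ABOVE_SCALE * hi, noise_halfwidth, rng)
    if placement == "fab_between":
        value = apply_noise((lo + hi) / 2.0, noise_halfwidth, rng)
        if lo < hi:
            value = min(max(value, lo + 1), hi - 1)
        else:
            value = lo
        return value
    raise ConfigError(
        f"unknown placement {placement!r}; expected one of: "
        + ", ".join(STUDY3_PLACEMENTS)
    )


def build_leaderboard(
    self_entry: LeaderboardEntry, other_entries: Iterable[LeaderboardEntry]
) -> Leaderboard:
    """Rank the participant and the other users by displayed steps, descending.

    Ties are broken by username ascending (a stable, documented convention),
    so the board is invariant to the order entries are supplied in.
    """
    others = list(other_entries)
    if not self_entry.is_self:
        raise InvalidInputError("self_entry must have is_self=True")
    if any(e.is_self for e in others):
        raise InvalidInputError("other_entries must not contain a self entry")
    if not others:
        raise InvalidInputError("at least one other entry is required")
    entries = [self_entry, *others]
    names = [e.username for e in entries]
    if len(set(names)) != len(names):
        raise InvalidInputError("duplicate usernames on one leaderboard")
    entries.sort(key=lambda e: (-e.displayed_steps, e.username))
    return Leaderboard(entries=tuple(entries))
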