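"""Agent-based synthetic cohort generator.

Produces complete study datasets — daily step series, condition schedules,
target offers, selections, motivation ratings, navigation telemetry and
missing days — so every downstream stage (cleaning, coding, multilevel
models) is exercisable without real participants.

The generative model, in brief:

* Steps are log-normal: person ``i`` has mean log-steps ``mu_i ~ Normal(mu,
  tau_between)`` and day-level noise ``sigma_day``, so the intraclass
  correlation of log steps is ``tau^2 / (tau^2 + sigma^2)`` by construction.
  An optional within-person feedback adds ``beta_within`` times the day's
  (centered) post-comparison motivation on the log scale.
* Selections follow a multinomial logit: utility ``upward_affinity`` for
  upward targets minus ``distance_penalty * |scale - 1|``, plus Gumbel noise
  (the Gumbel-max draw is the softmax sampler).
* Motivation ratings discretize a latent Normal: pre ~ Normal(person
  baseline, 1) mapped to 1-5 by unit-width bins centered on the scale points;
  post shifts the latent pre by a direction bonus and a distance penalty.
* Navigation: Details-page dwell time is log-normal and the number of
  elements viewed is Poisson, both with person-level intercepts and a small
  positive age coefficient (so an age association is present to recover).
* Missing days are MCAR with probability ``p_miss``; occasional non-wear days
  (steps under 100) and extreme dwell times emulate the rows the cleaning
  rules exist to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .designs import (
    LeaderboardEntry,
    StudyDesign,
    TargetProfile,
    assign_conditions,
    build_leaderboard,
    direction_of,
    generate_detail_elements,
    generate_fabricated_steps,
    generate_target_set,
    generate_username,
    study_design,
    _unique_usernames,
)
from .errors import ConfigError, InvalidInputError
from .telemetry import read_session_jsonl, write_session_jsonl

__all__ = [
    "AgentParams",
    "SimConfig",
    "CohortData",
    "simulate_steps",
    "simulate_selection",
    "simulate_motivation_pair",
    "simulate_cohort",
    "sim_config",
]

_AGE_CENTER = 22.0  # approximate cohort mean age used inside the generator

_GENDERS = ("woman", "man")
_GENDER_P = (0.57, 0.43)
_RACES = ("White", "Asian", "Multiracial", "Black", "Other", "AIAN")
_RACE_P = (0.53, 0.25, 0.09, 0.08, 0.03, 0.02)


@dataclass(frozen=True)
class AgentParams:
    """One synthetic participant's generative parameters."""

    mu_log_steps: float
    sigma_day: float
    upward_affinity: float
    distance_penalty: float
    motivation_baseline: float
    beta_direction: float
    beta_distance: float
    beta_within: float
    p_miss: float
    age: int = 22
    gender: str = "woman"
    race: str = "White"

    def __post_init__(self):
        if self.sigma_day < 0 or self.distance_penalty < 0:
            raise ConfigError("sigma_day and distance_penalty must be >= 0")
        if not (0.0 <= self.p_miss < 1.0):
            raise ConfigError("p_miss must lie in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation configuration.

    Population distributions for :class:`AgentParams` plus design and seed.
    ``mean_steps`` is the cohort's typical steps/day on the natural scale
    (``exp`` of the population mean of log steps).
    """

    design: StudyDesign
    n_participants: int = 53
    n_days: int = 9
    seed: int = 0
    mean_steps: float = 6376.0
    sigma_day: float = 0.35
    tau_between: float = 0.35
    upward_affinity: float = 0.7
    distance_penalty: float = 1.0
    motivation_baseline: float = 3.0
    tau_motivation: float = 0.5
    beta_direction: float = 0.15
    beta_distance: float = 0.3
    sigma_post: float = 0.5
    beta_within: float = 0.0
    p_miss: float = 0.01
    p_nonwear: float = 0.04
    p_view_outlier: float = 0.005
    mean_viewing_seconds: float = 18.0
    tau_viewing: float = 0.75
    sigma_viewing: float = 0.65
    beta_age_viewing: float = 0.03
    mean_elements: float = 9.0
    tau_elements: float = 0.6
    beta_age_elements: float = 0.03
    p_first_final: float = 0.9
    start_date: str = "2025-01-06"
    step_distribution: str = "lognormal"  # or "gamma"

    def __post_init__(self):
        if self.n_participants < 1 or self.n_days < 1:
            raise ConfigError("n_participants and n_days must be >= 1")
        if not (0.0 <= self.p_miss < 1.0):
            raise ConfigError("p_miss must lie in [0, 1)")
        if self.step_distribution not in ("lognormal", "gamma"):
            raise ConfigError(f"unknown step_distribution {self.step_distribution!r}")

    @property
    def mu_log_steps(self) -> float:
        return math.log(self.mean_steps)

    @property
    def icc_log_steps(self) -> float:
        """The log-step ICC implied by the variance components."""
        t2, s2 = self.tau_between**2, self.sigma_day**2
        return t2 / (t2 + s2) if (t2 + s2) > 0 else 0.0


_STUDY_DEFAULTS = {
    # per-study conditions: sample size, schedule length, typical steps/day
    # and observed missing-day rates
    1: dict(n_participants=5, n_days=7, mean_steps=4690.0, p_miss=0.20),
    2: dict(n_participants=53, n_days=9, mean_steps=6376.0, p_miss=0.01),
    3: dict(n_participants=54, n_days=9, mean_steps=3609.0, p_miss=0.049),
}


def sim_config(study_id: int, **overrides) -> SimConfig:
    """Canonical simulation configuration for one of the three studies."""
    if study_id not in _STUDY_DEFAULTS:
        raise ConfigError(f"study_id must be 1, 2 or 3, got {study_id!r}")
    kwargs = dict(_STUDY_DEFAULTS[study_id])
    kwargs["design"] = overrides.pop("design", study_design(study_id))
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def simulate_steps(
    agent: AgentParams,
    rng: np.random.Generator,
    motivation_dev: float = 0.0,
    distribution: str = "lognormal",
) -> int:
    """Draw one day's step total for an agent.

    Log-normal with the agent's person mean and day-level SD; the centered
    post-comparison motivation enters on the log scale through
    ``beta_within`` when motivation feedback is enabled.  A gamma alternative
    with the same mean and coefficient of variation is selectable.
    """
    mean_log = agent.mu_log_steps + agent.beta_within * motivation_dev
    if agent.sigma_day == 0:
        return int(math.floor(math.exp(mean_log) + 0.5))
    if distribution == "gamma":
        cv2 = math.expm1(agent.sigma_day**2)
        shape = 1.0 / cv2
        scale = math.exp(mean_log + agent.sigma_day**2 / 2.0) / shape
        value = rng.gamma(shape, scale)
    else:
        value = rng.lognormal(mean=mean_log, sigma=agent.sigma_day)
    return int(math.floor(value + 0.5))


def _profile_scale(profile: TargetProfile, prev_day_steps: int | None) -> float:
    if profile.nominal_scale is not None:
        return profile.nominal_scale
    if prev_day_steps:
        return profile.displayed_steps / prev_day_steps
    return 1.0


def simulate_selection(
    offered: Sequence[TargetProfile],
    agent: AgentParams,
    rng: np.random.Generator,
    prev_day_steps: int | None = None,
) -> str:
    """Pick one offered profile by Gumbel-max over comparison utilities.

    Utility = ``upward_affinity`` for upward targets minus
    ``distance_penalty * |scale - 1|``; adding i.i.d. Gumbel noise and taking
    the argmax samples the softmax distribution over the offer set.
    """
    if not offered:
        raise InvalidInputError("offer set is empty")
    utilities = np.empty(len(offered))
    for i, p in enumerate(offered):
        scale = _profile_scale(p, prev_day_steps)
        utilities[i] = (
            agent.upward_affinity * (p.direction == "upward")
            - agent.distance_penalty * abs(scale - 1.0)
        )
    gumbel = rng.gumbel(size=len(offered))
    return offered[int(np.argmax(utilities + gumbel))].username


def _discretize_rating(latent: float) -> int:
    """Map a latent motivation value to the 1-5 scale by unit-width bins."""
    return int(min(5, max(1, math.floor(latent + 0.5))))


def simulate_motivation_pair(
    agent: AgentParams,
    selected: TargetProfile,
    rng: np.random.Generator,
    prev_day_steps: int | None = None,
    sigma_post: float = 0.5,
) -> tuple[int, int]:
    """Draw the pre- and post-exposure motivation ratings for one session.

    Latent pre ~ Normal(person baseline, 1); latent post adds the direction
    bonus, subtracts the distance penalty, and re-discretizes.  Both ratings
    are clipped to 1-5.
    """
    latent_pre = rng.normal(agent.motivation_baseline, 1.0)
    scale = _profile_scale(selected, prev_day_steps)
    latent_post = (
        latent_pre
        + agent.beta_direction * (selected.direction == "upward")
        - agent.beta_distance * abs(scale - 1.0)
        + rng.normal(0.0, sigma_post)
    )
    return _discretize_rating(latent_pre), _discretize_rating(latent_post)


@dataclass
class CohortData:
    """A full synthetic study dataset."""

    steps: pd.DataFrame  # participant_id, day_index, date, steps, source, synced
    sessions: list[dict]  # SessionLog fields + offer context, one per completed day
    assignments: pd.DataFrame  # participant_id, day_index, condition_label
    demographics: pd.DataFrame  # participant_id, age, gender, race
    config: SimConfig | None = None

    def day_table(self) -> pd.DataFrame:
        from .prep import build_day_table

        return build_day_table(self.steps, self.sessions, self.demographics)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "steps": out / "steps.csv",
            "sessions": out / "sessions.jsonl",
            "assignments": out / "assignments.csv",
            "demographics": out / "demographics.csv",
        }
        self.steps.to_csv(paths["steps"], index=False)
        write_session_jsonl(paths["sessions"], self.sessions)
        self.assignments.to_csv(paths["assignments"], index=False)
        self.demographics.to_csv(paths["demographics"], index=False)
        return paths

    @classmethod
    def read(cls, data_dir: str | Path) -> "CohortData":
        data = Path(data_dir)
        for name in ("steps.csv", "sessions.jsonl", "assignments.csv", "demographics.csv"):
            if not (data / name).exists():
                raise ConfigError(f"dataset file missing: {data / name}")
        return cls(
            steps=pd.read_csv(data / "steps.csv"),
            sessions=read_session_jsonl(data / "sessions.jsonl"),
            assignments=pd.read_csv(data / "assignments.csv"),
            demographics=pd.read_csv(data / "demographics.csv"),
        )


def _draw_agent(config: SimConfig, rng: np.random.Generator) -> AgentParams:
    age = int(min(56, 18 + math.floor(rng.gamma(1.2, 3.5))))
    return AgentParams(
        mu_log_steps=rng.normal(config.mu_log_steps, config.tau_between),
        sigma_day=config.sigma_day,
        upward_affinity=config.upward_affinity,
        distance_penalty=config.distance_penalty,
        motivation_baseline=rng.normal(
            config.motivation_baseline, config.tau_motivation
        ),
        beta_direction=config.beta_direction,
        beta_distance=config.beta_distance,
        beta_within=config.beta_within,
        p_miss=config.p_miss,
        age=age,
        gender=_GENDERS[int(rng.choice(len(_GENDERS), p=_GENDER_P))],
        race=_RACES[int(rng.choice(len(_RACES), p=_RACE_P))],
    )


def _viewing_seconds(config: SimConfig, person_effect: float, age: int,
                     rng: np.random.Generator) -> float:
    if rng.uniform() < config.p_view_outlier:
        return round(float(rng.uniform(361.0, 600.0)), 1)
    mu = (
        math.log(config.mean_viewing_seconds)
        + config.beta_age_viewing * (age - _AGE_CENTER)
        + person_effect
    )
    return round(float(np.clip(rng.lognormal(mu, config.sigma_viewing), 1.0, 360.0)), 1)


def _elements_viewed(config: SimConfig, person_effect: float, age: int,
                     rng: np.random.Generator) -> int:
    lam = math.exp(
        math.log(config.mean_elements)
        + config.beta_age_elements * (age - _AGE_CENTER)
        + person_effect
    )
    return int(min(64, rng.poisson(lam)))


def _peek_sequence(
    offered: Sequence[TargetProfile],
    final: str,
    login_iso: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Peek events ending in commitment to ``final``.

    With probability ``p_first_final`` the first profile peeked is the one
    ultimately committed to (the dominant empirical pattern); otherwise the
    participant starts elsewhere and circles back.
    """
    names = [p.username for p in offered]
    others = [n for n in names if n != final]
    if not others or rng.uniform() < config.p_first_final:
        first = final
    else:
        first = others[int(rng.integers(0, len(others)))]
    extra = [n for n in names if n != first]
    n_extra = int(rng.integers(0, len(extra) + 1)) if extra else 0
    seq = [first] + [
        extra[int(i)] for i in rng.choice(len(extra), size=n_extra, replace=False)
    ] if extra else [first]
    if first != final and final not in seq:
        seq.append(final)
    base = pd.Timestamp(login_iso)
    return [
        (name, (base + pd.Timedelta(seconds=5 + 4 * i)).isoformat())
        for i, name in enumerate(seq)
    ]


def _teammate_profile(username: str, displayed: int, anchor: int,
                      rng: np.random.Generator) -> TargetProfile:
    return TargetProfile(
        username=username,
        displayed_steps=displayed,
        direction=direction_of(displayed, anchor),
        nominal_scale=None,
        fabricated=False,
        detail_elements=generate_detail_elements(rng),
    )


def simulate_cohort(config: SimConfig) -> CohortData:
    """Generate a complete synthetic study dataset under one master seed.

    Each participant-day is either missing (probability ``p_miss``, missing
    completely at random) or yields a full session record.  Step totals are
    recorded every day regardless (the tracker keeps counting); non-wear days
    draw a sub-100 total.  The previous day's recorded steps anchor the next
    day's comparison offers.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    design = config.design
    n, days = config.n_participants, config.n_days
    pids = [f"p{i + 1:03d}" for i in range(n)]
    agents = {pid: _draw_agent(config, rng) for pid in pids}
    sources = {pid: ("fitbit" if rng.uniform() < 0.6 else "phone") for pid in pids}
    view_effects = {pid: rng.normal(0.0, config.tau_viewing) for pid in pids}
    elem_effects = {pid: rng.normal(0.0, config.tau_elements) for pid in pids}
    start = date.fromisoformat(config.start_date)

    if design.study_id == 3:
        return _simulate_study3(
            config, rng, pids, agents, sources, view_effects, elem_effects, start
        )

    step_rows, sessions, assign_rows = [], [], []
    for pid in pids:
        agent = agents[pid]
        schedule = assign_conditions(pid, days, design, rng)
        assign_rows += [
            {"participant_id": a.participant_id, "day_index": a.day_index,
             "condition_label": a.condition_label}
            for a in schedule
        ]
        # baseline previous-day steps from the enrollment day
        anchor = max(1, simulate_steps(agent, rng, distribution=config.step_distribution))
        last_synced = anchor
        for day in range(days):
            day_date = start + timedelta(days=day)
            shown_anchor = last_synced if design.carry_forward_last_synced else anchor
            offered = generate_target_set(shown_anchor, schedule[day].condition_label,
                                          design, rng)
            missing = rng.uniform() < agent.p_miss
            motivation_dev = 0.0
            if not missing:
                selected_name = simulate_selection(offered, agent, rng, shown_anchor)
                selected = next(p for p in offered if p.username == selected_name)
                m_pre, m_post = simulate_motivation_pair(
                    agent, selected, rng, shown_anchor, config.sigma_post
                )
                motivation_dev = m_post - 3.0  # centered at the scale midpoint
                login = f"{day_date.isoformat()}T{int(rng.integers(8, 22)):02d}:" \
                        f"{int(rng.integers(0, 60)):02d}:00"
                sessions.append(
                    {
                        "participant_id": pid,
                        "day_index": day,
                        "login_time": login,
                        "m_pre": m_pre,
                        "peek_events": [
                            list(e)
                            for e in _peek_sequence(offered, selected_name, login,
                                                    config, rng)
                        ],
                        "final_selection": selected_name,
                        "elements_viewed": _elements_viewed(
                            config, elem_effects[pid], agent.age, rng
                        ),
                        "viewing_seconds": _viewing_seconds(
                            config, view_effects[pid], agent.age, rng
                        ),
                        "m_post": m_post,
                        "offered": [p.to_dict() for p in offered],
                        "prev_day_steps": shown_anchor,
                        "condition_label": schedule[day].condition_label,
                    }
                )
            if rng.uniform() < config.p_nonwear:
                steps_today = int(rng.integers(0, 100))
            else:
                steps_today = simulate_steps(
                    agent, rng, motivation_dev, config.step_distribution
                )
            synced = not (design.carry_forward_last_synced and rng.uniform() < 0.1)
            step_rows.append(
                {
                    "participant_id": pid,
                    "day_index": day,
                    "date": day_date.isoformat(),
                    "steps": steps_today,
                    "source": sources[pid],
                    "synced": synced,
                }
            )
            anchor = max(1, steps_today)
            if synced:
                last_synced = anchor
    demo = pd.DataFrame(
        {
            "participant_id": pids,
            "age": [agents[p].age for p in pids],
            "gender": [agents[p].gender for p in pids],
            "race": [agents[p].race for p in pids],
        }
    )
    return CohortData(
        steps=pd.DataFrame(step_rows),
        sessions=sessions,
        assignments=pd.DataFrame(assign_rows),
        demographics=demo,
        config=config,
    )


def _simulate_study3(config, rng, pids, agents, sources, view_effects,
                     elem_effects, start) -> CohortData:
    """Team/leaderboard variant: pairs of live teammates plus a fabricated user.

    Placement of the fabricated user is randomized per team-day (both
    teammates share one leaderboard); with an odd cohort the last participant
    is paired with a simulated non-enrolled partner whose sessions are not
    recorded.
    """
    design = config.design
    days = config.n_days
    usernames = {}
    taken: set[str] = set()
    for pid in pids:
        usernames[pid] = _unique_usernames(1, rng, taken)[0]
    ghost = None
    members = list(pids)
    if len(members) % 2 == 1:
        ghost = "__ghost__"
        agents[ghost] = _draw_agent(config, rng)
        usernames[ghost] = _unique_usernames(1, rng, taken)[0]
        members.append(ghost)
    teams = [(members[i], members[i + 1]) for i in range(0, len(members), 2)]

    step_rows, sessions, assign_rows = [], [], []
    anchors = {
        pid: max(1, simulate_steps(agents[pid], rng,
                                   distribution=config.step_distribution))
        for pid in members
    }
    schedules = {
        team: assign_conditions(f"team{t}", days, design, rng)
        for t, team in enumerate(teams)
    }
    for pid in pids:
        for day in range(days):
            team = next(t for t in teams if pid in t)
            assign_rows.append(
                {"participant_id": pid, "day_index": day,
                 "condition_label": schedules[team][day].condition_label}
            )
    motivation_dev = {pid: 0.0 for pid in members}
    for day in range(days):
        day_date = start + timedelta(days=day)
        for team in teams:
            placement = schedules[team][day].condition_label
            a, b = team
            fab_steps = generate_fabricated_steps(
                anchors[a], anchors[b], placement, rng, design.noise_halfwidth
            )
            fab_name = _unique_usernames(1, rng, taken)[0]
            fab_details = generate_detail_elements(rng)
            for me, mate in ((a, b), (b, a)):
                motivation_dev[me] = 0.0
                if me == ghost:
                    continue
                agent = agents[me]
                anchor = anchors[me]
                mate_profile = _teammate_profile(
                    usernames[mate], anchors[mate], anchor, rng
                )
                fab_profile = TargetProfile(
                    username=fab_name,
                    displayed_steps=fab_steps,
                    direction=direction_of(fab_steps, anchor),
                    nominal_scale=None,
                    fabricated=True,
                    detail_elements=fab_details,
                )
                offered = [mate_profile, fab_profile]
                board = build_leaderboard(
                    LeaderboardEntry(usernames[me], anchor, is_self=True),
                    [
                        LeaderboardEntry(mate_profile.username,
                                         mate_profile.displayed_steps),
                        LeaderboardEntry(fab_name, fab_steps, fabricated=True),
                    ],
                )
                if rng.uniform() < agent.p_miss:
                    continue
                selected_name = simulate_selection(offered, agent, rng, anchor)
                selected = next(p for p in offered if p.username == selected_name)
                m_pre, m_post = simulate_motivation_pair(
                    agent, selected, rng, anchor, config.sigma_post
                )
                motivation_dev[me] = m_post - 3.0
                login = f"{day_date.isoformat()}T{int(rng.integers(8, 22)):02d}:" \
                        f"{int(rng.integers(0, 60)):02d}:00"
                sessions.append(
                    {
                        "participant_id": me,
                        "day_index": day,
                        "login_time": login,
                        "m_pre": m_pre,
                        "peek_events": [
                            list(e)
                            for e in _peek_sequence(offered, selected_name, login,
                                                    config, rng)
                        ],
                        "final_selection": selected_name,
                        "elements_viewed": _elements_viewed(
                            config, elem_effects[me], agent.age, rng
                        ),
                        "viewing_seconds": _viewing_seconds(
                            config, view_effects[me], agent.age, rng
                        ),
                        "m_post": m_post,
                        "offered": [p.to_dict() for p in offered],
                        "prev_day_steps": anchor,
                        "condition_label": placement,
                        "self_rank": board.self_rank,
                        "fabricated_rank": board.fabricated_rank(),
                    }
                )
        for pid in members:
            if rng.uniform() < config.p_nonwear:
                steps_today = int(rng.integers(0, 100))
            else:
                steps_today = simulate_steps(
                    agents[pid], rng, motivation_dev[pid], config.step_distribution
                )
            if pid != ghost:
                step_rows.append(
                    {
                        "participant_id": pid,
                        "day_index": day,
                        "date": day_date.isoformat(),
                        "steps": steps_today,
                        "source": sources.get(pid, "fitbit"),
                        "synced": True,
                    }
                )
            anchors[pid] = max(1, steps_today)
    demo = pd.DataFrame(
        {
            "participant_id": pids,
            "age": [agents[p].age for p in pids],
            "gender": [agents[p].gender for p in pids],
            "race": [agents[p].race for p in pids],
        }
    )
    return CohortData(
        steps=pd.DataFrame(step_rows),
        sessions=sessions,
        assignments=pd.DataFrame(assign_rows),
        demographics=demo,
        config=config,
    )
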