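"""Synthetic ATSET cohorts with the statistical structure the analysis assumes.

The real behavioral dataset is access-restricted, so the pipeline ships a
generator that emulates its structure: a study design of (ion, dose, n)
arms; a latent cognitive ability per subject shared between the prescreen
and post-irradiation phases; a dose- and ion-specific ability decrement
post-irradiation; trial-level Bernoulli outcomes with a logistic learning
curve; and the stage protocol (up to 30 trials/day, two days, six
consecutive correct to pass, dropout after two failed post stages).

The generative model, per subject with latent ability ``a``::

    P(correct at attempt t) = logistic(a + learning_rate * t)

with ``t`` the 0-based cumulative attempt index across both days of a
stage.  Post-irradiation ability is ``a - decrement(ion, stage, dose) + s``
where ``s`` is a subject-level normal retest/radiosensitivity noise, so
equal-prescreen subjects can diverge after exposure.  Latencies of correct
attempts are lognormal.  Every subject draws from its own substream keyed
on (seed, subject index), so enlarging the cohort never reshuffles
existing subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .scoring import (
    CRITERION_RUN,
    IONS,
    MAX_TRIALS_PER_DAY,
    POST_STAGES,
    PRESCREEN_STAGES,
    StagePerformance,
    Subject,
    TrialRecord,
)


@dataclass(frozen=True)
class Arm:
    ion: str
    dose_cgy: float
    n: int


@dataclass(frozen=True)
class StudyDesign:
    """Arm table plus the ordered stage lists of the two test phases."""

    arms: tuple[Arm, ...]
    stages_prescreen: tuple[str, ...] = PRESCREEN_STAGES
    stages_post: tuple[str, ...] = POST_STAGES

    def __post_init__(self) -> None:
        for stages, name in (
            (self.stages_prescreen, "prescreen"),
            (self.stages_post, "post"),
        ):
            if not stages:
                raise ValueError(f"{name} stage list is empty")
            if len(set(stages)) != len(stages):
                raise ValueError(f"{name} stage list has duplicates: {stages}")
        for arm in self.arms:
            if arm.ion not in IONS:
                raise ValueError(f"unknown ion label {arm.ion!r} (expected one of {IONS})")
            if arm.n < 0:
                raise ValueError(f"negative arm size {arm.n} for {arm.ion}@{arm.dose_cgy}")
            if arm.dose_cgy < 0 or not math.isfinite(arm.dose_cgy):
                raise ValueError(f"invalid dose {arm.dose_cgy} for {arm.ion}")
            if arm.ion == "sham" and arm.dose_cgy != 0:
                raise ValueError("sham arm must have dose 0")

    @property
    def total_n(self) -> int:
        return sum(arm.n for arm in self.arms)


def default_design() -> StudyDesign:
    """The study's arm table: 432 rats over five ions plus sham."""
    arms = [
        Arm("sham", 0.0, 62),
        Arm("He", 1.0, 19),
        Arm("He", 5.0, 20),
        Arm("He", 10.0, 15),
        Arm("O", 1.5, 6),
        Arm("O", 5.0, 18),
        Arm("O", 10.0, 11),
        Arm("Si", 1.0, 15),
        Arm("Si", 3.0, 14),
        Arm("Si", 5.0, 63),
        Arm("Si", 10.0, 45),
        Arm("Si", 15.0, 15),
        Arm("Ti", 3.0, 8),
        Arm("Ti", 5.0, 16),
        Arm("Ti", 10.0, 12),
        Arm("Ti", 15.0, 10),
        Arm("Fe", 1.0, 9),
        Arm("Fe", 3.0, 15),
        Arm("Fe", 5.0, 26),
        Arm("Fe", 10.0, 17),
        Arm("Fe", 15.0, 16),
    ]
    return StudyDesign(arms=tuple(arms))


# Susceptibility: ability decrement per cGy for each (ion, stage), with
# optional per-dose overrides for non-monotone responses.  Defaults encode
# the qualitative dose responses the analysis is meant to recover: a strong
# monotone effect of Fe in SD and CD, a monotone Si effect in SD, a null He
# effect in SD, and a non-monotone Si response in CD (mid-dose ~ no effect).
DEFAULT_SUSCEPTIBILITY: dict[tuple[str, str], float] = {
    ("Fe", "SD"): 0.140,
    ("Fe", "CD"): 0.135,
    ("Si", "SD"): 0.110,
    ("He", "SD"): 0.0,
    ("He", "CD"): 0.020,
    ("O", "SD"): 0.060,
    ("Ti", "SD"): 0.070,
}
DEFAULT_DOSE_OVERRIDES: dict[tuple[str, str], dict[float, float]] = {
    # total decrement at each dose, not per-cGy; mid dose deliberately flat
    ("Si", "CD"): {1.0: 0.15, 5.0: 0.05, 10.0: 0.85, 15.0: 1.20},
}
# decrement per cGy for (ion, stage) pairs not listed above
DEFAULT_BASELINE_COEF = 0.050


@dataclass(frozen=True)
class GenerativeParams:
    """Knobs of the latent-ability cohort model (all unitless unless noted)."""

    ability_mean: float = 1.6
    ability_sd: float = 0.3
    susceptibility: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SUSCEPTIBILITY)
    )
    dose_overrides: Mapping[tuple[str, str], Mapping[float, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DOSE_OVERRIDES.items()}
    )
    baseline_coef: float = DEFAULT_BASELINE_COEF
    learning_rate: float = 0.12  # added to success log-odds per attempt
    retest_sd: float = 0.8  # subject-level post-phase ability noise
    latency_meanlog: float = math.log(10.0)  # seconds, lognormal
    latency_sdlog: float = 0.4
    max_stage_failures: int = 2

    def __post_init__(self) -> None:
        if not (self.ability_sd > 0 and self.latency_sdlog > 0):
            raise ValueError("sd parameters must be positive")
        if self.retest_sd < 0:
            raise ValueError("retest_sd must be non-negative")
        values = [
            self.ability_mean,
            self.learning_rate,
            self.latency_meanlog,
            self.baseline_coef,
            *self.susceptibility.values(),
            *(d for ov in self.dose_overrides.values() for d in ov.values()),
        ]
        if not all(math.isfinite(v) for v in values):
            raise ValueError("generative parameters must be finite")
        if self.max_stage_failures < 1:
            raise ValueError("max_stage_failures must be >= 1")

    def decrement(self, ion: str, stage: str, dose_cgy: float) -> float:
        """Ability loss for a given ion/stage/dose."""
        if ion == "sham" or dose_cgy == 0:
            return 0.0
        overrides = self.dose_overrides.get((ion, stage))
        if overrides is not None and dose_cgy in overrides:
            return overrides[dose_cgy]
        coef = self.susceptibility.get((ion, stage), self.baseline_coef)
        return coef * dose_cgy


def simulate_stage(
    ability: float, params: GenerativeParams, rng: np.random.Generator, stage: str = "SD"
) -> StagePerformance:
    """Simulate one stage: Bernoulli trials under a logistic learning curve.

    The attempt index keeps counting across the two days, so learning
    carries over the overnight rest.  Degenerate abilities are allowed; the
    success probability is clamped inside (0, 1).
    """
    if math.isnan(ability):
        raise ValueError("ability must not be NaN")
    days: list[list[TrialRecord]] = []
    t = 0  # cumulative attempt index
    for _day in (1, 2):
        trials: list[TrialRecord] = []
        run = 0
        while len(trials) < MAX_TRIALS_PER_DAY and run < CRITERION_RUN:
            p = expit(ability + params.learning_rate * t)
            p = min(max(p, 1e-12), 1 - 1e-12)
            correct = rng.random() < p
            latency = float(rng.lognormal(params.latency_meanlog, params.latency_sdlog)) if correct else None
            trials.append(TrialRecord(correct, latency))
            run = run + 1 if correct else 0
            t += 1
        days.append(trials)
        if run >= CRITERION_RUN:
            break
    day2 = days[1] if len(days) > 1 else []
    return StagePerformance(stage=stage, day1=days[0], day2=day2)


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def generate_subject(
    index: int, ion: str, dose_cgy: float, params: GenerativeParams, seed: int
) -> Subject:
    rng = _subject_rng(seed, index)
    ability = float(rng.normal(params.ability_mean, params.ability_sd))
    retest = float(rng.normal(0.0, params.retest_sd)) if params.retest_sd > 0 else 0.0
    subject = Subject(
        subject_id=f"S{index:04d}", ion=ion, dose_cgy=float(dose_cgy)
    )
    for stage in PRESCREEN_STAGES:
        subject.prescreen[stage] = simulate_stage(ability, params, rng, stage)
    failures = 0
    for stage in POST_STAGES:
        post_ability = ability - params.decrement(ion, stage, dose_cgy) + retest
        perf = simulate_stage(post_ability, params, rng, stage)
        subject.post[stage] = perf
        if not perf.reached_criterion:
            failures += 1
            if failures >= params.max_stage_failures:
                break  # subsequent stages are never administered
    return subject


def generate_cohort(
    design: StudyDesign,
    params: GenerativeParams | None = None,
    seed: int = 0,
) -> list[Subject]:
    """Generate the full cohort; (design, params, seed) fully determine it."""
    params = params or GenerativeParams()
    subjects: list[Subject] = []
    index = 0
    for arm in design.arms:
        for _ in range(arm.n):
            subjects.append(generate_subject(index, arm.ion, arm.dose_cgy, params, seed))
            index += 1
    return subjects


def stage_list(design: StudyDesign, phase: str) -> Sequence[str]:
    return design.stages_prescreen if phase == "prescreen" else design.stages_post


def null_params(params: GenerativeParams | None = None) -> GenerativeParams:
    """Copy of ``params`` with every radiation effect switched off."""
    params = params or GenerativeParams()
    return replace(
        params,
        susceptibility={k: 0.0 for k in params.susceptibility},
        dose_overrides={k: {d: 0.0 for d in v} for k, v in params.dose_overrides.items()},
        baseline_coef=0.0,
    )


def criterion_day1_probability(
    per_trial_p: float, n_trials: int = MAX_TRIALS_PER_DAY, run: int = CRITERION_RUN
) -> float:
    """Exact P(a run of ``run`` successes occurs within ``n_trials`` i.i.d.
    Bernoulli(p) attempts), by dynamic programming over (attempt, current
    streak).  Used as an independent oracle for the trial simulator.
    """
    if not 0.0 <= per_trial_p <= 1.0:
        raise ValueError("probability outside [0, 1]")
    # state: current consecutive-success count 0..run-1; absorbing success
    probs = np.zeros(run)
    probs[0] = 1.0
    reached = 0.0
    for _ in range(n_trials):
        new = np.zeros(run)
        new[0] = probs.sum() * (1 - per_trial_p)
        new[1:] = probs[:-1] * per_trial_p
        reached += probs[-1] * per_trial_p
        probs = new
    return float(reached)
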