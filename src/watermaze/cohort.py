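"""Cohort design: groups, behavioral parameters and the trial schedule.

The default design mirrors a 2-genotype × 4-treatment study of spatial
learning in the Ts65Dn mouse model of Down syndrome: wild-type (WT) and
trisomic (TS) animals, each untreated (NT) or treated with environmental
enrichment (EE), the green-tea polyphenol EGCG, or both (EE-EGCG), with
group sizes 10, 11, 14, 11, 11, 9, 12 and 8.  The protocol is one
pretraining trial, five acquisition sessions of four trials, one probe
trial (platform removed, fixed 60 s), one cued trial (visible platform),
and three reversal sessions of four trials with the platform moved to the
opposite quadrant.

Behavioral parameters are per group.  ``goal_bias(session)`` — the weight
of goal-directed heading — grows linearly with the session index at
``learning_rate``, which is what makes latency fall across sessions; the
default rates encode the qualitative ordering seen in middle-aged Ts65Dn
cohorts (WT learn fastest; TS-EE ≈ TS-EE-EGCG intermediate; TS ≈ TS-EGCG
flat), elevated thigmotaxis in trisomic groups, and a lower off-target
swim speed under EGCG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

GENOTYPES = ("WT", "TS")
TREATMENTS = ("NT", "EE", "EGCG", "EE-EGCG")

#: Printed group sizes, in (genotype, treatment) order WT/TS × NT/EE/EGCG/EE-EGCG.
DEFAULT_GROUP_SIZES = {
    ("WT", "NT"): 10,
    ("TS", "NT"): 11,
    ("WT", "EE"): 14,
    ("TS", "EE"): 11,
    ("WT", "EGCG"): 11,
    ("TS", "EGCG"): 9,
    ("WT", "EE-EGCG"): 12,
    ("TS", "EE-EGCG"): 8,
}


@dataclass(frozen=True)
class GroupBehavior:
    """Generative movement parameters for one experimental group.

    initial_goal_bias and learning_rate parameterize the session-dependent
    weight of goal-directed heading, clipped to [0, 1]; thigmotaxis_weight
    is the wall-following share of the non-goal-directed heading; speed is
    drawn once per trial from N(base_speed, speed_sd) cm/s;
    heading_noise_sd (radians) perturbs each step's heading; cue_bias is
    the goal bias used when the platform is visible (pretraining and cued
    trials), overriding the learned bias.  subject_rate_sd and
    subject_speed_sd are between-subject SDs of the learning rate and the
    base speed (good vs poor learners, fast vs slow swimmers), applied
    once per subject.
    """

    initial_goal_bias: float = 0.1
    learning_rate: float = 0.1
    thigmotaxis_weight: float = 0.2
    base_speed: float = 18.0
    speed_sd: float = 2.0
    heading_noise_sd: float = 1.2
    cue_bias: float = 0.85
    subject_rate_sd: float = 0.025
    subject_speed_sd: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.initial_goal_bias <= 1.0:
            raise ValueError("initial_goal_bias must lie in [0, 1]")
        if not 0.0 <= self.thigmotaxis_weight <= 1.0:
            raise ValueError("thigmotaxis_weight must lie in [0, 1]")
        if self.base_speed <= 0:
            raise ValueError("base_speed must be positive")
        if min(self.speed_sd, self.heading_noise_sd, self.subject_rate_sd,
               self.subject_speed_sd) < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")

    def goal_bias(self, session: int) -> float:
        """Goal-directed heading weight for 1-based acquisition session."""
        b = self.initial_goal_bias + self.learning_rate * (session - 1)
        return min(max(b, 0.0), 1.0)


#: Study-condition behavior defaults per (genotype, treatment).
DEFAULT_BEHAVIOR = {
    ("WT", "NT"): GroupBehavior(0.12, 0.12, 0.12, 18.0, 2.0),
    ("WT", "EE"): GroupBehavior(0.12, 0.12, 0.08, 18.0, 2.0),
    ("WT", "EGCG"): GroupBehavior(0.12, 0.11, 0.12, 15.5, 2.0),
    ("WT", "EE-EGCG"): GroupBehavior(0.12, 0.12, 0.08, 15.5, 2.0),
    ("TS", "NT"): GroupBehavior(0.08, 0.025, 0.35, 18.0, 2.0),
    ("TS", "EE"): GroupBehavior(0.08, 0.07, 0.25, 18.0, 2.0),
    ("TS", "EGCG"): GroupBehavior(0.08, 0.03, 0.38, 15.5, 2.0),
    ("TS", "EE-EGCG"): GroupBehavior(0.08, 0.08, 0.22, 15.5, 2.0),
}


@dataclass(frozen=True)
class GroupSpec:
    genotype: str
    treatment: str
    n_subjects: int
    behavior: GroupBehavior = field(default_factory=GroupBehavior)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def label(self) -> str:
        return self.genotype if self.treatment == "NT" else f"{self.genotype}-{self.treatment}"


@dataclass(frozen=True)
class CohortDesign:
    """Full cohort and protocol description."""

    groups: tuple[GroupSpec, ...]
    n_acquisition_sessions: int = 5
    trials_per_session: int = 4
    n_reversal_sessions: int = 3
    trial_cutoff: float = 60.0
    sample_rate: float = 10.0
    include_pretraining: bool = True
    include_probe: bool = True
    include_cued: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        if self.n_acquisition_sessions < 1 or self.trials_per_session < 1:
            raise ValueError("acquisition schedule must be non-empty")
        if self.n_reversal_sessions < 0:
            raise ValueError("n_reversal_sessions must be >= 0")
        n = self.trial_cutoff * self.sample_rate
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("trial_cutoff × sample_rate must be a positive integer")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def cutoff_samples(self) -> int:
        return int(round(self.trial_cutoff * self.sample_rate))

    @property
    def n_subjects(self) -> int:
        return sum(g.n_subjects for g in self.groups)

    @property
    def group_labels(self) -> list[str]:
        return [g.label for g in self.groups]

    def trials_per_subject(self) -> int:
        """Scheduled trial count per subject across all phases."""
        n = self.n_acquisition_sessions * self.trials_per_session
        n += self.n_reversal_sessions * self.trials_per_session
        n += int(self.include_pretraining) + int(self.include_probe) + int(self.include_cued)
        return n

    def subject_ids(self) -> list[tuple[str, str]]:
        """(subject_id, group label) pairs; ids are stable per group."""
        out = []
        for g in self.groups:
            for k in range(g.n_subjects):
                out.append((f"{g.label}_{k + 1:02d}", g.label))
        return out


def default_cohort(seed: int = 0, **overrides) -> CohortDesign:
    """The study-condition cohort: 8 groups with the printed sizes and the
    default behavior parameters."""
    groups = tuple(
        GroupSpec(gt, tr, DEFAULT_GROUP_SIZES[(gt, tr)], DEFAULT_BEHAVIOR[(gt, tr)])
        for gt in GENOTYPES
        for tr in TREATMENTS
    )
    return CohortDesign(groups=groups, seed=seed, **overrides)
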