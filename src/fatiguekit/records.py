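"""Shared study containers: athletes, sessions, cohort datasets, questionnaires.

These are the in-memory objects every stage of the pipeline exchanges.  A
:class:`StudyDataset` is either loaded from a study directory (manifest +
per-session CSVs) or produced by the synthetic generator, in which case it
also carries the generator's ground truth for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .jumps import BoscoResult
from .sessions import GnssTrack, HeartRateSeries, WingateTrial

TRAINING_GROUPS = ("<45min", ">=45min")

#: Parameters analysed by the pipeline.  ``hr_bpm`` and ``distance_m`` are
#: session-level quantities without a pre/post contrast; everything else is
#: measured before and after the fatigue protocol.
SESSION_PARAMETERS = ("hr_bpm", "distance_m")
PREPOST_PARAMETERS = (
    "wingate_mean_w",
    "wingate_max_w",
    "h_max_m",
    "bosco_power_w",
    "rsi_ms",
    "stiffness_nm",
    "tc_s",
    "tf_s",
)
ALL_PARAMETERS = SESSION_PARAMETERS + PREPOST_PARAMETERS

#: Parameters where a *smaller* value means better performance (heart rate at
#: a fixed workload, and ground contact time).
SMALLER_IS_BETTER = ("hr_bpm", "tc_s")


@dataclass(frozen=True)
class AthleteProfile:
    athlete_id: str
    mass_kg: float
    height_cm: float
    age_y: float
    training_group: str

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError(f"mass_kg must be positive, got {self.mass_kg}")
        if self.training_group not in TRAINING_GROUPS:
            raise ValueError(
                f"training_group must be one of {TRAINING_GROUPS}, "
                f"got {self.training_group!r}"
            )


@dataclass
class SessionRecord:
    """One athlete-session: raw series plus (optionally) extracted results.

    ``wingate_pre``/``wingate_post`` and ``bosco_pre``/``bosco_post`` may be
    raw trials/traces to be processed by the extraction stage, or already
    extracted results — the pipeline accepts either.
    """

    athlete_id: str
    date: str
    week_index: int
    hr_series: Optional[HeartRateSeries] = None
    gnss: Optional[GnssTrack] = None
    wingate_pre: Optional[WingateTrial] = None
    wingate_post: Optional[WingateTrial] = None
    bosco_pre: Optional[object] = None  # AccelTrace or BoscoResult
    bosco_post: Optional[object] = None

    def __post_init__(self) -> None:
        if self.week_index < 1:
            raise ValueError("week_index is 1-based and must be >= 1")


@dataclass
class QuestionnaireResponse:
    """Answers of one athlete to the lockdown-training questionnaire."""

    athlete_id: str
    answers: dict = field(default_factory=dict)


@dataclass
class StudyDataset:
    """Cohort container: athletes x weeks x sessions.

    ``ground_truth`` is present only for synthetic datasets; it is a tidy
    DataFrame of the generator's true per-session parameter values used by
    validation tests, never by the analysis itself.
    """

    athletes: list[AthleteProfile]
    sessions: list[SessionRecord]
    questionnaire: list[QuestionnaireResponse] = field(default_factory=list)
    ground_truth: Optional[object] = None  # pandas.DataFrame
    n_weeks: int = 4

    def __post_init__(self) -> None:
        ids = {a.athlete_id for a in self.athletes}
        for s in self.sessions:
            if s.athlete_id not in ids:
                raise ValueError(f"session references unknown athlete {s.athlete_id!r}")
            if not (1 <= s.week_index <= self.n_weeks):
                raise ValueError(
                    f"session week_index {s.week_index} outside 1..{self.n_weeks}"
                )

    def athlete(self, athlete_id: str) -> AthleteProfile:
        for a in self.athletes:
            if a.athlete_id == athlete_id:
                return a
        raise KeyError(athlete_id)
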