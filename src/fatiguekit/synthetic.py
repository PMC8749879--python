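"""Synthetic study generator with exact ground truth.

Emulates every input of the monitoring pipeline so the whole analysis is
testable without recordings: repeated-jump accelerometry with known contact
and flight times, 5-s heart-rate series, GNSS shuttle tracks of fixed
prescribed geometry, 30-s Wingate power traces, and a full multi-week
cohort following a configurable downfall-recovery trajectory (worst
performance at a configurable nadir week, improvement afterwards) with two
lockdown-training subgroups.

Default configuration mirrors the study design this package analyses:
8 athletes, 4 weeks with (2, 2, 1, 1) sessions, pre/post trials per
session, nadir at week 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .jumps import (
    BodyParams,
    JumpEvent,
    flight_height,
    leg_stiffness,
    mean_power,
    reactive_strength_index,
)
from .records import (
    AthleteProfile,
    QuestionnaireResponse,
    SessionRecord,
    StudyDataset,
    TRAINING_GROUPS,
)
from .sessions import EARTH_RADIUS_M, GnssTrack, HeartRateSeries, WingateTrial

__all__ = [
    "JumpSpec",
    "AccelTrace",
    "CohortConfig",
    "flight_time_from_height",
    "simulate_jump_trace",
    "simulate_session",
    "simulate_cohort",
    "simulate_parameter_table",
    "default_questionnaire",
    "QUESTIONNAIRE_ITEMS",
]


# ---------------------------------------------------------------------------
# Jump accelerometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JumpSpec:
    """Ground-truth description of one contact -> flight cycle."""

    tc_s: float
    tf_s: float
    peak_contact_gain: float = 3.0

    def __post_init__(self) -> None:
        if self.tc_s <= 0 or self.tf_s <= 0:
            raise ValueError(f"durations must be positive: tc={self.tc_s}, tf={self.tf_s}")
        if self.peak_contact_gain <= 1:
            raise ValueError("peak_contact_gain must exceed 1 (quiet standing reads 1 g)")


@dataclass
class AccelTrace:
    """Uniformly sampled vertical specific force, in units of g."""

    fs_hz: float
    t0: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.samples.size == 0:
            raise ValueError("empty trace")

    @property
    def time_s(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs_hz


def flight_time_from_height(h_m: float, g: float = 9.81) -> float:
    """Flight duration producing apex height h: Tf = sqrt(8*h/g).

    Inverse of the flight-time height formula h = g*Tf^2/8, so the
    round-trip holds to machine precision.
    """
    if h_m < 0:
        raise ValueError(f"height must be non-negative, got {h_m}")
    if g <= 0:
        raise ValueError(f"g must be positive, got {g}")
    return math.sqrt(8.0 * h_m / g)


def simulate_jump_trace(
    jumps: Sequence[JumpSpec],
    fs_hz: float = 100.0,
    noise_sd_g: float = 0.0,
    lead_s: float = 1.0,
    tail_s: float = 1.0,
    seed: Optional[int] = None,
) -> tuple[AccelTrace, list[JumpEvent]]:
    """Render a repeated-jump trace with exact ground-truth boundaries.

    The signal is 1 g during quiet standing, 0 g during flight (ideal free
    fall) and a half-sine pulse rising from 1 g to ``peak_contact_gain``
    during contact; Gaussian noise of ``noise_sd_g`` is added on top.  All
    durations are rounded to whole samples, so the returned ground-truth
    events sit exactly on the sample grid: a threshold detector recovers
    them to the sample on noiseless traces, and the residual error against
    the requested durations is at most half a sample period.
    """
    jumps = list(jumps)
    if not jumps:
        raise ValueError("empty jump specification")
    if fs_hz < 50:
        raise ValueError(f"fs_hz must be >= 50 Hz for resolvable flights, got {fs_hz}")
    segments: list[np.ndarray] = [np.ones(int(round(lead_s * fs_hz)))]
    truth: list[JumpEvent] = []
    pos = segments[0].size
    for k, j in enumerate(jumps):
        n_c = int(round(j.tc_s * fs_hz))
        n_f = int(round(j.tf_s * fs_hz))
        if n_f < 3:
            raise ValueError(
                f"jump {k}: flight of {j.tf_s} s spans only {n_f} samples at "
                f"{fs_hz} Hz (need >= 3); raise fs_hz or tf_s"
            )
        if n_c < 1:
            raise ValueError(f"jump {k}: contact of {j.tc_s} s shorter than one sample")
        # half-sine contact pulse: non-zero slope at both edges keeps
        # noiseless onset detection within one sample
        phase = (np.arange(n_c) + 0.5) / n_c
        pulse = 1.0 + (j.peak_contact_gain - 1.0) * np.sin(math.pi * phase)
        segments.append(pulse)
        segments.append(np.zeros(n_f))
        truth.append(
            JumpEvent(
                contact_start_s=pos / fs_hz,
                takeoff_s=(pos + n_c) / fs_hz,
                landing_s=(pos + n_c + n_f) / fs_hz,
            )
        )
        pos += n_c + n_f
    segments.append(np.ones(max(1, int(round(tail_s * fs_hz)))))
    samples = np.concatenate(segments)
    if noise_sd_g > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd_g, samples.size)
    return AccelTrace(fs_hz=fs_hz, t0=0.0, samples=samples), truth


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupOffsets:
    """How the two lockdown-training subgroups differ.

    Athletes who trained < 45 min/day during the lockdown show higher heart
    rates and larger fatigue effects.  The fatigue gammas scale the weekly
    *deficit* (1 - effect), so a week with no configured effect stays
    effect-free in both groups.
    """

    hr_bpm_lt45: float = 4.0
    fatigue_gamma_lt45: float = 1.25
    fatigue_gamma_ge45: float = 0.75


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and noise parameters of the synthetic cohort.

    The defaults are the study conditions this package models: 8 athletes,
    4 weeks with (2, 2, 1, 1) sessions, weekly mean heart rates declining
    from ~157 to ~141 bpm, post/pre fatigue effects worst at week 2 and
    recovering afterwards, and a fixed 5-phase shuttle protocol of 25-m
    legs (4000 m prescribed distance).
    """

    n_athletes: int = 8
    n_weeks: int = 4
    sessions_per_week: tuple = (2, 2, 1, 1)
    nadir_week: int = 2
    # pre-effort baselines
    baseline_by_param: dict = field(
        default_factory=lambda: {
            "wingate_mean_w": 420.0,
            "wingate_max_w": 525.0,
            "tc_s": 0.25,
            "tf_s": 0.50,
        }
    )
    hr_mean_by_week: tuple = (157.0, 158.0, 146.0, 141.0)
    # multiplicative post/pre effects, in (0, 1]
    fatigue_effect_by_week: tuple = (0.92, 0.78, 0.92, 0.95)  # Wingate powers
    bosco_effect_by_week: tuple = (0.90, 0.80, 0.90, 1.00)  # jump parameters
    recovery_slope: float = 0.06  # weekly effect improvement used by profile builders
    subgroup_offsets: SubgroupOffsets = field(default_factory=SubgroupOffsets)
    # noise
    noise_cv: float = 0.03  # session-level measurement/biological CV
    athlete_cv: float = 0.08  # between-athlete performance CV
    jump_cv: float = 0.02  # jump-to-jump variability within a trial
    accel_noise_sd_g: float = 0.02
    gnss_jitter_m: float = 0.0
    # session structure
    session_duration_min: float = 45.0
    hr_sample_period_s: float = 5.0
    bosco_duration_s: float = 30.0
    accel_fs_hz: float = 100.0
    peak_contact_gain: float = 3.0
    wingate_fs_hz: float = 10.0
    wingate_duration_s: float = 30.0
    # fatigue-protocol geometry (5 phases of 25-m shuttle legs, 2-min rests)
    n_phases: int = 5
    phase_duration_s: float = 300.0
    rest_duration_s: float = 120.0
    legs_per_phase: int = 32
    leg_length_m: float = 25.0
    origin_lat_deg: float = 43.72
    origin_lon_deg: float = 10.40
    include_traces: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_athletes < 1 or self.n_weeks < 1:
            raise ValueError("cohort needs at least one athlete and one week")
        if len(self.sessions_per_week) != self.n_weeks:
            raise ValueError("sessions_per_week length must equal n_weeks")
        if any(s < 1 for s in self.sessions_per_week):
            raise ValueError("every week needs at least one session")
        if not 1 <= self.nadir_week <= self.n_weeks:
            raise ValueError(f"nadir_week {self.nadir_week} outside 1..{self.n_weeks}")
        for name in ("fatigue_effect_by_week", "bosco_effect_by_week"):
            eff = getattr(self, name)
            if len(eff) != self.n_weeks:
                raise ValueError(f"{name} length must equal n_weeks")
            if any(not 0 < e <= 1 for e in eff):
                raise ValueError(f"{name} values must lie in (0, 1]")
        if len(self.hr_mean_by_week) != self.n_weeks:
            raise ValueError("hr_mean_by_week length must equal n_weeks")
        if self.noise_cv < 0 or self.athlete_cv < 0 or self.jump_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")

    def noiseless(self) -> "CohortConfig":
        """Copy with every stochastic component switched off."""
        return replace(
            self,
            noise_cv=0.0,
            athlete_cv=0.0,
            jump_cv=0.0,
            accel_noise_sd_g=0.0,
            gnss_jitter_m=0.0,
        )

    def null(self) -> "CohortConfig":
        """Copy with no week effect: flat fatigue and heart-rate profiles."""
        return replace(
            self,
            fatigue_effect_by_week=(0.9,) * self.n_weeks,
            bosco_effect_by_week=(0.9,) * self.n_weeks,
            hr_mean_by_week=(150.0,) * self.n_weeks,
        )

    @property
    def prescribed_distance_m(self) -> float:
        return self.n_phases * self.legs_per_phase * self.leg_length_m


# ---------------------------------------------------------------------------
# Scalar layer: per-session parameter draws
# ---------------------------------------------------------------------------

def _group_effect(effect: float, group: str, off: SubgroupOffsets) -> float:
    gamma = off.fatigue_gamma_lt45 if group == "<45min" else off.fatigue_gamma_ge45
    return 1.0 - (1.0 - effect) * gamma


def _draw_athletes(rng: np.random.Generator, cfg: CohortConfig):
    """Profiles plus latent per-athlete factors (performance, timing, HR)."""
    profiles, latents = [], []
    half = (cfg.n_athletes + 1) // 2
    hr_mu = float(np.mean(cfg.hr_mean_by_week))
    for i in range(cfg.n_athletes):
        group = TRAINING_GROUPS[0] if i < half else TRAINING_GROUPS[1]
        profiles.append(
            AthleteProfile(
                athlete_id=f"A{i + 1:02d}",
                mass_kg=float(np.clip(rng.normal(72.4, 8.3), 55.0, 95.0)),
                height_cm=float(np.clip(rng.normal(180.8, 6.3), 165.0, 200.0)),
                age_y=float(np.clip(rng.normal(23.0, 3.0), 18.0, 34.0)),
                training_group=group,
            )
        )
        latents.append(
            dict(
                power=math.exp(rng.normal(0.0, cfg.athlete_cv)),
                tf=math.exp(rng.normal(0.0, cfg.athlete_cv / 2)),
                tc=math.exp(rng.normal(0.0, cfg.athlete_cv / 2)),
                hr=rng.normal(0.0, 0.25 * cfg.athlete_cv * hr_mu),
            )
        )
    return profiles, latents


def _session_scalars(
    rng: np.random.Generator,
    cfg: CohortConfig,
    latent: dict,
    group: str,
    week: int,
) -> dict:
    """True parameter values of one session (week is 1-based)."""
    cv = cfg.noise_cv
    off = cfg.subgroup_offsets
    eff_w = _group_effect(cfg.fatigue_effect_by_week[week - 1], group, off)
    eff_b = _group_effect(cfg.bosco_effect_by_week[week - 1], group, off)
    base = cfg.baseline_by_param

    def jitter(sd_scale: float = 1.0) -> float:
        return 1.0 + rng.normal(0.0, cv * sd_scale) if cv > 0 else 1.0

    wm_pre = base["wingate_mean_w"] * latent["power"] * jitter()
    wx_pre = max(base["wingate_max_w"] * latent["power"] * jitter(), 1.05 * wm_pre)
    wm_post = wm_pre * eff_w * jitter()
    wx_post = max(wx_pre * eff_w * jitter(), 1.05 * wm_post)

    tc_pre = base["tc_s"] * latent["tc"] * jitter(0.5)
    tf_pre = base["tf_s"] * latent["tf"] * jitter(0.5)
    # fatigue shortens flight (height scales with the configured effect) and
    # lengthens ground contact
    tc_post = tc_pre * eff_b ** (-0.25) * jitter(0.5)
    tf_post = tf_pre * math.sqrt(eff_b) * jitter(0.5)

    hr_group = off.hr_bpm_lt45 if group == "<45min" else 0.0
    hr = (cfg.hr_mean_by_week[week - 1] + hr_group + latent["hr"]) * jitter()

    return dict(
        hr_bpm=hr,
        distance_m=cfg.prescribed_distance_m,
        wingate_mean_w_pre=wm_pre,
        wingate_mean_w_post=wm_post,
        wingate_max_w_pre=wx_pre,
        wingate_max_w_post=wx_post,
        tc_s_pre=tc_pre,
        tc_s_post=tc_post,
        tf_s_pre=tf_pre,
        tf_s_post=tf_post,
    )


def _scalars_to_truth_rows(scalars: dict, athlete: AthleteProfile, week: int,
                           session_index: int) -> list[dict]:
    """Tidy ground-truth rows including the derived jump parameters."""
    body = BodyParams(mass_kg=athlete.mass_kg)
    rows = []

    def add(parameter: str, phase: str, value: float) -> None:
        rows.append(
            dict(
                athlete_id=athlete.athlete_id,
                week_index=week,
                session_index=session_index,
                parameter=parameter,
                phase=phase,
                value=float(value),
            )
        )

    add("hr_bpm", "overall", scalars["hr_bpm"])
    add("distance_m", "overall", scalars["distance_m"])
    for phase in ("pre", "post"):
        add("wingate_mean_w", phase, scalars[f"wingate_mean_w_{phase}"])
        add("wingate_max_w", phase, scalars[f"wingate_max_w_{phase}"])
        tc, tf = scalars[f"tc_s_{phase}"], scalars[f"tf_s_{phase}"]
        h = flight_height(tf, body.g_ms2)
        add("tc_s", phase, tc)
        add("tf_s", phase, tf)
        add("h_max_m", phase, h)
        add("bosco_power_w", phase, mean_power(body, tc, tf))
        add("rsi_ms", phase, reactive_strength_index(h, tc))
        add("stiffness_nm", phase, leg_stiffness(body, tc, tf))
    return rows


# ---------------------------------------------------------------------------
# Trace layer: render raw series from scalars
# ---------------------------------------------------------------------------

def _render_hr(scalars: dict, cfg: CohortConfig, rng: np.random.Generator) -> HeartRateSeries:
    n = int(round(cfg.session_duration_min * 60.0 / cfg.hr_sample_period_s))
    t = np.arange(n) / max(n - 1, 1)
    profile = 6.0 * np.sin(math.pi * t)  # warm-up / wind-down arc
    noise = rng.normal(0.0, 3.0, n) if cfg.noise_cv > 0 else np.zeros(n)
    v = profile + noise
    v = v - v.mean() + scalars["hr_bpm"]  # series mean == session value exactly
    return HeartRateSeries(bpm=v, sample_period_s=cfg.hr_sample_period_s)


def _shuttle_xy(cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """(time_s, x_m) polyline of the 5-phase shuttle protocol.

    Each phase is ``legs_per_phase`` out-and-back 25-m legs run at constant
    speed; phases are separated by rests during which no points are emitted.
    Leg vertices are always included so the polyline length equals the
    prescribed distance exactly.
    """
    speed = cfg.legs_per_phase * cfg.leg_length_m / cfg.phase_duration_s
    pts_per_leg = 3  # vertex + two interior points
    ts, xs = [], []
    t_phase = 0.0
    for _ in range(cfg.n_phases):
        s = 0.0
        x0, direction = 0.0, 1.0
        for _leg in range(cfg.legs_per_phase):
            for k in range(pts_per_leg):
                frac = k / pts_per_leg
                ts.append(t_phase + (s + frac * cfg.leg_length_m) / speed)
                xs.append(x0 + direction * frac * cfg.leg_length_m)
            s += cfg.leg_length_m
            x0 += direction * cfg.leg_length_m
            direction *= -1.0
        ts.append(t_phase + s / speed)  # closing vertex of the phase
        xs.append(x0)
        t_phase += cfg.phase_duration_s + cfg.rest_duration_s
    return np.asarray(ts), np.asarray(xs)


def _render_gnss(cfg: CohortConfig, rng: np.random.Generator) -> GnssTrack:
    t, x = _shuttle_xy(cfg)
    y = np.zeros_like(x)
    if cfg.gnss_jitter_m > 0:
        x = x + rng.normal(0.0, cfg.gnss_jitter_m, x.size)
        y = y + rng.normal(0.0, cfg.gnss_jitter_m, y.size)
    # local equirectangular inverse around the origin
    lat0 = math.radians(cfg.origin_lat_deg)
    lat = cfg.origin_lat_deg + np.degrees(y / EARTH_RADIUS_M)
    lon = cfg.origin_lon_deg + np.degrees(x / (EARTH_RADIUS_M * math.cos(lat0)))
    return GnssTrack(time_s=t, lat_deg=lat, lon_deg=lon)


def _render_wingate(mean_w: float, max_w: float, cfg: CohortConfig) -> WingateTrial:
    """Ramp -> plateau -> linear-decay power profile with the given
    time-average and plateau (peak) level."""
    fs, total = cfg.wingate_fs_hz, cfg.wingate_duration_s
    t_rise, t_plateau = 3.0, 2.0
    t_decay = total - t_rise - t_plateau
    p_end = (2.0 * (total * mean_w - t_rise * max_w / 2.0 - t_plateau * max_w)) / t_decay - max_w
    p_end = max(p_end, 0.0)
    t = (np.arange(int(round(total * fs))) + 0.5) / fs
    p = np.where(
        t < t_rise,
        max_w * t / t_rise,
        np.where(
            t < t_rise + t_plateau,
            max_w,
            max_w + (p_end - max_w) * (t - t_rise - t_plateau) / t_decay,
        ),
    )
    return WingateTrial(power_w=p, fs_hz=fs, duration_s=total)


def _render_bosco(
    tc_s: float, tf_s: float, cfg: CohortConfig, rng: np.random.Generator
) -> AccelTrace:
    n_jumps = max(1, int(cfg.bosco_duration_s // (tc_s + tf_s)))
    specs = []
    for _ in range(n_jumps):
        jc = 1.0 + rng.normal(0.0, cfg.jump_cv) if cfg.jump_cv > 0 else 1.0
        jf = 1.0 + rng.normal(0.0, cfg.jump_cv) if cfg.jump_cv > 0 else 1.0
        specs.append(
            JumpSpec(tc_s=tc_s * jc, tf_s=tf_s * jf, peak_contact_gain=cfg.peak_contact_gain)
        )
    trace, _ = simulate_jump_trace(
        specs,
        fs_hz=cfg.accel_fs_hz,
        noise_sd_g=cfg.accel_noise_sd_g,
        seed=int(rng.integers(2**31)),
    )
    return trace


def _render_session(
    athlete: AthleteProfile,
    week: int,
    scalars: dict,
    cfg: CohortConfig,
    rng: np.random.Generator,
    date: str,
) -> SessionRecord:
    return SessionRecord(
        athlete_id=athlete.athlete_id,
        date=date,
        week_index=week,
        hr_series=_render_hr(scalars, cfg, rng),
        gnss=_render_gnss(cfg, rng),
        wingate_pre=_render_wingate(
            scalars["wingate_mean_w_pre"], scalars["wingate_max_w_pre"], cfg
        ),
        wingate_post=_render_wingate(
            scalars["wingate_mean_w_post"], scalars["wingate_max_w_post"], cfg
        ),
        bosco_pre=_render_bosco(scalars["tc_s_pre"], scalars["tf_s_pre"], cfg, rng),
        bosco_post=_render_bosco(scalars["tc_s_post"], scalars["tf_s_post"], cfg, rng),
    )


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def simulate_session(
    athlete: AthleteProfile,
    week: int,
    cfg: CohortConfig,
    seed: int = 0,
) -> SessionRecord:
    """One synthetic training session for a given athlete and week."""
    if not 1 <= week <= cfg.n_weeks:
        raise ValueError(f"week {week} outside 1..{cfg.n_weeks}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, week]))
    hr_mu = float(np.mean(cfg.hr_mean_by_week))
    latent = dict(
        power=math.exp(rng.normal(0.0, cfg.athlete_cv)),
        tf=math.exp(rng.normal(0.0, cfg.athlete_cv / 2)),
        tc=math.exp(rng.normal(0.0, cfg.athlete_cv / 2)),
        hr=rng.normal(0.0, 0.25 * cfg.athlete_cv * hr_mu),
    )
    scalars = _session_scalars(rng, cfg, latent, athlete.training_group, week)
    return _render_session(athlete, week, scalars, cfg, rng, date=f"week{week}-s1")


def _cohort_scalars(cfg: CohortConfig):
    """Scalar pass shared by the table and full-dataset generators."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    profiles, latents = _draw_athletes(rng, cfg)
    sessions = []  # (athlete index, week, session_index, scalars)
    for week in range(1, cfg.n_weeks + 1):
        for s_idx in range(1, cfg.sessions_per_week[week - 1] + 1):
            for i, prof in enumerate(profiles):
                scal = _session_scalars(rng, cfg, latents[i], prof.training_group, week)
                sessions.append((i, week, s_idx, scal))
    return profiles, sessions


def simulate_parameter_table(cfg: CohortConfig) -> pd.DataFrame:
    """Tidy per-session true parameter values, without rendering any trace.

    Columns: athlete_id, week_index, session_index, parameter, phase, value.
    Identical to the ``ground_truth`` table of :func:`simulate_cohort` for
    the same config.
    """
    profiles, sessions = _cohort_scalars(cfg)
    rows: list[dict] = []
    for i, week, s_idx, scal in sessions:
        rows.extend(_scalars_to_truth_rows(scal, profiles[i], week, s_idx))
    return pd.DataFrame(rows)


def simulate_cohort(cfg: CohortConfig = CohortConfig()) -> StudyDataset:
    """Full synthetic study: athletes, sessions with raw series, ground truth.

    Bit-identical for identical (cfg, seed).  When ``cfg.include_traces`` is
    False, sessions carry no raw series (scalar studies for statistical
    calibration); the ground-truth table is produced either way.
    """
    profiles, scalar_sessions = _cohort_scalars(cfg)
    rows: list[dict] = []
    sessions: list[SessionRecord] = []
    for counter, (i, week, s_idx, scal) in enumerate(scalar_sessions):
        prof = profiles[i]
        rows.extend(_scalars_to_truth_rows(scal, prof, week, s_idx))
        date = f"2020-W{week:02d}-S{s_idx}"
        if cfg.include_traces:
            rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1, counter]))
            sessions.append(_render_session(prof, week, scal, cfg, rng, date))
        else:
            sessions.append(
                SessionRecord(athlete_id=prof.athlete_id, date=date, week_index=week)
            )
    return StudyDataset(
        athletes=profiles,
        sessions=sessions,
        questionnaire=default_questionnaire(),
        ground_truth=pd.DataFrame(rows),
        n_weeks=cfg.n_weeks,
    )


# ---------------------------------------------------------------------------
# Questionnaire
# ---------------------------------------------------------------------------

#: Item schema: name -> ("categorical", options) or ("numeric", unit).
QUESTIONNAIRE_ITEMS: dict = {
    "self_training": ("categorical", ("yes", "no")),
    "aerobic_training": ("categorical", ("yes", "no")),
    "aerobic_frequency": (
        "categorical",
        ("daily", "every alternate day", "2 times a week", "once a week"),
    ),
    "aerobic_intensity": ("numeric", "1-10"),
    "strength_training": ("categorical", ("yes", "no")),
    "strength_frequency": (
        "categorical",
        ("daily", "every alternate day", "2 times a week", "once a week"),
    ),
    "strength_intensity": ("numeric", "1-10"),
    "workout_duration": ("categorical", ("<30 min", "30-45 min", "45-60 min", ">60 min")),
    "pre_lockdown_extra": (
        "categorical",
        ("several times a week", "once a week", "rarely", "no"),
    ),
    "post_lockdown_extra": (
        "categorical",
        ("several times a week", "once a week", "rarely", "no"),
    ),
}


def default_questionnaire() -> list[QuestionnaireResponse]:
    """Canonical 8-athlete response set.

    Synthetic: per-athlete answers are invented, but the marginal tallies
    follow the qualitative pattern of a post-lockdown cohort (everyone
    self-trained, mostly light intensity, a 4/4 split of workout durations
    around 45 min that defines the two training subgroups).
    """
    durations = ["<30 min", "30-45 min", "30-45 min", "30-45 min",
                 "45-60 min", "45-60 min", "45-60 min", ">60 min"]
    aerobic_yes = [True, True, True, True, True, True, True, False]
    aerobic_freq = ["every alternate day", "2 times a week", "2 times a week",
                    "every alternate day", "2 times a week", "2 times a week",
                    "every alternate day", None]
    aerobic_int = [5, 6, 6, 6, 7, 7, 8, None]
    strength_yes = [True, True, False, True, True, False, True, True]
    strength_freq = ["daily", "every alternate day", None, "2 times a week",
                     "every alternate day", None, "2 times a week", "once a week"]
    strength_int = [6, 6, None, 7, 7, None, 7, 8]
    pre_extra = ["rarely", "rarely", "no", "no", "rarely", "no", "rarely", "no"]
    post_extra = ["several times a week", "once a week", "rarely", "several times a week",
                  "once a week", "rarely", "several times a week", "no"]
    out = []
    for i in range(8):
        out.append(
            QuestionnaireResponse(
                athlete_id=f"A{i + 1:02d}",
                answers={
                    "self_training": "yes",
                    "aerobic_training": "yes" if aerobic_yes[i] else "no",
                    "aerobic_frequency": aerobic_freq[i],
                    "aerobic_intensity": aerobic_int[i],
                    "strength_training": "yes" if strength_yes[i] else "no",
                    "strength_frequency": strength_freq[i],
                    "strength_intensity": strength_int[i],
                    "workout_duration": durations[i],
                    "pre_lockdown_extra": pre_extra[i],
                    "post_lockdown_extra": post_extra[i],
                },
            )
        )
    return out
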