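"""Week-by-week fatigue/recovery analysis.

Orchestrates the study workflow on an extracted parameter table:

1. weekly grouping — weeks with several sessions are averaged per athlete;
2. pre/post contrasts per week — exact Wilcoxon signed-rank + Cliff's delta;
3. temporal trend — Friedman across weeks with Bonferroni post hoc, run on
   raw weekly values for heart rate and covered distance and on pre/post
   normalized variations for the performance parameters;
4. subgroup descriptives for the two lockdown-training groups;
5. two-phase (downfall/recovery) characterization around the nadir week;
6. questionnaire descriptive statistics.

The tidy parameter table has columns (athlete_id, week_index,
session_index, parameter, phase, value) with phase in {"overall", "pre",
"post"}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .jumps import (
    BodyParams,
    BoscoResult,
    ValidityBounds,
    bosco_summary,
    detect_jump_events,
)
from .records import (
    ALL_PARAMETERS,
    PREPOST_PARAMETERS,
    QuestionnaireResponse,
    SESSION_PARAMETERS,
    SMALLER_IS_BETTER,
    StudyDataset,
    TRAINING_GROUPS,
)
from .sessions import mean_heart_rate, total_distance, wingate_powers
from .stats import (
    AnalysisConfig,
    TestResult,
    bonferroni_posthoc,
    cliffs_delta,
    cqv,
    friedman,
    ks_normality,
    median_iqr,
    wilcoxon_signed_rank,
)
__all__ = [
    "extract_parameter_table",
    "weekly_group",
    "prepost_analysis",
    "temporal_analysis",
    "subgroup_analysis",
    "detect_phases",
    "questionnaire_summary",
    "build_report",
    "WeeklyTable",
    "TemporalResult",
    "Report",
]

log = logging.getLogger("fatiguekit")

#: Parameters whose temporal trend is tested on raw weekly values; all other
#: parameters are analysed through their pre/post normalized variations.
RAW_TEMPORAL_PARAMETERS = ("hr_bpm", "distance_m")


# ---------------------------------------------------------------------------
# Extraction: raw sessions -> tidy parameter table
# ---------------------------------------------------------------------------

def extract_parameter_table(
    dataset: StudyDataset,
    validity: ValidityBounds = ValidityBounds(),
    flight_threshold_g: float = 0.3,
    min_flight_s: float = 0.08,
    peak_window_s: float = 1.0,
) -> pd.DataFrame:
    """Compute every session-level parameter from the raw series.

    Jump traces go through event detection and trial aggregation; heart
    rate, distance and Wingate powers through their session metrics.  A
    missing pre or post trial drops only that parameter for that session
    (logged), mirroring the absence of a missing-data rule in small
    monitored cohorts.
    """
    rows: list[dict] = []
    for s_idx, sess in enumerate(dataset.sessions, start=1):
        athlete = dataset.athlete(sess.athlete_id)
        body = BodyParams(mass_kg=athlete.mass_kg)
        key = dict(
            athlete_id=sess.athlete_id,
            week_index=sess.week_index,
            session_index=s_idx,
        )
        if sess.hr_series is not None:
            rows.append(dict(key, parameter="hr_bpm", phase="overall",
                             value=mean_heart_rate(sess.hr_series)))
        if sess.gnss is not None:
            rows.append(dict(key, parameter="distance_m", phase="overall",
                             value=total_distance(sess.gnss)))
        for phase, trial in (("pre", sess.wingate_pre), ("post", sess.wingate_post)):
            if trial is None:
                log.warning("session %s/%s: missing %s Wingate trial",
                            sess.athlete_id, sess.date, phase)
                continue
            mean_w, max_w = wingate_powers(trial, peak_window_s=peak_window_s)
            rows.append(dict(key, parameter="wingate_mean_w", phase=phase, value=mean_w))
            rows.append(dict(key, parameter="wingate_max_w", phase=phase, value=max_w))
        for phase, trial in (("pre", sess.bosco_pre), ("post", sess.bosco_post)):
            if trial is None:
                log.warning("session %s/%s: missing %s jump trial",
                            sess.athlete_id, sess.date, phase)
                continue
            if isinstance(trial, BoscoResult):
                res = trial
            else:
                events = detect_jump_events(
                    trial,
                    flight_threshold_g=flight_threshold_g,
                    min_flight_s=min_flight_s,
                )
                res = bosco_summary(events, body, validity)
            rows.append(dict(key, parameter="h_max_m", phase=phase, value=res.h_max_m))
            rows.append(dict(key, parameter="bosco_power_w", phase=phase,
                             value=res.mean_power_w))
            rows.append(dict(key, parameter="rsi_ms", phase=phase, value=res.rsi_ms))
            rows.append(dict(key, parameter="stiffness_nm", phase=phase,
                             value=res.stiffness_nm))
            rows.append(dict(key, parameter="tc_s", phase=phase, value=res.tc_s))
            rows.append(dict(key, parameter="tf_s", phase=phase, value=res.tf_s))
    if not rows:
        raise ValueError("dataset produced no parameter values")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weekly grouping
# ---------------------------------------------------------------------------

def weekly_group(table: pd.DataFrame, n_weeks: Optional[int] = None) -> pd.DataFrame:
    """Collapse sessions to one value per (athlete, week, parameter, phase).

    Weeks with several acquisitions are averaged; single-session weeks pass
    through unchanged.  Raises if any athlete misses a week entirely.
    """
    required = {"athlete_id", "week_index", "parameter", "phase", "value"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"parameter table lacks columns {sorted(missing_cols)}")
    weeks = sorted(table["week_index"].unique()) if n_weeks is None else list(
        range(1, n_weeks + 1)
    )
    gaps = []
    for aid in sorted(table["athlete_id"].unique()):
        have = set(table.loc[table["athlete_id"] == aid, "week_index"])
        gaps.extend((aid, w) for w in weeks if w not in have)
    if gaps:
        raise ValueError(f"missing (athlete, week) cells: {gaps}")
    out = (
        table.groupby(["athlete_id", "week_index", "parameter", "phase"], as_index=False)[
            "value"
        ].mean()
    )
    return out


def _pivot(weekly: pd.DataFrame, parameter: str, phase: str) -> pd.DataFrame:
    """athletes x weeks matrix of one parameter/phase."""
    sub = weekly[(weekly["parameter"] == parameter) & (weekly["phase"] == phase)]
    if sub.empty:
        raise ValueError(f"no values for parameter {parameter!r}, phase {phase!r}")
    return sub.pivot(index="athlete_id", columns="week_index", values="value").sort_index()


def _normalized_variation_matrix(weekly: pd.DataFrame, parameter: str) -> pd.DataFrame:
    pre = _pivot(weekly, parameter, "pre")
    post = _pivot(weekly, parameter, "post")
    if not pre.index.equals(post.index) or not pre.columns.equals(post.columns):
        raise ValueError(f"pre/post matrices misaligned for {parameter!r}")
    return 100.0 * (post - pre) / pre


def temporal_quantity(weekly: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Athletes x weeks matrix analysed for the temporal trend.

    Raw weekly values for heart rate and distance; pre/post normalized
    variation for the performance parameters.
    """
    if parameter in RAW_TEMPORAL_PARAMETERS:
        return _pivot(weekly, parameter, "overall")
    return _normalized_variation_matrix(weekly, parameter)


# ---------------------------------------------------------------------------
# Pre/post contrasts
# ---------------------------------------------------------------------------

@dataclass
class WeeklyTable:
    """Per-week pre/post contrast of one parameter."""

    parameter: str
    table: pd.DataFrame  # one row per week


def prepost_analysis(
    weekly: pd.DataFrame,
    parameter: str,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> WeeklyTable:
    """Week-by-week paired comparison of pre- vs post-effort values.

    For each week: exact Wilcoxon signed-rank across athletes, Cliff's
    delta of pre vs post (positive when fatigue lowers the values), and
    median/IQR of both phases.
    """
    if parameter not in PREPOST_PARAMETERS:
        raise ValueError(f"{parameter!r} has no pre/post contrast")
    pre = _pivot(weekly, parameter, "pre")
    post = _pivot(weekly, parameter, "post")
    rows = []
    for week in pre.columns:
        x, y = pre[week].to_numpy(), post[week].to_numpy()
        if np.array_equal(x, y):
            # no effect whatsoever this week: nothing to test
            res = TestResult("wilcoxon-signed-rank", 0.0, 1.0, (x.size,),
                             exact=True, notes="pre == post for every athlete")
        else:
            try:
                res = wilcoxon_signed_rank(x, y, cfg)
            except ValueError as err:
                raise ValueError(f"{parameter}, week {week}: {err}") from err
        es = cliffs_delta(x, y)
        pre_med, pre_iqr = median_iqr(x)
        post_med, post_iqr = median_iqr(y)
        rows.append(
            dict(
                week=int(week), n=x.size,
                pre_median=pre_med, pre_iqr=pre_iqr,
                post_median=post_med, post_iqr=post_iqr,
                statistic=res.statistic, p_value=res.p_value, exact=res.exact,
                cliffs_delta=es.delta, significant=res.p_value < cfg.alpha,
            )
        )
    return WeeklyTable(parameter=parameter, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Temporal trend
# ---------------------------------------------------------------------------

@dataclass
class TemporalResult:
    parameter: str
    quantity: str  # "raw" or "normalized_variation"
    matrix: pd.DataFrame  # athletes x weeks
    test: TestResult
    posthoc: list = field(default_factory=list)
    weekly_summary: pd.DataFrame = None  # per-week median/IQR (+ CQV for raw)


def temporal_analysis(
    weekly: pd.DataFrame,
    parameter: str,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> TemporalResult:
    """Friedman test of the weekly evolution, with Bonferroni post hoc.

    The inter-subject dispersion (CQV) is reported for the raw-value
    parameters only; normalized variations are already per-athlete
    relative measures.
    """
    mat = temporal_quantity(weekly, parameter)
    try:
        test = friedman(mat.to_numpy())
        posthoc = bonferroni_posthoc(mat.to_numpy(), cfg)
    except ValueError as err:
        raise ValueError(f"{parameter}: {err}") from err
    quantity = "raw" if parameter in RAW_TEMPORAL_PARAMETERS else "normalized_variation"
    rows = []
    for week in mat.columns:
        med, iqr = median_iqr(mat[week].to_numpy())
        row = dict(week=int(week), median=med, iqr=iqr)
        if quantity == "raw":
            row["cqv_pct"] = cqv(mat[week].to_numpy())
        rows.append(row)
    return TemporalResult(
        parameter=parameter,
        quantity=quantity,
        matrix=mat,
        test=test,
        posthoc=posthoc,
        weekly_summary=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Subgroups
# ---------------------------------------------------------------------------

def subgroup_analysis(
    weekly: pd.DataFrame,
    athletes: Sequence,
    parameter: str,
) -> pd.DataFrame:
    """Per-training-group weekly median/IQR of the temporal quantity.

    Descriptive only — no inferential contrast is attached to the
    subgroup split.
    """
    groups = {a.athlete_id: a.training_group for a in athletes}
    present = set(groups.values())
    if len(present) < 2:
        raise ValueError(f"both training groups required, found only {sorted(present)}")
    mat = temporal_quantity(weekly, parameter)
    rows = []
    for g in TRAINING_GROUPS:
        ids = [aid for aid in mat.index if groups.get(aid) == g]
        if not ids:
            raise ValueError(f"training group {g!r} is empty")
        sub = mat.loc[ids]
        for week in sub.columns:
            med, iqr = median_iqr(sub[week].to_numpy())
            rows.append(dict(group=g, week=int(week), n=len(ids), median=med, iqr=iqr))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phase detection
# ---------------------------------------------------------------------------

def detect_phases(
    weekly_medians: Sequence[float], larger_is_better: bool = True
) -> tuple[int, list[str]]:
    """Locate the nadir week and label the downfall/recovery phases.

    The nadir is the week of worst performance: the minimum for
    larger-is-better parameters, the maximum for inverted ones (heart
    rate, contact time).  Ties break toward the earlier week.  Weeks up to
    and including the nadir are labelled "downfall", later weeks
    "recovery".
    """
    m = np.asarray(weekly_medians, dtype=float)
    if m.size < 3:
        raise ValueError(f"need >= 3 weeks to separate phases, got {m.size}")
    nadir = int(np.argmin(m) if larger_is_better else np.argmax(m)) + 1
    labels = ["downfall" if w <= nadir else "recovery" for w in range(1, m.size + 1)]
    return nadir, labels


# ---------------------------------------------------------------------------
# Questionnaire descriptives
# ---------------------------------------------------------------------------

def questionnaire_summary(
    responses: Sequence[QuestionnaireResponse],
    items: Optional[dict] = None,
) -> pd.DataFrame:
    """Descriptive statistics of the questionnaire.

    Categorical items: count and percent of respondents per option (missing
    answers excluded from the denominator).  Numeric items: mean and sample
    standard deviation.
    """
    from .synthetic import QUESTIONNAIRE_ITEMS

    if items is None:
        items = QUESTIONNAIRE_ITEMS
    responses = list(responses)
    if not responses:
        raise ValueError("no questionnaire responses")
    rows = []
    for item, spec in items.items():
        kind = spec[0]
        answers = [r.answers.get(item) for r in responses]
        answered = [a for a in answers if a is not None]
        if kind == "categorical":
            options = spec[1]
            for a in answered:
                if a not in options:
                    raise ValueError(f"unknown option {a!r} for item {item!r}")
            n = len(answered)
            for opt in options:
                c = sum(a == opt for a in answered)
                rows.append(
                    dict(item=item, option=opt, count=c,
                         percent=100.0 * c / n if n else np.nan,
                         mean=np.nan, sd=np.nan)
                )
        else:
            vals = np.asarray(answered, dtype=float)
            rows.append(
                dict(item=item, option=None, count=vals.size, percent=np.nan,
                     mean=float(vals.mean()) if vals.size else np.nan,
                     sd=float(vals.std(ddof=1)) if vals.size > 1 else np.nan)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class Report:
    """All analysis tables of one study run, ready for serialization."""

    weekly_prepost: pd.DataFrame
    temporal_tests: pd.DataFrame
    posthoc_pairs: pd.DataFrame
    weekly_summaries: pd.DataFrame
    subgroup_tables: pd.DataFrame
    phases: pd.DataFrame
    normality_tests: pd.DataFrame
    questionnaire: pd.DataFrame


def _report_tables(
    table: pd.DataFrame,
    dataset: StudyDataset,
    cfg: AnalysisConfig,
    seed: int,
) -> Report:
    weekly = weekly_group(table, n_weeks=dataset.n_weeks)
    parameters = [p for p in ALL_PARAMETERS if (weekly["parameter"] == p).any()]

    prepost_rows, temporal_rows, posthoc_rows = [], [], []
    summary_rows, subgroup_rows, phase_rows, norm_rows = [], [], [], []
    for param in parameters:
        larger_better = param not in SMALLER_IS_BETTER
        if param in PREPOST_PARAMETERS:
            wt = prepost_analysis(weekly, param, cfg).table.assign(parameter=param)
            prepost_rows.append(wt)
        tr = temporal_analysis(weekly, param, cfg)
        temporal_rows.append(
            dict(parameter=param, quantity=tr.quantity, statistic=tr.test.statistic,
                 p_value=tr.test.p_value, significant=tr.test.p_value < cfg.alpha)
        )
        posthoc_rows.append(pd.DataFrame(tr.posthoc).assign(parameter=param))
        summary_rows.append(tr.weekly_summary.assign(parameter=param, quantity=tr.quantity))
        subgroup_rows.append(
            subgroup_analysis(weekly, dataset.athletes, param).assign(parameter=param)
        )
        nadir, labels = detect_phases(
            tr.weekly_summary["median"].to_numpy(), larger_is_better=larger_better
        )
        phase_rows.append(
            dict(parameter=param, quantity=tr.quantity, nadir_week=nadir,
                 phase_labels="|".join(labels))
        )
        pooled = tr.matrix.to_numpy().ravel()
        if np.std(pooled) > 0:
            ks = ks_normality(pooled, cfg, seed=seed)
            norm_rows.append(
                dict(parameter=param, quantity=tr.quantity, statistic=ks.statistic,
                     p_value=ks.p_value, normal_rejected=ks.p_value < cfg.alpha)
            )
    questionnaire = (
        questionnaire_summary(dataset.questionnaire)
        if dataset.questionnaire
        else pd.DataFrame()
    )
    return Report(
        weekly_prepost=pd.concat(prepost_rows, ignore_index=True),
        temporal_tests=pd.DataFrame(temporal_rows),
        posthoc_pairs=pd.concat(posthoc_rows, ignore_index=True),
        weekly_summaries=pd.concat(summary_rows, ignore_index=True),
        subgroup_tables=pd.concat(subgroup_rows, ignore_index=True),
        phases=pd.DataFrame(phase_rows),
        normality_tests=pd.DataFrame(norm_rows),
        questionnaire=questionnaire,
    )


def build_report(
    dataset: StudyDataset,
    out_dir=None,
    cfg: AnalysisConfig = AnalysisConfig(),
    seed: int = 0,
    table: Optional[pd.DataFrame] = None,
    use_ground_truth: bool = False,
    make_figures: bool = True,
    metadata: Optional[dict] = None,
) -> Report:
    """Run every analysis and (optionally) write the report directory.

    ``table`` may supply a pre-extracted parameter table; otherwise it is
    computed from the raw sessions, or taken from the generator's ground
    truth when ``use_ground_truth`` is set.  Output is deterministic for a
    given dataset, config and seed.
    """
    if not dataset.sessions:
        raise ValueError("empty dataset: nothing to report")
    if table is None:
        if use_ground_truth:
            if dataset.ground_truth is None:
                raise ValueError("dataset carries no ground truth")
            table = dataset.ground_truth
        else:
            table = extract_parameter_table(dataset)
    report = _report_tables(table, dataset, cfg, seed)
    if out_dir is not None:
        from .io import write_report  # avoids an import cycle at module load

        write_report(report, out_dir, cfg=cfg, seed=seed,
                     make_figures=make_figures, metadata=metadata)
    return report
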