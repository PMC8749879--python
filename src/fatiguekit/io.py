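"""File formats, run configuration and report serialization.

All trace files are plain CSV with a single comment-prefixed header line
declaring the kind and units, e.g.::

    # fatiguekit kind=accel columns=time_s,accel_g
    time_s,accel_g
    0.00,1.002
    ...

Timestamps are seconds from session start; the session date lives in the
study manifest.  A study directory is::

    study/
      manifest.csv          one row per session, pointing at the files
      questionnaire.csv     long form: athlete_id,item,answer
      sessions/*.csv        per-session traces
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .jumps import ValidityBounds
from .records import (
    AthleteProfile,
    QuestionnaireResponse,
    SessionRecord,
    StudyDataset,
)
from .sessions import GnssTrack, HeartRateSeries, WingateTrial
from .stats import AnalysisConfig
from .synthetic import AccelTrace, CohortConfig, SubgroupOffsets

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "write_study",
    "load_study",
    "write_report",
    "RunConfig",
    "DetectionConfig",
]

log = logging.getLogger("fatiguekit")

TRACE_COLUMNS = {
    "accel": ("time_s", "accel_g"),
    "hr": ("time_s", "bpm"),
    "gnss": ("time_s", "lat_deg", "lon_deg"),
    "power": ("time_s", "power_w"),
}


# ---------------------------------------------------------------------------
# Trace CSV round-trip
# ---------------------------------------------------------------------------

def _header_line(kind: str) -> str:
    return f"# fatiguekit kind={kind} columns={','.join(TRACE_COLUMNS[kind])}"


def write_trace_csv(path, kind: str, columns: dict) -> None:
    if kind not in TRACE_COLUMNS:
        raise ValueError(f"unknown trace kind {kind!r}")
    names = TRACE_COLUMNS[kind]
    arrays = [np.asarray(columns[n], dtype=float) for n in names]
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_line(kind) + "\n")
        fh.write(",".join(names) + "\n")
        for row in zip(*arrays):
            fh.write(",".join(format(v, ".12g") for v in row) + "\n")


def read_trace_csv(path, kind: str):
    """Read and validate a trace CSV, returning the typed series.

    accel -> AccelTrace (uniform sampling required), hr -> HeartRateSeries,
    gnss -> GnssTrack, power -> WingateTrial.
    """
    if kind not in TRACE_COLUMNS:
        raise ValueError(f"unknown trace kind {kind!r}")
    names = TRACE_COLUMNS[kind]
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: missing unit-declaring comment header")
    if f"kind={kind}" not in lines[0]:
        raise ValueError(f"{path}: header declares a different kind than {kind!r}")
    if len(lines) < 2 or tuple(lines[1].strip().split(",")) != names:
        raise ValueError(f"{path}: column header must be {','.join(names)}")
    data_lines = [ln for ln in lines[2:] if ln.strip()]
    if not data_lines:
        raise ValueError(f"{path}: no data rows")
    values = np.empty((len(data_lines), len(names)))
    for i, ln in enumerate(data_lines):
        parts = ln.split(",")
        if len(parts) != len(names):
            raise ValueError(f"{path}: malformed row at line {i + 3}: {ln!r}")
        try:
            values[i] = [float(p) for p in parts]
        except ValueError as err:
            raise ValueError(f"{path}: non-numeric value at line {i + 3}: {ln!r}") from err
    t = values[:, 0]
    if t.size >= 2 and not (np.diff(t) > 0).all():
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise ValueError(f"{path}: non-increasing timestamp at line {bad + 4}")

    if kind == "accel":
        if t.size < 2:
            raise ValueError(f"{path}: accel trace needs >= 2 samples")
        dt = np.diff(t)
        if np.ptp(dt) > 1e-6 * dt.mean():
            raise ValueError(f"{path}: accel trace must be uniformly sampled")
        return AccelTrace(fs_hz=1.0 / float(dt.mean()), t0=float(t[0]), samples=values[:, 1])
    if kind == "hr":
        period = float(np.mean(np.diff(t))) if t.size >= 2 else 5.0
        return HeartRateSeries(bpm=values[:, 1], sample_period_s=period)
    if kind == "gnss":
        return GnssTrack(time_s=t, lat_deg=values[:, 1], lon_deg=values[:, 2])
    dt = float(np.mean(np.diff(t)))
    return WingateTrial(
        power_w=values[:, 1], fs_hz=1.0 / dt, duration_s=float(t[-1] - t[0] + dt)
    )


# ---------------------------------------------------------------------------
# Study directory
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = (
    "athlete_id", "mass_kg", "height_cm", "age_y", "training_group",
    "session_date", "week_index", "hr_file", "gnss_file",
    "wingate_pre_file", "wingate_post_file", "bosco_pre_file", "bosco_post_file",
)


def write_study(dataset: StudyDataset, out_dir) -> Path:
    """Materialize a study directory (manifest + per-session trace CSVs)."""
    out = Path(out_dir)
    (out / "sessions").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sess in enumerate(dataset.sessions, start=1):
        athlete = dataset.athlete(sess.athlete_id)
        stem = f"{sess.athlete_id}_w{sess.week_index}_n{i:03d}"
        row = dict(
            athlete_id=athlete.athlete_id,
            mass_kg=athlete.mass_kg,
            height_cm=athlete.height_cm,
            age_y=athlete.age_y,
            training_group=athlete.training_group,
            session_date=sess.date,
            week_index=sess.week_index,
        )

        def save(kind: str, suffix: str, columns: Optional[dict]) -> str:
            if columns is None:
                return ""
            rel = f"sessions/{stem}_{suffix}.csv"
            write_trace_csv(out / rel, kind, columns)
            return rel

        hr = sess.hr_series
        row["hr_file"] = save(
            "hr", "hr",
            None if hr is None else dict(
                time_s=np.arange(hr.bpm.size) * hr.sample_period_s, bpm=hr.bpm
            ),
        )
        g = sess.gnss
        row["gnss_file"] = save(
            "gnss", "gnss",
            None if g is None else dict(time_s=g.time_s, lat_deg=g.lat_deg, lon_deg=g.lon_deg),
        )
        for tag, trial in (("wingate_pre", sess.wingate_pre), ("wingate_post", sess.wingate_post)):
            row[f"{tag}_file"] = save(
                "power", tag,
                None if trial is None else dict(
                    time_s=(np.arange(trial.power_w.size) + 0.5) / trial.fs_hz,
                    power_w=trial.power_w,
                ),
            )
        for tag, trace in (("bosco_pre", sess.bosco_pre), ("bosco_post", sess.bosco_post)):
            row[f"{tag}_file"] = save(
                "accel", tag,
                None if trace is None else dict(time_s=trace.time_s, accel_g=trace.samples),
            )
        rows.append(row)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(out / "manifest.csv", index=False)
    if dataset.questionnaire:
        qrows = [
            dict(athlete_id=r.athlete_id, item=k, answer="" if v is None else v)
            for r in dataset.questionnaire
            for k, v in r.answers.items()
        ]
        pd.DataFrame(qrows).to_csv(out / "questionnaire.csv", index=False)
    return out


def load_study(study_dir) -> StudyDataset:
    """Load a study directory written by :func:`write_study`."""
    study = Path(study_dir)
    manifest_path = study / "manifest.csv"
    if not manifest_path.exists():
        raise ValueError(f"no manifest.csv in {study}")
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    athletes: dict[str, AthleteProfile] = {}
    sessions: list[SessionRecord] = []
    for _, row in manifest.iterrows():
        aid = str(row["athlete_id"])
        if aid not in athletes:
            athletes[aid] = AthleteProfile(
                athlete_id=aid,
                mass_kg=float(row["mass_kg"]),
                height_cm=float(row["height_cm"]),
                age_y=float(row["age_y"]),
                training_group=str(row["training_group"]),
            )

        def read(col: str, kind: str):
            rel = str(row[col])
            if not rel:
                return None
            path = study / rel
            if not path.exists():
                raise ValueError(f"manifest references missing file {rel}")
            return read_trace_csv(path, kind)

        week = int(row["week_index"])
        if week < 1:
            raise ValueError(f"manifest week_index must be positive, got {week}")
        sessions.append(
            SessionRecord(
                athlete_id=aid,
                date=str(row["session_date"]),
                week_index=week,
                hr_series=read("hr_file", "hr"),
                gnss=read("gnss_file", "gnss"),
                wingate_pre=read("wingate_pre_file", "power"),
                wingate_post=read("wingate_post_file", "power"),
                bosco_pre=read("bosco_pre_file", "accel"),
                bosco_post=read("bosco_post_file", "accel"),
            )
        )
    questionnaire: list[QuestionnaireResponse] = []
    qpath = study / "questionnaire.csv"
    if qpath.exists():
        qdf = pd.read_csv(qpath, keep_default_na=False)
        for aid, grp in qdf.groupby("athlete_id", sort=True):
            answers = {}
            for _, r in grp.iterrows():
                val = r["answer"]
                if val == "":
                    answers[r["item"]] = None
                else:
                    try:
                        answers[r["item"]] = float(val)
                    except (TypeError, ValueError):
                        answers[r["item"]] = val
            questionnaire.append(QuestionnaireResponse(athlete_id=str(aid), answers=answers))
    n_weeks = int(manifest["week_index"].max())
    return StudyDataset(
        athletes=list(athletes.values()),
        sessions=sessions,
        questionnaire=questionnaire,
        n_weeks=n_weeks,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DetectionConfig:
    """Jump event detection and Wingate extraction tunables."""

    flight_threshold_g: float = 0.3
    min_flight_s: float = 0.08
    min_contact_s: float = 0.05
    peak_window_s: float = 1.0
    validity: ValidityBounds = dataclasses.field(default_factory=ValidityBounds)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Every tunable of a pipeline run, loadable from YAML.

    Unknown keys in a config file are rejected rather than ignored, so
    typos cannot silently fall back to defaults.
    """

    seed: int = 0
    out_dir: str = "report"
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)
    detection: DetectionConfig = dataclasses.field(default_factory=DetectionConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw, source=str(path))

    @classmethod
    def from_dict(cls, raw: dict, source: str = "<dict>") -> "RunConfig":
        def build(dc_type, data: dict, ctx: str):
            fields = {f.name: f for f in dataclasses.fields(dc_type)}
            unknown = set(data) - set(fields)
            if unknown:
                raise ValueError(f"{source}: unknown keys in {ctx}: {sorted(unknown)}")
            kwargs = {}
            for name, value in data.items():
                ftype = fields[name].type
                if isinstance(value, dict) and name in ("cohort", "analysis",
                                                        "detection", "validity",
                                                        "subgroup_offsets"):
                    nested = {
                        "cohort": CohortConfig,
                        "analysis": AnalysisConfig,
                        "detection": DetectionConfig,
                        "validity": ValidityBounds,
                        "subgroup_offsets": SubgroupOffsets,
                    }[name]
                    kwargs[name] = build(nested, value, f"{ctx}.{name}")
                elif isinstance(value, list):
                    kwargs[name] = tuple(value)
                else:
                    kwargs[name] = value
            return dc_type(**kwargs)

        return build(cls, raw, "run config")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

def write_report(
    report,
    out_dir,
    cfg: Optional[AnalysisConfig] = None,
    seed: int = 0,
    make_figures: bool = True,
    metadata: Optional[dict] = None,
) -> Path:
    """Write the report bundle: tidy CSV tables, figures, run metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "weekly_prepost.csv": report.weekly_prepost,
        "temporal_tests.csv": report.temporal_tests,
        "posthoc_pairs.csv": report.posthoc_pairs,
        "weekly_summaries.csv": report.weekly_summaries,
        "subgroup_tables.csv": report.subgroup_tables,
        "phases.csv": report.phases,
        "normality_tests.csv": report.normality_tests,
        "questionnaire_summary.csv": report.questionnaire,
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False, float_format="%.10g")
    meta = dict(metadata or {})
    meta.update(seed=seed, alpha=None if cfg is None else cfg.alpha)
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    if make_figures:
        _write_figures(report, out)
    log.info("report written to %s (seed=%s)", out, seed)
    return out


def _write_figures(report, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    for param, grp in report.weekly_summaries.groupby("parameter", sort=True):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        weeks = grp["week"].to_numpy()
        med = grp["median"].to_numpy()
        iqr = grp["iqr"].to_numpy()
        ax.errorbar(weeks, med, yerr=iqr / 2, fmt="o-", capsize=3)
        ax.set_xlabel("week")
        quantity = grp["quantity"].iloc[0]
        ax.set_ylabel("normalized variation (%)" if quantity != "raw" else param)
        ax.set_title(param)
        ax.set_xticks(weeks)
        fig.tight_layout()
        fig.savefig(fig_dir / f"{param}.png", dpi=110)
        plt.close(fig)
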