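"""End-to-end orchestration: calibrate, filter, frames, angles, events,
measures, and cohort statistics.

``run_subject`` consumes one subject's trial bundle (in-memory Trials or
file paths) and produces per-condition values for every reported
variable; ``run_cohort`` aggregates subjects into the study-table
summary, the named condition deltas, repeated-measures ANOVAs, the
stepwise regression of foot abduction on the pronation variables, and the
correlations between hindfoot eversion and the seated external-rotation
measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events as ev
from . import footmodel, jointkin, measures, signalproc, stats
from .markerio import DEFAULT_SCHEMA, MarkerSchema, Trial, read_trial

__all__ = ["SubjectResult", "CohortReport", "PipelineError", "run_subject", "run_cohort"]

log = logging.getLogger("footkin")

#: map trial labels to summary condition names
_CONDITION_OF_LABEL = {
    "natural": "natural",
    "functional_turnout": "functional",
    "forced_turnout": "forced",
    "saute": "saute",
}

_ANGLE_VARIABLES = (
    "hindfoot_eversion",
    "midfoot_abduction",
    "forefoot_abduction",
    "foot_abduction",
    "mtpj_abduction",
    "knee_external_rotation",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and trial."""


@dataclass
class SubjectResult:
    """Per-subject outputs of the kinematic pipeline."""

    subject: str
    values: dict[str, dict[str, float]]  # variable -> condition -> value
    events: ev.EventSet | None = None
    classifications: dict[str, dict[str, str]] = field(default_factory=dict)
    calibration: footmodel.Calibration | None = None

    def tidy(self) -> pd.DataFrame:
        rows = [
            {"subject": self.subject, "condition": c, "variable": v, "value": x}
            for v, conds in self.values.items()
            for c, x in conds.items()
        ]
        return pd.DataFrame(rows)

    def events_table(self, rate: float = 250.0) -> pd.DataFrame:
        """Long-format event export: one row per detected jump cycle."""
        if self.events is None:
            return pd.DataFrame()
        ev = self.events
        return pd.DataFrame(
            {
                "subject": self.subject,
                "cycle": np.arange(len(ev.minima_frames)),
                "frame": ev.minima_frames,
                "time_s": ev.minima_frames / rate,
                "excursion_mm": ev.excursions,
                "selected": [k in ev.selected for k in range(len(ev.minima_frames))],
            }
        )


def angle_series(
    trial: Trial, schema: MarkerSchema, cal: footmodel.Calibration
) -> dict[str, np.ndarray]:
    """All reported angle streams plus the navicular and pelvis heights
    for one (already filtered) trial."""
    frames, virtuals = footmodel.build_frames(trial, schema, cal)
    side = cal.side
    out: dict[str, np.ndarray] = {}

    def rel(parent: str, child: str, component: int, signed: bool) -> np.ndarray | None:
        if parent not in frames.rotations or child not in frames.rotations:
            return None
        ang = jointkin.jcs_angles_series(frames.rotations[parent], frames.rotations[child])
        v = ang[:, component]
        return v * jointkin.side_sign(side) if signed else v

    pairs = {
        "hindfoot_eversion": ("tibia", "hindfoot", 1),
        "midfoot_abduction": ("hindfoot", "midfoot", 2),
        "forefoot_abduction": ("midfoot", "forefoot", 2),
        "foot_abduction": ("tibia", "foot", 2),
        "knee_external_rotation": ("thigh", "shank", 2),
    }
    for name, (p, c, comp) in pairs.items():
        v = rel(p, c, comp, signed=True)
        if v is not None:
            out[name] = v
    if (
        "MT1" in virtuals
        and "X_MET" in virtuals
        and trial.has("HAL")
        and "first_metatarsal" in frames.rotations
    ):
        out["mtpj_abduction"] = np.atleast_1d(
            jointkin.mtpj_transverse_angle(
                virtuals["MT1"],
                virtuals["X_MET"],
                trial.get("HAL"),
                frames.rotations["first_metatarsal"],
                side=side,
            )
        )
    if trial.has("NAV"):
        out["navicular_height"] = trial.get("NAV")[:, trial.up_index]
    if "pelvis" in frames.origins:
        out["pelvis_height"] = frames.origins["pelvis"][:, trial.up_index]
    return out


def angles_to_tidy(trial_label: str, series: dict[str, np.ndarray]) -> pd.DataFrame:
    """Long-format angle export (trial, variable, frame, value)."""
    rows = []
    for name, values in series.items():
        v = np.atleast_1d(np.asarray(values))
        rows.append(
            pd.DataFrame(
                {
                    "trial": trial_label,
                    "variable": name,
                    "frame": np.arange(len(v)),
                    "value": v,
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def _as_trials(obj, label: str) -> list[Trial]:
    items = obj if isinstance(obj, (list, tuple)) else [obj]
    out = []
    for it in items:
        t = it if isinstance(it, Trial) else read_trial(it)
        if t.label != label:
            log.warning("trial labelled %r used as %r", t.label, label)
        out.append(t)
    return out


def run_subject(
    trials: dict[str, object],
    schema: MarkerSchema = DEFAULT_SCHEMA,
    subject: str = "S1",
    cutoff_hz: float = signalproc.DEFAULT_CUTOFF_HZ,
    filter_order: int = 4,
    tempo_bpm: float = 95.0,
) -> SubjectResult:
    """Process one subject's trial bundle.

    ``trials`` maps trial labels to a Trial, a path, or a list of either
    (repeated statics).  Required: ``natural``; optional: the remaining
    protocol trials.  Saute marker data are low-pass filtered at
    ``cutoff_hz`` before pose estimation; static trials are averaged
    unfiltered.
    """
    if "natural" not in trials:
        raise PipelineError("calibration requires a 'natural' stance trial")

    stage = "stance calibration"
    try:
        natural = _as_trials(trials["natural"], "natural")
        cal = footmodel.calibrate_stance(natural[0], schema)
        if "lunge" in trials:
            stage = "knee calibration (lunge)"
            cal = footmodel.calibrate_knee(_as_trials(trials["lunge"], "lunge")[0], cal)
        if "squat_circumduction" in trials:
            stage = "functional calibration (squat_circumduction)"
            cal = footmodel.calibrate_functional(
                _as_trials(trials["squat_circumduction"], "squat_circumduction")[0], cal
            )
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc
    log.info("subject %s calibrated (side=%s)", subject, cal.side)

    values: dict[str, dict[str, float]] = {}

    def put(variable: str, condition: str, value: float) -> None:
        values.setdefault(variable, {})[condition] = float(value)

    nav_heights: dict[str, float] = {}
    # static conditions: mean across frames, then across repeated trials
    for label, condition in _CONDITION_OF_LABEL.items():
        if label == "saute" or label not in trials:
            continue
        try:
            per_trial: dict[str, list[float]] = {}
            for t in _as_trials(trials[label], label):
                series = angle_series(t, schema, cal)
                for k, v in series.items():
                    per_trial.setdefault(k, []).append(float(np.mean(v)))
            for k, reps in per_trial.items():
                if k == "pelvis_height":
                    continue
                if k == "navicular_height":
                    nav_heights[condition] = float(np.mean(reps))
                else:
                    put(k, condition, float(np.mean(reps)))
        except Exception as exc:
            raise PipelineError(f"static condition {label}: {exc}") from exc

    # seated external-rotation trials (single static value each)
    for label in ("seated_passive_er", "seated_active_er"):
        if label not in trials:
            continue
        try:
            t = _as_trials(trials[label], label)[0]
            series = angle_series(t, schema, cal)
            if "knee_external_rotation" in series:
                put("knee_external_rotation", label, np.mean(series["knee_external_rotation"]))
        except Exception as exc:
            raise PipelineError(f"seated trial {label}: {exc}") from exc

    event_set = None
    if "saute" in trials:
        try:
            t = _as_trials(trials["saute"], "saute")[0]
            filtered = Trial(
                label=t.label,
                rate=t.rate,
                markers=list(t.markers),
                data=signalproc.lowpass_zero_lag(t.data, t.rate, cutoff_hz, filter_order),
                lab_up_axis=t.lab_up_axis,
                gaps=t.gaps,
                side=t.side,
            )
            series = angle_series(filtered, schema, cal)
            if "pelvis_height" not in series:
                raise PipelineError("saute trial lacks the pelvis cluster")
            minima = ev.detect_minima(
                series["pelvis_height"], t.rate, ev.default_min_cycle_s(tempo_bpm)
            )
            exc_mm = ev.cycle_excursions(series["pelvis_height"], minima)
            triplet = ev.select_consistent_triplet(minima, exc_mm)
            event_set = ev.EventSet(minima_frames=minima, excursions=exc_mm, selected=triplet)
            at_plie = ev.extract_at_events(
                {k: v for k, v in series.items() if k != "pelvis_height"}, event_set
            )
            for k, v in at_plie.items():
                if k == "navicular_height":
                    nav_heights["saute"] = v
                else:
                    put(k, "saute", v)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"saute processing: {exc}") from exc

    # navicular drop relative to the natural posture
    if "natural" in nav_heights:
        for condition, h in nav_heights.items():
            if condition == "natural":
                continue
            put(
                "navicular_drop_mm",
                condition,
                measures.navicular_drop(h, nav_heights["natural"]),
            )

    classifications: dict[str, dict[str, str]] = {}
    for cond, drop in values.get("navicular_drop_mm", {}).items():
        classifications.setdefault("arch_stability", {})[cond] = measures.classify_navicular(drop)
    for cond, ang in values.get("mtpj_abduction", {}).items():
        classifications.setdefault("hallux_valgus", {})[cond] = measures.classify_hallux_valgus(
            ang
        )

    return SubjectResult(
        subject=subject,
        values=values,
        events=event_set,
        classifications=classifications,
        calibration=cal,
    )


@dataclass
class CohortReport:
    """Study-level report: summary table, deltas, and inferential stats."""

    summary: measures.ConditionSummary | None
    deltas: pd.DataFrame
    anova: dict[str, stats.RmAnovaResult]
    regression: dict[str, stats.StepwiseResult]
    correlations: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def run_cohort(
    results: list[SubjectResult],
    anova_conditions: tuple[str, ...] = ("natural", "functional", "forced", "saute"),
) -> CohortReport:
    """Aggregate per-subject results into the study-style report.

    Subjects missing a variable/condition cell are excluded from that
    variable's analyses (with a note).  Requires >= 2 complete subjects
    per analysed variable.
    """
    notes: list[str] = []
    tidy = pd.concat([r.tidy() for r in results], ignore_index=True)
    if tidy["subject"].nunique() < 2:
        notes.append("single subject: cohort statistics skipped")
        return CohortReport(
            summary=None,
            deltas=pd.DataFrame(),
            anova={},
            regression={},
            correlations=pd.DataFrame(),
            notes=notes,
        )
    summary = measures.summarise_conditions(_complete_cells(tidy, notes))
    deltas = measures.table2_deltas(summary)

    anova: dict[str, stats.RmAnovaResult] = {}
    for var in tidy["variable"].unique():
        if var in ("navicular_height", "pelvis_height"):
            continue
        conds = [
            c
            for c in anova_conditions
            if ((tidy["variable"] == var) & (tidy["condition"] == c)).any()
        ]
        if len(conds) < 2:
            continue
        wide = (
            tidy[(tidy["variable"] == var) & tidy["condition"].isin(conds)]
            .pivot(index="subject", columns="condition", values="value")
            .reindex(columns=conds)
            .dropna()
        )
        if len(wide) >= 2:
            anova[var] = stats.rm_anova_gg(wide.to_numpy())

    regression: dict[str, stats.StepwiseResult] = {}
    predictors = [
        "hindfoot_eversion",
        "midfoot_abduction",
        "forefoot_abduction",
        "navicular_drop_mm",
    ]
    for cond in ("functional", "forced", "saute"):
        sub = tidy[tidy["condition"] == cond].pivot(
            index="subject", columns="variable", values="value"
        )
        have = [p for p in predictors if p in sub.columns]
        if "foot_abduction" not in sub.columns or not have:
            continue
        sub = sub.dropna(subset=["foot_abduction"] + have)
        if len(sub) > len(have) + 1:
            regression[cond] = stats.stepwise_regression(
                sub["foot_abduction"].to_numpy(), sub[have].to_numpy(), names=have
            )

    corr_rows = []
    er = tidy[tidy["variable"] == "knee_external_rotation"].pivot(
        index="subject", columns="condition", values="value"
    )
    ev_wide = tidy[tidy["variable"] == "hindfoot_eversion"].pivot(
        index="subject", columns="condition", values="value"
    )
    for er_cond in ("seated_passive_er", "seated_active_er"):
        if er_cond not in er.columns:
            continue
        for cond in ("functional", "forced", "saute"):
            if cond not in ev_wide.columns:
                continue
            pair = pd.concat([er[er_cond], ev_wide[cond]], axis=1).dropna()
            if len(pair) >= 3:
                r, p = stats.pearson_r(
                    pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
                )
                corr_rows.append(
                    {
                        "er_measure": er_cond,
                        "condition": cond,
                        "r": r,
                        "p": p,
                        "n": len(pair),
                    }
                )
    correlations = pd.DataFrame(corr_rows)
    return CohortReport(
        summary=summary,
        deltas=deltas,
        anova=anova,
        regression=regression,
        correlations=correlations,
        notes=notes,
    )


def _complete_cells(tidy: pd.DataFrame, notes: list[str]) -> pd.DataFrame:
    """Drop (variable, condition) cells not measured for every subject so
    the summary stays balanced; record what was dropped."""
    n_subj = tidy["subject"].nunique()
    keep = []
    for (var, cond), grp in tidy.groupby(["variable", "condition"], sort=False):
        if grp["subject"].nunique() == n_subj:
            keep.append((var, cond))
        else:
            notes.append(f"dropped incomplete cell {var}/{cond}")
    mask = tidy.set_index(["variable", "condition"]).index.isin(keep)
    return tidy[mask]
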