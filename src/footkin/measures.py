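"""Study-level measures: navicular drop, clinical classifications, and
condition summaries.

Navicular drop is the decrease in vertical height of the navicular
tuberosity marker relative to the natural double-leg upright posture;
negative values mean the navicular rose.  Drops are graded into arch
height stability classes (excellent / stable / unstable), and the
first-MTPJ transverse angle into hallux-valgus severity classes
(normal / mild / moderate / severe).  Group summaries report
mean, standard error and 95% confidence interval per variable and
condition, plus the named between-condition mean differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConditionSummary",
    "navicular_drop",
    "classify_navicular",
    "classify_hallux_valgus",
    "summarise_conditions",
    "table2_deltas",
    "CONDITION_ORDER",
    "VARIABLES",
]

CONDITION_ORDER = ("natural", "functional", "forced", "saute")

VARIABLES = (
    "hindfoot_eversion",
    "midfoot_abduction",
    "forefoot_abduction",
    "navicular_drop_mm",
    "mtpj_abduction",
    "foot_abduction",
    "knee_external_rotation",
)

#: CI multiplier (normal-approximation 95% interval).
CI_Z = 1.96


def navicular_drop(nav_height_condition: float, nav_height_natural: float) -> float:
    """Navicular drop in mm: natural-posture height minus condition height.
    Negative = the navicular tuberosity rose."""
    return float(nav_height_natural - nav_height_condition)


def classify_navicular(drop_mm: float) -> str:
    """Arch height stability class from navicular drop (mm):
    < 7 excellent stabilisation; 7 to 13 inclusive stable; > 13 unstable."""
    if not np.isfinite(drop_mm):
        raise ValueError("navicular drop must be finite")
    if drop_mm < 7.0:
        return "excellent"
    if drop_mm <= 13.0:
        return "stable"
    return "unstable"


def classify_hallux_valgus(angle_deg: float) -> str:
    """Hallux-valgus severity from the first-MTPJ transverse angle:
    < 15 normal; 15-20 mild; 21-39 moderate; >= 40 severe.  The published
    scheme leaves (20, 21) unassigned; such values are graded mild."""
    if not np.isfinite(angle_deg):
        raise ValueError("MTPJ angle must be finite")
    if angle_deg < 15.0:
        return "normal"
    if angle_deg < 21.0:
        return "mild"
    if angle_deg < 40.0:
        return "moderate"
    return "severe"


@dataclass
class ConditionSummary:
    """Per-variable, per-condition group summary (the study-table layout).

    ``table`` has a (variable, condition) MultiIndex and columns
    mean / se / ci_lo / ci_hi / n.
    """

    table: pd.DataFrame

    def mean(self, variable: str, condition: str) -> float:
        return float(self.table.loc[(variable, condition), "mean"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def summarise_conditions(per_subject: pd.DataFrame) -> ConditionSummary:
    """Summarise a tidy table of per-subject values.

    Parameters
    ----------
    per_subject : DataFrame
        Columns ``subject``, ``condition``, ``variable``, ``value``; one
        row per subject x condition x variable (values already averaged
        over repeated trials / the three demi-plies upstream).

    Raises
    ------
    ValueError
        If any present (variable, condition) cell is missing a subject,
        or fewer than 2 subjects are supplied.
    """
    req = {"subject", "condition", "variable", "value"}
    if not req.issubset(per_subject.columns):
        raise ValueError(f"tidy table must have columns {sorted(req)}")
    n_subj = per_subject["subject"].nunique()
    if n_subj < 2:
        raise ValueError("need >= 2 subjects")
    rows = []
    for (var, cond), grp in per_subject.groupby(["variable", "condition"], sort=False):
        if grp["subject"].nunique() != n_subj or grp["subject"].duplicated().any():
            raise ValueError(f"incomplete or duplicated cell: {var} / {cond}")
        vals = grp["value"].to_numpy(dtype=float)
        mean = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        rows.append(
            {
                "variable": var,
                "condition": cond,
                "mean": mean,
                "se": se,
                "ci_lo": mean - CI_Z * se,
                "ci_hi": mean + CI_Z * se,
                "n": len(vals),
            }
        )
    table = pd.DataFrame(rows).set_index(["variable", "condition"])
    return ConditionSummary(table=table)


_DELTAS = (
    ("functional_minus_natural", "functional", "natural"),
    ("forced_minus_natural", "forced", "natural"),
    ("forced_minus_functional", "forced", "functional"),
    ("saute_minus_functional", "saute", "functional"),
)


def table2_deltas(
    summary: ConditionSummary | dict[str, dict[str, float]]
) -> pd.DataFrame:
    """Named pairwise differences of condition means per variable.

    Accepts a :class:`ConditionSummary` or a plain
    ``{variable: {condition: mean}}`` mapping.  Differences are reported
    raw and rounded to the study's printed precision (1 decimal for
    degrees, nearest integer for millimetre variables).  Conditions absent
    for a variable yield no row (e.g. navicular drop has no natural-stance
    cell: it is zero there by definition).
    """
    if isinstance(summary, ConditionSummary):
        means: dict[str, dict[str, float]] = {}
        for (var, cond), row in summary.table.iterrows():
            means.setdefault(var, {})[cond] = float(row["mean"])
    else:
        means = {v: dict(c) for v, c in summary.items()}
    rows = []
    for var, conds in means.items():
        digits = 0 if var.endswith("_mm") else 1
        for name, a, b in _DELTAS:
            if a in conds and b in conds:
                d = conds[a] - conds[b]
                rows.append(
                    {
                        "variable": var,
                        "contrast": name,
                        "delta": d,
                        "delta_rounded": round(d, digits) if digits else float(round(d)),
                    }
                )
    return pd.DataFrame(rows)
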