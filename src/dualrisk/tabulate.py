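"""Baseline characterisation of outcome groups.

Group summaries, absolute standardized differences (ASD, the Austin
pooled-variance definitions), the >10% imbalance flag, and outcome
prevalence/corroboration summaries — the machinery behind a clinical
"Table 1".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "BaselineRow",
    "asd_binary",
    "asd_continuous",
    "baseline_table",
    "baseline_frame",
    "outcome_summary",
    "write_baseline_table",
]

IMBALANCE_THRESHOLD = 10.0  # percent


@dataclass(frozen=True)
class BaselineRow:
    variable: str
    group0_summary: tuple[float, float]  # (count, proportion) or (mean, sd)
    group1_summary: tuple[float, float]
    asd_percent: float
    imbalanced: bool
    kind: str = "binary"


def asd_binary(count1: int, n1: int, count2: int, n2: int) -> float:
    """ASD (in percent) between two binary proportions.

    100*|p1-p2| / sqrt((p1(1-p1)+p2(1-p2))/2).  Zero when both groups
    have the same degenerate proportion; symmetric in group order.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= count1 <= n1 and 0 <= count2 <= n2):
        raise ValueError("counts must lie in [0, n]")
    p1, p2 = count1 / n1, count2 / n2
    pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2
    if pooled == 0:
        if p1 == p2:
            return 0.0  # both groups degenerate at the same value
        raise ValueError("ASD undefined: zero pooled variance with unequal proportions")
    return 100.0 * abs(p1 - p2) / np.sqrt(pooled)


def asd_continuous(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """ASD (in percent) between two means: 100*|m1-m2|/sqrt((sd1^2+sd2^2)/2)."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = (sd1**2 + sd2**2) / 2
    if pooled == 0:
        if mean1 == mean2:
            return 0.0
        raise ValueError("ASD undefined: zero variance with unequal means")
    return 100.0 * abs(mean1 - mean2) / np.sqrt(pooled)


def baseline_table(cohort: Cohort, group_by: str = "y") -> list[BaselineRow]:
    """One row per binary/continuous feature and per categorical level.

    Group 0/1 are defined by the ``group_by`` label.  Continuous rows
    carry (mean, SD); binary and categorical-level rows carry
    (count, proportion).  ``imbalanced`` flags ASD > 10%.
    """
    g = cohort.labels(group_by)
    if g.min() == g.max():
        raise ValueError("both outcome groups must be non-empty")
    rows: list[BaselineRow] = []
    mask1 = g == 1
    n0, n1 = int((~mask1).sum()), int(mask1.sum())
    for spec in cohort.feature_specs:
        col = cohort.features[spec.name]
        if spec.kind == "continuous":
            x0, x1 = col[~mask1], col[mask1]
            asd = asd_continuous(x0.mean(), x0.std(ddof=1), x1.mean(), x1.std(ddof=1))
            rows.append(
                BaselineRow(
                    spec.name,
                    (float(x0.mean()), float(x0.std(ddof=1))),
                    (float(x1.mean()), float(x1.std(ddof=1))),
                    asd,
                    asd > IMBALANCE_THRESHOLD,
                    kind="continuous",
                )
            )
        elif spec.kind == "binary":
            c0 = int(col[~mask1].sum())
            c1 = int(col[mask1].sum())
            asd = asd_binary(c0, n0, c1, n1)
            rows.append(
                BaselineRow(
                    spec.name,
                    (c0, c0 / n0),
                    (c1, c1 / n1),
                    asd,
                    asd > IMBALANCE_THRESHOLD,
                )
            )
        else:
            for level in spec.categories:
                c0 = int((col[~mask1] == level).sum())
                c1 = int((col[mask1] == level).sum())
                asd = asd_binary(c0, n0, c1, n1)
                rows.append(
                    BaselineRow(
                        f"{spec.name}={level}",
                        (c0, c0 / n0),
                        (c1, c1 / n1),
                        asd,
                        asd > IMBALANCE_THRESHOLD,
                        kind="categorical-level",
                    )
                )
    return rows


def baseline_frame(rows: list[BaselineRow]) -> pd.DataFrame:
    rec = []
    for r in rows:
        if r.kind == "continuous":
            s0 = f"{r.group0_summary[0]:.1f} ± {r.group0_summary[1]:.1f}"
            s1 = f"{r.group1_summary[0]:.1f} ± {r.group1_summary[1]:.1f}"
        else:
            s0 = f"{int(r.group0_summary[0])} ({100 * r.group0_summary[1]:.0f}%)"
            s1 = f"{int(r.group1_summary[0])} ({100 * r.group1_summary[1]:.0f}%)"
        rec.append(
            {
                "variable": r.variable,
                "group0": s0,
                "group1": s1,
                "asd_percent": round(r.asd_percent),
                "imbalanced": r.imbalanced,
            }
        )
    return pd.DataFrame(rec)


def write_baseline_table(rows: list[BaselineRow], path: str | Path) -> None:
    """Emit CSV plus an aligned plain-text rendering next to it."""
    path = Path(path)
    frame = baseline_frame(rows)
    frame.to_csv(path, index=False)
    txt = frame.to_string(index=False)
    Path(path.with_suffix(".txt")).write_text(txt + "\n")


def outcome_summary(cohort: Cohort) -> dict:
    """Counts and one-decimal percentages for each outcome label.

    Includes the corroboration rate — the fraction of coded cases that
    are also documented; reported as None when there are no coded cases.
    """
    n = cohort.n
    out: dict = {"n": n}
    for name in ("y", "y_documented", "y_coded"):
        c = int(cohort.labels(name).sum())
        out[name] = {"count": c, "percent": round(100.0 * c / n, 1)}
    coded = cohort.y_coded == 1
    if coded.sum() == 0:
        out["corroboration_percent"] = None
    else:
        out["corroboration_percent"] = round(
            100.0 * float(cohort.y_documented[coded].mean()), 1
        )
    return out
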