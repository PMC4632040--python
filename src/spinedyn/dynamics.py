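"""Formation, elimination and turnover rates of dendritic protrusions.

The formation (elimination) rate is the percentage of protrusions that
appeared (disappeared) between two successive frames, relative to the
total protrusion number; turnover is formed plus eliminated divided by
twice the total, so turnover is identically the mean of the two rates
under a shared denominator.  The denominator is, by default, the frame-1
count of the relevant class ("initial" convention); the "union"
convention (distinct protrusions seen in either frame) is available for
sensitivity analyses.  The unit of analysis is the dendrite: condition
summaries are means ± SEM over dendrites.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import pandas as pd

from .types import DendriteFrame, DynamicsSummary, ProtrusionClass
from .morphometry import classify_frame
from .tracking import track_frame_pair

logger = logging.getLogger(__name__)

CLASS_SCOPES = ("spine", "filopodium", "all")


class UndefinedRateError(ZeroDivisionError):
    """A rate is undefined because its denominator is zero."""


def formation_rate(n_formed: int, n_total: int) -> float:
    """Percentage of protrusions that appeared, relative to ``n_total``."""
    if n_total <= 0:
        raise UndefinedRateError("formation rate undefined for n_total = 0")
    return 100.0 * n_formed / n_total


def elimination_rate(n_eliminated: int, n_total: int) -> float:
    """Percentage of protrusions that disappeared, relative to ``n_total``."""
    if n_total <= 0:
        raise UndefinedRateError("elimination rate undefined for n_total = 0")
    return 100.0 * n_eliminated / n_total


def turnover_rate(n_formed: int, n_eliminated: int, n_total: int) -> float:
    """Formed plus eliminated, divided by twice the total, as a percent."""
    if n_total <= 0:
        raise UndefinedRateError("turnover rate undefined for n_total = 0")
    return 100.0 * (n_formed + n_eliminated) / (2.0 * n_total)


def dendrite_dynamics(
    frame1: DendriteFrame,
    frame2: DendriteFrame,
    cap_um: float = 0.7,
    matching_scope: str = "by_class",
    transition_convention: str = "within_class",
    denominator: str = "initial",
) -> list[DynamicsSummary]:
    """Full classify→track→rate computation for one dendrite frame pair.

    Returns one summary per class scope (spine, filopodium, all); scopes
    with a zero denominator are excluded and logged.
    """
    if denominator not in ("initial", "union"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    classes1 = classify_frame(frame1)
    classes2 = classify_frame(frame2)
    events, _tracks = track_frame_pair(
        frame1,
        frame2,
        classes1,
        classes2,
        cap_um=cap_um,
        matching_scope=matching_scope,
        transition_convention=transition_convention,
    )
    interval = frame2.timepoint_h - frame1.timepoint_h

    def initial_count(scope: str) -> int:
        if scope == "all":
            return len(frame1)
        cls = ProtrusionClass(scope)
        return sum(1 for c in classes1.values() if c is cls)

    out = []
    for scope in CLASS_SCOPES:
        ev = events[scope]
        n_initial = initial_count(scope)
        if denominator == "initial":
            n_total = n_initial
        else:
            # distinct protrusions of the scope seen in either frame
            n_total = n_initial + ev["formed"]
        if n_total <= 0:
            logger.warning(
                "dendrite %s: no %s protrusions in denominator; excluded",
                frame1.dendrite_id,
                scope,
            )
            continue
        out.append(
            DynamicsSummary(
                dendrite_id=frame1.dendrite_id,
                class_scope=scope,
                interval_h=interval,
                n_initial=n_initial,
                n_formed=ev["formed"],
                n_eliminated=ev["eliminated"],
                formation_rate_pct=formation_rate(ev["formed"], n_total),
                elimination_rate_pct=elimination_rate(ev["eliminated"], n_total),
                turnover_rate_pct=turnover_rate(
                    ev["formed"], ev["eliminated"], n_total
                ),
                genotype=frame1.genotype,
                age_weeks=frame1.age_weeks,
            )
        )
    return out


def rates_from_events(
    events: pd.DataFrame, denominator: str = "initial"
) -> pd.DataFrame:
    """Per-dendrite rates computed from an events table.

    ``events`` has one row per dendrite × class scope with columns
    ``dendrite_id, genotype, age_weeks, interval_h, class, n_initial,
    n_persisting, n_formed, n_eliminated``.  Rows whose denominator is
    zero are excluded and logged.
    """
    if denominator not in ("initial", "union"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    rows = []
    for _, ev in events.iterrows():
        n_total = int(ev["n_initial"])
        if denominator == "union":
            n_total += int(ev["n_formed"])
        if n_total <= 0:
            logger.warning(
                "dendrite %s: no %s protrusions in denominator; excluded",
                ev["dendrite_id"],
                ev["class"],
            )
            continue
        row = {
            k: ev[k]
            for k in (
                "dendrite_id",
                "genotype",
                "age_weeks",
                "interval_h",
                "class",
                "n_initial",
                "n_formed",
                "n_eliminated",
            )
            if k in ev
        }
        row["formation_rate_pct"] = formation_rate(int(ev["n_formed"]), n_total)
        row["elimination_rate_pct"] = elimination_rate(
            int(ev["n_eliminated"]), n_total
        )
        row["turnover_rate_pct"] = turnover_rate(
            int(ev["n_formed"]), int(ev["n_eliminated"]), n_total
        )
        rows.append(row)
    return pd.DataFrame(rows)


def dynamics_table(summaries: Iterable[DynamicsSummary]) -> pd.DataFrame:
    """Long-format per-dendrite dynamics table."""
    return pd.DataFrame(
        [
            {
                "dendrite_id": s.dendrite_id,
                "genotype": s.genotype,
                "age_weeks": s.age_weeks,
                "interval_h": s.interval_h,
                "class": s.class_scope,
                "n_initial": s.n_initial,
                "n_formed": s.n_formed,
                "n_eliminated": s.n_eliminated,
                "formation_rate_pct": s.formation_rate_pct,
                "elimination_rate_pct": s.elimination_rate_pct,
                "turnover_rate_pct": s.turnover_rate_pct,
            }
            for s in summaries
        ]
    )


def summarize_condition(values: Sequence[float]) -> tuple[float, float, int]:
    """(mean, SEM, n) over dendrites; SEM = sample SD / sqrt(n).

    A single value has an undefined SEM, reported as 0 with a warning.
    """
    vals = [float(v) for v in values if not math.isnan(float(v))]
    n = len(vals)
    if n == 0:
        raise ValueError("cannot summarize an empty condition")
    mean = sum(vals) / n
    if n == 1:
        logger.warning("condition with a single dendrite: SEM undefined, reported 0")
        return mean, 0.0, 1
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return mean, math.sqrt(var / n), n


def condition_summary_table(
    dynamics: pd.DataFrame,
    group_cols: Sequence[str] = ("genotype", "age_weeks", "interval_h", "class"),
    rate_cols: Sequence[str] = (
        "formation_rate_pct",
        "elimination_rate_pct",
        "turnover_rate_pct",
    ),
) -> pd.DataFrame:
    """Mean ± SEM over dendrites for every condition × class scope."""
    rows = []
    for keys, grp in dynamics.groupby(list(group_cols), dropna=False, sort=True):
        row = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        for col in rate_cols:
            mean, sem, n = summarize_condition(grp[col].tolist())
            stem = col.replace("_rate_pct", "")
            row[f"{stem}_mean"] = mean
            row[f"{stem}_sem"] = sem
            row["n_dendrites"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def compile_across_ages(
    dynamics: pd.DataFrame, class_scope: str = "spine"
) -> pd.DataFrame:
    """Long-format age × genotype turnover table for the two-way ANOVA.

    One row per dendrite, restricted to one class scope, with columns
    ``genotype``, ``age_weeks`` and ``turnover_rate_pct``.  Raises if any
    age × genotype cell is empty.
    """
    sub = dynamics[dynamics["class"] == class_scope]
    if sub.empty:
        raise ValueError(f"no dendrites with class scope {class_scope!r}")
    ages = sorted(sub["age_weeks"].unique())
    genos = sorted(sub["genotype"].unique())
    for a in ages:
        for g in genos:
            if sub[(sub["age_weeks"] == a) & (sub["genotype"] == g)].empty:
                raise ValueError(f"empty cell: genotype {g!r} at age {a} weeks")
    return sub[
        ["dendrite_id", "genotype", "age_weeks", "interval_h", "turnover_rate_pct"]
    ].reset_index(drop=True)
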