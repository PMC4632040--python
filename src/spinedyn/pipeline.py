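"""End-to-end pipeline: simulate/read → classify → track → rates → compare.

Each stage consumes and produces plain tables so the command-line
interface can re-enter the pipeline at any point.  Group comparisons are
between genotypes within each age × interval stratum: t-tests on
per-dendrite densities, class percentages and rates; KS tests on pooled
morphometric distributions; and, when several ages are present, a
genotype × age ANOVA on spine turnover with Bonferroni-corrected
per-age contrasts.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import io as sio
from . import morphometry as morpho
from . import stats as st
from . import tracking
from .synthetic import SimulatedCohort, simulate_cohort
from .types import DendriteFrame

logger = logging.getLogger(__name__)


def pair_frames(
    frames: Iterable[DendriteFrame],
) -> list[tuple[DendriteFrame, Optional[DendriteFrame]]]:
    """Group frames into per-dendrite (first, second) pairs by timepoint."""
    by_dendrite: dict[str, list[DendriteFrame]] = {}
    for f in frames:
        by_dendrite.setdefault(f.dendrite_id, []).append(f)
    pairs = []
    for did in sorted(by_dendrite):
        fs = sorted(by_dendrite[did], key=lambda f: f.timepoint_h)
        if len(fs) == 1:
            pairs.append((fs[0], None))
        elif len(fs) == 2:
            pairs.append((fs[0], fs[1]))
        else:
            raise ValueError(
                f"dendrite {did}: expected 1 or 2 frames, got {len(fs)} "
                "(multi-frame trajectories are not supported)"
            )
    return pairs


def events_from_frames(
    frames: Iterable[DendriteFrame], config: sio.PipelineConfig
) -> pd.DataFrame:
    """Classify and track every dendrite frame pair into an events table."""
    rows = []
    for frame1, frame2 in pair_frames(frames):
        if frame2 is None:
            continue
        classes1 = morpho.classify_frame(
            frame1, config.head_neck_ratio_max, config.length_neck_ratio_min
        )
        classes2 = morpho.classify_frame(
            frame2, config.head_neck_ratio_max, config.length_neck_ratio_min
        )
        events, _tracks = tracking.track_frame_pair(
            frame1,
            frame2,
            classes1,
            classes2,
            cap_um=config.match_cap_um,
            matching_scope=config.matching_scope,
            transition_convention=config.transition_convention,
        )
        for scope, ev in events.items():
            if scope == "all":
                n_initial = len(frame1)
            else:
                n_initial = sum(1 for c in classes1.values() if c.value == scope)
            rows.append(
                {
                    "dendrite_id": frame1.dendrite_id,
                    "genotype": frame1.genotype,
                    "age_weeks": frame1.age_weeks,
                    "interval_h": frame2.timepoint_h - frame1.timepoint_h,
                    "class": scope,
                    "n_initial": n_initial,
                    "n_persisting": ev["persisting"],
                    "n_formed": ev["formed"],
                    "n_eliminated": ev["eliminated"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "dendrite_id",
            "genotype",
            "age_weeks",
            "interval_h",
            "class",
            "n_initial",
            "n_persisting",
            "n_formed",
            "n_eliminated",
        ],
    )


def first_frames(frames: Iterable[DendriteFrame]) -> list[DendriteFrame]:
    """The earliest frame of each dendrite (density/percentage statistics)."""
    return [pair[0] for pair in pair_frames(frames)]


def compare_groups(
    frame_summary: pd.DataFrame,
    dynamics: pd.DataFrame,
    morphometry: pd.DataFrame,
    config: sio.PipelineConfig,
) -> pd.DataFrame:
    """All genotype comparisons supported by the tables at hand."""
    results: list[st.TestResult] = []

    def _two_groups(df: pd.DataFrame) -> Optional[tuple]:
        genos = sorted(df["genotype"].unique())
        if len(genos) != 2:
            return None
        return genos

    # densities and class percentages, per age (first frames only)
    for age, sub in frame_summary.groupby("age_weeks"):
        genos = _two_groups(sub)
        if genos is None:
            continue
        for col in ("density_total", "density_spine", "density_filo", "pct_spine", "pct_filo"):
            x = sub[sub["genotype"] == genos[0]][col].dropna()
            y = sub[sub["genotype"] == genos[1]][col].dropna()
            if len(x) >= 2 and len(y) >= 2:
                r = st.ttest_unpaired(x, y)
                r.name = f"{col}_age{age:g}_{genos[0]}_vs_{genos[1]}"
                results.append(r)

    # formation/elimination/turnover rates, per age x interval x class scope
    for (age, interval, scope), sub in dynamics.groupby(
        ["age_weeks", "interval_h", "class"]
    ):
        genos = _two_groups(sub)
        if genos is None:
            continue
        for col in ("formation_rate_pct", "elimination_rate_pct", "turnover_rate_pct"):
            x = sub[sub["genotype"] == genos[0]][col]
            y = sub[sub["genotype"] == genos[1]][col]
            if len(x) >= 2 and len(y) >= 2:
                r = st.ttest_unpaired(x, y)
                r.name = (
                    f"{scope}_{col}_age{age:g}_{interval:g}h_"
                    f"{genos[0]}_vs_{genos[1]}"
                )
                results.append(r)

    # pooled morphometric distributions, per age
    if not morphometry.empty:
        for age, sub in morphometry.groupby("age_weeks"):
            genos = _two_groups(sub)
            if genos is None:
                continue
            for col in ("head_width_um", "length_um"):
                x = sub[sub["genotype"] == genos[0]][col]
                y = sub[sub["genotype"] == genos[1]][col]
                if len(x) >= 1 and len(y) >= 1:
                    r = st.ks_two_sample(x, y)
                    r.name = f"ks_{col}_age{age:g}_{genos[0]}_vs_{genos[1]}"
                    results.append(r)

    # genotype x age ANOVA on spine turnover, with per-age Bonferroni contrasts
    spine_turn = dynamics[dynamics["class"] == "spine"]
    if (
        not spine_turn.empty
        and spine_turn["age_weeks"].nunique() >= 2
        and spine_turn["genotype"].nunique() == 2
    ):
        cells = spine_turn.groupby(["genotype", "age_weeks"]).size()
        if (cells > 0).all() and len(cells) == (
            spine_turn["genotype"].nunique() * spine_turn["age_weeks"].nunique()
        ):
            anova = st.two_way_anova(
                spine_turn["turnover_rate_pct"],
                spine_turn["genotype"],
                spine_turn["age_weeks"],
            )
            for short, r in anova.effects.items():
                r.name = f"anova_spine_turnover_{short}"
                results.append(r)
            results.extend(
                st.bonferroni_pairwise(
                    spine_turn["turnover_rate_pct"],
                    spine_turn["genotype"],
                    spine_turn["age_weeks"],
                    m=config.bonferroni_family,
                    anova=anova,
                )
            )

    return st.results_table(results)


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return round(x, -int(np.floor(np.log10(abs(x)))) + (sig - 1))


def render_report(
    condition_summary: pd.DataFrame, stats_table: pd.DataFrame
) -> str:
    """Human-readable report with values rounded to 2 significant figures."""
    lines = ["# spinedyn report", "", "## Condition summaries (mean ± SEM over dendrites)", ""]
    for _, row in condition_summary.iterrows():
        lines.append(
            f"- {row['genotype']} {row['age_weeks']:g} wk, "
            f"{row['interval_h']:g} h, {row['class']}: "
            f"formation {_round_sig(row['formation_mean'])} ± {_round_sig(row['formation_sem'])}%, "
            f"elimination {_round_sig(row['elimination_mean'])} ± {_round_sig(row['elimination_sem'])}%, "
            f"turnover {_round_sig(row['turnover_mean'])} ± {_round_sig(row['turnover_sem'])}% "
            f"(n = {int(row['n_dendrites'])} dendrites)"
        )
    lines += ["", "## Statistical comparisons", ""]
    for _, row in stats_table.iterrows():
        lines.append(
            f"- {row['comparison']}: statistic {_round_sig(row['statistic'], 3)}, "
            f"p = {_round_sig(row['p_adjusted'], 2)} {row['significance']}"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(
    config: sio.PipelineConfig,
    source: str | Path = "simulate",
    out_dir: Optional[str | Path] = None,
) -> dict[str, pd.DataFrame]:
    """Execute classify → track → rates → compare and write the bundle.

    ``source`` is either the literal ``"simulate"`` (uses the configured
    conditions, reseeded from ``config.seed``) or a path to an annotation
    table.  Returns the result tables; when ``out_dir`` (or the
    configured output directory) exists/created, writes them plus a run
    manifest and a human-readable report.
    """
    cohort: Optional[SimulatedCohort] = None
    if str(source) == "simulate":
        if not config.conditions:
            raise ValueError("simulate requested but no conditions configured")
        conditions = {
            label: dataclasses.replace(params, seed=config.seed)
            for label, params in config.conditions.items()
        }
        cohort = simulate_cohort(conditions)
        frames = cohort.frames()
        logger.info("simulated %d dendrites", len(cohort.dendrites))
    else:
        frames = sio.read_annotations(source)
        logger.info("read %d frames from %s", len(frames), source)

    frame_summary = morpho.frame_summary_table(
        first_frames(frames), config.head_neck_ratio_max, config.length_neck_ratio_min
    )
    morph_table = morpho.pooled_morphometry_table(first_frames(frames))
    events = events_from_frames(frames, config)
    dynamics = dyn.rates_from_events(events, config.rate_denominator)
    condition_summary = (
        dyn.condition_summary_table(dynamics) if not dynamics.empty else pd.DataFrame()
    )
    stats_table = compare_groups(frame_summary, dynamics, morph_table, config)

    tables = {
        "frame_summary": frame_summary,
        "morphometry": morph_table,
        "events": events,
        "dynamics": dynamics,
        "condition_summary": condition_summary,
        "statistics": stats_table,
    }

    out = Path(out_dir) if out_dir is not None else Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    if cohort is not None:
        sio.write_annotations(frames, out / "annotations.tsv")
        sio.write_table(cohort.ground_truth_table(), out / "ground_truth.tsv", h)
    for name, table in tables.items():
        sio.write_table(table, out / f"{name}.tsv", h)
    report = render_report(condition_summary, stats_table) if not dynamics.empty else "# spinedyn report\n\n(no frame pairs: dynamics unavailable)\n"
    (out / "report.txt").write_text(report)
    sio.write_manifest(
        config,
        out / "manifest.json",
        n_frames=len(frames),
        n_dendrites=len({f.dendrite_id for f in frames}),
    )
    return tables
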