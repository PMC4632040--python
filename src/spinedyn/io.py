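"""File formats: annotation tables, SWC backbones, configs and manifests.

The annotation table is the interchange format standing in for manual
tracing output: delimited text (tab by default, comma sniffed on read),
one row per protrusion per frame, all lengths in μm, timepoints in hours
and ages in weeks.  Intermediate tables written by the pipeline carry a
``config_hash`` column so that tables produced under different
configurations cannot be silently mixed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .synthetic import CONDITIONS, SimulationParams, get_condition, params_to_dict
from .types import DendriteFrame, ProtrusionObservation, SchemaError

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "dendrite_id",
    "frame_id",
    "timepoint_h",
    "genotype",
    "age_weeks",
    "dendrite_length_um",
    "protrusion_id",
    "arc_position_um",
    "head_width_um",
    "neck_width_um",
    "length_um",
]

_NUMERIC = [
    "timepoint_h",
    "age_weeks",
    "dendrite_length_um",
    "arc_position_um",
    "head_width_um",
    "neck_width_um",
    "length_um",
]
_POSITIVE = ["dendrite_length_um", "head_width_um", "neck_width_um", "length_um"]


def _sniff_sep(path: Path) -> str:
    header = Path(path).open("r", encoding="utf-8").readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise SchemaError(f"{path}: could not detect a tab or comma delimiter")


def read_annotations(path: str | Path) -> list[DendriteFrame]:
    """Read an annotation table into frames grouped by (dendrite, frame).

    Schema violations (missing columns, missing values, non-positive
    measurements, duplicate protrusion ids) raise :class:`SchemaError`
    citing the offending rows (1-based data rows, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    problems = []
    for i, row in df.iterrows():
        rownum = i + 1
        for col in ANNOTATION_COLUMNS:
            if row[col] == "":
                problems.append(f"row {rownum}: missing value in {col!r}")
        for col in _NUMERIC:
            if row[col] == "":
                continue
            try:
                val = float(row[col])
            except ValueError:
                problems.append(f"row {rownum}: non-numeric {col!r} = {row[col]!r}")
                continue
            if col in _POSITIVE and not val > 0:
                problems.append(f"row {rownum}: non-positive {col!r} = {val}")
            if col == "arc_position_um" and val < 0:
                problems.append(f"row {rownum}: negative arc position {val}")
    if problems:
        raise SchemaError(f"{path}: schema errors:\n  " + "\n  ".join(problems))

    frames = []
    for (did, fid), grp in df.groupby(["dendrite_id", "frame_id"], sort=True):
        pids = grp["protrusion_id"].tolist()
        if len(pids) != len(set(pids)):
            dupes = sorted({p for p in pids if pids.count(p) > 1})
            rows = [
                str(i + 1) for i in grp.index[grp["protrusion_id"].isin(dupes)]
            ]
            raise SchemaError(
                f"{path}: duplicate protrusion_id(s) {dupes} in frame "
                f"({did}, {fid}), rows {', '.join(rows)}"
            )
        first = grp.iloc[0]
        observations = [
            ProtrusionObservation(
                dendrite_id=did,
                frame_id=fid,
                protrusion_id=row["protrusion_id"],
                arc_position_um=float(row["arc_position_um"]),
                head_width_um=float(row["head_width_um"]),
                neck_width_um=float(row["neck_width_um"]),
                length_um=float(row["length_um"]),
            )
            for _, row in grp.iterrows()
        ]
        frames.append(
            DendriteFrame(
                dendrite_id=did,
                frame_id=fid,
                timepoint_h=float(first["timepoint_h"]),
                dendrite_length_um=float(first["dendrite_length_um"]),
                genotype=first["genotype"],
                age_weeks=float(first["age_weeks"]),
                observations=observations,
            )
        )
    return frames


def annotations_frame(frames: Iterable[DendriteFrame]) -> pd.DataFrame:
    """Annotation-table DataFrame for a collection of frames."""
    rows = []
    for f in frames:
        for o in f.observations:
            rows.append(
                {
                    "dendrite_id": f.dendrite_id,
                    "frame_id": f.frame_id,
                    "timepoint_h": f.timepoint_h,
                    "genotype": f.genotype,
                    "age_weeks": f.age_weeks,
                    "dendrite_length_um": f.dendrite_length_um,
                    "protrusion_id": o.protrusion_id,
                    "arc_position_um": o.arc_position_um,
                    "head_width_um": o.head_width_um,
                    "neck_width_um": o.neck_width_um,
                    "length_um": o.length_um,
                }
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotations(frames: Iterable[DendriteFrame], path: str | Path) -> None:
    """Write frames as a tab-delimited annotation table (full precision)."""
    df = annotations_frame(frames)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str = "") -> None:
    """Write an intermediate table, stamping the configuration hash."""
    out = df.copy()
    if config_hash:
        out["config_hash"] = config_hash
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path, expect_hash: str = "") -> pd.DataFrame:
    """Read an intermediate table, refusing a mismatched config hash."""
    df = pd.read_csv(path, sep="\t")
    if expect_hash and "config_hash" in df.columns:
        hashes = set(df["config_hash"].astype(str).unique())
        if hashes != {expect_hash}:
            raise SchemaError(
                f"{path}: config hash mismatch (table {sorted(hashes)}, "
                f"expected {expect_hash!r}); refusing to mix configurations"
            )
    return df


# ---------------------------------------------------------------------------
# SWC backbone geometry


def read_swc_backbone(path: str | Path) -> tuple[float, dict[int, float]]:
    """Arc-length parameterization of an unbranched SWC reconstruction.

    Returns ``(total_length_um, arc_position_by_node_id)`` where arc
    positions accumulate Euclidean segment lengths from the root.
    Branched reconstructions (a parent with more than one child), unknown
    parents and cyclic references are rejected.
    """
    nodes: dict[int, tuple[float, float, float, int]] = {}
    for lineno, line in enumerate(Path(path).open("r", encoding="utf-8"), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SchemaError(f"{path}:{lineno}: expected 7 SWC fields, got {len(fields)}")
        try:
            nid = int(fields[0])
            x, y, z = float(fields[2]), float(fields[3]), float(fields[4])
            parent = int(fields[6])
        except ValueError as exc:
            raise SchemaError(f"{path}:{lineno}: malformed SWC record") from exc
        if nid in nodes:
            raise SchemaError(f"{path}:{lineno}: duplicate node id {nid}")
        nodes[nid] = (x, y, z, parent)

    if not nodes:
        raise SchemaError(f"{path}: no SWC node records")
    children: dict[int, list[int]] = {}
    roots = []
    for nid, (_, _, _, parent) in nodes.items():
        if parent == -1:
            roots.append(nid)
        else:
            if parent not in nodes:
                raise SchemaError(f"{path}: node {nid} references unknown parent {parent}")
            children.setdefault(parent, []).append(nid)
    if len(roots) != 1:
        raise SchemaError(f"{path}: expected exactly one root node, found {len(roots)}")
    for parent, kids in children.items():
        if len(kids) > 1:
            raise SchemaError(
                f"{path}: branched reconstruction (node {parent} has "
                f"{len(kids)} children); only unbranched backbones are supported"
            )

    arc: dict[int, float] = {}
    nid = roots[0]
    arc[nid] = 0.0
    visited = {nid}
    while nid in children:
        child = children[nid][0]
        if child in visited:
            raise SchemaError(f"{path}: cyclic parent references at node {child}")
        x1, y1, z1, _ = nodes[nid]
        x2, y2, z2, _ = nodes[child]
        seg = ((x2 - x1) ** 2 + (y2 - y1) ** 2 + (z2 - z1) ** 2) ** 0.5
        arc[child] = arc[nid] + seg
        visited.add(child)
        nid = child
    if len(visited) != len(nodes):
        raise SchemaError(f"{path}: disconnected or cyclic SWC records")
    return arc[nid], arc


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PipelineConfig:
    """End-to-end analysis/simulation configuration."""

    match_cap_um: float = 0.7
    head_neck_ratio_max: float = 1.2
    length_neck_ratio_min: float = 3.0
    rate_denominator: str = "initial"  # or "union"
    matching_scope: str = "by_class"  # or "pooled"
    transition_convention: str = "within_class"  # or "persistence"
    bonferroni_family: Optional[int] = None  # None -> one contrast per age
    seed: int = 0
    output_dir: str = "spinedyn_out"
    conditions: dict[str, SimulationParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.match_cap_um <= 0:
            raise ValueError("match_cap_um must be > 0")
        if self.head_neck_ratio_max <= 0 or self.length_neck_ratio_min <= 0:
            raise ValueError("classification thresholds must be > 0")
        if self.rate_denominator not in ("initial", "union"):
            raise ValueError(f"unknown rate_denominator {self.rate_denominator!r}")
        if self.matching_scope not in ("by_class", "pooled"):
            raise ValueError(f"unknown matching_scope {self.matching_scope!r}")
        if self.transition_convention not in ("within_class", "persistence"):
            raise ValueError(
                f"unknown transition_convention {self.transition_convention!r}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = {k: params_to_dict(v) for k, v in self.conditions.items()}
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration.

    Simulation conditions may be given either as a preset name (string)
    or as a mapping of :class:`SimulationParams` fields; a preset name
    with overrides uses the ``preset`` key.
    """
    raw = yaml.safe_load(Path(path).open("r", encoding="utf-8")) or {}
    cond_raw = raw.pop("conditions", {})
    conditions = {}
    for label, spec in cond_raw.items():
        if isinstance(spec, str):
            conditions[label] = get_condition(spec)
        elif isinstance(spec, dict):
            preset = spec.pop("preset", None)
            if preset is not None:
                conditions[label] = get_condition(preset, **spec)
            else:
                conditions[label] = SimulationParams(**spec)
        else:
            raise SchemaError(f"condition {label!r}: expected a preset name or mapping")
    return PipelineConfig(conditions=conditions, **raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    yaml.safe_dump(config.to_dict(), Path(path).open("w", encoding="utf-8"), sort_keys=True)


def write_manifest(config: PipelineConfig, path: str | Path, **extra) -> None:
    """Machine-readable run manifest: config, hash, seed and versions."""
    import numpy
    import scipy
    import statsmodels

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "versions": {
            "spinedyn": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        **extra,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def default_conditions() -> dict[str, SimulationParams]:
    """All packaged presets, keyed by their catalogue names."""
    return {name: get_condition(name) for name in CONDITIONS}
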