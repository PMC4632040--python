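"""Core data containers for dendritic-protrusion analysis.

All lengths are in micrometres (μm), positions are 1-D arc-length
coordinates along the dendrite backbone, timepoints in hours and ages in
weeks.  A *protrusion* is any membranous projection from the dendrite
shaft; each one is classified as a mature *spine* or an immature
*filopodium* (see :mod:`spinedyn.morphometry`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class ProtrusionClass(str, enum.Enum):
    """Exhaustive, mutually exclusive protrusion classes."""

    SPINE = "spine"
    FILOPODIUM = "filopodium"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class InvalidMeasurementError(ValueError):
    """A morphometric measurement violates its domain (e.g. neck width ≤ 0)."""


class InvalidParameterError(ValueError):
    """A simulation or analysis parameter violates its domain."""


class SchemaError(ValueError):
    """A table or file does not conform to the expected schema."""


@dataclass(frozen=True)
class ProtrusionObservation:
    """One protrusion measured in one imaging frame.

    Parameters
    ----------
    arc_position_um
        Position along the dendrite backbone arc, μm from its origin.
    head_width_um, neck_width_um, length_um
        Morphometry of the protrusion in μm; all strictly positive.
    """

    dendrite_id: str
    frame_id: str
    protrusion_id: str
    arc_position_um: float
    head_width_um: float
    neck_width_um: float
    length_um: float

    def __post_init__(self) -> None:
        if self.arc_position_um < 0:
            raise InvalidMeasurementError(
                f"arc_position_um must be >= 0, got {self.arc_position_um}"
            )
        for name in ("head_width_um", "neck_width_um", "length_um"):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidMeasurementError(
                    f"{name} must be > 0, got {value} "
                    f"(protrusion {self.protrusion_id})"
                )


@dataclass
class DendriteFrame:
    """All protrusion observations for one dendrite at one timepoint."""

    dendrite_id: str
    frame_id: str
    timepoint_h: float
    dendrite_length_um: float
    genotype: str
    age_weeks: float
    observations: list[ProtrusionObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.dendrite_length_um > 0:
            raise InvalidParameterError(
                f"dendrite_length_um must be > 0, got {self.dendrite_length_um}"
            )
        if self.timepoint_h < 0:
            raise InvalidParameterError("timepoint_h must be >= 0")
        ids = [o.protrusion_id for o in self.observations]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(
                f"duplicate protrusion_id(s) in frame {self.frame_id}: {dupes}"
            )

    def __len__(self) -> int:
        return len(self.observations)

    def positions(self) -> list[float]:
        return [o.arc_position_um for o in self.observations]


@dataclass
class TrackResult:
    """Identity correspondence between two successive frames of a dendrite.

    ``matched_pairs`` holds ``(frame1_id, frame2_id, displacement_um)``
    triples; displacements are measured after global arc alignment and
    never exceed ``max_displacement_um``.  Unmatched frame-1 protrusions
    are *eliminated*, unmatched frame-2 protrusions are *formed*.
    """

    matched_pairs: list[tuple[str, str, float]]
    formed_ids: list[str]
    eliminated_ids: list[str]
    max_displacement_um: float = 0.7
    arc_offset_um: float = 0.0

    def __post_init__(self) -> None:
        f1 = [p[0] for p in self.matched_pairs] + list(self.eliminated_ids)
        f2 = [p[1] for p in self.matched_pairs] + list(self.formed_ids)
        if len(f1) != len(set(f1)) or len(f2) != len(set(f2)):
            raise SchemaError("a protrusion id appears twice in the track result")
        for _, _, d in self.matched_pairs:
            if d > self.max_displacement_um + 1e-9:
                raise SchemaError(
                    f"matched displacement {d} exceeds cap {self.max_displacement_um}"
                )

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)


@dataclass
class DynamicsSummary:
    """Per-dendrite formation/elimination/turnover rates for one class scope."""

    dendrite_id: str
    class_scope: str  # "spine" | "filopodium" | "all"
    interval_h: float
    n_initial: int
    n_formed: int
    n_eliminated: int
    formation_rate_pct: float
    elimination_rate_pct: float
    turnover_rate_pct: float
    genotype: str = ""
    age_weeks: float = float("nan")


@dataclass
class GroundTruth:
    """Generating truth for one simulated frame pair.

    ``correspondence`` maps frame-1 protrusion ids to frame-2 ids for
    persisting protrusions; ``formed_ids``/``eliminated_ids`` list frame-2
    births and frame-1 deaths; ``true_class`` maps every id (both frames)
    to its generating class.
    """

    correspondence: dict[str, str]
    formed_ids: list[str]
    eliminated_ids: list[str]
    true_class: dict[str, ProtrusionClass]

    def event_counts(self, cls: Optional[ProtrusionClass] = None) -> dict[str, int]:
        """True (persisting, formed, eliminated) counts, optionally per class."""

        def keep(pid: str) -> bool:
            return cls is None or self.true_class[pid] is cls

        return {
            "persisting": sum(1 for a in self.correspondence if keep(a)),
            "formed": sum(1 for b in self.formed_ids if keep(b)),
            "eliminated": sum(1 for a in self.eliminated_ids if keep(a)),
        }
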