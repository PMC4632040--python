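"""Spine/filopodium classification and morphometric summaries.

Filopodia are the long, thin immature protrusions; a protrusion is a
filopodium iff its head-to-neck width ratio is below 1.2 *and* its
length-to-neck ratio exceeds 3.  Every other protrusion is a spine.  Both
comparisons are strict, so boundary values fall to the spine class, and
the rule is invariant under a common rescaling of all three measurements.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import (
    DendriteFrame,
    InvalidMeasurementError,
    ProtrusionClass,
    ProtrusionObservation,
)

#: Filopodium criterion: head_width / neck_width strictly below this.
HEAD_NECK_RATIO_MAX = 1.2
#: Filopodium criterion: length / neck_width strictly above this.
LENGTH_NECK_RATIO_MIN = 3.0


def classify_protrusion(
    obs: ProtrusionObservation,
    head_neck_ratio_max: float = HEAD_NECK_RATIO_MAX,
    length_neck_ratio_min: float = LENGTH_NECK_RATIO_MIN,
) -> ProtrusionClass:
    """Classify one protrusion as spine or filopodium.

    Returns ``FILOPODIUM`` iff ``head/neck < head_neck_ratio_max`` and
    ``length/neck > length_neck_ratio_min``; otherwise ``SPINE``.
    """
    if not obs.neck_width_um > 0:
        raise InvalidMeasurementError(
            f"neck_width_um must be > 0, got {obs.neck_width_um}"
        )
    head_neck = obs.head_width_um / obs.neck_width_um
    length_neck = obs.length_um / obs.neck_width_um
    if head_neck < head_neck_ratio_max and length_neck > length_neck_ratio_min:
        return ProtrusionClass.FILOPODIUM
    return ProtrusionClass.SPINE


def classify_frame(
    frame: DendriteFrame,
    head_neck_ratio_max: float = HEAD_NECK_RATIO_MAX,
    length_neck_ratio_min: float = LENGTH_NECK_RATIO_MIN,
) -> dict[str, ProtrusionClass]:
    """Map every protrusion id in the frame to its class."""
    return {
        o.protrusion_id: classify_protrusion(
            o, head_neck_ratio_max, length_neck_ratio_min
        )
        for o in frame.observations
    }


def protrusion_density(
    frame: DendriteFrame,
    class_filter: Optional[ProtrusionClass] = None,
    classes: Optional[dict[str, ProtrusionClass]] = None,
) -> float:
    """Protrusion count per μm of dendrite, optionally for one class.

    ``classes`` may supply precomputed classifications; otherwise they are
    computed with the default thresholds.
    """
    if class_filter is None:
        count = len(frame)
    else:
        if classes is None:
            classes = classify_frame(frame)
        count = sum(
            1 for o in frame.observations if classes[o.protrusion_id] is class_filter
        )
    return count / frame.dendrite_length_um


class EmptyFrameError(ValueError):
    """Raised where a statistic is undefined on a frame with no protrusions."""


def class_percentages(
    frame: DendriteFrame,
    classes: Optional[dict[str, ProtrusionClass]] = None,
) -> tuple[float, float]:
    """(spine %, filopodium %) of total protrusions in one frame.

    Undefined (raises :class:`EmptyFrameError`) on an empty frame; callers
    exclude such dendrites from group means.
    """
    if len(frame) == 0:
        raise EmptyFrameError(
            f"class percentages undefined for empty frame {frame.frame_id}"
        )
    if classes is None:
        classes = classify_frame(frame)
    n_spine = sum(
        1
        for o in frame.observations
        if classes[o.protrusion_id] is ProtrusionClass.SPINE
    )
    pct_spine = 100.0 * n_spine / len(frame)
    return pct_spine, 100.0 - pct_spine


def morphometry_distribution(
    frames: Iterable[DendriteFrame],
    measure: str,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pooled empirical cumulative distribution of a morphometric measure.

    Parameters
    ----------
    measure
        ``"head_width"`` (the protrusion width of cumulative-frequency
        plots) or ``"length"``.

    Returns
    -------
    values, cum_fraction, mean
        Sorted pooled values, the ECDF evaluated at each (reaching 1.0 at
        the maximum), and the pooled mean.
    """
    attr = {"head_width": "head_width_um", "length": "length_um"}.get(measure)
    if attr is None:
        raise ValueError(f"unknown measure {measure!r}")
    pooled = np.array(
        [getattr(o, attr) for f in frames for o in f.observations], dtype=float
    )
    if pooled.size == 0:
        raise EmptyFrameError("no observations pooled for distribution")
    values = np.sort(pooled)
    cum = np.arange(1, values.size + 1) / values.size
    return values, cum, float(values.mean())


def frame_summary_table(
    frames: Iterable[DendriteFrame],
    head_neck_ratio_max: float = HEAD_NECK_RATIO_MAX,
    length_neck_ratio_min: float = LENGTH_NECK_RATIO_MIN,
) -> pd.DataFrame:
    """Per-dendrite-frame summary: densities and class percentages.

    Empty frames get densities of 0 and NaN percentages (excluded from
    group means downstream, matching the per-dendrite averaging
    convention in which n counts dendrites).
    """
    rows = []
    for frame in frames:
        classes = classify_frame(frame, head_neck_ratio_max, length_neck_ratio_min)
        try:
            pct_spine, pct_filo = class_percentages(frame, classes)
        except EmptyFrameError:
            pct_spine = pct_filo = float("nan")
        rows.append(
            {
                "dendrite_id": frame.dendrite_id,
                "frame_id": frame.frame_id,
                "genotype": frame.genotype,
                "age_weeks": frame.age_weeks,
                "timepoint_h": frame.timepoint_h,
                "dendrite_length_um": frame.dendrite_length_um,
                "density_total": protrusion_density(frame),
                "density_spine": protrusion_density(
                    frame, ProtrusionClass.SPINE, classes
                ),
                "density_filo": protrusion_density(
                    frame, ProtrusionClass.FILOPODIUM, classes
                ),
                "pct_spine": pct_spine,
                "pct_filo": pct_filo,
            }
        )
    return pd.DataFrame(rows)


def pooled_morphometry_table(frames: Iterable[DendriteFrame]) -> pd.DataFrame:
    """One row per protrusion with its morphometry, class and metadata."""
    rows = []
    for frame in frames:
        for o in frame.observations:
            rows.append(
                {
                    "dendrite_id": o.dendrite_id,
                    "frame_id": o.frame_id,
                    "protrusion_id": o.protrusion_id,
                    "genotype": frame.genotype,
                    "age_weeks": frame.age_weeks,
                    "head_width_um": o.head_width_um,
                    "neck_width_um": o.neck_width_um,
                    "length_um": o.length_um,
                    "class": classify_protrusion(o).value,
                }
            )
    return pd.DataFrame(rows)
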