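"""Synthetic dendrite frame-pair generator with known ground truth.

The generator emulates the statistical structure of time-lapse dendritic
protrusion annotations: protrusions are placed as a Poisson process along
a 1-D dendrite arc, assigned a spine/filopodium class from a mixture, and
given class-conditional log-normal morphometry; between two sessions each
protrusion is independently eliminated with its class probability,
survivors keep their identity and morphometry with a small positional
jitter, and new protrusions are born with a per-class Poisson budget
whose mean is the class formation probability times the class count in
the first frame — so the downstream rate estimators are unbiased for the
generating probabilities.

Packaged condition presets (:data:`CONDITIONS`) carry the densities,
class mixtures and per-interval event probabilities of a developmental
SCA1 imaging study (4/6/8-week cortex at 1 h and 48 h intervals, 5/12-week
hippocampal cross-sections); they are the regimes the acceptance suite
exercises.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import (
    DendriteFrame,
    GroundTruth,
    InvalidParameterError,
    ProtrusionClass,
    ProtrusionObservation,
)

# ---------------------------------------------------------------------------
# Parameters

#: Class-conditional log-normal morphometry: (median, sigma of log) for the
#: neck width (μm), the head/neck width ratio and the length/neck ratio.
#: Chosen so spines centre at head/neck ≈ 1.8 and filopodia at ≈ 1.0 with
#: length/neck ≈ 5.5, giving ≈ 99% agreement between generating class and
#: the ratio-threshold classifier.
DEFAULT_MORPHOMETRY: dict[str, dict[str, tuple[float, float]]] = {
    "spine": {
        "neck_um": (0.22, 0.25),
        "head_neck_ratio": (1.8, 0.20),
        "length_neck_ratio": (3.0, 0.35),
    },
    "filopodium": {
        "neck_um": (0.18, 0.20),
        "head_neck_ratio": (1.0, 0.08),
        "length_neck_ratio": (5.5, 0.20),
    },
}


@dataclass
class SimulationParams:
    """Generative settings for one simulated condition.

    Probabilities are per imaging interval (``interval_h``); densities are
    per μm of dendrite arc.  ``jitter_sd_um`` is the SD of the zero-mean
    positional perturbation of persisting protrusions between frames and
    should stay well below half the 0.7 μm matching cap for ground-truth
    correspondences to be recoverable.
    """

    dendrite_length_um: float = 40.0
    protrusion_density_per_um: float = 0.38
    filopodium_fraction: float = 0.19
    spine_formation_prob: float = 0.036
    spine_elimination_prob: float = 0.045
    filo_formation_prob: float = 0.27
    filo_elimination_prob: float = 0.23
    jitter_sd_um: float = 0.15
    morphometry_params: dict = field(
        default_factory=lambda: {
            c: dict(v) for c, v in DEFAULT_MORPHOMETRY.items()
        }
    )
    n_dendrites: int = 14
    seed: int = 0
    # condition metadata
    interval_h: float = 1.0
    genotype: str = "control"
    age_weeks: float = 4.0
    cross_sectional: bool = False
    # optional generative refinements
    nascent_filopodium_fraction: Optional[float] = None
    rate_dispersion: float = 0.0
    head_width_scale: float = 1.0
    length_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.dendrite_length_um > 0:
            raise InvalidParameterError("dendrite_length_um must be > 0")
        if self.protrusion_density_per_um < 0:
            raise InvalidParameterError("protrusion_density_per_um must be >= 0")
        for name in (
            "filopodium_fraction",
            "spine_formation_prob",
            "spine_elimination_prob",
            "filo_formation_prob",
            "filo_elimination_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if self.nascent_filopodium_fraction is not None and not (
            0.0 <= self.nascent_filopodium_fraction <= 1.0
        ):
            raise InvalidParameterError(
                "nascent_filopodium_fraction must be in [0, 1]"
            )
        if self.jitter_sd_um < 0:
            raise InvalidParameterError("jitter_sd_um must be >= 0")
        if not 0.0 <= self.rate_dispersion < 1.0:
            raise InvalidParameterError("rate_dispersion must be in [0, 1)")
        if self.n_dendrites < 1:
            raise InvalidParameterError("n_dendrites must be >= 1")
        if self.head_width_scale <= 0 or self.length_scale <= 0:
            raise InvalidParameterError("morphometry scales must be > 0")

    def formation_prob(self, cls: ProtrusionClass) -> float:
        return (
            self.spine_formation_prob
            if cls is ProtrusionClass.SPINE
            else self.filo_formation_prob
        )

    def elimination_prob(self, cls: ProtrusionClass) -> float:
        return (
            self.spine_elimination_prob
            if cls is ProtrusionClass.SPINE
            else self.filo_elimination_prob
        )


# ---------------------------------------------------------------------------
# Packaged condition presets


def _cond(genotype, age, interval, density, filo_frac, s_f, s_e, f_f, f_e, n):
    return SimulationParams(
        protrusion_density_per_um=density,
        filopodium_fraction=filo_frac,
        spine_formation_prob=s_f,
        spine_elimination_prob=s_e,
        filo_formation_prob=f_f,
        filo_elimination_prob=f_e,
        n_dendrites=n,
        interval_h=interval,
        genotype=genotype,
        age_weeks=age,
    )


#: Cortical time-lapse and hippocampal cross-sectional condition presets.
#: Densities (/μm), class fractions and per-interval event probabilities are
#: the group means reported for the corresponding genotype/age/interval.
CONDITIONS: dict[str, SimulationParams] = {
    "cortex_4wk_control_1h": _cond("control", 4, 1, 0.38, 0.19, 0.036, 0.045, 0.27, 0.23, 14),
    "cortex_4wk_mutant_1h": _cond("mutant", 4, 1, 0.33, 0.24, 0.09, 0.12, 0.35, 0.42, 17),
    "cortex_4wk_control_48h": _cond("control", 4, 48, 0.38, 0.19, 0.08, 0.10, 0.59, 0.70, 18),
    "cortex_4wk_mutant_48h": _cond("mutant", 4, 48, 0.33, 0.24, 0.23, 0.28, 0.52, 0.72, 12),
    "cortex_6wk_control_1h": _cond("control", 6, 1, 0.35, 0.12, 0.023, 0.021, 0.18, 0.14, 14),
    "cortex_6wk_mutant_1h": _cond("mutant", 6, 1, 0.28, 0.19, 0.09, 0.13, 0.36, 0.35, 14),
    "cortex_8wk_control_1h": _cond("control", 8, 1, 0.36, 0.10, 0.027, 0.020, 0.05, 0.21, 12),
    "cortex_8wk_mutant_1h": _cond("mutant", 8, 1, 0.30, 0.15, 0.13, 0.12, 0.25, 0.42, 10),
}
CONDITIONS.update(
    {
        # Fixed-tissue cross-sections: density and morphometry only.  The
        # mutant morphometry scales emulate the narrower-protrusion /
        # longer-protrusion distribution shifts seen ex vivo.
        "hippocampus_5wk_control": replace(
            _cond("control", 5, 0, 1.66, 0.10, 0, 0, 0, 0, 15), cross_sectional=True
        ),
        "hippocampus_5wk_mutant": replace(
            _cond("mutant", 5, 0, 1.53, 0.10, 0, 0, 0, 0, 15),
            cross_sectional=True,
            head_width_scale=0.97,
            length_scale=1.10,
        ),
        "hippocampus_12wk_control": replace(
            _cond("control", 12, 0, 1.53, 0.05, 0, 0, 0, 0, 20), cross_sectional=True
        ),
        "hippocampus_12wk_mutant": replace(
            _cond("mutant", 12, 0, 1.28, 0.05, 0, 0, 0, 0, 25),
            cross_sectional=True,
            head_width_scale=0.85,
            length_scale=1.05,
        ),
    }
)


def get_condition(name: str, **overrides) -> SimulationParams:
    """A copy of a packaged condition preset, with optional field overrides."""
    try:
        base = CONDITIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown condition {name!r}; available: {sorted(CONDITIONS)}"
        ) from None
    return replace(base, **overrides) if overrides else replace(base)


# ---------------------------------------------------------------------------
# Simulation


def _draw_morphometry(
    params: SimulationParams, cls: ProtrusionClass, rng: np.random.Generator
) -> tuple[float, float, float]:
    """(head, neck, length) in μm from the class-conditional log-normals."""
    m = params.morphometry_params[cls.value]
    neck = rng.lognormal(np.log(m["neck_um"][0]), m["neck_um"][1])
    head = neck * rng.lognormal(
        np.log(m["head_neck_ratio"][0]), m["head_neck_ratio"][1]
    )
    length = neck * rng.lognormal(
        np.log(m["length_neck_ratio"][0]), m["length_neck_ratio"][1]
    )
    return head * params.head_width_scale, neck, length * params.length_scale


def _rng_for(params: SimulationParams, *keys) -> np.random.Generator:
    entropy = [params.seed & 0x7FFFFFFF] + [
        zlib.crc32(str(k).encode()) for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def simulate_initial_frame(
    params: SimulationParams,
    dendrite_id: str,
    rng: Optional[np.random.Generator] = None,
    true_classes: Optional[dict[str, ProtrusionClass]] = None,
) -> DendriteFrame:
    """Simulate the first imaging frame of one dendrite.

    The protrusion count is Poisson with mean density × length, positions
    are uniform on the arc, classes follow the filopodium-fraction
    mixture, morphometry the class-conditional log-normals.  If
    ``true_classes`` (a dict) is supplied it is filled with the
    generating class per protrusion id.
    """
    if rng is None:
        rng = _rng_for(params, dendrite_id, "t0")
    n = rng.poisson(params.protrusion_density_per_um * params.dendrite_length_um)
    positions = np.sort(rng.uniform(0.0, params.dendrite_length_um, size=n))
    observations = []
    for i, pos in enumerate(positions):
        cls = (
            ProtrusionClass.FILOPODIUM
            if rng.random() < params.filopodium_fraction
            else ProtrusionClass.SPINE
        )
        head, neck, length = _draw_morphometry(params, cls, rng)
        pid = f"p{i:03d}"
        observations.append(
            ProtrusionObservation(
                dendrite_id=dendrite_id,
                frame_id=f"{dendrite_id}_t0",
                protrusion_id=pid,
                arc_position_um=float(pos),
                head_width_um=head,
                neck_width_um=neck,
                length_um=length,
            )
        )
        if true_classes is not None:
            true_classes[pid] = cls
    return DendriteFrame(
        dendrite_id=dendrite_id,
        frame_id=f"{dendrite_id}_t0",
        timepoint_h=0.0,
        dendrite_length_um=params.dendrite_length_um,
        genotype=params.genotype,
        age_weeks=params.age_weeks,
        observations=observations,
    )


def _dendrite_event_probs(
    params: SimulationParams, rng: np.random.Generator
) -> dict[str, float]:
    """Per-dendrite event probabilities, optionally Beta-dispersed.

    With ``rate_dispersion`` d > 0, each probability p is replaced by a
    Beta draw with mean p and variance d·p·(1−p), modelling animal-level
    heterogeneity between dendrites; d = 0 keeps the probabilities fixed.
    """
    probs = {
        "spine_formation": params.spine_formation_prob,
        "spine_elimination": params.spine_elimination_prob,
        "filo_formation": params.filo_formation_prob,
        "filo_elimination": params.filo_elimination_prob,
    }
    d = params.rate_dispersion
    if d == 0.0:
        return probs
    k = (1.0 - d) / d
    return {
        name: (p if p in (0.0, 1.0) else float(rng.beta(p * k, (1.0 - p) * k)))
        for name, p in probs.items()
    }


def simulate_next_frame(
    frame: DendriteFrame,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    true_classes: Optional[dict[str, ProtrusionClass]] = None,
) -> tuple[DendriteFrame, GroundTruth]:
    """Simulate the second imaging session and its generating truth.

    Each frame-1 protrusion is independently eliminated with its class
    probability; survivors keep identity and morphometry and receive
    zero-mean Gaussian positional jitter (clipped to the arc).  New
    protrusions arrive with a per-class Poisson budget with mean equal to
    the class formation probability times the class count in frame 1,
    uniform positions and fresh morphometry; by default a newborn carries
    the class of the budget that created it (``nascent_filopodium_fraction``
    overrides the newborn class mixture when set).

    ``true_classes`` maps frame-1 protrusion ids to their generating
    class; when omitted, classes are recovered with the morphometric
    classifier (which agrees with the generating class for ≈99% of draws
    under the default morphometry).
    """
    if rng is None:
        rng = _rng_for(params, frame.dendrite_id, "t1")
    if true_classes is None:
        from .morphometry import classify_frame

        true_classes = classify_frame(frame)

    probs = _dendrite_event_probs(params, rng)
    length = frame.dendrite_length_um
    frame2_id = f"{frame.dendrite_id}_t1"
    observations: list[ProtrusionObservation] = []
    correspondence: dict[str, str] = {}
    eliminated: list[str] = []
    formed: list[str] = []
    gt_class: dict[str, ProtrusionClass] = dict(true_classes)

    counter = 0
    for obs in frame.observations:
        cls = true_classes[obs.protrusion_id]
        p_elim = (
            probs["spine_elimination"]
            if cls is ProtrusionClass.SPINE
            else probs["filo_elimination"]
        )
        if rng.random() < p_elim:
            eliminated.append(obs.protrusion_id)
            continue
        new_pos = obs.arc_position_um + rng.normal(0.0, params.jitter_sd_um)
        new_pos = float(np.clip(new_pos, 0.0, length))
        pid = f"q{counter:03d}"
        counter += 1
        observations.append(
            ProtrusionObservation(
                dendrite_id=frame.dendrite_id,
                frame_id=frame2_id,
                protrusion_id=pid,
                arc_position_um=new_pos,
                head_width_um=obs.head_width_um,
                neck_width_um=obs.neck_width_um,
                length_um=obs.length_um,
            )
        )
        correspondence[obs.protrusion_id] = pid
        gt_class[pid] = cls

    n_class = {
        cls: sum(1 for c in true_classes.values() if c is cls)
        for cls in ProtrusionClass
    }
    for cls in ProtrusionClass:
        p_form = (
            probs["spine_formation"]
            if cls is ProtrusionClass.SPINE
            else probs["filo_formation"]
        )
        n_new = rng.poisson(p_form * n_class[cls])
        for _ in range(n_new):
            born_cls = cls
            if params.nascent_filopodium_fraction is not None:
                born_cls = (
                    ProtrusionClass.FILOPODIUM
                    if rng.random() < params.nascent_filopodium_fraction
                    else ProtrusionClass.SPINE
                )
            head, neck, plen = _draw_morphometry(params, born_cls, rng)
            pid = f"q{counter:03d}"
            counter += 1
            observations.append(
                ProtrusionObservation(
                    dendrite_id=frame.dendrite_id,
                    frame_id=frame2_id,
                    protrusion_id=pid,
                    arc_position_um=float(rng.uniform(0.0, length)),
                    head_width_um=head,
                    neck_width_um=neck,
                    length_um=plen,
                )
            )
            formed.append(pid)
            gt_class[pid] = born_cls

    observations.sort(key=lambda o: o.arc_position_um)
    frame2 = DendriteFrame(
        dendrite_id=frame.dendrite_id,
        frame_id=frame2_id,
        timepoint_h=frame.timepoint_h + params.interval_h,
        dendrite_length_um=length,
        genotype=frame.genotype,
        age_weeks=frame.age_weeks,
        observations=observations,
    )
    truth = GroundTruth(
        correspondence=correspondence,
        formed_ids=formed,
        eliminated_ids=eliminated,
        true_class=gt_class,
    )
    return frame2, truth


@dataclass
class SimulatedDendrite:
    """One simulated dendrite: frame pair (or single frame) plus truth."""

    condition: str
    frame1: DendriteFrame
    frame2: Optional[DendriteFrame]
    ground_truth: Optional[GroundTruth]
    true_classes_frame1: dict[str, ProtrusionClass]


@dataclass
class SimulatedCohort:
    """A labelled collection of simulated dendrites across conditions."""

    dendrites: list[SimulatedDendrite]

    def frames(self) -> list[DendriteFrame]:
        out = []
        for d in self.dendrites:
            out.append(d.frame1)
            if d.frame2 is not None:
                out.append(d.frame2)
        return out

    def frame_pairs(self) -> list[tuple[DendriteFrame, DendriteFrame]]:
        return [
            (d.frame1, d.frame2) for d in self.dendrites if d.frame2 is not None
        ]

    def ground_truth_table(self) -> pd.DataFrame:
        """Sidecar truth: one row per protrusion identity event."""
        rows = []
        for d in self.dendrites:
            gt = d.ground_truth
            if gt is None:
                continue
            did = d.frame1.dendrite_id
            for a, b in sorted(gt.correspondence.items()):
                rows.append(
                    {
                        "dendrite_id": did,
                        "frame1_id": a,
                        "frame2_id": b,
                        "event": "persisting",
                        "true_class": gt.true_class[a].value,
                    }
                )
            for a in sorted(gt.eliminated_ids):
                rows.append(
                    {
                        "dendrite_id": did,
                        "frame1_id": a,
                        "frame2_id": "",
                        "event": "eliminated",
                        "true_class": gt.true_class[a].value,
                    }
                )
            for b in sorted(gt.formed_ids):
                rows.append(
                    {
                        "dendrite_id": did,
                        "frame1_id": "",
                        "frame2_id": b,
                        "event": "formed",
                        "true_class": gt.true_class[b].value,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["dendrite_id", "frame1_id", "frame2_id", "event", "true_class"],
        )


def simulate_dendrite(
    params: SimulationParams, dendrite_id: str, condition: str = "condition"
) -> SimulatedDendrite:
    """Simulate one dendrite (frame pair unless cross-sectional)."""
    true_classes: dict[str, ProtrusionClass] = {}
    rng = _rng_for(params, condition, dendrite_id)
    frame1 = simulate_initial_frame(
        params, dendrite_id, rng=rng, true_classes=true_classes
    )
    if params.cross_sectional:
        return SimulatedDendrite(condition, frame1, None, None, true_classes)
    frame2, truth = simulate_next_frame(
        frame1, params, rng=rng, true_classes=true_classes
    )
    return SimulatedDendrite(condition, frame1, frame2, truth, true_classes)


def simulate_cohort(
    conditions: Mapping[str, SimulationParams]
    | Iterable[tuple[str, SimulationParams]],
) -> SimulatedCohort:
    """Simulate every condition's dendrites; reproducible given seeds.

    ``conditions`` maps labels to :class:`SimulationParams`; each
    condition contributes ``params.n_dendrites`` dendrites.  Per-dendrite
    random substreams are derived deterministically from the condition
    seed, label and dendrite index, so partial re-runs reproduce
    identical dendrites.  Duplicate labels are an error.
    """
    pairs = list(conditions.items()) if isinstance(conditions, Mapping) else list(conditions)
    labels = [label for label, _ in pairs]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise InvalidParameterError(f"duplicate condition labels: {dupes}")
    dendrites = []
    for label, params in pairs:
        for i in range(params.n_dendrites):
            dendrite_id = f"{label}_d{i:04d}"
            dendrites.append(simulate_dendrite(params, dendrite_id, label))
    return SimulatedCohort(dendrites)


def params_to_dict(params: SimulationParams) -> dict:
    """Plain-dict form of the parameters (for configs and manifests)."""
    return dataclasses.asdict(params)
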