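import numpy as np
import pytest

from spinedyn.types import DendriteFrame, ProtrusionObservation


def make_obs(
    pid,
    pos,
    head=0.40,
    neck=0.22,
    length=0.70,
    dendrite_id="d0",
    frame_id="d0_t0",
):
    """A protrusion observation with spine-like defaults."""
    return ProtrusionObservation(
        dendrite_id=dendrite_id,
        frame_id=frame_id,
        protrusion_id=pid,
        arc_position_um=pos,
        head_width_um=head,
        neck_width_um=neck,
        length_um=length,
    )


def make_filo_obs(pid, pos, **kw):
    """A protrusion observation with filopodium-like morphometry."""
    return make_obs(pid, pos, head=0.18, neck=0.18, length=1.0, **kw)


def make_frame(
    positions,
    dendrite_id="d0",
    frame_id=None,
    timepoint_h=0.0,
    length_um=40.0,
    genotype="control",
    age_weeks=4.0,
    filo_flags=None,
):
    """Frame with spine-like protrusions at the given arc positions.

    ``filo_flags`` optionally marks which protrusions get
    filopodium-like morphometry.
    """
    frame_id = frame_id or f"{dendrite_id}_t{timepoint_h:g}"
    obs = []
    for i, pos in enumerate(positions):
        maker = (
            make_filo_obs if filo_flags and filo_flags[i] else make_obs
        )
        obs.append(
            maker(f"p{i:03d}", pos, dendrite_id=dendrite_id, frame_id=frame_id)
        )
    return DendriteFrame(
        dendrite_id=dendrite_id,
        frame_id=frame_id,
        timepoint_h=timepoint_h,
        dendrite_length_um=length_um,
        genotype=genotype,
        age_weeks=age_weeks,
        observations=obs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
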