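"""Shared fixtures: small rendered scenes and pre-trained tiny models."""

import numpy as np
import pytest

from kennelscope import depth_scene as ds
from kennelscope import synthetic as syn
from kennelscope.ssvm import BlobFeatures, StructuredBodyPartSVM

SMALL_GRID = dict(n_torso_angles=12, n_torso_lengths=3, n_head_angles=4,
                  n_tail_angles=4, n_leg_configs=3)


def annotate(dataset):
    """(BlobFeatures, GT skeleton) pairs for every frame of a dataset."""
    out = []
    for frame, gt, motion in zip(dataset.video.frames, dataset.skeletons,
                                 dataset.motions):
        blob = ds.segment_frame(frame, dataset.scene,
                                dataset.video.intrinsics)
        assert blob is not None
        out.append((BlobFeatures.from_blob(blob, motion,
                                           floor=dataset.scene.floor), gt))
    return out


@pytest.fixture(scope="session")
def stand_dataset():
    """Eight noiseless standing frames at varied poses."""
    return syn.posture_frames("stand", 8, seed=11, noise_mm=0.0)


@pytest.fixture(scope="session")
def stand_items(stand_dataset):
    return annotate(stand_dataset)


@pytest.fixture(scope="session")
def walk_dataset():
    """A 3-second straight walk at 0.5 m/s."""
    script = syn.posture_script("stand", 3.0, (1.5, 1.5), heading=0.1,
                                speed=0.5)
    return syn.render_sequence(syn.QuadrupedModel(), script, seed=5)


@pytest.fixture(scope="session")
def tiny_model(stand_items):
    """Small-grid body-part model trained on the standing frames."""
    model = StructuredBodyPartSVM(posture_class="stand", n_epochs=8,
                                  random_state=0, **SMALL_GRID)
    model.fit([f for f, _ in stand_items], [g for _, g in stand_items])
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_skeleton(rng, posture="stand"):
    """A randomly posed quadruped skeleton (world frame)."""
    model = syn.QuadrupedModel().randomised(rng, 0.2)
    x, y = rng.uniform(1.0, 2.0, size=2)
    heading = rng.uniform(-np.pi, np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    from kennelscope.skeleton import Skeleton
    segs = syn.pose_skeleton(model, x, y, heading, posture, gait_phase=phase)
    return Skeleton(segments=segs, posture=posture)
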