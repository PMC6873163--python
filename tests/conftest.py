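import numpy as np
import pytest

from synquant import (
    NeuronSkeleton,
    PipelineConfig,
    SceneParams,
    VoxelGridSpec,
    run_pipeline,
)


@pytest.fixture
def small_grid():
    return VoxelGridSpec(shape=(32, 32, 32))


def build_skeleton(nodes):
    """nodes: list of (id, (z,y,x), radius, parent, compartment)."""
    return NeuronSkeleton(
        node_ids=np.array([n[0] for n in nodes]),
        positions=np.array([n[1] for n in nodes], dtype=float),
        radii=np.array([n[2] for n in nodes], dtype=float),
        parents=np.array([n[3] for n in nodes]),
        compartments=np.array([n[4] for n in nodes], dtype=object),
    )


@pytest.fixture
def straight_apical_skeleton():
    """Soma plus one unbranched apical stem along +y."""
    return build_skeleton(
        [
            (1, (5.0, 5.0, 5.0), 2.0, -1, "soma"),
            (2, (5.0, 7.5, 5.0), 0.4, 1, "soma"),
            (3, (5.0, 10.0, 5.0), 0.4, 2, "apical"),
            (4, (5.0, 14.0, 5.0), 0.4, 3, "apical"),
        ]
    )


def ideal_round_trip_config(seed=11):
    """Ideal-optics, noise-free, distractor-free scene (~200 synapses on a
    64x256x256 stack) used for exact round-trip checks."""
    cfg = PipelineConfig()
    cfg.scene = SceneParams(
        psf_sigma=(0.0, 0.0, 0.0),
        photon_scale=None,
        read_noise=0.0,
        amplitude_sigma=0.0,
        n_distractors=0,
        marker_miss_rate=0.0,
        seed=seed,
    )
    cfg.skeleton_kwargs = dict(
        apical_lengths=(4.0, 3.5, 3.0),
        basal_lengths=(3.5, 3.0, 2.5),
        soma_radius=3.5,
    )
    return cfg


@pytest.fixture(scope="session")
def ideal_round_trip_result():
    """Shared full-pipeline run on the ideal-optics scene."""
    return run_pipeline(ideal_round_trip_config())
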