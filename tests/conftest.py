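import numpy as np
import pandas as pd
import pytest

from l5et.core_model import Connectome, Skeleton, VolumeGeometry
from l5et.synthetic import GeneratorConfig, generate_connectome


@pytest.fixture(scope="session")
def default_connectome():
    """Default-configuration synthetic connectome shared across the suite."""
    return generate_connectome(GeneratorConfig(), seed=0)


@pytest.fixture(scope="session")
def small_connectome():
    """A small connectome for I/O and round-trip tests."""
    return generate_connectome(GeneratorConfig(n_neurons=600), seed=11)


def straight_skeleton(n=11, step=10.0, compartment=2, axis=1):
    """Unbranched skeleton along one axis, root at origin."""
    xyz = np.zeros((n, 3))
    xyz[:, axis] = step * np.arange(n)
    return Skeleton(
        node_ids=np.arange(1, n + 1),
        xyz=xyz,
        radius=np.full(n, 0.5),
        compartment=np.array([1] + [compartment] * (n - 1)),
        parent=np.array([-1] + list(range(1, n))),
    )


def y_skeleton():
    """Y-shaped skeleton: trunk 1-2-3, arms 3-4-5 and 3-6-7 (10 µm edges)."""
    xyz = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, 10.0, 0.0],
            [0.0, 20.0, 0.0],
            [7.0, 27.0, 0.0],
            [14.0, 34.0, 0.0],
            [-7.0, 27.0, 0.0],
            [-14.0, 34.0, 0.0],
        ]
    )
    return Skeleton(
        node_ids=np.arange(1, 8),
        xyz=xyz,
        radius=np.full(7, 0.5),
        compartment=np.array([1, 2, 2, 2, 2, 2, 2]),
        parent=np.array([-1, 1, 2, 3, 4, 3, 6]),
    )


def build_connectome(neurons, synapses, skeletons=None, bounds=None):
    bounds = bounds if bounds is not None else [[-1000, 1000], [-1000, 1000], [-1000, 1000]]
    return Connectome(
        neurons=pd.DataFrame(neurons),
        synapses=pd.DataFrame(synapses),
        skeletons=skeletons or {},
        geometry=VolumeGeometry(bounds=np.asarray(bounds, dtype=float)),
    )


def neuron_row(nid, x=0.0, y=0.0, z=0.0, area="VISp", layer="L5",
               cell_class="excitatory", subclass="L5-IT", proof="none"):
    return dict(neuron_id=nid, x=x, y=y, z=z, area=area, layer=layer,
                cell_class=cell_class, subclass=subclass, proofread_status=proof)


def synapse_row(sid, pre, post, x=0.0, y=0.0, z=0.0, size=100,
                compartment="shaft", pre_node=1):
    return dict(synapse_id=sid, pre_id=pre, post_id=post, x=x, y=y, z=z,
                size_voxels=size, post_compartment=compartment, pre_node=pre_node)
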