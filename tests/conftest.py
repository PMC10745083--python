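import numpy as np
import pytest

import mesoconn as mc


@pytest.fixture(scope="session")
def small_brain():
    """2 majors × 2 leafs × (3,3,3) voxel blocks, mirrored hemispheres."""
    return mc.make_brain(n_major=2, leafs_per_major=2, leaf_shape_voxels=(3, 3, 3))


@pytest.fixture(scope="session")
def noisy_dataset(small_brain):
    """A normalized synthetic dataset with class structure and mild noise."""
    _, ont = small_brain
    gt = mc.sample_ground_truth(ont, n_classes=3, class_effect=1.0,
                                smoothness_scale_um=1000.0, seed=7)
    d = mc.simulate_experiments(gt, mc.dense_design(gt, 3), noise_sd=0.2, seed=8)
    return d.normalized("total_projection")


def make_experiment(ont, eid, v, voxel, y):
    """Experiment at a voxel centre with an explicit regionalized vector."""
    lattice = ont.lattice
    centroid = (np.asarray(voxel, dtype=float) + 0.5) * lattice.spacing_um
    return mc.Experiment(id=eid, cell_class=v, centroid_um=centroid,
                         regionalized=np.asarray(y, dtype=float))
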