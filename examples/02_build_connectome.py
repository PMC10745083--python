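"""Build class-specific connectivity matrices and inspect derived products.

Fits the expected-loss (EL) estimator on simulated data, assembles the
class × source × target connectivity tensor (strength variant), averages over
classes ignoring missing rows, and lists the top-decile targets of one source.
Missing rows mark (class, source) pairs with no injection centroid — they are
distinct from zero connectivity.
"""

import numpy as np

import mesoconn as mc
from mesoconn.connectome import cre_average_matrix, normalize_connectivity, top_targets

_, ontology = mc.make_brain(n_major=2, leafs_per_major=2, leaf_shape_voxels=(3, 3, 3))
gt = mc.sample_ground_truth(ontology, n_classes=3, class_effect=1.0, seed=11)
# leave one (class, leaf) cell empty so a missing row is visible
design = [(v, leaf, 3) for v in gt.classes for leaf in ontology.source_leafs
          if not (v == "C1" and leaf == ontology.source_leafs[0])]
dataset = mc.simulate_experiments(gt, design, noise_sd=0.2, seed=12).normalized("total_projection")

model = mc.select_hyperparameters("el", dataset, sigma_x_grid=(100.0, 300.0),
                                  sigma_c_grid=(0.1, 1.0), alpha_grid=(0.0, 0.5, 1.0))
tensor = mc.build_tensor(model, dataset, ontology)

for v in tensor.classes:
    C = tensor.matrix(v)
    n_missing = int(np.isnan(C).all(axis=1).sum())
    print(f"class {v}: strength matrix {C.shape}, {n_missing} missing source row(s)")

avg = cre_average_matrix(tensor)
print(f"class-averaged matrix has {int(np.isnan(avg).all(axis=1).sum())} missing rows "
      "(a row is filled whenever any class covers it)")

CN = normalize_connectivity(tensor.matrix("wt"), ontology, "normalized")
labels = ontology.target_labels()
src = ontology.acronym(ontology.source_leafs[0])
top = top_targets(CN[0], percentile=90.0)
print(f"top-decile targets of {src} (wild type): {[labels[t] for t in top]}")
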