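"""Nested-CV classification of a synthetic cohort plus LRP explanation.

Trains the compact conv net on energy feature maps of a 8+8 cohort with a
strong smoothness contrast, reports the pooled cross-validated metrics, and
explains one prediction as a voxel relevance heatmap.
"""

import numpy as np

from braintexture.classify import nested_cv_train
from braintexture.quantize import equalize_histogram
from braintexture.relevance import lrp_relevance, mean_relevance
from braintexture.synthetic import SyntheticCohortSpec, generate_cohort
from braintexture.texture import texture_feature_maps

spec = SyntheticCohortSpec(
    n_per_class=8, volume_shape=(32, 32, 32),
    smoothness_by_class={"VisDys-": 0.0, "VisDys+": 2.5},
    folding_amplitude_by_class={"VisDys-": 2.0, "VisDys+": 2.0},
    noise_sd=0.0, seed=1)
cohort = generate_cohort(spec)
maps = {}
for sid, vol in cohort.volumes.items():
    q = equalize_histogram(vol, 16)
    maps[sid] = texture_feature_maps(q, cube_size=5, stride=1,
                                     features=("energy",))["energy"]
labels = cohort.labels.to_dict()

result = nested_cv_train(maps, labels, outer_k=4, inner_k=2,
                         hyper_grid={"lr": [3e-3, 1e-2]}, seed=0, epochs=60)
m = result.pooled_metrics
print(f"pooled nested-CV metrics over {len(maps)} subjects:")
print(f"  balanced accuracy {m.balanced_accuracy:.2f}%   "
      f"sensitivity {m.sensitivity:.2f}%   specificity {m.specificity:.2f}%")
print(f"  winner hyperparameters: {result.selected_hyperparams}")

sid = "S001"
heatmap = lrp_relevance(result.winner_model, maps[sid], subject_id=sid)
mask = maps[sid].valid_mask
print(f"\nLRP heatmap for {sid} "
      f"(predicted class {heatmap.predicted_class}):")
print(f"  output score {heatmap.output_score:.4f}, "
      f"relevance sum {heatmap.relevance.sum():.4f} "
      "(conservation: the two match up to the epsilon stabilizer)")
print(f"  mean brain relevance {mean_relevance(heatmap, mask):.3e} — the "
      "scalar later correlated\n  with clinical scores; positive relevance "
      "marks voxels whose texture supported the decision.")
assert np.isfinite(heatmap.relevance).all()
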