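"""Generate a small synthetic cohort and inspect its structure.

Creates two classes of brain-like volumes (VisDys+ with smoother tissue
boundaries, VisDys- with sharper ones) plus a clinical table whose scores
are rank-coupled to a latent severity, and prints what was made.
"""

import numpy as np

from braintexture.synthetic import SyntheticCohortSpec, generate_cohort

spec = SyntheticCohortSpec(
    n_per_class=4,
    volume_shape=(32, 32, 32),
    smoothness_by_class={"VisDys-": 0.5, "VisDys+": 2.0},
    noise_sd=0.05,
    seed=42,
)
cohort = generate_cohort(spec)

print(f"{len(cohort.volumes)} volumes of shape {spec.volume_shape}")
vol = cohort.volumes["S001"]
print(f"S001: brain fills {vol.brain_mask.mean():.0%} of the volume, "
      f"intensities in [{vol.voxels.min():.2f}, {vol.voxels.max():.2f}]")
print("\nClinical table (baseline rows):")
t0 = cohort.clinical[cohort.clinical["timepoint"] == "T0"]
print(t0.round(1).to_string(index=False))
print("\nThe visdys score was generated with a target Spearman correlation "
      "of 0.6 to the latent severity;\nVisDys+ subjects sit higher on that "
      "latent, so their scores trend higher:")
for cls in ("VisDys-", "VisDys+"):
    sel = t0[t0["visdys_label"] == cls]
    print(f"  mean visdys score {cls}: {sel['visdys'].mean():.1f}")
assert np.isfinite(t0["visdys"]).all()
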