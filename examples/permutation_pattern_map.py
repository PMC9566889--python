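"""Permutation inference on the classifier's voxel weight map.

Trains on a planted-effect cohort, retrains the model on 500 label-shuffled
cohorts to build the per-voxel null, thresholds the signed weight map at
p < 0.05, and compares the recovered pattern with the planted spheres (Dice
overlap; sign agreement says whether recovered hyper/hypo directions match
what was planted). The pattern volume is written as NIfTI next to this
script's working directory.
"""

import numpy as np

import petstratify as ps
from petstratify.synthetic import effect_field, planted_voxels

cfg = ps.SimulationConfig(n_per_class=(25, 25), noise_sd=0.1, seed=7)
cohort = ps.simulate_cohort(cfg)
features = ps.vectorize(cohort)

res = ps.permutation_null(features, n_permutations=500, seed=13)
pmap = ps.voxel_pvalues(res.true_model, res.exceedance_counts, res.n_effective,
                        alpha=0.05)
pattern = ps.threshold_pattern(pmap, res.true_model, mask=cohort.mask)

planted = planted_voxels(cfg, cohort.mask)
recovered = pattern.data != 0
dice = 2 * np.sum(recovered & planted) / (recovered.sum() + planted.sum())
sel = recovered & planted
signs = np.mean(np.sign(pattern.data[sel]) == np.sign(effect_field(cfg, cohort.mask)[sel]))
print(f"significant voxels at p<0.05: {int(recovered.sum())} of {cohort.mask.n_voxels}")
print(f"Dice overlap with planted regions: {dice:.3f} (1 = perfect recovery)")
print(f"sign agreement at recovered planted voxels: {signs:.3f}")

ps.write_volume(pattern, "pattern.nii.gz")
print("signed pattern map written to pattern.nii.gz "
      "(positive = hypermetabolism predictive of conversion)")
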