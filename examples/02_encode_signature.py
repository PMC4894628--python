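"""Encode one slice into its Fisher-vector signature, step by step.

Shows the stages: ROI augmentation by dilation, intensity-order partition,
raw-patch extraction with PCA reduction, per-subregion Fisher vectors, and
power + L2 normalization of the concatenated signature.
"""

import numpy as np

from tumorcbir import (
    PhantomParams, PipelineConfig, augment_tumor_region, build_signature,
    divide_by_intensity_order, fit_feature_models, generate_cohort,
)

cohort = generate_cohort(PhantomParams(n_patients=12, seed=0))
config = PipelineConfig.ci_profile(seed=0)
case = cohort.cases[0]

roi = augment_tumor_region(case.tumor_mask, config.R)
print(f"tumor {case.tumor_mask.sum()} px -> ROI {roi.pixel_count} px "
      f"after dilation with radius R={config.R}")

partition = divide_by_intensity_order(case.image, roi, config.N)
print(f"intensity-order partition into N={config.N} subregions of sizes "
      f"{partition.sizes}")

models = fit_feature_models(cohort.cases, config)
print(f"PCA: {config.W}x{config.W} patches ({config.W**2} dims) -> "
      f"{models.pca.d} dims ({models.pca.explained_fraction:.1%} variance)")

sig = build_signature(case, config, models.pca, models.vocabulary)
print(f"signature length 2*d*K*N = 2*{models.pca.d}*{config.K}*{config.N} "
      f"= {sig.values.size}, L2 norm = {np.linalg.norm(sig.values):.6f}")
# The signature is the image's fixed-length representation: the gradient of
# each subregion's patch log-likelihood under the GMM vocabulary.
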