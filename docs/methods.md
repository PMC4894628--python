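# Methods

This note documents the models, numerical choices and limitations behind
`tumorcbir`, at the level a maintainer or reviewer needs to interpret what
the tests and the acceptance script do and do not establish.

## Pipeline model and assumptions

The retrieval representation assumes that (i) tumor texture and
peri-tumoral context together identify the tumor class, (ii) raw intensity
patches are more informative than gradient descriptors in brain MRI, and
(iii) a diagonal-covariance GMM over PCA-decorrelated patches is an
adequate generative vocabulary. No intensity normalization is applied to
slices before patch extraction; users mixing scanners should be aware that
the pipeline inherits whatever intensity scale the data carries.

Stages and their contracts:

- **ROI augmentation** — a pixel is in the ROI iff its Euclidean distance
  to a tumor pixel is ≤ R. The structuring element is the discrete disk
  {(di,dj): di²+dj² ≤ R²}; results are clipped at image borders (no
  padding). R is in pixels; R=0 means the raw mask.
- **Intensity-order partition** — pixels sorted ascending by intensity,
  ties broken by row-major pixel index (a stable sort), split into N
  consecutive blocks; with |ROI| = qN + r the first r blocks get q+1
  pixels. Any fixed tie/remainder rule would do; these make the partition
  reproducible bit-for-bit.
- **Patches and PCA** — W×W windows at every subregion pixel, border
  windows completed by edge replication so the descriptor count always
  equals the subregion size. PCA keeps the smallest d whose cumulative
  explained variance reaches the target (0.99 default; 0.95 in the reduced
  profile); component signs are fixed so each row's largest-magnitude
  entry is positive. No whitening — the GMM's diagonal covariances absorb
  per-dimension scale. The PCA/GMM samples are drawn uniformly over
  training-set ROI pixels only, with seeds derived deterministically from
  the config seed (`stage_seed`), so test-fold pixels can never reach the
  fitted models; a canary test corrupts held-out images and asserts the
  fitted models are unchanged.
- **Fisher vectors** — mean- and variance-gradient blocks only (no
  mixture-weight block), normalized by the diagonal closed-form Fisher
  information approximation: 1/(T√w_k) for the mean block and 1/(T√(2w_k))
  for the variance block. The analytic encoder is validated against a
  central-difference numerical gradient of the sample log-likelihood
  (step 1e-5) to relative error ≲ 1e-9. Posteriors are computed in the
  log domain; responsibilities below 1e-12 are truncated to zero and
  renormalized. An empty patch set encodes to the zero vector with a
  warning. Power (α = 0.5) + L2 normalization is applied once, to the
  concatenated signature; BoW signatures are plain L2-normalized so both
  encoders feed the same metrics.
- **GMM fitting** — EM with k-means initialization, tolerance 1e-6, at
  most 200 iterations (scikit-learn's `GaussianMixture`). The variance
  floor is 1e-6 × the mean per-dimension variance of the training sample
  (a scalar floor; the per-dimension variant is not expressible through
  `reg_covar`). On small noisy samples EM may hit the iteration cap; the
  vocabulary is still usable and the warning is benign.
- **CFML** — the scatters M_S and M_D are the exact all-pairs averages,
  computed via per-class sum identities rather than O(n²) loops and
  validated against a brute-force double loop. The projection solves
  M_D v = η (M_S + λI) v (scipy `eigh`), keeping the D largest-η
  eigenvectors, which `eigh` returns B-orthonormal so L(M_S+λI)Lᵀ = I
  holds to machine precision. λ defaults to 1.5e-4, applied as a bare
  constant (not trace-scaled). The regularized form is used throughout;
  λ = 0 with degenerate data raises with advice to regularize.
- **Evaluation** — patients are shuffled with the CV seed and dealt
  round-robin into 5 folds. Every held-out slice queries the training
  database; rankings break exact distance ties by database index. AP uses
  the full ranking. prec@n is evaluated at min(n, database size); queries
  whose class is absent from the database are skipped and counted.
  Per-class mAP averages the APs of queries of that class, so the
  query-count-weighted per-class values reproduce the overall mAP exactly.

## Synthetic phantoms: what they emulate, and what not

Each phantom slice is a 64×64 image containing a randomly deformed
star-shaped tumor (radius 8–13 px, low-order radial harmonics) filled with
class-specific smoothed-noise texture (class-dependent mean, variance and
correlation length), a peri-tumoral annulus of class-specific mean
intensity and width (so ROI augmentation genuinely adds class information),
and background noise. Patients own 2–3 slices of one class and share a
N(0, 0.03) intensity offset, which is what makes patient-stratified CV
strictly harder than slice-random CV. A single `separability` scalar
multiplies all between-class parameter differences; at 0 every class is
drawn from one distribution and labels are exchangeable by construction.
One seeded generator drawn in a fixed order makes a seed fully determine
the cohort.

The phantoms deliberately do not emulate anatomy, MRI physics, partial
volume, bias fields, inter-scanner intensity shifts, 3-D slice coherence,
or class imbalance. Passing the retrieval-recovery tests therefore shows
that the pipeline recovers class structure that resides in tumor texture
and peri-tumoral context under patient-level nuisance variation — not that
it attains any particular accuracy on clinical data.

The reduced profile used with phantoms (`PipelineConfig.ci_profile`):
R=6, N=4, W=5, K=8, D=2, PCA target 0.95, sample sizes 30k/20k. These are
scaled to the 64-px phantom geometry (R=24 would swallow most of a 64-px
image) and were chosen once, as the package's study conditions, to keep a
full 5-fold evaluation near ten seconds of CPU.

## The permutation null of a learned metric

With labels permuted (at patient level) and the whole pipeline re-run, the
Euclidean-distance ranking scores indistinguishably from the empirical
class-prior chance baseline (random-ranking mAP ≈ 0.35 for three balanced
classes) — the evaluation harness leaks no label information. The CFML
pipeline, however, scores ≈ 0.46 under the same permuted labels. This is
not leakage: with signature dimension F ≈ 700 far above the ~100 training
signatures, the projection can organize the training database into blocks
of any labeling whatsoever. AP of a ranking in which the relevant items
form one contiguous block among three equal blocks averages roughly
(1 + 0.38 + 0.19)/3 ≈ 0.52 regardless of label information, so the correct
reference for the learned-metric pipeline is the permutation-null mean
itself, simulated with independent permutation seeds — which is what the
test asserts, alongside the class-prior check on the label-independent
ranking. The same F ≫ n regime holds for full-scale signatures, so this
property is intrinsic to the method, and a reminder that mAP gaps should
always be judged against a permutation null rather than a naive prior.

## Numerical conventions

Intensities are handled as float64 internally regardless of stored dtype;
the reader never rescales. Coordinates are row-major and 0-based. All
eigenvector-valued outputs (PCA components, CFML rows) fix signs by making
the largest-magnitude entry positive. The global seed fans out to
per-stage seeds via a CRC-based derivation so stages are independently
reproducible. Identical config + seed + data reproduce reports
bit-identically on one platform; exact bit-reproducibility across BLAS
builds is not promised.

## Known limitations

2-D slices only; masks are inputs (no segmentation); no DICOM/NIfTI
ingestion; no intensity standardization; no approximate-nearest-neighbor
indexing; AP is undefined (and the query skipped) when the database lacks
the query's class.
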