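# Methods

## The classification problem and model

A far-UV CD spectrum reports protein secondary structure as a per-residue
signal over ~175–250 nm. The package classifies a spectrum into one of two
classes — ORDERED or DISORDERED — from the CD values at two or three
wavelengths only. The flagship model is a k-nearest-neighbor classifier with
cosine distance, k = 10: the feature vector of a query is compared to a
labeled reference collection by the angle between vectors seen from the
origin, and the majority label among the 10 nearest references is returned
together with the vote fraction.

The cosine metric is the scientific point: a protein-concentration error
rescales the whole spectrum by a positive factor, which changes the length of
the feature vector but not its direction. Cosine-KNN verdicts are therefore
exactly invariant under rescaling, whereas margin- or likelihood-based
models (SVMs, discriminants, trees on raw amplitudes) are not. For IDPs,
whose unusual amino-acid composition makes concentration determination
unreliable (errors of ~20% are routine), this invariance matters more than a
marginal accuracy gain on perfectly normalized data.

Assumptions: the binary label refers to *global* disorder — a disordered
region in an otherwise ordered protein is not detectable from three
wavelengths; "random coil" and "premolten globule" flavors of disorder are
not distinguished; the reference collection is trusted as labeled ground
truth and the query is not excluded from it if present.

## Units

All classification runs in mean-residue delta-epsilon (Δε, M⁻¹cm⁻¹);
mean residue ellipticity converts as MRE = 3298.2 × Δε (the standard
factor). Loaders require an explicit unit flag and never guess, because
digitized literature spectra circulate in both conventions. Off-grid
wavelengths are linearly interpolated (reference data are on 1 nm grids, so
the interpolation error is negligible); a query within 10⁻⁶ nm of a grid
point returns the stored value exactly. Duplicate wavelengths in a file are
an error rather than being averaged, since they usually indicate a
concatenated or corrupted export.

## Reference subsets and the wavelength cutoff

Measured spectra differ in their lowest wavelength ("cutoff"). For a study
at cutoff c with wavelength tuple T, the usable subset contains exactly the
spectra whose lowest measured wavelength is ≤ c *and* whose range covers
every member of T. This makes subsets monotone in c and means different
tuples are scored on different n; reported results carry the per-class
counts to keep that visible. Subsets may legally be empty or single-class;
cross-validation consumers raise `InsufficientDataError` when a class has
fewer than 2 members.

## The screened classifier family

Thirteen variants are screened behind one train/predict contract: simple and
medium decision trees (Gini impurity, ≤ 4 and ≤ 20 leaves), linear and RBF
SVMs, Euclidean KNN with k = 1/10/100, squared-inverse-distance weighted
KNN (k = 10), cosine KNN (k = 10), and Gaussian discriminants with pooled
(linear) or per-class (quadratic) covariance, each also in a
diagonal-covariance restriction. Deterministic conventions, chosen where a
toolbox would silently pick one:

- KNN vote ties (possible with even k) are broken by the label of the single
  nearest neighbor; equidistant neighbors at the k-th rank enter in stable
  training-index order; k is clamped to the training size.
- Weighted KNN with an exact-match neighbor (distance 0): that neighbor's
  class wins outright, the limit of 1/d² weighting.
- KNN families act on raw Δε features (distances are the physics); SVM and
  discriminant families standardize each feature to the training mean and
  variance, mirroring common toolbox defaults (configurable).
- The RBF kernel scale defaults to the median pairwise training distance
  ("median heuristic") and the margin penalty to 1; both are config-exposed,
  since published error tables produced with unnamed toolbox defaults cannot
  be reproduced exactly without knowing them.
- Discriminant covariances use n−K (pooled) or n_c−1 (per-class) denominators
  with empirical class priors; singular covariances are ridged by
  10⁻⁹·trace/dim on the diagonal.

Trees and SVMs delegate to scikit-learn (`DecisionTreeClassifier`, `SVC`)
behind this surface; the KNN variants and Gaussian discriminants are
implemented in-package so the tie-break and covariance conventions above
hold exactly, with scikit-learn's KNN/LDA/QDA serving as independent
cross-checks in the test suite.

## Model selection

Candidate features are all increasing integer wavelength pairs/triplets in
175–250 nm with pairwise gaps ≥ 3 nm (2,701 pairs, 59,640 triplets); closer
wavelengths carry nearly redundant information. Every (classifier, tuple)
combination is scored by leave-one-out cross-validation: each retained
spectrum is predicted by a model trained on all the others; misclassified
spectra are summed and divided by the class totals, giving per-class errors
whose count-weighted mean is the global error (an exact identity, asserted
everywhere). One spectrum — not one protein — is left out, so sequence
variants measured separately count separately.

Ranking follows: global error ascending, then disordered-class error
ascending (missing an IDP is the costlier mistake), then preference for
higher wavelengths, operationalized as two descending tie-breaks (largest
smallest-member first, then lexicographically larger tuple first). The
robustness analyses are deliberately *not* folded into the automatic
ranking; they are reported alongside the top candidates, since a scalar
combination of accuracy and robustness would be arbitrary.

For KNN families the LOOCV loop reuses distances against the full feature
matrix with the self-distance masked — provably identical to naive
refitting (and tested as such) because removing a point only removes it from
the candidate-neighbor pool. This is what makes the 59,640-triplet ×
LOOCV-at-n≈160 search run in a couple of minutes on one CPU.

## Robustness analyses

*Concentration rescaling*: each held-out feature row is multiplied by a
factor (default grid 0.5–2.0 in steps of 0.05, 31 points including 1.0;
only the range is scientifically prescribed, the step is a resolution
choice) before prediction, training rows untouched — emulating a mis-assumed
concentration of the test sample against a correctly normalized reference
set. The factor-1 entry equals the plain LOOCV result exactly; cosine-KNN
curves are exactly flat.

*Experimental noise*: i.i.d. Gaussian noise (μ = 0, σ in Δε units; the
studied levels are 0.05 and 0.1 M⁻¹cm⁻¹) is added to the held-out feature
values and the LOOCV errors averaged over 1,000 Monte Carlo repetitions.
Noise is injected at the tuple wavelengths only: the classifier consumes
nothing else, so this is equivalent at the classifier interface to noising
the whole spectrum. Per-repetition streams are spawned from one root
`SeedSequence`, so results are bit-reproducible and extending the number of
repetitions never reshuffles earlier ones; σ = 0 reproduces the noiseless
result exactly in every repetition. The spread across repetitions (standard
deviation) is reported alongside the mean. Correlated (wavelength-smooth)
noise models are out of scope.

## Triplet recommendation rule

The frontend selects the feature triplet from the query's own lowest
measured wavelength: ≤ 197 nm → 197-206-233 nm; (197, 212] nm →
212-217-225 nm; above 212 nm no recommended triplet is covered and the
query is rejected. The low triplet is preferred when both are available
(lower error, more robust to noise than triplets with adjacent members such
as 214-218-232 nm, whose two close wavelengths double-count the same noisy
band); a flag forces the high triplet for absorbing-buffer comparisons. The
reference subset used is the triplet-covering subset at the triplet's first
wavelength, and at least 10 references must cover it (k = 10 needs that many
meaningful neighbors).

## Synthetic data: what it emulates and what it does not

The generator emulates the two classes as sums of Gaussian bands in Δε:
coil (deep ~200 nm minimum, weak 222 nm signal), helix-rich (positive
~192 nm, minima at 208/222 nm), sheet-rich (positive ~196 nm, minimum
~217 nm), and twisted-β confounders that share the coil's deep ~200 nm
minimum and differ mainly in 210–230 nm curvature — deliberately close to
the coil class so the benchmark contains the confusion that motivates the
method, including visible sensitivity to σ = 0.05–0.1 noise. Default set
size is 60 ordered / 40 disordered (~3:2, echoing the class imbalance of
curated reference collections); amplitude jitter is lognormal with σ = 0.15,
modeling the multiplicative ~15–20% concentration error, and per-point
Gaussian noise defaults to 0.02 Δε (a good synchrotron-quality baseline).

Band parameters are package constants chosen to satisfy the assertable shape
constraints; they are not fits to measured spectra. Passing tests on this
generator therefore demonstrate the machinery's correctness and the
geometric properties (scale invariance, noise degradation, separability by
construction) — not field accuracy on real proteins, which depends on the
breadth and quality of a real labeled reference collection. Real spectra
also carry baseline errors, wavelength-correlated noise and genuine
conformational diversity the four templates do not span.

## Problem sizes and numerical choices

The test suite and the acceptance script run LOOCV at n = 24–160, the full
59,640-triplet search at n = 160, and noise Monte Carlos at 100–1,000
repetitions — sizes at which every quantity is stable to well below the
asserted tolerances. Distances and votes are double precision throughout;
determinism is guaranteed by fixed seeds for anything stochastic and by the
stable tie-break rules above. Degenerate inputs fail loudly: zero vectors
under the cosine metric, single-class training sets, queries outside the
measured range, and spectra with cutoffs above 212 nm each raise a dedicated
error type.

## Known limitations

- Binary, global verdicts only: no disordered-region localization, no
  secondary-structure fractions, no molten-globule class.
- Published error-table values can only be reproduced against the published
  labeled reference collection, which cannot be bundled; the loaders accept
  it as a manifest CSV when available.
- SVM rows of published comparisons are sensitive to unrecorded toolbox
  hyperparameters (kernel scale, margin penalty); defaults here are the
  median heuristic and C = 1, both configurable.
- The noise model is uncorrelated across wavelengths; instrument noise is
  smoother in practice.
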