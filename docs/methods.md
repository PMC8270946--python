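# Methods

## The model

`imanifold` estimates the low-dimensional *intrinsic manifold* underlying
parcellated BOLD dynamics and decodes brain states (wakefulness and
non-REM sleep stages) on it. The pipeline, per subject:

1. **Band-pass filtering.** Each region's series is filtered to the
   ultraslow band, 0.04–0.07 Hz, with a sixth-order Butterworth filter
   applied forward–backward (`sosfiltfilt`). Zero-phase filtering is
   essential: any group delay would bias the instantaneous phases that
   everything downstream consumes. "Order 6" refers to the designed
   filter before the bidirectional pass. The filter is realised in
   second-order sections for numerical stability at the very low
   normalised frequencies involved (band edges ≈ 0.17–0.29 of Nyquist at
   TR = 2.08 s).

2. **Instantaneous phase.** Each filtered region is mean-centred and its
   analytic signal computed with the Hilbert transform; the phase is
   wrapped to (−π, π]. The construction assumes narrowband input, so the
   function warns when called on series without band metadata, and
   refuses constant regions (phase undefined).

3. **Coherence states and the CCD matrix.** At TR *t* the coherence
   vector V(t) holds cos(θᵢ(t) − θⱼ(t)) for all region pairs i < j
   (upper triangle, row-major; the constant diagonal is excluded since
   it only rescales norms). The coherence connectivity dynamics matrix
   is the cosine similarity between coherence vectors,
   CCD(tᵢ, tⱼ) = V(tᵢ)·V(tⱼ)/(|V(tᵢ)||V(tⱼ)|). No temporal windowing is
   involved; each TR contributes one state.

4. **Graph construction (RMST).** The similarity is converted to a
   distance d = 1 − CCD and sparsified with a relaxed minimum spanning
   tree: starting from the MST (Kruskal, deterministic lexicographic
   (weight, i, j) tie-break), the pair (i, j) is added as an edge when

       mw_ij + γ (dᵢᵏ + dⱼᵏ) > d_ij,

   with mw_ij the largest edge weight on the MST path i→j, dᵢᵏ node i's
   distance to its k-th nearest neighbour (k = 1 by default), γ = 3.
   Candidates are examined in ascending distance and each node accepts
   at most kₙ = 5 relaxation additions on top of its (mandatory) MST
   degree; MST edges do not count toward the cap because connectivity
   cannot be budgeted away. γ = 0 reduces exactly to the MST. The MST
   path maxima are computed by replaying Kruskal's merges in ascending
   edge order, which yields all pairs in O(T²).

5. **Laplacian eigenmaps.** The combinatorial Laplacian L = Deg − A of
   the RMST graph (binary adjacency by default; similarity weights
   1 − d optional) is diagonalised and the eigenvectors of the d
   smallest non-trivial eigenvalues are the manifold coordinates
   (d = 7 by default). Eigenvector signs are fixed by making each
   column's largest-magnitude entry positive so runs are reproducible.
   Dense `eigh` is used up to T = 2000 nodes, a shift-invert sparse
   solver above. A PCA baseline embeds the filtered signal directly
   (timepoints as observations, regions as features).

6. **Group alignment.** Per stage, the embedded timepoints with minimum
   and maximum Euclidean norm are landmarks (ties broken by the
   earliest TR). A full Procrustes fit (orthogonal transform with
   reflections allowed — eigenvector sign/axis ambiguity makes
   reflections physically meaningless — plus isotropic scale and
   translation) maps each subject's landmarks onto a reference subject
   (index 0 by default; an iterative generalized-Procrustes mode is
   available). The fitted transform is applied to all timepoints.

7. **Decoding.** Linear SVMs only (C = 1): nonlinearity is supposed to
   live in the embedding, so linear separability on the manifold is the
   quantity of interest. Pairwise comparisons use per-stage stratified
   10-fold CV (each stage split into 10 parts; fold f tests part f of
   every stage). Multiclass uses K one-vs-all SVMs whose training
   decision scores are Platt-calibrated (a logistic fit on the scores);
   the argmax posterior wins. Accuracy is always correctly-classified
   timepoints over tested timepoints (trace/total of the confusion
   matrix). Group decoding is leave-one-subject-out on the aligned
   embedding. When mean accuracies over m pairwise comparisons are
   reported, their pooled uncertainty is (1/m)·√(Σ eᵢ²) over the
   per-comparison across-subject SDs.

8. **Significance.** The null model is the phase-randomized surrogate:
   every positive frequency bin of the real FFT receives one
   Uniform(0, 2π) phase shift shared by all regions (DC untouched; for
   even-length series the Nyquist bin gets a random sign flip so the
   inverse transform stays real). This preserves each region's amplitude
   spectrum *and* all between-region cross-spectral phase relations,
   destroying only the time-locking of coupling regimes to the label
   track — exactly the null needed to show that manifold clustering is
   not a filtering artefact. For each of N_perm surrogates the *entire*
   pipeline (filter → phase → CCD → RMST → eigenmaps → SVM) is re-run;
   the Monte-Carlo p-value is (#{a < a_perm} + 1)/(N_perm + 1), ties
   favouring the observed accuracy. Multiple comparisons are corrected
   with Benjamini–Hochberg FDR; distribution comparisons use the
   two-sided Wilcoxon rank-sum test (exact for ≤ 10 untied samples per
   group, tie-corrected normal approximation otherwise).

9. **ROC.** Along a single embedding dimension, thresholds sweep all
   midpoints between consecutive unique coordinates (plus ±∞), giving a
   monotone ROC curve integrated by the trapezoid rule; the orientation
   giving AUC ≥ 0.5 is chosen and recorded. A scan over the first
   dimensions returns the best single dimension (lowest index on ties).

10. **Intrinsic dimension.** Decoding accuracy is measured per embedding
    dimension (Laplacian eigenvectors are nested, so one eigen-solve at
    the largest dimension serves the whole sweep, with per-fold
    accuracies as samples). The estimate d\* is the smallest dimension
    such that no larger dimension improves accuracy significantly
    (rank-sum tests, FDR-corrected at α = 0.05). If accuracy keeps
    rising to the last dimension scanned, that dimension is returned
    with an explicit no-plateau flag.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| band | 0.04–0.07 Hz | ultraslow BOLD band carrying the coherence signal |
| filter order | 6 | Butterworth design order (before the forward–backward pass) |
| γ | 3 | RMST relaxation strength; 0 = plain MST |
| kₙ | 5 | max relaxation-added neighbours per node |
| k (local scale) | 1 | which nearest-neighbour distance enters the relaxation |
| d | 7 | embedding dimension |
| C | 1 | linear-SVM regularisation (no tuning by design) |
| folds | 10 | per-stage stratified cross-validation |
| N_perm | 1000 | surrogates for the Monte-Carlo p (tests use 99) |
| α | 0.05 | FDR level |

Fold assignment is random (seeded) by default; a `contiguous` scheme
keeps each stage's TRs in temporal order. For *significance testing* the
contiguous scheme is the right choice: band-pass filtering leaves ~10 TRs
of autocorrelation, and random folds place temporally adjacent (hence
correlated) TRs on both sides of the train/test split, lifting the
surrogate null to ~0.65 instead of ~0.5 in 1-vs-1 problems. The pipeline
default remains random because contiguous folds are pessimistic for the
observed accuracy; the acceptance runs use contiguous folds wherever a
null distribution is involved.

## The synthetic generator

No public dataset accompanies the method, so the package ships a
generator that emulates exactly the structure the pipeline detects:

- **Hypnogram.** Stage runs have geometric (memoryless) dwell times with
  mean 100 TRs (~3.5 min at TR = 2.08 s, matching multi-minute real NREM
  bouts). The stage *sequence* cycles through seeded random permutations
  of the stage set, like a sleep cycle; this also guarantees every stage
  appears once the track holds at least n_stages runs.
- **Dynamics.** A stage-switching Kuramoto model: each region is an
  oscillator with a natural frequency drawn in 0.04–0.07 Hz; within the
  active stage's coupling template, regions pull each other's phases
  together (Euler integration at TR/10; phase noise 0.05 rad/√s). The
  observation is cos(θ) plus white noise (SD 0.1).
- **Templates.** Each stage partitions regions into equal blocks by a
  seeded permutation, with row-normalised within-block coupling (gain
  K = 2 rad/s, roughly ten times the natural-frequency spread, i.e. well
  above the synchronization threshold). By default the block count
  descends from n_stages (fragmented "Awake") to 1 (globally coupled
  deepest stage), mirroring the increase of global BOLD synchrony with
  sleep depth.

What the generator does **not** emulate: hemodynamic convolution,
scanner/physiological noise spectra, REM, gradual stage transitions,
within-stage microstructure, or inter-subject variability in coupling
topology (cohort subjects share templates and differ only by seed).
Passing tests therefore show the pipeline recovers planted
phase-coupling structure under realistic sampling — not that it decodes
real sleep.

## Numerical choices

- Distances clipped to [0, 2]; CCD symmetrised and its diagonal forced
  to exactly 1 before graph construction.
- MST ties broken lexicographically on (weight, i, j); RMST candidates
  ordered by (distance, i, j). Both orders are part of the contract and
  covered by brute-force oracle tests.
- Eigen-solve: `scipy.linalg.eigh` with an index subset for T ≤ 2000;
  `eigsh` with shift σ = −10⁻⁶ above. A second eigenvalue below 10⁻⁸
  raises (disconnected graph — impossible for RMST output by
  construction).
- Procrustes: SVD of the centred cross-covariance; scale
  Σσ/‖X_src‖²; degenerate (coincident) landmark sets raise.
- Surrogate FFTs use the real FFT, which enforces conjugate symmetry by
  construction.

## Known limitations

- **Group alignment across realizations.** Spectral embeddings of
  *different* subjects are not, in general, related by a similarity
  transform; with only two norm-extremal landmarks per stage the
  Procrustes fit leaves substantial residual on independently simulated
  subjects, and synthetic LOSO accuracy (~50–60% for four balanced
  stages, chance 25%) sits well below within-subject accuracy (~92%).
  The controlled case — subjects that are exact rotations/scalings of
  one embedding — realigns to machine precision and LOSO then equals
  pooled CV; the gap on free realizations is a property of the minimal
  landmark scheme, kept as specified.
- Timepoints near stage transitions are intrinsically ambiguous: the
  band-pass impulse response (~1/0.03 Hz ≈ 16 TRs) mixes the coherence
  signatures of adjacent stages, and essentially all decoding errors on
  synthetic data fall within ~10 TRs of a transition.
- The intrinsic-dimension estimate on the default synthetic conditions
  plateaus around 2–3: the planted regimes are low-dimensional by
  construction, so the estimator is exercised, not the specific value 7.
- The full surrogate test re-runs the entire pipeline per surrogate and
  scales accordingly (~1 s per surrogate at T = 400, N = 20 on one
  core); the problem sizes used in the shipped tests and acceptance runs
  were chosen to keep complete runs in the tens of seconds to minutes.
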