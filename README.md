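# imanifold

Intrinsic manifolds of brain-state dynamics: a pipeline that maps
parcellated BOLD fMRI time series to per-timepoint phase-coherence
states, embeds them on a low-dimensional nonlinear manifold, and decodes
brain states — wakefulness and the non-REM sleep stages N1–N3 — with
linear classifiers.

## Who this is for

Researchers working on dynamic functional connectivity and brain-state
decoding who want a reproducible, text-format, scriptable implementation
of the phase-coherence → manifold → decoding chain, with a built-in
synthetic generator so every stage can be validated without access to
clinical sleep-fMRI data.

## The method

For a subject with N parcellated regions sampled at T TRs:

1. band-pass filter each region to the ultraslow band (0.04–0.07 Hz,
   sixth-order zero-phase Butterworth) and extract instantaneous phases
   θᵢ(t) with the Hilbert transform;
2. form the coherence state V(t) = (cos(θᵢ(t) − θⱼ(t)))_{i<j} and the
   T × T **coherence connectivity dynamics** matrix
   CCD(tᵢ, tⱼ) = V(tᵢ)·V(tⱼ) / (|V(tᵢ)||V(tⱼ)|);
3. convert to distances d = 1 − CCD and sparsify with a **relaxed
   minimum spanning tree**: keep the MST and add (i, j) whenever
   mw_ij + γ(dᵢᵏ + dⱼᵏ) > d_ij (γ = 3, at most kₙ = 5 additions per
   node), where mw_ij is the heaviest edge on the MST path i→j;
4. embed with **Laplacian eigenmaps**: the eigenvectors of the graph
   Laplacian L = Deg − A for the d smallest non-trivial eigenvalues are
   the manifold coordinates (d = 7 by default; PCA on the filtered
   signal is the linear baseline);
5. align subjects by full Procrustes (rotation/reflection + scale +
   translation) fitted on per-stage norm-extremal landmarks;
6. decode stages with linear SVMs (pairwise 10-fold CV, multiclass
   one-vs-all with Platt-calibrated posteriors, leave-one-subject-out on
   the aligned group embedding), and assess significance against
   phase-randomized surrogates with the Monte-Carlo p-value
   p = (#{a < a_perm} + 1)/(N_perm + 1), FDR-corrected.

A stage-switching Kuramoto oscillator generator provides multi-subject
synthetic cohorts with planted, stage-dependent phase coupling and
ground-truth hypnograms. See `docs/methods.md` for assumptions,
parameter meanings and limitations.

## Worked example

```python
from imanifold import BrainStateManifold, PipelineConfig
from imanifold import synthetic as syn

stages = ["Awake", "N1", "N2", "N3"]
templates = syn.stage_coupling_templates(20, stages, seed=0)
spec = syn.SimulationSpec(n_regions=20, templates=templates, seed=3)
ts, labels = syn.simulate_subject(800, spec)

model = BrainStateManifold(ts, labels, PipelineConfig(dim=7, seed=1))
results = model.fit()
print(results.summary())
```

prints

```
Intrinsic manifold analysis
============================================================
subjects: 1   embedding: laplacian_eigenmaps (d=7)   graph: RMST (gamma=3.0, k_n=5)
band: 0.04-0.07 Hz (Butterworth order 6, zero-phase)
------------------------------------------------------------
subject_0: multiclass accuracy 95.1% (PCA baseline 37.2%), graph edges 2206
    Awake vs N1: 81.7%
    Awake vs N2: 92.1%
    Awake vs N3: 92.0%
    N1 vs N2: 84.2%
    N1 vs N3: 91.5%
    N2 vs N3: 65.2%
best single-dimension AUC: 1.000 (dimension 3)
```

Reading this: the subject's 800 timepoints, embedded on the 7-dimensional
manifold, are classified into the four planted stages with 95.1%
accuracy by a *linear* SVM, while the same classifier on a 7-component
PCA of the raw filtered signal reaches only 37.2% — the stage structure
lives in the nonlinear phase-coherence geometry, not in the linear
signal subspace. The pairwise accuracies show which stage pairs share
coupling structure (here N2 vs N3 overlap most), and at least one single
manifold dimension already separates a stage pair perfectly (AUC 1.0).

The same pipeline is scriptable from the shell:

```bash
imanifold simulate --n-subjects 2 --n-trs 400 --out-dir sim/
imanifold run --ts sim/bold_subject_0.tsv --labels sim/labels_subject_0.tsv \
    --ts sim/bold_subject_1.tsv --labels sim/labels_subject_1.tsv \
    --tr 2.08 --out report_dir --seed 42
```

which writes per-subject embeddings, graph edge lists, the aligned group
embedding and a single self-describing `report.json` (config echo,
accuracies, confusion matrices, seeds); repeated runs with the same seed
are byte-identical.

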