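# topocode

Topographic (topological) sparse coding for cell-cycle phase recognition in
time-lapse microscopy.

Automated analysis of phase-contrast microscopy of cultured cells — for
example breast-cancer lines imaged over many hours — needs to recognize, for
every segmented nucleus, which mitotic phase it is in: **interphase,
prophase, metaphase, or anaphase**. `topocode` implements a complete
recognition pipeline whose centerpiece is a dictionary-learning step with a
*topographic* sparsity penalty: dictionary atoms live on a 2-D grid and the
penalty groups neighboring atoms, so nearby atoms learn similar features —
the same continuity property by which adjacent areas of visual cortex
respond to similar stimuli.

## The model

Feature vectors `x ∈ R^d` (one per nucleus, stacked as columns of a `d × N`
matrix) are decomposed over a dictionary `A ∈ R^{d×k}` with sparse codes
`s ∈ R^{k×N}`, `x = A s + r`. Training minimizes

```
J(A, s) = ‖As − x‖₂² + λ Σ_{g,n} √( (V (s∘s))_{g,n} + ε ) + γ ‖A‖₂²
          subject to ‖s_n‖₂² ≤ C for every sample n
```

where `V` is a binary grouping matrix whose rows are overlapping
`group_size × group_size` neighborhoods of the atom grid (toroidal by
default), `s∘s` is the elementwise square, `ε > 0` smooths the group-L1 term
so plain gradient descent applies, and `γ‖A‖₂²` is weight decay. With
singleton groups and `ε → 0` the penalty is exactly `‖s‖₁`. Optimization
alternates mini-batch projected-gradient updates of the codes (a convex
subproblem for fixed `A`) with backtracking gradient steps on the dictionary,
renormalizing atoms to unit norm. Defaults: `λ = γ = 0.1`, `C = 1`,
`ε = 10⁻²`.

Around this core the package provides:

- `topocode.synthetic` — generators for labeled synthetic microscopy scenes
  (four morphologically distinct phase classes) and for numeric sparse-coding
  instances with a known ground-truth dictionary;
- `topocode.preprocess` — Otsu/manual binarization, seeded-watershed
  segmentation on the distance transform, fixed-size ROI extraction;
- `topocode.features` — RAW (54-element resampled intensity), HoG, GIST
  (Gabor bank), and dense aggregated SIFT descriptors per ROI;
- `topocode.classify` / `topocode.metrics` — one-vs-rest SVM with the
  Gaussian kernel `exp(−‖x−x′‖²/δ)` and confusion-count metrics
  (sensitivity, specificity, precision, F1, accuracy, error rate);
- `topocode.pipeline` / `topocode.cli` — the end-to-end runner with a
  temporal-prefix train/test split and a `topocode` command-line tool
  (`simulate`, `segment`, `featurize`, `learn`, `encode`, `run-all`).

## Worked example

```python
from dataclasses import replace
from topocode.pipeline import PipelineConfig, EvalConfig, run_pipeline
from topocode.synthetic import SynthImageConfig
from topocode.tsc import TscConfig

cfg = PipelineConfig(
    synth=SynthImageConfig(n_frames=16),       # 16 frames x 12 nuclei
    tsc=TscConfig(k=16, max_outer_iters=100),  # 4x4 atom grid, 3x3 groups
    evaluation=EvalConfig(train_frames=10),    # temporal prefix split
    run_seed=1,
)
_, with_tsc = run_pipeline(cfg)
_, no_tsc = run_pipeline(replace(cfg, use_tsc=False))
print(f"accuracy with sparse coding: {with_tsc.accuracy:.3f}")
print(f"accuracy without           : {no_tsc.accuracy:.3f}")
```

prints

```
accuracy with sparse coding: 1.000
accuracy without           : 0.985
```

i.e. on 68 held-out nuclei from the last six frames, classifying the learned
sparse codes recognizes every phase correctly, slightly ahead of classifying
the raw intensity features directly — the qualitative benefit the topographic
coding step is designed to provide. Per-class sensitivities, specificities,
precisions, F1 scores, and the macro averages are in
`with_tsc.per_class` / `with_tsc.macro`.

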