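# Methods

## Model

`topocode` learns a sparse-coding representation of per-nucleus feature
vectors and classifies the codes into the four mitotic phases. Samples are
columns of `x ∈ R^{d×N}`; the model is `x = A s + r` with a dictionary
`A ∈ R^{d×k}` (unit-norm atoms) and codes `s ∈ R^{k×N}`. Training minimizes

```
J(A, s) = ‖As − x‖₂²
        + λ Σ_{g,n} √( (V (s∘s))_{g,n} + ε )
        + γ ‖A‖₂²                 s.t. ‖s_n‖₂² ≤ C per sample column n
```

The grouping matrix `V ∈ {0,1}^{G×k}` arranges atoms on a
`grid_rows × grid_cols` grid and assigns each grid position the
`group_size × group_size` window anchored there (toroidal wraparound by
default, so `G = k` and every atom sits in exactly `group_size²` groups).
Because a coefficient that becomes active inside an already-active group is
almost free while activating a new group costs a full `√`-term, co-active
atoms are pulled into neighboring grid positions: the topographic-map
property. Two limiting cases anchor the implementation and its tests: with
singleton groups the penalty is the smoothed L1 norm
(`|penalty(ε) − ‖s‖₁| ≤ kN√ε`), and with `ε = 0` it is the exact group-L2/L1
norm, which is not differentiable at zero — gradients therefore require
`ε > 0` and refuse `ε = 0` rather than silently returning a subgradient.

A note on the objective's notation as it circulates in the literature this
implements: written per code row the grouped term does not type-check, so the
package adopts the standard topographic reading — groups over dictionary
atoms, penalty summed per sample — which is the only form consistent with
both the penalty's claimed L1 reduction and a 9-term 3×3 worked example.

## Optimization

* **Codes (`encode`)** — for fixed `A` the subproblem is convex. Projected
  gradient descent with backtracking line search (halving steps, Armijo
  sufficient decrease measured after projection onto the per-column C-ball)
  starting from the analytic initialization `s = Aᵀx` with row `r` divided by
  `‖A_r‖`. Accepted steps never increase the objective; iteration stops when
  the relative change drops below `tol_rel` (default `10⁻⁶`) or after
  `max_inner_iters` (default 200). Restart agreement of the final objective
  (5 random initializations within `10⁻⁴` relative) is part of the test
  suite, as are constraint feasibility and the monotone trace.
* **Dictionary (`learn`)** — alternating minimization. Each outer iteration
  draws a mini-batch of sample columns with the seeded generator (default
  `batch_size = 256`), encodes the batch, takes a backtracking gradient step
  on `A` (gradient `2(As−x)sᵀ + 2γA`), and renormalizes atoms to unit norm
  (the decay term alone does not pin the scale against compensating code
  rescaling under the smoothed penalty). Atoms are initialized from randomly
  chosen data columns (`init="data"`), which starts the search inside the
  data span; a seeded Gaussian init is available.
* **Atom refresh** — every `atom_refresh_every` outer iterations (default
  40), atoms whose mean absolute coefficient falls below
  `refresh_usage_frac` of the maximum, or whose coherence with another atom
  exceeds `refresh_coherence` (default 0.9), are replaced by the direction of
  a poorly reconstructed residual. This is the classical escape from
  dead-atom and duplicate-atom local minima; it may transiently raise the
  objective, so it is suspended for the last 60 iterations and can be
  disabled (`atom_refresh_every=0`), in which case full-batch runs are plain
  alternating minimization with a non-increasing objective trace.
* **Convergence** — declared on the relative change of the full-data
  objective (with freshly encoded codes). Mini-batch runs require five
  consecutive sub-tolerance changes before stopping, since a single small
  change can be batch noise rather than convergence.

Defaults `λ = γ = 0.1` and `C = 1` are the canonical settings for this
objective; `ε = 10⁻²` and `batch_size = 256` have no canonical value and are
plain package choices. `C` is interpreted per sample column (projection
rescales offending columns); `math.inf` disables it.

## Synthetic data

Two generators make every stage testable without microscopy data; both are
deterministic functions of their config, including the seed.

* **Scenes** (`generate_cell_frames`) — 16-bit frames (default 256×256,
  12 nuclei, background 2000, amplitude 20000, Gaussian noise sd 300) with
  nuclei rendered as Gaussian-shaded ellipses whose phase classes differ in
  area, eccentricity, and texture: interphase large/round/smooth, prophase
  medium with coarse multiplicative speckle, metaphase an elongated bright
  band (higher amplitude, axis ratio ≈ 3–4), anaphase two overlapping
  sub-blobs offset along the major axis so the nucleus remains one connected
  component. Centroids are rejection-sampled to pairwise separation
  ≥ 36 px (error after 1000 failed draws). These designs are stand-ins
  chosen so that intensity, shape, and local-structure features can all
  separate the classes; they do not model phase-contrast optics, cell
  motion, division events, or tracking, so pipeline accuracies on them
  bound nothing about real imagery — they verify the machinery, not the
  biology.
* **Numeric instances** (`generate_tsc_instance`) — a unit-norm Gaussian
  dictionary, codes with exactly `atoms_active_per_sample` nonzeros per
  column (magnitudes uniform in `[0.5, 1.5)·code_scale`, random signs), and
  samples `A s +` Gaussian noise. With `topographic=True` the active set is
  drawn within one `group_size²` grid neighborhood, matching the structure
  the topographic penalty models.

## Pipeline stages and their defaults

* **Binarization** — Otsu threshold (manual override available) followed by
  a binary opening with a 1-px disc. A constant frame yields an all-false
  mask with a warning.
* **Segmentation** — seeded watershed on the inverted Euclidean distance
  transform, seeded at distance-transform maxima ≥ `min_seed_distance`
  apart within each component. The pipeline default of 12 px (the scale of
  a nucleus radius in the synthetic scenes) keeps anaphase chromatid lobes
  in one region while still splitting touching nuclei; the library default
  of 5 px is the conventional aggressive setting. Regions under
  `min_area = 10` px are removed and labels recompacted. Coordinates are
  0-based row-major; bounding boxes half-open.
* **ROIs** — a square window the size of the region's larger bbox side,
  centered on the bbox, padded with the frame median at edges, resampled to
  `roi_shape` (default 48×48; no canonical value exists).
* **Features** — RAW resamples the ROI to 9×6 and min-max rescales,
  giving the canonical 54-element vector (how that length arises from an
  ROI is not otherwise specified, and the shape is configurable); HoG uses
  a 3×3 cell grid, 9 orientations, 2×2 L2-Hys blocks; GIST a 4-scale ×
  8-orientation Gabor bank pooled on a 4×4 grid (512 entries, patch mean
  removed so constant patches map to zero); SIFT a dense 4×4×8 descriptor
  per grid window with the usual L2/clip-0.2/renormalize contrast
  normalization, averaged to one 128-vector. All extractors are pure and
  fixed-length for fixed config.
* **Feature conditioning** — per-feature standardization is fit on the
  training split only, then columns are scaled by `1/√d` so sample norms are
  near 1 and the `C = 1` code ball is a natural constraint rather than a
  hard shrinkage.
* **Classification** — one-vs-rest SVMs (scikit-learn SVC, precomputed
  kernel) over the canonical phase order with
  `k(x, x′) = exp(−‖x−x′‖²/δ)`. A widely printed variant of this kernel
  omits the exponential; that form grows with distance and is not positive
  semidefinite, so it cannot act as a similarity — it is retained behind
  `literal_kernel=True` for fidelity experiments only. `δ = 0.5` and
  `C_svm = 100` are package defaults (documented here, not canonical
  values) suited to unit-scale code vectors. Ties in the decision values
  break toward the earlier canonical class.
* **Split** — temporal prefix by frame index (train on the first
  `train_frames`, test on the rest), mirroring the first-part/last-part
  design of time-lapse studies and preventing leakage between adjacent
  frames of the same cells.
* **Metrics** — one-vs-rest confusion counts per phase; sensitivity
  `TP/(TP+FN)`, specificity `TN/(TN+FP)`, precision `TP/(TP+FP)`, accuracy
  `(TP+TN)/total`, `F1 = 2·precision·sensitivity/(precision+sensitivity)`,
  `error_rate = 1 − accuracy`. Zero-denominator ratios are NaN with an
  explicit flag, never silently zero. The multi-class report adds macro
  averages and overall accuracy from the 4-class confusion diagonal.

## Problem sizes used by the acceptance script

Gradient checks sweep 54 randomized instances (`d ≤ 8`, `k = 9`, `N ≤ 5`;
`λ, γ ∈ {0, 0.1, 1}`, `ε ∈ {10⁻⁴, 10⁻²}`) against central finite
differences. Dictionary recovery uses `d = 16`, `k = 16` (4×4 grid),
`N = 2000`, 3 active atoms per sample drawn topographically, noise sd 0.01,
600 outer iterations with the norm constraint disabled (true code columns
have squared norm ≈ 3, so a unit ball would distort the target); recovered
and true atoms are matched greedily by absolute cosine. The pipeline run
uses 16 frames × 12 nuclei with a 10-frame training prefix, in both the
sparse-coding and ablation arms. These sizes were chosen as the smallest at
which the measured properties are stable across seeds.

## Known limitations

* The synthetic phase morphologies are plausible but invented; class
  separability is by construction, so pipeline accuracy is a mechanism
  check, not a biological benchmark.
* The encoder is plain projected gradient descent — robust and easy to
  verify, but slower than proximal or accelerated solvers on large `N`.
* Atom refresh trades the monotone-descent guarantee for better minima;
  disable it when a strictly non-increasing trace matters.
* Frame-to-frame tracking of nuclei is out of scope; frames are treated as
  independent collections of nuclei.
* Greedy cosine matching slightly underestimates recovery when two learned
  atoms both resemble one true atom.
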