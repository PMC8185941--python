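# Methods

## Problem and model

PD-L1 tumor proportion scoring asks what fraction of viable tumor cells
shows membranous PD-L1 staining on a DAB/hematoxylin IHC slide. The
package follows the clinical reading process: regions first, cells
second. A cell-localization network (C-Net) works at cell scale (nominal
40×) and a region segmenter (R-Net) at 1/4 linear resolution (nominal
10×); the two are combined multiplicatively — the multistage ensemble.

### C-Net

Point annotations (one coordinate + class per cell) are expanded into
per-class binary disk targets of radius `disk_radius` (how dense targets
arise from points is a modeling choice; disks are the simplest shape that
gives the network mass to regress). The network is a compact U-shaped
FCN: one 3×3 conv + ReLU per encoder level (two at the bottom), widths
`base_width · 2^level`, transition blocks (1×1 conv + 2×2 average pool)
between levels, nearest ×2 upsampling with skip concatenation in the
decoder, five sigmoid 1×1-conv heads (one-vs-rest; channels deliberately
do not compete through a softmax), and an auxiliary deep-supervision head
at half resolution whose loss is added with weight 0.4 during training
only.

The training loss is the weighted pixel-wise cross-entropy
φ = λ·|p − t|^γ, L = −mean(φ·[t·log p + (1−t)·log(1−p)]), λ = γ = 3. The
printed form of this loss in the source derivation places the binary
ground truth inside the logarithms, which is undefined at t ∈ {0, 1}; we
implement the standard orientation (target multiplies log-prediction),
the only numerically meaningful reading. The norm is read as the
per-pixel absolute difference, the only reading consistent with a
per-pixel weight matrix. Predictions are clamped at ε = 1e−7; the
gradient is taken through φ as well (as in focal-loss practice).

Sigmoid heads are initialized with a −2.0 prior bias. Without it the
focal weighting stalls: a diffuse background prediction near p ≈ 0.15
receives almost no gradient (φ ∝ |p|³) and peaks never clear the
detection threshold. The prior-bias init is part of the architecture for
every loss configuration, including the plain-BCE ablation arm.

Detection extraction: per channel, local maxima ≥ threshold (default
0.5) within a `min_distance` window; plateaus (e.g. binary disks) reduce
to their centroid; a single greedy non-maximum-suppression pass across
all channels keeps, among detections within `min_distance` of each other
(same or different class), the highest-scoring one, ties broken by
row-major order then channel order.

### R-Net and the ensemble

R-Net is the same encoder–decoder family with a 3-class softmax head
(TC(+) region, TC(−) region, normal region) at region scale, trained with
pixel-wise cross-entropy; background (bare glass) pixels in training
masks fold into the normal class, since both are non-tumor for the
ensemble. A published large pretrained segmenter would serve equally —
the backbone is a replaceable contract; the ensemble mechanism is the
point. The tumor-probability map (P(TC+ region) + P(TC− region)) is
bilinearly upsampled to cell scale and multiplies the TC(+) and TC(−)
probability channels *after* the activation. Masking post-activation
probabilities rather than encoder features keeps the two networks
decoupled and independently testable while giving non-tumor cells a
minimal probability after activation, the same suppression effect.
Whether TC(+)- and TC(−)-region probabilities should gate their
respective channels separately is undecidable from the problem statement;
we use their sum for both channels.

### Scoring

TPS = 100·nTC+/(nTC+ + nTC−) from detection counts; slides aggregate by
summing counts across tiles, never averaging per-tile TPS (the
count-ratio definition). Zero tumor cells → the slide is flagged not
amenable rather than dividing by zero. Expression bins: < 1% negative,
1–25% low, 25–50% moderate, ≥ 50% high; boundaries belong to the upper
bin, and dichotomization at a cutoff likewise counts the boundary as
positive. IPS counts lymphocyte/histocyte detections whose center lies
on a tumor-region pixel; positivity is an intensity rule (no algorithmic
rule is fixed by the source): mean DAB optical density — OD = −log10(I/255)
per RGB channel projected onto the Ruifrok–Johnston H-DAB basis — in a
disk of `disk_radius` around the center, threshold 0.15 OD (configurable).

### Statistics

* Object-level F1: per class, maximum-cardinality minimum-distance
  one-to-one matching within `match_radius` (Hungarian algorithm with a
  big-M penalty on out-of-radius pairs), verified against exhaustive
  enumeration on all instances with ≤ 8 points. The default match radius
  equals the target disk radius.
* Count errors: MAE, RMSE, and MAPE over patches; MAPE excludes
  zero-truth patches (they still count in MAE/RMSE) and is flagged
  undefined when no patch has nonzero truth.
* ICC(2,1): two-way random effects, absolute agreement, single measure —
  the natural form for "image analysis vs pathologist consensus" — from
  the two-way mean squares, CI by the standard F-based interval.
* Fleiss' kappa for two raters and two categories after dichotomizing at
  each cutoff in {1, 5, 10, 25, 50}%; undefined when all ratings fall in
  one category.
* Mann–Whitney U uses the normal approximation with tie correction and no
  continuity correction; chi-square on the 2×2 table at the simultaneous
  1% TPS/IPS cutoffs is uncorrected.

## Synthetic data

The generator emulates H-DAB bright-field tiles by linear stain mixing in
optical-density space (the same Ruifrok–Johnston basis the scoring-side
deconvolution uses) plus Gaussian pixel noise. Geometry: nuclei are
anti-aliased ellipses of radius 4–5 px at cell scale, membrane rings 2 px;
TC(+) = blue nucleus + brown ring, TC(−) = blue nucleus, lymphocytes
small/round/dark, histocytes larger/irregular/pale, fibrocytes elongated
spindles in stroma. PD-L1(+) histocytes carry membranous-style DAB (ring
plus faint cytoplasm): positive histocytes are near-lookalikes of TC(+)
at cell scale, which is exactly the confusion the regional ensemble
exists to resolve. PD-L1(+) lymphocytes have diffuse brown cytoplasm.
Regions come from thresholded smoothed Gaussian fields: nest-shaped tumor
areas covering exactly the requested `tumor_area_fraction`, split into
TC(+)/TC(−) sub-regions in the planned-TPS proportion, with faint
region-level washes (bluish tumor cytoplasm, light diffuse DAB in TC(+)
regions) that give the 10×-scale segmenter honest low-frequency cues.

Planned scores are realized exactly, not sampled:
`round(n_tumor_cells · planned_tps/100)` cells are TC(+), and similarly
for IPS, so ground-truth scoring recovers the plan bit-exactly. Cell
centers keep a minimum separation (10 px) except a configurable fraction
of deliberately adjacent pairs at 0.8× nuclear diameter; immune cells
additionally keep a best-effort clearance from TC(+) membrane rings so an
unstained IC's measured DAB reflects its own stain (at extreme density,
e.g. planned TPS ≈ 90+, the clearance falls back to plain separation).
Impossible packings raise an error rather than silently truncating.

What the generator does **not** emulate: photorealistic histology
texture, staining artifacts and batch variation, out-of-focus and scanner
noise, nuclear pleomorphism, necrosis, cytology preparations, or
pyramidal whole-slide formats. Tests passing on these tiles therefore
demonstrate the *mechanics* of the method — losses, ensemble, scoring and
statistics — not clinical-grade performance on real slides.

## Training and study conditions

Networks are trained with momentum SGD (momentum 0.9, batch 4). The
full-scale recipe (initial lr 0.001, up to 200 epochs on thousands of
512² patches) is available via `RunConfig(full_scale=True)`; the package
defaults are desk-scale conditions chosen once: 128×128 tiles, target
disk radius 4 (nuclei are 4–5 px here), C-Net base width 8 / depth 3
(~17k parameters), R-Net depth 2 at region scale, lr 0.1 with a ×0.1
step decay at 75% of training, 120 epochs for both networks; 20 training
and 5 validation tiles spanning planned TPS 0/5/25/50/90; 15 evaluation
slides (3 per level, 2 tiles each). At these sizes lr 0.001 moves far too
slowly; 0.1 reaches the same qualitative optimum in minutes.

The weighted loss occasionally leaves an initialization on a long plateau
(diffuse maps, slowly creeping loss) before the localization solution
emerges. The pipeline therefore trains the C-Net from two initialization
seeds and keeps the candidate with the better validation loss —
validation-based selection is already the training contract, extended
across restarts. Training is deterministic for a fixed seed; checkpoints
embed a hash of the architecture config plus the input-whitening
statistics (per-channel mean/SD of the training set).

The full online augmentation recipe (rotation ±180°, shear ±10°, shift
±10%, zoom 0.9–1.1, flips p = 0.5; whitening = the standardization above)
is implemented and tested but switched off in the desk-scale runs, whose
training sets are re-simulated fresh per run and do not overfit within
the short schedules.

### The two property experiments

*Ensemble (masking) experiment.* Fixture slides at planned TPS 30 with 8
DAB-positive stromal histocytes per tile — out-of-distribution
confounders the C-Net training never saw in stroma. TC(+) count MAE is
compared with and without R-Net masking; the median over 3 fixture seeds
is reported. Masking can only help where cell-level classification errs:
a perfectly discriminating detector yields a tie, which is why the
confounders are rendered as TC(+) lookalikes (see above).

*Close-cell (weighted-loss) experiment.* The adjacent-cell fixture puts
every tumor cell in an adhesive pair at 0.7× nuclear diameter (nuclei
touching) on 64² tiles. C-Nets are trained at a fixed budget (120 epochs,
8 tiles) once with λ = γ = 3 and once with plain BCE (λ = 1, γ = 0), over
7 training seeds; the median localization recall of tumor cells on 6
held-out tiles is compared. Two deliberate choices: (1) recall matches
predicted to true points irrespective of the TC(+)/TC(−) label, because
the close-cell failure mode is merging two cells into one detection — a
localization error — while label confusion between the tumor classes is
orthogonal noise; (2) the comparison runs at lr 0.05, a rate at which
*both* arms train stably — λ = 3 scales gradient magnitudes threefold, so
at higher rates the weighted arm occasionally diverges and the comparison
would measure stability, not the loss's focusing property.

## Numerical choices

* Probability clamp ε = 1e−7 in all cross-entropies.
* NMS tie-breaks: higher peak first, then row-major order, then channel
  order; plateau components reduce to rounded centroids.
* Optimal matching uses big-M = 1e9 for out-of-radius pairs; with ≤ 10³
  points and radii ≤ 10² px this cannot distort the valid-pair ordering.
* Bilinear upsampling of the tumor-probability map uses edge-mode
  interpolation and clips to [0, 1]; label (not probability) masks
  upsample by nearest neighbour.
* Tiling uses half-open ranges, 0-based x = column / y = row pixel-center
  coordinates, reflection padding at edges (recorded, and mirror-margin
  detections are dropped on the way back); overlap de-duplication keeps
  the copy closest to its own tile center.
* Weights are float32; gradient checks run the same code in float64.

## Known limitations

* The decoder, transition blocks and deep-supervision head are a
  documented stand-in for an incompletely specified architecture; the
  network is a contract, not a reproduction.
* Scores sitting exactly on a dichotomization cutoff make kappa at that
  cutoff sensitive to ±1-cell counting noise; slide-level agreement at a
  cutoff is only as stable as the per-slide count bias.
* IC positivity is an intensity rule with a fixed OD threshold; real
  assays grade partial membranous staining that this rule flattens.
* The numpy networks are CPU-bound and desk-scale; they are not meant to
  process gigapixel WSIs (tiling utilities exist, but throughput is the
  bottleneck).
* Whether the five C-Net channels should compete (softmax) instead of
  one-vs-rest sigmoids cannot be settled from the problem statement; the
  one-vs-rest choice keeps channels independent under masking.
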