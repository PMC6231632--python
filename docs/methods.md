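# Methods

## The descriptor

A color image is a map **I**: Z² → R³. Every pixel factors as
**I**(p) = I_M(p) · **I**_O(p), where I_M(p) = ‖**I**(p)‖ is the
brightness and **I**_O(p) = **I**(p)/I_M(p) is the unit chromaticity
orientation. Texture in the orientation field is coded per pixel by
comparing the center orientation with N bilinearly interpolated
neighbors on a circle of radius R: the cosine similarity
m_{p,i} = **I**_O(p)·**I**_O(i)ᵀ is binarized with a threshold T_O
(bit set iff m_{p,i} < T_O, i.e. iff the color separation exceeds
arccos T_O), and the N-bit word is reduced to its minimum over cyclic
shifts. The number of distinct labels is the number of binary
necklaces of length N — 36 for N = 8 — and the image feature is the
histogram of labels over all interior pixels. LBP is implemented on
the same ring with the order comparison neighbor ≥ center (ties set
the bit) applied to a scalar image (color magnitude, or luma for the
grayscale baseline). Fusion is by histogram concatenation (2P bins)
or by the flattened P×P label co-occurrence table.

Assumptions inherited from this construction:

- stain colors are separated in *orientation*, not only in brightness;
- color variation within one stain is small relative to arccos T_O;
- any slide-to-slide color variation has been removed beforehand by
  stain/color normalization (not provided here);
- image color is locally smooth enough that bilinear interpolation of
  the ring samples is meaningful.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| N (`n_samples`) | 8 | — | ring samples; fixes the 36-label space |
| R (`radius`) | 1.0 | px | ring radius; border band of width ⌈R⌉ is masked |
| T_O (`t_o`) | 0.80 | cosine | counter-color threshold, arccos 0.8 ≈ 36.9° |
| T_O grid | 0.55…1.00 step 0.05 | cosine | model-selection sweep range |
| color space | YCbCr | — | bare linear transform, no studio-swing offsets |
| normalization | L1 | — | histograms as frequencies for classifiers |

The default T_O sits inside the 0.75–0.85 band that works well for
stained tissue; smaller values yield coarse descriptors reacting only
to strong counter-color transitions, values near 1 react to any
chromaticity change (and hence to noise). With YCbCr's signed chroma
axes the useful threshold range is the whole [-1, 1], versus [0, 1]
in RGB where all orientations live in the positive octant.

## Conventions and numerical choices

- **Achromatic pixels.** Orientation is undefined at zero magnitude;
  pixels with ‖**I**(p)‖ ≤ 1e-12 get the unit vector (1, 0, 0) (the
  luma axis), keeping the field total and unit-norm. The same rule
  applies in every color space and to degenerate interpolated vectors.
- **RGB scaling.** 8-bit input is divided by 255. Orientation — and
  therefore the descriptor — is invariant to this choice; it only
  sets the magnitude scale.
- **Interpolation.** Componentwise bilinear interpolation via
  two-stage linear interpolation, a + t(b − a), which returns stored
  values exactly at integer coordinates and is exact on constant
  fields (a plain four-weight sum is not, and the rounding residue
  would flip LBP's tie-sensitive ≥ bits on constant images).
  Interpolated orientation vectors are renormalized to unit length
  because the similarity metric assumes unit inputs.
- **Ties.** m_{p,i} = T_O yields bit 0 (strict inequality); similarity
  values are clamped to [-1, 1] to absorb renormalization round-off.
- **Geometry.** x = column, y = row, pixel centers at integer
  coordinates, sample k at angle 2πk/N counterclockwise (y down),
  sample 0 due east. Rotation-invariant coding makes these choices
  immaterial, which the orbit-constancy tests assert.
- **Labels.** Histograms are indexed by dense labels 0..P−1 (ascending
  minimized-code order), not by sparse minimized codes, so feature
  length is exactly P (36), 2P (72), or P² (1296).
- **Joint fusion order.** The co-occurrence table is flattened
  row-major with the counter-color label as the row index; any fixed
  order is classifier-equivalent, this one is frozen for
  reproducibility.
- **Monotone invariance of LBP.** Exact under positive-affine
  transforms of the scalar image on any ring, and under *arbitrary*
  strictly increasing transforms only where samples land on integer
  coordinates (e.g. N = 4, R = 1): bilinear interpolation does not
  commute with nonlinear monotone maps, so isolated bit flips can
  occur at interpolated samples near ties.
- **Degenerate feature matrices.** A very low T_O can map every image
  to the identical all-agree histogram; classifier fitting then falls
  back to a majority-class rule with uninformative decision scores
  rather than failing the whole protocol.

## Synthetic benchmark

The generator emulates the two texture regimes the descriptor is meant
to tell apart, on 64×64 RGB patches:

- **counter** class: a red background chromaticity
  (0.80, 0.35, 0.40)/‖·‖, Masson's-trichrome-like, with
  Poisson-scattered soft disks of a blue-green foreground chromaticity
  rotated exactly `chroma_separation_deg` (default 40°) away; defaults
  80 disks per 100×100 px with radii 2–4 px — a dense, fine-grained
  interleaving like glomerular micro-texture;
- **smooth** class: the background chromaticity everywhere.

Both classes share the same brightness model: a Gaussian-smoothed
random field (σ = 6 px, mean ≈ 0.7) with 3% multiplicative pixel
noise, clipped as a *scalar* to [0.05, 1] and multiplied onto the unit
chroma vector. Brightness therefore never alters orientation, pixel
values stay in [0, 1] without per-channel clipping, and the class
difference lives purely in chromaticity — which is what makes the
LBP-vs-QDCP ablation meaningful (the luma baseline sees nearly
identical brightness statistics in both classes).

Disk edges use a half-pixel linear ramp: sub-pixel softness keeps the
edge continuous for the bilinear sampler, while still letting adjacent
pixels realize the full stain-to-stain angular step. A multi-pixel
ramp would halve the per-pixel angular change below arccos(0.8) for a
40° stain pair and hide the structure from a unit-radius ring
entirely.

What the generator does **not** model: nuclei morphology, stain
density variation within a structure, slide-level color shifts,
chromatic aberration, compression artifacts. Passing benchmarks here
demonstrate that the implementation measures counter-color structure
as designed — not that any particular accuracy transfers to real
histology data.

## Evaluation protocol

Stratified outer 10-fold cross-validation, inner stratified 5-fold
grid search on each outer training split selecting T_O (grid above)
and classifier hyper-parameters by inner accuracy, winner refit on the
full outer training split and scored on the held-out fold; the whole
procedure repeated (default 10 times) with reshuffled folds, and
ACC/AUC summarized over all n_repeats × 10 fold results. Folds are
stratified to protect the small-sample regime. Grids: SVM-RBF γ ∈
{0.1, 1, 10} × (1/median squared pairwise distance of the training
features) and C ∈ {0.1, 1, 10, 100}; k-NN k ∈ {1, 3, 5, 7, 9} with
Euclidean or city-block distance; the Fisher discriminant has no
tuned hyper-parameter. AUC uses the Mann–Whitney formulation (ties
count ½) on decision scores — signed discriminant/SVM decision values,
or the positive-class neighbor fraction for k-NN — computed per fold
and averaged. Feature histograms for the entire T_O grid are
precomputed per image (the similarity stack is sampled once and
re-binarized per threshold); this is a pure caching step, unsupervised
and per-image, so it introduces no train/test leakage.

Problem sizes used by the shipped benchmark runs (tests and the
acceptance script): 65 images per class, 40° separation, and 2
protocol repeats — enough for stable means on a strongly separable
benchmark while keeping a full run in the minutes range on one CPU.
The protocol default in `nested_cv` remains 10 repeats.

## Known limitations

- Single-radius, single-scale neighborhoods only; no uniform-pattern
  (riu2) reduction — the full 36-label rotation-invariant space is
  used.
- No multi-threshold or fuzzy-threshold variants.
- The joint 1296-bin fusion is sparse on small images (≈ 3.8k valid
  pixels per 64×64 patch) and can be noise-sensitive there; the
  concatenated fusion is the safer default.
- Exact rotation invariance holds for quarter-turns; arbitrary-angle
  rotation invariance is approximate through the interpolated ring.
- Color/stain normalization is out of scope and assumed done upstream.
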