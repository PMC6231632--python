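# qdcp — counter-color texture descriptors for stained pathology images

Chemical stains give pathology images their diagnostic color: in a
Masson's trichrome section, collagen and mucus are blue-green while
muscle and cytoplasm are red, and the *spatial interleaving of those
counter colors* encodes tissue architecture (a glomerulus looks very
different from smooth stroma even at identical brightness). Classic
texture descriptors built on intensity orderings are blind to this
structure and over-sensitive to the small color variations common in
stained slides.

This package implements the **quantized diagnostic counter-color
pattern (QDCP)** descriptor family for that problem, aimed at anyone
classifying small stained-tissue patches (glomerulus vs non-glomerulus
texture, blast vs normal blood cells, and the like):

- **QDCP** — each pixel's color vector **I**(p) is split into brightness
  and a unit chromaticity orientation, **I**(p) = I_M(p) · **I**_O(p)
  with ‖**I**_O(p)‖ = 1. On a circular ring of N neighbors (bilinearly
  interpolated), the similarity m_{p,i} = **I**_O(p) · **I**_O(i)ᵀ is
  binarized as b_{p,i} = 1 iff m_{p,i} < T_O — i.e. iff the colors are
  separated by more than arccos(T_O) degrees — and the N-bit word is
  made rotation-invariant by cyclic-shift minimization:
  min over n of Σ b_{p,i} 2^((i+n) mod N).
  For N = 8 there are exactly 36 such patterns; the image feature is
  the 36-bin histogram of pattern labels.
- **LBP** — the classic rotation-invariant local binary pattern on the
  brightness (magnitude) image, sharing the same ring and label table.
- **QDCP-LBP** — concatenation of both histograms (72 bins): color
  texture plus brightness texture.
- **QDCP/LBP** — their joint co-occurrence histogram (36² = 1296 bins).

Orientations are taken in YCbCr (the bare linear transform, no
offsets): its signed chroma axes spread stain colors over most of the
unit hemisphere, so the useful threshold range is the whole [-1, 1].
RGB, CIELab and I1H2H3 are also available for comparison. Because the
descriptor only sees chromaticity orientation, it is exactly invariant
to global intensity scaling and to 90°/180°/270° image rotations.

The package also ships a synthetic two-class stained-texture generator
(counter-color micro-structure vs single-chroma brightness texture)
and the evaluation protocol used to benchmark the descriptors:
repeated stratified nested cross-validation (outer 10-fold, inner
5-fold) that selects T_O and the classifier hyper-parameters (Fisher's
linear discriminant, RBF-kernel SVM, or k-NN) on the training side
only, reporting accuracy and ROC-AUC.

## Worked example

```python
import numpy as np
from qdcp import (StainTextureParams, generate_image, qdcp_feature,
                  threshold_to_angle, build_rotation_code_table)

table = build_rotation_code_table(8)
print(table.n_labels)                 # 36 rotation-invariant patterns

img = generate_image(StainTextureParams(seed=0), "counter")
h = qdcp_feature(img, t_o=0.8)        # default YCbCr, N=8, R=1
print(threshold_to_angle(0.8))        # 36.86989764584401 (deg)
print(h.n_valid)                      # 3844 interior pixels of 64x64
print(np.sort(h.bins)[::-1][:3])      # [0.8595 0.0489 0.0458]

smooth = generate_image(StainTextureParams(seed=0), "smooth")
hs = qdcp_feature(smooth, t_o=0.8)
print(np.abs(h.bins - hs.bins).sum()) # 0.28095733610822066
```

At T_O = 0.8 (a 36.87° color-separation threshold), the smooth-class
patch puts all of its mass in the all-agree pattern (bin 0 = 1.0): its
chromaticity never changes. The counter-class patch moves ~14% of its
mass into transition patterns at stain boundaries, so the two
histograms sit 0.28 apart in L1 — the contrast the classifiers then
exploit.

The same pipeline is available as scikit-learn transformers
(`QDCPDescriptor`, `LBPDescriptor`, `FusedDescriptor`) that compose
with `Pipeline` and the model-selection tools, and as a CLI:

```sh
qdcp synth --n-per-class 65 --separation 40 --seed 7 --out data/
qdcp extract --data data/ --descriptor qdcp-lbp --t-o 0.8 --out feats.csv
qdcp classify --features feats.csv --classifier svm --report report.json
qdcp sweep --data data/ --out sweep.csv     # accuracy vs T_O
```

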