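# fmshift — fast mean-shift colour clustering for histological images

Quantitative histology (e.g. scoring liver fibrosis on Masson's-trichrome
sections) starts from a pixel-level segmentation of stained tissue classes.
Mean-shift clustering is a natural fit — it assumes nothing about cluster
shape or count — but the textbook algorithm costs O(n²) per sweep over the
n = H·W pixels, which is prohibitive for slide-scanner images.

`fmshift` implements a grid-accelerated mean shift for colour segmentation:

1. **Features.** The image is converted from sRGB to CIE L\*a\*b\* (D65) and
   only the chromatic channels (a\*, b\*) are kept, so staining differences
   drive the clustering while brightness variation is ignored.
2. **Density grid.** The occupied feature rectangle is tiled with tiny
   squares of side 2e; each cell stores its point count w(i,j) and centre
   c(i,j). Summed-area tables W and M of w and w·c turn any box sum into four
   lookups.
3. **Mode seeking.** The uniform-kernel mean-shift vector at x,
   m_h(x) = mean of the points in a window around x, minus x, is approximated
   on the grid as

   m̂_h(x) = Σ w(i,j)·c(i,j) / Σ w(i,j) − x,

   summed over the (2h_c+1)² cells around x's cell and evaluated in O(1)
   via the tables. Iterating x ← x + m̂_h(x) from every occupied cell centre
   finds the density modes; each cell, and hence each pixel, inherits its
   mode. The k most massive clusters are kept and the rest reassigned to the
   nearest kept mode.

Defaults follow the cell-size rule e = max(range a\*, range b\*)/1000 and
window h = 40·e. The per-iteration cost depends only on the number of
occupied cells, not on the pixel count.

The package also provides the exact spherical-window mean shift as a
reference implementation, the three evaluation metrics (per-class Dice, Rand
index, Variation of Information, with Hungarian label matching for
unsupervised output), and a seeded generator of synthetic trichrome-like
images (fibrosis ribbons / vessel blobs / background) with ground-truth
labels.

## Worked example

```python
import fmshift as fm

# a 128x128 synthetic trichrome-like image with per-pixel ground truth
spec = fm.default_tissue_spec(size=(128, 128), sigma=2.0, seed=42)
img, gt = fm.make_histology_image(spec)

lm = fm.fmshift_segment(img, fm.PipelineConfig(k=3))
print("k =", lm.k)
print("cluster sizes:", lm.class_sizes().tolist())
print("e = %.4f  h = %.4f" % (lm.provenance["e"], lm.provenance["h"]))

rep = fm.evaluate(lm.labels, gt.labels)
print("dice per class:", {k: round(v, 4) for k, v in rep["dice_per_class"].items()})
print("rand index: %.4f   VoI: %.4f bits" % (rep["rand_index"], rep["voi"]))
```

prints

```
k = 3
cluster sizes: [12148, 2592, 1644]
e = 0.0502  h = 2.0094
dice per class: {0: 1.0, 1: 1.0, 2: 1.0}
rand index: 1.0000   VoI: 0.0000 bits
```

Label 0 is always the largest cluster (here the background; labels are
sorted by pixel count). At noise σ = 2 Lab units the three stain classes
are ≈ 27–36 Lab units apart in (a\*, b\*), and the segmentation recovers the
ground truth exactly: Dice = 1 for every class, Rand index 1, VoI 0 bits.

The same pipeline is available from the shell:

```sh
fmshift synth --size 256 256 --sigma 2 --seed 42 --out img.png --gt gt.png
fmshift segment img.png --k 3 --out labels.png --colorized view.png \
        --ref gt.png --metrics metrics.json
fmshift metrics labels.png gt.png
```

`DensityGrid` and `IntegralTables` can be cached to disk with their
`save`/`load` methods (numpy `.npz` archives holding the cell size, bounds
and matrices).

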