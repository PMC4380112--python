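# Methods

## Model and procedure

The segmenter treats an H×W colour image as n = H·W points in the 2-D
chromatic feature space V_ab of CIE (a\*, b\*) values and clusters them by
mode seeking on a kernel density estimate with a uniform kernel.

**Mean-shift vector (MSV).** For a window S_h(x) (sphere of radius h) the
MSV is m_h(x) = (1/K) Σ_{x_i ∈ S_h(x)} (x_i − x). Iterating x ← x + m_h(x)
converges to a stationary point of the estimated density (a mode); points
sharing a mode form one cluster.

**Grid approximation.** All features lie in a bounded rectangle R, tiled by
cells of side 2e with counts w(i,j) and centres c(i,j). Two approximations
make the MSV cheap:

1. the sphere S_h is replaced by its circumscribing square R_h (Chebyshev
   ball of half-width h), so membership aligns with whole cells;
2. each point is replaced by its cell centre (error ≤ e per coordinate),
   giving m̂_h(x) = Σ w·c / Σ w − x over the cells within h_c =
   round(h/(2e)) cells of x's cell.

Summed-area tables W(k,l) = Σ_{i≤k,j≤l} w and M(k,l) = Σ_{i≤k,j≤l} w·c
evaluate both box sums with four lookups each. We use the exclusive
lower-corner convention (corners at indices m−h_c−1, n−h_c−1, zero outside
the table), which makes the four-lookup result *exactly* equal to the
inclusive double sum; windows are clipped at the grid edges, equivalent to
zero frequency outside the grid. Binning uses half-open intervals
[lo, lo+2e) with the top cell closed, so every point lands in exactly one
cell and interior boundary ties go to the higher-index cell.

**Seeding and assignment.** Mode seeking starts from the centre of every
occupied cell — not from raw pixels — which is what makes the clustering
cost a function of the number of occupied cells only. Each occupied cell
inherits the mode its seed converges to; each pixel inherits its cell's
mode through a constant-time cell lookup. Finally only the k most massive
clusters are kept; the cells of dropped modes move as blocks to the kept
mode whose mode point is nearest in Euclidean (a\*, b\*) distance (ties to
the larger-mass mode). Output labels are renumbered by cluster size
descending, so label 0 is always the largest cluster.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| e | max(range a\*, range b\*)/1000 | Lab | cell half-width; grid resolution |
| h | 40·e | Lab | window size (square half-width / sphere radius) |
| h_c | round(h/(2e)) = 20 | cells | window half-width on the grid |
| tol | max(e, 1e-3·h) | Lab | stop when ‖MSV‖₂ < tol |
| max_iter | 100 | — | iteration cap per seed (non-convergence flagged) |
| merge_radius | h | Lab | converged points closer than this join one mode |
| k | 3 | — | clusters kept after pruning |

The range/1000 rule ties the grid to the colour gamut actually used by the
stain; 40·e then puts ≈ 41×41 cells in a window, comfortably inside the
e ≪ h regime the cell-centre approximation needs (a warning fires below
h < 10·e). tol defaults to the cell resolution because sub-cell convergence
carries no information. The sRGB→Lab transform assumes the D65 white point
(2° observer); the illuminant is configurable for calibrated scanners.

**Merge radius.** Modes are deduplicated at one full bandwidth h, not a
fraction of it. Two reasons: the density estimate at bandwidth h cannot
resolve peaks closer than one window, and — decisive in practice — the
uniform kernel makes the shifted density piecewise constant, so iterates
from different seeds stall on plateaus scattered across a single basin.
With a smaller radius those stalled points surface as separate "modes",
and mass-ranked top-k pruning can then keep two fragments of one colour
class while dropping a genuine smaller class entirely. Merging within h
(the same rule scikit-learn's MeanShift applies) collapses the fragments;
well-separated classes (tens of Lab units apart at h ≈ 2) are unaffected.

**Vacuum windows.** A window containing no mass leaves the MSV undefined;
iteration stops immediately at the current point with a vacuum flag. With
occupied-cell seeding this can only arise through boundary clipping.

## Exact reference and oracle chain

`standard_ms_segment` runs the textbook algorithm — every raw pixel's
feature point iterated with the exact spherical-window MSV over all n
points — with the same merge and pruning rules. It is O(n²) per sweep and
guarded to ≤ 200×200 pixels (overridable), existing purely as the reference
the fast path is validated against.

The tests exploit a three-link oracle chain: sphere MSV (definition) →
square MSV (explicit filter-then-average) → four-lookup MSV. The last two
agree to 1e-9 when the points are snapped to their cell centres and the
square's half-width is set to e·(2h_c+1), which selects exactly the cells
the table lookups cover; against the raw points the discrepancy is bounded
by the snapping error e per coordinate.

## Synthetic fixtures

The generator emulates the colour statistics and gross geometry of
trichrome-stained liver sections: a lavender background (L\*60, a\*25,
b\*−15), white elliptical vessel/sinusoid blobs (L\*95, a\*0, b\*0) and
light-blue fibrosis ribbons (L\*70, a\*−10, b\*−25) drawn as smooth
random-walk curves 2–6 px wide; default area fractions 0.75/0.15/0.10.
Blobs are painted first with an inflated target so that ribbons overdrawing
them still leave achieved fractions within ±20 % of the request. Colour
noise is Gaussian per Lab channel (default σ = 2), applied in Lab — the
space the clustering operates in — so class separability is directly the
ratio of class distance (≈ 27–36 units) to σ. All randomness flows from one
integer seed through NumPy's PCG64 generator; fixed seed gives bit-identical
images across runs and platforms.

What the fixtures do *not* model: texture, nuclei, stain variation between
slides, chromatic aberration, or illumination fields. Passing tests
therefore demonstrate correctness of the clustering machinery under the
stated colour-mixture model, not segmentation quality on real slides, where
class overlap in (a\*, b\*) is the dominant difficulty.

A 2-D Gaussian-mixture generator provides feature-space fixtures for the
mode-seeking layer directly. For those point clouds the analysis bandwidth
is set relative to the component spread (h = 2 for unit-σ components) rather
than by the range/1000 image rule, which on a raw mixture yields h ≈ σ —
too narrow to treat one component as one peak.

## Numerical choices and degenerate inputs

* Integer frequencies accumulate in int64; tables in float64. Box sums over
  W are exact; over M they match brute force to better than 1e-12 here.
* Points outside the grid (possible only through iterate drift) clamp to
  the nearest boundary cell.
* A constant-colour image has a degenerate (zero-extent) feature space; the
  pipeline returns a single-cluster result with a warning instead of
  failing. Fewer modes than k likewise degrades gracefully.
* Mode ordering is deterministic: sorted by mass descending, ties broken by
  the row-major order of the first contributing cell; merging walks
  candidates in row-major seed order with first-come canonical
  representatives. The core contains no randomness.
* VoI uses base-2 logarithms (bits) with 0·log 0 ≡ 0; the base is
  configurable. The Rand index counts unordered pairs.

## Problem sizes used in the checks

The test suite and the acceptance script run on synthetic images between
32×32 and 256×256 pixels and mixtures up to 6 000 points: the exact O(n²)
reference is the binding constraint, and at 64×64 it already takes ~10 s
per image while the fast path takes ~0.03 s. The fast/exact agreement and
the constant-time evidence (bit-identical mode search under 4× pixel
replication, wall-time growth ratios) are invariant to this scale by
construction of the method.

## Known limitations

* Uniform kernels only; no Gaussian/Epanechnikov variants and no adaptive
  bandwidth.
* The feature space is strictly 2-D (a\*, b\*); higher-dimensional integral
  tables would be straightforward but are out of scope.
* No spatial regularisation or connectivity analysis: labels depend on
  colour alone (which the permutation-invariance test asserts as a
  feature).
* No stain normalisation or deconvolution; images from differently
  calibrated scanners should be harmonised upstream.
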