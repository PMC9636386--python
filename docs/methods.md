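# Methods

## Orientation analysis

### Model

Local orientation is estimated with a structure tensor: image gradients are
computed by Gaussian-derivative filtering at scale `sigma_gradient`
(default 1 px), the outer-product tensor components are smoothed with a
Gaussian window `sigma_window` (default 2 px), and each pixel receives the
orientation of the eigenvector belonging to the smaller eigenvalue — the
direction of least intensity variation, i.e. along tube-like structures.
Coherence (λ₁−λ₂)/(λ₁+λ₂) ∈ [0, 1] measures anisotropy; energy λ₁+λ₂
measures how much oriented structure is present. The defaults suit tube
widths ≥ 3 px; both sigmas are exposed.

Angles are degrees, counterclockwise positive as displayed, 0° = image
horizontal; orientations are axial and live on (−90°, 90°]. Analysis
follows the field's protocol: rotate the image so the contraction axis is
horizontal (right-angle rotations are exact index permutations, others
bilinear with zero fill), binarize, then estimate orientations *of the
binary image* under its own foreground mask.

### Distribution and bands

Orientations are accumulated into 180 half-open 1° bins covering
[−90°, 90°) (the single value +90° folds onto −90°). Pixels must pass the
mask, a coherence gate (default ≥ 0.2), and a relative energy gate
(default ≥ 1% of the image maximum); each contributes its energy (default;
`coherence*energy` and raw counts available). The parallel band is
[−10°, 10°), the perpendicular band [80°, 90°) ∪ [−90°, −80°) — half-open,
equal 20° widths, so an exactly uniform distribution yields ratio 1.0,
which is the parallel-equals-perpendicular reference line. A zero
perpendicular weight is reported as a flagged infinity rather than capped;
a fully gated-out distribution is flagged empty and the ratio is NaN.
Band sums are plain bin sums, and by construction equal the direct
per-pixel sums over the band, which the tests verify against an
independent per-pixel oracle.

The dominant orientation is the axial (double-angle) circular mean of the
binned distribution; with 1° bins its discretization bias is ≤ 0.5°.

### Binarization and cleanup

Otsu's method is implemented as an exhaustive search over observed
intensity levels (float images are quantized to 256 levels) maximizing
between-class variance, with ties resolved to the lowest threshold and the
inclusive convention foreground = intensity ≥ t, so masks are
bit-reproducible. A constant image is a flagged degenerate case (empty
mask plus warning), and a fixed-threshold mode exists for reproducibility.

The outlier-removal filter replaces a pixel by the median of its disk
neighborhood (default radius 3 px) when it deviates from that median by
more than `n_sd` (default 2) global standard deviations of the input.
The deviation gauge is stated in SD units; an absolute-threshold mode
(`abs_threshold`) matches the convention of common despeckle plugins whose
threshold is an absolute gray-level difference. Defaults sit at the
conservative ends of the commonly used 3–10 px / 1.5–2 SD ranges.

### Morphometry and content

Objects are 8-connected components; each is summarized by pixel area and
the moments-equivalent ellipse (axes from the eigenvalues of the
normalized second central moments, the standard "fit ellipse" convention),
giving aspect ratio = major/minor ≥ 1. Content is
100 × |structure ∧ fiber| / |fiber| with an explicit error on an empty
fiber mask. When no fiber tracing is available the full frame is the fiber
mask (the CLI default).

## Synthetic images

Tubes are infinite straight lines drawn with anti-aliased coverage
(clip(halfwidth + 0.5 − distance, 0, 1)) and binarized at ≥ 50% coverage,
so the truth mask is unambiguous; trig factors are rounded at 1e−12 so
right-angle families are exact and the two grid families receive equal
pixel weight. Jitter is one angle draw per tube — matching the visual
character of micrographs while keeping per-tube orientation truth well
defined. Gaussian read noise is additive. Generator defaults (256×256,
tube width 5 px, spacing 16 px, jitter 0, noise 0) are clean fixtures whose
ground truth is exact; realistic noise levels are opt-in parameters.

What the generator does *not* emulate: curved or branching mitochondria,
intensity variation along tubes, out-of-focus haze, tube ends inside the
frame, or sarcomere-locked spacing variation. Passing orientation tests on
these fixtures therefore demonstrates correctness of the estimator and the
band statistic, not robustness to every property of real micrographs.

## Synthetic proteomes

The default design mirrors the five-muscle study layout: wild-type flight
(fibrillar/parallel/salm-high), jump (tubular/parallel/salm-low), leg
(tubular/grid/salm-none), salm-KD flight (tubular/grid), and salm-OE leg
(fibrillar, leg-like network) with two replicate channels per muscle
(replicate count is a free parameter; the original multiplex layout is not
specified), baseline abundance 1e5 and mean-one multiplicative log-normal
noise (default CV 10%, a typical TMT reporter-level spread).

A protein planted for phenotype *p* with fold change *f* and sign + is
multiplied by f^strength_p(m) in muscle *m* (sign −: f^−strength). The
strengths are graded rather than 0/1:

| muscle          | fibrillar | tubular | parallel | grid | salm |
|-----------------|-----------|---------|----------|------|------|
| flight_wt       | 1         | 0       | 1        | 0    | 1    |
| jump_wt         | 0         | 1       | 1        | 0    | 0.75 |
| leg_wt          | 0         | 1       | 0.25     | 0.85 | 0    |
| flight_salm_kd  | 0         | 0.4     | 0        | 1    | 0.55 |
| leg_salm_oe     | 1         | 0       | 0.25     | 0.2  | 1    |

The grading is biologically motivated — whole-leg samples mix parallel
(Fiber I) and grid-like (Fibers II/III) fiber regions; RNAi knockdown
leaves residual salm expression (~half) and an incomplete molecular
conversion toward the tubular program; jump muscle expresses intermediate
salm — and it is also what makes the ten phenotype/sign classes
identifiable. With strictly 0/1 strengths, complementary classes (e.g. a
protein down in the fibrillar muscles vs one up in the tubular muscles)
would have abundance patterns identical up to a constant factor, hence
identical fold changes in *every* possible comparison: no ratio-threshold
screen could separate them, and that ambiguity is intrinsic, not an
implementation artifact.

At zero noise, realized fold changes between full-strength carriers and
non-carriers equal the requested fold change exactly; identical seeds give
bitwise-identical tables.

## Screen

Replicates are aggregated per muscle (mean by default; median available —
which convention the original analysis used is not stated, so both are
exposed and the published-table check tries both). fc = A/B with inclusive
thresholds: up iff fc ≥ 2.0, down iff fc ≤ 0.5. With the default
down = 1/up, the down-set of (A, B) equals the up-set of (B, A) exactly.
"Within 25%" is implemented symmetrically as max(fc, 1/fc) ≤ 1.25 since
the directionality of the published rule is not stated; the similarity
rule is available as an optional concordance filter but is not wired into
the default intersection logic, because where it gated the published
screen is likewise not stated.

Two comparison designs ship:

* **paper** — the Fibrillar± pairs are the four comparisons stated
  explicitly (flight vs leg, flight vs jump, flight vs salm-KD flight,
  salm-OE leg vs leg). The Tubular±, Parallel±, Grid± (three comparisons —
  grid-like muscles have one fewer informative contrast), and salm±
  designs are reconstructions from the phenotype table, marked
  `reconstructed` in their provenance fields: their exact published pair
  lists are not printed, only their Venn counts.
* **benchmark** — pair lists chosen, jointly with the strength table
  above, so that each planted class passes exactly its own design: for
  every other class at least one pair's fold change falls short of the
  threshold by a finite margin (e.g. a salm-responsive protein shows only
  4^0.25 ≈ 1.4 between flight and jump and is excluded from the Fibrillar+
  design by the flight-vs-jump pair). The derivation is a small linear
  constraint system over log-fold doses and was solved analytically; the
  recovery benchmarks use this design.

Every run asserts its structural invariants (each intersection contained
in each contributing comparison set; +/− sets of a phenotype disjoint;
union equals the union of the final sets) and echoes its full
configuration.

## Benchmark problem sizes and numerical choices

The recovery benchmarks use 300 background proteins plus 10 planted
proteins per class at fold change 4 (the noisy benchmark plants the
25-protein Fibrillar+ class over 20 seeds at CV 10%), and 256×256 images —
sizes at which every ground-truth property is exercised while the whole
suite runs in seconds. The noisy benchmark plants the Fibrillar+ class
because its four contrasts all carry the full fold change; classes that
rely on graded contrasts near the threshold (salm± through the 4^0.55 ≈
2.14 jump/KD contrasts) have intrinsically boundary-limited per-pair pass
probabilities under noise and are covered by the zero-noise exactness
check instead.

Morphometry fixtures place ellipses at half-pixel centers so
lattice-boundary effects (the Gauss circle-problem deficit of
integer-centered disks) stay well below the measurement tolerances.

## Limitations

* 2D only; no 3D network segmentation, rendering, or FIB-SEM handling.
* No ROI tracing: connected components replace manual per-mitochondrion
  tracing, so touching mitochondria merge into one object.
* The orientation plugin settings used in the original image analyses are
  not stated; the defaults here are declared choices, and per-image ratios
  are averaged per animal (pooling is the caller's choice).
* The screen operates on aggregated profiles; per-replicate concordance
  requirements are not imposed.
* External-filter protein identity is by plain id/gene-symbol match with a
  user-supplied list; no identifier-mapping service is consulted.
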