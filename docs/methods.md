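# Methods

## The evaluation model

`segscore` scores a test instance segmentation against a ground-truth
segmented image of the same dimensions. Both inputs are 2-D grids of
non-negative integers with background 0. The ground truth encodes objects
with a small set of non-zero intensity classes, reusing values across
non-touching objects (the four-color convention familiar from
hand-painted cell masks); the test image carries instance labels.

Two evaluations are computed from the same pair:

**Pixel level (traditional).** Both images are binarized (any non-zero
pixel is foreground) and pixels tallied as TP (foreground in both), FP
(test only) or FN (ground truth only). Precision = TP/(TP+FP),
Recall = TP/(TP+FN), F-measure = 2PR/(P+R). This view cannot see pixels
that land in the *wrong neighbouring object*: two segmentations with the
same foreground footprint but different internal boundaries score a
perfect 1.

**Per object.** Ground-truth objects are enumerated as connected
components within each intensity class (8-connectivity by default,
4 selectable). Each ground-truth object is matched to the test object
whose label is the most frequent within the object's footprint (modal
overlap; background ignored; ties resolve to the smallest label so runs
are deterministic). For object *k* with matched test object *m*:

    tp_k = |k ∩ m|,  fp_k = |m| − tp_k,  fn_k = |k| − tp_k

and an unmatched object (footprint entirely over test background) gets
tp = fp = 0, fn = |k|. Image-level per-object counts are
TP = Σ tp_k, FP = (total test foreground) − TP,
FN = (total gt foreground) − TP, so spurious test objects that match
nothing are still charged to precision and no test pixel is charged
twice even when one test object is the match of several ground-truth
objects (under-segmentation). At the per-object level, by contrast, the
literal formula above does double-charge a shared test object's pixels
in each of its matches; both behaviours are intentional and reported.

### Conventions and edge cases

- **0/0 → 0** for all three metrics, uniformly. Comparing an all-background
  image with an all-background image therefore scores precision 0: an empty
  segmentation is "nothing segmented", not "perfect". Only the precision
  case is forced by the tool's required extreme-case behaviour; extending
  the same convention to recall and F-measure is our choice, made for
  consistency.
- Pixel values must be non-negative integers (floats accepted only when
  exactly integral): labels are identities, not magnitudes.
- Any number (≥1) of ground-truth intensity classes is accepted. Four
  suffice to separate touching objects in a planar image, but nothing is
  gained by demanding exactly four — the binary and two-class validation
  fixtures would otherwise be rejected.
- Test labels need not be sequential; distinct values are canonicalized
  to 1..n, one instance per distinct value. With
  `split_test_components=True` a reused value is first split into its
  connected components.
- Metrics are kept at full float precision; rounding is purely a display
  concern (the CLI prints 4 decimals).

### Known properties and their limits

- Role-swap duality: swapping ground truth and test exchanges precision
  and recall, at the pixel level always and per object whenever the
  matching is bijective.
- Per-object TP summed over objects equals image-level per-object TP and
  is bounded by pixel-level TP.
- Metrics are invariant under relabeling test instances, remapping
  ground-truth class values, translating the whole scene, and adding
  disjoint copies of the scene. One caveat: when two test objects tie
  exactly on modal overlap, the deterministic smallest-label tie-break can
  select a different object after relabeling, changing that single
  object's fp; per-object tp/fn and all image-level metrics are unaffected
  by ties.

## Synthetic validation data

The `synthesis` module generates every input the validation suite uses;
no external data is required.

- `make_constant` / `make_half`: the binary extreme cases — all-1 vs
  all-1 (precision 1), all-0 vs all-0 (precision 0), and the four
  half-white 256×256 images whose pairwise precision matrix is exactly
  {diagonal 1, complements 0, orthogonal 0.5}.
- `make_adjacent_pair`: two grayscale images of two adjacent objects
  (intensities 100 and 200) sharing one connected footprint — by default
  a two-overlapping-disc blob centered in a 256×256 frame — but split at
  different vertical boundaries. Any such pair has pixel-level precision
  1 while per-object precision < 1; that gap is the point of the
  per-object method. The published two-circle figure this emulates does
  not state its geometry (centers, radii, boundary shape), so the exact
  per-object values of that figure are not reproduced; a 10×10
  all-foreground rectangle split at columns 5 vs 7 serves as the
  hand-enumerable reference instead (object 1: P = 50/70 ≈ 0.7143,
  R = 1; object 2: P = 1, R = 0.6; image level P = R = F = 0.8).
- `make_cell_field`: seeded random fields of non-overlapping discs
  (defaults: 256×256, 12 discs of radius 6–14 px, ≥3 px gaps), four-colored
  into a ground-truth image, plus a test labeling perturbed per object
  (delete, 1-px dilate, 1-px erode, or merge of a pair) whose per-object
  TP/FP/FN are known analytically — the ≥3 px gap guarantees a dilation
  ring stays in background, keeping the truth table exact.
- `four_color_relabel`: greedy coloring of the object-adjacency graph
  (descending size, ties by id) onto intensities {50, 100, 150, 200},
  extending the palette in the (practically unreached) case greedy needs
  more colors.

What the generator does *not* emulate: fluorescence texture, intensity
noise, irregular cell shapes, out-of-focus boundaries, or annotation
error. Passing tests therefore demonstrate the correctness of the
counting and matching arithmetic, not segmentation quality on real
microscopy — on real data the evaluator is only as meaningful as its
hand-segmented reference.

## Problem sizes

All validation fixtures are desk scale: 256×256 single pairs evaluate in
well under a second, and the brute-force cross-checks run on 200 random
scenes of up to 20×20 pixels, where a per-pixel Python loop is still an
honest independent oracle.

## Limitations

- One object class at a time; multi-class outputs must be evaluated
  class by class.
- 2-D only; no 3-D stacks.
- Hard label maps only; no probabilistic/soft masks.
- Matching is ground-truth-driven and modal: a test object can be the
  match of several ground-truth objects, and an unmatched test object
  appears only in the image-level FP and the `n_unmatched_test` count,
  not as a report row.
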