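# segscore

Per-object evaluation of multi-object instance segmentation.

Segmentation results — CellProfiler masks of fluorescence microscopy
images, hand-painted cell annotations, color-coded instance maps — are
usually scored against a ground truth at the pixel level: binarize both
images, count TP/FP/FN pixels, report Precision, Recall and F-measure.
That view is blind to the error that matters most for densely packed
cells: a pixel correctly called *foreground* but attributed to the wrong
neighbouring cell. Two segmentations with identical outlines but
different internal cell boundaries score a perfect 1.

`segscore` computes, alongside the traditional pixel-level metrics, a
**per-object** evaluation: each ground-truth object is matched to the
test object whose label is most frequent inside its footprint (modal
overlap), and TP/FP/FN pixels are counted per matched pair,

```
tp_k = |gt_k ∩ test_m|      fp_k = |test_m| − tp_k      fn_k = |gt_k| − tp_k
P = TP/(TP+FP)              R = TP/(TP+FN)              F = 2PR/(P+R)
```

with image-level per-object counts charging every unmatched test pixel
(TP = Σ tp_k, FP = total test foreground − TP, FN = total ground-truth
foreground − TP). Misassigned boundary pixels now cost precision and
recall, and each object gets its own metric row so poorly segmented
cells can be found individually. All 0/0 denominators yield 0, so an
empty-vs-empty comparison scores 0, not 1.

Ground-truth images encode objects with a handful of intensity values
reused across non-touching objects (four values always suffice — the
four-color convention); test images carry one label per instance. The
package is for anyone tuning or benchmarking an instance segmenter:
microscopists comparing CellProfiler pipelines, method developers
validating a new cell segmentation model.

## Worked example

Two 256×256 grayscale images of two adjacent objects (intensities 100
and 200) that share the same outer footprint but split it at different
internal boundaries:

```python
from segscore import evaluate, make_adjacent_pair
from segscore.reporting_io import format_summary, report_to_frame

gt, test = make_adjacent_pair(256, 256)
report = evaluate(gt, test)
print(format_summary(report))
print(report_to_frame(report, image_id="adjacent_b").to_string(index=False))
```

prints

```
ground-truth intensity classes: [100, 200]
ground-truth objects: 2   test objects: 2   unmatched test objects: 0
pixel-level:  precision=1.0000  recall=1.0000  f-measure=1.0000
per-object:   precision=0.7929  recall=0.7929  f-measure=0.7929

  image_id  gt_id  matched_test_id   tp   fp   fn  precision   recall  f_measure
adjacent_b      1                1 7667 3188    0    0.70631 1.000000   0.827880
adjacent_b      2                2 4542    0 3188    1.00000 0.587581   0.740222
```

Read: the two foreground footprints coincide exactly, so the pixel-level
metrics are all 1 — the traditional method calls this segmentation
perfect. Per object, the 3188 pixels lying between the two candidate
boundaries belong to object 2 in the ground truth but were assigned to
object 1 in the test image: object 1's match contains them as false
positives (precision 0.71) and object 2's match misses them as false
negatives (recall 0.59). Swapping ground truth and test transposes each
object's precision and recall.

The same evaluation is available from a shell:

```sh
segscore fixtures adjacent-pair --out-dir fixtures
segscore evaluate --gt fixtures/adjacent_a.png --test fixtures/adjacent_b.png \
    --out-csv per_object_metrics.csv
```

which prints the summary above (classes first, then pixel-level, then
per-object metrics) and writes one CSV row per ground-truth object.
`segscore fixtures` also generates the other validation families:
constant images, the four half-white/half-black images, and seeded
random cell fields with a known per-object truth table.

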