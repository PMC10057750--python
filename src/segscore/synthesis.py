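"""Deterministic generation of validation images with known ground truth.

Provides the canonical fixture families used to validate the evaluator:
constant binary images, half-white/half-black images, adjacent-object
pairs that share a foreground footprint but split it differently, and
randomized cell fields (non-overlapping discs, four-colored) with a
perturbed test labeling whose per-object TP/FP/FN counts are known
analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_metrics import PixelCounts, validate_label_image
from .object_eval import ObjectMap, _structure, label_objects

__all__ = [
    "SceneSpec",
    "make_constant",
    "make_half",
    "make_adjacent_pair",
    "disc_pair_footprint",
    "make_cell_field",
    "four_color_relabel",
]

FOUR_COLOR_PALETTE = (50, 100, 150, 200)


@dataclass
class SceneSpec:
    """Parameters of a randomized cell field.

    Discs are placed by rejection sampling with at least *min_gap*
    background pixels between any two objects, so a one-pixel dilation
    of one object cannot touch another.
    """

    height: int = 256
    width: int = 256
    n_objects: int = 12
    radius_range: tuple[int, int] = (6, 14)
    min_gap: int = 3
    seed: int = 0
    # per-object perturbations of the test image: id -> "delete"|"dilate"|"erode"
    perturb: dict[int, str] = field(default_factory=dict)
    # pairs of gt object ids merged into one test label
    merge_pairs: list[tuple[int, int]] = field(default_factory=list)


def make_constant(height: int, width: int, value: int) -> np.ndarray:
    """Constant image (all pixels equal to *value*)."""
    if height <= 0 or width <= 0:
        raise ValueError("dimensions must be positive")
    if value not in (0, 1):
        raise ValueError("constant fixtures are binary: value must be 0 or 1")
    return np.full((height, width), value, dtype=np.uint8)


def make_half(
    height: int, width: int, orientation: str, white_side: str
) -> np.ndarray:
    """Half-white (1), half-black (0) image split along one axis.

    ``orientation`` "horizontal" splits into top/bottom halves,
    "vertical" into left/right; ``white_side`` "first"/"second" selects
    which half is foreground.  The four combinations give one quadrant
    of overlap between any horizontal/vertical pair and zero overlap
    between complements.
    """
    if orientation not in ("horizontal", "vertical"):
        raise ValueError(f"orientation must be horizontal or vertical: {orientation}")
    if white_side not in ("first", "second"):
        raise ValueError(f"white_side must be first or second: {white_side}")
    split_dim = height if orientation == "horizontal" else width
    if split_dim % 2:
        raise ValueError(f"split dimension {split_dim} must be even")
    img = np.zeros((height, width), dtype=np.uint8)
    if orientation == "horizontal":
        half = slice(None, height // 2) if white_side == "first" else slice(height // 2, None)
        img[half, :] = 1
    else:
        half = slice(None, width // 2) if white_side == "first" else slice(width // 2, None)
        img[:, half] = 1
    return img


def disc_pair_footprint(height: int, width: int, radius: int | None = None) -> np.ndarray:
    """Connected blob formed by two overlapping discs, centered in the image.

    Emulates a cluster of two adjacent round cells whose outer perimeter
    is shared between ground truth and test.
    """
    if radius is None:
        radius = min(height, width) // 5
    cy = height // 2
    yy, xx = np.mgrid[0:height, 0:width]
    cx1 = width // 2 - int(radius * 0.8)
    cx2 = width // 2 + int(radius * 0.8)
    blob = ((yy - cy) ** 2 + (xx - cx1) ** 2 <= radius**2) | (
        (yy - cy) ** 2 + (xx - cx2) ** 2 <= radius**2
    )
    return blob


def _split_footprint(footprint: np.ndarray, split_col: int) -> np.ndarray:
    """Partition a footprint at a column: left part 100, right part 200."""
    img = np.zeros(footprint.shape, dtype=np.uint8)
    img[footprint] = 200
    left = footprint.copy()
    left[:, split_col:] = False
    img[left] = 100
    if not left.any() or not (footprint & ~left).any():
        raise ValueError(f"split at column {split_col} leaves an empty part")
    for part in (left, footprint & ~left):
        _, n = ndimage.label(part, structure=_structure(8))
        if n != 1:
            raise ValueError(f"split at column {split_col} disconnects a part")
    return img


def make_adjacent_pair(
    height: int,
    width: int,
    footprint: np.ndarray | None = None,
    split_a: int | None = None,
    split_b: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two images of two adjacent objects sharing one foreground footprint.

    Each image partitions the same connected footprint into two adjacent
    objects at a vertical boundary (columns < split → intensity 100,
    remainder → 200); the two images differ only in where the boundary
    lies.  With *footprint* omitted, a two-disc blob is used and the
    splits default to the blob's vertical midline shifted by ∓/± one
    fifth of the blob width.
    """
    if footprint is None:
        footprint = disc_pair_footprint(height, width)
    else:
        footprint = np.asarray(footprint).astype(bool)
        if footprint.shape != (height, width):
            raise ValueError(
                f"footprint shape {footprint.shape} != ({height}, {width})"
            )
    if not footprint.any():
        raise ValueError("empty footprint")
    cols = np.where(footprint.any(axis=0))[0]
    if split_a is None:
        split_a = width // 2
    if split_b is None:
        split_b = width // 2 + max(1, (cols[-1] - cols[0]) // 5)
    return _split_footprint(footprint, split_a), _split_footprint(footprint, split_b)


def four_color_relabel(
    objects: ObjectMap, connectivity: int = 8, palette: tuple[int, ...] = FOUR_COLOR_PALETTE
) -> np.ndarray:
    """Recolor an object map so touching objects get distinct intensities.

    Greedy coloring of the object-adjacency graph (objects adjacent iff
    any two of their pixels touch within *connectivity*), visiting
    objects in descending size (ties by id).  Four intensities suffice
    for planar adjacency in practice; extra levels are appended if the
    greedy order ever needs more.
    """
    labels = objects.labels
    structure = _structure(connectivity)
    adjacency: dict[int, set[int]] = {i: set() for i in range(1, objects.n_objects + 1)}
    # neighbors via one dilation per object would be O(K*N); instead compare
    # label pairs across each neighbor offset once
    offsets = np.argwhere(structure) - 1
    for dy, dx in offsets:
        if dy == 0 and dx == 0:
            continue
        a = labels[max(0, dy) : labels.shape[0] + min(0, dy),
                   max(0, dx) : labels.shape[1] + min(0, dx)]
        b = labels[max(0, -dy) : labels.shape[0] + min(0, -dy),
                   max(0, -dx) : labels.shape[1] + min(0, -dx)]
        touching = (a > 0) & (b > 0) & (a != b)
        for u, v in zip(a[touching].tolist(), b[touching].tolist()):
            adjacency[u].add(v)
            adjacency[v].add(u)

    order = sorted(
        range(1, objects.n_objects + 1), key=lambda i: (-objects.sizes[i - 1], i)
    )
    colors = list(palette)
    assigned: dict[int, int] = {}
    for obj in order:
        used = {assigned[n] for n in adjacency[obj] if n in assigned}
        choice = next((c for c in colors if c not in used), None)
        if choice is None:
            choice = max(colors) + 50
            colors.append(choice)
        assigned[obj] = choice

    out = np.zeros(labels.shape, dtype=np.int32)
    for obj, color in assigned.items():
        out[labels == obj] = color
    return out


def _place_discs(spec: SceneSpec) -> ObjectMap:
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    labels = np.zeros((spec.height, spec.width), dtype=np.int32)
    occupied = np.zeros_like(labels, dtype=bool)  # objects + their exclusion margin
    sizes = []
    placed = 0
    attempts = 0
    max_attempts = 2000 * spec.n_objects
    while placed < spec.n_objects:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_objects} discs in "
                f"{spec.height}x{spec.width} after {max_attempts} attempts"
            )
        r = int(rng.integers(spec.radius_range[0], spec.radius_range[1] + 1))
        margin = r + spec.min_gap + 1
        cy = int(rng.integers(margin, spec.height - margin))
        cx = int(rng.integers(margin, spec.width - margin))
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disc = d2 <= r * r
        halo = d2 <= (r + spec.min_gap) ** 2
        if (halo & occupied).any():
            continue
        placed += 1
        labels[disc] = placed
        occupied |= halo
        sizes.append(int(disc.sum()))
    return ObjectMap(
        labels=labels,
        sizes=np.asarray(sizes, dtype=np.int64),
        source_class=np.arange(1, placed + 1, dtype=np.int64),
    )


def make_cell_field(
    spec: SceneSpec,
) -> tuple[np.ndarray, np.ndarray, dict[int, PixelCounts]]:
    """Randomized cell field with an analytically known truth table.

    Returns ``(gt, test, truth)`` where *gt* is the four-colored
    ground-truth image, *test* a label image derived from the same
    objects by the perturbations in the spec, and *truth* maps each
    ground-truth object id to the exact per-object TP/FP/FN counts the
    evaluator must report.

    Supported perturbations per object: ``delete`` (object missing from
    test), ``dilate`` (grown by one pixel into guaranteed background),
    ``erode`` (shrunk by one pixel).  ``merge_pairs`` assigns two
    objects one shared test label (under-segmentation); a merged pair
    cannot also carry another perturbation.
    """
    objects = _place_discs(spec)
    gt = four_color_relabel(objects)

    merged = {i for pair in spec.merge_pairs for i in pair}
    for pair in spec.merge_pairs:
        if len(set(pair)) != 2:
            raise ValueError(f"merge pair {pair} must name two distinct objects")
        if any(i in spec.perturb for i in pair):
            raise ValueError(f"merge pair {pair} overlaps with perturbed objects")
    for oid, kind in spec.perturb.items():
        if kind not in ("delete", "dilate", "erode"):
            raise ValueError(f"unknown perturbation {kind!r} for object {oid}")
        if not 1 <= oid <= objects.n_objects:
            raise ValueError(f"perturbed object {oid} does not exist")

    structure = _structure(8)
    test = np.zeros_like(objects.labels)
    truth: dict[int, PixelCounts] = {}
    test_sizes: dict[int, int] = {}
    next_label = 1
    label_of: dict[int, int] = {}

    handled: set[int] = set()
    for a, b in spec.merge_pairs:
        lab = next_label
        next_label += 1
        size = 0
        for oid in (a, b):
            m = objects.mask(oid)
            test[m] = lab
            size += int(m.sum())
            label_of[oid] = lab
            handled.add(oid)
        test_sizes[lab] = size

    for oid in range(1, objects.n_objects + 1):
        if oid in handled:
            continue
        kind = spec.perturb.get(oid)
        if kind == "delete":
            continue
        m = objects.mask(oid)
        if kind == "dilate":
            m = ndimage.binary_dilation(m, structure=structure)
        elif kind == "erode":
            m = ndimage.binary_erosion(m, structure=structure)
            if not m.any():
                raise ValueError(f"erosion removed object {oid} entirely")
        lab = next_label
        next_label += 1
        test[m] = lab
        label_of[oid] = lab
        test_sizes[lab] = int(m.sum())

    for oid in range(1, objects.n_objects + 1):
        size = int(objects.sizes[oid - 1])
        if oid in merged:
            lab = label_of[oid]
            truth[oid] = PixelCounts(tp=size, fp=test_sizes[lab] - size, fn=0)
            continue
        kind = spec.perturb.get(oid)
        if kind == "delete":
            truth[oid] = PixelCounts(tp=0, fp=0, fn=size)
        elif kind == "dilate":
            lab = label_of[oid]
            truth[oid] = PixelCounts(tp=size, fp=test_sizes[lab] - size, fn=0)
        elif kind == "erode":
            lab = label_of[oid]
            truth[oid] = PixelCounts(
                tp=test_sizes[lab], fp=0, fn=size - test_sizes[lab]
            )
        else:
            truth[oid] = PixelCounts(tp=size, fp=0, fn=0)

    # Re-key the truth table to the canonical gt object ids an evaluator
    # derives from the four-colored image (class-ascending, scan order),
    # which generally differ from placement order.
    gt_map = label_objects(gt, connectivity=8)
    canonical_truth: dict[int, PixelCounts] = {}
    for oid in range(1, objects.n_objects + 1):
        ys, xs = np.nonzero(objects.labels == oid)
        canonical_id = int(gt_map.labels[ys[0], xs[0]])
        canonical_truth[canonical_id] = truth[oid]

    validate_label_image(gt)
    return gt, test.astype(np.int32), canonical_truth
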