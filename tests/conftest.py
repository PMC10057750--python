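"""Shared fixtures and brute-force reference implementations.

The oracles here deliberately use per-pixel Python loops and explicit
flood fill so they stay independent of the vectorized implementation
they check.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest


# ---------------------------------------------------------------- oracles
def brute_pixel_counts(gt_mask, test_mask):
    """Per-pixel double loop TP/FP/FN tally."""
    tp = fp = fn = 0
    for i in range(gt_mask.shape[0]):
        for j in range(gt_mask.shape[1]):
            g, t = gt_mask[i, j] > 0, test_mask[i, j] > 0
            if g and t:
                tp += 1
            elif t:
                fp += 1
            elif g:
                fn += 1
    return tp, fp, fn


def brute_flood_fill(image, connectivity=8):
    """Connected components per intensity class via BFS flood fill.

    Returns a label array with ids assigned class-ascending then in scan
    order of each component's first pixel, matching the canonical order.
    """
    h, w = image.shape
    labels = np.zeros((h, w), dtype=int)
    if connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    next_id = 1
    for value in sorted(set(image.ravel().tolist()) - {0}):
        for i in range(h):
            for j in range(w):
                if image[i, j] != value or labels[i, j] != 0:
                    continue
                queue = deque([(i, j)])
                labels[i, j] = next_id
                while queue:
                    y, x = queue.popleft()
                    for dy, dx in offsets:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and labels[ny, nx] == 0 \
                                and image[ny, nx] == value:
                            labels[ny, nx] = next_id
                            queue.append((ny, nx))
                next_id += 1
    return labels


def brute_per_object(gt, test_labels, connectivity=8):
    """Reference per-object evaluation by direct overlap enumeration.

    test_labels must already be canonical 1..n.  Returns a list of
    (gt_id, matched_or_None, tp, fp, fn) in gt id order.
    """
    gt_objects = brute_flood_fill(gt, connectivity)
    n_gt = gt_objects.max()
    test_sizes = {}
    for lab in set(test_labels.ravel().tolist()) - {0}:
        test_sizes[lab] = int((test_labels == lab).sum())
    results = []
    for gid in range(1, n_gt + 1):
        overlap = {}
        size = 0
        for i in range(gt.shape[0]):
            for j in range(gt.shape[1]):
                if gt_objects[i, j] != gid:
                    continue
                size += 1
                lab = test_labels[i, j]
                if lab > 0:
                    overlap[lab] = overlap.get(lab, 0) + 1
        if not overlap:
            results.append((gid, None, 0, 0, size))
            continue
        best = max(overlap.values())
        matched = min(lab for lab, c in overlap.items() if c == best)
        tp = overlap[matched]
        results.append((gid, matched, tp, test_sizes[matched] - tp, size - tp))
    return results


def random_scene(rng, max_side=20, n_classes=2, n_test_labels=3, density=0.45):
    """Random small ground-truth/test pair for oracle comparisons."""
    h = int(rng.integers(4, max_side + 1))
    w = int(rng.integers(4, max_side + 1))
    class_values = [100, 200, 50, 150][:n_classes]
    gt = np.zeros((h, w), dtype=int)
    fg = rng.random((h, w)) < density
    gt[fg] = rng.choice(class_values, size=int(fg.sum()))
    test = np.zeros((h, w), dtype=int)
    fg_t = rng.random((h, w)) < density
    test[fg_t] = rng.integers(1, n_test_labels + 1, size=int(fg_t.sum()))
    return gt, test


# ---------------------------------------------------------------- fixtures
@pytest.fixture
def split_rect_pair():
    """10x10 all-foreground rectangle split at column 5 (gt) vs column 7 (test)."""
    gt = np.zeros((10, 10), dtype=int)
    gt[:, :5] = 100
    gt[:, 5:] = 200
    test = np.zeros((10, 10), dtype=int)
    test[:, :7] = 100
    test[:, 7:] = 200
    return gt, test


@pytest.fixture
def rng():
    return np.random.default_rng(20230329)
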