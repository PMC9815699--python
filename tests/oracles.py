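"""Independent brute-force oracles used by the test suite.

These deliberately use the most literal algorithm available (explicit
queues, nested loops, exhaustive enumeration) and share no code with the
implementations they check.
"""

from collections import deque

import numpy as np


def bfs_region_grow(image: np.ndarray, seed: tuple[int, int],
                    threshold: float, connectivity: int = 8) -> np.ndarray:
    """Breadth-first flood fill with a fixed seed-color criterion."""
    h, w = image.shape[:2]
    seed_color = image[seed].astype(float)
    mask = np.zeros((h, w), dtype=bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    queue = deque([seed])
    mask[seed] = True
    while queue:
        r, c = queue.popleft()
        for dr, dc in nbrs:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and not mask[nr, nc]:
                d = np.linalg.norm(image[nr, nc].astype(float) - seed_color)
                if d <= threshold:
                    mask[nr, nc] = True
                    queue.append((nr, nc))
    return mask


def nms_quadratic(boxes, iou_threshold: float, conf_threshold: float):
    """O(n^2) greedy class-wise suppression over
    (cls, conf, x1, y1, x2, y2) tuples."""
    def iou(a, b):
        ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
        iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
        inter = ix * iy
        u = ((a[2] - a[0]) * (a[3] - a[1])
             + (b[2] - b[0]) * (b[3] - b[1]) - inter)
        return inter / u if u > 0 else 0.0

    remaining = sorted([b for b in boxes if b[1] >= conf_threshold],
                       key=lambda b: -b[1])
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [b for b in remaining
                     if b[0] != best[0] or iou(b[2:], best[2:]) <= iou_threshold]
    return kept


def ap_enumerated(tp_flags, n_truth: int) -> float:
    """Area under the precision-envelope/recall step function, built point
    by point from the ranked TP/FP sequence."""
    points = [(0.0, 1.0)]
    tp = fp = 0
    for flag in tp_flags:
        tp, fp = tp + int(flag), fp + int(not flag)
        points.append((tp / n_truth, tp / (tp + fp)))
    # precision envelope: max precision at any recall >= r
    area = 0.0
    recalls = sorted({r for r, _ in points})
    for r0, r1 in zip(recalls[:-1], recalls[1:]):
        p_env = max(p for r, p in points if r >= r1)
        area += (r1 - r0) * p_env
    return area


def involution_nested_loops(x: np.ndarray, kernels: np.ndarray,
                            groups: int, k: int) -> np.ndarray:
    """Per-position, per-tap, per-channel involution (stride 1)."""
    n, c, h, w = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros_like(x)
    cpg = c // groups
    for b in range(n):
        for ch in range(c):
            g = ch // cpg
            for i in range(h):
                for j in range(w):
                    acc = 0.0
                    for a in range(k):
                        for bb in range(k):
                            acc += (kernels[b, g * k * k + a * k + bb, i, j]
                                    * xp[b, ch, i + a, j + bb])
                    out[b, ch, i, j] = acc
    return out


def asff_pixel_loops(maps, weights: np.ndarray) -> np.ndarray:
    """Per-position scalar weighted sum of three maps."""
    n, c, h, w = maps[0].shape
    out = np.zeros((n, c, h, w))
    for b in range(n):
        for ch in range(c):
            for i in range(h):
                for j in range(w):
                    out[b, ch, i, j] = sum(
                        weights[b, s, i, j] * maps[s][b, ch, i, j]
                        for s in range(3))
    return out


def greedy_match_bruteforce(dets, truths, thr):
    """Confidence-ordered greedy matching returning TP flags + FN count."""
    def iou(a, b):
        ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
        iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
        inter = ix * iy
        u = ((a[2] - a[0]) * (a[3] - a[1])
             + (b[2] - b[0]) * (b[3] - b[1]) - inter)
        return inter / u if u > 0 else 0.0

    order = sorted(range(len(dets)), key=lambda i: -dets[i][0])
    used = set()
    flags = []
    for i in order:
        cands = [(iou(dets[i][1:], t), j) for j, t in enumerate(truths)
                 if j not in used]
        cands = [c for c in cands if c[0] >= thr]
        if cands:
            best = max(cands)
            used.add(best[1])
            flags.append(True)
        else:
            flags.append(False)
    return flags, len(truths) - len(used)
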