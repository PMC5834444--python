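"""Independent brute-force oracles used to verify the package's fast paths.

Everything here is written as plainly as possible — explicit loops, explicit
enumeration — and must stay independent of the implementation it checks.
"""
import heapq
import itertools

import numpy as np


# ---------------------------------------------------------------------------
# first-order histogram oracle
# ---------------------------------------------------------------------------

def entropy_uniformity_oracle(levels, n_levels):
    """Histogram entropy (bits) and uniformity by direct counting."""
    counts = {}
    for v in levels:
        counts[int(v)] = counts.get(int(v), 0) + 1
    n = len(levels)
    entropy = 0.0
    uniformity = 0.0
    for c in counts.values():
        p = c / n
        entropy -= p * np.log2(p)
        uniformity += p * p
    return entropy, uniformity


def first_order_oracle(values, levels, n_levels):
    """All 14 first-order statistics computed with explicit loops."""
    x = [float(v) for v in values]
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    entropy, uniformity = entropy_uniformity_oracle(levels, n_levels)
    return {
        "energy": sum(v * v for v in x),
        "entropy": entropy,
        "kurtosis": (m4 / m2**2 - 3.0) if m2 > 0 else 0.0,
        "maximum": max(x),
        "mean": mean,
        "mean_absolute_deviation": sum(abs(v - mean) for v in x) / n,
        "median": float(np.median(x)),
        "minimum": min(x),
        "range": max(x) - min(x),
        "root_mean_square": (sum(v * v for v in x) / n) ** 0.5,
        "skewness": (m3 / m2**1.5) if m2 > 0 else 0.0,
        "standard_deviation": m2**0.5,
        "uniformity": uniformity,
        "variance": m2,
    }


# ---------------------------------------------------------------------------
# GLCM pair-enumeration oracle
# ---------------------------------------------------------------------------

def glcm_oracle_matrix(level_volume, n_levels, direction):
    """Symmetric normalised co-occurrence matrix by explicit pair enumeration."""
    shape = level_volume.shape
    mat = np.zeros((n_levels, n_levels))
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                a = level_volume[i, j, k]
                if a == 0:
                    continue
                ii, jj, kk = i + direction[0], j + direction[1], k + direction[2]
                if not (0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]):
                    continue
                b = level_volume[ii, jj, kk]
                if b == 0:
                    continue
                mat[a - 1, b - 1] += 1
                mat[b - 1, a - 1] += 1
    total = mat.sum()
    return mat / total if total else None


# ---------------------------------------------------------------------------
# GLRLM run-enumeration oracle
# ---------------------------------------------------------------------------

def glrlm_oracle_matrix(level_volume, n_levels, direction):
    """Run-length matrix by walking every line in ``direction`` voxel by voxel."""
    shape = level_volume.shape
    d = tuple(direction)
    runs = {}

    def in_bounds(p):
        return all(0 <= p[a] < shape[a] for a in range(3))

    visited = set()
    for start in itertools.product(*(range(s) for s in shape)):
        prev = (start[0] - d[0], start[1] - d[1], start[2] - d[2])
        if in_bounds(prev):
            continue  # not the head of a line
        p = start
        run_level, run_len = 0, 0
        while in_bounds(p):
            assert p not in visited
            visited.add(p)
            lev = int(level_volume[p])
            if lev == run_level and lev != 0:
                run_len += 1
            else:
                if run_level != 0:
                    runs[(run_level, run_len)] = runs.get((run_level, run_len), 0) + 1
                run_level, run_len = lev, (1 if lev != 0 else 0)
            p = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
        if run_level != 0:
            runs[(run_level, run_len)] = runs.get((run_level, run_len), 0) + 1

    if not runs:
        return np.zeros((n_levels, 1))
    max_len = max(l for _, l in runs)
    mat = np.zeros((n_levels, max_len))
    for (g, l), c in runs.items():
        mat[g - 1, l - 1] = c
    return mat


# ---------------------------------------------------------------------------
# marker-flood watershed oracle (Meyer's algorithm, 6-connectivity)
# ---------------------------------------------------------------------------

def flood_oracle(image, markers, mask):
    """Priority flood of -image from markers, ascending by flooding height.

    Matches marker-based watershed on tie-free images: voxels are popped in
    increasing order of ``-image`` (i.e. decreasing SUV) and take the label of
    the neighbour that queued them.
    """
    shape = image.shape
    labels = np.zeros(shape, dtype=np.int32)
    heap = []
    counter = 0
    neighbours = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

    marker_voxels = np.argwhere(markers > 0)
    for v in marker_voxels:
        p = tuple(int(x) for x in v)
        labels[p] = markers[p]
    for v in marker_voxels:
        p = tuple(int(x) for x in v)
        for d in neighbours:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if all(0 <= q[a] < shape[a] for a in range(3)) and mask[q] and labels[q] == 0:
                heapq.heappush(heap, (-float(image[q]), counter, q, labels[p]))
                counter += 1
    while heap:
        _, _, p, lab = heapq.heappop(heap)
        if labels[p] != 0:
            continue
        labels[p] = lab
        for d in neighbours:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if all(0 <= q[a] < shape[a] for a in range(3)) and mask[q] and labels[q] == 0:
                heapq.heappush(heap, (-float(image[q]), counter, q, lab))
                counter += 1
    return labels


# ---------------------------------------------------------------------------
# exhaustive constrained-assignment oracle
# ---------------------------------------------------------------------------

def exhaustive_assignment_oracle(prob, classes, tumor_class="tumor", eps=1e-9):
    """Best feasible labelling by enumerating every label tuple."""
    n, k = prob.shape
    logp = np.log(prob + eps)
    normal = [c for c in classes if c != tumor_class]
    best_obj, best_labels = -np.inf, None
    for combo in itertools.product(range(k), repeat=n):
        used = [classes[c] for c in combo if classes[c] != tumor_class]
        if len(used) != len(set(used)):
            continue
        obj = sum(logp[i, c] for i, c in enumerate(combo))
        if obj > best_obj:
            best_obj = obj
            best_labels = tuple(classes[c] for c in combo)
    return best_obj, best_labels


# ---------------------------------------------------------------------------
# closed-form OLS oracle
# ---------------------------------------------------------------------------

def ols_oracle(x, y):
    """Slope, intercept and R^2 from the textbook normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    syy = ((y - ym) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    return slope, ym - slope * xm, sxy**2 / (sxx * syy)


def feasible_label_tuples(n_regions, n_classes, tumor_index):
    """All labelings using each non-tumor class at most once (enumerated once,
    reused across matrices)."""
    tuples = [
        combo
        for combo in itertools.product(range(n_classes), repeat=n_regions)
        if all(
            c == tumor_index or combo.count(c) == 1
            for c in set(combo)
        )
    ]
    return np.array(tuples, dtype=np.intp).reshape(len(tuples), n_regions)


def exhaustive_assignment_oracle_fast(prob, classes, tumor_class="tumor", eps=1e-9,
                                      _cache={}):
    """Vectorised exhaustive search over all feasible label tuples."""
    n, k = prob.shape
    key = (n, k, classes.index(tumor_class))
    if key not in _cache:
        _cache[key] = feasible_label_tuples(n, k, classes.index(tumor_class))
    tuples = _cache[key]
    logp = np.log(prob + eps)
    objs = logp[np.arange(n)[None, :], tuples].sum(axis=1)
    best = int(np.argmax(objs))
    return float(objs[best]), tuple(classes[c] for c in tuples[best])
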