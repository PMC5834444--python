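"""Radiomics features: 14 first-order, 14 shape (8 standard + 6 spatial) and
34 texture (23 GLCM + 11 GLRLM) features per segmented region.

First-order features are statistics of the region's SUV samples; entropy and
uniformity are computed on a fixed equal-width discretization (default 32
levels per region).  Shape features use a marching-cubes surface mesh of the
binary region mask.  The six spatial features are the SUV-weighted centroid
normalised to the scan bounding box (only relative location is comparable
across scans of different axial coverage) and the principal axis of the voxel
coordinate covariance, sign-fixed to a non-negative z component.

Texture features are computed per direction over the 13 unique 3-D offsets at
distance 1 (GLCM symmetric) and averaged across directions.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure
from sklearn.base import BaseEstimator, TransformerMixin

from .segmentation import Region
from .volumes import ParameterError

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 16

FIRST_ORDER_NAMES = (
    "energy",
    "entropy",
    "kurtosis",
    "maximum",
    "mean",
    "mean_absolute_deviation",
    "median",
    "minimum",
    "range",
    "root_mean_square",
    "skewness",
    "standard_deviation",
    "uniformity",
    "variance",
)

SHAPE_NAMES = (
    "volume",
    "surface_area",
    "surface_to_volume_ratio",
    "sphericity",
    "spherical_disproportion",
    "compactness1",
    "compactness2",
    "max_diameter_3d",
    "centroid_x",
    "centroid_y",
    "centroid_z",
    "major_axis_x",
    "major_axis_y",
    "major_axis_z",
)

GLCM_NAMES = tuple(
    "glcm_" + n
    for n in (
        "autocorrelation",
        "cluster_prominence",
        "cluster_shade",
        "cluster_tendency",
        "contrast",
        "correlation",
        "difference_entropy",
        "difference_variance",
        "dissimilarity",
        "energy",
        "entropy",
        "homogeneity1",
        "homogeneity2",
        "imc1",
        "imc2",
        "idmn",
        "idn",
        "inverse_variance",
        "maximum_probability",
        "sum_average",
        "sum_entropy",
        "sum_variance",
        "variance",
    )
)

GLRLM_NAMES = tuple(
    "glrlm_" + n
    for n in (
        "short_run_emphasis",
        "long_run_emphasis",
        "gray_level_nonuniformity",
        "run_length_nonuniformity",
        "run_percentage",
        "low_gray_level_run_emphasis",
        "high_gray_level_run_emphasis",
        "short_run_low_gray_level_emphasis",
        "short_run_high_gray_level_emphasis",
        "long_run_low_gray_level_emphasis",
        "long_run_high_gray_level_emphasis",
    )
)

TEXTURE_NAMES = GLCM_NAMES + GLRLM_NAMES
CORE28_NAMES = FIRST_ORDER_NAMES + SHAPE_NAMES
FULL62_NAMES = CORE28_NAMES + TEXTURE_NAMES

FEATURE_SETS = {"core28": CORE28_NAMES, "full62": FULL62_NAMES}

#: 13 unique 3-D direction offsets at chessboard distance 1 (one of each +/- pair).
DIRECTIONS_13 = tuple(
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and d > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13


@dataclass(frozen=True)
class DiscretizedRegion:
    """Gray-level quantisation of a region's SUV samples."""

    gray_levels: np.ndarray
    n_levels: int
    bin_edges: np.ndarray

    def __post_init__(self):
        lev = np.asarray(self.gray_levels)
        if lev.size and (lev.min() < 1 or lev.max() > self.n_levels):
            raise ValueError("gray levels must lie in 1..n_levels")
        object.__setattr__(self, "gray_levels", lev.astype(np.int64, copy=False))


def discretize(region: Region, n_levels: int = DEFAULT_N_BINS) -> DiscretizedRegion:
    """Equal-width binning of the region's SUV range into ``n_levels`` levels.

    Constant regions map all voxels to level 1.
    """
    if n_levels < 2:
        raise ParameterError(f"n_levels must be >= 2, got {n_levels}")
    x = region.suv_values
    lo, hi = float(x.min()), float(x.max())
    edges = np.linspace(lo, hi, n_levels + 1)
    if hi == lo:
        levels = np.ones(x.shape, dtype=np.int64)
    else:
        levels = np.minimum(
            ((x - lo) / (hi - lo) * n_levels).astype(np.int64) + 1, n_levels
        )
    return DiscretizedRegion(gray_levels=levels, n_levels=n_levels, bin_edges=edges)


# ---------------------------------------------------------------------------
# first-order
# ---------------------------------------------------------------------------

def first_order_features(
    region: Region, disc: DiscretizedRegion | None = None
) -> dict[str, float]:
    """The 14 first-order SUV statistics.

    Entropy (base 2) and uniformity are computed on the discretized levels;
    all moments use population (1/N) normalisation; kurtosis is excess
    kurtosis and, like skewness, is 0 by convention for constant regions.
    """
    x = region.suv_values
    disc = disc or discretize(region)
    n = x.size
    mean = float(x.mean())
    dev = x - mean
    m2 = float(np.mean(dev**2))
    sd = float(np.sqrt(m2))
    if m2 > 0:
        skew = float(np.mean(dev**3)) / m2**1.5
        kurt = float(np.mean(dev**4)) / m2**2 - 3.0
    else:
        skew = 0.0
        kurt = 0.0
    counts = np.bincount(disc.gray_levels, minlength=disc.n_levels + 1)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())
    return {
        "energy": float((x**2).sum()),
        "entropy": entropy,
        "kurtosis": kurt,
        "maximum": float(x.max()),
        "mean": mean,
        "mean_absolute_deviation": float(np.abs(dev).mean()),
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "range": float(x.max() - x.min()),
        "root_mean_square": float(np.sqrt(np.mean(x**2))),
        "skewness": skew,
        "standard_deviation": sd,
        "uniformity": uniformity,
        "variance": m2,
    }


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def surface_mesh(region: Region, antialias_sigma: float = 0.8):
    """Marching-cubes triangulation (iso-level 0.5) of the region mask.

    The mask is anti-aliased with a small Gaussian before meshing so that the
    staircase of the voxel grid does not inflate the surface area (a raw
    binary mesh biases sphericity of a digitised sphere down to ~0.93).  Thin
    regions whose smoothed maximum falls below the iso-level fall back to the
    raw binary mesh.  Returns vertices (mm, relative to the padded crop) and
    faces.
    """
    m, _ = region.mask(pad=2)
    s = region.spacing
    vol = m.astype(np.float32)
    if antialias_sigma > 0:
        from scipy import ndimage

        smoothed = ndimage.gaussian_filter(vol, antialias_sigma)
        if smoothed.max() >= 0.6:
            vol = smoothed
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5, spacing=(s, s, s))
    return verts, faces


def shape_indices(volume_mm3: float, area_mm2: float) -> dict[str, float]:
    """Dimensionless shape indices from a volume/surface-area measurement.

    Exposed separately so the formula chain can be checked against closed-form
    solids (e.g. the exact cube surface) independent of the mesh.
    """
    v, a = float(volume_mm3), float(area_mm2)
    r_eq = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
    return {
        "surface_to_volume_ratio": a / v,
        "sphericity": np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / a,
        "spherical_disproportion": a / (4.0 * np.pi * r_eq**2),
        "compactness1": v / (np.sqrt(np.pi) * a**1.5),
        "compactness2": 36.0 * np.pi * v**2 / a**3,
    }


def max_diameter_3d(verts: np.ndarray) -> float:
    """Largest pairwise distance between surface vertices (mm)."""
    pts = verts
    if pts.shape[0] > 4:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # degenerate (coplanar) meshes fall back to all verts
            pass
    if pts.shape[0] < 2:
        return 0.0
    return float(pdist(pts).max())


def shape_features(region: Region) -> dict[str, float]:
    """The 14 shape features (8 standard + 6 spatial).

    Volume is reported in mL, surface area in mm^2, the surface-to-volume
    ratio in 1/mm; centroid components are the SUV-weighted centre of mass as
    fractions of the scan bounding box; the major axis is the unit principal
    eigenvector of the voxel-coordinate covariance, degenerate cases mapping
    to +z.
    """
    shape = np.asarray(region.grid_shape, dtype=float)
    if np.any(shape <= 0):
        raise ValueError("scan grid has a zero-extent axis")
    s = region.spacing
    v_mm3 = region.n_voxels * s**3
    verts, faces = surface_mesh(region)
    area = float(measure.mesh_surface_area(verts, faces))
    out = {"volume": v_mm3 / 1000.0, "surface_area": area}
    out.update(shape_indices(v_mm3, area))
    out["max_diameter_3d"] = max_diameter_3d(verts)

    idx = region.voxel_indices.astype(float)
    w = region.suv_values
    wsum = float(w.sum())
    com = (idx * w[:, None]).sum(axis=0) / wsum if wsum > 0 else idx.mean(axis=0)
    cen = (com + 0.5) / shape
    out["centroid_x"], out["centroid_y"], out["centroid_z"] = (float(c) for c in cen)

    centered = idx - idx.mean(axis=0)
    cov = centered.T @ centered / idx.shape[0]
    if np.allclose(cov, 0.0):
        axis = np.array([0.0, 0.0, 1.0])
    else:
        evals, evecs = np.linalg.eigh(cov)
        axis = evecs[:, -1]
        # sign fix: non-negative z, ties broken toward +x then +y
        for k in (2, 0, 1):
            if abs(axis[k]) > 1e-12:
                if axis[k] < 0:
                    axis = -axis
                break
    out["major_axis_x"], out["major_axis_y"], out["major_axis_z"] = (
        float(a) for a in axis
    )
    return out


# ---------------------------------------------------------------------------
# texture
# ---------------------------------------------------------------------------

def _level_volume(region: Region, disc: DiscretizedRegion) -> np.ndarray:
    """Cropped integer volume: 0 outside the region, gray level inside."""
    lo, hi = region.bbox
    vol = np.zeros(tuple(hi - lo + 1), dtype=np.int64)
    rel = region.voxel_indices - lo
    vol[rel[:, 0], rel[:, 1], rel[:, 2]] = disc.gray_levels
    return vol


def _pair_slices(shape, d):
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step > 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def glcm_matrix(lev: np.ndarray, n_levels: int, d) -> np.ndarray | None:
    """Symmetric normalised co-occurrence matrix for one direction offset.

    Returns None when the direction yields no voxel pairs.
    """
    src, dst = _pair_slices(lev.shape, d)
    a = lev[src].ravel()
    b = lev[dst].ravel()
    ok = (a > 0) & (b > 0)
    if not ok.any():
        return None
    a, b = a[ok] - 1, b[ok] - 1
    counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels).astype(float)
    counts = counts.reshape(n_levels, n_levels)
    counts = counts + counts.T
    return counts / counts.sum()


def glcm_statistics(p: np.ndarray) -> dict[str, float]:
    """The 23 co-occurrence statistics of a normalised symmetric GLCM.

    Level values are the integers 1..n.  Correlation and the information
    measures are 0 by convention for single-level (constant) regions.
    """
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())

    diff = np.abs(ii - jj)
    # distributions of i+j (2..2n) and |i-j| (0..n-1)
    p_sum = np.zeros(2 * n + 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(n)
    np.add.at(p_diff, diff.astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * n + 1, dtype=float)
    k_diff = np.arange(n, dtype=float)

    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    pd_nz = p_diff[p_diff > 0]
    ps_nz = p_sum[p_sum > 0]
    sum_average = float((k_sum * p_sum).sum())
    dissimilarity = float((diff * p).sum())

    if var > 0:
        correlation = float(((ii * jj * p).sum() - mu * mu) / var)
    else:
        logger.warning("GLCM correlation undefined for constant region; emitting 0")
        correlation = 0.0

    # information measures of correlation
    px_nz = px[px > 0]
    hx = float(-(px_nz * np.log2(px_nz)).sum())
    outer = np.outer(px, px)
    with np.errstate(divide="ignore"):
        log_outer = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
    hxy1 = float(-(p * log_outer).sum())
    hxy2 = float(-(outer[outer > 0] * np.log2(outer[outer > 0])).sum())
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    off = diff > 0
    return {
        "glcm_autocorrelation": float((ii * jj * p).sum()),
        "glcm_cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "glcm_cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "glcm_cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "glcm_contrast": float(((ii - jj) ** 2 * p).sum()),
        "glcm_correlation": correlation,
        "glcm_difference_entropy": float(-(pd_nz * np.log2(pd_nz)).sum()),
        "glcm_difference_variance": float(((k_diff - dissimilarity) ** 2 * p_diff).sum()),
        "glcm_dissimilarity": dissimilarity,
        "glcm_energy": float((p**2).sum()),
        "glcm_entropy": entropy,
        "glcm_homogeneity1": float((p / (1.0 + diff)).sum()),
        "glcm_homogeneity2": float((p / (1.0 + diff**2)).sum()),
        "glcm_imc1": float(imc1),
        "glcm_imc2": imc2,
        "glcm_idmn": float((p / (1.0 + (diff / n) ** 2)).sum()),
        "glcm_idn": float((p / (1.0 + diff / n)).sum()),
        "glcm_inverse_variance": float((p[off] / diff[off] ** 2).sum()),
        "glcm_maximum_probability": float(p.max()),
        "glcm_sum_average": sum_average,
        "glcm_sum_entropy": float(-(ps_nz * np.log2(ps_nz)).sum()),
        "glcm_sum_variance": float(((k_sum - sum_average) ** 2 * p_sum).sum()),
        "glcm_variance": var,
    }


def glrlm_matrix(lev: np.ndarray, n_levels: int, d) -> np.ndarray:
    """Run-length matrix (n_levels x max_run) for one direction offset.

    A run is a maximal sequence of region voxels of equal gray level along
    lines in direction ``d``; non-region voxels break runs.
    """
    coords = np.argwhere(lev > 0)
    if coords.shape[0] == 0:
        return np.zeros((n_levels, 1))
    g = lev[coords[:, 0], coords[:, 1], coords[:, 2]]
    d_arr = np.asarray(d)
    k0 = int(np.nonzero(d_arr)[0][0])
    t = coords[:, k0] * d_arr[k0]
    base = coords - t[:, None] * d_arr
    order = np.lexsort((t, base[:, 2], base[:, 1], base[:, 0]))
    base_s, t_s, g_s = base[order], t[order], g[order]
    contiguous = np.all(base_s[1:] == base_s[:-1], axis=1) & (t_s[1:] == t_s[:-1] + 1)
    same_run = contiguous & (g_s[1:] == g_s[:-1])
    run_id = np.concatenate([[0], np.cumsum(~same_run)])
    lengths = np.bincount(run_id)
    starts = np.concatenate([[0], np.flatnonzero(~same_run) + 1])
    run_gray = g_s[starts]
    mat = np.zeros((n_levels, int(lengths.max())))
    np.add.at(mat, (run_gray - 1, lengths - 1), 1.0)
    return mat


def glrlm_statistics(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 11 run-length statistics of one direction's GLRLM."""
    g = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    nr = mat.sum()
    rg = mat.sum(axis=1)
    rl = mat.sum(axis=0)
    return {
        "glrlm_short_run_emphasis": float((mat / l**2).sum() / nr),
        "glrlm_long_run_emphasis": float((mat * l**2).sum() / nr),
        "glrlm_gray_level_nonuniformity": float((rg**2).sum() / nr),
        "glrlm_run_length_nonuniformity": float((rl**2).sum() / nr),
        "glrlm_run_percentage": float(nr / n_voxels),
        "glrlm_low_gray_level_run_emphasis": float((mat / g**2).sum() / nr),
        "glrlm_high_gray_level_run_emphasis": float((mat * g**2).sum() / nr),
        "glrlm_short_run_low_gray_level_emphasis": float((mat / (g**2 * l**2)).sum() / nr),
        "glrlm_short_run_high_gray_level_emphasis": float((mat * g**2 / l**2).sum() / nr),
        "glrlm_long_run_low_gray_level_emphasis": float((mat * l**2 / g**2).sum() / nr),
        "glrlm_long_run_high_gray_level_emphasis": float((mat * (g * l) ** 2).sum() / nr),
    }


def texture_features(
    region: Region,
    disc: DiscretizedRegion | None = None,
    directions=DIRECTIONS_13,
) -> dict[str, float]:
    """The 34 texture features, averaged over the direction set.

    GLCM features average over directions that yield at least one voxel pair;
    GLRLM features average over all directions (every voxel belongs to a run).
    """
    if region.n_voxels < 2:
        raise ParameterError("texture features require a region with >= 2 voxels")
    disc = disc or discretize(region)
    lev = _level_volume(region, disc)
    n = disc.n_levels

    glcm_acc: dict[str, float] = {k: 0.0 for k in GLCM_NAMES}
    n_glcm = 0
    glrlm_acc: dict[str, float] = {k: 0.0 for k in GLRLM_NAMES}
    for d in directions:
        p = glcm_matrix(lev, n, d)
        if p is not None:
            stats = glcm_statistics(p)
            for k in GLCM_NAMES:
                glcm_acc[k] += stats[k]
            n_glcm += 1
        rstats = glrlm_statistics(glrlm_matrix(lev, n, d), region.n_voxels)
        for k in GLRLM_NAMES:
            glrlm_acc[k] += rstats[k]

    out: dict[str, float] = {}
    for k in GLCM_NAMES:
        out[k] = glcm_acc[k] / n_glcm if n_glcm else 0.0
    for k in GLRLM_NAMES:
        out[k] = glrlm_acc[k] / len(directions)
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def compute_features(
    region: Region,
    feature_set: str = "core28",
    n_bins: int = DEFAULT_N_BINS,
) -> dict[str, float]:
    """All features of one region, as an ordered name -> value mapping."""
    if feature_set not in FEATURE_SETS:
        raise ParameterError(f"unknown feature set {feature_set!r}")
    disc = discretize(region, n_bins)
    values = first_order_features(region, disc)
    values.update(shape_features(region))
    if feature_set == "full62":
        values.update(texture_features(region, disc))
    ordered = {name: values[name] for name in FEATURE_SETS[feature_set]}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values for region {region.id}: {bad}")
    return ordered


class RadiomicsExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping a list of Regions to a feature DataFrame.

    Parameters
    ----------
    feature_set : {"core28", "full62"}
        core28 = 14 first-order + 14 shape; full62 appends 34 texture features.
    n_bins : int
        Equal-width gray levels per region for entropy/uniformity/texture.
    """

    def __init__(self, feature_set: str = "core28", n_bins: int = DEFAULT_N_BINS):
        self.feature_set = feature_set
        self.n_bins = n_bins

    def fit(self, X, y=None):
        if self.feature_set not in FEATURE_SETS:
            raise ParameterError(f"unknown feature set {self.feature_set!r}")
        self.feature_names_ = list(FEATURE_SETS[self.feature_set])
        return self

    def transform(self, X):
        import pandas as pd

        if not hasattr(self, "feature_names_"):
            self.fit(X)
        rows = [compute_features(r, self.feature_set, self.n_bins) for r in X]
        index = [r.id for r in X]
        return pd.DataFrame(rows, index=index, columns=self.feature_names_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_SETS[self.feature_set], dtype=object)
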