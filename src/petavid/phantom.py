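"""Synthetic whole-body FDG-PET phantom generator with ground truth.

Each phantom scan is a torso-scale grid (default 140 x 70 x 340 voxels at
5 mm) holding ellipsoidal high-uptake organs at anatomically ordered anchors
(brain superior, heart mid-thorax left of midline, paired posterior kidneys,
bladder inferior midline) plus 0-4 tumors at random non-organ sites.  Organ
volume statistics, visibility rates and partial-uptake patterns (apex-only
heart, collecting-system-only kidney) follow the printed whole-body FDG
statistics the pipeline is designed around; organ SUV levels are set in the
physiological range with the bladder hottest.  Activity is back-converted
from the drawn SUV field using a realistic paediatric weight and a
5.55 MBq/kg injected dose, so that SUV conversion recovers the intended field
exactly (up to the additive Gaussian voxel noise).

Axis convention: x = left-right, y = anterior(0)-posterior(1), z =
inferior(0)-superior(1), all as fractions of the grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import F18_HALFLIFE_MIN, PETScan, RegionLabelMap

PARTIAL_UPTAKE_MODES = ("full", "apex_only", "collecting_system", "absent")


@dataclass(frozen=True)
class OrganSpec:
    """Generation parameters for one organ class."""

    name: str
    volume_mean_ml: float
    volume_sd_ml: float
    volume_min_ml: float
    suv_mean: float
    suv_sd: float
    suv_min: float
    axes_ratio: tuple[float, float, float]
    anchor: tuple[float, float, float]
    presence: float = 1.0
    modes: tuple[tuple[str, float], ...] = (("full", 1.0),)
    anchor_jitter: float = 0.02
    texture_sd: float = 0.0
    texture_scale: float = 1.0
    tilt_deg: float = 0.0

    def __post_init__(self):
        if self.volume_mean_ml <= 0 or self.volume_min_ml <= 0:
            raise ValueError("organ volumes must be positive")
        if not (0.0 <= self.presence <= 1.0):
            raise ValueError("presence probability must lie in [0, 1]")
        for mode, _ in self.modes:
            if mode not in PARTIAL_UPTAKE_MODES:
                raise ValueError(f"unknown partial-uptake mode {mode!r}")


@dataclass(frozen=True)
class TumorSpec:
    """Tumor generation: log-normal volumes (heavy right tail), random sites."""

    volume_mean_ml: float = 193.90
    volume_sd_ml: float = 394.46
    volume_min_ml: float = 1.0
    suv_mean: float = 6.3
    suv_sd: float = 0.9
    suv_min: float = 4.8
    count_probs: tuple[float, ...] = (0.25, 0.40, 0.20, 0.10, 0.05)
    box: tuple[tuple[float, float], ...] = ((0.10, 0.90), (0.15, 0.85), (0.05, 0.78))
    axes_jitter: tuple[float, float] = (0.60, 1.60)
    texture_sd: float = 0.70
    texture_scale: float = 2.5


def _default_organs() -> tuple[OrganSpec, ...]:
    kidney_modes = (("full", 0.70), ("collecting_system", 0.30))
    return (
        OrganSpec(
            name="brain",
            volume_mean_ml=1468.37, volume_sd_ml=266.15, volume_min_ml=700.0,
            suv_mean=6.0, suv_sd=0.7, suv_min=4.5,
            axes_ratio=(1.15, 1.0, 0.9), anchor=(0.50, 0.45, 0.90),
            presence=1.0, texture_sd=0.35, texture_scale=2.0,
        ),
        OrganSpec(
            name="heart",
            volume_mean_ml=197.59, volume_sd_ml=125.63, volume_min_ml=60.0,
            suv_mean=4.8, suv_sd=0.4, suv_min=4.1,
            axes_ratio=(1.0, 0.95, 1.1), anchor=(0.40, 0.45, 0.66),
            presence=0.48, modes=(("full", 0.75), ("apex_only", 0.25)),
            texture_sd=0.35, texture_scale=0.8,
        ),
        OrganSpec(
            name="kidney_left",
            volume_mean_ml=30.70, volume_sd_ml=22.61, volume_min_ml=12.0,
            suv_mean=6.0, suv_sd=0.6, suv_min=4.8,
            axes_ratio=(0.8, 0.9, 1.6), anchor=(0.62, 0.62, 0.58),
            presence=0.91, modes=kidney_modes, texture_sd=0.30, texture_scale=1.0,
            tilt_deg=15.0,
        ),
        OrganSpec(
            name="kidney_right",
            volume_mean_ml=31.20, volume_sd_ml=22.85, volume_min_ml=12.0,
            suv_mean=6.0, suv_sd=0.6, suv_min=4.8,
            axes_ratio=(0.8, 0.9, 1.6), anchor=(0.38, 0.62, 0.53),
            presence=0.86, modes=kidney_modes, texture_sd=0.30, texture_scale=1.0,
            tilt_deg=-15.0,
        ),
        OrganSpec(
            name="bladder",
            volume_mean_ml=118.94, volume_sd_ml=153.07, volume_min_ml=25.0,
            suv_mean=7.2, suv_sd=0.8, suv_min=5.5,
            axes_ratio=(1.0, 1.0, 1.0), anchor=(0.50, 0.50, 0.12),
            presence=1.0, texture_sd=0.05, texture_scale=1.0,
        ),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for synthetic scan generation."""

    shape: tuple[int, int, int] = (140, 70, 340)
    spacing_mm: float = 5.0
    background_suv: float = 0.5
    noise_fraction: float = 0.10
    organs: tuple[OrganSpec, ...] = field(default_factory=_default_organs)
    tumor: TumorSpec = field(default_factory=TumorSpec)
    weight_kg_mean: float = 55.0
    weight_kg_sd: float = 15.0
    weight_kg_range: tuple[float, float] = (26.0, 115.0)
    dose_mbq_per_kg: float = 5.55
    dose_mbq_range: tuple[float, float] = (74.0, 444.0)
    elapsed_min: float = 60.0
    halflife_min: float = F18_HALFLIFE_MIN
    min_gap_vox: int = 3
    apex_fraction: float = 0.45
    core_fraction: float = 0.75
    superscan_probability: float = 0.0
    max_placement_tries: int = 200

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(name)


@dataclass(frozen=True)
class PhantomScan:
    """One synthetic scan: activity volume, truth labels and manifest."""

    scan: PETScan
    truth: RegionLabelMap
    classes: dict[int, str]
    modes: dict[int, str]
    manifest: pd.DataFrame
    seed: int


def _truncated_normal(rng, mean, sd, lo, hi=np.inf, max_tries=1000) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def _lognormal_from_arith(rng, mean, sd, lo, max_tries=1000) -> float:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    for _ in range(max_tries):
        v = rng.lognormal(mu, np.sqrt(sigma2))
        if v >= lo:
            return float(v)
    return float(lo)


def _draw_scan_plan(spec: PhantomSpec, rng: np.random.Generator) -> list[dict]:
    """Draw presence, volumes, SUVs and uptake modes (no geometry).

    Split out from rasterisation so that cohort-level statistics (visibility
    rates, volume distributions) can be exercised cheaply.
    """
    plan = []
    for organ in spec.organs:
        present = bool(rng.random() < organ.presence)
        volume = _truncated_normal(
            rng, organ.volume_mean_ml, organ.volume_sd_ml, organ.volume_min_ml
        )
        suv = _truncated_normal(rng, organ.suv_mean, organ.suv_sd, organ.suv_min)
        mode_names = [m for m, _ in organ.modes]
        mode_probs = np.array([p for _, p in organ.modes], dtype=float)
        mode = str(rng.choice(mode_names, p=mode_probs / mode_probs.sum()))
        if not present:
            mode = "absent"
        plan.append(
            {"class": organ.name, "present": present, "volume_ml": volume,
             "suv": suv, "mode": mode}
        )
    t = spec.tumor
    probs = np.asarray(t.count_probs, dtype=float)
    count = int(rng.choice(len(probs), p=probs / probs.sum()))
    for _ in range(count):
        plan.append(
            {
                "class": "tumor",
                "present": True,
                "volume_ml": _lognormal_from_arith(
                    rng, t.volume_mean_ml, t.volume_sd_ml, t.volume_min_ml
                ),
                "suv": _truncated_normal(rng, t.suv_mean, t.suv_sd, t.suv_min),
                "mode": "full",
            }
        )
    return plan


def _ellipsoid(center, radii, shape, tilt_deg=0.0):
    """Boolean ellipsoid mask on the full grid (cheap local rasterisation).

    ``tilt_deg`` rotates the ellipsoid about the y (anterior-posterior) axis,
    so a positive tilt splays the inferior pole toward +x.
    """
    extent = np.full(3, float(np.max(radii))) if tilt_deg else np.asarray(radii, float)
    lo = np.maximum(np.floor(center - extent).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(center + extent).astype(int) + 1, np.asarray(shape) - 1)
    if np.any(hi < lo):
        return None
    grids = np.meshgrid(
        *(np.arange(l, h + 1, dtype=float) for l, h in zip(lo, hi)), indexing="ij"
    )
    d = [g - c for g, c in zip(grids, center)]
    if tilt_deg:
        th = np.deg2rad(tilt_deg)
        dx = np.cos(th) * d[0] + np.sin(th) * d[2]
        dz = -np.sin(th) * d[0] + np.cos(th) * d[2]
        d = [dx, d[1], dz]
    val = sum((dd / r) ** 2 for dd, r in zip(d, radii))
    local = val <= 1.0
    if not local.any():
        return None
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = local
    return mask


def apply_partial_uptake(
    mask: np.ndarray,
    mode: str,
    apex_fraction: float = 0.45,
    core_fraction: float = 0.75,
) -> np.ndarray:
    """Restrict an organ mask to its FDG-avid sub-volume.

    ``full`` keeps the mask; ``apex_only`` keeps the inferior cap of the organ
    (the partial myocardial-uptake pattern); ``collecting_system`` keeps an
    ellipsoidal core around the organ centroid (renal pelvis activity without
    cortical uptake); ``absent`` removes all activity.
    """
    if mode not in PARTIAL_UPTAKE_MODES:
        raise ValueError(f"unknown partial-uptake mode {mode!r}")
    if mode == "full":
        return mask.copy()
    if mode == "absent":
        return np.zeros_like(mask)
    idx = np.argwhere(mask)
    out = np.zeros_like(mask)
    if idx.shape[0] == 0:
        return out
    if mode == "apex_only":
        zmin, zmax = idx[:, 2].min(), idx[:, 2].max()
        cut = zmin + apex_fraction * (zmax - zmin)
        keep = idx[idx[:, 2] <= cut]
    else:  # collecting_system
        c = idx.mean(axis=0)
        half_extent = np.maximum((idx.max(axis=0) - idx.min(axis=0)) / 2.0, 0.5)
        r = ((idx - c) / half_extent) ** 2
        keep = idx[r.sum(axis=1) <= core_fraction**2]
        if keep.shape[0] == 0:  # tiny organ: keep the centre voxel
            keep = idx[[int(np.argmin(r.sum(axis=1)))]]
    out[keep[:, 0], keep[:, 1], keep[:, 2]] = True
    return out


def _gap_free(mask: np.ndarray, occupied: np.ndarray, gap: int) -> bool:
    """Whether ``mask`` keeps at least ``gap`` voxels of background from
    everything already placed."""
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - gap, 0)
    hi = np.minimum(idx.max(axis=0) + gap, np.asarray(mask.shape) - 1)
    box = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))
    if not occupied[box].any():
        return True
    grown = ndimage.binary_dilation(
        mask[box], structure=ndimage.generate_binary_structure(3, 3), iterations=gap
    )
    return not (grown & occupied[box]).any()


def _radii_from_volume(volume_ml, spacing_mm, axes_ratio, jitter) -> np.ndarray:
    v_vox = volume_ml * 1000.0 / spacing_mm**3
    ratio = np.asarray(axes_ratio, dtype=float) * jitter
    base = (3.0 * v_vox / (4.0 * np.pi * np.prod(ratio))) ** (1.0 / 3.0)
    return np.maximum(base * ratio, 0.6)


def generate_scan(spec: PhantomSpec, seed: int) -> PhantomScan:
    """Generate one phantom scan deterministically from ``seed``."""
    rng = np.random.default_rng(seed)
    shape = tuple(spec.shape)
    grid = np.asarray(shape, dtype=float)
    plan = _draw_scan_plan(spec, rng)

    weight_kg = _truncated_normal(
        rng, spec.weight_kg_mean, spec.weight_kg_sd, *spec.weight_kg_range
    )
    dose_mbq = float(np.clip(spec.dose_mbq_per_kg * weight_kg, *spec.dose_mbq_range))
    superscan = bool(rng.random() < spec.superscan_probability)

    suv_img = np.full(shape, spec.background_suv, dtype=float)
    truth = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    classes: dict[int, str] = {}
    modes: dict[int, str] = {}
    rows = []
    label = 0

    organ_by_name = {o.name: o for o in spec.organs}
    for item in plan:
        if not item["present"]:
            continue
        is_tumor = item["class"] == "tumor"
        placed = False
        for attempt in range(spec.max_placement_tries):
            if is_tumor:
                t = spec.tumor
                center_frac = np.array([rng.uniform(a, b) for a, b in t.box])
                jitter = rng.uniform(*t.axes_jitter, size=3)
                radii = _radii_from_volume(
                    item["volume_ml"], spec.spacing_mm, (1.0, 1.0, 1.0), jitter
                )
            else:
                organ = organ_by_name[item["class"]]
                center_frac = np.asarray(organ.anchor) + rng.uniform(
                    -organ.anchor_jitter, organ.anchor_jitter, size=3
                )
                jitter = rng.uniform(0.92, 1.08, size=3)
                radii = _radii_from_volume(
                    item["volume_ml"], spec.spacing_mm, organ.axes_ratio, jitter
                )
            tilt = 0.0 if is_tumor else organ.tilt_deg
            center = center_frac * (grid - 1)
            reach = np.full(3, radii.max()) if tilt else radii
            if np.any(center - reach < 1) or np.any(center + reach > grid - 2):
                continue
            mask = _ellipsoid(center, radii, shape, tilt_deg=tilt)
            if mask is None:
                continue
            if _gap_free(mask, occupied, spec.min_gap_vox):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {item['class']} after "
                f"{spec.max_placement_tries} tries (seed={seed})"
            )
        active = apply_partial_uptake(
            mask, item["mode"], spec.apex_fraction, spec.core_fraction
        )
        occupied |= mask
        label += 1
        if active.any():
            tex_sd = spec.tumor.texture_sd if is_tumor else organ.texture_sd
            tex_scale = spec.tumor.texture_scale if is_tumor else organ.texture_scale
            if tex_sd > 0:
                # class-specific intra-organ heterogeneity (grey/white matter,
                # myocardial wall, necrotic tumor cores); clipped so avid
                # tissue stays above the detection threshold
                idx = np.argwhere(active)
                lo, hi = idx.min(axis=0), idx.max(axis=0)
                local = rng.standard_normal(tuple(hi - lo + 1))
                local = ndimage.gaussian_filter(local, tex_scale)
                sd = local.std()
                if sd > 0:
                    local = (local - local.mean()) * (tex_sd / sd)
                vals = item["suv"] + local[tuple((idx - lo).T)]
                suv_img[idx[:, 0], idx[:, 1], idx[:, 2]] = np.maximum(vals, 3.2)
            else:
                suv_img[active] = item["suv"]
            truth[active] = label
        classes[label] = item["class"]
        modes[label] = item["mode"]
        n_active = int(active.sum())
        voxel_ml = spec.spacing_mm**3 / 1000.0
        rows.append(
            {
                "label": label,
                "class": item["class"],
                "mode": item["mode"],
                "suv": item["suv"],
                "target_volume_ml": item["volume_ml"],
                "organ_volume_ml": float(mask.sum()) * voxel_ml,
                "active_volume_ml": n_active * voxel_ml,
                "center_x": center_frac[0],
                "center_y": center_frac[1],
                "center_z": center_frac[2],
                "superscan": superscan,
                "seed": seed,
            }
        )

    if superscan:
        # diffuse skeletal uptake: a midline rod just above threshold
        cx, cy = int(grid[0] / 2), int(grid[1] / 2)
        z0, z1 = int(0.2 * grid[2]), int(0.8 * grid[2])
        rod = np.zeros(shape, dtype=bool)
        rod[cx - 2:cx + 3, cy - 2:cy + 3, z0:z1] = True
        rod &= truth == 0
        suv_img[rod] = np.maximum(suv_img[rod], 3.5)

    noise_sd = spec.noise_fraction * spec.background_suv
    if noise_sd > 0:
        suv_img = suv_img + rng.normal(0.0, noise_sd, size=shape)
    np.maximum(suv_img, 0.0, out=suv_img)

    weight_g = weight_kg * 1000.0
    dose_bq = dose_mbq * 1e6
    decay = 2.0 ** (-spec.elapsed_min / spec.halflife_min)
    activity = suv_img * decay * dose_bq / weight_g

    scan = PETScan(
        voxels=activity,
        spacing=(spec.spacing_mm,) * 3,
        weight_g=weight_g,
        dose_bq=dose_bq,
        elapsed_min=spec.elapsed_min,
        halflife_min=spec.halflife_min,
    )
    truth_map = RegionLabelMap(truth, (spec.spacing_mm,) * 3)
    manifest = pd.DataFrame(
        rows,
        columns=[
            "label", "class", "mode", "suv", "target_volume_ml", "organ_volume_ml",
            "active_volume_ml", "center_x", "center_y", "center_z", "superscan",
            "seed",
        ],
    )
    return PhantomScan(
        scan=scan, truth=truth_map, classes=classes, modes=modes,
        manifest=manifest, seed=seed,
    )


def cohort_seeds(master_seed: int, n_scans: int) -> list[int]:
    """Independent per-scan seeds (< 2^31) derived from a master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_scans, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def iter_cohort(spec: PhantomSpec, n_scans: int, seed: int):
    """Yield ``(scan_index, PhantomScan)`` lazily; memory-friendly for large
    cohorts."""
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    for i, s in enumerate(cohort_seeds(seed, n_scans)):
        yield i, generate_scan(spec, s)


def generate_cohort(spec: PhantomSpec, n_scans: int, seed: int) -> list[PhantomScan]:
    return [ph for _, ph in iter_cohort(spec, n_scans, seed)]


def cohort_truth_table(scans: list[PhantomScan]) -> pd.DataFrame:
    """Cohort-level truth table: one row per generated region."""
    frames = []
    for i, ph in enumerate(scans):
        m = ph.manifest.copy()
        m.insert(0, "scan", i)
        frames.append(m)
    return pd.concat(frames, ignore_index=True)
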