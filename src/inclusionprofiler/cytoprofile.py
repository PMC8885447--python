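"""Per-cell cytoprofiles: intensity, size/shape, texture, granularity, radial.

Each segmented cell is summarized by the five feature families used for
inclusion-phenotype profiling:

* intensity — moments of the masked GFP pixel distribution;
* size/shape — area, perimeter, eccentricity, form factor, solidity,
  equivalent diameter;
* texture — the 13 classical Haralick gray-level co-occurrence statistics,
  angle-averaged over the four principal directions, at pixel offsets 3 and
  8, computed on a mask-aware co-occurrence matrix (only pixel pairs that
  both lie inside the cell mask are counted);
* granularity — a 16-element granulometry spectrum: the fraction of
  background-subtracted intensity removed by grayscale openings of
  increasing size, which concentrates at small scales for punctate cells;
* radial intensity distribution — fraction of intensity, area-normalized
  mean fraction, and angular coefficient of variation in 4 concentric rings
  of normalized distance from the cell edge.

Features are z-scored per plate/batch before classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops

from .plateio import FieldImage, ImageKey
from .segment import CellObject

__all__ = [
    "CytoProfile",
    "compute_profile",
    "profiles_to_frame",
    "normalize_features",
    "apply_normalization",
    "feature_columns",
    "HARALICK_NAMES",
]

N_GRAY_LEVELS = 32
TEXTURE_SCALES = (3, 8)
N_GRANULARITY = 16
N_RADIAL_BINS = 4
N_WEDGES = 8

HARALICK_NAMES = (
    "asm", "contrast", "correlation", "variance", "idm", "sum_average",
    "sum_variance", "sum_entropy", "entropy", "diff_variance", "diff_entropy",
    "infocorr1", "infocorr2",
)

_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))  # 0, 45, 90, 135 degrees


@dataclass
class CytoProfile:
    """Named feature vector of one cell, flat ``{name: value}``."""

    cell_id: int
    key: ImageKey
    features: dict[str, float]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _masked_glcm(levels: np.ndarray, mask: np.ndarray, distance: int) -> np.ndarray:
    """Symmetric, angle-summed co-occurrence matrix counting only in-mask pairs."""
    L = N_GRAY_LEVELS
    glcm = np.zeros((L, L), dtype=np.float64)
    h, w = mask.shape
    for dr, dc in _OFFSETS:
        dr_, dc_ = dr * distance, dc * distance
        r0, r1 = max(0, -dr_), min(h, h - dr_)
        c0, c1 = max(0, -dc_), min(w, w - dc_)
        if r0 >= r1 or c0 >= c1:
            continue
        a = levels[r0:r1, c0:c1]
        b = levels[r0 + dr_:r1 + dr_, c0 + dc_:c1 + dc_]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr_:r1 + dr_, c0 + dc_:c1 + dc_]
        np.add.at(glcm, (a[valid], b[valid]), 1.0)
    glcm = glcm + glcm.T  # symmetric
    total = glcm.sum()
    return glcm / total if total > 0 else glcm


def _haralick(P: np.ndarray) -> dict[str, float]:
    """The 13 Haralick statistics of a normalized co-occurrence matrix."""
    L = P.shape[0]
    i = np.arange(L)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())

    k_sum = np.arange(2 * L - 1)
    k_diff = np.arange(L)

    asm = float((P ** 2).sum())
    contrast = float((k_diff ** 2 * p_diff).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float(((ii - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = _entropy(p_sum)
    ent = _entropy(P.ravel())
    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    diff_ent = _entropy(p_diff)

    pxpy = np.outer(px, py)
    nz = pxpy > 0
    hxy1 = float(-(P[nz] * np.log(pxpy[nz])).sum())
    hxy2 = _entropy(pxpy.ravel())
    hx, hy = _entropy(px), _entropy(py)
    denom = max(hx, hy)
    infocorr1 = (ent - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * max(hxy2 - ent, 0.0))
    infocorr2 = float(np.sqrt(max(arg, 0.0)))

    return dict(zip(HARALICK_NAMES, (
        asm, contrast, correlation, variance, idm, sum_avg, sum_var,
        sum_ent, ent, diff_var, diff_ent, infocorr1, infocorr2)))


def _granularity(patch: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fraction of background-subtracted intensity removed per opening size.

    Background is the masked minimum; openings use square structuring
    elements of half-width 1..16 (separable, hence cheap).  Entries are
    nonnegative and sum to <= 1.
    """
    vals = patch[mask]
    base = float(vals.min())
    img = np.where(mask, patch - base, 0.0)
    total = float(img.sum())
    spectrum = np.zeros(N_GRANULARITY)
    if total <= 0:
        return spectrum
    prev = total
    for r in range(1, N_GRANULARITY + 1):
        size = 2 * r + 1
        opened = ndimage.grey_opening(img, size=(size, size), mode="constant", cval=0.0)
        s = float(opened[mask].sum())
        spectrum[r - 1] = (prev - s) / total
        prev = s
    return np.clip(spectrum, 0.0, 1.0)


def _radial(patch: np.ndarray, mask: np.ndarray,
            centroid_rc: tuple[float, float]) -> dict[str, float]:
    """Radial intensity distribution over 4 rings of normalized edge distance.

    ``frac`` is the fraction of total masked intensity per ring (innermost
    ring last), summing to 1; ``meanfrac`` normalizes by ring area fraction;
    ``cv`` is the coefficient of variation of mean intensity across 8 angular
    wedges within the ring (0 where the ring spans fewer than 2 wedges).
    """
    dist = ndimage.distance_transform_edt(mask)
    dmax = dist[mask].max()
    rel = np.where(mask, dist / max(dmax, 1e-9), 0.0)  # 0 at edge, 1 at core
    # ring 1 = outermost shell, ring 4 = core
    ring = np.clip(np.ceil(rel * N_RADIAL_BINS), 1, N_RADIAL_BINS).astype(int)
    ring[~mask] = 0

    vals = patch.astype(float)
    total = float(vals[mask].sum())
    area = int(mask.sum())
    cy, cx = centroid_rc
    yy, xx = np.nonzero(mask)
    theta = np.arctan2(yy - cy, xx - cx)
    wedge = np.floor((theta + np.pi) / (2 * np.pi) * N_WEDGES).astype(int) % N_WEDGES

    out: dict[str, float] = {}
    for b in range(1, N_RADIAL_BINS + 1):
        sel = ring == b
        ring_sum = float(vals[sel].sum())
        frac = ring_sum / total if total > 0 else 0.0
        area_frac = sel.sum() / area
        out[f"rad_frac_{b}"] = frac
        out[f"rad_meanfrac_{b}"] = frac / area_frac if area_frac > 0 else 0.0
        sel_flat = sel[yy, xx]
        if sel_flat.sum() >= 2:
            wmeans = []
            wv = wedge[sel_flat]
            vv = vals[yy[sel_flat], xx[sel_flat]]
            for k in range(N_WEDGES):
                m = wv == k
                if m.any():
                    wmeans.append(vv[m].mean())
            wmeans = np.asarray(wmeans)
            mean = wmeans.mean()
            out[f"rad_cv_{b}"] = float(wmeans.std() / mean) if len(wmeans) >= 2 and mean > 0 else 0.0
        else:
            out[f"rad_cv_{b}"] = 0.0
    return out


def compute_profile(cell: CellObject, gfp: FieldImage) -> CytoProfile:
    """Compute all five feature families on the masked pixels of one cell.

    Deterministic; raises for masks smaller than 9 px (texture is degenerate)
    or masks extending outside the image.
    """
    r0, c0, r1, c1 = cell.bbox
    h, w = gfp.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"cell {cell.cell_id}: bbox {cell.bbox} outside image {gfp.shape}")
    mask = cell.mask
    if mask.sum() < 9:
        raise ValueError(f"cell {cell.cell_id}: mask of {mask.sum()} px is too small to profile")
    patch = gfp.pixels[r0:r1, c0:c1]
    vals = patch[mask]

    f: dict[str, float] = {
        "int_mean": float(vals.mean()),
        "int_integrated": float(vals.sum()),
        "int_sd": float(vals.std()),
        "int_max": float(vals.max()),
        "int_min": float(vals.min()),
        "int_median": float(np.median(vals)),
    }

    p = regionprops(mask.astype(np.uint8))[0]
    perim = float(p.perimeter)
    area = float(p.area)
    f.update({
        "shape_area_px": area,
        "shape_perimeter_px": perim,
        "shape_eccentricity": float(p.eccentricity),
        "shape_form_factor": float(4 * np.pi * area / perim ** 2) if perim > 0 else 0.0,
        "shape_solidity": float(p.solidity),
        "shape_equivalent_diameter_px": float(p.equivalent_diameter_area),
    })

    # quantize masked intensities for co-occurrence
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax > vmin:
        levels = np.clip(((patch - vmin) / (vmax - vmin) * N_GRAY_LEVELS).astype(int),
                         0, N_GRAY_LEVELS - 1)
    else:
        levels = np.zeros_like(patch, dtype=int)
    for scale in TEXTURE_SCALES:
        P = _masked_glcm(levels, mask, scale)
        for name, v in _haralick(P).items():
            f[f"tex_{name}_s{scale}"] = v

    for idx, v in enumerate(_granularity(patch, mask), start=1):
        f[f"gran_{idx:02d}"] = float(v)

    # centroid of the mask within the patch for wedge angles
    cy = float(np.mean(np.nonzero(mask)[0]))
    cx = float(np.mean(np.nonzero(mask)[1]))
    f.update(_radial(patch, mask, (cy, cx)))

    assert all(np.isfinite(v) for v in f.values()), "profile features must be finite"
    return CytoProfile(cell_id=cell.cell_id, key=cell.key, features=f)


METADATA_COLUMNS = ["well", "field", "cell_id"]


def profiles_to_frame(profiles: list[CytoProfile]) -> pd.DataFrame:
    """One row per cell: metadata columns first, then the named features."""
    rows = []
    for p in profiles:
        row = {"well": p.key.well, "field": p.key.field, "cell_id": p.cell_id}
        row.update(p.features)
        rows.append(row)
    return pd.DataFrame(rows)


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in METADATA_COLUMNS
            and pd.api.types.is_numeric_dtype(df[c])]


def normalize_features(
    df: pd.DataFrame,
    batch_col: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score each feature per batch; drop zero-variance features with a warning.

    Returns (normalized frame, stats frame with per-batch mean/sd per
    feature).  Raises for batches of fewer than 2 cells.
    """
    feats = feature_columns(df)
    groups = df.groupby(batch_col) if batch_col else [("__all__", df)]
    out_parts, stats_rows, dropped = [], [], set()
    for batch, g in groups:
        if len(g) < 2:
            raise ValueError(f"batch {batch!r} has {len(g)} cell(s); need >= 2 to normalize")
        mean = g[feats].mean()
        sd = g[feats].std(ddof=0)
        zero_var = sd[sd == 0].index
        dropped.update(zero_var)
        norm = g.copy()
        keep = [c for c in feats if c not in zero_var]
        norm[keep] = (g[keep] - mean[keep]) / sd[keep]
        out_parts.append(norm)
        for c in feats:
            stats_rows.append({"batch": batch, "feature": c,
                               "mean": mean[c], "sd": sd[c]})
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s) from classification: "
            f"{sorted(dropped)}", stacklevel=2)
    out = pd.concat(out_parts).loc[df.index]
    out = out.drop(columns=sorted(dropped))
    return out, pd.DataFrame(stats_rows)


def apply_normalization(df: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Z-score *df* with previously retained normalization stats.

    Used to score new cells in the same normalized feature space the
    classifier was trained in: per-plate re-normalization would shift the
    space whenever the class mix differs from the training batch.  Features
    whose retained sd is 0 are dropped, mirroring training.
    """
    if stats["batch"].nunique() > 1:
        raise ValueError("stats from multiple batches are ambiguous; pass one batch")
    out = df.copy()
    dropped = []
    for _, row in stats.iterrows():
        c = row["feature"]
        if c not in out.columns:
            continue
        if row["sd"] == 0:
            dropped.append(c)
        else:
            out[c] = (out[c] - row["mean"]) / row["sd"]
    return out.drop(columns=dropped)
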