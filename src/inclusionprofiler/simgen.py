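"""Ground-truthed synthetic plates for pipeline validation.

No public dataset accompanies the inclusion-formation screen this package
targets, so every stage is validated against a simulator that emulates its
inputs: transfected cells with lognormal diffuse GFP expression, an inclusion
phenotype rendered as bright compact puncta, a smooth multiplicative vignette,
Poisson-Gaussian camera noise, dose-dependent inclusion prevalence with
injectable combination synergy, and exponential GFP+ cell-count decline.

The simulator emits exact ground truth (masks, per-cell phenotype labels,
bias field, generating parameters) alongside the rendered 16-bit images, so
segmentation recall, classifier accuracy and synergy recovery can all be
scored against known answers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .plateio import FieldImage, ImageKey, format_key, write_field
from .synergy import Checkerboard

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "HillCurve",
    "ComboTruthSpec",
    "generate_field",
    "generate_plate",
    "generate_checkerboard",
    "generate_timeseries",
]

INCLUSION = "inclusion"
NO_INCLUSION = "no_inclusion"


@dataclass(frozen=True)
class SceneSpec:
    """Generating parameters for one two-channel field.

    Diameters are (mean, sd) of truncated normals in pixels; the default cell
    diameter distribution sits inside the 17-50 px analysis gate.  Diffuse GFP
    intensity is lognormal(mu, sigma) in camera units.  ``puncta_contrast`` is
    the ratio of a punctum's rendered peak to the cell's diffuse level.
    ``bias_field`` is (vignette amplitude, radial scale); ``noise`` is
    (gaussian sd, poisson gain) — gain 0 disables shot noise.  Identical seeds
    yield bit-identical images.
    """

    image_shape: tuple[int, int] = (600, 600)
    n_cells: int = 40
    inclusion_prevalence: float = 0.25
    nucleus_diameter_px: tuple[float, float] = (13.0, 1.5)
    cell_diameter_px: tuple[float, float] = (31.0, 5.0)
    cell_diameter_range: tuple[float, float] = (20.0, 46.0)
    diffuse_intensity: tuple[float, float] = (8.0, 0.35)
    puncta_per_cell: tuple[int, int] = (1, 3)
    puncta_diameter_px: tuple[float, float] = (6.0, 1.0)
    puncta_contrast: float = 5.0
    bias_field: tuple[float, float] = (0.3, 1.0)
    noise: tuple[float, float] = (10.0, 0.5)
    background_offset: float = 100.0
    nucleus_intensity: tuple[float, float] = (8.2, 0.2)
    transfected_fraction: float = 1.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inclusion_prevalence <= 1.0:
            raise ValueError("inclusion_prevalence must be in [0, 1]")
        if not 0.0 <= self.transfected_fraction <= 1.0:
            raise ValueError("transfected_fraction must be in [0, 1]")
        for name in ("nucleus_diameter_px", "cell_diameter_px", "puncta_diameter_px"):
            mean, _sd = getattr(self, name)
            if mean <= 0:
                raise ValueError(f"{name} mean must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.puncta_contrast < 1.0:
            raise ValueError("puncta_contrast must be >= 1 (puncta are brighter than diffuse)")

    def with_(self, **overrides) -> "SceneSpec":
        return dataclasses.replace(self, **overrides)


@dataclass
class GroundTruth:
    """Exact scene truth: label images, per-cell table and the bias field.

    ``cells`` has one row per cell: cell_id, label (inclusion / no_inclusion),
    transfected, centroid_x, centroid_y, equivalent_diameter_px,
    diffuse_intensity.  ``cell_masks`` / ``nucleus_masks`` are labeled images
    whose labels are the cell_ids.
    """

    cell_masks: np.ndarray
    nucleus_masks: np.ndarray
    cells: pd.DataFrame
    bias_field: np.ndarray
    spec: SceneSpec

    def __post_init__(self) -> None:
        n = len(self.cells)
        labels = set(np.unique(self.cell_masks)) - {0}
        if labels != set(self.cells["cell_id"]):
            raise ValueError("cell mask labels do not match truth table cell ids")
        counts = self.cells["label"].value_counts()
        if int(counts.sum()) != n:
            raise ValueError("per-label counts must sum to n_cells")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap at the requested density."""


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, lo, hi)


def _place_centers(rng: np.random.Generator, shape: tuple[int, int],
                   diameters: np.ndarray, spacing: float = 3.0,
                   max_retries: int = 5000) -> np.ndarray:
    """Rejection-sample cell centers so cell masks stay disjoint and off the border."""
    h, w = shape
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for d in diameters:
        r = d / 2.0
        margin = r + 4.0
        if 2 * margin >= min(h, w):
            raise PlacementError(f"cell diameter {d:.0f}px does not fit in field {shape}")
        for attempt in range(max_retries):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            ok = True
            for (py, px), pr in zip(centers, placed_r):
                if (cy - py) ** 2 + (cx - px) ** 2 < (r + pr + spacing) ** 2:
                    ok = False
                    break
            if ok:
                centers.append((cy, cx))
                placed_r.append(r)
                break
        else:
            raise PlacementError(
                f"could not place cell {len(centers) + 1}/{len(diameters)} after "
                f"{max_retries} retries; reduce n_cells or cell diameter for field {shape}"
            )
    return np.asarray(centers).reshape(-1, 2)


def _draw_ellipse(mask_img: np.ndarray, label: int, center: tuple[float, float],
                  equiv_diameter: float, aspect: float, angle: float) -> None:
    from skimage.draw import ellipse

    r0 = equiv_diameter / 2.0
    a = r0 / np.sqrt(aspect)
    b = r0 * np.sqrt(aspect)
    rr, cc = ellipse(center[0], center[1], a, b, shape=mask_img.shape, rotation=angle)
    mask_img[rr, cc] = label


def _vignette(shape: tuple[int, int], amplitude: float, scale: float) -> np.ndarray:
    """Smooth multiplicative bias, 1 at center falling to 1-amplitude at the
    corner radius scaled by *scale*; normalized to max 1."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rmax = np.hypot(cy, cx) * scale
    rho2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / max(rmax, 1e-9) ** 2
    bias = 1.0 - amplitude * rho2
    return bias / bias.max()


def generate_field(
    spec: SceneSpec,
    well: str = "A1",
    field_index: int = 1,
    image_number: int | None = None,
) -> tuple[FieldImage, FieldImage, GroundTruth]:
    """Render one two-channel field (nuclear dye + GFP) with exact ground truth.

    Cells are smoothed ellipses with flat diffuse GFP; inclusions are 2-D
    Gaussian puncta clipped to the cell mask, with peak amplitude set so that
    peak / diffuse = ``puncta_contrast`` in the noise-free, bias-free render.
    The vignette multiplies the clean scene, then Poisson shot noise and
    Gaussian read noise are added, and the result is rounded and saturated to
    the camera bit depth.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    image_number = field_index if image_number is None else image_number
    n = spec.n_cells

    cell_masks = np.zeros((h, w), dtype=np.int32)
    nucleus_masks = np.zeros((h, w), dtype=np.int32)
    gfp_clean = np.zeros((h, w), dtype=np.float64)
    dapi_clean = np.zeros((h, w), dtype=np.float64)

    rows = []
    if n > 0:
        cd_mean, cd_sd = spec.cell_diameter_px
        lo, hi = spec.cell_diameter_range
        cell_d = _truncnorm(rng, cd_mean, cd_sd, lo, hi, n)
        nd_mean, nd_sd = spec.nucleus_diameter_px
        nuc_d = _truncnorm(rng, nd_mean, nd_sd, max(4.0, nd_mean - 3 * nd_sd), nd_mean + 3 * nd_sd, n)
        nuc_d = np.minimum(nuc_d, 0.8 * cell_d)
        centers = _place_centers(rng, (h, w), cell_d)
        aspects = rng.uniform(0.7, 1.0, n)
        angles = rng.uniform(0.0, np.pi, n)
        inclusion = rng.random(n) < spec.inclusion_prevalence
        transfected = rng.random(n) < spec.transfected_fraction
        mu, sigma = spec.diffuse_intensity
        diffuse = rng.lognormal(mu, sigma, n)
        nmu, nsigma = spec.nucleus_intensity
        nuc_int = rng.lognormal(nmu, nsigma, n)

        for i in range(n):
            cid = i + 1
            _draw_ellipse(cell_masks, cid, tuple(centers[i]), cell_d[i], aspects[i], angles[i])
            _draw_ellipse(nucleus_masks, cid, tuple(centers[i]), nuc_d[i],
                          min(1.0, aspects[i] + 0.1), angles[i])

        cell_slices = ndimage.find_objects(cell_masks)
        nuc_slices = ndimage.find_objects(nucleus_masks)
        body = np.zeros((h, w))
        for i in range(n):
            cid = i + 1
            sl = cell_slices[cid - 1]
            if transfected[i] and sl is not None:
                body[sl][cell_masks[sl] == cid] = diffuse[i]
            nsl = nuc_slices[cid - 1]
            if nsl is not None:
                dapi_clean[nsl][nucleus_masks[nsl] == cid] = nuc_int[i]
        # soften object edges; puncta are added afterwards so their peaks are exact
        gfp_clean = ndimage.gaussian_filter(body, 1.0)
        dapi_clean = ndimage.gaussian_filter(dapi_clean, 1.0)

        pd_mean, pd_sd = spec.puncta_diameter_px
        plo, phi = spec.puncta_per_cell
        for i in range(n):
            cid = i + 1
            sl = cell_slices[cid - 1]
            if not (inclusion[i] and transfected[i]) or sl is None:
                continue
            n_puncta = int(rng.integers(plo, phi + 1))
            mask_i = cell_masks[sl] == cid
            oy, ox = sl[0].start, sl[1].start
            # place puncta at least one punctum-radius inside the cell edge
            dist = ndimage.distance_transform_edt(mask_i)
            for _p in range(n_puncta):
                d_p = max(2.0, rng.normal(pd_mean, pd_sd))
                sigma_p = d_p / 2.355  # diameter read as FWHM
                cand = np.argwhere(dist > d_p / 2.0 + 1.0)
                if len(cand) == 0:
                    cand = np.argwhere(mask_i)
                py, px = cand[rng.integers(len(cand))]
                py, px = py + oy, px + ox
                amp = (spec.puncta_contrast - 1.0) * diffuse[i]
                r = int(np.ceil(3 * sigma_p))
                y0, y1 = max(0, py - r), min(h, py + r + 1)
                x0, x1 = max(0, px - r), min(w, px + r + 1)
                yy, xx = np.mgrid[y0:y1, x0:x1]
                blob = amp * np.exp(-((yy - py) ** 2 + (xx - px) ** 2) / (2 * sigma_p ** 2))
                in_cell = cell_masks[y0:y1, x0:x1] == cid
                gfp_clean[y0:y1, x0:x1] += blob * in_cell

        from skimage.measure import regionprops
        props = {p.label: p for p in regionprops(cell_masks)}
        for i in range(n):
            cid = i + 1
            p = props[cid]
            rows.append({
                "cell_id": cid,
                "label": INCLUSION if (inclusion[i] and transfected[i]) else NO_INCLUSION,
                "transfected": bool(transfected[i]),
                "centroid_x": p.centroid[1],
                "centroid_y": p.centroid[0],
                "equivalent_diameter_px": p.equivalent_diameter_area,
                "diffuse_intensity": diffuse[i] if transfected[i] else 0.0,
            })

    cells = pd.DataFrame(
        rows, columns=["cell_id", "label", "transfected", "centroid_x", "centroid_y",
                       "equivalent_diameter_px", "diffuse_intensity"],
    )

    amp, scale = spec.bias_field
    bias = _vignette((h, w), amp, scale) if amp > 0 else np.ones((h, w))
    gauss_sd, gain = spec.noise
    ceiling = float(2 ** spec.bit_depth - 1)

    out = []
    for clean in (dapi_clean, gfp_clean):
        img = (clean + spec.background_offset) * bias
        if gain > 0:
            img = rng.poisson(np.clip(img, 0, None) / gain) * gain
        if gauss_sd > 0:
            img = img + rng.normal(0.0, gauss_sd, img.shape)
        out.append(np.clip(np.round(img), 0, ceiling))
    dapi_img, gfp_img = out

    dapi = FieldImage(ImageKey(well, field_index, "DAPI", image_number), dapi_img, spec.bit_depth)
    gfp = FieldImage(ImageKey(well, field_index, "GFP", image_number), gfp_img, spec.bit_depth)
    truth = GroundTruth(cell_masks=cell_masks, nucleus_masks=nucleus_masks,
                        cells=cells, bias_field=bias, spec=spec)
    return dapi, gfp, truth


def _sub_seed(seed: int, *key: int) -> int:
    """Deterministic 31-bit sub-seed for one field of one plate."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_plate(
    layout: pd.DataFrame,
    out_dir: str | Path,
    base_spec: SceneSpec | None = None,
    fields_per_well: int = 4,
    spec_overrides: dict[str, dict] | None = None,
    seed: int = 0,
    write_images: bool = True,
) -> pd.DataFrame:
    """Render a plate: TIFFs named ``WELL_FIELD_CHANNEL_IMAGE.tif`` plus a truth table.

    *layout* needs a ``well`` column; optional per-well overrides (e.g. the
    inclusion prevalence implied by a dose) come via *spec_overrides*, a
    mapping well -> SceneSpec field overrides.  Each field gets its own
    sub-seed derived from the plate seed, so plates are reproducible without
    cross-field correlation.  Returns the truth table (one row per cell) and
    writes it as ``truth.csv`` beside the images.
    """
    base_spec = base_spec or SceneSpec()
    spec_overrides = spec_overrides or {}
    out_dir = Path(out_dir)
    if write_images:
        out_dir.mkdir(parents=True, exist_ok=True)
    if fields_per_well < 1:
        raise ValueError("fields_per_well must be >= 1")

    all_rows = []
    for w_idx, well in enumerate(layout["well"]):
        overrides = dict(spec_overrides.get(well, {}))
        for f_idx in range(1, fields_per_well + 1):
            spec = base_spec.with_(seed=_sub_seed(seed, w_idx, f_idx), **overrides)
            dapi, gfp, truth = generate_field(spec, well=well, field_index=f_idx)
            if write_images:
                for img in (dapi, gfp):
                    path = out_dir / format_key(img.key)
                    if path.exists():
                        raise FileExistsError(f"output name collision: {path}")
                    write_field(out_dir, img)
            t = truth.cells.copy()
            t.insert(0, "well", well)
            t.insert(1, "field", f_idx)
            all_rows.append(t)

    table = pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame(
        columns=["well", "field", "cell_id", "label", "transfected",
                 "centroid_x", "centroid_y", "equivalent_diameter_px", "diffuse_intensity"])
    if write_images:
        table.to_csv(out_dir / "truth.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# checkerboard response surfaces


@dataclass(frozen=True)
class HillCurve:
    """Monotherapy effect curve: percentage-point inclusion reduction vs dose.

    effect(d) = e0 + (emax − e0) · d^h / (d^h + ec50^h); e0 is the zero-dose
    effect and must be 0 so the control well is effect-free.
    """

    emax: float
    ec50: float
    hill: float = 1.0
    e0: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.e0 != 0.0:
            raise ValueError("zero-dose effect must be 0 for a checkerboard margin")

    def effect(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            dh = np.where(dose > 0, dose ** self.hill, 0.0)
        return self.e0 + (self.emax - self.e0) * dh / (dh + self.ec50 ** self.hill)


@dataclass(frozen=True)
class ComboTruthSpec:
    """Generating parameters for a synthetic checkerboard.

    Default dose series mirror a CuATSM-like twofold series up to 0.5 µM and
    an ebselen-like twofold series up to 10 µM, each including the zero-dose
    margin.  ``synergy_offset`` is the percentage-point excess effect over the
    HSA reference: a scalar applies at every dose pair where both doses are
    nonzero; an array gives per-pair offsets (margins must be 0).
    """

    doses_a: tuple = (0.0, 0.03125, 0.0625, 0.125, 0.25, 0.5)
    doses_b: tuple = (0.0, 1.25, 2.5, 5.0, 10.0)
    mono_a: HillCurve = field(default_factory=lambda: HillCurve(emax=75.0, ec50=0.1, hill=1.5))
    mono_b: HillCurve = field(default_factory=lambda: HillCurve(emax=65.0, ec50=2.5, hill=1.5))
    baseline_pct: float = 27.7
    synergy_offset: object = 0.0
    noise_sd: float = 2.0
    replicates: int = 3
    seed: int = 0

    def offset_matrix(self) -> np.ndarray:
        na, nb = len(self.doses_a), len(self.doses_b)
        off = np.asarray(self.synergy_offset, dtype=float)
        if off.ndim == 0:
            m = np.zeros((na, nb))
            m[1:, 1:] = float(off)
            return m
        if off.shape != (na, nb):
            raise ValueError(f"synergy_offset shape {off.shape} != dose grid {(na, nb)}")
        if np.any(off[0, :] != 0) or np.any(off[:, 0] != 0):
            raise ValueError("synergy_offset must be 0 on the zero-dose margins")
        return off


def generate_checkerboard(spec: ComboTruthSpec) -> tuple[Checkerboard, dict]:
    """Simulate raw inclusion-% grids per replicate plus the noiseless truth.

    The noiseless effect surface is max(mono_a, mono_b) + synergy_offset,
    clipped to [0, 100]; the observed response at each dose pair is
    baseline · (100 − effect)/100 plus Gaussian noise, clipped to >= 0, so the
    no-drug cell equals the baseline prevalence.  With synergy_offset = 0 and
    noise 0 the surface is exactly the HSA reference.
    """
    rng = np.random.default_rng(spec.seed)
    da = np.asarray(spec.doses_a, dtype=float)
    db = np.asarray(spec.doses_b, dtype=float)
    ea = spec.mono_a.effect(da)
    eb = spec.mono_b.effect(db)
    effect = np.clip(np.maximum.outer(ea, eb) + spec.offset_matrix(), 0.0, 100.0)
    clean = spec.baseline_pct * (100.0 - effect) / 100.0
    reps = []
    for _ in range(spec.replicates):
        obs = clean.copy()
        if spec.noise_sd > 0:
            obs = obs + rng.normal(0.0, spec.noise_sd, obs.shape)
        reps.append(np.clip(obs, 0.0, 100.0))
    board = Checkerboard(doses_a=da, doses_b=db, replicates=reps)
    truth = {"effect": effect, "response_clean": clean,
             "mono_a": ea, "mono_b": eb, "offset": spec.offset_matrix()}
    return board, truth


# ---------------------------------------------------------------------------
# live-cell count series


def generate_timeseries(
    death_rates: dict[str, float],
    timepoints,
    n0: int = 200,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate GFP+ cell counts per arm over time.

    Counts follow a stochastic exponential-decline model: the mean curve is
    n0 · exp(−rate · t) per arm and observed counts are Poisson draws around
    it.  Returns (counts, truth) where *truth* holds the deterministic mean
    curves.  Negative timepoints or nonpositive n0 raise.
    """
    t = np.asarray(timepoints, dtype=float)
    if np.any(t < 0):
        raise ValueError("timepoints must be nonnegative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if n0 <= 0:
        raise ValueError("starting count must be > 0")
    for arm, r in death_rates.items():
        if not np.isfinite(r):
            raise ValueError(f"rate for arm {arm!r} is not finite")

    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for arm, rate in death_rates.items():
        mean = n0 * np.exp(-rate * t)
        for ti, m in zip(t, mean):
            truth_rows.append({"arm": arm, "time_h": ti, "mean_count": m})
        for rep in range(1, replicates + 1):
            counts = rng.poisson(mean)
            counts[0] = max(int(counts[0]), 1)  # a well begins with at least one cell
            for ti, c in zip(t, counts):
                rows.append({"arm": arm, "replicate": rep, "time_h": ti, "count": int(c)})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
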