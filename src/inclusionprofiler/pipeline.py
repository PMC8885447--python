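"""End-to-end assembly: images → corrected fields → cells → profiles → wells.

Thin orchestration over the stage modules, used by the CLI, the validation
suite and anyone scoring a plate in one call.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cytoprofile import compute_profile, profiles_to_frame
from .illumcorr import IlluminationFunction, apply_correction, estimate_illumination
from .plateio import FieldImage
from .segment import CellObject, match_to_truth, segment_cells, segment_nuclei
from .simgen import GroundTruth, SceneSpec, generate_field

__all__ = [
    "correct_fields",
    "segment_field",
    "profile_field",
    "process_fields",
    "truth_cell_objects",
    "labeled_pool",
    "segmentation_recall",
]

FieldTriple = tuple[FieldImage, FieldImage, "GroundTruth | None"]


def correct_fields(
    fields: Sequence[tuple[FieldImage, FieldImage]],
    smoothing_scale_px: float = 500.0,
) -> list[tuple[FieldImage, FieldImage]]:
    """Estimate one illumination function per channel across the set and
    subtract it from every field."""
    dapis = [d for d, _g in fields]
    gfps = [g for _d, g in fields]
    fn_d = estimate_illumination(dapis, smoothing_scale_px)
    fn_g = estimate_illumination(gfps, smoothing_scale_px)
    return [(apply_correction(d, fn_d), apply_correction(g, fn_g))
            for d, g in fields]


def segment_field(dapi: FieldImage | None, gfp: FieldImage, **kwargs) -> list[CellObject]:
    """Nucleus-seeded segmentation when a nuclear channel is given, GFP-only
    otherwise."""
    nuclei = segment_nuclei(dapi) if dapi is not None else None
    return segment_cells(gfp, nuclei, **kwargs)


def profile_field(cells: Iterable[CellObject], gfp: FieldImage) -> pd.DataFrame:
    return profiles_to_frame([compute_profile(c, gfp) for c in cells])


def process_fields(
    fields: Sequence[tuple[FieldImage, FieldImage]],
    smoothing_scale_px: float = 500.0,
    correct: bool = True,
) -> tuple[pd.DataFrame, list[list[CellObject]]]:
    """Correct, segment and profile a set of two-channel fields.

    Returns the concatenated per-cell profile frame (metadata columns first)
    and the per-field cell lists.  Cell ids are unique within (well, field).
    """
    pairs = correct_fields(fields, smoothing_scale_px) if correct else list(fields)
    frames, all_cells = [], []
    for dapi, gfp in pairs:
        cells = segment_field(dapi, gfp)
        all_cells.append(cells)
        if cells:
            frames.append(profile_field(cells, gfp))
    profiles = (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame(columns=["well", "field", "cell_id"]))
    return profiles, all_cells


def truth_cell_objects(truth: GroundTruth, key_channel: str = "GFP",
                       transfected_only: bool = True) -> list[CellObject]:
    """Build CellObjects directly from simulator truth masks (oracle route)."""
    from skimage.measure import regionprops

    from .plateio import ImageKey

    keep = set(truth.cells.loc[truth.cells["transfected"], "cell_id"]
               if transfected_only else truth.cells["cell_id"])
    key = ImageKey("A1", 1, key_channel, 1)
    out = []
    for p in regionprops(truth.cell_masks):
        if p.label not in keep:
            continue
        r0, c0, r1, c1 = p.bbox
        out.append(CellObject(
            cell_id=int(p.label), key=key, bbox=(r0, c0, r1, c1),
            mask=p.image.copy(),
            equivalent_diameter_px=float(p.equivalent_diameter_area),
            centroid=(float(p.centroid[1]), float(p.centroid[0])),
        ))
    return out


def labeled_pool(
    seeds,
    prevalence: float = 0.5,
    base_spec: SceneSpec | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Segmented, truth-labeled cytoprofiles from simulated fields.

    Renders one field per seed at the given inclusion prevalence, runs the
    standard correct-segment-profile route, and labels each detected cell by
    IoU matching against the simulator truth — the closest automated analogue
    of a reviewer labeling segmented thumbnails.  Unmatched detections are
    dropped.  Returns (profiles, labels); profiles carry a ``field`` column
    set to the generating seed.
    """
    base_spec = base_spec or SceneSpec()
    triples = [generate_field(base_spec.with_(seed=s, inclusion_prevalence=prevalence))
               for s in seeds]
    pairs = correct_fields([(d, g) for d, g, _t in triples])
    frames = []
    for (dc, gc), (_d, _g, truth) in zip(pairs, triples):
        cells = segment_field(dc, gc)
        if not cells:
            continue
        matched = match_to_truth(cells, truth.cell_masks)
        cells = [c for c in cells if c.cell_id in matched]
        df = profile_field(cells, gc)
        truth_labels = truth.cells.set_index("cell_id")["label"]
        df["true_label"] = [truth_labels[matched[c.cell_id]] for c in cells]
        df["field"] = truth.spec.seed
        frames.append(df)
    pool = pd.concat(frames, ignore_index=True)
    labels = pool.pop("true_label")
    return pool, labels


def segmentation_recall(
    cells: list[CellObject],
    truth: GroundTruth,
    iou_threshold: float = 0.5,
    min_d: float = 17.0,
    max_d: float = 50.0,
) -> tuple[float, int, int]:
    """Recall of in-gate transfected truth cells at the IoU match rule.

    Returns (recall, n_matched, n_eligible); recall is NaN when no truth cell
    is eligible.
    """
    t = truth.cells
    eligible = t[(t["transfected"])
                 & (t["equivalent_diameter_px"] >= min_d)
                 & (t["equivalent_diameter_px"] <= max_d)]
    if len(eligible) == 0:
        return float("nan"), 0, 0
    matched = match_to_truth(cells, truth.cell_masks, iou_threshold)
    hit = len(set(matched.values()) & set(eligible["cell_id"]))
    return hit / len(eligible), hit, len(eligible)
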