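"""Plate image I/O and filename metadata.

Automated plate imagers emit one grayscale TIFF per channel per field, named
``(WELL)_(FIELD)_(CHANNEL)_(IMAGE)`` — e.g. ``B4_2_GFP_2`` — so that the plate
position and channel of every image can be recovered from its filename alone.
This module parses and formats those keys, and assembles a directory of TIFFs
into channel-paired fields per well.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as _dc_field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageKey",
    "FieldImage",
    "PlateImages",
    "parse_key",
    "format_key",
    "load_plate",
    "inventory",
]

#: default channel vocabulary; extensible via the ``channels`` argument of
#: :func:`load_plate` (e.g. to add TdTomato)
DEFAULT_CHANNELS = ("DAPI", "GFP")

_KEY_RE = re.compile(
    r"^(?P<well>[A-Za-z]{1,2}0*\d{1,2})_(?P<field>\d+)_(?P<channel>[^_]+)_(?P<image>\d+)$"
)
_WELL_RE = re.compile(r"^(?P<row>[A-Za-z]{1,2})0*(?P<col>\d{1,2})$")


class KeyParseError(ValueError):
    """Raised when a filename does not follow the WELL_FIELD_CHANNEL_IMAGE scheme."""


def normalize_well(well: str) -> str:
    """Normalize a well name to uppercase letter(s) + unpadded column ("B04" -> "B4")."""
    m = _WELL_RE.match(well)
    if m is None:
        raise KeyParseError(f"invalid well name {well!r}")
    return m.group("row").upper() + str(int(m.group("col")))


@dataclass(frozen=True, order=True)
class ImageKey:
    """Identity of one channel of one microscope field on a plate."""

    well: str
    field: int
    channel: str
    image_number: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "well", normalize_well(self.well))
        if self.field < 1:
            raise ValueError(f"field index must be >= 1, got {self.field}")
        if self.image_number < 1:
            raise ValueError(f"image number must be >= 1, got {self.image_number}")

    @property
    def row(self) -> str:
        return _WELL_RE.match(self.well).group("row")

    @property
    def col(self) -> int:
        return int(_WELL_RE.match(self.well).group("col"))


def parse_key(filename: str | Path) -> ImageKey:
    """Parse an ``ImageKey`` from a filename like ``B4_2_GFP_2.tif``.

    The extension is optional.  Raises :class:`KeyParseError` naming the
    offending token when the basename does not match the scheme.
    """
    stem = Path(filename).name
    for ext in (".tif", ".tiff", ".TIF", ".TIFF"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
            break
    m = _KEY_RE.match(stem)
    if m is None:
        raise KeyParseError(
            f"filename {Path(filename).name!r} does not match WELL_FIELD_CHANNEL_IMAGE"
        )
    return ImageKey(
        well=m.group("well"),
        field=int(m.group("field")),
        channel=m.group("channel"),
        image_number=int(m.group("image")),
    )


def format_key(key: ImageKey, ext: str = ".tif") -> str:
    """Inverse of :func:`parse_key`: the canonical filename for a key."""
    return f"{key.well}_{key.field}_{key.channel}_{key.image_number}{ext}"


@dataclass
class FieldImage:
    """One channel of one field: pixel data plus its plate metadata."""

    key: ImageKey
    pixels: np.ndarray
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("FieldImage pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("FieldImage pixels must be finite")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("FieldImage pixels must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PlateImages:
    """Channel-paired fields grouped by (well, field).

    ``fields`` maps ``(well, field_index)`` to ``{channel: FieldImage}``.
    ``unpaired`` lists keys whose expected partner channel was missing.
    """

    fields: dict[tuple[str, int], dict[str, FieldImage]]
    unpaired: list[ImageKey] = _dc_field(default_factory=list)

    def wells(self) -> list[str]:
        """Wells present, enumerated in row-major plate order (A1..H12)."""
        seen = {w for (w, _f) in self.fields}
        return sorted(seen, key=lambda w: (_WELL_RE.match(w).group("row"), int(_WELL_RE.match(w).group("col"))))

    def __len__(self) -> int:
        return len(self.fields)


def load_plate(
    directory: str | Path,
    channels: Iterable[str] = DEFAULT_CHANNELS,
    required_channel: str = "DAPI",
    gfp_only: bool = False,
) -> PlateImages:
    """Read every TIFF in *directory* and group fields by well with channel pairing.

    Every GFP field is expected to have a same-(well, field) partner in
    *required_channel*; fields lacking one are reported in ``unpaired`` (and
    still loaded).  With ``gfp_only=True`` no pairing is required.

    Raises on duplicate keys and on unreadable TIFFs (naming the file).
    """
    directory = Path(directory)
    channels = tuple(channels)
    entries: dict[ImageKey, FieldImage] = {}
    for path in sorted(directory.glob("*.tif")) + sorted(directory.glob("*.tiff")):
        key = parse_key(path.name)
        if key.channel not in channels:
            raise KeyParseError(
                f"{path.name}: channel {key.channel!r} not in declared channel list {channels}"
            )
        if key in entries:
            raise ValueError(f"duplicate image key {key} in {directory}")
        try:
            pixels = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - depends on corrupt input
            raise IOError(f"unreadable TIFF {path}: {exc}") from exc
        entries[key] = FieldImage(key=key, pixels=pixels)

    fields: dict[tuple[str, int], dict[str, FieldImage]] = {}
    for key, img in sorted(entries.items()):
        fields.setdefault((key.well, key.field), {})[key.channel] = img

    unpaired: list[ImageKey] = []
    if not gfp_only:
        for (_well, _field), by_channel in sorted(fields.items()):
            for ch, img in by_channel.items():
                if ch != required_channel and required_channel not in by_channel:
                    unpaired.append(img.key)
    shapes = {img.shape for by_ch in fields.values() for img in by_ch.values()}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent image shapes within plate: {sorted(shapes)}")
    return PlateImages(fields=fields, unpaired=unpaired)


def inventory(directory: str | Path) -> pd.DataFrame:
    """Tabulate the keys of every TIFF in *directory* (one row per image)."""
    rows = []
    for path in sorted(Path(directory).glob("*.tif")) + sorted(Path(directory).glob("*.tiff")):
        k = parse_key(path.name)
        rows.append(
            {"filename": path.name, "well": k.well, "field": k.field,
             "channel": k.channel, "image_number": k.image_number}
        )
    return pd.DataFrame(rows, columns=["filename", "well", "field", "channel", "image_number"])


def write_field(directory: str | Path, img: FieldImage) -> Path:
    """Write a field image as a single-plane 16-bit TIFF named by its key."""
    path = Path(directory) / format_key(img.key)
    data = np.clip(np.round(img.pixels), 0, 2 ** img.bit_depth - 1).astype(np.uint16)
    tifffile.imwrite(path, data)
    return path


def read_layout(path: str | Path) -> pd.DataFrame:
    """Read a plate-layout CSV (columns: well, construct, dose_a, dose_b, replicate)."""
    layout = pd.read_csv(path)
    if "well" not in layout.columns:
        raise ValueError("layout must have a 'well' column")
    layout = layout.copy()
    layout["well"] = layout["well"].map(normalize_well)
    if layout["well"].duplicated().any():
        dup = layout.loc[layout["well"].duplicated(), "well"].iloc[0]
        raise ValueError(f"duplicate well {dup} in layout")
    return layout
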