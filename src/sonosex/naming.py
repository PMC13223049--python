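"""Canonical filename grammar and per-frame metadata.

Frames are named ``<ID>_<location>_<sex>_<size>_<YYYYMMDD>_<frame>.png``
(e.g. ``A012_BML_F_large_20240301_03.png``). The identity of an animal is the
composite key (individual_id, location, sex, size_class): the same ID string
may recur across collection sites, and sex/size are part of how frames are
organized on disk.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass

SEXES = ("F", "M")
SIZE_CLASSES = ("small", "large")

_TOKEN_RE = {
    "individual_id": re.compile(r"^[A-Za-z0-9]+$"),
    "location": re.compile(r"^[A-Za-z0-9]+$"),
    "date": re.compile(r"^\d{8}$"),
    "frame_index": re.compile(r"^\d+$"),
}


class FilenameError(ValueError):
    """Raised when a frame filename does not follow the canonical grammar."""

    def __init__(self, name: str, field: str, reason: str):
        self.field = field
        super().__init__(f"cannot parse {name!r}: bad {field} ({reason})")


@dataclass(frozen=True)
class FrameMeta:
    """Metadata for one frame, as encoded in its filename."""

    individual_id: str
    location: str
    sex: str
    size_class: str
    date: datetime.date
    frame_index: int

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"size_class must be one of {SIZE_CLASSES}, got {self.size_class!r}")

    @property
    def individual_key(self) -> tuple[str, str, str, str]:
        return (self.individual_id, self.location, self.sex, self.size_class)


def parse_filename(name: str) -> FrameMeta:
    """Parse a canonical frame filename into :class:`FrameMeta`.

    Raises :class:`FilenameError` naming the first offending field.
    """
    base = name.rsplit("/", 1)[-1]
    if not base.endswith(".png"):
        raise FilenameError(name, "extension", "expected .png")
    stem = base[: -len(".png")]
    parts = stem.split("_")
    if len(parts) != 6:
        raise FilenameError(name, "structure", f"expected 6 underscore-separated fields, got {len(parts)}")
    ind, loc, sex, size, date_s, frame_s = parts
    if not _TOKEN_RE["individual_id"].match(ind):
        raise FilenameError(name, "individual_id", "must be alphanumeric")
    if not _TOKEN_RE["location"].match(loc):
        raise FilenameError(name, "location", "must be alphanumeric")
    if sex not in SEXES:
        raise FilenameError(name, "sex", f"must be one of {SEXES}")
    if size not in SIZE_CLASSES:
        raise FilenameError(name, "size_class", f"must be one of {SIZE_CLASSES}")
    if not _TOKEN_RE["date"].match(date_s):
        raise FilenameError(name, "date", "must be YYYYMMDD")
    try:
        date = datetime.date(int(date_s[:4]), int(date_s[4:6]), int(date_s[6:8]))
    except ValueError as e:
        raise FilenameError(name, "date", str(e)) from None
    if not _TOKEN_RE["frame_index"].match(frame_s):
        raise FilenameError(name, "frame_index", "must be an integer")
    return FrameMeta(ind, loc, sex, size, date, int(frame_s))


def format_filename(meta: FrameMeta) -> str:
    """Inverse of :func:`parse_filename` (zero-padded two-digit frame index)."""
    return (
        f"{meta.individual_id}_{meta.location}_{meta.sex}_{meta.size_class}_"
        f"{meta.date.strftime('%Y%m%d')}_{meta.frame_index:02d}.png"
    )
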