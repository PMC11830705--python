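"""YOLO-style plain-text label I/O.

Dialect: one object per row, ``class cx cy w h``, whitespace-separated,
coordinates normalized to [0, 1] relative to the tile.  Values are written
with 6 decimals, so ``write -> read -> write`` is bit-identical after the
first write.
"""

from __future__ import annotations

from pathlib import Path

from ..errors import LabelParseError
from .losses import BBox, Detection

LabelRow = tuple[int, BBox]


def read_labels(path) -> list[LabelRow]:
    """Parse a label file into ``(class_id, normalized BBox)`` rows."""
    path = Path(path)
    rows: list[LabelRow] = []
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise LabelParseError(
                f"{path}:{line_no}: expected 5 fields, got {len(parts)}",
                path=path, line_no=line_no,
            )
        try:
            cls = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
        except ValueError as exc:
            raise LabelParseError(
                f"{path}:{line_no}: non-numeric field ({exc})",
                path=path, line_no=line_no,
            ) from None
        if not (0 <= cx <= 1 and 0 <= cy <= 1 and 0 <= w <= 1 and 0 <= h <= 1):
            raise LabelParseError(
                f"{path}:{line_no}: coordinates must be normalized to [0, 1]",
                path=path, line_no=line_no,
            )
        rows.append((cls, BBox(cx, cy, w, h, frame="tile")))
    return rows


def write_labels(rows, path) -> None:
    """Write ``(class_id, BBox)`` rows (or Detections) to a label file."""
    path = Path(path)
    lines = []
    for row in rows:
        if isinstance(row, Detection):
            cls, box = row.class_id, row.bbox
        else:
            cls, box = row
        lines.append(
            f"{cls} {box.cx:.6f} {box.cy:.6f} {box.w:.6f} {box.h:.6f}"
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
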