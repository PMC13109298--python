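"""Minimal ESRI shapefile polygon writer/reader.

Implements just enough of the shapefile specification for plot-boundary
export: polygon geometry (shape type 5, single outer ring per record) in the
.shp/.shx pair and integer / logical attributes in the companion .dbf
(dBASE III). Coordinates are doubles in the file's native units.
"""

from __future__ import annotations

import struct
from datetime import date
from pathlib import Path

__all__ = ["write_polygon_shapefile", "read_polygon_shapefile"]

_SHAPE_POLYGON = 5


def _ring_closed_clockwise(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    pts = list(points)
    if pts[0] != pts[-1]:
        pts.append(pts[0])
    # signed area > 0 means counter-clockwise; shapefile outer rings are CW
    area2 = sum(
        (x1 - x0) * (y1 + y0) for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:])
    )
    if area2 < 0:
        pts = pts[::-1]
    return pts


def write_polygon_shapefile(
    path: str | Path,
    polygons: list[list[tuple[float, float]]],
    fields: list[tuple[str, str, int, int]],
    records: list[tuple],
) -> None:
    """Write polygons plus attribute records to ``path`` (.shp/.shx/.dbf).

    ``fields`` entries are (name, type, length, decimals) with type 'N'
    (numeric) or 'L' (logical). One attribute tuple per polygon.
    """
    if not polygons:
        raise ValueError("no polygons to write")
    if len(records) != len(polygons):
        raise ValueError("one attribute record is required per polygon")
    path = Path(path)
    base = path.with_suffix("")

    shp_records = []
    for i, poly in enumerate(polygons, start=1):
        ring = _ring_closed_clockwise(poly)
        xs = [p[0] for p in ring]
        ys = [p[1] for p in ring]
        content = struct.pack(
            "<i4dii", _SHAPE_POLYGON, min(xs), min(ys), max(xs), max(ys), 1, len(ring)
        )
        content += struct.pack("<i", 0)  # single part starting at point 0
        for x, y in ring:
            content += struct.pack("<2d", x, y)
        header = struct.pack(">2i", i, len(content) // 2)
        shp_records.append(header + content)

    all_x = [p[0] for poly in polygons for p in poly]
    all_y = [p[1] for poly in polygons for p in poly]
    bbox = (min(all_x), min(all_y), max(all_x), max(all_y))

    def file_header(length_words: int) -> bytes:
        head = struct.pack(">i5i", 9994, 0, 0, 0, 0, 0)
        head += struct.pack(">i", length_words)
        head += struct.pack("<2i", 1000, _SHAPE_POLYGON)
        head += struct.pack("<4d", *bbox)
        head += struct.pack("<4d", 0.0, 0.0, 0.0, 0.0)
        return head

    shp_len = (100 + sum(len(r) for r in shp_records)) // 2
    with open(base.with_suffix(".shp"), "wb") as fh:
        fh.write(file_header(shp_len))
        for rec in shp_records:
            fh.write(rec)

    shx_len = (100 + 8 * len(shp_records)) // 2
    with open(base.with_suffix(".shx"), "wb") as fh:
        fh.write(file_header(shx_len))
        offset = 50
        for rec in shp_records:
            content_words = (len(rec) - 8) // 2
            fh.write(struct.pack(">2i", offset, content_words))
            offset += len(rec) // 2

    _write_dbf(base.with_suffix(".dbf"), fields, records)


def _write_dbf(
    path: Path, fields: list[tuple[str, str, int, int]], records: list[tuple]
) -> None:
    today = date.today()
    n_rec = len(records)
    rec_size = 1 + sum(f[2] for f in fields)
    header_size = 32 + 32 * len(fields) + 1
    with open(path, "wb") as fh:
        fh.write(
            struct.pack(
                "<4BIHH20x",
                0x03,
                today.year - 1900,
                today.month,
                today.day,
                n_rec,
                header_size,
                rec_size,
            )
        )
        for name, ftype, length, deci in fields:
            fh.write(struct.pack("<11s c 4x B B 14x", name.encode()[:10], ftype.encode(), length, deci))
        fh.write(b"\x0d")
        for rec in records:
            fh.write(b" ")
            for (name, ftype, length, deci), value in zip(fields, rec):
                if ftype == "L":
                    fh.write(b"T" if value else b"F")
                elif ftype == "N":
                    if deci:
                        text = f"{float(value):.{deci}f}"
                    else:
                        text = str(int(value))
                    fh.write(text.rjust(length).encode()[:length])
                else:
                    fh.write(str(value).ljust(length).encode()[:length])
        fh.write(b"\x1a")


def read_polygon_shapefile(
    path: str | Path,
) -> tuple[list[list[tuple[float, float]]], list[dict]]:
    """Read back polygons (outer ring each) and attribute dicts."""
    base = Path(path).with_suffix("")
    polygons: list[list[tuple[float, float]]] = []
    with open(base.with_suffix(".shp"), "rb") as fh:
        data = fh.read()
    (code,) = struct.unpack(">i", data[:4])
    if code != 9994:
        raise ValueError("not a shapefile")
    pos = 100
    while pos < len(data):
        _, content_words = struct.unpack(">2i", data[pos : pos + 8])
        pos += 8
        shape_type, _, _, _, _, n_parts, n_points = struct.unpack(
            "<i4dii", data[pos : pos + 44]
        )
        if shape_type != _SHAPE_POLYGON:
            raise ValueError(f"unsupported shape type {shape_type}")
        parts_off = pos + 44
        pts_off = parts_off + 4 * n_parts
        pts = [
            struct.unpack("<2d", data[pts_off + 16 * k : pts_off + 16 * k + 16])
            for k in range(n_points)
        ]
        polygons.append([(x, y) for x, y in pts])
        pos += content_words * 2

    attrs = _read_dbf(base.with_suffix(".dbf"))
    return polygons, attrs


def _read_dbf(path: Path) -> list[dict]:
    with open(path, "rb") as fh:
        data = fh.read()
    n_rec, header_size, rec_size = struct.unpack("<IHH", data[4:12])
    fields = []
    pos = 32
    while data[pos] != 0x0D:
        name = data[pos : pos + 11].split(b"\x00")[0].decode()
        ftype = chr(data[pos + 11])
        length = data[pos + 16]
        fields.append((name, ftype, length))
        pos += 32
    records = []
    pos = header_size
    for _ in range(n_rec):
        rec: dict = {}
        off = pos + 1  # skip deletion flag
        for name, ftype, length in fields:
            raw = data[off : off + length].decode().strip()
            if ftype == "L":
                rec[name] = raw in ("T", "t", "Y", "y")
            elif ftype == "N":
                rec[name] = float(raw) if "." in raw else int(raw)
            else:
                rec[name] = raw
            off += length
        records.append(rec)
        pos += rec_size
    return records
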