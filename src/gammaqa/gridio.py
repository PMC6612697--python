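"""Reading and writing dose grids.

The native exchange format is a plain-text "dose-grid TSV": a header block
of ``key<TAB>value`` lines (format_version, nx, ny, dx_mm, dy_mm,
origin_x_mm, origin_y_mm, dose_unit), a blank line, then ny rows of nx
tab-separated dose values — row j holds the doses at constant y for
increasing x.  Values are serialized with 17 significant digits so a
write/read round trip is bit-exact for float64.

DICOM RT Dose ingestion (single planar frame) is provided for
planning-system exports; it is read-only.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import DicomImportError, GridFormatError
from .model import DoseGrid

FORMAT_VERSION = "1"
_HEADER_KEYS = (
    "format_version", "nx", "ny", "dx_mm", "dy_mm",
    "origin_x_mm", "origin_y_mm", "dose_unit",
)


def write_grid(grid: DoseGrid, path: str | Path) -> None:
    """Write a DoseGrid in the dose-grid TSV format."""
    path = Path(path)
    lines = [
        f"format_version\t{FORMAT_VERSION}",
        f"nx\t{grid.nx}",
        f"ny\t{grid.ny}",
        f"dx_mm\t{grid.dx:.17g}",
        f"dy_mm\t{grid.dy:.17g}",
        f"origin_x_mm\t{grid.origin[0]:.17g}",
        f"origin_y_mm\t{grid.origin[1]:.17g}",
        f"dose_unit\t{grid.dose_unit}",
        "",
    ]
    for j in range(grid.ny):
        lines.append("\t".join(f"{v:.17g}" for v in grid.values[:, j]))
    path.write_text("\n".join(lines) + "\n")


def read_grid(path: str | Path) -> DoseGrid:
    """Read a dose-grid TSV file; diagnostics name the offending line."""
    path = Path(path)
    raw = path.read_text().splitlines()

    header: dict[str, str] = {}
    body_start = None
    for ln, line in enumerate(raw, start=1):
        if line.strip() == "":
            body_start = ln  # 1-based index of the blank separator
            break
        if "\t" not in line:
            raise GridFormatError(f"line {ln}: expected 'key<TAB>value' header line")
        key, _, value = line.partition("\t")
        header[key.strip()] = value.strip()
    if body_start is None:
        raise GridFormatError("missing blank line separating header and dose matrix")

    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"missing header key(s): {', '.join(missing)}")

    def _int(key):
        try:
            return int(header[key])
        except ValueError as e:
            raise GridFormatError(f"header key '{key}' is not an integer") from e

    def _float(key):
        try:
            return float(header[key])
        except ValueError as e:
            raise GridFormatError(f"header key '{key}' is not numeric") from e

    nx, ny = _int("nx"), _int("ny")
    dx, dy = _float("dx_mm"), _float("dy_mm")
    if dx <= 0 or dy <= 0:
        raise GridFormatError("invalid spacing: dx_mm and dy_mm must be > 0")
    x0, y0 = _float("origin_x_mm"), _float("origin_y_mm")

    rows = []
    for off, line in enumerate(raw[body_start:]):
        ln = body_start + 1 + off
        if line.strip() == "":
            continue
        cells = line.split("\t")
        if len(cells) != nx:
            raise GridFormatError(
                f"line {ln}: expected nx={nx} values, found {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as e:
            raise GridFormatError(f"line {ln}: non-numeric cell") from e
    if len(rows) != ny:
        raise GridFormatError(
            f"dose matrix has {len(rows)} row(s), header declares ny={ny}"
        )
    values = np.asarray(rows, dtype=float).T  # rows are constant y
    return DoseGrid(values, (dx, dy), (x0, y0), header["dose_unit"])


def read_rtdose(path: str | Path, frame: int | None = None) -> DoseGrid:
    """Read a planar DICOM RT Dose object into a DoseGrid.

    Pixel data are scaled by DoseGridScaling; spacing comes from
    PixelSpacing (row, column → dy, dx) and the origin from
    ImagePositionPatient (x, y).  Multi-frame objects need an explicit
    ``frame`` index.
    """
    import pydicom

    ds = pydicom.dcmread(str(path), force=True)
    modality = getattr(ds, "Modality", None)
    if modality != "RTDOSE":
        raise DicomImportError(
            f"not an RT Dose object (Modality={modality!r})"
        )
    if "DoseGridScaling" not in ds or "PixelSpacing" not in ds:
        raise DicomImportError("missing DoseGridScaling or PixelSpacing attribute")
    arr = ds.pixel_array
    nframes = int(getattr(ds, "NumberOfFrames", 1))
    if nframes > 1 or arr.ndim == 3:
        if frame is None:
            raise DicomImportError(
                f"multi-frame RT Dose ({nframes} frames): a frame index is "
                "required (pass frame=..., or --frame on the command line)"
            )
        arr = arr[frame]
    scaling = float(ds.DoseGridScaling)
    dy, dx = (float(v) for v in ds.PixelSpacing)  # row spacing, column spacing
    ipp = getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])
    x0, y0 = float(ipp[0]), float(ipp[1])
    unit = getattr(ds, "DoseUnits", "GY")
    # pixel_array is (rows, cols) = (y, x); our layout is values[i=x, j=y]
    values = (arr.astype(float) * scaling).T
    return DoseGrid(values, (dx, dy), (x0, y0), str(unit))
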