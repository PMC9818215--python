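"""Minimal ENVI header + raw cube reader/writer (BSQ and BIL interleaves)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cube import HyperCube
from .grid import WavelengthGrid

_DTYPES = {4: np.float32, 5: np.float64}
_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_envi(cube: HyperCube, path: str | Path, interleave: str = "bsq") -> None:
    """Write ``path`` (raw binary) and ``path + '.hdr'`` (text header)."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil"):
        raise ValueError("interleave must be 'bsq' or 'bil'")
    path = Path(path)
    rows, cols, bands = cube.shape
    data = cube.data.astype(np.float32)
    if interleave == "bsq":  # (bands, rows, cols)
        arr = np.transpose(data, (2, 0, 1))
    else:  # bil: (rows, bands, cols)
        arr = np.transpose(data, (0, 2, 1))
    arr.tofile(path)
    wl = ", ".join(f"{w:.4f}" for w in cube.grid.values)
    hdr = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODES[np.dtype(np.float32)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    Path(str(path) + ".hdr").write_text(hdr)


def _parse_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf = ""
    in_block = False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI":
            continue
        if in_block:
            buf += " " + line
            if "}" in line:
                fields[key] = buf
                in_block = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if "{" in val and "}" not in val:
            in_block = True
            buf = val
        else:
            fields[key] = val
    return fields


def read_envi(path: str | Path) -> HyperCube:
    """Read an ENVI raw cube given the data-file path (header at path + '.hdr')."""
    path = Path(path)
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    fields = _parse_header(hdr_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _DTYPES[int(fields.get("data type", "4"))]
    interleave = fields.get("interleave", "bsq").lower()
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise ValueError("raw file size does not match header dimensions")
    if interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    wl_field = fields.get("wavelength")
    if wl_field is not None:
        wl = np.array(
            [float(v) for v in wl_field.strip("{} ").split(",") if v.strip()]
        )
        grid = WavelengthGrid(wl)
    else:
        grid = WavelengthGrid.default(bands)
    return HyperCube(data.astype(float), grid, kind="raw")
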