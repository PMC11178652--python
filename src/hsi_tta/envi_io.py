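"""Minimal ENVI header + raw binary I/O for hyperspectral cubes, plus masks.

Cubes are stored as a text ``.hdr`` in standard ENVI key/value syntax next
to a raw binary file (float64, BIP interleave, little endian), which keeps
round-trips bit-exact. Only the small subset of ENVI needed here is
supported: 100-band cubes with an explicit wavelength list.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DataError
from .optics import WavelengthGrid, camera_grid
from .spectral_db import HSICube

__all__ = ["write_cube", "read_cube", "write_mask", "read_mask", "write_sidecar", "read_sidecar"]

_DTYPES = {4: np.float32, 5: np.float64}


def _hdr_path(path: Path) -> Path:
    return path.with_suffix(".hdr")


def _raw_path(path: Path) -> Path:
    return path.with_suffix(".raw")


def write_cube(cube: HSICube, path) -> None:
    """Write ENVI header + raw float64 BIP pair; ``path`` extension is ignored."""
    path = Path(path)
    H, W, B = cube.values.shape
    wl = ", ".join(f"{w:g}" for w in cube.grid.wavelengths_nm)
    hdr = (
        "ENVI\n"
        "description = {hsi-tta cube}\n"
        f"samples = {W}\n"
        f"lines = {H}\n"
        f"bands = {B}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 5\n"
        "interleave = bip\n"
        "byte order = 0\n"
        f"subject id = {{{cube.subject_id}}}\n"
        f"image id = {{{cube.image_id}}}\n"
        f"normalized = {int(cube.normalized)}\n"
        f"wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
    )
    _hdr_path(path).write_text(hdr)
    cube.values.astype("<f8").tofile(_raw_path(path))


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise DataError("not an ENVI header")
    # join brace-delimited values across lines, then split on top-level keys
    out = {}
    for m in re.finditer(r"^([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n{]*)$", text, re.M | re.S):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1].strip()
        out[key] = val
    return out


def read_cube(path, expect_wavelengths: np.ndarray | None = None) -> HSICube:
    """Read an ENVI pair written by :func:`write_cube`.

    The header must declare 100 bands and wavelengths equal to the camera
    grid (500...995 nm step 5) unless ``expect_wavelengths`` overrides the
    expectation explicitly.
    """
    path = Path(path)
    hdr = _parse_header(_hdr_path(path).read_text())
    H, W, B = int(hdr["lines"]), int(hdr["samples"]), int(hdr["bands"])
    if B != 100:
        raise DataError(f"expected a 100-band cube, header declares {B} bands")
    dtype = _DTYPES.get(int(hdr.get("data type", 5)))
    if dtype is None:
        raise DataError(f"unsupported ENVI data type {hdr.get('data type')}")
    if hdr.get("interleave", "bip").lower() != "bip":
        raise DataError("only BIP interleave is supported")
    wav = np.array([float(x) for x in hdr["wavelength"].split(",")])
    if wav.size != B:
        raise DataError("wavelength list length does not match band count")
    expected = expect_wavelengths if expect_wavelengths is not None else camera_grid().wavelengths_nm
    if not np.allclose(wav, expected):
        raise DataError("header wavelengths differ from the expected camera grid")
    raw = np.fromfile(_raw_path(path), dtype=np.dtype(dtype).newbyteorder("<"))
    if raw.size != H * W * B:
        raise DataError(
            f"raw file has {raw.size} values, header implies {H * W * B}"
        )
    values = raw.reshape(H, W, B).astype(np.float64)
    return HSICube(
        values,
        WavelengthGrid(wav, float(np.diff(wav)[0])),
        subject_id=hdr.get("subject id", ""),
        image_id=hdr.get("image id", ""),
        normalized=bool(int(hdr.get("normalized", 0))),
    )


def write_mask(mask: np.ndarray, path) -> None:
    """8-bit PNG label mask."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > 255:
        raise DataError("mask labels must fit 8-bit PNG")
    Image.fromarray(mask.astype(np.uint8), mode="L").save(path)


def read_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.int64)


def write_sidecar(obj: dict, path) -> None:
    def _convert(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: _convert(x) for k, x in v.items()}
        return v

    Path(path).write_text(json.dumps(_convert(obj), indent=2))


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
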