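"""Minimal ENVI hypercube I/O: text header + raw float32 BSQ binary, plus a
compressed single-file ``.npz`` container."""

from __future__ import annotations

import os

import numpy as np

from .spectra import SpectralGrid
from .spectral import Hypercube

__all__ = ["write_envi", "read_envi", "write_npz", "read_npz"]


def write_envi(cube: Hypercube, path_base: str | os.PathLike) -> tuple[str, str]:
    """Write ``<base>.hdr`` and ``<base>.raw`` (float32, band-sequential)."""
    base = os.fspath(path_base)
    h, w, nb = cube.shape
    wl = ", ".join(f"{v:g}" for v in cube.grid.wavelengths)
    header = (
        "ENVI\n"
        "description = {reconstructed reflectance hypercube}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {nb}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    hdr, raw = base + ".hdr", base + ".raw"
    with open(hdr, "w") as fh:
        fh.write(header)
    np.ascontiguousarray(
        np.moveaxis(cube.values.astype(np.float32), 2, 0)
    ).tofile(raw)
    return hdr, raw


def _parse_header(path: str) -> dict[str, str]:
    text = open(path).read()
    if not text.startswith("ENVI"):
        raise ValueError(f"{path}: not an ENVI header")
    fields: dict[str, str] = {}
    buf = ""
    for line in text.splitlines()[1:]:
        buf += line
        if "{" in buf and "}" not in buf:
            buf += " "
            continue
        if "=" in buf:
            key, val = buf.split("=", 1)
            fields[key.strip()] = val.strip().strip("{}").strip()
        buf = ""
    return fields


def read_envi(path_base: str | os.PathLike) -> Hypercube:
    base = os.fspath(path_base)
    fields = _parse_header(base + ".hdr")
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    if int(fields["data type"]) != 4:
        raise ValueError("only float32 (data type 4) is supported")
    w = int(fields["samples"])
    h = int(fields["lines"])
    nb = int(fields["bands"])
    wl = np.array([float(v) for v in fields["wavelength"].split(",")])
    step = wl[1] - wl[0]
    grid = SpectralGrid(float(wl[0]), float(wl[-1]), float(step))
    data = np.fromfile(base + ".raw", dtype=np.float32).reshape(nb, h, w)
    return Hypercube(grid, np.moveaxis(data, 0, 2))


def write_npz(cube: Hypercube, path: str | os.PathLike) -> None:
    np.savez_compressed(
        path,
        values=cube.values.astype(np.float32),
        grid=np.array([cube.grid.start_nm, cube.grid.end_nm, cube.grid.step_nm]),
    )


def read_npz(path: str | os.PathLike) -> Hypercube:
    with np.load(path) as data:
        start, end, step = data["grid"]
        return Hypercube(SpectralGrid(start, end, step), data["values"])
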