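"""File I/O: multi-page TIFF cubes, ENVI hdr/raw cubes, library and lamp
CSV tables, and plain-text series manifests.

TIFF cubes are written one page per band, shortest wavelength first, with
the wavelength axis and bit depth embedded in the image description as
JSON.  ENVI cubes use the standard text header (band-sequential
interleave) next to a raw binary file.
"""

from __future__ import annotations

import json
import os
import re

import numpy as np
import pandas as pd
import tifffile

from .datamodel import (
    AcquisitionSeries,
    Roi,
    SpectralCube,
    SpectralLibrary,
    WavelengthAxis,
    make_wavelength_axis,
)

__all__ = [
    "save_cube_tiff", "load_cube_tiff",
    "write_envi", "read_envi",
    "write_library_csv", "read_library_csv",
    "read_lamp_csv",
    "save_series", "load_series",
    "save_image_tiff", "load_image_tiff",
]


def _axis_meta(axis: WavelengthAxis) -> dict:
    return {"start_nm": axis.start_nm, "stop_nm": axis.stop_nm, "step_nm": axis.step_nm}


def save_cube_tiff(cube: SpectralCube, path) -> None:
    """Write a cube as a multi-page TIFF, one page per band."""
    pages = np.moveaxis(np.asarray(cube.data), 2, 0)
    desc = json.dumps({
        "axis": _axis_meta(cube.axis),
        "bit_depth": cube.bit_depth,
        "meta": {k: v for k, v in cube.meta.items() if isinstance(v, (str, int, float, bool))},
    })
    tifffile.imwrite(path, pages.astype(np.float32), description=desc, photometric="minisblack")


def load_cube_tiff(path) -> SpectralCube:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    info = json.loads(desc)
    a = info["axis"]
    axis = make_wavelength_axis(a["start_nm"], a["stop_nm"], a["step_nm"])
    data = np.moveaxis(pages, 0, 2)
    meta = dict(info.get("meta", {}))
    meta["source"] = str(path)
    return SpectralCube(data, axis, int(info["bit_depth"]), meta)


def save_image_tiff(image: np.ndarray, path) -> None:
    """Write a single 2-D image (abundance map, RMS-error map, ROI mask)."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32), photometric="minisblack")


def load_image_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path))


# --- ENVI ------------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def write_envi(cube: SpectralCube, base_path) -> tuple:
    """Write ``base.hdr`` + ``base.raw`` (band-sequential float32).

    Returns the (hdr, raw) paths.
    """
    base = os.fspath(base_path)
    if base.endswith(".hdr") or base.endswith(".raw"):
        base = base[:-4]
    hdr, raw = base + ".hdr", base + ".raw"
    data = np.asarray(cube.data, dtype=np.float32)
    bsq = np.moveaxis(data, 2, 0)  # (bands, lines, samples)
    bsq.tofile(raw)
    wl = ", ".join(f"{w:g}" for w in cube.axis.centers)
    with open(hdr, "w") as fh:
        fh.write("ENVI\n")
        fh.write(f"samples = {cube.n_cols}\n")
        fh.write(f"lines = {cube.n_rows}\n")
        fh.write(f"bands = {cube.axis.n_bands}\n")
        fh.write("header offset = 0\n")
        fh.write("file type = ENVI Standard\n")
        fh.write(f"data type = {_ENVI_CODES[np.dtype(np.float32)]}\n")
        fh.write("interleave = bsq\n")
        fh.write("byte order = 0\n")
        fh.write(f"bit depth = {cube.bit_depth}\n")
        fh.write("wavelength units = Nanometers\n")
        fh.write("wavelength = { " + wl + " }\n")
    return hdr, raw


def _parse_envi_header(hdr_path) -> dict:
    text = open(hdr_path).read()
    if not text.lstrip().startswith("ENVI"):
        raise ValueError(f"{hdr_path} is not an ENVI header")
    fields = {}
    # brace-delimited values may span lines
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", text, re.MULTILINE):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
    return fields


def read_envi(hdr_path, raw_path=None) -> SpectralCube:
    hdr_path = os.fspath(hdr_path)
    if raw_path is None:
        raw_path = hdr_path[:-4] + ".raw" if hdr_path.endswith(".hdr") else hdr_path + ".raw"
    f = _parse_envi_header(hdr_path)
    samples, lines, bands = (int(f[k]) for k in ("samples", "lines", "bands"))
    dtype = _ENVI_DTYPES[int(f.get("data type", 4))]
    interleave = f.get("interleave", "bsq").lower()
    offset = int(f.get("header offset", 0))
    raw = np.fromfile(raw_path, dtype=dtype, offset=offset)
    if raw.size != samples * lines * bands:
        raise ValueError(
            f"{raw_path}: expected {samples * lines * bands} values, found {raw.size}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples)
        data = np.moveaxis(data, 0, 2)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples)
        data = np.moveaxis(data, 1, 2)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    wl_field = f.get("wavelength", "")
    wl = np.array([float(x) for x in wl_field.strip("{} \n").split(",") if x.strip()])
    if len(wl) != bands:
        raise ValueError(f"{hdr_path}: wavelength list length {len(wl)} != bands {bands}")
    step = wl[1] - wl[0] if bands > 1 else 1.0
    axis = make_wavelength_axis(wl[0], wl[-1], step)
    if not np.allclose(axis.centers, wl, atol=1e-6):
        raise ValueError(f"{hdr_path}: wavelength list is not uniformly spaced")
    bit_depth = int(f.get("bit depth", 16))
    return SpectralCube(data.astype(float), axis, bit_depth, {"source": hdr_path})


# --- CSV tables ------------------------------------------------------------

def write_library_csv(library: SpectralLibrary, path) -> None:
    """Library CSV: first column wavelength_nm, one column per endmember."""
    df = pd.DataFrame({"wavelength_nm": library.axis.centers})
    for name, spec in zip(library.names, library.spectra):
        df[name] = spec
    df.to_csv(path, index=False)


def read_library_csv(path, normalization: str = "raw") -> SpectralLibrary:
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError(f"{path}: first column must be wavelength_nm, got {df.columns[0]!r}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    step = wl[1] - wl[0] if len(wl) > 1 else 1.0
    axis = make_wavelength_axis(wl[0], wl[-1], step)
    names = [c for c in df.columns[1:]]
    spectra = df[names].to_numpy(dtype=float).T
    return SpectralLibrary(names, spectra, axis, normalization)


def read_lamp_csv(path) -> np.ndarray:
    """Two-column lamp table (wavelength_nm, irradiance) → (n, 2) array."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: lamp spectrum needs two columns (wavelength, irradiance)")
    table = df.iloc[:, :2].to_numpy(dtype=float)
    if np.any(np.diff(table[:, 0]) <= 0):
        raise ValueError(f"{path}: lamp wavelengths must be strictly increasing")
    return table


# --- series manifests -------------------------------------------------------

def save_series(series: AcquisitionSeries, directory, stem: str = "cube") -> str:
    """Write member cubes as TIFFs plus a plain-text manifest; returns the
    manifest path."""
    os.makedirs(directory, exist_ok=True)
    names = []
    for i, cube in enumerate(series.cubes):
        name = f"{stem}_{i:03d}.tif"
        save_cube_tiff(cube, os.path.join(directory, name))
        names.append(name)
    manifest = os.path.join(directory, f"{stem}_manifest.txt")
    with open(manifest, "w") as fh:
        fh.write(f"kind = {series.kind}\n")
        if series.times_s is not None:
            fh.write("times_s = " + ", ".join(f"{t:g}" for t in series.times_s) + "\n")
        for name in names:
            fh.write(f"cube = {name}\n")
    return manifest


def load_series(manifest_path) -> AcquisitionSeries:
    directory = os.path.dirname(os.fspath(manifest_path))
    kind, times, files = None, None, []
    for line in open(manifest_path):
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, val = (p.strip() for p in line.split("=", 1))
        if key == "kind":
            kind = val
        elif key == "times_s":
            times = np.array([float(x) for x in val.split(",")])
        elif key == "cube":
            files.append(val)
    if kind is None or not files:
        raise ValueError(f"{manifest_path}: manifest needs a kind and at least one cube entry")
    cubes = [load_cube_tiff(os.path.join(directory, f)) for f in files]
    return AcquisitionSeries(cubes, kind, times)
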