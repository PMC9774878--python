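"""Cube and label-map I/O plus spectral resampling.

The canonical on-disk container is HDF5 (datasets ``data``, ``axis``,
optional ``truth`` plus axis metadata).  Band-stacked TIFF (bands as pages,
axis in a CSV sidecar) and ENVI header+binary (BSQ/BIL/BIP interleaves,
plain-text ``.hdr``) are supported for interoperability with spectroscopy
tooling.  Label maps are written as an indexed PNG with a seeded palette and
a CSV of integers.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np
import tifffile
from scipy.interpolate import interp1d
from PIL import Image
from PIL.PngImagePlugin import PngInfo

from .core import HSICube, WavenumberAxis, make_wavenumber_axis
from .patchwork import LabelMap

__all__ = [
    "write_hsi",
    "read_hsi",
    "resample_band",
    "write_label_map",
    "read_label_map",
    "save_cae",
    "load_cae",
    "save_patchset",
    "load_patchset",
]

_ENVI_DTYPES = {4: np.float32, 5: np.float64, 2: np.int16, 12: np.uint16, 1: np.uint8}
_ENVI_CODES = {np.dtype(v).name: k for k, v in _ENVI_DTYPES.items()}


# --------------------------------------------------------------------------
# cubes
# --------------------------------------------------------------------------
def write_hsi(cube: HSICube, path: str | Path, format: str | None = None) -> None:
    """Write a cube as HDF5 (default), band-stacked TIFF, or ENVI."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=cube.data)
            f.create_dataset("axis", data=cube.axis.values)
            f.attrs["axis_start"] = cube.axis.start
            f.attrs["axis_step"] = cube.axis.step
            f.attrs["axis_count"] = cube.axis.count
            if cube.truth is not None:
                f.create_dataset("truth", data=cube.truth)
    elif fmt == "tiff_stack":
        # pages are bands: (B, H, W)
        tifffile.imwrite(path, np.moveaxis(cube.data, 2, 0).astype(np.float32))
        _write_axis_csv(path.with_suffix(".axis.csv"), cube.axis)
    elif fmt == "envi":
        _write_envi(cube, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_hsi(path: str | Path, format: str | None = None) -> HSICube:
    """Read a cube written by `write_hsi` (HDF5, TIFF stack, or ENVI)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "axis" not in f and "axis_start" not in f.attrs:
                raise ValueError(f"{path}: no wavenumber axis; write one under 'axis'")
            data = f["data"][...]
            axis = make_wavenumber_axis(
                f.attrs["axis_start"], f.attrs["axis_step"], int(f.attrs["axis_count"])
            )
            truth = f["truth"][...] if "truth" in f else None
        return HSICube(data, axis, truth=truth)
    if fmt == "tiff_stack":
        stack = tifffile.imread(path)
        axis = _read_axis_csv(path.with_suffix(".axis.csv"))
        if stack.shape[0] != len(axis):
            raise ValueError(
                f"{path}: {stack.shape[0]} pages but axis has {len(axis)} points"
            )
        return HSICube(np.moveaxis(stack, 0, 2).astype(np.float64), axis)
    if fmt == "envi":
        return _read_envi(path)
    raise ValueError(f"unknown format {fmt!r}")


def _infer_format(path: Path) -> str:
    suf = path.suffix.lower()
    if suf in (".h5", ".hdf5"):
        return "hdf5"
    if suf in (".tif", ".tiff"):
        return "tiff_stack"
    if suf in (".hdr", ".img", ".raw", ".envi"):
        return "envi"
    return "hdf5"


def _write_axis_csv(path: Path, axis: WavenumberAxis) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["index", "wavenumber_cm-1"])
        for i, v in enumerate(axis.values):
            w.writerow([i, repr(float(v))])


def _read_axis_csv(path: Path) -> WavenumberAxis:
    if not path.exists():
        raise ValueError(f"missing axis sidecar {path}; regenerate with write_hsi")
    vals = np.loadtxt(path, delimiter=",", skiprows=1, usecols=1, ndmin=1)
    if len(vals) < 2:
        raise ValueError(f"{path}: axis needs at least 2 points")
    step = float(vals[1] - vals[0])
    return make_wavenumber_axis(float(vals[0]), step, len(vals))


# --------------------------------------------------------------------------
# ENVI header + binary (hand-rolled: plain-text header, raw little-endian data)
# --------------------------------------------------------------------------
def _write_envi(cube: HSICube, path: Path, interleave: str = "bsq") -> None:
    hdr = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    binpath = hdr.with_suffix(".img")
    H, W, B = cube.shape
    data = cube.data.astype(np.float32)
    if interleave == "bsq":
        arr = np.moveaxis(data, 2, 0)  # (B, H, W)
    elif interleave == "bil":
        arr = np.moveaxis(data, 2, 1)  # (H, B, W)
    elif interleave == "bip":
        arr = data  # (H, W, B)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    arr.tofile(binpath)
    wl = ", ".join(f"{v:.6f}" for v in cube.axis.values)
    hdr.write_text(
        "ENVI\n"
        f"samples = {W}\n"
        f"lines = {H}\n"
        f"bands = {B}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES['float32']}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = cm-1\n"
        f"wavelength = {{ {wl} }}\n"
    )


def _parse_envi_header(hdr: Path) -> dict:
    text = hdr.read_text()
    if not text.lstrip().startswith("ENVI"):
        raise ValueError(f"{hdr}: not an ENVI header")
    fields: dict = {}
    # brace-delimited values may span lines; normalise first
    body = text.replace("\n", " \n")
    i = 0
    lines = []
    while i < len(body):
        j = body.find("\n", i)
        line = body[i:j if j != -1 else len(body)]
        if "{" in line and "}" not in line:
            k = body.find("}", i)
            line = body[i : k + 1].replace("\n", " ")
            i = k + 1
        else:
            i = j + 1 if j != -1 else len(body)
        lines.append(line)
    for line in lines:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def _read_envi(path: Path) -> HSICube:
    hdr = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    if not hdr.exists():
        raise FileNotFoundError(hdr)
    fields = _parse_envi_header(hdr)
    try:
        W = int(fields["samples"])
        H = int(fields["lines"])
        B = int(fields["bands"])
        dtype = _ENVI_DTYPES[int(fields["data type"])]
        interleave = fields["interleave"].lower()
    except KeyError as e:
        raise ValueError(f"{hdr}: missing required ENVI field {e}") from e
    if "wavelength" not in fields:
        raise ValueError(f"{hdr}: no wavelength block; add 'wavelength = {{...}}'")
    wl = np.array(
        [float(v) for v in fields["wavelength"].strip("{} ").split(",") if v.strip()]
    )
    if len(wl) != B:
        raise ValueError(f"{hdr}: {len(wl)} wavelengths for {B} bands")
    binpath = hdr.with_suffix(".img")
    raw = np.fromfile(binpath, dtype=dtype)
    if raw.size != H * W * B:
        raise ValueError(
            f"{binpath}: {raw.size} values, expected {H * W * B} ({H}x{W}x{B})"
        )
    if interleave == "bsq":
        data = np.moveaxis(raw.reshape(B, H, W), 0, 2)
    elif interleave == "bil":
        data = np.moveaxis(raw.reshape(H, B, W), 1, 2)
    elif interleave == "bip":
        data = raw.reshape(H, W, B)
    else:
        raise ValueError(f"{hdr}: unknown interleave {interleave!r}")
    step = float(wl[1] - wl[0]) if len(wl) > 1 else 1.0
    axis = make_wavenumber_axis(float(wl[0]), step, len(wl))
    return HSICube(data.astype(np.float64), axis)


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------
def resample_band(cube: HSICube, lo: float, hi: float, step: float) -> HSICube:
    """Truncate the band to [lo, hi] and linearly interpolate to a new grid.

    The output axis is the arithmetic grid lo, lo+step, ... capped at hi
    (inclusive when it lands on the grid), e.g. 1000-1800 at 1 cm^-1 gives
    801 points.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    old = cube.axis.values
    if lo < old[0] or hi > old[-1]:
        raise ValueError(
            f"requested range [{lo}, {hi}] outside axis [{old[0]}, {old[-1]}]"
        )
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    count = int(np.floor((hi - lo) / step + 1e-9)) + 1
    new_axis = make_wavenumber_axis(lo, step, count)
    new = new_axis.values
    H, W, B = cube.shape
    out = interp1d(old, cube.data, axis=2, assume_sorted=True)(new)
    return HSICube(out, new_axis, truth=cube.truth)


# --------------------------------------------------------------------------
# patch sets
# --------------------------------------------------------------------------
def save_patchset(ps, path: str | Path) -> None:
    """Persist a patch set (patches, coords, geometry, normalisation)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("patches", data=ps.patches)
        f.create_dataset("coords", data=ps.coords)
        f.attrs["patch_size"] = ps.patch_size
        f.attrs["step"] = ps.step
        f.attrs["source_shape"] = ps.source_shape
        if ps.norm is not None:
            f.attrs["global_max"] = ps.norm.global_max
            f.attrs["negatives_zeroed"] = ps.norm.negatives_zeroed


def load_patchset(path: str | Path):
    from .patchwork import NormalizationRecord, PatchSet

    with h5py.File(path, "r") as f:
        norm = None
        if "global_max" in f.attrs:
            norm = NormalizationRecord(
                float(f.attrs["global_max"]), bool(f.attrs["negatives_zeroed"])
            )
        return PatchSet(
            patches=f["patches"][...],
            coords=f["coords"][...],
            patch_size=int(f.attrs["patch_size"]),
            step=int(f.attrs["step"]),
            source_shape=tuple(int(v) for v in f.attrs["source_shape"]),
            norm=norm,
        )


# --------------------------------------------------------------------------
# model checkpoints (self-describing: config embedded alongside the weights)
# --------------------------------------------------------------------------
def save_cae(cae, path: str | Path) -> None:
    """Save CAE weights with the architecture config embedded."""
    from .cae_models import CAE  # local import to avoid a cycle

    cfg = cae.cfg
    with h5py.File(path, "w") as f:
        g = f.create_group("config")
        g.attrs["arch"] = cfg.arch
        g.attrs["patch_size"] = cfg.patch_size
        g.attrs["bands"] = cfg.bands
        g.attrs["latent_total"] = cfg.latent_total
        g.attrs["branches"] = cfg.branches
        g.attrs["seed"] = cfg.seed
        g.attrs["filter_budget"] = repr(cfg.filter_budget)
        w = f.create_group("weights")
        for i, (p, _) in enumerate(cae.param_pairs()):
            w.create_dataset(f"p{i:04d}", data=p)


def load_cae(path: str | Path):
    """Rebuild a CAE from a checkpoint written by `save_cae`."""
    import ast

    from .cae_models import ArchitectureConfig, build_cae

    with h5py.File(path, "r") as f:
        g = f["config"]
        cfg = ArchitectureConfig(
            arch=str(g.attrs["arch"]),
            patch_size=int(g.attrs["patch_size"]),
            bands=int(g.attrs["bands"]),
            latent_total=int(g.attrs["latent_total"]),
            branches=int(g.attrs["branches"]),
            filter_budget=ast.literal_eval(str(g.attrs["filter_budget"])),
            seed=int(g.attrs["seed"]),
        )
        cae = build_cae(cfg)
        for i, (p, _) in enumerate(cae.param_pairs()):
            p[...] = f["weights"][f"p{i:04d}"][...]
    return cae


# --------------------------------------------------------------------------
# label maps
# --------------------------------------------------------------------------
def _palette(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    pal = rng.integers(40, 255, size=(max(n, 1), 3), dtype=np.uint8)
    pal[0] = (40, 40, 40)
    return pal


def write_label_map(m: LabelMap, path: str | Path, palette_seed: int = 0) -> None:
    """Write an indexed PNG (seeded palette) plus a CSV of integer labels."""
    path = Path(path)
    png_path = path if path.suffix == ".png" else path.with_suffix(".png")
    csv_path = png_path.with_suffix(".csv")
    pal = _palette(m.n_classes, palette_seed)
    img = Image.fromarray(m.labels.astype(np.uint8), mode="P")
    full = np.zeros((256, 3), dtype=np.uint8)
    full[: len(pal)] = pal
    img.putpalette(full.ravel().tolist())
    info = PngInfo()
    info.add_text("n_classes", str(m.n_classes))
    info.add_text("provenance", m.provenance)
    info.add_text("palette_seed", str(palette_seed))
    img.save(png_path, pnginfo=info)
    np.savetxt(csv_path, m.labels, fmt="%d", delimiter=",")


def read_label_map(path: str | Path) -> LabelMap:
    """Read the CSV written by `write_label_map` (PNG is presentation only)."""
    path = Path(path)
    csv_path = path if path.suffix == ".csv" else path.with_suffix(".csv")
    labels = np.loadtxt(csv_path, delimiter=",", dtype=np.int64, ndmin=2)
    return LabelMap(labels, n_classes=int(labels.max()) + 1, provenance="truth")
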