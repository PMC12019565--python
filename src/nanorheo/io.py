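"""File formats: curve tables, PSD tables, map rasters and map bundles.

Curve tables are plain delimited text with a commented JSON metadata
header; columns are named with explicit units.  Force channels may be
stored calibrated (``f_n_N``, ``f_s_N``) or raw (``deflection_V`` with an
``invols``+``k_flex`` in the metadata, ``dv_l_V`` with ``gamma_tors`` and
``k_lat``); raw channels are materialized to newtons on read.  Maps are
written both as single-channel 32-bit float TIFF (pixel size and
provenance in the image description tag) and as a CSV pixel list.  A
hierarchical HDF5 container bundles a whole map (D, height, phase, ground
truth) in one file.
"""

from __future__ import annotations

import json
from typing import Any

import numpy as np
import pandas as pd

from .calibration import ThermalSpectrum
from .lockin import ShearDrive
from .pipeline import ForceCurve
from .spatial import DiffusivityMap

__all__ = [
    "SchemaError",
    "write_curve_table",
    "read_curve_table",
    "write_psd_table",
    "read_psd_table",
    "write_map_tiff",
    "read_map_tiff",
    "write_map_csv",
    "read_map_csv",
    "write_map_bundle",
    "read_map_bundle",
]

_MAGIC = "nanorheo-curve v1"


class SchemaError(ValueError):
    """A file does not match the expected schema."""


def _meta_to_json(meta: dict[str, Any]) -> str:
    out = {}
    for k, v in meta.items():
        if isinstance(v, ShearDrive):
            out[k] = {"__sheardrive__": v.__dict__}
        elif isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, dict):
            out[k] = json.loads(_meta_to_json(v))
        elif isinstance(v, (np.floating, np.integer)):
            out[k] = v.item()
        else:
            out[k] = v
    return json.dumps(out)


def _meta_from_json(s: str) -> dict[str, Any]:
    def hook(obj):
        if "__sheardrive__" in obj:
            return ShearDrive(**obj["__sheardrive__"])
        return obj

    return json.loads(s, object_hook=hook)


def write_curve_table(curve: ForceCurve, path) -> None:
    """Write a curve as commented-header CSV (lossless float round trip)."""
    meta = {k: v for k, v in curve.meta.items() if k != "truth"}
    truth = curve.meta.get("truth")
    if truth is not None:
        meta["truth"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in truth.items()
        }
    df = pd.DataFrame({
        "z_m": curve.z, "f_n_N": curve.f_n, "f_s_N": curve.f_s, "theta_deg": curve.theta,
    })
    with open(path, "w") as fh:
        fh.write(f"# {_MAGIC}\n")
        fh.write(f"# meta: {_meta_to_json(meta)}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


_UNIT_COLS = {
    "z": ("z_m", 1.0),
    "f_n": ("f_n_N", 1.0),
    "f_s": ("f_s_N", 1.0),
    "theta": ("theta_deg", 1.0),
}


def read_curve_table(path) -> ForceCurve:
    """Read a curve table, materializing raw voltage channels to newtons.

    Requires a unit-suffixed header for every channel; raises
    :class:`SchemaError` naming the first missing mandatory column.
    """
    meta: dict[str, Any] = {}
    with open(path) as fh:
        first = fh.readline()
        if _MAGIC not in first:
            raise SchemaError(f"not a nanorheo curve table: {path}")
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.startswith("# meta:"):
                meta = _meta_from_json(line[len("# meta:"):].strip())
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")

    cols = set(df.columns)
    if "z_m" not in cols:
        raise SchemaError("missing mandatory column 'z_m' (z position with unit header)")
    if "theta_deg" not in cols:
        raise SchemaError("missing mandatory column 'theta_deg'")

    if "f_n_N" in cols:
        f_n = df["f_n_N"].to_numpy()
    elif "deflection_V" in cols:
        invols, k_flex = meta.get("invols"), meta.get("k_flex")
        if invols is None or k_flex is None:
            raise SchemaError(
                "column 'deflection_V' needs 'invols' and 'k_flex' in metadata"
            )
        f_n = df["deflection_V"].to_numpy() * invols * k_flex
    else:
        raise SchemaError("missing mandatory column 'f_n_N' (or 'deflection_V')")

    if "f_s_N" in cols:
        f_s = df["f_s_N"].to_numpy()
    elif "dv_l_V" in cols:
        gamma, k_lat = meta.get("gamma_tors"), meta.get("k_lat")
        if gamma is None or k_lat is None:
            raise SchemaError("column 'dv_l_V' needs 'gamma_tors' and 'k_lat' in metadata")
        f_s = df["dv_l_V"].to_numpy() * gamma * k_lat
    else:
        raise SchemaError("missing mandatory column 'f_s_N' (or 'dv_l_V')")

    truth = meta.get("truth")
    if truth is not None:
        for k, v in truth.items():
            if isinstance(v, list):
                truth[k] = np.asarray(v, dtype=float)
    return ForceCurve(
        z=df["z_m"].to_numpy(), f_n=f_n, f_s=f_s, theta=df["theta_deg"].to_numpy(),
        meta=meta,
    )


def write_psd_table(spectrum: ThermalSpectrum, path) -> None:
    df = pd.DataFrame({"frequency_Hz": spectrum.frequency, "psd_V2_per_Hz": spectrum.psd})
    with open(path, "w") as fh:
        fh.write(f"# nanorheo-psd v1 medium={spectrum.medium} "
                 f"n_averages={spectrum.n_averages}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_psd_table(path) -> ThermalSpectrum:
    medium, n_avg = "liquid", 1
    with open(path) as fh:
        header = fh.readline()
        if "nanorheo-psd" not in header:
            raise SchemaError(f"not a nanorheo PSD table: {path}")
        for tok in header.split():
            if tok.startswith("medium="):
                medium = tok.split("=", 1)[1]
            elif tok.startswith("n_averages="):
                n_avg = int(tok.split("=", 1)[1])
        df = pd.read_csv(fh, float_precision="round_trip")
    for col in ("frequency_Hz", "psd_V2_per_Hz"):
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column '{col}'")
    return ThermalSpectrum(
        frequency=df["frequency_Hz"].to_numpy(), psd=df["psd_V2_per_Hz"].to_numpy(),
        medium=medium, n_averages=n_avg,
    )


# ---------------------------------------------------------------------------
# map rasters
# ---------------------------------------------------------------------------


def write_map_tiff(dmap: DiffusivityMap, path, channel: str = "d") -> None:
    """Single-channel float32 TIFF with pixel size + metadata in the
    description tag.  ``channel`` is 'd' (m^2/s) or 'height' (m)."""
    import tifffile

    data = getattr(dmap, channel).astype(np.float32)
    desc = json.dumps({
        "nanorheo": "map v1",
        "channel": channel,
        "pixel_size_m": dmap.pixel_size,
        "meta": {k: v for k, v in dmap.meta.items()
                 if isinstance(v, (int, float, str, bool, type(None), list, tuple))},
    })
    tifffile.imwrite(path, data, description=desc)


def read_map_tiff(path) -> tuple[np.ndarray, float, dict]:
    """Returns (grid, pixel_size_m, meta)."""
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        info = json.loads(desc.value) if desc is not None else {}
    if info.get("nanorheo") != "map v1":
        raise SchemaError(f"not a nanorheo map TIFF: {path}")
    return data, float(info["pixel_size_m"]), info.get("meta", {})


def write_map_csv(dmap: DiffusivityMap, path) -> None:
    """Portable pixel-list CSV: row, col, x/y (m), D (m^2/s), height, phase."""
    rows, cols = dmap.d.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    phase = (np.asarray(dmap.phase).ravel() if dmap.phase is not None
             else np.full(rows * cols, "", dtype=object))
    df = pd.DataFrame({
        "row": rr.ravel(), "col": cc.ravel(),
        "x_m": cc.ravel() * dmap.pixel_size, "y_m": rr.ravel() * dmap.pixel_size,
        "d_m2_s": dmap.d.ravel(), "height_m": dmap.height.ravel(), "phase": phase,
    })
    with open(path, "w") as fh:
        fh.write(f"# nanorheo-map v1 pixel_size_m={dmap.pixel_size!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_map_csv(path) -> DiffusivityMap:
    with open(path) as fh:
        header = fh.readline()
        if "nanorheo-map" not in header:
            raise SchemaError(f"not a nanorheo map CSV: {path}")
        pixel_size = float(header.split("pixel_size_m=")[1].strip())
        df = pd.read_csv(fh, float_precision="round_trip")
    df["phase"] = df["phase"].fillna("").astype(str)
    rows = int(df["row"].max()) + 1
    cols = int(df["col"].max()) + 1
    d = np.full((rows, cols), np.nan)
    h = np.zeros((rows, cols))
    ph = np.full((rows, cols), "", dtype=object)
    r, c = df["row"].to_numpy(), df["col"].to_numpy()
    d[r, c] = df["d_m2_s"].to_numpy()
    h[r, c] = df["height_m"].to_numpy()
    ph[r, c] = df["phase"].astype(str).to_numpy()
    phase = ph if (ph != "").any() else None
    return DiffusivityMap(d=d, height=h, pixel_size=pixel_size, phase=phase)


def write_map_bundle(path, dmap: DiffusivityMap, truth: dict | None = None) -> None:
    """HDF5 bundle: /d, /height, /phase plus optional /truth group."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format"] = "nanorheo-map-bundle v1"
        f.attrs["pixel_size_m"] = dmap.pixel_size
        f.create_dataset("d", data=dmap.d)
        f.create_dataset("height", data=dmap.height)
        if dmap.phase is not None:
            f.create_dataset("phase", data=np.asarray(dmap.phase, dtype="S8"))
        if truth:
            g = f.create_group("truth")
            for k, v in truth.items():
                g.create_dataset(k, data=np.asarray(v))


def read_map_bundle(path) -> tuple[DiffusivityMap, dict]:
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "nanorheo-map-bundle v1":
            raise SchemaError(f"not a nanorheo map bundle: {path}")
        phase = None
        if "phase" in f:
            phase = f["phase"][()].astype(str)
        dmap = DiffusivityMap(
            d=f["d"][()], height=f["height"][()],
            pixel_size=float(f.attrs["pixel_size_m"]), phase=phase,
        )
        truth = {k: f["truth"][k][()] for k in f["truth"]} if "truth" in f else {}
    return dmap, truth
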