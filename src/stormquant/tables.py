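"""Localization table container and on-disk formats.

A :class:`LocalizationTable` wraps a pandas DataFrame of fitted
single-molecule events plus the metadata needed to interpret it (pixel
size, number of movie frames) and a provenance list recording every
transformation applied.  The HDF5 layout is Picasso-compatible: positions
and PSF widths are stored in *pixel* units under ``/locs`` with the pixel
size as an attribute, so third-party SMLM viewers can open the files;
the in-memory API works in nanometres throughout.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

__all__ = ["LocalizationTable"]

REQUIRED_COLUMNS = ("frame", "x_nm", "y_nm", "sx_nm", "sy_nm",
                    "photons", "bg", "lpx_nm", "lpy_nm", "net_gradient")

# column name mapping nm-domain -> Picasso pixel-domain dataset names
_PX_NAMES = {"x_nm": "x", "y_nm": "y", "sx_nm": "sx", "sy_nm": "sy",
             "lpx_nm": "lpx", "lpy_nm": "lpy"}


class LocalizationTable:
    """Sorted-by-frame table of localizations with provenance metadata."""

    def __init__(self, df: pd.DataFrame, pixel_size_nm: float,
                 n_frames: int | None = None, provenance: list | None = None):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        if pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        df = df.reset_index(drop=True)
        if len(df) > 1 and not df["frame"].is_monotonic_increasing:
            df = df.sort_values("frame", kind="stable").reset_index(drop=True)
        self.df = df
        self.pixel_size_nm = float(pixel_size_nm)
        if n_frames is None:
            n_frames = int(df["frame"].max()) + 1 if len(df) else 0
        self.n_frames = int(n_frames)
        self.provenance = list(provenance) if provenance else []

    # -- basics ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x_nm", "y_nm"]].to_numpy()

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(self.df.copy(), self.pixel_size_nm,
                                 self.n_frames, list(self.provenance))

    def replace(self, df: pd.DataFrame) -> "LocalizationTable":
        return LocalizationTable(df, self.pixel_size_nm, self.n_frames,
                                 list(self.provenance))

    def with_provenance(self, operation: str, params: dict,
                        n_in: int | None = None, n_out: int | None = None
                        ) -> "LocalizationTable":
        out = self.copy()
        out.provenance.append({
            "operation": operation,
            "params": _jsonable(params),
            "n_in": n_in if n_in is not None else len(self),
            "n_out": n_out if n_out is not None else len(self),
        })
        return out

    # -- I/O -----------------------------------------------------------------

    def to_hdf5(self, path) -> None:
        px = self.pixel_size_nm
        with h5py.File(path, "w") as f:
            g = f.create_group("locs")
            for col in self.df.columns:
                data = self.df[col].to_numpy()
                if col in _PX_NAMES:
                    g.create_dataset(_PX_NAMES[col], data=data / px)
                elif col == "frame":
                    g.create_dataset("frame", data=data.astype(np.int64))
                else:
                    g.create_dataset(col, data=data)
            f.attrs["pixel_size_nm"] = px
            f.attrs["n_frames"] = self.n_frames
            f.attrs["provenance"] = json.dumps(self.provenance)

    @classmethod
    def from_hdf5(cls, path) -> "LocalizationTable":
        with h5py.File(path, "r") as f:
            g = f["locs"]
            px = float(f.attrs["pixel_size_nm"])
            n_frames = int(f.attrs.get("n_frames", 0)) or None
            prov = json.loads(f.attrs.get("provenance", "[]"))
            cols = {}
            inv = {v: k for k, v in _PX_NAMES.items()}
            for name in g:
                data = g[name][...]
                if name in inv:
                    cols[inv[name]] = data * px
                else:
                    cols[name] = data
        return cls(pd.DataFrame(cols), px, n_frames, prov)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pixel_size_nm: float,
                 n_frames: int | None = None) -> "LocalizationTable":
        return cls(pd.read_csv(path), pixel_size_nm, n_frames)


def _jsonable(params: dict) -> dict:
    out = {}
    for k, v in params.items():
        if isinstance(v, (np.integer,)):
            out[k] = int(v)
        elif isinstance(v, (np.floating,)):
            out[k] = float(v)
        elif isinstance(v, np.ndarray):
            out[k] = v.tolist() if v.size <= 16 else f"<array shape={v.shape}>"
        else:
            out[k] = v
    return out
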