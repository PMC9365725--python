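"""Movie I/O: multi-page 16-bit TIFF plus a YAML metadata sidecar."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .simulate import AcquisitionConfig, Movie

__all__ = ["write_movie", "read_movie"]


def _sidecar_path(tiff_path) -> Path:
    p = Path(tiff_path)
    return p.with_suffix(p.suffix + ".yaml")


def write_movie(movie: Movie, path) -> None:
    """Write the frame stack as multi-page TIFF with a YAML sidecar holding
    pixel size, integration time, camera gain/offset and frame count."""
    tifffile.imwrite(path, movie.frames, photometric="minisblack")
    acq = movie.acquisition
    meta = {
        "pixel_size_nm": acq.pixel_size_nm,
        "integration_ms": acq.integration_ms,
        "psf_sigma_nm": acq.psf_sigma_nm,
        "gain": acq.gain,
        "offset": acq.offset,
        "read_noise": acq.read_noise,
        "background_photons": acq.background_photons,
        "n_frames": int(movie.n_frames),
    }
    with open(_sidecar_path(path), "w") as f:
        yaml.safe_dump(meta, f, sort_keys=False)


def read_movie(path) -> Movie:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as f:
            meta = yaml.safe_load(f)
    else:
        meta = {}
    acq = AcquisitionConfig(
        n_frames=frames.shape[0],
        integration_ms=float(meta.get("integration_ms", 30.0)),
        pixel_size_nm=float(meta.get("pixel_size_nm", 121.0)),
        psf_sigma_nm=float(meta.get("psf_sigma_nm", 121.0)),
        gain=float(meta.get("gain", 1.0)),
        offset=float(meta.get("offset", 0.0)),
        read_noise=float(meta.get("read_noise", 0.0)),
        background_photons=float(meta.get("background_photons", 0.0)),
    )
    return Movie(frames=np.asarray(frames), acquisition=acq)
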