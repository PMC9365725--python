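"""Density maps, cell outlines, per-region signal densities, distances.

After clustering, each signal is reduced to its center of mass (COM).
A density map places one count at each COM; the cell outline is
segmented from the reconstructed (2D histogram) image; the per-region
density is the number of COMs inside a mask divided by the mask area in
square micrometres.  Nearest-neighbor COM distances summarize signal
spacing, together with the lattice spacing 1/sqrt(rho) expected for the
measured density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .tables import LocalizationTable

__all__ = ["DensityMap", "CellOutline", "RegionDensity",
           "render_histogram_image", "com_density_map", "segment_cell",
           "region_density", "com_nn_distances"]


@dataclass
class DensityMap:
    """Raster of cluster-COM counts per bin; integral = number of clusters."""

    counts: np.ndarray
    bin_nm: float


@dataclass
class CellOutline:
    """Segmented cell mask with its area and the segmentation parameters."""

    mask: np.ndarray
    bin_nm: float
    area_um2: float
    params: dict = dc_field(default_factory=dict)


@dataclass(frozen=True)
class RegionDensity:
    region: str
    n_signals: int
    area_um2: float

    @property
    def density_per_um2(self) -> float:
        return self.n_signals / self.area_um2


def _extent_shape(extent_nm, bin_nm):
    return (int(np.ceil(extent_nm[1] / bin_nm)), int(np.ceil(extent_nm[0] / bin_nm)))


def render_histogram_image(table: LocalizationTable, bin_nm: float = 10.0,
                           extent_nm=None) -> np.ndarray:
    """Reconstructed super-resolution image: localization counts per bin."""
    xy = table.xy
    if extent_nm is None:
        extent_nm = (xy[:, 0].max() + bin_nm, xy[:, 1].max() + bin_nm) \
            if len(xy) else (bin_nm, bin_nm)
    shape = _extent_shape(extent_nm, bin_nm)
    if len(xy) == 0:
        return np.zeros(shape)
    h, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=shape,
                             range=[[0, shape[0] * bin_nm], [0, shape[1] * bin_nm]])
    return h


def com_density_map(com_xy: np.ndarray, bin_nm: float,
                    extent_nm=None) -> DensityMap:
    """+1 at the bin of each cluster COM (collisions sum)."""
    com_xy = np.asarray(com_xy, dtype=float).reshape(-1, 2)
    if extent_nm is None:
        extent_nm = (com_xy[:, 0].max() + bin_nm, com_xy[:, 1].max() + bin_nm) \
            if len(com_xy) else (bin_nm, bin_nm)
    shape = _extent_shape(extent_nm, bin_nm)
    counts = np.zeros(shape)
    if len(com_xy):
        c = np.floor(com_xy[:, 0] / bin_nm).astype(int)
        r = np.floor(com_xy[:, 1] / bin_nm).astype(int)
        ok = (r >= 0) & (r < shape[0]) & (c >= 0) & (c < shape[1])
        np.add.at(counts, (r[ok], c[ok]), 1.0)
    return DensityMap(counts, bin_nm)


def segment_cell(raster: np.ndarray, bin_nm: float,
                 blur_sigma_nm: float = 400.0,
                 threshold: str = "half_interior",
                 closing_radius_bins: int = 2,
                 min_object_um2: float = 1.0) -> CellOutline:
    """Cell outline from a reconstructed image.

    The raster is binarized (bin occupied or not) before blurring, which
    flattens the enormous dynamic range of rendered SMLM images (bright
    nanoclusters over sparse interstitial signal) so the threshold tracks
    the cell footprint rather than the cluster peaks.  The blurred
    occupancy is then thresholded, closed (disk), hole-filled, and
    reduced to its largest connected component.

    Threshold rules: ``"half_interior"`` (default) thresholds at half the
    typical interior occupancy level (75th percentile of nonzero blurred
    values) -- for a blurred step edge the half-level contour sits on the
    true boundary regardless of how densely the cell is sampled;
    ``"otsu"`` is the classic histogram split, adequate when the cell
    fills a minority of the frame.  This chain stands in for interactive
    outline drawing; every parameter is recorded on the returned
    outline.  The half-level rule recovers densely sampled rectangular
    test cells to within a few percent; sparse peripheries are eroded
    and an externally supplied outline should be preferred when accuracy
    matters (see docs).
    """
    from skimage.filters import gaussian, threshold_otsu
    from skimage.measure import label
    from skimage.morphology import closing, disk

    if raster.sum() == 0:
        raise ValueError("cannot segment an empty image")
    blurred = gaussian((raster > 0).astype(float), sigma=blur_sigma_nm / bin_nm)
    if threshold == "half_interior":
        thr = 0.5 * np.percentile(blurred[blurred > 0], 75)
    elif threshold == "otsu":
        thr = threshold_otsu(blurred)
    else:
        raise ValueError(f"unknown threshold rule {threshold!r}")
    mask = blurred > thr
    if not mask.any():
        raise ValueError("empty foreground after thresholding")
    mask = closing(mask, disk(closing_radius_bins))
    mask = ndimage.binary_fill_holes(mask)
    lab = label(mask)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    biggest = int(sizes.argmax())
    mask = lab == biggest
    area_um2 = float(mask.sum()) * (bin_nm / 1000.0) ** 2
    if area_um2 < min_object_um2:
        raise ValueError(f"largest object ({area_um2:.2f} um^2) below "
                         f"min_object_um2={min_object_um2}")
    return CellOutline(mask, bin_nm, area_um2,
                       params=dict(blur_sigma_nm=blur_sigma_nm,
                                   threshold=threshold,
                                   closing_radius_bins=closing_radius_bins,
                                   min_object_um2=min_object_um2))


def region_density(com_xy: np.ndarray, mask: np.ndarray, bin_nm: float,
                   region: str = "cell") -> RegionDensity:
    """Signals per um^2: COMs inside the mask / mask area.

    Membership follows the mask's bin raster, so a COM exactly on a
    boundary counts as inside when its bin is inside.
    """
    com_xy = np.asarray(com_xy, dtype=float).reshape(-1, 2)
    area_um2 = float(mask.sum()) * (bin_nm / 1000.0) ** 2
    if area_um2 <= 0:
        raise ValueError("mask has zero area")
    if len(com_xy) == 0:
        return RegionDensity(region, 0, area_um2)
    c = np.floor(com_xy[:, 0] / bin_nm).astype(int)
    r = np.floor(com_xy[:, 1] / bin_nm).astype(int)
    ok = (r >= 0) & (r < mask.shape[0]) & (c >= 0) & (c < mask.shape[1])
    inside = np.zeros(len(com_xy), dtype=bool)
    inside[ok] = mask[r[ok], c[ok]]
    return RegionDensity(region, int(inside.sum()), area_um2)


def com_nn_distances(com_xy: np.ndarray, mask: np.ndarray | None = None,
                     bin_nm: float | None = None) -> dict:
    """Nearest-neighbor distances between signal COMs.

    Returns the per-signal NN distance list plus summary statistics,
    including the lattice spacing 1/sqrt(rho) when a mask is given (the
    two spacing notions differ for random point fields: the mean NN
    distance of a Poisson field of density rho is 1/(2 sqrt(rho))).
    """
    com_xy = np.asarray(com_xy, dtype=float).reshape(-1, 2)
    if mask is not None:
        if bin_nm is None:
            raise ValueError("bin_nm required with a mask")
        c = np.floor(com_xy[:, 0] / bin_nm).astype(int)
        r = np.floor(com_xy[:, 1] / bin_nm).astype(int)
        ok = (r >= 0) & (r < mask.shape[0]) & (c >= 0) & (c < mask.shape[1])
        inside = np.zeros(len(com_xy), dtype=bool)
        inside[ok] = mask[r[ok], c[ok]]
        com_xy = com_xy[inside]
    if len(com_xy) < 2:
        warnings.warn("fewer than 2 COMs; no nearest-neighbor distances")
        return {"distances_nm": np.empty(0), "mean_nm": float("nan"),
                "median_nm": float("nan"), "lattice_spacing_nm": float("nan")}
    tree = cKDTree(com_xy)
    d, _ = tree.query(com_xy, k=2)
    nn = d[:, 1]
    out = {"distances_nm": nn, "mean_nm": float(nn.mean()),
           "median_nm": float(np.median(nn)),
           "lattice_spacing_nm": float("nan")}
    if mask is not None:
        area_um2 = float(mask.sum()) * (bin_nm / 1000.0) ** 2
        rho = len(com_xy) / area_um2
        out["lattice_spacing_nm"] = 1000.0 / np.sqrt(rho) if rho > 0 else float("nan")
    return out
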