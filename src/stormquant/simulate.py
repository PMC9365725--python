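"""Synthetic dSTORM acquisition with known ground truth.

This module emulates a single-color dSTORM experiment on labeled
membrane-protein nano-assemblies: clustered fluorophores inside a
cell-shaped mask, stochastic photoswitching over a long camera movie with
a stepwise 405 nm activation ramp, stage drift, and camera noise.  Every
generated object carries its ground truth (cluster centers and diameters,
fluorophore positions, blink schedules, drift trace) so each stage of the
analysis pipeline can be validated against a known answer.

Two output routes are provided:

* :func:`render_movie` produces a camera movie (16-bit counts) that feeds
  the spot-detection/fitting front end, and
* :func:`emit_localization_table` bypasses the camera and emits the
  localization table directly, with a configurable localization error.
  This is the fast path for testing drift correction, linking and
  clustering at realistic event numbers.

Coordinates are continuous, in nanometres, origin at the field's top-left
corner, x to the right (columns), y down (rows).  Pixel ``(r, c)`` covers
the half-open square ``[c*px, (c+1)*px) x [r*px, (r+1)*px)``.  Frames are
0-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.special import erf

from .tables import LocalizationTable

__all__ = [
    "FieldGeometry",
    "AcquisitionConfig",
    "BlinkKinetics",
    "GroundTruthField",
    "Movie",
    "rect_geometry",
    "default_cell_geometry",
    "make_linear_drift",
    "generate_field",
    "sample_blinks",
    "render_movie",
    "emit_localization_table",
]


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldGeometry:
    """Field extent plus binary rasters for the cell and named sub-regions.

    ``cell_mask`` and every entry of ``region_masks`` share one bin size
    (``bin_nm``); region masks must be subsets of the cell mask.
    """

    width_nm: float
    height_nm: float
    bin_nm: float
    cell_mask: np.ndarray                      # bool, shape (rows, cols)
    region_masks: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.width_nm <= 0 or self.height_nm <= 0 or self.bin_nm <= 0:
            raise ValueError("field extents and bin size must be positive")
        mask = np.asarray(self.cell_mask, dtype=bool)
        object.__setattr__(self, "cell_mask", mask)
        rows = int(np.ceil(self.height_nm / self.bin_nm))
        cols = int(np.ceil(self.width_nm / self.bin_nm))
        if mask.shape != (rows, cols):
            raise ValueError(
                f"cell_mask shape {mask.shape} does not match extent "
                f"({rows}, {cols}) at bin {self.bin_nm} nm"
            )
        fixed = {}
        for name, rmask in self.region_masks.items():
            rmask = np.asarray(rmask, dtype=bool)
            if rmask.shape != mask.shape:
                raise ValueError(f"region {name!r} shape mismatch")
            if np.any(rmask & ~mask):
                raise ValueError(f"region {name!r} is not a subset of the cell mask")
            fixed[name] = rmask
        object.__setattr__(self, "region_masks", fixed)

    # -- helpers -----------------------------------------------------------

    def mask(self, region=None) -> np.ndarray:
        if region is None or region == "cell":
            return self.cell_mask
        return self.region_masks[region]

    def mask_area_um2(self, region=None) -> float:
        return float(self.mask(region).sum()) * (self.bin_nm / 1000.0) ** 2

    def contains(self, xy: np.ndarray, region=None) -> np.ndarray:
        """Boolean membership of nm coordinates in a mask (bin rule)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        mask = self.mask(region)
        c = np.floor(xy[:, 0] / self.bin_nm).astype(int)
        r = np.floor(xy[:, 1] / self.bin_nm).astype(int)
        ok = (r >= 0) & (r < mask.shape[0]) & (c >= 0) & (c < mask.shape[1])
        out = np.zeros(len(xy), dtype=bool)
        out[ok] = mask[r[ok], c[ok]]
        return out

    def sample_in_mask(self, n: int, rng: np.random.Generator, region=None) -> np.ndarray:
        """Uniform points (nm) inside a mask: uniform bin, uniform within bin."""
        mask = self.mask(region)
        rr, cc = np.nonzero(mask)
        if len(rr) == 0:
            raise ValueError("cannot sample from an empty mask")
        idx = rng.integers(0, len(rr), size=n)
        x = (cc[idx] + rng.random(n)) * self.bin_nm
        y = (rr[idx] + rng.random(n)) * self.bin_nm
        return np.column_stack([x, y])


def rect_geometry(width_um: float, height_um: float, bin_nm: float = 100.0,
                  margin_um: float = 0.25) -> FieldGeometry:
    """Rectangular cell mask with a small empty margin around it."""
    w_nm = (width_um + 2 * margin_um) * 1000.0
    h_nm = (height_um + 2 * margin_um) * 1000.0
    rows = int(np.ceil(h_nm / bin_nm))
    cols = int(np.ceil(w_nm / bin_nm))
    mask = np.zeros((rows, cols), dtype=bool)
    r0 = int(round(margin_um * 1000.0 / bin_nm))
    c0 = int(round(margin_um * 1000.0 / bin_nm))
    r1 = int(round((margin_um + height_um) * 1000.0 / bin_nm))
    c1 = int(round((margin_um + width_um) * 1000.0 / bin_nm))
    mask[r0:r1, c0:c1] = True
    return FieldGeometry(w_nm, h_nm, bin_nm, mask)


def default_cell_geometry(bin_nm: float = 100.0) -> FieldGeometry:
    """Dendritic-cell-like geometry: elliptical soma plus a tapering
    protrusion ending in a "tip" region.

    The soma and tip are exposed as named region masks so that
    region-specific cluster densities can be planted and recovered.
    """
    width_nm, height_nm = 22000.0, 10000.0
    rows = int(np.ceil(height_nm / bin_nm))
    cols = int(np.ceil(width_nm / bin_nm))
    yy, xx = np.mgrid[0:rows, 0:cols]
    x_nm = (xx + 0.5) * bin_nm
    y_nm = (yy + 0.5) * bin_nm

    # soma: ellipse centered left of field
    cx, cy, ax, ay = 5000.0, 5000.0, 4200.0, 3600.0
    soma = ((x_nm - cx) / ax) ** 2 + ((y_nm - cy) / ay) ** 2 <= 1.0

    # protrusion: tapering band from soma edge to the right
    x0, x1 = 7500.0, 21000.0
    half0, half1 = 1500.0, 600.0
    t = np.clip((x_nm - x0) / (x1 - x0), 0.0, 1.0)
    half = half0 + (half1 - half0) * t
    protrusion = (x_nm >= x0) & (x_nm <= x1) & (np.abs(y_nm - cy) <= half)

    cell = soma | protrusion
    tip = protrusion & (x_nm >= x1 - 3000.0)
    return FieldGeometry(width_nm, height_nm, bin_nm, cell,
                         region_masks={"soma": soma & ~protrusion, "tip": tip})


# --------------------------------------------------------------------------
# acquisition / kinetics configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera and illumination settings of the emulated acquisition.

    Defaults follow a typical sCMOS dSTORM recording: 30,000 frames at
    30 ms integration, 121 nm pixels, and a stepwise 405 nm activation
    increase every 10,000 frames (``activation_levels`` multiply the base
    activation rate per block).
    """

    n_frames: int = 30000
    integration_ms: float = 30.0
    pixel_size_nm: float = 121.0
    psf_sigma_nm: float = 121.0
    gain: float = 2.0                      # counts per photon
    offset: float = 100.0                  # counts
    read_noise: float = 1.5                # counts RMS
    background_photons: float = 10.0       # photons / pixel / frame
    activation_levels: tuple = (1.0, 2.0, 4.0)
    block_frames: int = 10000
    drift_nm: np.ndarray | None = None     # (n_frames, 2) per-frame (dx, dy)
    fiducials: tuple = ()                  # ((x_nm, y_nm, photons_per_frame), ...)

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.drift_nm is not None:
            d = np.asarray(self.drift_nm, dtype=float)
            if d.shape != (self.n_frames, 2):
                raise ValueError("drift trace length must equal n_frames")
            object.__setattr__(self, "drift_nm", d)

    def drift(self) -> np.ndarray:
        if self.drift_nm is None:
            return np.zeros((self.n_frames, 2))
        return self.drift_nm


def make_linear_drift(n_frames: int, rate_nm_per_frame, angle_deg: float = 30.0) -> np.ndarray:
    """Linear stage drift at ``rate_nm_per_frame`` along a fixed direction."""
    t = np.arange(n_frames, dtype=float)
    th = np.deg2rad(angle_deg)
    return np.column_stack([t * rate_nm_per_frame * np.cos(th),
                            t * rate_nm_per_frame * np.sin(th)])


@dataclass(frozen=True)
class BlinkKinetics:
    """Photoswitching fixture parameters.

    Emission is modeled at two time scales, as observed for cyanine dyes
    under thiol photoswitching: a fluorophore survives a geometric number
    of *bursts* (``p_bleach``; mean ``1/p_bleach`` bursts), separated by
    long geometric dark times (``mean_dark_frames``); within a burst it
    flickers, emitting a geometric number of short on-events
    (``flickers_per_burst_mean``) whose on-times are geometric
    (``mean_on_frames``) and whose intra-burst dark gaps are short
    (``1 + Geometric(intra_dark_frames_mean)`` frames), so that
    spatiotemporal linking with a small dark-frame allowance collapses a
    burst into approximately one signal while the raw table holds several
    localizations per burst.  The first burst starts at an activation
    time drawn from a piecewise-constant-rate exponential following the
    stepwise 405 nm ramp (base ``activation_rate`` per frame, multiplied
    by the acquisition's per-block levels).  Photons per frame are
    log-normal.  None of these values is a claim about a specific dye;
    they are fixtures calibrated so the derived analysis parameters land
    in their typical published operating ranges (see docs/methods.md).
    """

    p_bleach: float = 1.0 / 9.0
    flickers_per_burst_mean: float = 4.0
    mean_on_frames: float = 1.5
    intra_dark_frames_mean: float = 0.4
    mean_dark_frames: float = 600.0
    activation_rate: float = 6.6e-5
    photons_median: float = 800.0
    photons_sigma_ln: float = 0.5

    def __post_init__(self):
        for name in ("p_bleach", "flickers_per_burst_mean", "mean_on_frames",
                     "mean_dark_frames", "activation_rate", "photons_median",
                     "photons_sigma_ln"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.intra_dark_frames_mean < 0:
            raise ValueError("intra_dark_frames_mean must be >= 0")
        if self.p_bleach > 1:
            raise ValueError("p_bleach is a probability")


# --------------------------------------------------------------------------
# ground truth container
# --------------------------------------------------------------------------

@dataclass
class GroundTruthField:
    """Planted clusters, fluorophores, blink schedules and acquisition.

    Cluster truth (one entry per planted assembly):
      ``cluster_xy`` (K, 2) nm, ``cluster_diameter_nm`` (K,),
      ``cluster_n_fluor`` (K,), ``cluster_region`` (K,) str labels.

    Emitter truth (one entry per fluorophore; background fluorophores have
    ``emitter_cluster == -1``):
      ``emitter_xy`` (M, 2) nm = assembly position + antibody-linker
      displacement, ``emitter_cluster`` (M,).

    Blink schedules (populated by :func:`sample_blinks`; one entry per
    blink event): ``blink_emitter``, ``blink_start``, ``blink_duration``
    (frames), ``blink_photons`` (photons per frame while on).
    """

    geometry: FieldGeometry
    acquisition: AcquisitionConfig
    kinetics: BlinkKinetics | None
    seed: int
    params: dict

    cluster_xy: np.ndarray
    cluster_diameter_nm: np.ndarray
    cluster_n_fluor: np.ndarray
    cluster_region: np.ndarray

    emitter_xy: np.ndarray
    emitter_cluster: np.ndarray

    blink_emitter: np.ndarray | None = None
    blink_start: np.ndarray | None = None
    blink_duration: np.ndarray | None = None
    blink_photons: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_xy)

    @property
    def n_emitters(self) -> int:
        return len(self.emitter_xy)

    @property
    def n_blinks(self) -> int:
        return 0 if self.blink_start is None else len(self.blink_start)

    def cluster_density_per_um2(self, region=None) -> float:
        if region is None:
            n = self.n_clusters
        else:
            n = int(np.sum(self.cluster_region == region))
        return n / self.geometry.mask_area_um2(region)


# --------------------------------------------------------------------------
# field generation
# --------------------------------------------------------------------------

def _as_region_dict(value, regions):
    if isinstance(value, dict):
        unknown = set(value) - set(regions)
        if unknown:
            raise ValueError(f"unknown region(s) {sorted(unknown)}")
        return dict(value)
    return {r: value for r in regions}


def generate_field(
    geometry: FieldGeometry,
    density_per_um2,
    diameter_nm,
    mean_fluor_per_cluster: float = 5.0,
    background_per_um2: float = 0.1,
    sigma_link_nm: float = 10.0,
    min_separation_nm: float = 150.0,
    acquisition: AcquisitionConfig | None = None,
    kinetics: BlinkKinetics | None = None,
    seed: int = 0,
) -> GroundTruthField:
    """Plant clustered fluorophores in the cell mask.

    Cluster *counts* per region follow the homogeneous Poisson law at
    the stated density (clusters/um^2); centers are placed by sequential
    inhibition with a hard minimum separation (``min_separation_nm``,
    default 150 nm), because the imaged assemblies are solid bodies of
    several tens of nanometres carrying an antibody shell and cannot
    interpenetrate -- fully independent placement would superimpose a
    noticeable fraction of clusters at the higher densities, which no
    analysis could ever separate again.  ``density_per_um2`` and
    ``diameter_nm`` may be scalars (applied to the whole cell) or dicts
    keyed by region name.  Fluorophore positions are the cluster center
    plus a uniform-in-disk offset of radius ``diameter_nm/2`` plus two
    independent isotropic Gaussian antibody-linker offsets of
    ``sigma_link_nm`` each (primary + secondary antibody).  Background
    fluorophores (single nonspecifically bound antibodies) are scattered
    uniformly over the cell at ``background_per_um2``; the default is
    small because isotype-control measurements of the emulated
    experiment found negligible nonspecific signal.  Fluorophores per
    cluster are ``1 + Poisson(mean - 1)`` (at least one dye per labeled
    assembly).
    """
    rng = np.random.default_rng(seed)
    if acquisition is None:
        acquisition = AcquisitionConfig()

    if isinstance(density_per_um2, dict):
        regions = list(density_per_um2)
    elif geometry.region_masks:
        regions = list(geometry.region_masks)
    else:
        regions = ["cell"]
    dens = _as_region_dict(density_per_um2, regions)
    diam = _as_region_dict(diameter_nm, regions)
    for r, d in dens.items():
        if d < 0:
            raise ValueError(f"negative density for region {r!r}")
        if diam[r] <= 0:
            raise ValueError(f"diameter must be positive (region {r!r})")
    if background_per_um2 < 0:
        raise ValueError("background_per_um2 must be >= 0")
    if mean_fluor_per_cluster < 1:
        raise ValueError("mean_fluor_per_cluster must be >= 1")

    centers, diams, nfls, labels = [], [], [], []
    placed: list[np.ndarray] = []
    for r in regions:
        area = geometry.mask_area_um2(None if r == "cell" else r)
        k = rng.poisson(dens[r] * area)
        if k == 0:
            continue
        pts = _place_inhibited(geometry, None if r == "cell" else r, k,
                               min_separation_nm, placed, rng)
        placed.append(pts)
        centers.append(pts)
        diams.append(np.full(k, float(diam[r])))
        nfls.append(1 + rng.poisson(mean_fluor_per_cluster - 1.0, size=k))
        labels.extend([r] * k)

    if centers:
        cluster_xy = np.concatenate(centers)
        cluster_diameter = np.concatenate(diams)
        cluster_n_fluor = np.concatenate(nfls).astype(int)
        cluster_region = np.asarray(labels, dtype=object)
    else:
        cluster_xy = np.empty((0, 2))
        cluster_diameter = np.empty(0)
        cluster_n_fluor = np.empty(0, dtype=int)
        cluster_region = np.empty(0, dtype=object)

    # fluorophores: disk offset + two linker displacements
    M = int(cluster_n_fluor.sum())
    parent = np.repeat(np.arange(len(cluster_xy)), cluster_n_fluor)
    if M:
        radius = np.repeat(cluster_diameter / 2.0, cluster_n_fluor)
        u = rng.random(M)
        th = rng.random(M) * 2 * np.pi
        rr = radius * np.sqrt(u)
        disk = np.column_stack([rr * np.cos(th), rr * np.sin(th)])
        link = rng.normal(0.0, sigma_link_nm, size=(M, 2)) \
            + rng.normal(0.0, sigma_link_nm, size=(M, 2))
        emitter_xy = cluster_xy[parent] + disk + link
    else:
        emitter_xy = np.empty((0, 2))

    n_bg = rng.poisson(background_per_um2 * geometry.mask_area_um2())
    if n_bg:
        bg_xy = geometry.sample_in_mask(n_bg, rng)
        emitter_xy = np.concatenate([emitter_xy, bg_xy]) if M else bg_xy
        parent = np.concatenate([parent, np.full(n_bg, -1)])

    return GroundTruthField(
        geometry=geometry,
        acquisition=acquisition,
        kinetics=kinetics,
        seed=seed,
        params=dict(density_per_um2=dens, diameter_nm=diam,
                    mean_fluor_per_cluster=mean_fluor_per_cluster,
                    background_per_um2=background_per_um2,
                    sigma_link_nm=sigma_link_nm),
        cluster_xy=cluster_xy,
        cluster_diameter_nm=cluster_diameter,
        cluster_n_fluor=cluster_n_fluor,
        cluster_region=cluster_region,
        emitter_xy=emitter_xy,
        emitter_cluster=parent.astype(int),
    )


def _place_inhibited(geometry, region, k, min_sep_nm, placed, rng,
                     max_rounds: int = 400) -> np.ndarray:
    """Sequential-inhibition placement of k points in a mask.

    Keeps the Poisson count (k is drawn upstream) but rejects candidate
    centers closer than ``min_sep_nm`` to any already placed center
    (including those of previously filled regions).
    """
    if min_sep_nm <= 0:
        return geometry.sample_in_mask(k, rng, region)
    from scipy.spatial import cKDTree
    accepted = np.empty((0, 2))
    prior = np.concatenate(placed) if placed else np.empty((0, 2))
    for _ in range(max_rounds):
        need = k - len(accepted)
        if need == 0:
            break
        cand = geometry.sample_in_mask(max(2 * need, 16), rng, region)
        anchors = np.concatenate([prior, accepted])
        if len(anchors):
            d, _ = cKDTree(anchors).query(cand, k=1)
            cand = cand[d >= min_sep_nm]
        # enforce separation inside the candidate batch sequentially
        for c in cand:
            if len(accepted) == k:
                break
            if len(accepted) and np.min(np.linalg.norm(accepted - c, axis=1)) < min_sep_nm:
                continue
            accepted = np.vstack([accepted, c])
    if len(accepted) < k:
        raise ValueError(
            f"could not place {k} clusters at min separation {min_sep_nm} nm "
            f"in region {region or 'cell'}; lower the density or separation")
    return accepted


# --------------------------------------------------------------------------
# blinking
# --------------------------------------------------------------------------

def _sample_activation_frames(n, acq: AcquisitionConfig, rate: float,
                              rng: np.random.Generator) -> np.ndarray:
    """First-activation frame per fluorophore from a piecewise-constant-rate
    exponential over the acquisition's activation blocks.  Fluorophores whose
    activation falls beyond the movie never turn on (frame = n_frames)."""
    levels = np.asarray(acq.activation_levels, dtype=float)
    n_blocks = int(np.ceil(acq.n_frames / acq.block_frames))
    if len(levels) < n_blocks:                       # repeat last level
        levels = np.concatenate([levels, np.full(n_blocks - len(levels), levels[-1])])
    levels = levels[:n_blocks]
    block_len = np.full(n_blocks, acq.block_frames, dtype=float)
    block_len[-1] = acq.n_frames - acq.block_frames * (n_blocks - 1)
    hazard = rate * levels * block_len
    cum = np.concatenate([[0.0], np.cumsum(hazard)])
    e = rng.exponential(1.0, size=n)
    blk = np.searchsorted(cum, e, side="right") - 1
    frames = np.full(n, acq.n_frames, dtype=float)
    inside = blk < n_blocks
    b = blk[inside]
    frames[inside] = b * acq.block_frames + (e[inside] - cum[b]) / (rate * levels[b])
    return np.floor(frames).astype(int)


def sample_blinks(field: GroundTruthField, kinetics: BlinkKinetics | None = None,
                  seed: int = 1) -> GroundTruthField:
    """Populate per-fluorophore blink schedules.

    Per fluorophore: number of blinks ~ Geometric(p_bleach); first blink at
    a piecewise-exponential activation time following the 405 nm ramp;
    on-durations and inter-blink dark times geometric; photons/frame
    log-normal (one draw per blink).  Blinks starting after the last frame
    are discarded; durations are clipped to the movie end.
    """
    kin = kinetics or field.kinetics or BlinkKinetics()
    acq = field.acquisition
    rng = np.random.default_rng(seed)
    M = field.n_emitters
    if M == 0:
        return dataclasses.replace(
            field, kinetics=kin,
            blink_emitter=np.empty(0, dtype=int), blink_start=np.empty(0, dtype=int),
            blink_duration=np.empty(0, dtype=int), blink_photons=np.empty(0))

    n_bursts = rng.geometric(kin.p_bleach, size=M)
    act = _sample_activation_frames(M, acq, kin.activation_rate, rng)

    BT = int(n_bursts.sum())
    burst_fluor = np.repeat(np.arange(M), n_bursts)
    n_flick = rng.geometric(1.0 / kin.flickers_per_burst_mean, size=BT)
    B = int(n_flick.sum())
    blink_burst = np.repeat(np.arange(BT), n_flick)
    fl = burst_fluor[blink_burst]
    pos_in_burst = _ragged_arange(n_flick)
    last_in_burst = pos_in_burst == n_flick[blink_burst] - 1

    on = rng.geometric(1.0 / kin.mean_on_frames, size=B)
    dark = np.where(last_in_burst,
                    rng.geometric(1.0 / kin.mean_dark_frames, size=B),
                    1 + rng.poisson(kin.intra_dark_frames_mean, size=B))
    step = on + dark
    cum = np.cumsum(step)
    prev = cum - step                                 # exclusive cumsum
    blinks_per_fluor = np.bincount(fl, minlength=M)
    first = np.cumsum(blinks_per_fluor) - blinks_per_fluor
    start = act[fl] + prev - prev[first][fl]

    photons = np.exp(rng.normal(np.log(kin.photons_median), kin.photons_sigma_ln, size=B))

    keep = start < acq.n_frames
    start, on, fl, photons = start[keep], on[keep], fl[keep], photons[keep]
    on = np.minimum(on, acq.n_frames - start)

    order = np.argsort(start, kind="stable")
    return dataclasses.replace(
        field, kinetics=kin,
        blink_emitter=fl[order].astype(int),
        blink_start=start[order].astype(int),
        blink_duration=on[order].astype(int),
        blink_photons=photons[order],
    )


# --------------------------------------------------------------------------
# camera movie rendering
# --------------------------------------------------------------------------

@dataclass
class Movie:
    """Frame stack of camera counts plus acquisition metadata."""

    frames: np.ndarray                     # (n_frames, rows, cols) uint16
    acquisition: AcquisitionConfig

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape

    def photons(self, frame: int) -> np.ndarray:
        """Counts converted to photons (offset subtracted, clipped at 0)."""
        acq = self.acquisition
        return np.clip(self.frames[frame].astype(float) - acq.offset, 0, None) / acq.gain


def _pixel_gaussian(x_px, y_px, sigma_px, shape, photons):
    """Gaussian PSF integrated over pixel areas, on a local window."""
    rows, cols = shape
    w = max(3, int(np.ceil(4 * sigma_px)))
    c0 = max(0, int(np.floor(x_px)) - w)
    c1 = min(cols, int(np.floor(x_px)) + w + 1)
    r0 = max(0, int(np.floor(y_px)) - w)
    r1 = min(rows, int(np.floor(y_px)) + w + 1)
    if c0 >= c1 or r0 >= r1:
        return None
    s2 = sigma_px * np.sqrt(2.0)
    cx = np.arange(c0, c1 + 1) - x_px
    ry = np.arange(r0, r1 + 1) - y_px
    ex = 0.5 * (erf(cx[1:] / s2) - erf(cx[:-1] / s2))
    ey = 0.5 * (erf(ry[1:] / s2) - erf(ry[:-1] / s2))
    return (r0, r1, c0, c1), photons * np.outer(ey, ex)


def render_movie(field: GroundTruthField, shot_noise: bool = True,
                 read_noise: bool = True, background: bool = True,
                 seed: int = 2) -> Movie:
    """Render the blink schedules into a 16-bit camera movie.

    Each frame is the sum of integrated Gaussian PSFs of the emitters that
    are on (plus fiducials), over a uniform photon background, Poisson
    sampled, scaled by the camera gain, offset added, and Gaussian read
    noise applied.  Stage drift displaces emitter positions before
    rendering.
    """
    if field.blink_start is None:
        raise ValueError("blink schedules are not populated; run sample_blinks first")
    acq = field.acquisition
    px = acq.pixel_size_nm
    rows = int(np.ceil(field.geometry.height_nm / px))
    cols = int(np.ceil(field.geometry.width_nm / px))
    if rows * cols > 4096 * 4096:
        raise ValueError("field too large to render as a camera image")
    rng = np.random.default_rng(seed)
    drift = acq.drift()
    sigma_px = acq.psf_sigma_nm / px

    # expand blinks to per-frame emission events, grouped by frame
    n_on = field.blink_duration
    ev_frame = np.repeat(field.blink_start, n_on) + _ragged_arange(n_on)
    ev_emitter = np.repeat(field.blink_emitter, n_on)
    ev_photons = np.repeat(field.blink_photons, n_on)
    order = np.argsort(ev_frame, kind="stable")
    ev_frame, ev_emitter, ev_photons = ev_frame[order], ev_emitter[order], ev_photons[order]
    bounds = np.searchsorted(ev_frame, np.arange(acq.n_frames + 1))

    stack = np.zeros((acq.n_frames, rows, cols), dtype=np.uint16)
    for f in range(acq.n_frames):
        img = np.zeros((rows, cols))
        if background:
            img += acq.background_photons
        for i in range(bounds[f], bounds[f + 1]):
            e = ev_emitter[i]
            x = (field.emitter_xy[e, 0] + drift[f, 0]) / px
            y = (field.emitter_xy[e, 1] + drift[f, 1]) / px
            res = _pixel_gaussian(x, y, sigma_px, (rows, cols), ev_photons[i])
            if res is not None:
                (r0, r1, c0, c1), patch = res
                img[r0:r1, c0:c1] += patch
        for (fx, fy, fph) in acq.fiducials:
            res = _pixel_gaussian((fx + drift[f, 0]) / px, (fy + drift[f, 1]) / px,
                                  sigma_px, (rows, cols), fph)
            if res is not None:
                (r0, r1, c0, c1), patch = res
                img[r0:r1, c0:c1] += patch
        if shot_noise:
            img = rng.poisson(img).astype(float)
        counts = acq.offset + acq.gain * img
        if read_noise and acq.read_noise > 0:
            counts = counts + rng.normal(0.0, acq.read_noise, size=counts.shape)
        stack[f] = np.clip(np.round(counts), 0, 65535).astype(np.uint16)
    return Movie(frames=stack, acquisition=acq)


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    """[0..c0), [0..c1), ... concatenated."""
    if len(counts) == 0:
        return np.empty(0, dtype=int)
    total = int(counts.sum())
    out = np.arange(total)
    starts = np.cumsum(counts) - counts
    return out - np.repeat(starts, counts)


# --------------------------------------------------------------------------
# localization-table bypass
# --------------------------------------------------------------------------

def emit_localization_table(field: GroundTruthField, sigma_loc_nm: float = 12.1,
                            detection_efficiency: float = 1.0,
                            sigma_psf_jitter_nm: float = 8.0,
                            seed: int = 3) -> LocalizationTable:
    """Emit the localization table directly, bypassing camera rendering.

    One localization per ON-frame of each surviving blink event, at the
    emitter's position plus stage drift plus independent N(0, sigma_loc^2)
    error per axis; a blink spanning k frames therefore yields k repeated
    localizations in consecutive frames, exactly the signature exploited
    by nearest-neighbor precision estimation and by spatiotemporal
    linking.  ``detection_efficiency`` thins whole blink events
    binomially.  Truth cross-references (emitter id, cluster id) ride
    along as extra columns.
    """
    if sigma_loc_nm < 0:
        raise ValueError("sigma_loc_nm must be >= 0")
    if not 0 <= detection_efficiency <= 1:
        raise ValueError("detection_efficiency must be in [0, 1]")
    if field.blink_start is None:
        raise ValueError("blink schedules are not populated; run sample_blinks first")
    acq = field.acquisition
    rng = np.random.default_rng(seed)

    keep = rng.random(field.n_blinks) <= detection_efficiency \
        if detection_efficiency < 1 else np.ones(field.n_blinks, dtype=bool)
    start = field.blink_start[keep]
    dur = field.blink_duration[keep]
    emitter = field.blink_emitter[keep]
    photons = field.blink_photons[keep]
    blink_id = np.nonzero(keep)[0]

    n_rows = int(dur.sum())
    frame = np.repeat(start, dur) + _ragged_arange(dur)
    row_emitter = np.repeat(emitter, dur)
    row_blink = np.repeat(blink_id, dur)
    row_photons = np.repeat(photons, dur)

    drift = acq.drift()
    xy = field.emitter_xy[row_emitter] + drift[frame]
    if sigma_loc_nm > 0:
        xy = xy + rng.normal(0.0, sigma_loc_nm, size=(n_rows, 2))

    # fiducial localizations: one per frame per fiducial, tight jitter
    fid_frames, fid_xy, fid_ph, fid_ids = [], [], [], []
    for k, (fx, fy, fph) in enumerate(acq.fiducials):
        f = np.arange(acq.n_frames)
        pos = np.column_stack([np.full(acq.n_frames, fx), np.full(acq.n_frames, fy)])
        pos = pos + drift + rng.normal(0.0, 2.0, size=(acq.n_frames, 2))
        fid_frames.append(f)
        fid_xy.append(pos)
        fid_ph.append(np.full(acq.n_frames, fph))
        fid_ids.append(np.full(acq.n_frames, -100 - k))

    if fid_frames:
        frame = np.concatenate([frame] + fid_frames)
        xy = np.concatenate([xy] + fid_xy)
        row_photons = np.concatenate([row_photons] + fid_ph)
        row_emitter = np.concatenate([row_emitter] + fid_ids)
        row_blink = np.concatenate([row_blink] + [np.full(acq.n_frames, -1)] * len(fid_ids))
        n_rows = len(frame)

    sx = np.clip(acq.psf_sigma_nm + rng.normal(0.0, sigma_psf_jitter_nm, n_rows), 1.0, None)
    sy = np.clip(acq.psf_sigma_nm + rng.normal(0.0, sigma_psf_jitter_nm, n_rows), 1.0, None)

    cluster_id = np.full(n_rows, -1, dtype=int)
    real = row_emitter >= 0
    cluster_id[real] = field.emitter_cluster[row_emitter[real]]

    import pandas as pd
    df = pd.DataFrame({
        "frame": frame.astype(int),
        "x_nm": xy[:, 0],
        "y_nm": xy[:, 1],
        "sx_nm": sx,
        "sy_nm": sy,
        "photons": row_photons,
        "bg": np.full(n_rows, acq.background_photons),
        "lpx_nm": np.full(n_rows, max(sigma_loc_nm, 1e-3)),
        "lpy_nm": np.full(n_rows, max(sigma_loc_nm, 1e-3)),
        "net_gradient": row_photons,
        "emitter_id": row_emitter.astype(int),
        "cluster_id": cluster_id,
        "blink_id": row_blink.astype(int),
    })
    table = LocalizationTable(df, pixel_size_nm=acq.pixel_size_nm,
                              n_frames=acq.n_frames)
    return table.with_provenance("emit_localization_table",
                                 dict(sigma_loc_nm=sigma_loc_nm,
                                      detection_efficiency=detection_efficiency,
                                      seed=seed),
                                 n_in=field.n_blinks, n_out=len(df))
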