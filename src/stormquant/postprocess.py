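"""Drift correction, quality filtering, precision estimation, linking.

The post-processing chain mirrors the standard single-color dSTORM
workflow: estimate and subtract stage drift (redundant cross-correlation
over temporal blocks, or fiducial beads), reject mis-shapen PSF fits by
their fitted sigma, estimate the experimental localization precision from
nearest-neighbor distances across consecutive frames (NeNA-style), and
merge repeated emissions of one molecule into single signals by
spatiotemporal linking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .tables import LocalizationTable

__all__ = ["DriftTrace", "FilterConfig", "LinkConfig", "PrecisionEstimate",
           "estimate_drift_rcc", "estimate_drift_fiducial", "apply_drift",
           "filter_sigma", "nearest_neighbor_precision", "derive_link_radius",
           "link_localizations"]

log = logging.getLogger(__name__)


@dataclass
class DriftTrace:
    """Per-frame stage displacement (nm), gauge-fixed to zero mean."""

    dx_nm: np.ndarray
    dy_nm: np.ndarray
    method: str
    window: int | None = None

    def __post_init__(self):
        self.dx_nm = np.asarray(self.dx_nm, dtype=float)
        self.dy_nm = np.asarray(self.dy_nm, dtype=float)
        if self.dx_nm.shape != self.dy_nm.shape:
            raise ValueError("dx/dy length mismatch")

    def __len__(self):
        return len(self.dx_nm)

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.dx_nm, self.dy_nm])

    def __neg__(self) -> "DriftTrace":
        return DriftTrace(-self.dx_nm, -self.dy_nm, self.method, self.window)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"frame": np.arange(len(self)),
                      "dx_nm": self.dx_nm, "dy_nm": self.dy_nm}).to_csv(path, index=False)


@dataclass(frozen=True)
class FilterConfig:
    """Inclusive fitted-PSF-sigma acceptance band (nm), both axes."""

    sigma_min_nm: float = 48.4
    sigma_max_nm: float = 193.6

    def __post_init__(self):
        if not 0 < self.sigma_min_nm < self.sigma_max_nm:
            raise ValueError("need 0 < sigma_min < sigma_max")


@dataclass(frozen=True)
class LinkConfig:
    """Spatiotemporal linking settings.

    ``radius_nm`` defaults to 72.6 nm = 6 x 12.1 nm experimental
    precision; derive it for a given measurement with
    :func:`derive_link_radius`.
    """

    radius_nm: float = 72.6
    max_dark_frames: int = 2

    def __post_init__(self):
        if self.radius_nm <= 0:
            raise ValueError("radius_nm must be positive")
        if self.max_dark_frames < 0:
            raise ValueError("max_dark_frames must be >= 0")


@dataclass
class PrecisionEstimate:
    """Global experimental localization precision (per-axis SD, nm)."""

    sigma_loc_nm: float
    n_pairs: int
    bin_centers_nm: np.ndarray = dc_field(repr=False, default=None)
    counts: np.ndarray = dc_field(repr=False, default=None)
    model_counts: np.ndarray = dc_field(repr=False, default=None)
    residual_norm: float = float("nan")


# --------------------------------------------------------------------------
# drift
# --------------------------------------------------------------------------

def _render_hist(xy, bin_nm, shape):
    h, _, _ = np.histogram2d(xy[:, 1], xy[:, 0],
                             bins=shape,
                             range=[[0, shape[0] * bin_nm], [0, shape[1] * bin_nm]])
    return h


def _xcorr_shift(a, b, max_shift_bins=None):
    """Shift of b relative to a by FFT cross-correlation, 3x3 centroid subpixel."""
    fa = np.fft.rfft2(a - a.mean())
    fb = np.fft.rfft2(b - b.mean())
    corr = np.fft.irfft2(fa * np.conj(fb), s=a.shape)
    corr = np.fft.fftshift(corr)
    if max_shift_bins is not None:
        cy, cx = corr.shape[0] // 2, corr.shape[1] // 2
        mask = np.zeros_like(corr, dtype=bool)
        mask[cy - max_shift_bins:cy + max_shift_bins + 1,
             cx - max_shift_bins:cx + max_shift_bins + 1] = True
        corr = np.where(mask, corr, corr[mask].min())
    r, c = np.unravel_index(np.argmax(corr), corr.shape)

    def parabolic(vm, v0, vp):
        den = vm - 2 * v0 + vp
        return 0.5 * (vm - vp) / den if den < 0 else 0.0

    r_sub, c_sub = float(r), float(c)
    if 0 < r < corr.shape[0] - 1:
        r_sub += parabolic(corr[r - 1, c], corr[r, c], corr[r + 1, c])
    if 0 < c < corr.shape[1] - 1:
        c_sub += parabolic(corr[r, c - 1], corr[r, c], corr[r, c + 1])
    dy = r_sub - corr.shape[0] // 2
    dx = c_sub - corr.shape[1] // 2
    # correlation peak at +d means b lies at -d relative to a in this
    # conjugation order; flip so the return is "shift of b w.r.t. a"
    return -dx, -dy


def estimate_drift_rcc(table: LocalizationTable, window_frames: int = 1000,
                       render_bin_nm: float = 10.0,
                       max_shift_nm: float = 2000.0,
                       max_pair_gap: int = 10) -> DriftTrace:
    """Redundant cross-correlation drift estimation.

    The table is split into temporal blocks of ``window_frames``; each
    block is rendered as a 2D histogram at ``render_bin_nm``; shifts are
    measured between *all* block pairs and the per-block drift solved by
    least squares over the redundant pair set (gauge: mean drift zero).
    The per-frame trace interpolates linearly between block centers and
    extrapolates linearly beyond the first/last center.
    """
    n_frames = table.n_frames
    n_blocks = int(np.ceil(n_frames / window_frames))
    if n_blocks < 2:
        raise ValueError("need at least 2 drift windows")
    frames = table.df["frame"].to_numpy()
    xy = table.xy
    extent = xy.max(axis=0) + render_bin_nm
    shape = (int(np.ceil(extent[1] / render_bin_nm)),
             int(np.ceil(extent[0] / render_bin_nm)))

    blocks = []
    for b in range(n_blocks):
        sel = (frames >= b * window_frames) & (frames < (b + 1) * window_frames)
        if not np.any(sel):
            raise ValueError(f"drift block {b} contains no localizations")
        blocks.append(_render_hist(xy[sel], render_bin_nm, shape))

    # pairs farther apart than max_pair_gap blocks share too few active
    # emitters (photoswitching turnover) to correlate reliably; the pair
    # set stays redundant without them
    max_bins = int(np.ceil(max_shift_nm / render_bin_nm))
    pairs, shifts = [], []
    for i in range(n_blocks):
        for j in range(i + 1, min(i + 1 + max_pair_gap, n_blocks)):
            dx, dy = _xcorr_shift(blocks[i], blocks[j], max_shift_bins=max_bins)
            pairs.append((i, j))
            shifts.append((dx * render_bin_nm, dy * render_bin_nm))
    shifts = np.asarray(shifts)

    # least squares: shift_ij ~= d_j - d_i, with sum(d) = 0.  The pair set
    # is redundant, so wrong pairwise peaks (from block pairs sharing too
    # little structure) can be identified and rejected.  Plain LS is not
    # robust to them, so residuals are first screened against a chained
    # estimate built from adjacent-block shifts only, which are reliable
    # because neighboring blocks always share most of their emitters.
    pairs = np.asarray(pairs)
    chain = np.zeros((n_blocks, 2))
    adj = {(i, j): s for (i, j), s in zip(map(tuple, pairs), shifts)
           if j == i + 1}
    for b in range(1, n_blocks):
        chain[b] = chain[b - 1] + adj[(b - 1, b)]

    def residuals(d):
        pred = d[pairs[:, 1]] - d[pairs[:, 0]]
        return np.hypot(*(shifts - pred).T)

    keep = residuals(chain) <= max(3.0 * render_bin_nm, 1.0)
    dsol = chain.copy()
    for _ in range(2):
        A = np.zeros((int(keep.sum()) + 1, n_blocks))
        for k, (i, j) in enumerate(pairs[keep]):
            A[k, i], A[k, j] = -1.0, 1.0
        A[-1, :] = 1.0
        bx = np.concatenate([shifts[keep, 0], [0.0]])
        by = np.concatenate([shifts[keep, 1], [0.0]])
        dsol = np.column_stack([np.linalg.lstsq(A, bx, rcond=None)[0],
                                np.linalg.lstsq(A, by, rcond=None)[0]])
        resid = residuals(dsol)
        tol = max(3.0 * np.median(resid[keep]), 2.0 * render_bin_nm)
        new_keep = resid <= tol
        # keep the adjacent chain connected whatever the residuals say
        new_keep |= pairs[:, 1] == pairs[:, 0] + 1
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    dxb, dyb = dsol[:, 0], dsol[:, 1]

    centers = np.minimum(np.arange(n_blocks) * window_frames + window_frames / 2.0,
                         n_frames - 0.5)
    t = np.arange(n_frames, dtype=float)
    dx = _interp_extrap(t, centers, dxb)
    dy = _interp_extrap(t, centers, dyb)
    dx -= dx.mean()
    dy -= dy.mean()
    return DriftTrace(dx, dy, method="rcc", window=window_frames)


def _interp_extrap(t, xp, fp):
    out = np.interp(t, xp, fp)
    if len(xp) >= 2:
        lo = t < xp[0]
        hi = t > xp[-1]
        s0 = (fp[1] - fp[0]) / (xp[1] - xp[0])
        s1 = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        out[lo] = fp[0] + s0 * (t[lo] - xp[0])
        out[hi] = fp[-1] + s1 * (t[hi] - xp[-1])
    return out


def estimate_drift_fiducial(table: LocalizationTable, picks) -> DriftTrace:
    """Drift from fiducial markers.

    ``picks`` is a list of ``(x_nm, y_nm, radius_nm)`` circles around
    stationary beads.  Per frame, the drift is the mean over fiducials of
    (bead position - bead time-mean); frames without a bead localization
    are linearly interpolated.
    """
    n_frames = table.n_frames
    frames = table.df["frame"].to_numpy()
    xy = table.xy
    traces = []
    for (cx, cy, r) in picks:
        sel = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2 <= r ** 2
        if not np.any(sel):
            raise ValueError(f"no fiducial localizations in pick ({cx}, {cy})")
        f = frames[sel]
        if len(np.unique(f)) < 0.5 * n_frames:
            raise ValueError(
                f"fiducial pick ({cx}, {cy}) present in fewer than half the frames")
        pos = xy[sel]
        # average per frame, subtract time-mean
        sums = np.zeros((n_frames, 2))
        cnts = np.zeros(n_frames)
        np.add.at(sums, f, pos)
        np.add.at(cnts, f, 1)
        have = cnts > 0
        mean_pos = sums[have] / cnts[have, None]
        mean_pos -= pos.mean(axis=0)
        t = np.arange(n_frames, dtype=float)
        trace = np.column_stack([
            np.interp(t, t[have], mean_pos[:, 0]),
            np.interp(t, t[have], mean_pos[:, 1])])
        traces.append(trace)
    tr = np.mean(traces, axis=0)
    tr -= tr.mean(axis=0)
    return DriftTrace(tr[:, 0], tr[:, 1], method="fiducial")


def apply_drift(table: LocalizationTable, trace: DriftTrace) -> LocalizationTable:
    """Subtract the drift trace from positions (invertible with ``-trace``)."""
    if len(trace) < table.n_frames:
        raise ValueError("drift trace shorter than the movie")
    df = table.df.copy()
    f = df["frame"].to_numpy()
    df["x_nm"] = df["x_nm"].to_numpy() - trace.dx_nm[f]
    df["y_nm"] = df["y_nm"].to_numpy() - trace.dy_nm[f]
    out = table.replace(df)
    return out.with_provenance("apply_drift", dict(method=trace.method,
                                                   window=trace.window))


# --------------------------------------------------------------------------
# sigma filter
# --------------------------------------------------------------------------

def filter_sigma(table: LocalizationTable,
                 config: FilterConfig = FilterConfig()) -> LocalizationTable:
    """Keep rows whose fitted sigma lies in the band on *both* axes.

    Bounds are inclusive: a localization with sx exactly at 48.4 nm is
    kept.
    """
    sx = table.df["sx_nm"].to_numpy()
    sy = table.df["sy_nm"].to_numpy()
    keep = ((config.sigma_min_nm <= sx) & (sx <= config.sigma_max_nm)
            & (config.sigma_min_nm <= sy) & (sy <= config.sigma_max_nm))
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("filter_sigma removed %d of %d rows", n_removed, len(table))
    out = table.replace(table.df.loc[keep].reset_index(drop=True))
    return out.with_provenance("filter_sigma",
                               dict(sigma_min_nm=config.sigma_min_nm,
                                    sigma_max_nm=config.sigma_max_nm),
                               n_in=len(table), n_out=int(keep.sum()))


# --------------------------------------------------------------------------
# NeNA precision
# --------------------------------------------------------------------------

def _nena_model(d, amp, sigma, bg_slope):
    # same-molecule term: Rayleigh with scale sigma*sqrt(2); background: linear
    return amp * d / (2 * sigma ** 2) * np.exp(-d ** 2 / (4 * sigma ** 2)) + bg_slope * d


def nearest_neighbor_precision(table: LocalizationTable, max_dist_nm: float = 500.0,
                               bin_nm: float = 2.0, hist_max_nm: float = 200.0,
                               min_pairs: int = 500) -> PrecisionEstimate:
    """NeNA-style estimate of the experimental localization precision.

    Collects, for every localization in frame f, the distance to its
    nearest neighbor in frame f+1 (within ``max_dist_nm``); repeated
    localizations of one still-emitting molecule produce a Rayleigh peak
    at sqrt(2) x sigma_loc while unrelated molecules contribute a
    linearly rising background.  The histogram is least-squares fit with
    p(d) = A * d/(2 sigma^2) exp(-d^2 / (4 sigma^2)) + B * d and sigma is
    returned.
    """
    frames = table.df["frame"].to_numpy()
    xy = table.xy
    order = np.argsort(frames, kind="stable")
    frames, xy = frames[order], xy[order]
    uniq, starts = np.unique(frames, return_index=True)
    starts = np.append(starts, len(frames))
    idx_of = {f: k for k, f in enumerate(uniq)}

    dists = []
    for k, f in enumerate(uniq):
        nk = idx_of.get(f + 1)
        if nk is None:
            continue
        a = xy[starts[k]:starts[k + 1]]
        b = xy[starts[nk]:starts[nk + 1]]
        tree = cKDTree(b)
        d, _ = tree.query(a, k=1, distance_upper_bound=max_dist_nm)
        d = d[np.isfinite(d)]
        if len(d):
            dists.append(d)
    dists = np.concatenate(dists) if dists else np.empty(0)
    if len(dists) < min_pairs:
        raise ValueError(f"only {len(dists)} consecutive-frame NN pairs "
                         f"(need >= {min_pairs})")

    edges = np.arange(0.0, hist_max_nm + bin_nm, bin_nm)
    counts, _ = np.histogram(dists, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    peak = centers[np.argmax(counts)]
    sigma0 = max(peak / np.sqrt(2.0), 1.0)
    amp0 = counts.max() * 2 * sigma0 ** 2 / max(peak, 1.0) * np.exp(0.5)
    bg0 = max(counts[-10:].mean() / centers[-5], 0.0)
    sigma_lo, sigma_hi = 0.25, hist_max_nm
    try:
        popt, _ = curve_fit(_nena_model, centers, counts,
                            p0=[max(amp0, 1.0), sigma0, bg0],
                            bounds=([0.0, sigma_lo, 0.0],
                                    [np.inf, sigma_hi, np.inf]),
                            maxfev=20000)
    except RuntimeError as e:
        raise ValueError(f"NeNA fit did not converge: {e}") from e
    amp, sigma, bg_slope = popt
    model = _nena_model(centers, *popt)
    resid = float(np.linalg.norm(counts - model) / max(np.linalg.norm(counts), 1.0))

    if sigma >= 0.98 * sigma_hi or sigma <= 1.02 * sigma_lo and sigma0 > 2 * sigma_lo:
        raise ValueError(f"NeNA sigma hit its bounds (sigma={sigma:.2f} nm)")
    same_mol_fraction = amp / max(counts.sum() * bin_nm, 1e-12)
    if same_mol_fraction < 0.02:
        raise ValueError(
            "no same-molecule peak: nearest-neighbor distances are consistent "
            f"with pure background (peak fraction {same_mol_fraction:.3f})")

    return PrecisionEstimate(sigma_loc_nm=float(sigma), n_pairs=len(dists),
                             bin_centers_nm=centers, counts=counts,
                             model_counts=model, residual_norm=resid)


def derive_link_radius(precision: PrecisionEstimate | float,
                       multiplier: float = 6.0) -> float:
    """Linking radius = multiplier x experimental precision (12.1 -> 72.6)."""
    sigma = precision.sigma_loc_nm if isinstance(precision, PrecisionEstimate) \
        else float(precision)
    if sigma <= 0:
        raise ValueError("precision must be positive")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    return multiplier * sigma


# --------------------------------------------------------------------------
# linking
# --------------------------------------------------------------------------

def link_localizations(table: LocalizationTable,
                       config: LinkConfig = LinkConfig()) -> LocalizationTable:
    """Merge repeated emissions of one molecule into single signals.

    Greedy frame-ordered chaining: an event joins an open chain when it
    lies within ``radius_nm`` of the chain's running mean position and
    the chain was last seen no more than ``max_dark_frames + 1`` frames
    ago.  Competing events resolve by distance, ties by lower row id; a
    chain accepts at most one event per frame.  Each chain collapses to
    one localization at the photon-weighted mean position with photons
    summed, precision = best (smallest) member precision, and the number
    of merged events recorded in ``n_events``.
    """
    df = table.df
    if len(df) > 1 and not df["frame"].is_monotonic_increasing:
        raise ValueError("table must be sorted by frame")
    frames = df["frame"].to_numpy()
    xy = table.xy
    n = len(df)
    group = np.full(n, -1, dtype=int)

    open_mean = []      # running mean positions
    open_last = []      # last frame seen
    open_members = []
    open_sumw = []      # photon-weight sums for running mean
    photons = df["photons"].to_numpy()
    active: list[int] = []   # indices into open_* lists

    uniq, starts = np.unique(frames, return_index=True)
    starts = np.append(starts, n)
    next_group = 0
    for k, f in enumerate(uniq):
        # retire chains that have been dark too long
        active = [c for c in active if f - open_last[c] <= config.max_dark_frames + 1]
        rows = np.arange(starts[k], starts[k + 1])
        if active:
            means = np.asarray([open_mean[c] for c in active])
            d = np.linalg.norm(xy[rows, None, :] - means[None, :, :], axis=2)
            cand = [(d[i, j], int(rows[i]), active[j])
                    for i in range(len(rows)) for j in range(len(active))
                    if d[i, j] <= config.radius_nm]
            cand.sort(key=lambda t: (t[0], t[1]))
            used_rows, used_chains = set(), set()
            for dist, row, chain in cand:
                if row in used_rows or chain in used_chains:
                    continue
                used_rows.add(row)
                used_chains.add(chain)
                group[row] = chain
                w = photons[row]
                tot = open_sumw[chain] + w
                open_mean[chain] = (open_mean[chain] * open_sumw[chain]
                                    + xy[row] * w) / tot
                open_sumw[chain] = tot
                open_last[chain] = f
                open_members[chain].append(row)
        for row in rows:
            if group[row] == -1:
                group[row] = next_group
                open_mean.append(xy[row].copy())
                open_last.append(f)
                open_members.append([row])
                open_sumw.append(photons[row])
                active.append(next_group)
                next_group += 1

    # collapse chains (vectorized per-group aggregation)
    import pandas as pd
    w = photons
    agg = pd.DataFrame({
        "group": group,
        "frame": frames,
        "wx": df["x_nm"].to_numpy() * w,
        "wy": df["y_nm"].to_numpy() * w,
        "w": w,
        "sx_nm": df["sx_nm"].to_numpy(),
        "sy_nm": df["sy_nm"].to_numpy(),
        "bg": df["bg"].to_numpy(),
        "lpx_nm": df["lpx_nm"].to_numpy(),
        "lpy_nm": df["lpy_nm"].to_numpy(),
        "net_gradient": df["net_gradient"].to_numpy(),
    })
    g = agg.groupby("group", sort=True)
    out_df = pd.DataFrame({
        "frame": g["frame"].first(),
        "x_nm": g["wx"].sum() / g["w"].sum(),
        "y_nm": g["wy"].sum() / g["w"].sum(),
        "sx_nm": g["sx_nm"].mean(),
        "sy_nm": g["sy_nm"].mean(),
        "photons": g["w"].sum(),
        "bg": g["bg"].mean(),
        "lpx_nm": g["lpx_nm"].min(),
        "lpy_nm": g["lpy_nm"].min(),
        "net_gradient": g["net_gradient"].max(),
        "n_events": g.size(),
    }).reset_index(names="group")
    if "emitter_id" in df.columns:
        gt = pd.DataFrame({"group": group,
                           "emitter_id": df["emitter_id"].to_numpy(),
                           "cluster_id": df["cluster_id"].to_numpy()})
        first = gt.groupby("group", sort=True).first()
        out_df["emitter_id"] = first["emitter_id"].to_numpy()
        out_df["cluster_id"] = first["cluster_id"].to_numpy()
    out_df = out_df.sort_values(["frame", "group"],
                                kind="stable").reset_index(drop=True)
    out = table.replace(out_df)
    return out.with_provenance("link_localizations",
                               dict(radius_nm=config.radius_nm,
                                    max_dark_frames=config.max_dark_frames),
                               n_in=n, n_out=len(out_df))
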