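"""Ground-truth recovery benchmarks.

Each function regenerates a synthetic dataset at the published operating
point of the emulated experiment, runs the analysis chain on it, and
returns the recovered quantity next to the planted truth.  They are the
substance of the acceptance checks and of the worked examples; everything
is deterministic in the single seed argument.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import postprocess as post
from .pipeline import (AnalysisConfig, FIXTURES, child_seed, make_fixture,
                       run_analyze)
from .simulate import (AcquisitionConfig, BlinkKinetics, generate_field,
                       emit_localization_table, make_linear_drift,
                       rect_geometry, sample_blinks)

__all__ = ["precision_pairs_table", "recover_precision",
           "recover_fixture_diameter", "recover_fixture_density",
           "recover_linear_drift"]

ANALYSIS_NO_DRIFT = AnalysisConfig(drift_method="none")


def precision_pairs_table(seed: int, sigma_loc_nm: float = 12.1,
                          n_pairs: int = 10000):
    """Sparse immobile emitters re-localized in consecutive frames.

    Emitters sit on a CSR background field; each stays on for a few frames
    so that every blink contributes consecutive-frame repeats with
    independent N(0, sigma^2) errors per axis -- the same-molecule signal
    the nearest-neighbor estimator fits.  Sized to give at least
    ``n_pairs`` NN pairs.
    """
    kin = BlinkKinetics(mean_on_frames=3.0, flickers_per_burst_mean=2.0)
    # each blink of duration d yields d-1 consecutive pairs; ~4 per emitter
    density = n_pairs / 4.0 / 400.0          # emitters per um^2 on 400 um^2
    geom = rect_geometry(20, 20)
    field = generate_field(geom, 0.0, 60.0, background_per_um2=density,
                           kinetics=kin, seed=child_seed(seed, "pairs-field"))
    field = sample_blinks(field, kin, seed=child_seed(seed, "pairs-blinks"))
    return emit_localization_table(field, sigma_loc_nm=sigma_loc_nm,
                                   seed=child_seed(seed, "pairs-table"))


def recover_precision(seed: int, sigma_loc_nm: float = 12.1,
                      link_multiplier: float = 6.0) -> dict:
    """Estimate the localization precision by NeNA and derive the linking
    radius from it, on a table whose true per-axis error is known."""
    table = precision_pairs_table(seed, sigma_loc_nm)
    est = post.nearest_neighbor_precision(table)
    return {
        "true_sigma_nm": sigma_loc_nm,
        "estimated_sigma_nm": est.sigma_loc_nm,
        "n_pairs": est.n_pairs,
        "link_radius_nm": post.derive_link_radius(est, link_multiplier),
    }


def _fixture_side_um(name: str, target_clusters: int) -> float:
    dens = FIXTURES[name]["density_per_um2"]
    return float(np.sqrt(target_clusters / dens))


def recover_fixture_diameter(name: str, seed: int,
                             min_clusters: int = 500) -> dict:
    """Full chain on one large cell of the named fixture; mean measured
    cluster diameter over at least ``min_clusters`` detected signals."""
    side = _fixture_side_um(name, int(min_clusters * 1.08))
    field, table = make_fixture(name, seed, width_um=side, height_um=side)
    res = run_analyze(table, ANALYSIS_NO_DRIFT, truth=field,
                      region_mask=field.geometry.cell_mask,
                      region_bin_nm=field.geometry.bin_nm)
    d = res.clusters.records.diameter_nm.to_numpy()
    return {
        "fixture": name,
        "truth_diameter_nm": FIXTURES[name]["truth_diameter_nm"],
        "n_clusters": int(len(d)),
        "mean_diameter_nm": float(d.mean()),
        "sd_diameter_nm": float(d.std()),
        "epsilon_nm": res.cluster_params.epsilon_nm,
        "min_pts": res.cluster_params.min_pts,
    }


def recover_fixture_density(name: str, seed: int, n_cells: int = 20,
                            cell_um: float = 5.5) -> dict:
    """Full chain on ``n_cells`` simulated cells; per-cell signal density
    against the planted density.  The generator's cell mask plays the role
    of the manually drawn outline."""
    per_cell = []
    for c in range(n_cells):
        field, table = make_fixture(name, child_seed(seed, f"{name}-cell{c}"),
                                    width_um=cell_um, height_um=cell_um)
        res = run_analyze(table, ANALYSIS_NO_DRIFT, truth=field,
                          region_mask=field.geometry.cell_mask,
                          region_bin_nm=field.geometry.bin_nm)
        per_cell.append(res.densities[0].density_per_um2)
    per_cell = np.asarray(per_cell)
    return {
        "fixture": name,
        "planted_density_per_um2": FIXTURES[name]["density_per_um2"],
        "n_cells": n_cells,
        "mean_density_per_um2": float(per_cell.mean()),
        "sem_density_per_um2": float(per_cell.std(ddof=1) / np.sqrt(n_cells)),
        "per_cell": per_cell,
    }


def recover_linear_drift(seed: int, rate_nm_per_frame: float = 0.02,
                         n_frames: int = 30000,
                         window_frames: int = 1000) -> dict:
    """Inject linear stage drift, re-estimate it by RCC, report the RMS
    error of the recovered per-frame trace."""
    drift = make_linear_drift(n_frames, rate_nm_per_frame)
    acq = AcquisitionConfig(n_frames=n_frames, drift_nm=drift)
    geom = rect_geometry(5, 5)
    field = generate_field(geom, 10.8, FIXTURES["mdc_soma"]["truth_diameter_nm"],
                           acquisition=acq, seed=child_seed(seed, "drift-field"))
    field = sample_blinks(field, seed=child_seed(seed, "drift-blinks"))
    table = emit_localization_table(field, seed=child_seed(seed, "drift-table"))
    trace = post.estimate_drift_rcc(table, window_frames, 10.0)
    truth = drift - drift.mean(axis=0)
    err = np.hypot(trace.dx_nm - truth[:, 0], trace.dy_nm - truth[:, 1])
    corrected = post.apply_drift(table, trace)
    re_trace = post.estimate_drift_rcc(corrected, window_frames, 10.0)
    return {
        "rate_nm_per_frame": rate_nm_per_frame,
        "rms_error_nm": float(np.sqrt(np.mean(err ** 2))),
        "max_error_nm": float(err.max()),
        "residual_rms_nm": float(np.sqrt(np.mean(
            re_trace.dx_nm ** 2 + re_trace.dy_nm ** 2))),
    }
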