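"""Drift correction, sigma filtering, precision estimation and linking."""

import numpy as np
import pandas as pd
import pytest

import stormquant as sq
from stormquant.postprocess import (DriftTrace, FilterConfig, LinkConfig,
                                    apply_drift, derive_link_radius,
                                    estimate_drift_fiducial, estimate_drift_rcc,
                                    filter_sigma, link_localizations,
                                    nearest_neighbor_precision)
from tests.conftest import make_simple_table


# --------------------------------------------------------------------------
# drift
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def dense_drift_free_table():
    geom = sq.rect_geometry(4, 4)
    acq = sq.AcquisitionConfig(n_frames=6000, activation_levels=(1.0,))
    field = sq.generate_field(geom, 10.8, 85.0, acquisition=acq, seed=31)
    field = sq.sample_blinks(field, seed=32)
    return sq.emit_localization_table(field, seed=33)


class TestRcc:
    def test_null_drift_recovers_near_zero(self, dense_drift_free_table):
        tr = estimate_drift_rcc(dense_drift_free_table, 1000, 10.0)
        rms = np.sqrt(np.mean(tr.dx_nm ** 2 + tr.dy_nm ** 2))
        assert rms < 5.0          # half the render bin
        assert tr.dx_nm.mean() == pytest.approx(0.0, abs=1e-9)

    def test_fewer_than_two_windows_rejected(self, dense_drift_free_table):
        with pytest.raises(ValueError, match="window"):
            estimate_drift_rcc(dense_drift_free_table, window_frames=6000)

    def test_empty_block_named_in_error(self):
        t = make_simple_table([[100, 100]] * 50, [0] * 50, n_frames=3000)
        with pytest.raises(ValueError, match="block 1"):
            estimate_drift_rcc(t, window_frames=1000)


class TestFiducial:
    def _fiducial_table(self, drift, jitter=0.0, n_fid=1, seed=0):
        rng = np.random.default_rng(seed)
        n = len(drift)
        frames = np.tile(np.arange(n), n_fid)
        pos = []
        for k in range(n_fid):
            base = np.array([500.0 + 800 * k, 600.0])
            p = base + drift + rng.normal(0, jitter, size=(n, 2))
            pos.append(p)
        return make_simple_table(np.concatenate(pos), frames, n_frames=n), \
            [(500.0 + 800 * k, 600.0, 300.0) for k in range(n_fid)]

    def test_stationary_fiducials_give_zero_trace(self):
        t, picks = self._fiducial_table(np.zeros((200, 2)))
        tr = estimate_drift_fiducial(t, picks)
        assert np.allclose(tr.as_array(), 0.0, atol=1e-9)

    def test_exact_transport_identity(self):
        drift = sq.make_linear_drift(200, 0.5)
        t, picks = self._fiducial_table(drift)
        tr = estimate_drift_fiducial(t, picks)
        centered = drift - drift.mean(axis=0)
        np.testing.assert_allclose(tr.as_array(), centered, atol=1e-9)

    def test_two_jittered_fiducials_average_down_noise(self):
        """With two beads of N(0, 2 nm) jitter the residual trace error has
        SD close to 2/sqrt(2) nm."""
        drift = sq.make_linear_drift(3000, 0.1)
        t, picks = self._fiducial_table(drift, jitter=2.0, n_fid=2, seed=5)
        tr = estimate_drift_fiducial(t, picks)
        resid = tr.as_array() - (drift - drift.mean(axis=0))
        sd = resid.std()
        assert sd == pytest.approx(2.0 / np.sqrt(2), rel=0.15)

    def test_missing_fiducial_rejected(self):
        t, _ = self._fiducial_table(np.zeros((100, 2)))
        with pytest.raises(ValueError, match="fiducial"):
            estimate_drift_fiducial(t, [(5000.0, 5000.0, 100.0)])


class TestApplyDrift:
    def test_zero_trace_is_identity(self):
        t = make_simple_table([[10, 20], [30, 40]], [0, 1], n_frames=2)
        tr = DriftTrace(np.zeros(2), np.zeros(2), "rcc")
        out = apply_drift(t, tr)
        np.testing.assert_array_equal(out.xy, t.xy)

    def test_apply_then_invert_restores_bitwise(self):
        rng = np.random.default_rng(1)
        t = make_simple_table(rng.random((50, 2)) * 1000,
                              np.arange(50) % 10, n_frames=10)
        tr = DriftTrace(rng.random(10), rng.random(10), "rcc")
        back = apply_drift(apply_drift(t, tr), -tr)
        np.testing.assert_array_equal(back.xy, t.xy)

    def test_subtracts_per_frame_truth(self):
        t = make_simple_table([[100, 100], [100, 100]], [0, 1], n_frames=2)
        tr = DriftTrace(np.array([0.0, 7.0]), np.array([0.0, -3.0]), "rcc")
        out = apply_drift(t, tr)
        np.testing.assert_allclose(out.xy[1], [93.0, 103.0])


# --------------------------------------------------------------------------
# sigma filter
# --------------------------------------------------------------------------

class TestFilterSigma:
    def test_bounds_inclusive(self):
        t = make_simple_table([[0, 0]] * 3, [0, 1, 2])
        t.df.loc[:, "sx_nm"] = [48.4, 48.3, 193.6]
        t.df.loc[:, "sy_nm"] = [100.0, 100.0, 193.6]
        out = filter_sigma(t)
        np.testing.assert_array_equal(out.df.sx_nm.to_numpy(), [48.4, 193.6])

    def test_empty_table_passes_through(self):
        t = make_simple_table(np.empty((0, 2)), np.empty(0, dtype=int))
        assert len(filter_sigma(t)) == 0

    def test_uniform_sigma_survival_fraction(self):
        """sigma ~ U(0, 300) on both axes independently: survival
        probability ((193.6 - 48.4)/300)^2 within 3 binomial SE."""
        rng = np.random.default_rng(8)
        n = 10000
        t = make_simple_table(rng.random((n, 2)) * 1000, np.zeros(n, dtype=int))
        t.df["sx_nm"] = rng.random(n) * 300
        t.df["sy_nm"] = rng.random(n) * 300
        out = filter_sigma(t)
        p = ((193.6 - 48.4) / 300) ** 2
        se = np.sqrt(n * p * (1 - p))
        assert abs(len(out) - n * p) < 3 * se

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(sigma_min_nm=200.0, sigma_max_nm=100.0)


# --------------------------------------------------------------------------
# NeNA precision
# --------------------------------------------------------------------------

class TestPrecision:
    def test_recovers_default_precision(self, repeated_emitter_table):
        est = nearest_neighbor_precision(repeated_emitter_table)
        assert est.sigma_loc_nm == pytest.approx(12.1, abs=0.5)
        assert est.n_pairs >= 500

    def test_degenerate_tight_repeats(self):
        rng = np.random.default_rng(2)
        base = rng.random((800, 2)) * 8000
        frames = (np.arange(800)[:, None] * 3 + np.array([0, 1])).ravel()
        pos = np.repeat(base, 2, axis=0) + rng.normal(0, 0.5, (1600, 2))
        t = make_simple_table(pos, frames, n_frames=1200)
        est = nearest_neighbor_precision(t)
        assert est.sigma_loc_nm < 1.0

    def test_pure_background_raises_non_identifiable(self):
        rng = np.random.default_rng(3)
        n = 30000
        t = make_simple_table(rng.random((n, 2)) * 20000,
                              rng.integers(0, 300, n), n_frames=300)
        with pytest.raises(ValueError, match="background|same-molecule|bounds"):
            nearest_neighbor_precision(t)

    def test_too_few_pairs_raises(self):
        t = make_simple_table([[0, 0], [5, 5]], [0, 1], n_frames=2)
        with pytest.raises(ValueError, match="pairs"):
            nearest_neighbor_precision(t)


class TestLinkRadius:
    def test_six_times_experimental_precision(self):
        assert derive_link_radius(12.1) == pytest.approx(72.6)
        assert derive_link_radius(11.0) == pytest.approx(66.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            derive_link_radius(0.0)
        with pytest.raises(ValueError):
            derive_link_radius(12.1, multiplier=0)


# --------------------------------------------------------------------------
# linking
# --------------------------------------------------------------------------

def closure_link_oracle(xy, frames, radius, max_dark):
    """Union-find transitive closure over (distance <= radius AND frame gap
    <= max_dark + 1); independent of the greedy chaining implementation."""
    n = len(xy)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            gap = abs(frames[i] - frames[j])
            if 0 < gap <= max_dark + 1 and np.linalg.norm(xy[i] - xy[j]) <= radius:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(tuple(sorted(g)) for g in groups.values())


class TestLinking:
    def test_radius_decides_one_or_two_signals(self):
        cfg = LinkConfig(radius_nm=72.6, max_dark_frames=2)
        near = make_simple_table([[0, 0], [50, 0]], [0, 1], n_frames=2)
        far = make_simple_table([[0, 0], [80, 0]], [0, 1], n_frames=2)
        assert len(link_localizations(near, cfg)) == 1
        assert len(link_localizations(far, cfg)) == 2

    def test_single_event_passes_through(self):
        t = make_simple_table([[10, 10]], [0], n_frames=1)
        out = link_localizations(t)
        assert len(out) == 1
        assert out.df.n_events.iloc[0] == 1

    def test_dark_gap_splits_chains(self):
        cfg = LinkConfig(radius_nm=72.6, max_dark_frames=2)
        gap2 = make_simple_table([[0, 0], [5, 0]], [0, 3], n_frames=4)
        gap3 = make_simple_table([[0, 0], [5, 0]], [0, 4], n_frames=5)
        assert len(link_localizations(gap2, cfg)) == 1
        assert len(link_localizations(gap3, cfg)) == 2

    def test_conserves_events(self, dense_drift_free_table):
        out = link_localizations(dense_drift_free_table,
                                 LinkConfig(72.6, 2))
        assert out.df.n_events.sum() == len(dense_drift_free_table)

    def test_collapse_statistics(self):
        t = make_simple_table([[0, 0], [10, 0]], [0, 1], n_frames=2)
        t.df["photons"] = [1000.0, 3000.0]
        t.df["lpx_nm"] = [12.0, 8.0]
        out = link_localizations(t, LinkConfig(72.6, 2))
        row = out.df.iloc[0]
        assert row.photons == 4000.0
        assert row.x_nm == pytest.approx(7.5)     # photon-weighted mean
        assert row.lpx_nm == 8.0                  # best member precision
        assert row.n_events == 2

    def test_matches_transitive_closure_on_separated_emitters(self):
        """Greedy chaining equals the union-find closure oracle on tables of
        well-separated emitters with tight repeats (<= 50 events)."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_emitters = rng.integers(3, 8)
            centers = rng.random((n_emitters, 2)) * 5000
            rows, frames = [], []
            for e in range(n_emitters):
                f = int(rng.integers(0, 20))
                for _ in range(int(rng.integers(1, 8))):
                    rows.append(centers[e] + rng.normal(0, 5, 2))
                    frames.append(f)
                    f += int(rng.integers(1, 3))
            t = make_simple_table(rows, frames, n_frames=60)
            cfg = LinkConfig(radius_nm=72.6, max_dark_frames=2)
            out = link_localizations(t, cfg)
            order = np.argsort(np.asarray(frames), kind="stable")
            xy_sorted = np.asarray(rows, dtype=float)[order]
            oracle = closure_link_oracle(xy_sorted,
                                         np.asarray(frames)[order], 72.6, 2)
            # emitters are far apart, so each sorted row belongs to the
            # nearest linked signal; compare the partitions
            means = out.df[["x_nm", "y_nm"]].to_numpy()
            lab = np.argmin(np.linalg.norm(
                xy_sorted[:, None, :] - means[None, :, :], axis=2), axis=1)
            got = {}
            for i, l in enumerate(lab):
                got.setdefault(l, []).append(i)
            got = sorted(tuple(g) for g in got.values())
            assert len(out) == len(oracle)
            assert got == oracle

    def test_unsorted_table_rejected(self):
        t = make_simple_table([[0, 0], [5, 5]], [1, 0], n_frames=2)
        t.df.loc[:, "frame"] = [1, 0]       # force unsorted
        with pytest.raises(ValueError, match="sorted"):
            link_localizations(t)

    def test_commutes_with_row_order(self, dense_drift_free_table):
        """Linking after an intra-frame row shuffle yields the same signals
        up to id relabeling."""
        t = dense_drift_free_table
        rng = np.random.default_rng(4)
        df = t.df.sample(frac=1.0, random_state=7).sort_values(
            "frame", kind="stable").reset_index(drop=True)
        t2 = sq.LocalizationTable(df, t.pixel_size_nm, t.n_frames)
        a = link_localizations(filter_sigma(t), LinkConfig(72.6, 2))
        b = link_localizations(filter_sigma(t2), LinkConfig(72.6, 2))
        key = lambda d: sorted(zip(d.frame, d.n_events,
                                   d.x_nm.round(6), d.y_nm.round(6)))
        assert key(a.df) == key(b.df)

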