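"""Spot detection and Gaussian-fit tests against independent oracles."""

import dataclasses

import numpy as np
import pytest

import stormquant as sq
from stormquant.localize import (crlb_precision_nm, detect_spots, fit_spot,
                                 localize_movie, net_gradient_map, SpotCandidate)
from stormquant.simulate import AcquisitionConfig, Movie, _pixel_gaussian


def brute_force_net_gradient(image, box_px):
    """Direct per-pixel evaluation of the net-gradient definition."""
    gy, gx = np.gradient(image.astype(float))
    half = box_px // 2
    rows, cols = image.shape
    out = np.zeros_like(gx)
    for r in range(rows):
        for c in range(cols):
            acc = 0.0
            for u in range(r - half, r + half + 1):
                for v in range(c - half, c + half + 1):
                    if (u, v) == (r, c) or not (0 <= u < rows and 0 <= v < cols):
                        continue
                    acc += gy[u, v] * (r - u) + gx[u, v] * (c - v)
            out[r, c] = acc
    return out


def spot_image(shape=(21, 21), x=10.3, y=10.6, sigma=1.0, photons=5000.0, bg=0.0):
    img = np.full(shape, float(bg))
    (r0, r1, c0, c1), patch = _pixel_gaussian(x, y, sigma, shape, photons)
    img[r0:r1, c0:c1] += patch
    return img


def movie_from_image(img, gain=2.0, offset=100.0):
    acq = AcquisitionConfig(n_frames=1, gain=gain, offset=offset,
                            read_noise=0.0, background_photons=0.0)
    frames = np.clip(np.round(offset + gain * img), 0, 65535).astype(np.uint16)[None]
    return Movie(frames=frames, acquisition=acq)


class TestNetGradient:
    def test_flat_field_gives_zero(self):
        ng = net_gradient_map(np.full((15, 15), 7.0), 7)
        assert np.allclose(ng, 0.0)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        img = spot_image() + rng.random((21, 21))
        ng = net_gradient_map(img, 5)
        oracle = brute_force_net_gradient(img, 5)
        np.testing.assert_allclose(ng, oracle, atol=1e-9)

    def test_box_larger_than_frame_rejected(self):
        with pytest.raises(ValueError, match="box"):
            net_gradient_map(np.zeros((5, 5)), 7)

    def test_single_spot_one_candidate_at_brightest_pixel(self):
        mov = movie_from_image(spot_image(bg=2.0))
        cands = detect_spots(mov, frame=0, box_px=7, threshold=5000.0)
        assert len(cands) == 1
        counts = mov.frames[0].astype(float)
        assert (cands[0].row, cands[0].col) == np.unravel_index(
            counts.argmax(), counts.shape)
        counts_img = np.clip(counts - 100.0, 0, None)
        oracle = brute_force_net_gradient(counts_img, 7)
        assert cands[0].net_gradient == pytest.approx(
            oracle[cands[0].row, cands[0].col])

    def test_detection_independent_of_frame_order(self):
        rng = np.random.default_rng(3)
        imgs = [spot_image(x=6.2, y=7.1, bg=2.0),
                spot_image(x=14.8, y=12.3, bg=2.0)]
        acq = AcquisitionConfig(n_frames=2, gain=2.0, offset=100.0,
                                read_noise=0.0)
        frames = np.stack([np.round(100 + 2 * (im + rng.poisson(2.0, im.shape)))
                           for im in imgs]).astype(np.uint16)
        fwd = detect_spots(Movie(frames, acq))
        rev = detect_spots(Movie(frames[::-1].copy(),
                                 dataclasses.replace(acq)))
        key = lambda c: (c.row, c.col, round(c.net_gradient, 6))
        assert sorted(map(key, fwd)) == sorted(map(key, rev))

    def test_overlapping_candidates_both_dropped(self):
        img = spot_image(x=8.0, y=10.0) + spot_image(x=12.0, y=10.0)
        mov = movie_from_image(img)
        assert detect_spots(mov, frame=0, box_px=7, threshold=5000.0) == []


class TestFitSpot:
    def test_centered_symmetric_spot_recovered(self):
        mov = movie_from_image(spot_image(x=10.5, y=10.5, bg=5.0))
        [cand] = detect_spots(mov, frame=0)
        loc = fit_spot(mov, cand, box_px=7)
        px = 121.0
        assert abs(loc["x_nm"] / px - 10.5) < 0.01
        assert abs(loc["y_nm"] / px - 10.5) < 0.01
        assert loc["sx_nm"] == pytest.approx(loc["sy_nm"], rel=0.01)
        assert loc["sx_nm"] == pytest.approx(121.0, rel=0.02)

    def test_offset_spot_matches_grid_search_oracle(self):
        """Fitted (x, y) agrees with a dense grid search of the Poisson
        likelihood over positions."""
        from stormquant.localize import _nll
        x_true, y_true = 10.80, 10.70       # +0.30, +0.20 from pixel center
        mov = movie_from_image(spot_image(x=x_true, y=y_true, bg=5.0))
        [cand] = detect_spots(mov, frame=0)
        loc = fit_spot(mov, cand, box_px=7)
        px = 121.0
        assert abs(loc["x_nm"] / px - x_true) < 0.01
        assert abs(loc["y_nm"] / px - y_true) < 0.01

        half = 3
        roi = mov.photons(0)[cand.row - half:cand.row + half + 1,
                             cand.col - half:cand.col + half + 1]
        edges = np.arange(8, dtype=float)
        grid = np.arange(3.0, 4.0, 0.005)
        best, best_nll = None, np.inf
        for gx in grid:
            for gy in grid:
                p = np.array([gx, gy, np.log(loc["sx_nm"] / px),
                              np.log(loc["sy_nm"] / px),
                              np.log(loc["photons"]), np.log(loc["bg"])])
                v = _nll(p, roi, edges, edges)
                if v < best_nll:
                    best, best_nll = (gx, gy), v
        assert abs(loc["x_nm"] / px - (cand.col - half + best[0])) < 0.01
        assert abs(loc["y_nm"] / px - (cand.row - half + best[1])) < 0.01

    def test_truncated_roi_skipped(self):
        mov = movie_from_image(spot_image(x=1.0, y=1.0))
        cand = SpotCandidate(0, 1, 1, 1e6)
        assert fit_spot(mov, cand, box_px=7) is None

    def test_empirical_scatter_matches_crlb(self):
        """SD of fitted positions over Poisson replicates within 25% of the
        Cramer-Rao bound (N = 5000, b = 10/px, sigma = 121 nm)."""
        rng = np.random.default_rng(7)
        clean = spot_image(shape=(9, 9), x=4.5, y=4.5, sigma=1.0,
                           photons=5000.0, bg=10.0)
        acq = AcquisitionConfig(n_frames=1, gain=1.0, offset=0.0,
                                read_noise=0.0)
        xs = []
        for _ in range(1000):
            noisy = rng.poisson(clean).astype(np.uint16)[None]
            mov = Movie(noisy, acq)
            loc = fit_spot(mov, SpotCandidate(0, 4, 4, 1e6), box_px=9)
            if loc is not None:
                xs.append(loc["x_nm"])
        xs = np.array(xs)
        assert len(xs) > 950
        crlb = crlb_precision_nm(5000.0, 10.0, 121.0, 121.0)
        assert np.std(xs) == pytest.approx(crlb, rel=0.25)

    def test_position_invariant_under_intensity_scaling(self):
        """Scaling noiseless photon counts leaves the fitted position fixed
        (to the optimizer's convergence tolerance; frames kept as floats so
        camera quantization does not break the exact scaling)."""
        acq = AcquisitionConfig(n_frames=1, gain=1.0, offset=0.0,
                                read_noise=0.0, background_photons=0.0)
        img = spot_image(x=10.3, y=10.6, bg=5.0)
        l1 = fit_spot(Movie(img[None], acq), SpotCandidate(0, 10, 10, 1e6),
                      box_px=7)
        l4 = fit_spot(Movie(4 * img[None], acq), SpotCandidate(0, 10, 10, 1e6),
                      box_px=7)
        assert abs(l1["x_nm"] - l4["x_nm"]) / 121.0 < 1e-5
        assert abs(l1["y_nm"] - l4["y_nm"]) / 121.0 < 1e-5


@pytest.fixture(scope="module")
def separated_movie():
    geom = sq.rect_geometry(3.5, 3.5, margin_um=0.6)
    acq = AcquisitionConfig(n_frames=200, background_photons=10.0)
    kin = sq.BlinkKinetics(photons_median=5000.0, photons_sigma_ln=0.4,
                           activation_rate=6e-4)
    field = sq.generate_field(geom, 0.0, 62.3, background_per_um2=3.0,
                              kinetics=kin, acquisition=acq, seed=7)
    field = sq.sample_blinks(field, kin, seed=8)
    return field, sq.render_movie(field, seed=9)


class TestLocalizeMovie:
    def test_empty_movie_gives_empty_table(self):
        acq = AcquisitionConfig(n_frames=3, background_photons=2.0)
        frames = np.full((3, 16, 16), 104, dtype=np.uint16)
        table = localize_movie(Movie(frames, acq))
        assert len(table) == 0
        assert table.provenance[-1]["operation"] == "localize_movie"

    def test_recall_on_separated_emitters(self, separated_movie):
        """>= 95% of bright (>= 1000 photon) events recovered within 50 nm,
        via Hungarian assignment gated at 100 nm."""
        from scipy.optimize import linear_sum_assignment
        field, mov = separated_movie
        table = localize_movie(mov)
        ev = []
        for b in range(field.n_blinks):
            if field.blink_photons[b] < 1000:
                continue
            e = field.blink_emitter[b]
            for k in range(field.blink_duration[b]):
                ev.append((field.blink_start[b] + k, *field.emitter_xy[e]))
        ev = np.array(ev)
        df = table.df
        matched = 0
        for f in np.unique(ev[:, 0]).astype(int):
            T = ev[ev[:, 0] == f][:, 1:]
            L = df[df.frame == f][["x_nm", "y_nm"]].to_numpy()
            if len(L) == 0:
                continue
            D = np.linalg.norm(T[:, None, :] - L[None, :, :], axis=2)
            ri, ci = linear_sum_assignment(D)
            matched += sum(D[a, b2] <= 50.0 for a, b2 in zip(ri, ci)
                           if D[a, b2] <= 100.0)
        assert matched / len(ev) >= 0.95

    def test_integer_pixel_shift_equivariance(self, separated_movie):
        field, mov = separated_movie
        sub = Movie(mov.frames[:40], mov.acquisition)
        shifted = Movie(np.roll(sub.frames, (2, 3), axis=(1, 2)),
                        mov.acquisition)
        t0 = localize_movie(sub)
        t1 = localize_movie(shifted)
        px = mov.acquisition.pixel_size_nm
        # match rows by frame and shifted position (drop edge-affected ones)
        a = t0.df.assign(x=t0.df.x_nm + 3 * px, y=t0.df.y_nm + 2 * px)
        hits = 0
        for row in a.itertuples():
            cand = t1.df[t1.df.frame == row.frame]
            if len(cand) == 0:
                continue
            d = np.hypot(cand.x_nm - row.x, cand.y_nm - row.y)
            if d.min() < 1.0:
                hits += 1
        assert hits >= 0.9 * len(a)

    def test_hdf5_roundtrip_bitwise(self, separated_movie, tmp_path):
        _, mov = separated_movie
        table = localize_movie(Movie(mov.frames[:30], mov.acquisition))
        path = tmp_path / "locs.hdf5"
        table.to_hdf5(path)
        back = sq.LocalizationTable.from_hdf5(path)
        assert back.pixel_size_nm == table.pixel_size_nm
        assert back.n_frames == table.n_frames
        assert back.provenance == table.provenance
        for col in table.df.columns:
            # position columns pass through a pixel-unit conversion, so
            # equality holds to float round-off rather than bitwise
            np.testing.assert_allclose(back.df[col].to_numpy(),
                                       table.df[col].to_numpy(),
                                       rtol=1e-12, err_msg=col)

    def test_hdf5_positions_stored_in_pixels(self, tmp_path):
        import h5py
        from tests.conftest import make_simple_table
        t = make_simple_table([[242.0, 121.0]], [0])
        p = tmp_path / "t.hdf5"
        t.to_hdf5(p)
        with h5py.File(p) as f:
            assert f["locs/x"][0] == pytest.approx(2.0)
            assert f["locs/y"][0] == pytest.approx(1.0)
            assert f.attrs["pixel_size_nm"] == 121.0
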