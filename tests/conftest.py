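import numpy as np
import pytest

import stormquant as sq


@pytest.fixture(scope="session")
def imdc_fixture():
    """Medium immature-DC-like field + bypass table, shared across tests."""
    return sq.make_fixture("imdc", seed=101, width_um=6.0, height_um=6.0)


@pytest.fixture(scope="session")
def imdc_analysis(imdc_fixture):
    field, table = imdc_fixture
    cfg = sq.AnalysisConfig(drift_method="none")
    res = sq.run_analyze(table, cfg, truth=field,
                         region_mask=field.geometry.cell_mask,
                         region_bin_nm=field.geometry.bin_nm)
    return field, table, res


@pytest.fixture(scope="session")
def repeated_emitter_table():
    """Sparse immobile emitters re-localized over consecutive frames with the
    default 12.1 nm per-axis error; the substrate for precision estimation."""
    geom = sq.rect_geometry(10, 10)
    kin = sq.BlinkKinetics(mean_on_frames=3.0, flickers_per_burst_mean=2.0)
    field = sq.generate_field(geom, 0.0, 62.3, background_per_um2=6.0,
                              kinetics=kin, seed=11)
    field = sq.sample_blinks(field, kin, seed=12)
    return sq.emit_localization_table(field, sigma_loc_nm=12.1, seed=13)


def make_simple_table(xy, frames, pixel_size_nm=121.0, n_frames=None, **extra):
    """Minimal localization table around explicit positions/frames."""
    import pandas as pd
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    frames = np.asarray(frames, dtype=int)
    n = len(xy)
    df = pd.DataFrame({
        "frame": frames,
        "x_nm": xy[:, 0], "y_nm": xy[:, 1],
        "sx_nm": np.full(n, 121.0), "sy_nm": np.full(n, 121.0),
        "photons": np.full(n, 1000.0), "bg": np.full(n, 10.0),
        "lpx_nm": np.full(n, 12.1), "lpy_nm": np.full(n, 12.1),
        "net_gradient": np.full(n, 6000.0),
    })
    for k, v in extra.items():
        df[k] = v
    return sq.LocalizationTable(df, pixel_size_nm, n_frames=n_frames)
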