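# stormquant

Quantitative dSTORM analysis of membrane-protein nano-assemblies, from
raw blinking movies (or localization tables) to per-region cluster
densities and diameters — built for the study design in which MHC class I
peptide-loading complexes (PLC, labeled via TAP1) are counted and sized
in immature dendritic cells and in the soma and tip regions of mature
dendritic cells.

The pipeline reproduces the standard single-color dSTORM chain:

- spot detection by **net gradient** (threshold 5000) and elliptical 2D
  Gaussian fitting by **Poisson maximum likelihood**, with per-event
  precision from the Cramér–Rao bound;
- **drift correction** by redundant cross-correlation (1000-frame
  windows) or fiducial beads;
- **PSF-shape filtering** (σ within 48.4–193.6 nm);
- **NeNA precision estimation** from consecutive-frame nearest-neighbor
  distances, p(d) = A·d/(2σ²)·e^(−d²/4σ²) + B·d;
- **spatiotemporal linking** of repeated emissions (radius 6×σ, e.g.
  72.6 nm at the 12.1 nm experimental precision, 2 dark frames);
- **DBSCAN with data-adaptive parameters**: observation radius
  ε = 2×σ (typically 22–35 nm) and min_pts = median − MAD of the
  localization counts in annotated + "pick similar" (1.5 SD) picks
  (typically 20–80);
- cluster **center-of-mass density maps**, cell outlines, signals/µm²
  per region, diameters (2√2 × radius of gyration), nearest-neighbor
  spacings;
- **Kruskal–Wallis with Dunn's correction** across conditions.

Since no raw data of the emulated experiment are deposited, the package
includes a first-class synthetic-acquisition module (`stormquant.simulate`)
producing camera movies or localization tables with complete ground truth
— clustered emitters with antibody-linker displacement, burst-like
photoswitching under a stepwise 405 nm activation ramp, stage drift,
camera noise — so every stage is validated by ground-truth recovery.
See `docs/methods.md` for the model and its calibration.

## Worked example

```bash
python examples/simulate_and_cluster.py
```

```
planted: 446 clusters (17.84 /um^2), truth diameter 76.5 nm, 110647 localizations over 30000 frames
estimated precision: 12.06 nm (table generated at 12.1 nm)
adaptive DBSCAN parameters: eps = 24.1 nm (2x precision), min_pts = 21 (median - MAD of linked-signal picks)
recovered: 460 signals / 25.0 um^2 = 18.40 /um^2
mean measured diameter: 79.0 nm
mean nearest-neighbor signal spacing: 163 nm
```

A 5×5 µm mature-DC-tip-like cell is planted at 17 clusters/µm² with a
76.5 nm true assembly diameter; after linker (2 × 10 nm) and precision
(12.1 nm) broadening the expected measured diameter is ~87 nm.  The chain
re-estimates the precision from the data, derives ε and min_pts from it
and from annotated picks, and recovers the planted density within the
seed's Poisson fluctuation and a diameter a few percent below the
broadened expectation (cluster-tail truncation by DBSCAN; quantified in
`docs/methods.md`).

Other examples: `localize_movie.py` (camera movie → localization table),
`drift_correction.py` (600 nm injected drift recovered at ~2 nm RMS),
`group_statistics.py` (Kruskal–Wallis + Dunn across the three
conditions).

A thin CLI mirrors the library for shell use:

```bash
stormquant simulate --fixture mdc_tip --seed 1 --out fixtures/
stormquant run-all fixtures/mdc_tip_locs.hdf5 --drift none --out analysis/
stormquant stats densities.csv
```

Localization tables are Picasso-compatible HDF5 (pixel-unit positions,
pixel size in attributes), so third-party SMLM viewers can open them.

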