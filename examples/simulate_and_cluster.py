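"""Plant a known nanocluster field, run the full analysis chain, and
compare recovered density and diameter to the planted truth.

The fixture emulates the mature-DC "tip" condition: 17 clusters/um^2 of
assemblies whose physical diameter, after antibody-linker and
localization-precision broadening, measures ~87 nm.
"""

import stormquant as sq

field, table = sq.make_fixture("mdc_tip", seed=7, width_um=5.0, height_um=5.0)
print(f"planted: {field.n_clusters} clusters "
      f"({field.cluster_density_per_um2():.2f} /um^2), "
      f"truth diameter {field.cluster_diameter_nm.mean():.1f} nm, "
      f"{len(table)} localizations over {field.acquisition.n_frames} frames")

res = sq.run_analyze(table, sq.AnalysisConfig(drift_method="none"),
                     truth=field,
                     region_mask=field.geometry.cell_mask,
                     region_bin_nm=field.geometry.bin_nm)

print(f"estimated precision: {res.precision.sigma_loc_nm:.2f} nm "
      f"(table generated at 12.1 nm)")
print(f"adaptive DBSCAN parameters: eps = {res.cluster_params.epsilon_nm:.1f} nm "
      f"(2x precision), min_pts = {res.cluster_params.min_pts} "
      f"(median - MAD of linked-signal picks)")
d = res.densities[0]
print(f"recovered: {d.n_signals} signals / {d.area_um2:.1f} um^2 "
      f"= {d.density_per_um2:.2f} /um^2")
print(f"mean measured diameter: "
      f"{res.clusters.records.diameter_nm.mean():.1f} nm")
print(f"mean nearest-neighbor signal spacing: "
      f"{res.nn_summary['mean_nm']:.0f} nm")
print("\nDensity should land near the planted 17.0 /um^2 and the diameter "
      "near 87 nm;\nthe spacing reflects the 150 nm hard-core placement of "
      "the assemblies.")
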