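"""Compare per-cell signal densities across three conditions with the
Kruskal-Wallis test and Dunn's corrected pairwise comparisons.

Eight simulated cells per condition at the published operating densities
(immature DC 4.9, mature-DC soma 10.8, mature-DC tip 17.0 signals/um^2).
"""

from stormquant import benchmarks as bm
from stormquant.stats import GroupSample, group_report

groups = []
for name, label in (("imdc", "imDC"), ("mdc_soma", "mDC soma"),
                    ("mdc_tip", "mDC tip")):
    out = bm.recover_fixture_density(name, seed=21, n_cells=8, cell_um=4.0)
    groups.append(GroupSample(label, out["per_cell"]))
    print(f"{label}: mean {out['mean_density_per_um2']:.2f} "
          f"+- {out['sem_density_per_um2']:.2f} signals/um^2 "
          f"(planted {out['planted_density_per_um2']})")

print()
print(group_report(groups))
print("\nThe omnibus test and the extreme pair (imDC vs tip) should be "
      "highly significant.\nAdjacent pairs max out at |z| ~ 2.3 with n = 8 "
      "per group even under perfect\nseparation -- a known ceiling of "
      "rank-based pairwise tests at this sample size.")
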