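"""Inject slow linear stage drift and recover it by redundant
cross-correlation (RCC) over 1000-frame blocks.

0.02 nm per frame accumulates to 600 nm across 30,000 frames -- far more
than a cluster diameter; without correction every cluster smears into a
streak.  RCC needs no fiducials: it aligns rendered histograms of
temporal blocks against each other.
"""

from stormquant import benchmarks as bm

out = bm.recover_linear_drift(seed=11, rate_nm_per_frame=0.02)
print(f"injected drift: {out['rate_nm_per_frame']} nm/frame (600 nm total)")
print(f"RCC trace error: {out['rms_error_nm']:.2f} nm RMS "
      f"(max {out['max_error_nm']:.2f} nm)")
print(f"re-estimated drift after correction: "
      f"{out['residual_rms_nm']:.2f} nm RMS")
print("\nThe RMS error should be ~2-3 nm, i.e. well below the 12.1 nm "
      "localization precision,\nand the residual after correction should "
      "be consistent with zero drift.")
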