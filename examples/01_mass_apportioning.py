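"""Convert measured viral DNA masses into genome-copy abundance intervals.

Loads the packaged three-horizon sediment measurement table (direct counts,
ssDNA/dsDNA mass concentrations) and derives the full report: abundance
intervals under the 1.8-24.9 kb ssDNA / 50 kb dsDNA genome-size assumptions,
the relative ssDNA share of the DNA virosphere, the virus-to-cell ratio, and
the fold difference against direct microscopy counts.
"""

from viromass import build_report, tohoku_samples

report = build_report(tohoku_samples())
print(report.to_frame(rounded=True).to_string(index=False))

lo, hi = report.relative_ss_envelope()
print(f"\nrelative ssDNA abundance across depths: {lo:.1f}-{hi:.1f}%")
print(f"max fold over direct counts (conservative lower bound): "
      f"{report.max_fold_vs_direct():.0f}x")
print(
    "\nReading: ss_copies_[low,high] bracket the ssDNA genome copies/cm^3 "
    "between the large- and small-genome assumptions; even the lower bound "
    "dwarfs the direct virus count at depth, showing how fluorescence "
    "counting misses small ssDNA virions."
)
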