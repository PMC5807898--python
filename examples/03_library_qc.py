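"""Screen virome libraries against the rRNA contamination criterion.

Uses the packaged six-library summary table (read totals, lengths, GC, rRNA-
associated read counts): a clean virome carries < 0.02% rRNA reads.
"""

from viromass import qc_evaluate, tohoku_library_table

print(f"{'library':>10} {'reads':>9} {'GC%':>5} {'rRNA':>4} {'ratio%':>8} pass")
for summary, n_rrna in tohoku_library_table():
    result = qc_evaluate(summary, n_rrna, threshold_percent=0.02)
    print(
        f"{summary.library_id:>10} {summary.n_reads:>9} "
        f"{summary.gc_percent:>5.1f} {n_rrna:>4} {result.ratio_display:>8} "
        f"{'yes' if result.passed else 'NO'}"
    )
print(
    "\nReading: at most 1 rRNA read per library (<= 0.0002% of total reads), "
    "two orders of magnitude below the 0.02% criterion — the viral fractions "
    "are essentially free of cellular contamination."
)
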