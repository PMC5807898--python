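"""Profile a virome library from BLAST tabular hits by LCA assignment.

Builds a tiny in-memory hit table against the packaged viral family registry,
assigns each read to the deepest taxon shared by its retained hits, and
aggregates a family-level composition with minor families collapsed.
"""

import io

from viromass import assign_reads, build_profile, collapse_minor, default_taxonomy, parse_blast_tab

tree = default_taxonomy()

# qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore
hits_text = """\
read1	Microviridae	92.1	80	6	0	1	80	1	80	1e-20	120
read1	Circoviridae	88.0	75	9	0	1	75	1	75	1e-18	115
read2	Circoviridae	95.0	82	4	0	1	82	1	82	1e-25	140
read3	Siphoviridae	90.0	78	8	0	1	78	1	78	1e-18	115
read4	Microviridae	91.0	80	7	0	1	80	1	80	1e-19	118
read5	Microviridae	89.5	79	8	0	1	79	1	79	2e-3	60
"""

parsed = parse_blast_tab(io.StringIO(hits_text))
assignments = assign_reads(parsed.hits, tree)  # E-value < 1e-5, LCA top-10%
for a in assignments:
    print(f"{a.query_id}: {a.assigned_taxon} (from {a.n_hits_used} hit(s))")

profile = build_profile(assignments, tree, scheme="family", library_id="demo")
print("\n" + collapse_minor(profile, 2.0, tree).to_frame().to_string(index=False))
print(
    "\nReading: read1's two ssDNA-family hits tie within the top-10% bit-score "
    "window, so it climbs to their common 'ssDNA viruses' ancestor; read5's "
    "E-value fails the < 1e-5 cutoff and the read is not assigned."
)
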