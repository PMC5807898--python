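# Methods

## The mass-apportioning estimator

A virion of genome length `L` kb carries `m(L) = L·1000·M/N_A` grams of DNA,
with `M = 331.2 g/mol` per ssDNA nucleotide and `M = 662.4 g/mol` per dsDNA
base pair (`N_A = 6.022×10²³ /mol`).  These working molecular weights are
chosen so that the reference per-virion masses come out at their commonly
cited values — 9.90×10⁻¹⁹ g for a 1.8 kb ssDNA genome, 1.37×10⁻¹⁷ g for
24.9 kb ssDNA, 5.5×10⁻¹⁷ g for 50 kb dsDNA — rather than the textbook
330/660 g/mol convention; the difference is 0.4% and the constants are
configurable, with the dsDNA-equals-twice-ssDNA relation enforced.

A bulk fluorometric mass concentration `C` (ng/cm³ sediment) then converts
to genome copies as `V = C·10⁻⁹/m(L)`.  The estimator's assumptions:

- **All measured DNA is encapsidated viral genome.**  DNase treatment of the
  viral fraction upstream is taken at face value; no extraction-efficiency
  or free-DNA correction is applied.
- **One genome per particle**, so genome copies ≈ particles.
- **The genome-size envelope brackets the community.**  The ssDNA default
  envelope is 1.8–24.9 kb (the span of recognized ssDNA viral family genome
  sizes); evaluating `V` at both ends yields the interval
  `[C/m(L_max), C/m(L_min)]`.  The registry treats this envelope as a
  community-level assumption, with per-family ranges (e.g. Circoviridae
  1.8–2.1 kb, Microviridae 4.4–6.1 kb) as refinements.  dsDNA uses a 50 kb
  point assumption by default — a long-standing average for tailed-phage-
  dominated communities — though the interface accepts a range.

Derived quantities: relative ssDNA abundance
`R = 100·V_ss/(V_ss+V_ds)` is reported as an interval with the conservative
pairing (ssDNA lower bound against dsDNA upper bound, and vice versa); with
a point dsDNA estimate this reduces to evaluating `R` at the two ssDNA
bounds.  VCR is the direct viral count over the direct cell count; the
standard deviations on both counts are carried as annotations only, with no
error propagation (none is standard for this ratio).  The fold-vs-direct
interval divides the abundance interval by the direct viral count; values
below 1 are legal and flagged.

Display rounding follows the field's table conventions — two significant
figures for copies, two decimals for VCR, one decimal for percentages, one
significant figure for contamination ratios — and is display-only; unrounded
values are always retained.  Recomputing derived columns from *printed*
(already-rounded) inputs can land one unit off in the last printed digit of
a published table; the report therefore keeps unrounded values first-class,
and the tests treat such cells with a correspondingly widened check.

## Taxonomy registry

A small rooted tree (TSV: name, rank, parent, na_type, genome size range)
with exactly one root, validated for duplicate names, missing parents and
cycles.  Ranks outside {root, superkingdom, order, family, genus, species}
coerce to "other" rather than erroring.  Genome-size and nucleic-acid-type
lookups walk up the ancestor chain to the nearest annotation.  The packaged
registry covers the families commonly observed in marine sediment viromes;
it is a curated default, not an NCBI taxonomy ingest, and users can supply
their own TSV.

## LCA profiling

Hit retention per read: E-value strictly below 10⁻⁵ (the strict inequality
matters at the boundary), bit score ≥ 50, and bit score within 10% of the
read's best retained hit (MEGAN-style defaults; all exposed as parameters).
Subjects are resolved to taxa through an explicit two-column map —
description-line parsing is dialect-fragile — and unresolvable subjects are
skipped with a warning count.  The read is placed at the deepest node shared
by all retained hits' root paths; in a tree the common ancestors form a
chain, so the placement is unique, and tied best bit scores simply retain
all tied hits.  An independent oracle (intersect full ancestor *sets*, take
the deepest member) backs the implementation in randomized property tests.

Profiles map assigned reads to categories by ancestor walk (family scheme
falls back to the assigned node's own name for placements above family
rank), count unassigned reads separately, and conserve totals exactly.
Minor-category collapsing merges viral categories strictly below a
percent-of-viral-reads threshold into "other ssDNA viruses" / "other dsDNA
viruses" / "others" bins by nucleic-acid type.

## QC

GC content is computed over unambiguous A/C/G/T only (ambiguity codes are
excluded from numerator and denominator).  The rRNA criterion is a strict
`ratio < threshold` with a 0.02% default; a zero threshold is accepted but
warned about, since it can never pass.  rRNA read identification is
upstream of this package; counts are inputs.

## Ordination

Input rows are relative abundances of the identified viral fraction (counts
over viral reads, structural zeros for absent categories); no transform is
applied by default, matching common practice for virome family profiles,
with an optional Hellinger (√p) transform for strongly skewed compositions.
PCA is computed by SVD on the column-centered matrix; components are sign-
fixed by making each component's largest-magnitude loading positive, so
score signs are reproducible.  Projection of new samples applies the fitted
means (and transform); categories unknown to the model are dropped with a
warning, missing ones zero-filled.  A degenerate all-rows-equal matrix
yields zero scores and zero explained-variance fractions rather than NaNs.
The choice of family-level proportions as the ordination input is a
documented assumption; rank and transform are caller-controlled.

## Synthetic communities

`SimulationConfig` defaults describe a "tohoku-like" study condition:

| parameter | default | meaning |
|---|---|---|
| n_ss_families / n_ds_families | 5 / 3 | community richness at family level |
| ss_abundance_mu / ds_abundance_mu | 17.4 / 13.7 | ln-scale lognormal means per family, chosen so median simulated masses land at ~2 ng/cm³ ssDNA and ~0.3 ng/cm³ dsDNA and direct counts at 10⁵–10⁷/cm³ |
| abundance_sigma | 1.0 | lognormal spread (an order-of-magnitude scatter across families) |
| ss_genome_kb_range / ds_genome_kb | 1.8–24.9 / 50 | genome sizes; ssDNA drawn uniformly in the envelope |
| mass_noise_cv | 0.1 | multiplicative lognormal, unit mean — typical fluorometric repeatability |
| mda_ss_bias | 10 | MDA preferential amplification of circular ssDNA templates (qualitative placeholder; the true magnitude is unknown) |
| s1_carryover_f | 0.05 | fraction of ssDNA mass surviving S1 digestion into the dsDNA channel (placeholder, as above) |
| stain_efficiency_ss / ds | 0.005 / 0.9 | detection probabilities in direct counts; the ssDNA value puts the truth/direct-count fold in the observed tens-to-hundreds regime |
| read_depth | 20 000 | multinomial reads per library |
| no_hit_fraction | 0.8 | reads with no database similarity, matching the >80% "unknown" fraction typical of sediment viromes |

Forward models: masses are the exact inverse of the estimator
(`C = Σ V_i·m(L_i)` plus noise), with carryover *added* to the dsDNA channel
without depleting the ssDNA channel — the two measurements come from
separate aliquots of the viral fraction, so incomplete S1 digestion
contaminates one without reducing the other.  Read weights are
`V_i·L_i·(bias if ssDNA)`; in the dsDNA library ssDNA families additionally
carry the carryover factor (and keep the MDA bias, since the dsDNA fraction
is also whole-genome amplified and surviving circular ssDNA is preferentially
amplified there too).  Direct counts are Poisson around the
efficiency-weighted community total; cells are an independent lognormal.
Hit tables give each non-"no-hit" read a best hit on its true family plus
0–4 decoys at 50–85% of the best bit score — below the top-10% retention
window, so profiling errors come from filtering, not from engineered
ambiguity — with some decoy E-values above 10⁻⁵ to exercise the filter.

All draws derive from a single root seed through fixed `SeedSequence` spawn
keys (community=0, masses=1, reads=2, counts=3, hits=4, fasta=5), so each
operation is independently bit-reproducible and new operations cannot
perturb existing streams.  Multi-sample studies derive per-sample seeds
arithmetically (`seed + 7919·(i+1) mod 2³¹`).

**What the generator does not emulate:** real sequences (reads are random
nucleotides; hit tables are synthesized, not aligned), database
incompleteness structure (the no-hit process is uniform, not
lineage-dependent), extraction-efficiency losses, within-family genome-size
variation, and spatial/depth autocorrelation between samples.  Passing
recovery tests therefore demonstrates correctness of the *inference chain*
under the stated statistical assumptions, not robustness to every bias of
real sediment viromes.

## Numerical and design notes

- Abundance intervals at zero mass are `[0, 0]`; relative-abundance bounds
  with a vanishing numerator and denominator pin to the vacuous extreme
  (0 for the lower, 100 for the upper bound), and the fully-zero case raises
  a named error.
- Interval containment and estimator recovery: with noise-free masses and a
  degenerate size range at the true genome size the inversion is exact to
  floating-point; with 10% noise the envelope interval (spanning a factor
  13.8 in genome size) contains the truth essentially always — failure
  would require the abundance-weighted mean genome size to sit at an extreme
  of the envelope *and* a multi-sigma noise draw.
- Problem sizes in the test and acceptance runs (200 estimator replicates,
  ≥1000 randomized LCA instances, 10⁴-read recovery libraries, 5×4
  ordination matrices) were chosen as the smallest sizes at which the
  checked statistics are stable; the full suite runs in seconds.
- The pipeline writes a manifest with SHA-256 digests of every artifact and
  no timestamps, making reruns byte-comparable.
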