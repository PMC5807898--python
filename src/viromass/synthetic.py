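"""Synthetic benthic viral communities and their simulated observations.

The generator emulates the measurement chain of a sediment virome study so
that every analysis stage can be exercised against known ground truth:

* a mixed community of small-genome ssDNA families (drawn within an assumed
  1.8–24.9 kb envelope) and ~50 kb dsDNA families, with log-normally
  distributed per-family particle abundances;
* fluorometric ssDNA/dsDNA mass measurements — the exact forward model of the
  mass-apportioning estimator (C = sum_i V_i * m_i), with multiplicative
  log-normal noise at a configurable CV and a configurable fraction of ssDNA
  mass leaking into the dsDNA channel (incomplete S1 nuclease digestion);
* multinomially sampled read profiles per library, with a multiplicative MDA
  amplification bias favouring ssDNA templates;
* epifluorescence direct counts with stain-dependent detection efficiencies
  (severely below one for small ssDNA virions) and Poisson sampling;
* BLAST-style tabular hit tables with decoy hits and a configurable no-hit
  fraction, for end-to-end profiler tests;
* plain FASTA read libraries with known length and GC bookkeeping for QC.

Randomness contract: every ``simulate_*`` operation derives its own
independent stream from the single root seed via fixed ``SeedSequence`` spawn
keys, so outputs are bit-for-bit reproducible per operation and adding a new
operation never perturbs existing ones.  Per-sample seeds in multi-sample
studies are derived arithmetically from the root seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .apportion import DirectCounts, DnaMassMeasurement, virion_dna_mass
from .constants import DEFAULT_CONSTANTS, Constants, NucleicAcidType
from .profiler import TaxonomicProfile
from .taxonomy import GenomeSizeRange, TaxonomyTree, build_taxonomy

# SeedSequence spawn keys, one per operation (documented stream-splitting order)
_STREAM_COMMUNITY = 0
_STREAM_MASSES = 1
_STREAM_READS = 2
_STREAM_COUNTS = 3
_STREAM_HITS = 4
_STREAM_FASTA = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one synthetic community and its observations.

    Defaults are "tohoku-like": they target the magnitudes measured in upper
    bathyal sediment — ssDNA masses of a few ng/cm^3, dsDNA masses an order of
    magnitude lower, direct counts of 10^5–10^7 per cm^3 — with an
    ssDNA-dominated community.  MDA bias and S1 carryover magnitudes are
    placeholders for sensitivity analysis; the real values are unknown.
    """

    seed: int = 0
    n_ss_families: int = 5
    n_ds_families: int = 3
    ss_abundance_mu: float = 17.4  # ln(copies/cm^3) per ssDNA family
    ds_abundance_mu: float = 13.7  # ln(copies/cm^3) per dsDNA family
    abundance_sigma: float = 1.0  # log-scale spread shared by both types
    ss_genome_kb_range: GenomeSizeRange = field(
        default_factory=lambda: GenomeSizeRange(1.8, 24.9)
    )
    ds_genome_kb: float = 50.0
    mass_noise_cv: float = 0.1
    mda_ss_bias: float = 10.0  # multiplicative amplification factor >= 1
    s1_carryover_f: float = 0.05  # fraction of ssDNA mass surviving into dsDNA channel
    stain_efficiency_ss: float = 0.005  # detection probability in direct counts
    stain_efficiency_ds: float = 0.9
    read_depth: int = 20000
    cells_mean: float = 5.0e6  # cells/cm^3
    cells_sigma: float = 0.5  # log-scale spread of the cell count draw
    no_hit_fraction: float = 0.8  # reads with no database similarity
    max_decoy_hits: int = 4

    def __post_init__(self) -> None:
        if self.n_ss_families < 0 or self.n_ds_families < 0:
            raise ValueError("family counts must be >= 0")
        if self.mass_noise_cv < 0:
            raise ValueError("mass_noise_cv must be >= 0")
        if self.mda_ss_bias < 1:
            raise ValueError("mda_ss_bias must be >= 1")
        for name in ("s1_carryover_f", "stain_efficiency_ss", "stain_efficiency_ds",
                     "no_hit_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be within [0, 1]")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be > 0")
        if self.ds_genome_kb <= 0:
            raise ValueError("ds_genome_kb must be > 0")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class FamilyTruth:
    name: str
    na_type: NucleicAcidType
    genome_kb: float
    abundance: float  # true particle (genome-copy) abundance, copies/cm^3


@dataclass(frozen=True)
class GroundTruth:
    """True state of a synthetic community."""

    families: tuple[FamilyTruth, ...]

    def __post_init__(self) -> None:
        if any(f.abundance < 0 for f in self.families):
            raise ValueError("abundances must be >= 0")

    def total(self, na_type: Optional[NucleicAcidType] = None) -> float:
        return sum(
            f.abundance
            for f in self.families
            if na_type is None or f.na_type is na_type
        )

    def true_mass_ng(
        self,
        na_type: NucleicAcidType,
        constants: Constants = DEFAULT_CONSTANTS,
    ) -> float:
        """Noise-free bulk DNA mass of one strandedness fraction, ng/cm^3."""
        return sum(
            f.abundance * virion_dna_mass(f.genome_kb, f.na_type, constants) * 1e9
            for f in self.families
            if f.na_type is na_type
        )

    def taxonomy(self) -> TaxonomyTree:
        """Minimal taxonomy covering the synthetic families."""
        records = [
            {"name": "root", "rank": "root", "parent": ""},
            {"name": "Viruses", "rank": "superkingdom", "parent": "root"},
            {"name": "ssDNA viruses", "rank": "other", "parent": "Viruses",
             "na_type": "ssDNA"},
            {"name": "dsDNA viruses", "rank": "other", "parent": "Viruses",
             "na_type": "dsDNA"},
        ]
        for f in self.families:
            records.append(
                {
                    "name": f.name,
                    "rank": "family",
                    "parent": f"{f.na_type.value} viruses",
                    "na_type": f.na_type.value,
                    "genome_min_kb": f.genome_kb,
                    "genome_max_kb": f.genome_kb,
                }
            )
        return build_taxonomy(records)

    def to_json(self, path: Optional[Path | str] = None) -> str:
        payload = [
            {
                "name": f.name,
                "na_type": f.na_type.value,
                "genome_kb": f.genome_kb,
                "abundance": f.abundance,
            }
            for f in self.families
        ]
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(
            tuple(
                FamilyTruth(
                    name=rec["name"],
                    na_type=NucleicAcidType.coerce(rec["na_type"]),
                    genome_kb=float(rec["genome_kb"]),
                    abundance=float(rec["abundance"]),
                )
                for rec in json.loads(text)
            )
        )


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_community(config: SimulationConfig) -> GroundTruth:
    """Draw a community: per-family abundances log-normal, ssDNA genome sizes
    uniform within the assumed envelope, dsDNA genomes at the point value."""
    rng = _rng(config, _STREAM_COMMUNITY)
    families: list[FamilyTruth] = []
    for i in range(config.n_ss_families):
        kb = rng.uniform(config.ss_genome_kb_range.min_kb, config.ss_genome_kb_range.max_kb)
        v = rng.lognormal(config.ss_abundance_mu, config.abundance_sigma)
        families.append(
            FamilyTruth(f"ssfam_{i + 1:02d}", NucleicAcidType.SSDNA, float(kb), float(v))
        )
    for i in range(config.n_ds_families):
        v = rng.lognormal(config.ds_abundance_mu, config.abundance_sigma)
        families.append(
            FamilyTruth(
                f"dsfam_{i + 1:02d}", NucleicAcidType.DSDNA, config.ds_genome_kb, float(v)
            )
        )
    return GroundTruth(tuple(families))


def simulate_dna_masses(
    truth: GroundTruth,
    config: SimulationConfig,
    constants: Constants = DEFAULT_CONSTANTS,
) -> tuple[DnaMassMeasurement, DnaMassMeasurement]:
    """Forward model of the two fluorometric channel measurements (ng/cm^3).

    The ssDNA channel measures the true ssDNA mass; the dsDNA channel measures
    the true dsDNA mass plus the S1-carryover fraction ``f`` of the ssDNA
    mass (the two channels are prepared from separate aliquots, so carryover
    adds to the dsDNA channel without depleting the ssDNA one).  Noise is
    multiplicative log-normal with mean one at the configured CV; ``cv=0``
    gives noise-free measurements.
    """
    rng = _rng(config, _STREAM_MASSES)
    ss_true = truth.true_mass_ng(NucleicAcidType.SSDNA, constants)
    ds_true = truth.true_mass_ng(NucleicAcidType.DSDNA, constants)
    ss_channel = ss_true
    ds_channel = ds_true + config.s1_carryover_f * ss_true
    if config.mass_noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(config.mass_noise_cv**2)))
        mu = -0.5 * sigma**2  # unit-mean noise
        ss_channel *= rng.lognormal(mu, sigma)
        ds_channel *= rng.lognormal(mu, sigma)
    return (
        DnaMassMeasurement(NucleicAcidType.SSDNA, float(ss_channel)),
        DnaMassMeasurement(NucleicAcidType.DSDNA, float(ds_channel)),
    )


def library_read_weights(
    truth: GroundTruth, config: SimulationConfig, library: NucleicAcidType
) -> dict[str, float]:
    """Expected (unnormalized) per-family read weights for one library.

    A family contributes reads in proportion to particle abundance times
    genome length; ssDNA templates get the MDA amplification factor.  In the
    dsDNA library, ssDNA families enter only through the S1-carryover
    fraction (and are still MDA-biased, being circular templates).
    """
    weights: dict[str, float] = {}
    for f in truth.families:
        w = f.abundance * f.genome_kb
        if f.na_type is NucleicAcidType.SSDNA:
            w *= config.mda_ss_bias
            if library is NucleicAcidType.DSDNA:
                w *= config.s1_carryover_f
        weights[f.name] = w
    return weights


def simulate_read_profiles(
    truth: GroundTruth, config: SimulationConfig
) -> dict[str, TaxonomicProfile]:
    """Multinomial per-family read counts for the ssDNA and dsDNA libraries,
    keyed by ``"ssDNA"``/``"dsDNA"``."""
    rng = _rng(config, _STREAM_READS)
    profiles: dict[str, TaxonomicProfile] = {}
    names = [f.name for f in truth.families]
    for library in (NucleicAcidType.SSDNA, NucleicAcidType.DSDNA):
        weights = library_read_weights(truth, config, library)
        w = np.array([weights[n] for n in names], dtype=float)
        total = w.sum()
        if total <= 0:
            counts = {}
        else:
            draw = rng.multinomial(config.read_depth, w / total)
            counts = {n: int(c) for n, c in zip(names, draw) if c > 0}
        profiles[library.value] = TaxonomicProfile(
            library_id=f"sim_{library.value}",
            counts=counts,
            total_reads=config.read_depth,
            viral_reads=sum(counts.values()),
        )
    return profiles


def simulate_direct_counts(
    truth: GroundTruth, config: SimulationConfig
) -> DirectCounts:
    """Stain-limited direct counts: expected particles are the efficiency-
    weighted community total, Poisson-sampled; cells are drawn log-normally
    around the configured magnitude."""
    rng = _rng(config, _STREAM_COUNTS)
    lam = (
        config.stain_efficiency_ss * truth.total(NucleicAcidType.SSDNA)
        + config.stain_efficiency_ds * truth.total(NucleicAcidType.DSDNA)
    )
    viral = float(rng.poisson(lam)) if lam > 0 else 0.0
    mu = np.log(config.cells_mean) - 0.5 * config.cells_sigma**2
    cells = float(rng.lognormal(mu, config.cells_sigma))
    return DirectCounts(
        viral_particles=viral,
        viral_sd=float(np.sqrt(lam)),
        cells=cells,
        cell_sd=cells * config.cells_sigma,
    )


def simulate_hit_table(
    profile: TaxonomicProfile,
    tree: TaxonomyTree,
    config: SimulationConfig,
) -> tuple[str, dict[str, Optional[str]]]:
    """BLAST 12-column tabular text for one library's reads, plus truth labels.

    Per read: with probability ``no_hit_fraction`` the read gets no lines
    (no database similarity; truth label None); otherwise the best hit lands
    on the true family and 0..max_decoy_hits decoys land on other taxa with
    bit scores 50–85% of the best, below the default top-percent retention
    window, so LCA assignment recovers the family whenever the best hit
    survives filtering.  Some decoys carry E-values above the standard 1e-5
    cutoff to exercise the filter.
    """
    rng = _rng(config, _STREAM_HITS)
    lines: list[str] = []
    labels: dict[str, Optional[str]] = {}
    decoy_pool = [n for n in tree.families()]
    read_no = 0
    for category in sorted(profile.counts):
        for _ in range(profile.counts[category]):
            read_no += 1
            qid = f"{profile.library_id}_read{read_no:06d}"
            if rng.random() < config.no_hit_fraction:
                labels[qid] = None
                continue
            labels[qid] = category
            best_bits = rng.uniform(80.0, 200.0)
            subjects = [(category, best_bits, 10.0 ** -rng.uniform(6.0, 30.0))]
            others = [t for t in decoy_pool if t != category]
            if others and config.max_decoy_hits > 0:
                for _ in range(rng.integers(0, config.max_decoy_hits + 1)):
                    decoy = others[rng.integers(0, len(others))]
                    subjects.append(
                        (
                            decoy,
                            best_bits * rng.uniform(0.50, 0.85),
                            10.0 ** -rng.uniform(3.0, 12.0),
                        )
                    )
            for subject, bits, evalue in subjects:
                length = int(max(30, rng.normal(80, 15)))
                pident = rng.uniform(60.0, 97.0)
                mismatch = int(length * (100.0 - pident) / 100.0)
                lines.append(
                    "\t".join(
                        [
                            qid,
                            subject,
                            f"{pident:.2f}",
                            str(length),
                            str(mismatch),
                            "0",
                            "1",
                            str(length),
                            "1",
                            str(length),
                            f"{evalue:.2e}",
                            f"{bits:.1f}",
                        ]
                    )
                )
    return "\n".join(lines) + ("\n" if lines else ""), labels


_BASES = np.array(list("ACGT"))


def simulate_fasta_reads(
    config: SimulationConfig,
    n_reads: int = 1000,
    mean_length: float = 230.0,
    sd_length: float = 30.0,
    gc_fraction: float = 0.5,
    library_id: str = "sim_reads",
) -> tuple[list[SeqRecord], dict[str, float]]:
    """Random read library plus the generator's own bookkeeping
    (exact n/mean length/GC of the emitted sequences) for summary checks."""
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    rng = _rng(config, _STREAM_FASTA)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    records: list[SeqRecord] = []
    total_bp = 0
    gc = 0
    for i in range(n_reads):
        length = int(max(50, rng.normal(mean_length, sd_length)))
        seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
        total_bp += length
        gc += seq.count("G") + seq.count("C")
        records.append(
            SeqRecord(Seq(seq), id=f"{library_id}_r{i + 1:06d}", description="")
        )
    bookkeeping = {
        "n_reads": float(n_reads),
        "mean_length": total_bp / n_reads,
        "total_length_mb": total_bp / 1e6,
        "gc_percent": 100.0 * gc / total_bp,
    }
    return records, bookkeeping


# ---------------------------------------------------------------------------
# multi-sample study emission
# ---------------------------------------------------------------------------

DEPTH_INTERVALS = ((0.0, 2.0), (5.0, 8.0), (10.0, 15.0))


def sample_config(config: SimulationConfig, index: int) -> SimulationConfig:
    """Per-sample config with an arithmetically derived seed (kept < 2^31)."""
    return dataclasses.replace(config, seed=(config.seed + 7919 * (index + 1)) % 2**31)


def write_simulation(
    config: SimulationConfig,
    out_dir: Path | str,
    n_samples: int = 3,
    fasta_reads_per_library: int = 500,
) -> dict:
    """Emit a complete synthetic study to ``out_dir``.

    Files: ``samples.tsv`` (apportion input), ``taxonomy.tsv``, per-sample
    ground truth JSON, and per-library profile TSVs, BLAST tabular hit tables,
    subject->taxon maps and FASTA read files.  Returns a manifest-style dict
    describing what was written.
    """
    from Bio import SeqIO

    from .apportion import SedimentSample, write_samples_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples: list[SedimentSample] = []
    emitted: dict = {"samples": [], "libraries": []}
    tree: Optional[TaxonomyTree] = None
    for i in range(min(n_samples, len(DEPTH_INTERVALS))):
        cfg = sample_config(config, i)
        truth = simulate_community(cfg)
        if tree is None:
            tree = truth.taxonomy()
            tree.to_tsv(out / "taxonomy.tsv")
        ss_mass, ds_mass = simulate_dna_masses(truth, cfg)
        counts = simulate_direct_counts(truth, cfg)
        top, bottom = DEPTH_INTERVALS[i]
        sid = f"sim{i + 1}_{top:g}-{bottom:g}"
        samples.append(
            SedimentSample(
                sample_id=sid,
                depth_top=top,
                depth_bottom=bottom,
                counts=counts,
                ss_mass=ss_mass,
                ds_mass=ds_mass,
            )
        )
        truth.to_json(out / f"truth_{sid}.json")
        emitted["samples"].append(sid)
        profiles = simulate_read_profiles(truth, cfg)
        for na_value, profile in profiles.items():
            lib_id = f"{sid}_{na_value}"
            profile = TaxonomicProfile(
                library_id=lib_id,
                counts=profile.counts,
                total_reads=profile.total_reads,
                viral_reads=profile.viral_reads,
            )
            profile.to_tsv(out / f"profile_{lib_id}.tsv")
            hit_text, _ = simulate_hit_table(profile, tree, cfg)
            (out / f"hits_{lib_id}.tsv").write_text(hit_text)
            with open(out / f"map_{lib_id}.tsv", "w") as mh:
                for fam in tree.families():
                    mh.write(f"{fam}\t{fam}\n")
            records, _ = simulate_fasta_reads(
                cfg, n_reads=fasta_reads_per_library, library_id=lib_id
            )
            SeqIO.write(records, out / f"reads_{lib_id}.fasta", "fasta")
            emitted["libraries"].append(lib_id)
    write_samples_tsv(samples, out / "samples.tsv")
    emitted["taxonomy"] = "taxonomy.tsv"
    emitted["samples_tsv"] = "samples.tsv"
    return emitted
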