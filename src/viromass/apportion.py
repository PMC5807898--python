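"""Mass apportioning: DNA mass concentrations to viral genome-copy abundances.

The estimator is deliberately simple.  A fluorometric measurement gives the
bulk concentration C (ng per cm^3 sediment) of viral ssDNA or dsDNA extracted
from a sediment horizon.  Dividing C by the DNA mass of a single virion —
``genome_kb * 1000 * mw_per_monomer / N_A`` grams — yields genome copies per
cm^3.  Because the community's true genome-size distribution is unknown, the
conversion is evaluated at both ends of an assumed genome-size envelope
(1.8–24.9 kb for ssDNA communities; a 50 kb point value for dsDNA), producing
an abundance *interval*: the small-genome assumption gives the upper bound,
the large-genome assumption the lower bound.

From the per-type intervals follow the derived community quantities: the
relative ssDNA abundance R = 100*V_ss/(V_ss+V_ds) (as a conservative interval,
pairing the ssDNA lower bound with the dsDNA upper bound and vice versa), the
virus-to-cell ratio from direct counts, and the fold-difference between the
mass-derived ssDNA abundance and the fluorescence-based direct virus count —
the quantity that exposes how badly direct counts miss small-genome ssDNA
virions.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from ._format import round_sig
from .constants import DEFAULT_CONSTANTS, Constants, NucleicAcidType
from .taxonomy import GenomeSizeRange

SAMPLES_COLUMNS = (
    "sample_id",
    "depth_top_cm",
    "depth_bottom_cm",
    "cells_per_cm3",
    "cells_sd",
    "viruses_per_cm3",
    "viruses_sd",
    "ssdna_ng_per_cm3",
    "dsdna_ng_per_cm3",
)

DEFAULT_SS_RANGE = GenomeSizeRange(1.8, 24.9)
DEFAULT_DS_SIZE_KB = 50.0


class ApportionError(ValueError):
    """Base class for apportioning failures."""


class UndefinedRelativeAbundanceError(ApportionError):
    """Both ssDNA and dsDNA abundance are zero."""


class ZeroCellCountError(ApportionError):
    pass


class ZeroDirectCountError(ApportionError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectCounts:
    """Epifluorescence direct counts for one sediment horizon (per cm^3).

    Standard deviations are annotations carried through to reports; they do
    not enter any derived quantity.  ``sd > mean`` is legal (observed in real
    deep horizons where counts approach the detection limit).
    """

    viral_particles: float
    viral_sd: float = 0.0
    cells: float = 0.0
    cell_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("viral_particles", "viral_sd", "cells", "cell_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DnaMassMeasurement:
    """Bulk viral DNA concentration of one strandedness fraction, ng/cm^3."""

    na_type: NucleicAcidType
    concentration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "na_type", NucleicAcidType.coerce(self.na_type))
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class SedimentSample:
    """One depth horizon's measured inputs."""

    sample_id: str
    depth_top: float  # cmbsf
    depth_bottom: float  # cmbsf
    counts: DirectCounts
    ss_mass: DnaMassMeasurement
    ds_mass: DnaMassMeasurement

    def __post_init__(self) -> None:
        if not self.depth_top < self.depth_bottom:
            raise ValueError("depth_top must be < depth_bottom")
        if self.ss_mass.na_type is not NucleicAcidType.SSDNA:
            raise ValueError("ss_mass must be the ssDNA measurement")
        if self.ds_mass.na_type is not NucleicAcidType.DSDNA:
            raise ValueError("ds_mass must be the dsDNA measurement")


@dataclass(frozen=True)
class AbundanceInterval:
    """Genome copies per cm^3 as [low, high] under a genome-size envelope.

    ``high`` corresponds to the minimum assumed genome size, ``low`` to the
    maximum.
    """

    low: float
    high: float
    size_assumption: GenomeSizeRange
    na_type: NucleicAcidType

    def __post_init__(self) -> None:
        if not (0 <= self.low <= self.high):
            raise ValueError(f"invalid interval [{self.low}, {self.high}]")

    @property
    def is_point(self) -> bool:
        return self.low == self.high

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def virion_dna_mass(
    genome_kb: float,
    na_type: NucleicAcidType | str,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """DNA mass of a single virion in grams.

    ``genome_kb`` is in kilobases (kilo-nucleotides for ssDNA, kilo-base-pairs
    for dsDNA).  The mass is linear in genome length, and a dsDNA genome of
    length L weighs exactly twice an ssDNA genome of length L.
    """
    if genome_kb <= 0:
        raise ValueError("genome size must be strictly positive")
    return genome_kb * 1000.0 * constants.mw_per_monomer(na_type) / constants.avogadro


def copies_interval(
    mass: DnaMassMeasurement,
    size_range: GenomeSizeRange,
    constants: Constants = DEFAULT_CONSTANTS,
) -> AbundanceInterval:
    """Convert a bulk DNA mass to a genome-copy abundance interval.

    ng are converted to grams (1e-9); a degenerate size range yields a point
    estimate, and zero mass yields [0, 0].
    """
    grams = mass.concentration * 1e-9
    high = grams / virion_dna_mass(size_range.min_kb, mass.na_type, constants)
    low = grams / virion_dna_mass(size_range.max_kb, mass.na_type, constants)
    return AbundanceInterval(low=low, high=high, size_assumption=size_range,
                             na_type=mass.na_type)


def relative_ssdna_percent(
    ss: AbundanceInterval, ds: AbundanceInterval
) -> tuple[float, float]:
    """Relative ssDNA abundance R = 100*V_ss/(V_ss+V_ds) as a percent interval.

    The conservative pairing evaluates the lower bound at (ss.low, ds.high)
    and the upper bound at (ss.high, ds.low); with a point dsDNA estimate this
    reduces to evaluating R at the two ssDNA bounds.  A bound whose numerator
    and denominator both vanish is pinned to the vacuous extreme (0 for the
    lower bound, 100 for the upper).
    """
    if ss.high == 0 and ds.high == 0:
        raise UndefinedRelativeAbundanceError(
            "relative ssDNA abundance undefined: both abundances are zero"
        )

    def bound(ss_k: float, ds_k: float, vacuous: float) -> float:
        denom = ss_k + ds_k
        if denom == 0:
            return vacuous
        return 100.0 * ss_k / denom

    low = bound(ss.low, ds.high, 0.0)
    high = bound(ss.high, ds.low, 100.0)
    return (low, high)


def vcr(counts: DirectCounts) -> float:
    """Virus-to-cell ratio from direct counts."""
    if counts.cells <= 0:
        raise ZeroCellCountError("cell count must be > 0 to form a VCR")
    return counts.viral_particles / counts.cells


def fold_vs_direct(
    est: AbundanceInterval, counts: DirectCounts
) -> tuple[float, float]:
    """Fold difference between the mass-derived abundance interval and the
    direct virus count: [est.low/count, est.high/count].  Values below 1
    (direct count exceeds the estimate) are valid and flagged in reports."""
    if counts.viral_particles <= 0:
        raise ZeroDirectCountError("direct viral count must be > 0")
    return (est.low / counts.viral_particles, est.high / counts.viral_particles)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

ROUNDING = {
    "copies": "2 significant figures",
    "vcr": "2 decimals",
    "percent": "1 decimal",
}


@dataclass(frozen=True)
class ApportionRow:
    sample: SedimentSample
    ss_copies: AbundanceInterval
    ds_copies: AbundanceInterval
    relative_ss_percent: tuple[float, float]
    vcr: float
    fold_vs_direct: tuple[float, float]

    @property
    def fold_below_one(self) -> bool:
        return self.fold_vs_direct[1] < 1.0


@dataclass(frozen=True)
class ApportionReport:
    """Per-sample derived quantities, ordered by depth, with display rounding
    metadata; unrounded values are retained for computation and testing."""

    rows: tuple[ApportionRow, ...]
    ss_range: GenomeSizeRange
    ds_range: GenomeSizeRange
    constants: Constants
    rounding: dict = field(default_factory=lambda: dict(ROUNDING))

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        records = []
        for row in self.rows:
            s = row.sample
            rec = {
                "sample_id": s.sample_id,
                "depth_top_cm": s.depth_top,
                "depth_bottom_cm": s.depth_bottom,
                "cells_per_cm3": s.counts.cells,
                "cells_sd": s.counts.cell_sd,
                "viruses_per_cm3": s.counts.viral_particles,
                "viruses_sd": s.counts.viral_sd,
                "ssdna_ng_per_cm3": s.ss_mass.concentration,
                "dsdna_ng_per_cm3": s.ds_mass.concentration,
                "vcr": row.vcr,
                "ss_copies_low": row.ss_copies.low,
                "ss_copies_high": row.ss_copies.high,
                "ds_copies_low": row.ds_copies.low,
                "ds_copies_high": row.ds_copies.high,
                "relative_ss_low_percent": row.relative_ss_percent[0],
                "relative_ss_high_percent": row.relative_ss_percent[1],
                "fold_vs_direct_low": row.fold_vs_direct[0],
                "fold_vs_direct_high": row.fold_vs_direct[1],
                "fold_below_one": row.fold_below_one,
            }
            if rounded:
                for key in ("ss_copies_low", "ss_copies_high", "ds_copies_low",
                            "ds_copies_high"):
                    rec[key] = round_sig(rec[key], 2)
                rec["vcr"] = round(rec["vcr"], 2)
                for key in ("relative_ss_low_percent", "relative_ss_high_percent"):
                    rec[key] = round(rec[key], 1)
                for key in ("fold_vs_direct_low", "fold_vs_direct_high"):
                    rec[key] = round_sig(rec[key], 2)
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_tsv(self, path: Union[str, Path], rounded: bool = True) -> None:
        self.to_frame(rounded=rounded).to_csv(path, sep="\t", index=False)

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        payload = {
            "ss_genome_kb_range": [self.ss_range.min_kb, self.ss_range.max_kb],
            "ds_genome_kb_range": [self.ds_range.min_kb, self.ds_range.max_kb],
            "constants": {
                "avogadro": self.constants.avogadro,
                "mw_ss_per_nt": self.constants.mw_ss_per_nt,
                "mw_ds_per_bp": self.constants.mw_ds_per_bp,
            },
            "rounding": self.rounding,
            "samples": self.to_frame(rounded=False).to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    # headline summaries --------------------------------------------------
    def relative_ss_envelope(self) -> tuple[float, float]:
        """(min lower bound, max upper bound) of R across samples."""
        lows = [r.relative_ss_percent[0] for r in self.rows]
        highs = [r.relative_ss_percent[1] for r in self.rows]
        return (min(lows), max(highs))

    def max_fold_vs_direct(self) -> float:
        """Max across samples of the conservative (lower-bound) fold ratio."""
        return max(r.fold_vs_direct[0] for r in self.rows)


def build_report(
    samples: Sequence[SedimentSample],
    ss_range: GenomeSizeRange = DEFAULT_SS_RANGE,
    ds_size_kb: Union[float, GenomeSizeRange] = DEFAULT_DS_SIZE_KB,
    constants: Constants = DEFAULT_CONSTANTS,
) -> ApportionReport:
    """Derive the full per-sample report from measured inputs.

    ``ds_size_kb`` may be a scalar (point assumption, the default 50 kb) or a
    :class:`GenomeSizeRange`.
    """
    if not samples:
        raise ApportionError("at least one sample is required")
    ds_range = (
        ds_size_kb
        if isinstance(ds_size_kb, GenomeSizeRange)
        else GenomeSizeRange.point(float(ds_size_kb))
    )
    rows = []
    for s in sorted(samples, key=lambda s: (s.depth_top, s.depth_bottom)):
        ss = copies_interval(s.ss_mass, ss_range, constants)
        ds = copies_interval(s.ds_mass, ds_range, constants)
        rel = relative_ssdna_percent(ss, ds)
        rows.append(
            ApportionRow(
                sample=s,
                ss_copies=ss,
                ds_copies=ds,
                relative_ss_percent=rel,
                vcr=vcr(s.counts),
                fold_vs_direct=fold_vs_direct(ss, s.counts),
            )
        )
    return ApportionReport(rows=tuple(rows), ss_range=ss_range, ds_range=ds_range,
                           constants=constants)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_samples_tsv(
    path_or_buf: Union[str, Path, io.TextIOBase]
) -> list[SedimentSample]:
    """Read the per-sample measurement table (strict header)."""
    df = pd.read_csv(path_or_buf, sep="\t")
    if tuple(df.columns) != SAMPLES_COLUMNS:
        raise ApportionError(
            f"bad samples header {list(df.columns)}; expected {list(SAMPLES_COLUMNS)}"
        )
    if df.empty:
        raise ApportionError("samples file contains no rows")
    samples = []
    for rec in df.to_dict(orient="records"):
        samples.append(
            SedimentSample(
                sample_id=str(rec["sample_id"]),
                depth_top=float(rec["depth_top_cm"]),
                depth_bottom=float(rec["depth_bottom_cm"]),
                counts=DirectCounts(
                    viral_particles=float(rec["viruses_per_cm3"]),
                    viral_sd=float(rec["viruses_sd"]),
                    cells=float(rec["cells_per_cm3"]),
                    cell_sd=float(rec["cells_sd"]),
                ),
                ss_mass=DnaMassMeasurement(
                    NucleicAcidType.SSDNA, float(rec["ssdna_ng_per_cm3"])
                ),
                ds_mass=DnaMassMeasurement(
                    NucleicAcidType.DSDNA, float(rec["dsdna_ng_per_cm3"])
                ),
            )
        )
    return samples


def write_samples_tsv(
    samples: Sequence[SedimentSample], path_or_buf: Union[str, Path, io.TextIOBase]
) -> None:
    records = []
    for s in samples:
        records.append(
            {
                "sample_id": s.sample_id,
                "depth_top_cm": s.depth_top,
                "depth_bottom_cm": s.depth_bottom,
                "cells_per_cm3": s.counts.cells,
                "cells_sd": s.counts.cell_sd,
                "viruses_per_cm3": s.counts.viral_particles,
                "viruses_sd": s.counts.viral_sd,
                "ssdna_ng_per_cm3": s.ss_mass.concentration,
                "dsdna_ng_per_cm3": s.ds_mass.concentration,
            }
        )
    pd.DataFrame.from_records(records, columns=list(SAMPLES_COLUMNS)).to_csv(
        path_or_buf, sep="\t", index=False
    )


def tohoku_samples() -> list[SedimentSample]:
    """The packaged canonical three-horizon measurement fixture (off-Tohoku
    upper bathyal sediment, 0–2 / 5–8 / 10–15 cmbsf)."""
    from importlib import resources

    ref = resources.files("viromass.data").joinpath("tohoku_table1.tsv")
    with ref.open("r") as handle:
        return read_samples_tsv(handle)
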