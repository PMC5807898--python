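"""Virome library summaries and the rRNA-contamination quality criterion.

A virome prepared from purified viral particles should carry essentially no
cellular rRNA genes; a widely used screen accepts libraries whose
rRNA-gene-associated reads make up less than 0.02% of total reads (strict
``<``).  rRNA read identification itself (e.g. BLAST against an SSU rRNA
database) happens upstream; counts arrive here as inputs, mirroring how they
are reported per library.

Library summaries (read counts, mean length, total megabases, GC content)
follow the usual conventions: GC is computed over unambiguous A/C/G/T bases
only, with ambiguity codes excluded from both numerator and denominator.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from Bio import SeqIO

from ._format import round_sig


class QcError(ValueError):
    pass


class EmptyLibraryError(QcError):
    pass


DEFAULT_RRNA_THRESHOLD_PERCENT = 0.02


@dataclass(frozen=True)
class LibrarySummary:
    library_id: str
    n_reads: int
    mean_length: float  # bases
    total_length_mb: float  # megabases
    gc_percent: float

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise EmptyLibraryError("library has no reads")
        if not (0 <= self.gc_percent <= 100):
            raise QcError("GC percent out of [0, 100]")
        implied_mb = self.n_reads * self.mean_length / 1e6
        # totals must be mutually consistent up to table rounding
        if implied_mb > 0 and abs(self.total_length_mb - implied_mb) > 0.02 * implied_mb + 0.5:
            raise QcError(
                f"inconsistent totals: {self.total_length_mb} Mb vs "
                f"{self.n_reads} reads x {self.mean_length} bp = {implied_mb:.1f} Mb"
            )


@dataclass(frozen=True)
class RrnaQcResult:
    library_id: str
    n_rrna_reads: int
    ratio_percent: float
    threshold_percent: float
    passed: bool

    @property
    def ratio_display(self) -> float:
        """Ratio rounded to one significant figure, the table convention."""
        return round_sig(self.ratio_percent, 1)


def _open_reads(source: Union[str, Path, io.TextIOBase], fmt: Optional[str]):
    if isinstance(source, (str, Path)):
        path = Path(source)
        suffixes = [s.lower() for s in path.suffixes]
        gz = suffixes and suffixes[-1] == ".gz"
        stem = suffixes[-2] if gz and len(suffixes) > 1 else (suffixes[-1] if suffixes else "")
        if fmt is None:
            if stem in (".fa", ".fasta", ".fna"):
                fmt = "fasta"
            elif stem in (".fq", ".fastq"):
                fmt = "fastq"
            else:
                raise QcError(f"cannot infer read format from {path.name!r}")
        handle = gzip.open(path, "rt") if gz else open(path)
        return handle, fmt, True
    if fmt is None:
        raise QcError("format must be given for stream input ('fasta' or 'fastq')")
    return source, fmt, False


def summarize_library(
    source: Union[str, Path, io.TextIOBase],
    fmt: Optional[str] = None,
    library_id: Optional[str] = None,
) -> LibrarySummary:
    """Stream a FASTA/FASTQ library (plain or gzip) into a summary.

    Raises :class:`EmptyLibraryError` on an empty stream.  Malformed records
    surface as errors with the offending record's position.
    """
    handle, fmt, close = _open_reads(source, fmt)
    n = 0
    total_bp = 0
    gc = 0
    unambiguous = 0
    try:
        try:
            for n, record in enumerate(SeqIO.parse(handle, fmt), start=1):
                seq = str(record.seq).upper()
                total_bp += len(seq)
                gc += seq.count("G") + seq.count("C")
                unambiguous += (
                    seq.count("A") + seq.count("C") + seq.count("G") + seq.count("T")
                )
        except ValueError as exc:
            raise QcError(f"malformed record near read {n + 1}: {exc}") from exc
    finally:
        if close:
            handle.close()
    if n == 0:
        raise EmptyLibraryError("empty read stream")
    if library_id is None:
        if isinstance(source, (str, Path)):
            p = Path(str(source))
            library_id = p.stem[: -len(p.suffixes[-2])] if p.suffix == ".gz" and len(p.suffixes) > 1 else p.stem
        else:
            library_id = "library"
    return LibrarySummary(
        library_id=library_id,
        n_reads=n,
        mean_length=total_bp / n,
        total_length_mb=total_bp / 1e6,
        gc_percent=100.0 * gc / unambiguous if unambiguous else 0.0,
    )


def merge_summaries(a: LibrarySummary, b: LibrarySummary) -> LibrarySummary:
    """Count-weighted merge, as if the two streams were concatenated.

    GC merging weights by unambiguous-base totals approximated from read
    lengths, which is exact when both inputs were computed over fully
    unambiguous reads.
    """
    n = a.n_reads + b.n_reads
    bp_a = a.n_reads * a.mean_length
    bp_b = b.n_reads * b.mean_length
    return LibrarySummary(
        library_id=f"{a.library_id}+{b.library_id}",
        n_reads=n,
        mean_length=(bp_a + bp_b) / n,
        total_length_mb=a.total_length_mb + b.total_length_mb,
        gc_percent=(a.gc_percent * bp_a + b.gc_percent * bp_b) / (bp_a + bp_b),
    )


def rrna_ratio(n_rrna: int, n_total: int) -> float:
    """rRNA-gene-associated reads as a percentage of total reads."""
    if n_total <= 0:
        raise QcError("total read count must be > 0")
    if not (0 <= n_rrna <= n_total):
        raise QcError("rRNA read count must be within [0, n_total]")
    return 100.0 * n_rrna / n_total


def qc_evaluate(
    summary: LibrarySummary,
    n_rrna: int,
    threshold_percent: float = DEFAULT_RRNA_THRESHOLD_PERCENT,
) -> RrnaQcResult:
    """Apply the strict-less-than rRNA contamination criterion."""
    if threshold_percent < 0:
        raise QcError("threshold must be >= 0")
    if threshold_percent == 0:
        warnings.warn(
            "rRNA QC threshold of 0% can never pass; check configuration",
            stacklevel=2,
        )
    ratio = rrna_ratio(n_rrna, summary.n_reads)
    return RrnaQcResult(
        library_id=summary.library_id,
        n_rrna_reads=n_rrna,
        ratio_percent=ratio,
        threshold_percent=threshold_percent,
        passed=ratio < threshold_percent,
    )


def tohoku_library_table() -> list[tuple[LibrarySummary, int]]:
    """The packaged six-library summary fixture (read totals, lengths, GC and
    per-library rRNA-read counts for the ssDNA/dsDNA viromes at three depths),
    as (summary, n_rrna_reads) pairs."""
    from importlib import resources

    ref = resources.files("viromass.data").joinpath("tohoku_table2.tsv")
    with ref.open("r") as handle:
        df = pd.read_csv(handle, sep="\t")
    out = []
    for rec in df.to_dict(orient="records"):
        out.append(
            (
                LibrarySummary(
                    library_id=str(rec["library_id"]),
                    n_reads=int(rec["n_reads"]),
                    mean_length=float(rec["mean_length_bp"]),
                    total_length_mb=float(rec["total_length_mb"]),
                    gc_percent=float(rec["gc_percent"]),
                ),
                int(rec["n_rrna_reads"]),
            )
        )
    return out
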