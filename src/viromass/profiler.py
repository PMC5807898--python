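"""Taxonomic profiling of virome reads from BLAST tabular hits.

Reads are placed on the taxonomy by MEGAN-style lowest-common-ancestor (LCA)
assignment: per read, hits are filtered by E-value (strict ``<``), a minimum
bit score, and a top-percent window below the best bit score; the read is
assigned to the deepest taxonomy node shared by all retained hits.  Profiles
aggregate assignments into family-level, nucleic-acid-type, or superkingdom
categories, and minor families (below a percent-of-viral-reads threshold,
strict ``<``) can be collapsed into "other ssDNA viruses" / "other dsDNA
viruses" / "others" bins for presentation.

BLAST search execution is out of scope: this module consumes the standard
12-column tabular output (qseqid sseqid pident length mismatch gapopen qstart
qend sstart send evalue bitscore).  Subject-to-taxon resolution is supplied as
an explicit two-column mapping rather than parsed out of subject description
lines.
"""

from __future__ import annotations

import csv
import io
import warnings
from collections import Counter, OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .constants import NucleicAcidType
from .taxonomy import TaxonomyTree

UNASSIGNED = "unassigned"

BLAST_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MIN_BITSCORE = 50.0
DEFAULT_TOP_PERCENT = 10.0

PROFILE_SCHEMES = ("family", "na_type", "superkingdom")


@dataclass(frozen=True)
class BlastHitRecord:
    """One line of 12-column BLAST tabular output.  ``subject`` carries the
    sseqid token, which a subject->taxon map resolves to a taxonomy label."""

    query_id: str
    subject: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class MalformedLine:
    lineno: int
    line: str
    reason: str


@dataclass(frozen=True)
class BlastParseResult:
    hits: tuple[BlastHitRecord, ...]
    malformed: tuple[MalformedLine, ...]


@dataclass(frozen=True)
class ReadAssignment:
    query_id: str
    assigned_taxon: str  # taxonomy label, or UNASSIGNED
    n_hits_used: int
    n_unresolved_subjects: int = 0


@dataclass(frozen=True)
class TaxonomicProfile:
    """Category -> read-count mapping for one library.

    ``total_reads`` is the library size (reads that never produced a hit may
    exceed the number of assignments); ``viral_reads`` is the number of reads
    assigned to viral categories and is the denominator for composition
    percentages.
    """

    library_id: str
    counts: Mapping[str, int]
    total_reads: int
    viral_reads: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))
        if sum(self.counts.values()) > self.total_reads:
            raise ValueError("category counts exceed total_reads")
        if self.viral_reads > self.total_reads:
            raise ValueError("viral_reads exceeds total_reads")

    def percent(self, category: str) -> float:
        """Category share as percent of viral reads."""
        if self.viral_reads == 0:
            return 0.0
        return 100.0 * self.counts.get(category, 0) / self.viral_reads

    def viral_categories(self) -> list[str]:
        return [c for c in self.counts if c != UNASSIGNED]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "library_id": self.library_id,
                "category": cat,
                "count": n,
                "percent": self.percent(cat) if cat != UNASSIGNED else float("nan"),
            }
            for cat, n in self.counts.items()
        ]
        return pd.DataFrame(rows, columns=["library_id", "category", "count", "percent"])

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: Union[str, Path]) -> TaxonomicProfile:
    df = pd.read_csv(path, sep="\t")
    needed = {"library_id", "category", "count"}
    if not needed.issubset(df.columns):
        raise ValueError(f"profile TSV needs columns {sorted(needed)}")
    library_id = str(df["library_id"].iloc[0])
    counts = {str(r["category"]): int(r["count"]) for _, r in df.iterrows()}
    viral = sum(n for c, n in counts.items() if c != UNASSIGNED)
    return TaxonomicProfile(
        library_id=library_id,
        counts=counts,
        total_reads=sum(counts.values()),
        viral_reads=viral,
    )


# ---------------------------------------------------------------------------
# parsing and filtering
# ---------------------------------------------------------------------------

def parse_blast_tab(
    source: Union[str, Path, io.TextIOBase, Iterable[str]]
) -> BlastParseResult:
    """Parse 12-column BLAST tabular text.

    Blank lines and ``#`` comment lines are skipped.  Malformed lines (wrong
    column count, unparseable numerics) are collected with their line numbers
    instead of aborting the parse.
    """
    close = False
    if isinstance(source, (str, Path)):
        handle: Iterable[str] = open(source)
        close = True
    else:
        handle = source
    hits: list[BlastHitRecord] = []
    malformed: list[MalformedLine] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                malformed.append(
                    MalformedLine(lineno, line, f"expected 12 columns, got {len(fields)}")
                )
                continue
            try:
                hits.append(
                    BlastHitRecord(
                        query_id=fields[0],
                        subject=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                malformed.append(MalformedLine(lineno, line, str(exc)))
    finally:
        if close:
            handle.close()  # type: ignore[union-attr]
    return BlastParseResult(hits=tuple(hits), malformed=tuple(malformed))


def filter_hits(
    hits: Sequence[BlastHitRecord], max_evalue: float = DEFAULT_MAX_EVALUE
) -> list[BlastHitRecord]:
    """Keep hits with ``evalue < max_evalue`` (strict), preserving order."""
    if max_evalue <= 0:
        raise ValueError("max_evalue must be > 0")
    return [h for h in hits if h.evalue < max_evalue]


def read_subject_map(
    source: Union[str, Path, io.TextIOBase]
) -> dict[str, str]:
    """Two-column TSV mapping sseqid tokens to taxonomy labels."""
    close = False
    if isinstance(source, (str, Path)):
        handle: io.TextIOBase = open(source)
        close = True
    else:
        handle = source
    try:
        mapping: dict[str, str] = {}
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise ValueError(f"subject map rows need 2 columns, got {row}")
            mapping[row[0]] = row[1]
        return mapping
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# LCA assignment
# ---------------------------------------------------------------------------

def _deepest_common_ancestor(taxa: Sequence[str], tree: TaxonomyTree) -> str:
    """Deepest node on every taxon's root-to-node path.

    In a tree the common ancestors of a set of nodes form a chain — the
    shared prefix of their root paths — so the deepest one is the last shared
    prefix element.
    """
    paths = [tree.lineage(t) for t in taxa]
    first = paths[0]
    k = min(len(p) for p in paths)
    lca = first[0]
    for i in range(k):
        name = first[i]
        if all(p[i] == name for p in paths):
            lca = name
        else:
            break
    return lca


def lca_assign(
    hits: Sequence[BlastHitRecord],
    tree: TaxonomyTree,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    top_percent: float = DEFAULT_TOP_PERCENT,
    subject_map: Optional[Mapping[str, str]] = None,
) -> ReadAssignment:
    """Assign one read from its hits by lowest-common-ancestor placement.

    Retention: resolve subjects to taxa (unresolvable subjects are skipped and
    counted), drop hits with ``bitscore < min_bitscore``, then drop hits below
    ``(1 - top_percent/100) * best_bitscore``.  The read is assigned to the
    deepest taxon shared by all retained hits' lineages; no retained hits
    leaves the read unassigned.  Tied best bit scores retain all tied hits.
    """
    if not hits:
        return ReadAssignment(query_id="", assigned_taxon=UNASSIGNED, n_hits_used=0)
    query_ids = {h.query_id for h in hits}
    if len(query_ids) != 1:
        raise ValueError(f"hits span multiple reads: {sorted(query_ids)}")
    query_id = hits[0].query_id

    resolved: list[tuple[str, BlastHitRecord]] = []
    n_unresolved = 0
    for h in hits:
        taxon = subject_map.get(h.subject, h.subject) if subject_map else h.subject
        if taxon in tree:
            resolved.append((taxon, h))
        else:
            n_unresolved += 1
    if n_unresolved:
        warnings.warn(
            f"read {query_id}: {n_unresolved} hit(s) with subjects absent from "
            "the taxonomy were skipped",
            stacklevel=2,
        )

    strong = [(t, h) for t, h in resolved if h.bitscore >= min_bitscore]
    if not strong:
        return ReadAssignment(query_id, UNASSIGNED, 0, n_unresolved)
    best = max(h.bitscore for _, h in strong)
    cutoff = (1.0 - top_percent / 100.0) * best
    retained = [(t, h) for t, h in strong if h.bitscore >= cutoff]
    taxa = [t for t, _ in retained]
    return ReadAssignment(
        query_id=query_id,
        assigned_taxon=_deepest_common_ancestor(taxa, tree),
        n_hits_used=len(retained),
        n_unresolved_subjects=n_unresolved,
    )


def assign_reads(
    hits: Sequence[BlastHitRecord],
    tree: TaxonomyTree,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    top_percent: float = DEFAULT_TOP_PERCENT,
    subject_map: Optional[Mapping[str, str]] = None,
) -> list[ReadAssignment]:
    """E-value filter then per-read LCA assignment, in first-seen read order."""
    kept = filter_hits(hits, max_evalue)
    by_read: "OrderedDict[str, list[BlastHitRecord]]" = OrderedDict()
    for h in kept:
        by_read.setdefault(h.query_id, []).append(h)
    return [
        lca_assign(read_hits, tree, min_bitscore, top_percent, subject_map)
        for read_hits in by_read.values()
    ]


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def _category_of(taxon: str, tree: TaxonomyTree, scheme: str) -> str:
    if scheme == "family":
        fam = tree.rank_ancestor(taxon, "family")
        return fam if fam is not None else taxon
    if scheme == "na_type":
        na = tree.na_type_of(taxon)
        return na.value if na is not None else "unknown"
    if scheme == "superkingdom":
        sk = tree.rank_ancestor(taxon, "superkingdom")
        return sk if sk is not None else "unknown"
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {PROFILE_SCHEMES}")


def build_profile(
    assignments: Sequence[ReadAssignment],
    tree: TaxonomyTree,
    scheme: str = "family",
    library_id: str = "library",
    total_reads: Optional[int] = None,
) -> TaxonomicProfile:
    """Aggregate read assignments into a category profile.

    Assigned reads are mapped to their scheme category by an ancestor walk
    (family scheme: nearest family-rank ancestor-or-self, falling back to the
    assigned node's own name for coarser placements).  Unassigned reads are
    counted under ``unassigned``.  The sum of category counts equals the
    number of input assignments.
    """
    if scheme not in PROFILE_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {PROFILE_SCHEMES}")
    counts: Counter[str] = Counter()
    viral = 0
    for a in assignments:
        if a.assigned_taxon == UNASSIGNED:
            counts[UNASSIGNED] += 1
            continue
        counts[_category_of(a.assigned_taxon, tree, scheme)] += 1
        if tree.is_viral(a.assigned_taxon):
            viral += 1
    n = len(assignments)
    return TaxonomicProfile(
        library_id=library_id,
        counts=dict(counts),
        total_reads=total_reads if total_reads is not None else n,
        viral_reads=viral,
    )


OTHER_SS = "other ssDNA viruses"
OTHER_DS = "other dsDNA viruses"
OTHER = "others"
_OTHER_BINS = (OTHER_SS, OTHER_DS, OTHER)


def _na_of_category(category: str, tree: TaxonomyTree) -> Optional[NucleicAcidType]:
    if category in tree:
        return tree.na_type_of(category)
    try:
        return NucleicAcidType(category)
    except ValueError:
        return None


def collapse_minor(
    profile: TaxonomicProfile,
    threshold_percent: float = 2.0,
    tree: Optional[TaxonomyTree] = None,
) -> TaxonomicProfile:
    """Merge viral categories below ``threshold_percent`` of viral reads
    (strict ``<``) into "other ssDNA viruses" / "other dsDNA viruses" /
    "others" bins by nucleic-acid type.  Counts are conserved; ``unassigned``
    and the three "other" bins themselves are never re-collapsed."""
    if not (0 <= threshold_percent <= 100):
        raise ValueError("threshold_percent must be within [0, 100]")
    if profile.viral_reads == 0 or threshold_percent == 0:
        return profile
    merged: Counter[str] = Counter()
    for cat, n in profile.counts.items():
        if cat == UNASSIGNED or cat in _OTHER_BINS:
            merged[cat] += n
            continue
        if profile.percent(cat) < threshold_percent:
            na = _na_of_category(cat, tree) if tree is not None else None
            if na is NucleicAcidType.SSDNA:
                merged[OTHER_SS] += n
            elif na is NucleicAcidType.DSDNA:
                merged[OTHER_DS] += n
            else:
                merged[OTHER] += n
        else:
            merged[cat] += n
    return TaxonomicProfile(
        library_id=profile.library_id,
        counts=dict(merged),
        total_reads=profile.total_reads,
        viral_reads=profile.viral_reads,
    )
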