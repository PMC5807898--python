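"""Viral taxonomy registry with nucleic-acid type and genome-size annotations.

A small rooted taxonomy is the reference frame for everything downstream:
genome-size ranges drive the mass-to-copies conversion, nucleic-acid types
drive profile categorisation, and the tree topology drives lowest-common-
ancestor read assignment.  The registry is deliberately lightweight — a TSV
with one row per taxon — rather than an NCBI taxonomy dump.

A default registry covering the ssDNA families (Circoviridae, Microviridae,
Inoviridae) and the common dsDNA families (Caudovirales members and
Phycodnaviridae) ships with the package; the community-level clade nodes carry
the envelope assumptions used for whole-community mass apportioning
(1.8–24.9 kb for ssDNA viruses, a 50 kb point for dsDNA viruses).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

from .constants import NucleicAcidType

RANKS = ("root", "superkingdom", "order", "family", "genus", "species", "other")

TAXONOMY_COLUMNS = ("name", "rank", "parent", "na_type", "genome_min_kb", "genome_max_kb")


class TaxonomyError(ValueError):
    """Base class for taxonomy construction/lookup failures."""


class DuplicateTaxonError(TaxonomyError):
    pass


class MissingParentError(TaxonomyError):
    pass


class TaxonomyCycleError(TaxonomyError):
    pass


class RootError(TaxonomyError):
    """Zero roots, or more than one."""


class UnknownTaxonError(TaxonomyError, KeyError):
    pass


class NoAnnotatedAncestorError(TaxonomyError):
    pass


@dataclass(frozen=True)
class GenomeSizeRange:
    """Closed interval of genome sizes in kilobases (kb = knt for ssDNA)."""

    min_kb: float
    max_kb: float

    def __post_init__(self) -> None:
        if not (0 < self.min_kb <= self.max_kb):
            raise ValueError(
                f"invalid genome size range [{self.min_kb}, {self.max_kb}] kb: "
                "need 0 < min_kb <= max_kb"
            )

    @property
    def is_point(self) -> bool:
        return self.min_kb == self.max_kb

    @classmethod
    def point(cls, kb: float) -> "GenomeSizeRange":
        return cls(kb, kb)


@dataclass(frozen=True)
class ViralTaxonNode:
    name: str
    rank: str
    parent: Optional[str]
    na_type: Optional[NucleicAcidType] = None
    genome_size: Optional[GenomeSizeRange] = None

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            # unknown ranks are coerced rather than rejected
            object.__setattr__(self, "rank", "other")


class TaxonomyTree:
    """Rooted tree of :class:`ViralTaxonNode`, keyed by unique taxon name."""

    def __init__(self, nodes: Mapping[str, ViralTaxonNode], root_name: str):
        self._nodes = dict(nodes)
        self.root_name = root_name
        self._depth: dict[str, int] = {}

    # -- container protocol -------------------------------------------------
    def __contains__(self, name: object) -> bool:
        return name in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[str]:
        return iter(self._nodes)

    def __getitem__(self, name: str) -> ViralTaxonNode:
        try:
            return self._nodes[name]
        except KeyError:
            raise UnknownTaxonError(f"taxon {name!r} not in taxonomy") from None

    @property
    def nodes(self) -> Mapping[str, ViralTaxonNode]:
        return self._nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyTree):
            return NotImplemented
        return self._nodes == other._nodes and self.root_name == other.root_name

    # -- traversal ----------------------------------------------------------
    def ancestors(self, name: str, include_self: bool = False) -> list[str]:
        """Names from (optionally) ``name`` up to and including the root."""
        node = self[name]
        chain = [name] if include_self else []
        while node.parent is not None:
            chain.append(node.parent)
            node = self[node.parent]
        return chain

    def lineage(self, name: str) -> list[str]:
        """Root-to-node path, inclusive."""
        return list(reversed(self.ancestors(name, include_self=True)))

    def depth(self, name: str) -> int:
        if name not in self._depth:
            self._depth[name] = len(self.ancestors(name))
        return self._depth[name]

    def na_type_of(self, name: str) -> Optional[NucleicAcidType]:
        """Nearest annotated nucleic-acid type walking up from ``name``."""
        for anc in self.ancestors(name, include_self=True):
            na = self[anc].na_type
            if na is not None:
                return na
        return None

    def rank_ancestor(self, name: str, rank: str) -> Optional[str]:
        """Nearest ancestor-or-self with the given rank, or None."""
        for anc in self.ancestors(name, include_self=True):
            if self[anc].rank == rank:
                return anc
        return None

    def families(self) -> list[str]:
        return [n for n, node in self._nodes.items() if node.rank == "family"]

    def is_viral(self, name: str) -> bool:
        """True if the taxon sits under a 'Viruses' superkingdom or has any
        nucleic-acid annotation in its lineage (permissive for synthetic trees
        that omit a superkingdom level)."""
        lineage = self.ancestors(name, include_self=True)
        for anc in lineage:
            node = self[anc]
            if node.rank == "superkingdom":
                return node.name == "Viruses"
            if node.na_type is not None:
                return True
        return False

    # -- serialization ------------------------------------------------------
    def to_records(self) -> list[dict[str, str]]:
        recs = []
        for node in self._nodes.values():
            recs.append(
                {
                    "name": node.name,
                    "rank": node.rank,
                    "parent": node.parent or "",
                    "na_type": node.na_type.value if node.na_type else "",
                    "genome_min_kb": (
                        repr(node.genome_size.min_kb) if node.genome_size else ""
                    ),
                    "genome_max_kb": (
                        repr(node.genome_size.max_kb) if node.genome_size else ""
                    ),
                }
            )
        return recs

    def to_tsv(self, path_or_buf: Union[str, Path, io.TextIOBase]) -> None:
        close = False
        if isinstance(path_or_buf, (str, Path)):
            handle: io.TextIOBase = open(path_or_buf, "w", newline="")
            close = True
        else:
            handle = path_or_buf
        try:
            writer = csv.DictWriter(handle, fieldnames=TAXONOMY_COLUMNS, delimiter="\t")
            writer.writeheader()
            writer.writerows(self.to_records())
        finally:
            if close:
                handle.close()


def build_taxonomy(records: Iterable[Mapping[str, object]]) -> TaxonomyTree:
    """Validate tabular taxon rows into a :class:`TaxonomyTree`.

    Each record needs ``name``, ``rank`` and ``parent`` (empty/None for the
    root); ``na_type`` and ``genome_min_kb``/``genome_max_kb`` are optional.

    Raises
    ------
    DuplicateTaxonError, MissingParentError, TaxonomyCycleError, RootError
    """
    nodes: dict[str, ViralTaxonNode] = {}
    for rec in records:
        name = str(rec["name"]).strip()
        if not name:
            raise TaxonomyError("empty taxon name")
        if name in nodes:
            raise DuplicateTaxonError(f"duplicate taxon name {name!r}")
        parent_raw = rec.get("parent")
        parent = str(parent_raw).strip() if parent_raw not in (None, "") else None
        if parent == "":
            parent = None
        na_raw = rec.get("na_type")
        na_type = None
        if na_raw not in (None, "", "unknown"):
            na_type = NucleicAcidType.coerce(str(na_raw))
        gmin, gmax = rec.get("genome_min_kb"), rec.get("genome_max_kb")
        genome_size = None
        if gmin not in (None, "") and gmax not in (None, ""):
            genome_size = GenomeSizeRange(float(gmin), float(gmax))
        elif (gmin in (None, "")) != (gmax in (None, "")):
            raise TaxonomyError(
                f"taxon {name!r}: genome_min_kb and genome_max_kb must be given together"
            )
        nodes[name] = ViralTaxonNode(
            name=name,
            rank=str(rec.get("rank", "other")).strip() or "other",
            parent=parent,
            na_type=na_type,
            genome_size=genome_size,
        )

    roots = [n for n in nodes.values() if n.parent is None]
    if len(roots) != 1:
        raise RootError(f"taxonomy must have exactly one root, found {len(roots)}")
    root = roots[0].name

    for node in nodes.values():
        if node.parent is not None and node.parent not in nodes:
            raise MissingParentError(
                f"taxon {node.name!r} references missing parent {node.parent!r}"
            )

    # cycle check: every chain must terminate at the root
    for name in nodes:
        seen = {name}
        cur = nodes[name]
        while cur.parent is not None:
            if cur.parent in seen:
                raise TaxonomyCycleError(f"cycle detected at taxon {cur.parent!r}")
            seen.add(cur.parent)
            cur = nodes[cur.parent]

    return TaxonomyTree(nodes, root)


def read_taxonomy_tsv(path_or_buf: Union[str, Path, io.TextIOBase]) -> TaxonomyTree:
    """Read a registry TSV (strict header) into a taxonomy tree."""
    close = False
    if isinstance(path_or_buf, (str, Path)):
        handle: io.TextIOBase = open(path_or_buf, newline="")
        close = True
    else:
        handle = path_or_buf
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        if tuple(reader.fieldnames or ()) != TAXONOMY_COLUMNS:
            raise TaxonomyError(
                f"bad taxonomy header {reader.fieldnames}; expected {list(TAXONOMY_COLUMNS)}"
            )
        return build_taxonomy(list(reader))
    finally:
        if close:
            handle.close()


def genome_size_lookup(tree: TaxonomyTree, taxon: str) -> GenomeSizeRange:
    """Nearest annotated genome-size range walking up the ancestor chain."""
    for name in tree.ancestors(taxon, include_self=True):
        size = tree[name].genome_size
        if size is not None:
            return size
    raise NoAnnotatedAncestorError(
        f"no genome-size annotation on {taxon!r} or any ancestor"
    )


def default_taxonomy() -> TaxonomyTree:
    """The packaged registry of common benthic ssDNA/dsDNA viral families."""
    ref = resources.files("viromass.data").joinpath("default_taxonomy.tsv")
    with ref.open("r") as handle:
        return read_taxonomy_tsv(handle)
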