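"""Orthogroup parsing, validation and merging.

Orthogroups arrive as partitions of species-qualified gene identifiers, in
either the OrthoMCL groups dialect (``GROUP: sp|gene sp|gene ...``) or the
OrthoFinder ``Orthogroups.tsv`` dialect (one column per species,
comma-separated local ids). Two partitions produced by different tools are
combined by the shared-member union rule: any two groups sharing at least one
member gene are replaced by the union of their members, iterated to a fixpoint
(i.e. connected components of the group-overlap graph), so the result is again
a partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx

__all__ = [
    "GeneId",
    "OrthoGroupSet",
    "OrthologyParseError",
    "PartitionError",
    "parse_orthomcl_groups",
    "parse_orthofinder_orthogroups",
    "merge_orthogroup_sets",
    "orthologs_of",
    "write_orthomcl_groups",
    "materialize_singletons",
]

logger = logging.getLogger(__name__)


class OrthologyParseError(ValueError):
    """A groups file is malformed."""


class PartitionError(ValueError):
    """A gene appears in more than one group."""


@dataclass(frozen=True, order=True)
class GeneId:
    """A species-qualified gene identifier, rendered ``species_tag|local_id``."""

    species_tag: str
    local_id: str

    def __post_init__(self) -> None:
        for part, label in ((self.species_tag, "species_tag"), (self.local_id, "local_id")):
            if not part:
                raise ValueError(f"GeneId {label} must be non-empty")
            if "|" in part:
                raise ValueError(f"GeneId {label} may not contain '|': {part!r}")

    def __str__(self) -> str:
        return f"{self.species_tag}|{self.local_id}"

    @classmethod
    def parse(cls, text: str) -> "GeneId":
        tag, sep, local = text.partition("|")
        if not sep:
            raise ValueError(f"not a species-qualified gene id: {text!r}")
        return cls(tag, local)


@dataclass(frozen=True)
class OrthoGroupSet:
    """A disjoint partition of gene identifiers into ortholog groups."""

    groups: tuple[tuple[str, frozenset[GeneId]], ...]
    provenance: str = ""
    _member_index: Mapping[GeneId, str] = field(repr=False, default_factory=dict)

    @classmethod
    def from_groups(
        cls, groups: Iterable[tuple[str, Iterable[GeneId]]], provenance: str = ""
    ) -> "OrthoGroupSet":
        """Build and validate a group set; raises on empty or overlapping groups."""
        frozen: list[tuple[str, frozenset[GeneId]]] = []
        index: dict[GeneId, str] = {}
        for gid, members in groups:
            mset = frozenset(members)
            if not mset:
                raise PartitionError(f"group {gid!r} is empty")
            for m in mset:
                if m in index:
                    raise PartitionError(
                        f"gene {m} appears in groups {index[m]!r} and {gid!r}"
                    )
                index[m] = gid
            frozen.append((gid, mset))
        return cls(groups=tuple(frozen), provenance=provenance, _member_index=index)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def members(self) -> frozenset[GeneId]:
        return frozenset(self._member_index)

    def group_of(self, gene: GeneId) -> str | None:
        return self._member_index.get(gene)

    def group_members(self, group_id: str) -> frozenset[GeneId]:
        for gid, members in self.groups:
            if gid == group_id:
                return members
        raise KeyError(group_id)


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------


def parse_orthomcl_groups(stream: IO[str] | Iterable[str]) -> OrthoGroupSet:
    """Parse the OrthoMCL groups dialect: ``GROUP_ID: member member ...``."""
    groups: list[tuple[str, set[GeneId]]] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gid, sep, rest = line.partition(":")
        if not sep:
            raise OrthologyParseError(f"line {lineno}: missing ':' separator")
        gid = gid.strip()
        if not gid:
            raise OrthologyParseError(f"line {lineno}: empty group id")
        members: set[GeneId] = set()
        tokens = rest.split()
        for tok in tokens:
            gene = GeneId.parse(tok)
            if gene in members:
                logger.warning("line %d: duplicate member %s collapsed", lineno, gene)
            members.add(gene)
        if not members:
            raise OrthologyParseError(f"line {lineno}: group {gid!r} has no members")
        groups.append((gid, members))
    return OrthoGroupSet.from_groups(groups, provenance="orthomcl")


def parse_orthofinder_orthogroups(
    stream: IO[str] | Iterable[str], species_map: Mapping[str, str]
) -> OrthoGroupSet:
    """Parse an OrthoFinder ``Orthogroups.tsv`` table.

    Parameters
    ----------
    species_map
        Column header -> species tag used to qualify the local gene ids in
        that column.
    """
    lines = iter(stream)
    try:
        header = next(lines).rstrip("\n").split("\t")
    except StopIteration:
        raise OrthologyParseError("empty stream: missing header row") from None
    if not header or header[0] != "Orthogroup":
        raise OrthologyParseError("missing 'Orthogroup' header column")
    tags: list[str] = []
    for col in header[1:]:
        if col not in species_map:
            raise OrthologyParseError(f"column {col!r} absent from species map")
        tags.append(species_map[col])

    groups: list[tuple[str, set[GeneId]]] = []
    for rowno, line in enumerate(lines, start=2):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if len(cells) != len(header):
            raise OrthologyParseError(
                f"row {rowno}: expected {len(header)} columns, got {len(cells)}"
            )
        gid = cells[0].strip()
        members: set[GeneId] = set()
        for tag, cell in zip(tags, cells[1:]):
            for local in (tok.strip() for tok in cell.split(",")):
                if not local:
                    continue
                gene = GeneId(tag, local)
                if gene in members:
                    logger.warning("row %d: duplicate member %s collapsed", rowno, gene)
                members.add(gene)
        if not members:
            raise OrthologyParseError(f"row {rowno}: group {gid!r} has no members")
        groups.append((gid, members))
    return OrthoGroupSet.from_groups(groups, provenance="orthofinder")


# ---------------------------------------------------------------------------
# merging and queries
# ---------------------------------------------------------------------------


def _synthesize_ids(
    member_sets: Iterable[frozenset[GeneId]],
) -> list[tuple[str, frozenset[GeneId]]]:
    """Deterministic ids: 'MG' + zero-padded rank of the smallest member."""
    ordered = sorted(member_sets, key=lambda s: min(s))
    width = max(len(str(len(ordered))), 1)
    return [(f"MG{i:0{width}d}", s) for i, s in enumerate(ordered, start=1)]


def merge_orthogroup_sets(a: OrthoGroupSet, b: OrthoGroupSet) -> OrthoGroupSet:
    """Merge two orthogroup partitions by the shared-member union rule.

    Groups from either input sharing at least one member gene collapse into
    the union of their members; the rule is applied to a fixpoint, i.e. the
    output groups are the connected components of the bipartite group-overlap
    graph. The operation is commutative and, up to group ids, idempotent.
    """
    graph: nx.Graph = nx.Graph()
    for prefix, gset in (("a", a), ("b", b)):
        for gid, members in gset.groups:
            node = (prefix, gid)
            graph.add_node(node, members=members)
            for m in members:
                graph.add_edge(node, ("gene", m))
    merged: list[frozenset[GeneId]] = []
    for component in nx.connected_components(graph):
        members = frozenset(
            node[1] for node in component if node[0] == "gene"
        )
        if members:
            merged.append(members)
    return OrthoGroupSet.from_groups(
        _synthesize_ids(merged), provenance=f"merge({a.provenance},{b.provenance})"
    )


def orthologs_of(
    groups: OrthoGroupSet, query: GeneId, target_species: str
) -> list[GeneId]:
    """Members of the query's group carrying the target species tag, sorted.

    Absence (query unassigned, or no member of the target species) is an
    empty result, not an error.
    """
    gid = groups.group_of(query)
    if gid is None:
        return []
    return sorted(
        g for g in groups.group_members(gid) if g.species_tag == target_species
    )


def materialize_singletons(
    groups: OrthoGroupSet, universe: Iterable[GeneId]
) -> OrthoGroupSet:
    """Add a singleton group for every universe gene absent from all groups."""
    extra = [g for g in set(universe) - groups.members]
    merged_sets = [m for _, m in groups.groups] + [frozenset([g]) for g in extra]
    return OrthoGroupSet.from_groups(
        _synthesize_ids(merged_sets), provenance=groups.provenance
    )


def write_orthomcl_groups(groups: OrthoGroupSet, stream: IO[str]) -> None:
    """Write a group set in the OrthoMCL dialect, deterministically ordered."""
    for gid, members in sorted(groups.groups, key=lambda g: g[0]):
        rendered = " ".join(str(m) for m in sorted(members))
        stream.write(f"{gid}: {rendered}\n")
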