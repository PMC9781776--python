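"""Reference sugar catabolic network of *Aspergillus niger*.

The network is a curated set of sugar catabolic pathways (glycolysis, pentose
catabolic and pentose phosphate pathways, the three D-galactose sub-pathways,
D-mannose, D-gluconate, D-galacturonic acid, L-rhamnose and glycerol
metabolism, TCA and glyoxylate cycles) expressed as reactions with EC numbers
and reference gene assignments. Reactions are either enzymatic or spontaneous;
a reaction whose catalyzing gene is unknown in every studied fungus is marked
*orphan* and excluded from completeness scoring downstream.

The packaged description (``data/aniger_sugar_network.yaml``) is a
human-editable YAML file; :func:`load_reference_network` validates it into an
immutable :class:`ReferenceNetwork` and :func:`serialize_network` emits a
canonical form so round-trips are bit-exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .orthology import GeneId

__all__ = [
    "GeneRef",
    "Reaction",
    "Pathway",
    "ReferenceNetwork",
    "NetworkStructureError",
    "NetworkLookupError",
    "load_reference_network",
    "serialize_network",
    "EC_PATTERN",
]

#: An EC number: four dot-separated fields, the last being a serial number, a
#: dash for an unassigned sub-subclass ("1.1.1.-"), or a preliminary "n" number.
EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-|n\d*)$")

_PACKAGED_NETWORK = "aniger_sugar_network.yaml"


class NetworkStructureError(ValueError):
    """The network description violates a structural invariant."""


class NetworkLookupError(KeyError):
    """A pathway or reaction identifier does not exist in the network."""


@dataclass(frozen=True)
class GeneRef:
    """A reference gene assignment: display name plus species-qualified locus."""

    name: str
    gene: GeneId
    placeholder: bool = False


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    name: str
    ec_numbers: tuple[str, ...]
    kind: str  # "enzymatic" | "spontaneous"
    role: str  # "core" | "auxiliary"
    orphan: bool
    pathway_ids: tuple[str, ...]
    genes: tuple[GeneRef, ...]
    substrates: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    note: str | None = None


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    parent: str | None = None  # sub-pathway of, e.g. leloir -> d_galactose


@dataclass(frozen=True)
class ReferenceNetwork:
    """Validated, immutable reference network with structural query methods."""

    name: str
    reference_species: str
    pathways: tuple[Pathway, ...]
    reactions: tuple[Reaction, ...]
    schema_version: int = 1
    _pathway_index: Mapping[str, Pathway] = field(repr=False, default_factory=dict)
    _reaction_index: Mapping[str, Reaction] = field(repr=False, default_factory=dict)

    # -- lookups ----------------------------------------------------------

    def pathway(self, pathway_id: str) -> Pathway:
        try:
            return self._pathway_index[pathway_id]
        except KeyError:
            raise NetworkLookupError(f"unknown pathway {pathway_id!r}") from None

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self._reaction_index[reaction_id]
        except KeyError:
            raise NetworkLookupError(f"unknown reaction {reaction_id!r}") from None

    @property
    def top_level_pathways(self) -> tuple[Pathway, ...]:
        return tuple(p for p in self.pathways if p.parent is None)

    def sub_pathways(self, pathway_id: str) -> tuple[Pathway, ...]:
        self.pathway(pathway_id)
        return tuple(p for p in self.pathways if p.parent == pathway_id)

    def _pathway_scope(self, pathway_id: str) -> set[str]:
        """The pathway itself plus its sub-pathways."""
        self.pathway(pathway_id)
        return {pathway_id} | {p.pathway_id for p in self.sub_pathways(pathway_id)}

    def pathway_reactions(
        self, pathway_id: str, include_auxiliary: bool = True
    ) -> tuple[Reaction, ...]:
        """All reactions of a pathway, aggregating over its sub-pathways."""
        scope = self._pathway_scope(pathway_id)
        out = tuple(
            r
            for r in self.reactions
            if scope.intersection(r.pathway_ids)
            and (include_auxiliary or r.role == "core")
        )
        return out

    def pathway_reaction_count(
        self, pathway_id: str, include_auxiliary: bool = False
    ) -> int:
        """Number of reactions of a pathway (core only unless told otherwise)."""
        return len(self.pathway_reactions(pathway_id, include_auxiliary))

    def shared_reactions(self, pathway_a: str, pathway_b: str) -> set[str]:
        """Reaction ids whose pathway memberships include both arguments."""
        scope_a = self._pathway_scope(pathway_a)
        scope_b = self._pathway_scope(pathway_b)
        return {
            r.reaction_id
            for r in self.reactions
            if scope_a.intersection(r.pathway_ids)
            and scope_b.intersection(r.pathway_ids)
        }

    def genes_for_reaction(self, reaction_id: str) -> tuple[GeneRef, ...]:
        return self.reaction(reaction_id).genes

    @property
    def gene_index(self) -> dict[GeneId, tuple[str, ...]]:
        """Reference gene -> ids of the reactions it catalyzes."""
        idx: dict[GeneId, list[str]] = {}
        for r in self.reactions:
            for g in r.genes:
                idx.setdefault(g.gene, []).append(r.reaction_id)
        return {g: tuple(rs) for g, rs in idx.items()}

    def scorable_reactions(self, pathway_id: str) -> tuple[Reaction, ...]:
        """Reactions entering completeness scoring: non-orphan, any kind/role."""
        return tuple(
            r for r in self.pathway_reactions(pathway_id) if not r.orphan
        )


# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------


def _parse_gene(raw: Mapping, species: str) -> GeneRef:
    name = raw["name"]
    locus = raw.get("locus", name)
    return GeneRef(
        name=name,
        gene=GeneId(species, locus),
        placeholder=bool(raw.get("placeholder", False)),
    )


def _validate(net: ReferenceNetwork) -> None:
    seen_pw: set[str] = set()
    for p in net.pathways:
        if p.pathway_id in seen_pw:
            raise NetworkStructureError(f"duplicate pathway id {p.pathway_id!r}")
        seen_pw.add(p.pathway_id)
    for p in net.pathways:
        if p.parent is not None and p.parent not in seen_pw:
            raise NetworkStructureError(
                f"pathway {p.pathway_id!r} references unknown parent {p.parent!r}"
            )

    seen_rx: set[str] = set()
    for r in net.reactions:
        if r.reaction_id in seen_rx:
            raise NetworkStructureError(f"duplicate reaction id {r.reaction_id!r}")
        seen_rx.add(r.reaction_id)
        if not r.pathway_ids:
            raise NetworkStructureError(
                f"reaction {r.reaction_id!r} belongs to no pathway"
            )
        for pid in r.pathway_ids:
            if pid not in seen_pw:
                raise NetworkStructureError(
                    f"reaction {r.reaction_id!r} references unknown pathway {pid!r}"
                )
        if r.kind not in ("enzymatic", "spontaneous"):
            raise NetworkStructureError(
                f"reaction {r.reaction_id!r} has invalid kind {r.kind!r}"
            )
        if r.role not in ("core", "auxiliary"):
            raise NetworkStructureError(
                f"reaction {r.reaction_id!r} has invalid role {r.role!r}"
            )
        if r.kind == "spontaneous" and r.genes:
            raise NetworkStructureError(
                f"spontaneous reaction {r.reaction_id!r} carries genes"
            )
        if r.orphan and (r.genes or r.kind != "enzymatic"):
            raise NetworkStructureError(
                f"orphan reaction {r.reaction_id!r} must be enzymatic and geneless"
            )
        for ec in r.ec_numbers:
            if not EC_PATTERN.match(ec):
                raise NetworkStructureError(
                    f"reaction {r.reaction_id!r} has malformed EC number {ec!r}"
                )

    # every pathway must have >=1 reaction, directly or through sub-pathways
    for p in net.pathways:
        if not net.pathway_reactions(p.pathway_id):
            raise NetworkStructureError(f"pathway {p.pathway_id!r} has no reactions")


def load_reference_network(source: str | Path | None = None) -> ReferenceNetwork:
    """Load and validate a network description.

    Parameters
    ----------
    source
        Path to a YAML network description. When omitted, the packaged
        *A. niger* network is loaded.
    """
    if source is None:
        text = (
            resources.files("sugarnet.data").joinpath(_PACKAGED_NETWORK).read_text()
        )
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise NetworkStructureError("network description is not a mapping")
    species = raw.get("reference_species", "anig")
    pathways = tuple(
        Pathway(p["id"], p.get("name", p["id"]), p.get("parent"))
        for p in raw.get("pathways", [])
    )
    reactions = tuple(
        Reaction(
            reaction_id=r["id"],
            name=r.get("name", r["id"]),
            ec_numbers=tuple(r.get("ec", [])),
            kind=r.get("kind", "enzymatic"),
            role=r.get("role", "core"),
            orphan=bool(r.get("orphan", False)),
            pathway_ids=tuple(r.get("pathways", [])),
            genes=tuple(_parse_gene(g, species) for g in r.get("genes", [])),
            substrates=tuple(r.get("substrates", [])),
            products=tuple(r.get("products", [])),
            note=r.get("note"),
        )
        for r in raw.get("reactions", [])
    )
    net = ReferenceNetwork(
        name=raw.get("name", "sugar catabolic network"),
        reference_species=species,
        pathways=pathways,
        reactions=reactions,
        schema_version=int(raw.get("schema_version", 1)),
        _pathway_index={p.pathway_id: p for p in pathways},
        _reaction_index={r.reaction_id: r for r in reactions},
    )
    _validate(net)
    return net


def serialize_network(net: ReferenceNetwork) -> str:
    """Canonical YAML serialization; ``load(serialize(net))`` is an identity."""
    doc = {
        "schema_version": net.schema_version,
        "name": net.name,
        "reference_species": net.reference_species,
        "pathways": [
            {
                "id": p.pathway_id,
                "name": p.name,
                **({"parent": p.parent} if p.parent else {}),
            }
            for p in net.pathways
        ],
        "reactions": [
            {
                "id": r.reaction_id,
                "name": r.name,
                "ec": list(r.ec_numbers),
                "kind": r.kind,
                "role": r.role,
                "orphan": r.orphan,
                "pathways": list(r.pathway_ids),
                "genes": [
                    {
                        "name": g.name,
                        **(
                            {"locus": g.gene.local_id}
                            if g.gene.local_id != g.name
                            else {}
                        ),
                        **({"placeholder": True} if g.placeholder else {}),
                    }
                    for g in r.genes
                ],
                "substrates": list(r.substrates),
                "products": list(r.products),
                **({"note": r.note} if r.note else {}),
            }
            for r in net.reactions
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False, width=88)
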