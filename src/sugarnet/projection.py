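"""Projection of the reference network onto target species.

A projection maps every reaction of the reference network to the candidate
genes of a target species, obtained as orthologs of the reaction's reference
genes in the merged orthogroup set. Candidates start out ``active`` (or
``excluded_by_list``); an expression filter demotes putative pseudogenes
(maximum FPKM < 10 across all tested conditions) to ``low_expression``, while
genes missing from the expression matrix are retained as
``no_expression_data``. Pathway completeness is the percentage of scorable
reference reactions (orphan steps excluded) that the species covers:
spontaneous steps always count as present; an enzymatic step is present when
at least one unfiltered candidate exists.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import GeneRef, ReferenceNetwork, NetworkLookupError
from .orthology import GeneId, OrthoGroupSet, orthologs_of

__all__ = [
    "GeneStatus",
    "CandidateGene",
    "ProjectedNetwork",
    "project_network",
    "apply_expression_filter",
    "completeness_score",
    "completeness_matrix",
    "export_pathologic",
    "ExpressionDataError",
]

#: Statuses counting as "present" for completeness and for gene counts.
_UNFILTERED = ("active", "no_expression_data")


class ExpressionDataError(ValueError):
    """An expression matrix violates a data invariant (e.g. negative FPKM)."""


class GeneStatus(str, Enum):
    ACTIVE = "active"
    LOW_EXPRESSION = "low_expression"
    NO_EXPRESSION_DATA = "no_expression_data"
    EXCLUDED_BY_LIST = "excluded_by_list"


@dataclass(frozen=True)
class CandidateGene:
    gene: GeneId
    source: GeneRef
    status: GeneStatus = GeneStatus.ACTIVE


@dataclass(frozen=True)
class ProjectedNetwork:
    species_tag: str
    candidates: Mapping[str, tuple[CandidateGene, ...]]  # reaction_id -> genes

    def reaction_candidates(self, reaction_id: str) -> tuple[CandidateGene, ...]:
        return self.candidates.get(reaction_id, ())


def project_network(
    net: ReferenceNetwork,
    orthos: OrthoGroupSet,
    species_tag: str,
    exclusion_list: Sequence[GeneId] | None = None,
) -> ProjectedNetwork:
    """Project the reference network onto ``species_tag`` via orthogroups.

    For each enzymatic reaction the candidates are the union, over the
    reaction's reference genes, of their orthologs in the target species.
    Projecting onto the reference species itself additionally includes each
    reference gene as its own candidate, so the reference row is complete by
    construction. Spontaneous reactions carry no candidates but are present.
    """
    excluded = frozenset(exclusion_list or ())
    for g in excluded:
        if g.species_tag != species_tag:
            raise ValueError(
                f"exclusion list entry {g} does not belong to species {species_tag!r}"
            )
    candidates: dict[str, tuple[CandidateGene, ...]] = {}
    for reaction in net.reactions:
        found: dict[GeneId, CandidateGene] = {}
        for ref_gene in reaction.genes:
            hits = list(orthologs_of(orthos, ref_gene.gene, species_tag))
            if species_tag == ref_gene.gene.species_tag and ref_gene.gene not in hits:
                hits.append(ref_gene.gene)
            for hit in hits:
                if hit in found:
                    continue
                status = (
                    GeneStatus.EXCLUDED_BY_LIST
                    if hit in excluded
                    else GeneStatus.ACTIVE
                )
                found[hit] = CandidateGene(gene=hit, source=ref_gene, status=status)
        candidates[reaction.reaction_id] = tuple(
            found[g] for g in sorted(found)
        )
    return ProjectedNetwork(species_tag=species_tag, candidates=candidates)


def apply_expression_filter(
    proj: ProjectedNetwork,
    expr: pd.DataFrame,
    threshold: float = 10.0,
) -> ProjectedNetwork:
    """Demote candidates whose maximum FPKM over all conditions is < threshold.

    Genes absent from the matrix are retained with status
    ``no_expression_data``; explicitly excluded genes are left untouched.
    Returns a new projection; the input projection and matrix are unchanged.
    """
    values = expr.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ExpressionDataError("expression matrix contains negative FPKM values")
    if not np.all(np.isfinite(values)):
        raise ExpressionDataError("expression matrix contains non-finite values")
    max_fpkm = expr.max(axis=1)

    def refilter(c: CandidateGene) -> CandidateGene:
        if c.status is GeneStatus.EXCLUDED_BY_LIST:
            return c
        key = str(c.gene)
        if key not in max_fpkm.index:
            return replace(c, status=GeneStatus.NO_EXPRESSION_DATA)
        if max_fpkm[key] < threshold:
            return replace(c, status=GeneStatus.LOW_EXPRESSION)
        return replace(c, status=GeneStatus.ACTIVE)

    new_candidates = {
        rid: tuple(refilter(c) for c in cands)
        for rid, cands in proj.candidates.items()
    }
    return ProjectedNetwork(species_tag=proj.species_tag, candidates=new_candidates)


def _reaction_present(proj: ProjectedNetwork, net: ReferenceNetwork, rid: str) -> bool:
    reaction = net.reaction(rid)
    if reaction.kind == "spontaneous":
        return True
    return any(
        c.status.value in _UNFILTERED for c in proj.reaction_candidates(rid)
    )


def completeness_score(
    proj: ProjectedNetwork, net: ReferenceNetwork, pathway_id: str
) -> float:
    """Pathway completeness: 100 x present / scorable, one decimal.

    Orphan reactions are excluded from numerator and denominator (no species,
    the reference included, carries a gene for them).
    """
    scorable = net.scorable_reactions(pathway_id)
    if not scorable:
        raise ZeroDivisionError(
            f"pathway {pathway_id!r} has no scorable reactions"
        )
    present = sum(
        1 for r in scorable if _reaction_present(proj, net, r.reaction_id)
    )
    return round(100.0 * present / len(scorable), 1)


def _pathway_gene_count(
    proj: ProjectedNetwork, net: ReferenceNetwork, pathway_id: str
) -> int:
    genes: set[GeneId] = set()
    for r in net.scorable_reactions(pathway_id):
        for c in proj.reaction_candidates(r.reaction_id):
            if c.status.value in _UNFILTERED:
                genes.add(c.gene)
    return len(genes)


def missing_reactions(
    proj: ProjectedNetwork, net: ReferenceNetwork, pathway_id: str
) -> tuple[str, ...]:
    return tuple(
        r.reaction_id
        for r in net.scorable_reactions(pathway_id)
        if not _reaction_present(proj, net, r.reaction_id)
    )


def completeness_matrix(
    projections: Sequence[ProjectedNetwork], net: ReferenceNetwork
) -> pd.DataFrame:
    """Per-(species, pathway) gene counts and completeness (the dot-matrix table).

    Rows cover every pathway of the network, sub-pathways included, so both
    aggregate and per-sub-pathway completeness are reported.
    """
    tags = [p.species_tag for p in projections]
    if len(set(tags)) != len(tags):
        raise ValueError(f"duplicated species tags in projections: {tags}")
    rows = []
    for proj in projections:
        for pw in net.pathways:
            rows.append(
                {
                    "species": proj.species_tag,
                    "pathway": pw.pathway_id,
                    "gene_count": _pathway_gene_count(proj, net, pw.pathway_id),
                    "completeness_pct": completeness_score(proj, net, pw.pathway_id),
                    "missing_reaction_ids": ",".join(
                        missing_reactions(proj, net, pw.pathway_id)
                    ),
                }
            )
    return pd.DataFrame(rows)


def projection_to_dict(proj: ProjectedNetwork) -> dict:
    """JSON-serializable dump of a projection."""
    return {
        "species_tag": proj.species_tag,
        "candidates": {
            rid: [
                {
                    "gene": str(c.gene),
                    "source": c.source.gene.local_id,
                    "status": c.status.value,
                }
                for c in cands
            ]
            for rid, cands in sorted(proj.candidates.items())
        },
    }


def projection_from_dict(data: Mapping, net: ReferenceNetwork) -> ProjectedNetwork:
    """Rebuild a projection from its JSON dump against the source network."""
    candidates: dict[str, tuple[CandidateGene, ...]] = {}
    for rid, cands in data["candidates"].items():
        reaction = net.reaction(rid)
        by_locus = {g.gene.local_id: g for g in reaction.genes}
        rebuilt = []
        for c in cands:
            source = by_locus.get(c["source"])
            if source is None:
                raise NetworkLookupError(
                    f"reaction {rid!r} has no reference gene {c['source']!r}"
                )
            rebuilt.append(
                CandidateGene(
                    gene=GeneId.parse(c["gene"]),
                    source=source,
                    status=GeneStatus(c["status"]),
                )
            )
        candidates[rid] = tuple(rebuilt)
    return ProjectedNetwork(species_tag=data["species_tag"], candidates=candidates)


# ---------------------------------------------------------------------------
# PathoLogic export
# ---------------------------------------------------------------------------


def export_pathologic(
    proj: ProjectedNetwork,
    net: ReferenceNetwork,
    coordinates: Mapping[GeneId, tuple[int, int]] | None = None,
) -> dict[str, str]:
    """Render the projection as PathoLogic flat files.

    One entry per unfiltered candidate gene, carrying ID, NAME, PRODUCT and EC
    lines inherited from the reaction(s) the gene is a candidate for.
    Coordinates are 1-based inclusive; a minus-strand gene is encoded by
    STARTBASE > ENDBASE. Output is byte-deterministic for identical input.
    """
    per_gene: dict[GeneId, dict] = {}
    for rid in sorted(proj.candidates):
        reaction = net.reaction(rid)
        for c in proj.reaction_candidates(rid):
            if c.status.value not in _UNFILTERED:
                continue
            entry = per_gene.setdefault(
                c.gene, {"names": [], "products": [], "ecs": []}
            )
            if c.source.name not in entry["names"]:
                entry["names"].append(c.source.name)
            if reaction.name not in entry["products"]:
                entry["products"].append(reaction.name)
            for ec in reaction.ec_numbers:
                if ec not in entry["ecs"]:
                    entry["ecs"].append(ec)

    lines: list[str] = []
    for gene in sorted(per_gene):
        entry = per_gene[gene]
        lines.append(f"ID\t{gene.local_id}")
        lines.append(f"NAME\t{' / '.join(entry['names'])}")
        lines.append("PRODUCT-TYPE\tP")
        for product in entry["products"]:
            lines.append(f"PRODUCT\t{product}")
        for ec in entry["ecs"]:
            lines.append(f"EC\t{ec}")
        if coordinates is not None and gene in coordinates:
            start, end = coordinates[gene]
            if start == 0 and end == 0:
                raise ValueError(f"gene {gene}: coordinates start=end=0")
            lines.append(f"STARTBASE\t{start}")
            lines.append(f"ENDBASE\t{end}")
        lines.append("//")
    pf_name = f"{proj.species_tag}.pf"
    elements = (
        f"ID\t{proj.species_tag.upper()}-CHROM-1\n"
        "NAME\tunplaced scaffold collection\n"
        "TYPE\t:CHRSM\n"
        "CIRCULAR?\tN\n"
        f"ANNOT-FILE\t{pf_name}\n"
        "//\n"
    )
    return {pf_name: "\n".join(lines) + ("\n" if lines else ""),
            "genetic-elements.dat": elements}
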