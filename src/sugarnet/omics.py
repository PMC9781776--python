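"""Multi-omics integration: transcriptome, proteome and metabolome screens.

The transcriptome side clusters growth conditions by correlation distance
over the sugar-metabolic gene set and flags sugar-specific induction. The
proteome side rolls protein-specific peptide abundances up to protein level
(de-log, sum, re-log, re-normalize), averages nonzero replicates per
condition, and summarizes per-pathway abundance distributions. The
metabolome side screens all gene x metabolite pairs with a Pearson
correlation filter (|PCC| >= 0.5, p < 0.05; strong when PCC >= 0.8).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .config import AnalysisConfig, PATHWAY_COGNATES
from .network import ReferenceNetwork
from .projection import ProjectedNetwork, GeneStatus

__all__ = [
    "cluster_conditions",
    "derive_cognate_map",
    "detect_sugar_induction",
    "normalize_central_tendency",
    "rollup_peptides_to_proteins",
    "summarize_replicates",
    "pathway_abundance_profile",
    "correlate_genes_metabolites",
    "OmicsDataError",
]

logger = logging.getLogger(__name__)


class OmicsDataError(ValueError):
    """An omics table violates a precondition."""


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------


def cluster_conditions(
    expr: pd.DataFrame, gene_subset: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of condition columns.

    Distance is 1 - Pearson correlation between condition profiles over the
    gene subset; linkage is average. Columns are processed in sorted label
    order so tied merges are deterministic.

    Returns the scipy linkage matrix and the condition labels in the order
    matching its leaf indices.
    """
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in expr.index]
        if missing:
            raise OmicsDataError(f"genes absent from expression matrix: {missing[:5]}")
        expr = expr.loc[list(gene_subset)]
    if expr.shape[1] < 2:
        raise OmicsDataError("need at least two conditions to cluster")
    if expr.shape[0] < 3:
        raise OmicsDataError("need at least three genes to cluster conditions")
    labels = sorted(expr.columns)
    mat = expr[labels].to_numpy(dtype=float)
    sd = mat.std(axis=0)
    for lab, s in zip(labels, sd):
        if s == 0:
            raise OmicsDataError(f"condition {lab!r} has a constant profile")
    corr = np.corrcoef(mat, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    z = linkage(squareform(dist, checks=False), method="average")
    return z, labels


def derive_cognate_map(
    proj: ProjectedNetwork,
    net: ReferenceNetwork,
    cognates: Mapping[str, str] = PATHWAY_COGNATES,
) -> dict[str, str]:
    """Map each sugar-specific candidate gene to its cognate condition.

    A candidate gene is sugar-specific when every pathway of every reaction it
    is a candidate for maps to the same cognate sugar; genes of central-carbon
    pathways or spanning differently-induced pathways are left unmapped.
    """
    gene_cognates: dict[str, set[str | None]] = {}
    for rid, cands in proj.candidates.items():
        pids = net.reaction(rid).pathway_ids
        for c in cands:
            bucket = gene_cognates.setdefault(str(c.gene), set())
            bucket.update(cognates.get(pid) for pid in pids)
    return {
        gene: next(iter(cs))
        for gene, cs in sorted(gene_cognates.items())
        if None not in cs and len(cs) == 1
    }


def detect_sugar_induction(
    expr: pd.DataFrame,
    cognate_map: Mapping[str, str],
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Flag genes induced on their cognate sugar.

    A gene is induced when its cognate-condition FPKM is the row maximum and
    at least ``induction_fold`` times the median of the other conditions
    (when that median is zero, the cognate FPKM must instead clear
    ``fpkm_threshold``). Returns a frame indexed by gene with columns
    ``cognate``, ``induced`` and ``fold``.
    """
    rows = []
    for gene, cognate in sorted(cognate_map.items()):
        if gene not in expr.index:
            raise OmicsDataError(f"gene {gene!r} absent from expression matrix")
        if cognate not in expr.columns:
            raise OmicsDataError(
                f"gene {gene!r} mapped to condition {cognate!r} absent from matrix"
            )
        row = expr.loc[gene]
        cognate_val = float(row[cognate])
        others = row.drop(labels=[cognate]).to_numpy(dtype=float)
        med = float(np.median(others)) if others.size else 0.0
        is_max = others.size == 0 or cognate_val >= others.max()
        if med > 0:
            fold = cognate_val / med
            induced = is_max and fold >= config.induction_fold
        else:
            fold = np.inf if cognate_val > 0 else 0.0
            induced = is_max and cognate_val >= config.fpkm_threshold
        rows.append(
            {"gene": gene, "cognate": cognate, "induced": bool(induced), "fold": fold}
        )
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------


def normalize_central_tendency(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean central-tendency normalization of a log2 abundance matrix.

    Each column is shifted so that its mean over non-missing entries equals
    the grand mean of the input; missing entries stay missing. Idempotent,
    and within-column differences are preserved exactly.
    """
    col_means = matrix.mean(axis=0, skipna=True)
    if col_means.isna().any():
        bad = list(col_means.index[col_means.isna()])
        raise OmicsDataError(f"all-missing column(s): {bad}")
    grand = float(np.nanmean(matrix.to_numpy(dtype=float)))
    return matrix + (grand - col_means)


def rollup_peptides_to_proteins(peptides: pd.DataFrame) -> pd.DataFrame:
    """Roll normalized peptide log2 abundances up to protein level.

    Expects a peptide table with metadata columns ``protein`` (parent protein
    id) and ``specific`` (protein-specific flag); remaining columns are
    samples. Non-specific peptides are dropped. Per protein and sample the
    normalized values are de-logged (2**x), summed over non-missing peptides
    and re-logged; a protein is missing in a sample iff all its peptides are.
    The rolled-up table is re-normalized by central tendency.
    """
    meta_cols = {"protein", "specific"}
    if not meta_cols.issubset(peptides.columns):
        raise OmicsDataError("peptide table needs 'protein' and 'specific' columns")
    sample_cols = [c for c in peptides.columns if c not in meta_cols]
    dropped = set(peptides.loc[~peptides["specific"].astype(bool), "protein"]) - set(
        peptides.loc[peptides["specific"].astype(bool), "protein"]
    )
    if dropped:
        logger.warning(
            "%d protein(s) had no protein-specific peptides and were dropped: %s",
            len(dropped),
            sorted(dropped)[:5],
        )
    specific = peptides.loc[peptides["specific"].astype(bool)]
    delogged = np.power(2.0, specific[sample_cols].astype(float))
    summed = delogged.groupby(specific["protein"]).sum(min_count=1)
    protein = np.log2(summed)
    protein.index.name = "protein"
    return normalize_central_tendency(protein)


def summarize_replicates(protein_table: pd.DataFrame) -> pd.DataFrame:
    """Average the strictly positive replicate values per condition.

    Expects columns as a (condition, replicate) MultiIndex with missing
    values already filled with zeros. A condition with no positive replicate
    yields 0.
    """
    if not isinstance(protein_table.columns, pd.MultiIndex):
        raise OmicsDataError("protein table columns must be (condition, replicate)")
    filled = protein_table.fillna(0.0)
    out = {}
    for condition in sorted({c for c, _ in filled.columns}):
        block = filled.loc[:, condition].to_numpy(dtype=float)
        positive = block > 0
        counts = positive.sum(axis=1)
        sums = np.where(positive, block, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        out[condition] = means
    return pd.DataFrame(out, index=filled.index)


def pathway_abundance_profile(
    protein_cond: pd.DataFrame,
    proj: ProjectedNetwork,
    net: ReferenceNetwork,
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Per-(pathway, condition) summary of protein abundance distributions.

    Proteins detected (> 0) in fewer than ``detection_fraction`` of the
    conditions are dropped. Remaining abundances are grouped by the pathways
    their gene is a candidate for; output columns: n, median, q1, q3.
    """
    n_cond = protein_cond.shape[1]
    detected_frac = (protein_cond > 0).sum(axis=1) / n_cond
    kept = protein_cond.loc[detected_frac >= config.detection_fraction]

    gene_pathways: dict[str, set[str]] = {}
    for rid, cands in proj.candidates.items():
        pids = net.reaction(rid).pathway_ids
        for c in cands:
            if c.status in (GeneStatus.ACTIVE, GeneStatus.NO_EXPRESSION_DATA):
                gene_pathways.setdefault(str(c.gene), set()).update(pids)

    rows = []
    all_pids = [p.pathway_id for p in net.pathways]
    for pid in all_pids:
        members = [g for g in kept.index if pid in gene_pathways.get(g, ())]
        for condition in kept.columns:
            vals = kept.loc[members, condition]
            vals = vals[vals > 0].to_numpy(dtype=float)
            if vals.size:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            rows.append(
                {
                    "pathway": pid,
                    "condition": condition,
                    "n": int(vals.size),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metabolome
# ---------------------------------------------------------------------------


def correlate_genes_metabolites(
    expr: pd.DataFrame,
    metab: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Pearson screen of every gene x metabolite pair over shared conditions.

    p-values come from the exact t transform with n - 2 degrees of freedom
    (two-sided). Pairs involving a zero-variance vector are excluded with a
    warning. Output columns: gene, metabolite, pcc, p, passes, strong, sign.
    """
    shared = [c for c in expr.columns if c in set(metab.columns)]
    if len(shared) < 4:
        raise OmicsDataError(
            f"need >= 4 shared conditions for the correlation screen, got {len(shared)}"
        )
    x = expr[shared].to_numpy(dtype=float)
    y = metab[shared].to_numpy(dtype=float)
    n = len(shared)

    x_sd = x.std(axis=1)
    y_sd = y.std(axis=1)
    bad_genes = [g for g, s in zip(expr.index, x_sd) if s == 0]
    bad_metabs = [m for m, s in zip(metab.index, y_sd) if s == 0]
    if bad_genes or bad_metabs:
        logger.warning(
            "zero-variance vectors excluded from correlation screen: %s %s",
            bad_genes[:5],
            bad_metabs[:5],
        )
    xi = [i for i, s in enumerate(x_sd) if s > 0]
    yi = [j for j, s in enumerate(y_sd) if s > 0]

    xz = (x[xi] - x[xi].mean(axis=1, keepdims=True)) / x_sd[xi][:, None]
    yz = (y[yi] - y[yi].mean(axis=1, keepdims=True)) / y_sd[yi][:, None]
    pcc = np.clip(xz @ yz.T / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = pcc * np.sqrt((n - 2) / np.maximum(1.0 - pcc**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(pcc) >= 1.0, 0.0, p)

    genes = expr.index[xi]
    metabolites = metab.index[yi]
    gi, mj = np.meshgrid(np.arange(len(genes)), np.arange(len(metabolites)), indexing="ij")
    flat_pcc = pcc[gi.ravel(), mj.ravel()]
    flat_p = p[gi.ravel(), mj.ravel()]
    passes = (np.abs(flat_pcc) >= config.pcc_min) & (flat_p < config.alpha)
    strong = passes & (flat_pcc >= config.pcc_strong)
    out = pd.DataFrame(
        {
            "gene": genes[gi.ravel()],
            "metabolite": metabolites[mj.ravel()],
            "pcc": flat_pcc,
            "p": flat_p,
            "passes": passes,
            "strong": strong,
            "sign": np.where(flat_pcc >= 0, "positive", "negative"),
        }
    )
    return out.reset_index(drop=True)
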