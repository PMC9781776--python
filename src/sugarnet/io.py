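"""TSV readers and writers for the pipeline's tabular interfaces."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import CONDITIONS
from .omics import OmicsDataError
from .projection import ExpressionDataError

__all__ = [
    "read_expression_tsv",
    "read_metabolites_tsv",
    "read_peptides_tsv",
    "peptide_samples_to_multiindex",
]

logger = logging.getLogger(__name__)


def _read_rectangular_tsv(path: str | Path, index_col: str) -> pd.DataFrame:
    """Read a TSV, rejecting ragged rows with the offending row number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise OmicsDataError(f"{path}: empty file")
    width = len(lines[0].split("\t"))
    for rowno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if len(line.split("\t")) != width:
            raise OmicsDataError(
                f"{path}: ragged row {rowno} (expected {width} fields)"
            )
    df = pd.read_csv(path, sep="\t")
    if index_col not in df.columns:
        raise OmicsDataError(f"{path}: missing index column {index_col!r}")
    df = df.set_index(index_col)
    if df.index.duplicated().any():
        dupes = list(df.index[df.index.duplicated()][:5])
        raise OmicsDataError(f"{path}: duplicate row labels {dupes}")
    return df


def _check_conditions(df: pd.DataFrame, path: Path, vocabulary=CONDITIONS) -> None:
    unknown = [c for c in df.columns if c not in vocabulary]
    if unknown:
        logger.warning("%s: non-canonical condition labels %s", path, unknown[:5])


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Gene x condition FPKM matrix; values must be finite and non-negative."""
    df = _read_rectangular_tsv(path, "gene").astype(float)
    if (df.to_numpy() < 0).any():
        raise ExpressionDataError(f"{path}: negative FPKM values")
    _check_conditions(df, Path(path))
    return df


def read_metabolites_tsv(path: str | Path) -> pd.DataFrame:
    """Metabolite x condition abundance matrix."""
    df = _read_rectangular_tsv(path, "metabolite").astype(float)
    if (df.to_numpy() < 0).any():
        raise OmicsDataError(f"{path}: negative metabolite abundances")
    _check_conditions(df, Path(path))
    return df


def read_peptides_tsv(path: str | Path) -> pd.DataFrame:
    """Peptide table: 'protein' and 'specific' metadata plus 'cond::rep' samples."""
    df = _read_rectangular_tsv(path, "peptide")
    for col in ("protein", "specific"):
        if col not in df.columns:
            raise OmicsDataError(f"{path}: missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("protein", "specific")]
    for col in sample_cols:
        if "::" not in col:
            raise OmicsDataError(
                f"{path}: sample column {col!r} is not 'condition::replicate'"
            )
    df["specific"] = df["specific"].astype(bool)
    df[sample_cols] = df[sample_cols].astype(float)
    return df


def peptide_samples_to_multiindex(table: pd.DataFrame) -> pd.DataFrame:
    """Convert 'condition::replicate' sample columns to a (condition, replicate)
    MultiIndex, validating that every condition carries the full replicate set."""
    pairs = [tuple(c.split("::", 1)) for c in table.columns]
    out = table.copy()
    out.columns = pd.MultiIndex.from_tuples(pairs, names=["condition", "replicate"])
    by_condition = {}
    for cond, rep in pairs:
        by_condition.setdefault(cond, set()).add(rep)
    expected = None
    for cond, reps in by_condition.items():
        if expected is None:
            expected = reps
        elif reps != expected:
            raise OmicsDataError(
                f"condition {cond!r} has replicates {sorted(reps)}, "
                f"expected {sorted(expected)}"
            )
    return out
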