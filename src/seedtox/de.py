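"""Differential-expression table IO, gene classification, and match joining.

Genes are classified against the volcano-plot convention: significance from
the adjusted p-value (padj <= alpha), direction from the sign of log2 fold
change.  Genes whose padj is missing (typically casualties of upstream
independent filtering) were never tested and are excluded from contingency
tables rather than counted as unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_de_table", "classify", "join_matches"]

LABELS = ("down", "up", "unchanged", "excluded")


def read_de_table(tsv) -> pd.DataFrame:
    """Read a DE TSV with columns gene_id, log2FC and optional pvalue, padj.

    Missing numeric cells (``NA``, empty) become NaN, never 0.  Raises with
    the offending row number on a non-numeric fold change.
    """
    df = pd.read_csv(tsv, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "log2FC"):
        if col not in df.columns:
            raise ValueError(f"DE table missing mandatory column {col!r}")
    for col in ("log2FC", "pvalue", "padj"):
        if col not in df.columns:
            df[col] = np.nan
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & ~df[col].astype(str).str.upper().isin(["NA", "NAN", ""])
        if col == "log2FC" and bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 1-based
            raise ValueError(f"non-numeric log2FC at row {row}: {df[col][bad].iloc[0]!r}")
        df[col] = coerced
    if df["log2FC"].isna().any():
        row = int(np.flatnonzero(df["log2FC"].isna())[0]) + 2
        raise ValueError(f"missing log2FC at row {row}")
    return df[["gene_id", "log2FC", "pvalue", "padj"]]


def classify(records: pd.DataFrame, alpha: float = 0.05, min_abs_lfc: float = 0.0) -> pd.DataFrame:
    """Label each gene down / up / unchanged / excluded.

    down: padj <= alpha and log2FC < -min_abs_lfc; up symmetric; excluded:
    padj missing; otherwise unchanged.  The labels partition the input.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    padj = records["padj"].to_numpy(float)
    lfc = records["log2FC"].to_numpy(float)
    label = np.full(len(records), "unchanged", dtype=object)
    sig = padj <= alpha  # NaN compares False
    label[sig & (lfc < -min_abs_lfc)] = "down"
    label[sig & (lfc > min_abs_lfc)] = "up"
    label[np.isnan(padj)] = "excluded"
    return pd.DataFrame({"gene_id": records["gene_id"].to_numpy(), "label": label})


def join_matches(classes: pd.DataFrame, matches: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Join class labels with the gene x spec match-count matrix.

    Genes lacking a UTR record are dropped; their number is returned as the
    exclusion tally.  Match counts are dichotomized to ``has_match`` columns
    (count >= 1), one per spec label.
    """
    classes = classes.set_index("gene_id") if "gene_id" in classes.columns else classes
    common = classes.index.intersection(matches.index)
    if len(common) == 0:
        raise ValueError("no genes shared between DE classes and UTR match table")
    n_excluded = len(classes.index) - len(common)
    joined = classes.loc[common, ["label"]].copy()
    for col in matches.columns:
        joined[f"has_match_{col}"] = (matches.loc[common, col] >= 1).to_numpy()
    joined.index.name = "gene_id"
    return joined, n_excluded
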