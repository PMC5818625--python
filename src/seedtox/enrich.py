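"""Fisher's exact enrichment of seed matches among regulated transcripts.

The 2x2 table crosses seed-match presence against membership in a regulation
class (downregulated for the off-target signal; upregulated and the
sense-strand seed serve as negative controls).  The primary statistic is the
one-sided hypergeometric tail P(X >= a) — enrichment of matches among the
chosen class; the minimum-likelihood two-sided p is reported alongside.
All tail computations run through log-space hypergeometric machinery and are
safe at transcriptome scale (totals ~1e5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .oligo import SeedSpec

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "build_table",
    "fisher_one_sided",
    "fisher_two_sided",
    "run_enrichment",
    "volcano_export",
]

# relative slack when comparing point probabilities in the two-sided sum:
# well above float error in the pmf, well below any genuine probability gap
_TIE_REL = 1e-11


@dataclass(frozen=True)
class ContingencyTable:
    """Counts: a = class & match, b = class & no match, c = rest & match, d = rest & no match."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.total < 1:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    spec_label: str
    direction: str
    table: ContingencyTable
    odds_ratio: float
    odds_ratio_haldane: bool
    p_one_sided: float
    p_two_sided: float


def build_table(analysis: pd.DataFrame, spec_label: str, direction: str) -> ContingencyTable:
    """Cross has_match for one seed spec against one regulation class.

    The class (e.g. ``down``) forms rows a+b; every other non-excluded gene is
    pooled into the complement rows c+d.
    """
    if direction not in ("down", "up"):
        raise ValueError(f"unknown direction {direction!r}")
    if len(analysis) == 0:
        raise ValueError("empty analysis table")
    col = f"has_match_{spec_label}"
    if col not in analysis.columns:
        raise ValueError(f"no match column for spec {spec_label!r}")
    kept = analysis[analysis["label"] != "excluded"]
    in_class = (kept["label"] == direction).to_numpy()
    match = kept[col].to_numpy(bool)
    return ContingencyTable(
        a=int((in_class & match).sum()),
        b=int((in_class & ~match).sum()),
        c=int((~in_class & match).sum()),
        d=int((~in_class & ~match).sum()),
    )


def _margins(t: ContingencyTable) -> tuple[int, int, int]:
    """(population N, matched K, class size n) for the hypergeometric law."""
    return t.total, t.a + t.c, t.a + t.b


def one_sided_tail(a, n_total: int, k_match: int, n_class: int) -> np.ndarray:
    """Vectorized P(X >= a) under the central hypergeometric law."""
    p = hypergeom.sf(np.asarray(a) - 1, n_total, k_match, n_class)
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def two_sided_minlike(a, n_total: int, k_match: int, n_class: int) -> np.ndarray:
    """Vectorized minimum-likelihood two-sided p.

    For each observed count the mass of every margin-compatible table whose
    point probability does not exceed the observed one (up to a relative tie
    slack well above pmf rounding error).
    """
    a = np.asarray(a)
    lo = max(0, n_class - (n_total - k_match))
    hi = min(k_match, n_class)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n_total, k_match, n_class)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    idx = np.searchsorted(sorted_pmf, pmf[a - lo] * (1.0 + _TIE_REL), side="right")
    p = cum[np.maximum(idx - 1, 0)]
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def fisher_one_sided(table: ContingencyTable) -> float:
    """P(X >= a): enrichment of matches among the chosen regulation class."""
    return float(one_sided_tail(table.a, *_margins(table)))


def fisher_two_sided(table: ContingencyTable) -> float:
    """Minimum-likelihood two-sided p: mass of all margin-compatible tables at
    most as probable as the observed one."""
    return float(two_sided_minlike(table.a, *_margins(table)))


def _odds_ratio(t: ContingencyTable) -> tuple[float, bool]:
    if 0 in (t.a, t.b, t.c, t.d):
        return (t.a + 0.5) * (t.d + 0.5) / ((t.b + 0.5) * (t.c + 0.5)), True
    return (t.a * t.d) / (t.b * t.c), False


def run_enrichment(
    analysis: pd.DataFrame,
    specs: list[SeedSpec],
    directions: list[str] = ("down", "up"),
) -> list[EnrichmentResult]:
    """One EnrichmentResult per (seed spec, direction) combination.

    With the default antisense and sense specs and both directions this
    produces the off-target signal cell (antisense, down) together with its
    negative controls (sense-strand seed; upregulated direction).
    """
    if not specs or not directions:
        raise ValueError("specs and directions must be non-empty")
    results = []
    for spec in specs:
        for direction in directions:
            t = build_table(analysis, spec.label, direction)
            orr, haldane = _odds_ratio(t)
            results.append(
                EnrichmentResult(
                    spec_label=spec.label,
                    direction=direction,
                    table=t,
                    odds_ratio=orr,
                    odds_ratio_haldane=haldane,
                    p_one_sided=fisher_one_sided(t),
                    p_two_sided=fisher_two_sided(t),
                )
            )
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular form of enrichment results (one row per spec x direction)."""
    return pd.DataFrame(
        {
            "spec_label": [r.spec_label for r in results],
            "direction": [r.direction for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "odds_ratio_haldane": [r.odds_ratio_haldane for r in results],
            "p_one_sided": [r.p_one_sided for r in results],
            "p_two_sided": [r.p_two_sided for r in results],
        }
    )


def volcano_export(
    de_records: pd.DataFrame, matches: pd.DataFrame, spec_label: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Plot-ready volcano table: log2FC vs -log10 padj, annotated by seed match.

    padj of exactly 0 is clamped to the smallest positive float before the log.
    """
    from .de import classify

    df = de_records.set_index("gene_id")
    common = df.index.intersection(matches.index)
    df = df.loc[common]
    padj = df["padj"].to_numpy(float)
    clamped = np.where(padj == 0, np.finfo(float).tiny, padj)
    labels = classify(df.reset_index(), alpha=alpha).set_index("gene_id")["label"]
    return pd.DataFrame(
        {
            "gene_id": common,
            "log2FC": df["log2FC"].to_numpy(),
            "neg_log10_padj": -np.log10(clamped),
            "has_match": (matches.loc[common, spec_label] >= 1).to_numpy(),
            "label": labels.loc[common].to_numpy(),
        }
    )
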