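"""Scan 3'UTR sequences for perfect seed-complementary sites.

A seed-match site is the exact reverse complement (DNA alphabet) of a strand
seed window, searched as a plain substring of the annotated 3'UTR.
Occurrences may overlap; windows containing ``N`` never match.  Coordinates
are 1-based, fully closed, on the UTR's own coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .oligo import SeedSpec, SiRNADuplex, seed_site

__all__ = ["UTRRecord", "SeedMatchResult", "load_utrs", "scan_utr", "scan_set", "find_all"]

_VALID_UTR = frozenset("ACGTN")


@dataclass(frozen=True)
class UTRRecord:
    """One gene's 3'UTR: DNA over {A,C,G,T,N}, upper-cased, U folded to T."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("empty gene_id")
        if len(self.sequence) < 1:
            raise ValueError(f"zero-length UTR for gene {self.gene_id}")
        bad = set(self.sequence) - _VALID_UTR
        if bad:
            raise ValueError(f"invalid characters in UTR {self.gene_id}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SeedMatchResult:
    gene_id: str
    site: str
    positions: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.positions)


def load_utrs(fasta, selection: str = "longest") -> list[UTRRecord]:
    """Load UTRs from FASTA, resolving multiple isoform records per gene.

    The gene identifier is the first whitespace-delimited header token.
    ``selection`` is one of ``longest`` (keep the longest isoform UTR, the
    default, maximizing site sensitivity), ``first`` (keep the first record
    seen), or ``concatenate`` (join all isoform UTRs in file order).
    """
    if selection not in ("longest", "first", "concatenate"):
        raise ValueError(f"unknown selection rule {selection!r}")
    per_gene: dict[str, list[str]] = {}
    n = 0
    for rec in SeqIO.parse(str(fasta), "fasta"):
        n += 1
        seq = str(rec.seq).upper().replace("U", "T")
        if len(seq) == 0:
            raise ValueError(f"zero-length record {rec.id!r}")
        per_gene.setdefault(rec.id, []).append(seq)
    if n == 0:
        raise ValueError(f"no FASTA records in {fasta}")
    out = []
    for gene_id, seqs in per_gene.items():
        if selection == "longest":
            seq = max(seqs, key=len)
        elif selection == "first":
            seq = seqs[0]
        else:
            seq = "".join(seqs)
        out.append(UTRRecord(gene_id=gene_id, sequence=seq))
    return out


def find_all(sequence: str, site: str) -> tuple[int, ...]:
    """1-based start positions of all (possibly overlapping) exact occurrences."""
    positions = []
    start = sequence.find(site)
    while start != -1:
        positions.append(start + 1)
        start = sequence.find(site, start + 1)
    return tuple(positions)


def scan_utr(utr: UTRRecord, site: str) -> SeedMatchResult:
    """All exact occurrences of ``site`` in one UTR (overlaps counted)."""
    if len(site) < 6:
        raise ValueError(f"site too short ({len(site)} < 6)")
    if set(site) - frozenset("ACGT"):
        raise ValueError(f"site must be DNA over ACGT: {site!r}")
    return SeedMatchResult(gene_id=utr.gene_id, site=site, positions=find_all(utr.sequence, site))


def scan_set(
    utrs: list[UTRRecord], duplex: SiRNADuplex, specs: list[SeedSpec]
) -> pd.DataFrame:
    """Complete gene x seed-spec match-count matrix (absent combinations are 0).

    Rows indexed by gene_id, one column per spec label; values are occurrence
    counts of that spec's seed-match site in the gene's 3'UTR.
    """
    data = {}
    for spec in specs:
        site = seed_site(duplex, spec)
        data[spec.label] = [scan_utr(u, site).count for u in utrs]
    return pd.DataFrame(data, index=pd.Index([u.gene_id for u in utrs], name="gene_id"), dtype=int)


def write_matches(utrs, duplex, specs, path) -> None:
    """TSV export: gene_id, spec_label, site, count, comma-joined positions."""
    rows = []
    for spec in specs:
        site = seed_site(duplex, spec)
        for u in utrs:
            res = scan_utr(u, site)
            rows.append(
                {
                    "gene_id": u.gene_id,
                    "spec_label": spec.label,
                    "site": site,
                    "count": res.count,
                    "positions": ",".join(map(str, res.positions)),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
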