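"""Screen short antidote-style oligonucleotides against a miRNA list.

A REVERSIR-type oligonucleotide silences siRNA-loaded RISC by full
complementarity to the guide strand; before use, such an oligo must be
checked for full complementarity to endogenous miRNAs it could inadvertently
block.  ``screen`` reports every contiguous window of a miRNA that is the
exact reverse complement of the entire oligo; an empty result is a "clean"
verdict.  Which miRNAs count as expressed in the tissue of interest (e.g.
liver) is the caller's responsibility — the module screens whatever list it
is given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .oligo import reverse_complement
from .scan import find_all

__all__ = ["MiRNARecord", "ComplementarityHit", "load_mirnas", "screen"]

_WOBBLE_OK = {  # miRNA base -> oligo bases it can pair with (G.U wobble included)
    "A": {"U"},
    "U": {"A", "G"},
    "G": {"C", "U"},
    "C": {"G"},
}


@dataclass(frozen=True)
class MiRNARecord:
    """One mature miRNA, U-alphabet canonicalized."""

    mir_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty miRNA sequence for {self.mir_id}")


@dataclass(frozen=True)
class ComplementarityHit:
    mir_id: str
    oligo_id: str
    start: int  # 1-based offset of the complementary window within the miRNA
    window_length: int


def load_mirnas(fasta) -> list[MiRNARecord]:
    """miRNA FASTA (miRBase-style headers accepted; id = first token)."""
    records = [
        MiRNARecord(mir_id=rec.id, sequence=str(rec.seq).upper().replace("T", "U"))
        for rec in SeqIO.parse(str(fasta), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {fasta}")
    return records


def screen(
    oligo: str,
    mirnas: list[MiRNARecord],
    oligo_id: str = "oligo",
    wobble: bool = False,
) -> list[ComplementarityHit]:
    """Full-complementarity hits of ``oligo`` against each miRNA.

    A hit is a miRNA window whose every position Watson-Crick pairs with the
    whole oligo (antiparallel).  With ``wobble=True``, G.U pairs also count;
    by default "full complementarity" is taken strictly.
    """
    oligo = oligo.upper().replace("T", "U")
    if not (6 <= len(oligo) <= 30):
        raise ValueError(f"oligo length {len(oligo)} outside 6..30")
    hits: list[ComplementarityHit] = []
    L = len(oligo)
    if mirnas and all(len(m.sequence) < L for m in mirnas):
        warnings.warn(f"oligo ({L} nt) longer than every miRNA; screen is vacuous")
        return hits
    if not wobble:
        site = reverse_complement(oligo, alphabet="RNA")
        for m in mirnas:
            for pos in find_all(m.sequence, site):
                hits.append(ComplementarityHit(m.mir_id, oligo_id, pos, L))
    else:
        rev_oligo = oligo[::-1]
        for m in mirnas:
            seq = m.sequence
            for pos in range(len(seq) - L + 1):
                if all(
                    rev_oligo[k] in _WOBBLE_OK.get(seq[pos + k], set())
                    for k in range(L)
                ):
                    hits.append(ComplementarityHit(m.mir_id, oligo_id, pos + 1, L))
    return hits


def hits_frame(hits: list[ComplementarityHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mir_id": [h.mir_id for h in hits],
            "oligo_id": [h.oligo_id for h in hits],
            "start": [h.start for h in hits],
            "window_length": [h.window_length for h in hits],
        }
    )
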