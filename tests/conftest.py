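import numpy as np
import pytest

from seedtox.oligo import (
    ModifiedNucleotide,
    OligoStrand,
    SiRNADuplex,
    reverse_complement,
)

RNA = "ACGU"


def make_duplex(
    as_bases: str,
    overhang: int = 2,
    sense_overhang_bases: str | None = None,
    rng: np.random.Generator | None = None,
) -> SiRNADuplex:
    """Canonical duplex from antisense bases: alternating 2'OMe/2'F, terminal
    PS linkages, complementary sense strand with a matching 3' overhang."""
    paired = len(as_bases) - overhang
    sense_paired = reverse_complement(as_bases[:paired], alphabet="RNA")
    if sense_overhang_bases is None:
        sense_overhang_bases = "U" * overhang
    sense_bases = sense_paired + sense_overhang_bases

    def build(bases, first):
        other = "2F" if first == "2OMe" else "2OMe"
        return OligoStrand(
            tuple(
                ModifiedNucleotide(
                    base=b,
                    sugar=first if i % 2 == 0 else other,
                    linkage_3prime="PS" if i in (0, 1) and i < len(bases) - 1 else "PO",
                )
                for i, b in enumerate(bases)
            )
        )

    return SiRNADuplex(
        antisense=build(as_bases, "2OMe"),
        sense=build(sense_bases, "2F"),
        overhang_length=overhang,
    )


def random_duplex(rng: np.random.Generator, length: int = 21, overhang: int = 2) -> SiRNADuplex:
    bases = "".join(rng.choice(list(RNA), size=length))
    return make_duplex(bases, overhang=overhang)


@pytest.fixture
def example_duplex() -> SiRNADuplex:
    """21-mer whose antisense nucleotides 2-8 read UACGCAU."""
    return make_duplex("UUACGCAUAAAGUCUUGGCUU")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def write_fasta(path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
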