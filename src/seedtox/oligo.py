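"""Sequence and chemistry model for modified siRNA duplexes.

An siRNA duplex is represented residue-by-residue: every nucleotide carries a
base, a sugar chemistry (ribose, 2'-O-methyl, 2'-fluoro, glycol nucleic acid,
locked nucleic acid, or 2'-deoxy) and the linkage to the following residue
(phosphodiester or phosphorothioate).  Strands may carry a 5'-cap that blocks
5'-phosphorylation — and hence RISC loading when placed on the antisense
(guide) strand — and a 3'-GalNAc conjugate used for hepatocyte delivery.

Strand text notation
--------------------
One residue = optional sugar prefix + base letter, optionally followed by
``*`` marking a phosphorothioate linkage to the next residue::

    m = 2'-O-methyl   f = 2'-fluoro   d = 2'-deoxy   l = LNA
    (gna)A            glycol nucleic acid residue with base A
    A (no prefix)     unmodified ribonucleotide
    X                 abasic residue (terminal only)

``[iB]``, ``[mor]`` and ``[5d]`` at the 5' terminus denote the inverted-abasic,
morpholino and 5'-deoxy caps; ``[GalNAc]`` at the 3' terminus denotes the
triantennary GalNAc conjugate.  Example::

    [iB]mU*fU*mAfCmGfCmAfUmA

Positions are 1-based from the 5' end of each strand; caps and conjugates are
strand-level annotations, not residues, and do not shift numbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace


__all__ = [
    "ModifiedNucleotide",
    "OligoStrand",
    "SiRNADuplex",
    "SeedSpec",
    "ParseError",
    "parse_strand",
    "serialize_strand",
    "reverse_complement",
    "extract_seed",
    "seed_site",
    "swap_seed",
    "place_gna",
    "set_cap",
    "mod_composition",
    "ModComposition",
    "read_duplex_table",
]

SUGARS = frozenset({"ribo", "2OMe", "2F", "GNA", "LNA", "2deoxy"})
LINKAGES = frozenset({"PO", "PS"})
CAPS_5PRIME = frozenset({"none", "iB", "morpholino", "5deoxy"})
CONJUGATES_3PRIME = frozenset({"none", "GalNAc"})
BASES = frozenset("ACGUTX")

_SUGAR_PREFIX = {"m": "2OMe", "f": "2F", "d": "2deoxy", "l": "LNA", "(gna)": "GNA"}
_SUGAR_TO_PREFIX = {v: k for k, v in _SUGAR_PREFIX.items()}
_SUGAR_TO_PREFIX["ribo"] = ""
_CAP_TOKEN = {"[iB]": "iB", "[mor]": "morpholino", "[5d]": "5deoxy"}
_CAP_TO_TOKEN = {v: k for k, v in _CAP_TOKEN.items()}

# A<->U/T, C<->G; N wildcards map to N and never count as a pair.
_COMPLEMENT_RNA = {"A": "U", "U": "A", "T": "A", "C": "G", "G": "C", "N": "N"}
_COMPLEMENT_DNA = {"A": "T", "U": "A", "T": "A", "C": "G", "G": "C", "N": "N"}


class ParseError(ValueError):
    """Raised when strand notation cannot be parsed; carries token and position."""


@dataclass(frozen=True)
class ModifiedNucleotide:
    """One residue: base identity, sugar chemistry, and 3'-linkage type.

    ``linkage_3prime`` describes the bond to the *following* residue; the value
    on the 3'-terminal residue is ignored.
    """

    base: str
    sugar: str = "ribo"
    linkage_3prime: str = "PO"

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise ValueError(f"unknown base {self.base!r}")
        if self.sugar not in SUGARS:
            raise ValueError(f"unknown sugar {self.sugar!r}")
        if self.linkage_3prime not in LINKAGES:
            raise ValueError(f"unknown linkage {self.linkage_3prime!r}")
        if self.base == "X" and self.sugar in ("GNA", "LNA"):
            raise ValueError("GNA/LNA residues must carry a standard base")

    @property
    def is_abasic(self) -> bool:
        return self.base == "X"


@dataclass(frozen=True)
class OligoStrand:
    """A single oligonucleotide strand, residues ordered 5'->3'."""

    residues: tuple[ModifiedNucleotide, ...]
    cap_5prime: str = "none"
    conjugate_3prime: str = "none"

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("strand must contain at least one residue")
        if self.cap_5prime not in CAPS_5PRIME:
            raise ValueError(f"unknown 5' cap {self.cap_5prime!r}")
        if self.conjugate_3prime not in CONJUGATES_3PRIME:
            raise ValueError(f"unknown 3' conjugate {self.conjugate_3prime!r}")
        for i, r in enumerate(self.residues):
            if r.is_abasic and i not in (0, len(self.residues) - 1):
                raise ValueError(
                    f"abasic residue only permitted at a terminus (position {i + 1})"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def bases(self) -> str:
        """Base sequence 5'->3' (chemistry annotations dropped)."""
        return "".join(r.base for r in self.residues)

    @property
    def ps_count(self) -> int:
        """Number of phosphorothioate internucleotide linkages."""
        return sum(1 for r in self.residues[:-1] if r.linkage_3prime == "PS")


@dataclass(frozen=True)
class SiRNADuplex:
    """Antisense/sense duplex with 3'-overhangs excluded from pairing.

    Alignment over the paired region: antisense position ``i`` pairs with
    sense position ``P - i + 1`` where ``P`` is the paired length (strand
    length minus the 3'-overhang).  Watson-Crick complementarity (U and T
    equivalent) is enforced at construction; abasic residues never pair.
    """

    antisense: OligoStrand
    sense: OligoStrand
    overhang_length: int = 2

    def __post_init__(self) -> None:
        if self.overhang_length < 0:
            raise ValueError("overhang_length must be >= 0")
        p_as = len(self.antisense) - self.overhang_length
        p_s = len(self.sense) - self.overhang_length
        if p_as != p_s:
            raise ValueError(
                f"paired regions disagree: antisense {p_as} vs sense {p_s} residues"
            )
        if p_as < 1:
            raise ValueError("paired region must contain at least one base pair")
        a, s = self.antisense.bases, self.sense.bases
        for i in range(1, p_as + 1):
            ab, sb = a[i - 1], s[p_as - i]
            if ab == "X" or sb == "X":
                raise ValueError(f"abasic residue inside paired region (antisense {i})")
            if _COMPLEMENT_RNA[ab].replace("U", "T") != sb.replace("U", "T"):
                raise ValueError(
                    f"duplex not complementary at antisense position {i}: {ab} vs {sb}"
                )

    @property
    def paired_length(self) -> int:
        return len(self.antisense) - self.overhang_length

    @property
    def risc_loading_competent(self) -> bool:
        """False iff the antisense 5' end is capped (5'-phosphorylation blocked)."""
        return self.antisense.cap_5prime == "none"


@dataclass(frozen=True)
class SeedSpec:
    """Strand selector plus a 1-based inclusive position window.

    The default window, antisense nucleotides 2-8, is the canonical seed whose
    perfect 3'UTR complement defines a seed-match site.
    """

    strand: str = "antisense"
    start: int = 2
    end: int = 8

    def __post_init__(self) -> None:
        if self.strand not in ("antisense", "sense"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if not (1 <= self.start < self.end):
            raise ValueError("require 1 <= start < end")

    @property
    def label(self) -> str:
        return f"{self.strand}_{self.start}_{self.end}"


# ---------------------------------------------------------------------------
# parsing / serialization

_TOKEN_RE = re.compile(
    r"\[iB\]|\[mor\]|\[5d\]|\[GalNAc\]|\(gna\)[ACGUT]|[mfdl][ACGUT]|[ACGUTX]|\*"
)


def parse_strand(text: str) -> OligoStrand:
    """Parse strand notation (see module docstring) into an :class:`OligoStrand`."""
    if not text:
        raise ParseError("empty sequence")
    residues: list[dict] = []
    cap = "none"
    conjugate = "none"
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ParseError(f"unknown token at position {pos + 1}: {text[pos:pos + 6]!r}")
        tok = m.group(0)
        if tok in _CAP_TOKEN:
            if pos != 0:
                raise ParseError(f"cap token {tok} not at 5' terminus (position {pos + 1})")
            cap = _CAP_TOKEN[tok]
        elif tok == "[GalNAc]":
            if m.end() != len(text):
                raise ParseError(f"[GalNAc] only permitted at the 3' terminus (position {pos + 1})")
            conjugate = "GalNAc"
        elif tok == "*":
            if not residues or residues[-1]["ps"]:
                raise ParseError(f"'*' must follow a residue (position {pos + 1})")
            residues[-1]["ps"] = True
        else:
            if tok.startswith("(gna)"):
                sugar, base = "GNA", tok[5]
            elif tok[0] in _SUGAR_PREFIX:
                sugar, base = _SUGAR_PREFIX[tok[0]], tok[1]
            else:
                sugar, base = "ribo", tok
            residues.append({"base": base, "sugar": sugar, "ps": False})
        pos = m.end()
    if not residues:
        raise ParseError("no residues in sequence")
    built = tuple(
        ModifiedNucleotide(
            base=r["base"],
            sugar=r["sugar"],
            # trailing linkage is meaningless; canonicalize to PO
            linkage_3prime="PS" if (r["ps"] and i < len(residues) - 1) else "PO",
        )
        for i, r in enumerate(residues)
    )
    try:
        return OligoStrand(built, cap_5prime=cap, conjugate_3prime=conjugate)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def serialize_strand(strand: OligoStrand) -> str:
    """Canonical text form; ``parse_strand(serialize_strand(s)) == s``."""
    parts: list[str] = []
    if strand.cap_5prime != "none":
        parts.append(_CAP_TO_TOKEN[strand.cap_5prime])
    last = len(strand.residues) - 1
    for i, r in enumerate(strand.residues):
        prefix = _SUGAR_TO_PREFIX[r.sugar]
        parts.append(f"({prefix[1:-1]}){r.base}" if prefix == "(gna)" else f"{prefix}{r.base}")
        if i < last and r.linkage_3prime == "PS":
            parts.append("*")
    if strand.conjugate_3prime == "GalNAc":
        parts.append("[GalNAc]")
    return "".join(parts)


# ---------------------------------------------------------------------------
# base-level operations

def reverse_complement(seq: str, alphabet: str = "DNA") -> str:
    """Reverse complement of a base string in the requested output alphabet.

    U and T are both accepted on input; N maps to N.
    """
    if not seq:
        raise ValueError("empty sequence")
    if alphabet not in ("RNA", "DNA"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    table = _COMPLEMENT_RNA if alphabet == "RNA" else _COMPLEMENT_DNA
    try:
        return "".join(table[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"character outside alphabet: {exc.args[0]!r}") from None


def _strand_for(duplex: SiRNADuplex, which: str) -> OligoStrand:
    return duplex.antisense if which == "antisense" else duplex.sense


def extract_seed(duplex: SiRNADuplex, spec: SeedSpec) -> str:
    """Bases of the selected strand at the seed window, 5'->3'."""
    strand = _strand_for(duplex, spec.strand)
    if spec.end > len(strand):
        raise ValueError(
            f"seed window {spec.start}..{spec.end} exceeds {spec.strand} length {len(strand)}"
        )
    window = strand.bases[spec.start - 1 : spec.end]
    if "X" in window:
        raise ValueError("seed window covers an abasic residue")
    return window


def seed_site(duplex: SiRNADuplex, spec: SeedSpec) -> str:
    """The DNA string a 3'UTR must contain for a perfect seed match.

    This is the reverse complement of the seed bases, so e.g. antisense seed
    ``UACGCAU`` yields the site ``ATGCGTA``.
    """
    return reverse_complement(extract_seed(duplex, spec), alphabet="DNA")


def _complement_keep_letter(base: str, old_base: str) -> str:
    """Watson-Crick complement of ``base``, writing U/T in the style of ``old_base``."""
    comp = _COMPLEMENT_RNA[base]
    if comp == "U" and old_base == "T":
        return "T"
    return comp


def swap_seed(recipient: SiRNADuplex, donor: SiRNADuplex, spec: SeedSpec | None = None) -> SiRNADuplex:
    """Replace the recipient's antisense seed bases with the donor's.

    Only base identities move: the recipient's sugar, linkage, cap and
    conjugate annotations are untouched at every position, mirroring seed
    swaps performed without changing the chemical modification pattern.
    Sense-strand bases at the paired positions are updated to restore duplex
    complementarity.
    """
    spec = spec or SeedSpec()
    if spec.strand != "antisense":
        raise ValueError("seed swapping is defined on the antisense strand")
    donor_bases = extract_seed(donor, spec)
    if spec.end > len(recipient.antisense):
        raise ValueError("recipient antisense shorter than seed window")
    p = recipient.paired_length
    new_as = list(recipient.antisense.residues)
    new_s = list(recipient.sense.residues)
    for offset, new_base in enumerate(donor_bases):
        i = spec.start + offset  # 1-based antisense position
        old = new_as[i - 1]
        keep = "T" if old.base == "T" else "U"
        new_as[i - 1] = replace(old, base=new_base.replace("T", "U") if keep == "U" else new_base.replace("U", "T"))
        if i <= p:
            j = p - i + 1  # paired sense position
            old_s = new_s[j - 1]
            new_s[j - 1] = replace(old_s, base=_complement_keep_letter(new_base, old_s.base))
    return replace(
        recipient,
        antisense=replace(recipient.antisense, residues=tuple(new_as)),
        sense=replace(recipient.sense, residues=tuple(new_s)),
    )


def place_gna(duplex: SiRNADuplex, position: int) -> SiRNADuplex:
    """Set the antisense residue at ``position`` (1-based) to glycol nucleic acid.

    GNA is thermally destabilizing; placed in the seed (canonically antisense
    position 7) it weakens seed-mediated off-target binding while leaving the
    base sequence — and hence on-target complementarity — unchanged.
    """
    if not (1 <= position <= len(duplex.antisense)):
        raise ValueError(f"position {position} outside antisense strand")
    old = duplex.antisense.residues[position - 1]
    if old.is_abasic:
        raise ValueError("cannot place GNA on an abasic residue")
    new_res = list(duplex.antisense.residues)
    new_res[position - 1] = replace(old, sugar="GNA")
    return replace(duplex, antisense=replace(duplex.antisense, residues=tuple(new_res)))


def set_cap(duplex: SiRNADuplex, strand: str, cap: str) -> SiRNADuplex:
    """Set the 5'-cap on one strand.

    Capping the antisense strand blocks its 5'-phosphorylation and renders the
    duplex RISC-loading incompetent; capping the sense strand alone does not.
    """
    if cap not in CAPS_5PRIME:
        raise ValueError(f"unknown cap symbol {cap!r}")
    if strand not in ("antisense", "sense"):
        raise ValueError(f"unknown strand {strand!r}")
    target = _strand_for(duplex, strand)
    return replace(duplex, **{strand: replace(target, cap_5prime=cap)})


@dataclass(frozen=True)
class ModComposition:
    """Sugar-chemistry percentages (over non-abasic residues) plus PS linkage count."""

    percent: dict
    ps_count: int
    n_residues: int


def mod_composition(strand: OligoStrand) -> ModComposition:
    """Percent of residues per sugar class; abasic cap residues excluded."""
    counted = [r for r in strand.residues if not r.is_abasic]
    if not counted:
        raise ValueError("strand has no non-abasic residues")
    n = len(counted)
    pct: dict[str, float] = {}
    for r in counted:
        pct[r.sugar] = pct.get(r.sugar, 0.0) + 100.0 / n
    return ModComposition(percent=pct, ps_count=strand.ps_count, n_residues=n)


def read_duplex_table(path) -> dict[str, SiRNADuplex]:
    """Read a TSV of duplexes: columns duplex_id, antisense, sense, overhang_length."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"duplex_id", "antisense", "sense"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"duplex table missing columns: {sorted(missing)}")
    out: dict[str, SiRNADuplex] = {}
    for _, row in df.iterrows():
        overhang = int(row["overhang_length"]) if "overhang_length" in df.columns else 2
        out[row["duplex_id"]] = SiRNADuplex(
            antisense=parse_strand(row["antisense"]),
            sense=parse_strand(row["sense"]),
            overhang_length=overhang,
        )
    return out
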