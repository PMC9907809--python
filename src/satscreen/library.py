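"""Site-saturation library definition and variant classification.

A site-saturated library substitutes each codon of a region of a coding
sequence with (nearly) every alternative codon, one mutated codon per clone.
This module defines the library (reference CDS, residue range, allowed codon
alphabet), enumerates every codon-level variant, and classifies each at the
amino-acid level as synonymous, missense, or nonsense.

Residue numbering follows the precursor protein (position 1 is the initiator
methionine), matching the "A55K"-style variant names used throughout.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "STOP",
    "CODONS_ALL",
    "CODONS_NNK",
    "CODON_ALPHABETS",
    "translate_codon",
    "CodonVariant",
    "ResidueVariant",
    "LibraryDesign",
    "build_library",
    "parse_variant_name",
    "format_variant_name",
]

STOP = "*"
_BASES = "ACGT"

CODONS_ALL: tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)
#: NNK degenerate codons (N = any base, K = G/T): 32 codons covering all
#: 20 amino acids plus one stop (TAG).
CODONS_NNK: tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in "GT"
)

CODON_ALPHABETS: dict[str, tuple[str, ...]] = {
    "all": CODONS_ALL,
    "NNK": CODONS_NNK,
}

_TRANSLATION: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _TRANSLATION[_stop] = STOP


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard genetic code ('*' for stop)."""
    try:
        return _TRANSLATION[codon.upper()]
    except KeyError:
        raise ValueError(f"not a valid codon: {codon!r}") from None


_VCLASSES = ("synonymous", "missense", "nonsense")


@dataclass(frozen=True, order=True)
class CodonVariant:
    """A single library member: one codon substitution at one position."""

    position: int
    ref_codon: str
    alt_codon: str

    def __post_init__(self) -> None:
        for codon in (self.ref_codon, self.alt_codon):
            if len(codon) != 3 or any(b not in _BASES for b in codon):
                raise ValueError(f"not a valid codon: {codon!r}")
        if self.alt_codon == self.ref_codon:
            raise ValueError("alt_codon must differ from ref_codon")

    @property
    def key(self) -> str:
        """Compact text form, e.g. ``'55:GCT>TAT'``."""
        return f"{self.position}:{self.ref_codon}>{self.alt_codon}"

    @classmethod
    def from_key(cls, text: str) -> "CodonVariant":
        m = re.fullmatch(r"(\d+):([ACGT]{3})>([ACGT]{3})", text)
        if m is None:
            raise ValueError(f"malformed codon-variant key: {text!r}")
        return cls(int(m.group(1)), m.group(2), m.group(3))


@dataclass(frozen=True, order=True)
class ResidueVariant:
    """An amino-acid-level variant, e.g. A55K (missense) or S127* (nonsense)."""

    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if len(self.ref_aa) != 1 or len(self.alt_aa) != 1:
            raise ValueError("amino acids are single letters ('*' for stop)")

    @property
    def vclass(self) -> str:
        if self.alt_aa == STOP:
            return "nonsense"
        if self.alt_aa == self.ref_aa:
            return "synonymous"
        return "missense"

    @property
    def name(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def parse_variant_name(
    text: str, library: "LibraryDesign | None" = None
) -> ResidueVariant:
    """Parse an ``A55K``-style variant name.

    If a library is given, the position must lie inside its residue range and
    the reference amino acid must match the library's translated reference.
    """
    m = re.fullmatch(r"([A-Z])(\d+)([A-Z*])", text.strip())
    if m is None:
        raise ValueError(f"malformed variant name: {text!r}")
    ref_aa, position, alt_aa = m.group(1), int(m.group(2)), m.group(3)
    if library is not None:
        if not library.contains(position):
            raise ValueError(
                f"position {position} outside library range "
                f"[{library.residue_start}, {library.residue_end}]"
            )
        expected = library.ref_aa(position)
        if ref_aa != expected:
            raise ValueError(
                f"reference amino acid mismatch at {position}: "
                f"{ref_aa!r} given, {expected!r} in reference"
            )
    return ResidueVariant(position, ref_aa, alt_aa)


def format_variant_name(variant: ResidueVariant) -> str:
    """Inverse of :func:`parse_variant_name`."""
    return variant.name


@dataclass(frozen=True)
class LibraryDesign:
    """A site-saturated library over ``[residue_start, residue_end]``.

    Parameters
    ----------
    reference_cds
        Reference coding sequence (no introns; length divisible by 3; a
        terminal stop codon is permitted but not required). Positions are
        1-based codon/residue indices into this CDS.
    residue_start, residue_end
        Inclusive residue range that was saturated.
    codon_alphabet
        Codons allowed as substitutions at every position.
    """

    reference_cds: str
    residue_start: int = 50
    residue_end: int = 134
    codon_alphabet: tuple[str, ...] = CODONS_ALL

    def __post_init__(self) -> None:
        cds = self.reference_cds.upper().replace("U", "T")
        object.__setattr__(self, "reference_cds", cds)
        if len(cds) == 0 or len(cds) % 3 != 0:
            raise ValueError("reference CDS length must be a positive multiple of 3")
        if any(b not in _BASES for b in cds):
            raise ValueError("reference CDS may contain only A/C/G/T")
        alphabet = tuple(sorted({c.upper() for c in self.codon_alphabet}))
        if not alphabet:
            raise ValueError("codon alphabet is empty")
        for codon in alphabet:
            if codon not in CODONS_ALL:
                raise ValueError(f"not a valid codon: {codon!r}")
        object.__setattr__(self, "codon_alphabet", alphabet)
        n = len(cds) // 3
        if not (1 <= self.residue_start <= self.residue_end <= n):
            raise ValueError(
                f"residue range [{self.residue_start}, {self.residue_end}] "
                f"outside CDS of {n} codons"
            )
        for pos in self.positions:
            if translate_codon(self.ref_codon(pos)) == STOP:
                raise ValueError(
                    f"reference codon at library position {pos} is a stop codon"
                )

    # -- basic geometry -------------------------------------------------

    @property
    def n_codons(self) -> int:
        return len(self.reference_cds) // 3

    @property
    def positions(self) -> range:
        """Residue positions covered by the library (inclusive range)."""
        return range(self.residue_start, self.residue_end + 1)

    @property
    def n_positions(self) -> int:
        return self.residue_end - self.residue_start + 1

    def contains(self, position: int) -> bool:
        return self.residue_start <= position <= self.residue_end

    def ref_codon(self, position: int) -> str:
        if not 1 <= position <= self.n_codons:
            raise ValueError(f"position {position} outside CDS")
        return self.reference_cds[(position - 1) * 3 : position * 3]

    def ref_aa(self, position: int) -> str:
        return translate_codon(self.ref_codon(position))

    @property
    def protein(self) -> str:
        """Translated reference (may end in '*' if the CDS keeps its stop)."""
        return "".join(
            translate_codon(self.reference_cds[i : i + 3])
            for i in range(0, len(self.reference_cds), 3)
        )

    @property
    def region_sequence(self) -> str:
        """Reference nucleotides over the saturated region."""
        return self.reference_cds[
            (self.residue_start - 1) * 3 : self.residue_end * 3
        ]

    # -- enumeration and classification ---------------------------------

    def variants(self) -> list[CodonVariant]:
        """Enumerate every codon variant, ordered by (position, alt codon)."""
        out: list[CodonVariant] = []
        for pos in self.positions:
            ref = self.ref_codon(pos)
            for alt in self.codon_alphabet:
                if alt != ref:
                    out.append(CodonVariant(pos, ref, alt))
        return out

    def classify(self, variant: CodonVariant) -> ResidueVariant:
        """Map a codon variant to its amino-acid identity and class."""
        if not self.contains(variant.position):
            raise ValueError(
                f"position {variant.position} outside library range"
            )
        ref = self.ref_codon(variant.position)
        if variant.ref_codon != ref:
            raise ValueError(
                f"ref codon mismatch at {variant.position}: "
                f"{variant.ref_codon} given, {ref} in reference"
            )
        return ResidueVariant(
            variant.position,
            translate_codon(ref),
            translate_codon(variant.alt_codon),
        )

    def aa_variants(self) -> list[ResidueVariant]:
        """Distinct amino-acid variants reachable from the codon alphabet."""
        return sorted({self.classify(v) for v in self.variants()})

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        names = [
            name
            for name, codons in CODON_ALPHABETS.items()
            if tuple(sorted(codons)) == self.codon_alphabet
        ]
        return {
            "reference_cds": self.reference_cds,
            "residue_start": self.residue_start,
            "residue_end": self.residue_end,
            "codon_alphabet": names[0] if names else list(self.codon_alphabet),
        }

    @classmethod
    def from_dict(cls, data: dict, base_dir: Path | str = ".") -> "LibraryDesign":
        data = dict(data)
        if "reference_cds_fasta" in data:
            fasta = Path(base_dir) / data.pop("reference_cds_fasta")
            record = next(SeqIO.parse(str(fasta), "fasta"))
            data["reference_cds"] = str(record.seq)
        alphabet = data.get("codon_alphabet", "all")
        if isinstance(alphabet, str):
            try:
                alphabet = CODON_ALPHABETS[alphabet]
            except KeyError:
                raise ValueError(f"unknown codon alphabet name: {alphabet!r}")
        return cls(
            reference_cds=data["reference_cds"],
            residue_start=int(data.get("residue_start", 50)),
            residue_end=int(data.get("residue_end", 134)),
            codon_alphabet=tuple(alphabet),
        )

    def to_json(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Path | str) -> "LibraryDesign":
        path = Path(path)
        return cls.from_dict(json.loads(path.read_text()), base_dir=path.parent)


def build_library(
    reference_cds: str,
    residue_start: int = 50,
    residue_end: int = 134,
    codon_alphabet: str | tuple[str, ...] = "all",
) -> LibraryDesign:
    """Construct and validate a :class:`LibraryDesign`.

    ``codon_alphabet`` may be an alphabet name (``"all"``, ``"NNK"``) or an
    explicit collection of codons. Variants are enumerated lazily via
    :meth:`LibraryDesign.variants`.
    """
    if isinstance(codon_alphabet, str):
        try:
            codon_alphabet = CODON_ALPHABETS[codon_alphabet]
        except KeyError:
            raise ValueError(f"unknown codon alphabet name: {codon_alphabet!r}")
    return LibraryDesign(
        reference_cds=reference_cds,
        residue_start=residue_start,
        residue_end=residue_end,
        codon_alphabet=tuple(codon_alphabet),
    )
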