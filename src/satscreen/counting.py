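"""Read assignment and codon → amino-acid count aggregation.

Reads are assumed to have been trimmed upstream so that they cover exactly
the saturated region of the reference CDS. Because the library carries one
mutated codon per molecule, a read is assigned to a codon variant only if it
differs from the reference at exactly one codon and that alternative codon is
in the library's alphabet; reads differing at two or more codons (likely
sequencing error or template recombination) are rejected, as are reads of the
wrong length or containing ambiguous bases.

Codon-level counts are aggregated to amino-acid level by summing reads over
all synonymous codon encodings of the same residue variant ("Reads (sum)").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

from .library import CodonVariant, LibraryDesign, ResidueVariant

__all__ = [
    "REJECT_LENGTH",
    "REJECT_MULTIPLE_CODONS",
    "REJECT_UNKNOWN_CODON",
    "REJECT_AMBIGUOUS_BASE",
    "ReadAssignment",
    "CountTable",
    "AACountTable",
    "assign_read",
    "count_reads",
    "count_fastq",
    "aggregate_aa_counts",
]

# reject reason codes
REJECT_LENGTH = "length_mismatch"
REJECT_MULTIPLE_CODONS = "multiple_codons"
REJECT_UNKNOWN_CODON = "codon_not_in_alphabet"
REJECT_AMBIGUOUS_BASE = "ambiguous_base"

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of assigning one read: WT, a codon variant, or a rejection."""

    kind: str  # "wt" | "variant" | "reject"
    variant: CodonVariant | None = None
    reason: str | None = None

    @property
    def is_wt(self) -> bool:
        return self.kind == "wt"

    @property
    def is_reject(self) -> bool:
        return self.kind == "reject"


def assign_read(
    read: str, library: LibraryDesign, revcomp: bool = False
) -> ReadAssignment:
    """Assign one read covering the saturated region.

    The read is compared to the reference on the given strand; pass
    ``revcomp=True`` if the sequencing orientation is antisense to the CDS.
    """
    read = read.upper().replace("U", "T")
    if revcomp:
        read = str(Seq(read).reverse_complement())
    region = library.region_sequence
    if len(read) != len(region):
        return ReadAssignment("reject", reason=REJECT_LENGTH)
    if not _BASES.issuperset(read):
        return ReadAssignment("reject", reason=REJECT_AMBIGUOUS_BASE)
    diffs = []
    for i, pos in enumerate(library.positions):
        codon = read[i * 3 : i * 3 + 3]
        ref = region[i * 3 : i * 3 + 3]
        if codon != ref:
            diffs.append((pos, ref, codon))
            if len(diffs) > 1:
                return ReadAssignment("reject", reason=REJECT_MULTIPLE_CODONS)
    if not diffs:
        return ReadAssignment("wt")
    pos, ref, alt = diffs[0]
    if alt not in library.codon_alphabet:
        return ReadAssignment("reject", reason=REJECT_UNKNOWN_CODON)
    return ReadAssignment("variant", variant=CodonVariant(pos, ref, alt))


@dataclass
class CountTable:
    """Per-sample read counts over codon variants.

    ``total_reads`` is the total nucleotide read count of the sample (the
    normalisation denominator); it must be at least the assigned total
    (WT + variants) and by default equals assigned + rejected.
    """

    sample_id: str
    condition: str  # "selective" | "control"
    replicate: int
    counts: dict[CodonVariant, int] = field(default_factory=dict)
    wt_count: int = 0
    total_reads: int = 0
    rejected_reads: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("selective", "control"):
            raise ValueError(f"unknown condition: {self.condition!r}")
        if self.replicate < 1:
            raise ValueError("replicate numbering starts at 1")
        if self.wt_count < 0 or any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.total_reads < self.assigned_reads:
            raise ValueError("total_reads smaller than assigned reads")

    @property
    def assigned_reads(self) -> int:
        return self.wt_count + sum(self.counts.values())


@dataclass
class AACountTable:
    """Per-sample "Reads (sum)" counts over amino-acid variants."""

    sample_id: str
    condition: str
    replicate: int
    aa_counts: dict[ResidueVariant, int] = field(default_factory=dict)
    wt_count: int = 0
    total_reads: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("selective", "control"):
            raise ValueError(f"unknown condition: {self.condition!r}")
        if self.replicate < 1:
            raise ValueError("replicate numbering starts at 1")

    @property
    def assigned_reads(self) -> int:
        return self.wt_count + sum(self.aa_counts.values())


def count_reads(
    reads: Iterable[str],
    library: LibraryDesign,
    sample_id: str,
    condition: str,
    replicate: int,
    revcomp: bool = False,
) -> CountTable:
    """Tally assignments of an iterable of read sequences into a CountTable."""
    counts: dict[CodonVariant, int] = {}
    wt = 0
    rejected = 0
    total = 0
    for read in reads:
        total += 1
        a = assign_read(read, library, revcomp=revcomp)
        if a.is_wt:
            wt += 1
        elif a.is_reject:
            rejected += 1
        else:
            counts[a.variant] = counts.get(a.variant, 0) + 1
    return CountTable(
        sample_id=sample_id,
        condition=condition,
        replicate=replicate,
        counts=counts,
        wt_count=wt,
        total_reads=total,
        rejected_reads=rejected,
    )


def count_fastq(
    path,
    library: LibraryDesign,
    sample_id: str,
    condition: str,
    replicate: int,
    revcomp: bool = False,
) -> CountTable:
    """Count variants directly from a FASTQ file (no quality filtering)."""
    reads = (str(rec.seq) for rec in SeqIO.parse(str(path), "fastq"))
    return count_reads(reads, library, sample_id, condition, replicate, revcomp)


def aggregate_aa_counts(table: CountTable, library: LibraryDesign) -> AACountTable:
    """Sum codon-level counts over synonymous encodings of each aa variant.

    The WT count and totals carry through unchanged. Raises if the table
    contains a codon variant the library cannot produce.
    """
    alphabet = set(library.codon_alphabet)
    aa_counts: dict[ResidueVariant, int] = {}
    for cv, n in table.counts.items():
        if not library.contains(cv.position) or cv.alt_codon not in alphabet:
            raise ValueError(f"count for codon variant not in library: {cv.key}")
        rv = library.classify(cv)  # also validates the ref codon
        aa_counts[rv] = aa_counts.get(rv, 0) + n
    return AACountTable(
        sample_id=table.sample_id,
        condition=table.condition,
        replicate=table.replicate,
        aa_counts=aa_counts,
        wt_count=table.wt_count,
        total_reads=table.total_reads,
    )
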