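"""Core domain types shared across the package.

Reads are plain DNA strings over {A, C, G, T, N}; tag (primer/adapter)
sequences may use the full IUPAC nucleotide alphabet, where ambiguity codes
act as wildcards during matching.  Coordinates are 0-based, half-open
everywhere in the library; conversion to 1-based happens only when headers
are annotated for output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

#: IUPAC nucleotide codes mapped to the set of concrete bases they accept.
#: U is normalised to T on ingest and never appears in stored sequences.
IUPAC_SETS: dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

READ_ALPHABET = "ACGTN"


class ValidationError(ValueError):
    """Raised for malformed sequences, tags, or configuration values."""


class End(Enum):
    """Which end of the read a tag is anchored to."""

    FIVE_PRIME = "5'"
    THREE_PRIME = "3'"


class MatchCategory(Enum):
    END5 = "5'-end"
    END3 = "3'-end"
    INTERNAL = "internal"


def normalize_tag_sequence(sequence: str) -> str:
    """Upper-case, map U->T, and validate against the IUPAC alphabet."""
    seq = sequence.upper().replace("U", "T")
    for pos, letter in enumerate(seq):
        if letter not in IUPAC_SETS:
            raise ValidationError(
                f"invalid IUPAC letter {letter!r} at position {pos} in tag sequence"
            )
    return seq


@dataclass(frozen=True)
class TagSpec:
    """A tag sequence bound to a read end.

    ``end`` may be None for derived patterns that are not anchored to a
    single end (e.g. the concatenated junction pattern used for splitting).
    """

    sequence: str
    end: End | None = None

    def __post_init__(self) -> None:
        seq = normalize_tag_sequence(self.sequence)
        if not seq:
            raise ValidationError("tag sequence must be non-empty")
        object.__setattr__(self, "sequence", seq)

    @property
    def m(self) -> int:
        return len(self.sequence)

    def reversed(self) -> "TagSpec":
        return TagSpec(self.sequence[::-1], self.end)


@dataclass
class SequenceRecord:
    """One read: identifier, DNA string, optional per-base quality.

    Quality is stored as a Phred+33 ASCII string so that trimming slices
    sequence and quality identically.
    """

    id: str
    sequence: str
    description: str = ""
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValidationError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def slice(self, start: int, end: int) -> "SequenceRecord":
        qual = self.quality[start:end] if self.quality is not None else None
        return SequenceRecord(self.id, self.sequence[start:end], self.description, qual)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TagMatch:
    """One located tag occurrence on a read (0-based, half-open interval)."""

    read_id: str
    start: int
    end: int
    distance: int
    category: MatchCategory

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid match interval [{self.start}, {self.end}) on {self.read_id!r}"
            )
        if self.distance < 0:
            raise ValidationError("match distance must be non-negative")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def normalize_read_sequence(sequence: str) -> tuple[str, int]:
    """Normalise a read string to {A,C,G,T,N}.

    Upper-cases, maps U->T, converts non-N IUPAC ambiguity letters to N
    (read-side wildcards are low-quality signals, not patterns), and rejects
    anything outside the IUPAC alphabet.  Returns the normalised string and
    the number of letters that were converted to N.
    """
    seq = sequence.upper().replace("U", "T")
    converted = 0
    if not all(c in "ACGTN" for c in seq):
        out = []
        for pos, letter in enumerate(seq):
            if letter in "ACGTN":
                out.append(letter)
            elif letter in IUPAC_SETS:
                out.append("N")
                converted += 1
            else:
                raise ValidationError(
                    f"invalid sequence letter {letter!r} at position {pos}"
                )
        seq = "".join(out)
    return seq, converted
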