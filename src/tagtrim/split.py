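"""Detection and splitting of fragment-to-fragment concatenations.

Blunt-end ligation during library preparation can join two fragments before
adapter ligation, so a single read carries the 3'-end tag of one fragment
immediately followed by the 5'-end tag of the next.  Such junctions are
located with the same approximate matcher used at the read ends, applied to
the concatenated pattern tag3·tag5 (quasi-random N positions of both tags
stay wildcards), and the read is split into its constituent fragments with
the junction bases removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .match import find_internal
from .records import SequenceRecord, TagSpec, ValidationError

__all__ = ["Junction", "Fragment", "junction_pattern", "detect_junctions", "split_read"]


@dataclass(frozen=True)
class Junction:
    """A matched concatenated-tag region strictly inside a read."""

    start: int
    end: int
    distance: int


@dataclass(frozen=True)
class Fragment:
    """One constituent fragment of a split read, in read order."""

    parent_id: str
    ordinal: int  # 1-based
    sequence: str
    quality: str | None = None

    @property
    def id(self) -> str:
        return f"{self.parent_id}.{self.ordinal}"


def junction_pattern(tag5: TagSpec, tag3: TagSpec) -> TagSpec:
    """The concatenated junction pattern tag3·tag5 as a single IUPAC tag."""
    if tag5 is None or tag3 is None:
        raise ValidationError("both 5' and 3' tags are required for splitting")
    return TagSpec(tag3.sequence + tag5.sequence, None)


def detect_junctions(
    read: SequenceRecord,
    pattern: TagSpec,
    max_mismatches: int,
    exclude: Sequence[tuple[int, int]] = (),
) -> list[Junction]:
    """All junction occurrences with distance <= ``max_mismatches``.

    With ``max_mismatches=0`` only exact junctions are reported (the
    conservative choice to avoid false splits).  ``exclude`` intervals are
    already-matched end regions.
    """
    matches = find_internal(read, pattern, max_mismatches, exclude)
    return [Junction(m.start, m.end, m.distance) for m in matches]


def split_read(read: SequenceRecord, junctions: Sequence[Junction]) -> list[Fragment]:
    """Split a read at its junctions into n+1 fragments.

    Junction intervals are removed from the output; fragments are numbered
    in read order.  With no junctions the read is returned whole with
    ordinal 0, meaning "no suffix is appended to the id".
    """
    if not junctions:
        return [Fragment(read.id, 0, read.sequence, read.quality)]
    ordered = sorted(junctions, key=lambda j: j.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValidationError("junctions must be non-overlapping")
    fragments: list[Fragment] = []
    pos = 0
    ordinal = 1
    for j in ordered:
        fragments.append(
            Fragment(
                read.id,
                ordinal,
                read.sequence[pos : j.start],
                read.quality[pos : j.start] if read.quality is not None else None,
            )
        )
        ordinal += 1
        pos = j.end
    fragments.append(
        Fragment(
            read.id,
            ordinal,
            read.sequence[pos:],
            read.quality[pos:] if read.quality is not None else None,
        )
    )
    return fragments
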