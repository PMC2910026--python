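"""IUPAC-extended bit-parallel approximate matching of tags against reads.

The matcher computes the semi-global (free-end-gap) unit-cost edit distance
of a tag pattern to substrings of a read using Myers' bit-vector formulation
of the dynamic-programming matrix: column j of the matrix is encoded as two
difference bit-vectors and updated in O(1) word operations, so one pass over
the read yields, for every end position j, the minimum edit distance of the
whole tag to any substring ending at j.  Python's arbitrary-precision
integers serve as the bit-vectors, so tags longer than a machine word work
unchanged; fixed-width words would be an optimisation, not a semantic
change.

IUPAC ambiguity codes in the tag are handled entirely during pattern
pre-processing: the per-letter match masks are widened so that e.g. Y
matches C or T at zero cost.  Ambiguity codes are wildcards only on the tag
side; an N in the read matches only a tag N.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Sequence

from .records import (
    End,
    MatchCategory,
    SequenceRecord,
    TagMatch,
    TagSpec,
    ValidationError,
    IUPAC_SETS,
    READ_ALPHABET,
)

__all__ = [
    "build_masks",
    "semiglobal_distance",
    "default_search_range",
    "find_tag_at_end",
    "continuous_trim",
    "find_internal",
]


def build_masks(tag: TagSpec) -> dict[str, int]:
    """Pre-process a tag into per-read-letter match bit masks.

    Bit i of ``masks[c]`` is set iff tag position i accepts read letter c at
    zero cost.  A tag N accepts any read letter (including read N); concrete
    tag letters and non-N ambiguity codes never accept a read N.
    """
    masks = {c: 0 for c in READ_ALPHABET}
    for i, letter in enumerate(tag.sequence):
        bit = 1 << i
        for c in IUPAC_SETS[letter]:
            masks[c] |= bit
        if letter == "N":
            masks["N"] |= bit
    return masks


def column_scores(masks: dict[str, int], m: int, text: str) -> Iterator[tuple[int, int]]:
    """Yield ``(j, score)`` for each text position j (0-based).

    ``score`` is the minimum edit distance of the full m-letter pattern to
    any substring of ``text`` ending at position j — the bottom row of the
    semi-global DP matrix, whose top row is all zeros (free gap before the
    pattern's match in the text).
    """
    full = (1 << m) - 1
    high = 1 << (m - 1)
    pv = full
    mv = 0
    score = m
    for j, c in enumerate(text):
        try:
            eq = masks[c]
        except KeyError:
            raise ValidationError(f"invalid read letter {c!r} at position {j}") from None
        xv = eq | mv
        xh = (((eq & pv) + pv) ^ pv) | eq
        ph = mv | (~(xh | pv) & full)
        mh = pv & xh
        if ph & high:
            score += 1
        elif mh & high:
            score -= 1
        ph = (ph << 1) & full
        mh = (mh << 1) & full
        pv = mh | (~(xv | ph) & full)
        mv = ph & xv
        yield j, score


def semiglobal_distance(tag: TagSpec, text: str) -> tuple[int, list[int]]:
    """Minimum semi-global edit distance of ``tag`` to ``text``.

    Gaps flanking the tag in the text are free, so the distance is the
    minimum number of insertions, deletions and substitutions turning the
    tag into some substring of the text.  Returns the minimum and the list
    of 0-based text indices of the last matched character for every
    alignment achieving it.
    """
    if not text:
        raise ValidationError("text must be non-empty")
    masks = build_masks(tag)
    best = tag.m + 1
    ends: list[int] = []
    for j, s in column_scores(masks, tag.m, text):
        if s < best:
            best, ends = s, [j]
        elif s == best:
            ends.append(j)
    return best, ends


def default_search_range(m: int) -> int:
    """Default end-window length max{10, 3m/2} for a tag of length m.

    The floor of 3m/2 is used (odd m rounds down).
    """
    if m < 1:
        raise ValidationError("tag length must be >= 1")
    return max(10, (3 * m) // 2)


def _locate_start(tag: TagSpec, text: str, end_excl: int, distance: int) -> int:
    """Recover the start of a match that ends at ``end_excl`` with ``distance``.

    Runs the matcher backwards over a bounded window ending at the match
    end; among starts consistent with the distance the smallest (longest
    extent) is chosen, matching the trimming tie-break.
    """
    lo = max(0, end_excl - tag.m - distance)
    window = text[lo:end_excl][::-1]
    masks = build_masks(tag.reversed())
    best_j = None
    for j, s in column_scores(masks, tag.m, window):
        if s == distance:
            best_j = j  # keep the largest j == smallest start
    if best_j is None:  # defensive; cannot happen for a genuine match
        raise AssertionError("match start not recoverable")
    return end_excl - (best_j + 1)


def _best_in_window(
    tag: TagSpec, window: str, early_exit: bool
) -> tuple[int, int] | None:
    """Best (distance, end index) in a window.

    Ties at distance 0 resolve to the first (leftmost end) occurrence — the
    scan stops as soon as a perfect match is seen; for positive distances
    the largest end (larger trimmed extent) wins.
    """
    if not window:
        return None
    masks = build_masks(tag)
    best: int | None = None
    best_j = -1
    for j, s in column_scores(masks, tag.m, window):
        if s == 0:
            if early_exit:
                return (0, j)
            if best != 0:
                best, best_j = 0, j
        elif best is None or s < best or (s == best and best > 0):
            best, best_j = s, j
    assert best is not None
    return (best, best_j)


def find_tag_at_end(
    read: SequenceRecord,
    tag: TagSpec,
    max_mismatches: int,
    search_range: int,
    *,
    early_exit: bool = True,
) -> TagMatch | None:
    """Locate the best tag occurrence within the end window of a read.

    For a 5' tag the window is the read prefix of ``search_range`` bases;
    for a 3' tag the symmetric suffix, searched on the reversed window
    against the reversed tag with coordinates mapped back.  Returns None
    when no occurrence has distance <= ``max_mismatches``.
    """
    if search_range < 1:
        raise ValidationError("search_range must be >= 1")
    seq = read.sequence
    if not seq:
        return None
    w = min(search_range, len(seq))
    if tag.end is End.THREE_PRIME:
        window = seq[len(seq) - w :][::-1]
        rtag = tag.reversed()
        res = _best_in_window(rtag, window, early_exit)
        if res is None or res[0] > max_mismatches:
            return None
        dist, j = res
        rstart = _locate_start(rtag, window, j + 1, dist)
        base = len(seq) - w
        return TagMatch(
            read.id, base + (w - (j + 1)), base + (w - rstart), dist, MatchCategory.END3
        )
    window = seq[:w]
    res = _best_in_window(tag, window, early_exit)
    if res is None or res[0] > max_mismatches:
        return None
    dist, j = res
    start = _locate_start(tag, window, j + 1, dist)
    return TagMatch(read.id, start, j + 1, dist, MatchCategory.END5)


def continuous_trim(
    read: SequenceRecord,
    tag: TagSpec,
    max_mismatches: int,
    search_range: int,
    *,
    continuous: bool = True,
) -> tuple[SequenceRecord, list[TagMatch]]:
    """Trim tag occurrences from one end, repeatedly if ``continuous``.

    Repeated trimming removes concatenated tag copies at the end; a read
    consisting only of tag copies trims down to an empty residue (a tag
    repeat, later removed by the length filter).  Match coordinates are
    reported on the input record of this call.
    """
    matches: list[TagMatch] = []
    current = read
    offset = 0  # cumulative bases removed at the 5' end
    while current.sequence:
        m = find_tag_at_end(current, tag, max_mismatches, search_range)
        if m is None:
            break
        if tag.end is End.THREE_PRIME:
            matches.append(m)
            current = current.slice(0, m.start)
        else:
            matches.append(
                TagMatch(read.id, m.start + offset, m.end + offset, m.distance, m.category)
            )
            offset += m.end
            current = current.slice(m.end, len(current))
        if not continuous:
            break
    return current, matches


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def find_internal(
    read: SequenceRecord,
    pattern: TagSpec,
    max_mismatches: int,
    exclude: Sequence[tuple[int, int]] = (),
) -> list[TagMatch]:
    """All non-overlapping internal occurrences of a pattern in a read.

    Candidates with distance <= ``max_mismatches`` are selected greedily by
    lowest distance, then leftmost end position; occurrences overlapping the
    ``exclude`` intervals (already-matched end regions) or a previously
    selected occurrence are dropped.  Results are sorted by start.
    """
    seq = read.sequence
    if len(seq) == 0:
        return []
    masks = build_masks(pattern)
    candidates = [
        (s, j)
        for j, s in column_scores(masks, pattern.m, seq)
        if s <= max_mismatches
    ]
    candidates.sort()
    taken: list[tuple[int, int]] = list(exclude)
    chosen: list[TagMatch] = []
    for s, j in candidates:
        start = _locate_start(pattern, seq, j + 1, s)
        interval = (start, j + 1)
        if any(_overlaps(interval, t) for t in taken):
            continue
        chosen.append(TagMatch(read.id, start, j + 1, s, MatchCategory.INTERNAL))
        taken.append(interval)
    chosen.sort(key=lambda m: m.start)
    return chosen
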