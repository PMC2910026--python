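"""Automatic tag-sequence prediction from positional nucleotide frequencies.

An artificial tag at a read end leaves a footprint in the per-position base
frequencies: fixed tag positions have one base near frequency 1,
quasi-random positions (the N tail of WTA primers) show a preferred but not
fixed base, and genuine sample sequence is near-uniform at 0.25 each.
Sequencing indels shift a fraction of reads by a few positions and blur
that footprint, so before classification the terminal k-mers of all reads
are clustered by gapless shift alignment and each read's frequencies are
re-registered by its k-mer's adjusted shift.

Positions are classified from the range r and median of the four base
frequencies: r > 3*median marks a fixed (specific) base, r < median +
variation marks background sequence, anything between is quasi-random.
The predicted tag is the maximal run of non-background positions starting
at the profiled end, with quasi-random positions emitted as N.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import End, SequenceRecord, TagSpec

__all__ = [
    "PositionClass",
    "KmerShift",
    "FrequencyProfile",
    "TagDetectionError",
    "TagDetectionResult",
    "extract_end_kmers",
    "filter_and_rank_kmers",
    "align_shift",
    "merge_kmers",
    "adjust_shifts",
    "corrected_frequencies",
    "classify_positions",
    "predict_tag",
    "detect_tag",
    "frequency_report",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class TagDetectionError(RuntimeError):
    """No usable end signal in the dataset (a valid outcome for tag-free data)."""


class PositionClass(Enum):
    SPECIFIC = "specific"
    QUASI_RANDOM = "quasi-random"
    BACKGROUND = "background"


@dataclass(frozen=True)
class KmerShift:
    """A terminal k-mer with its count and (possibly adjusted) shift.

    ``both`` marks the ambiguous case where the k-mer aligns equally well by
    |shift| in either direction (the ±l case); such k-mers contribute reads
    at the unshifted raw offset.
    """

    kmer: str
    count: int
    shift: int | None = None
    both: bool = False


def extract_end_kmers(
    reads: Iterable[SequenceRecord], k: int = 5, end: End = End.FIVE_PRIME
) -> Counter:
    """Count the terminal k-mer at the given end of every read.

    Reads shorter than k are skipped; counts sum to the number of
    contributing reads.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts: Counter = Counter()
    for r in reads:
        s = r.sequence
        if len(s) < k:
            continue
        counts[s[:k] if end is End.FIVE_PRIME else s[-k:]] += 1
    if not counts:
        raise TagDetectionError("no reads of length >= k; cannot profile ends")
    return counts


def filter_and_rank_kmers(
    counts: Mapping[str, int], n_reads: int, min_fraction: float = 0.10
) -> list[KmerShift]:
    """Keep k-mers carried by at least ``min_fraction`` of reads, ranked.

    Ordered by decreasing count, ties broken lexicographically.  Raises
    :class:`TagDetectionError` when nothing passes — there is no conserved
    end signal, as expected for tag-free data.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    cut = min_fraction * n_reads
    kept = [(kmer, c) for kmer, c in counts.items() if c >= cut]
    if not kept:
        raise TagDetectionError("no conserved end signal")
    kept.sort(key=lambda t: (-t[1], t[0]))
    return [KmerShift(kmer, c) for kmer, c in kept]


def _overlap_match(anchor: str, candidate: str, offset: int) -> bool:
    # candidate[0] sits at anchor coordinate `offset`; the gapless overlap
    # must be non-empty and match exactly
    lo = max(0, offset)
    hi = min(len(anchor), offset + len(candidate))
    if hi <= lo:
        return False
    return all(candidate[p - offset] == anchor[p] for p in range(lo, hi))


def align_shift(
    anchor: str, candidate: str, max_shift: int = 2
) -> tuple[int, bool] | None:
    """Minimum gapless shift aligning ``candidate`` to ``anchor``.

    Returns ``(l, both)`` where l is signed (negative = candidate shifted
    left relative to the anchor) and ``both`` flags the ±l case where both
    directions align at the same magnitude (e.g. ACACA vs CACAC); None when
    no |l| <= ``max_shift`` gives an exact overlap.
    """
    for l in range(max_shift + 1):
        if l == 0:
            if _overlap_match(anchor, candidate, 0):
                return (0, False)
            continue
        neg = _overlap_match(anchor, candidate, -l)
        pos = _overlap_match(anchor, candidate, l)
        if neg and pos:
            return (l, True)
        if neg:
            return (-l, False)
        if pos:
            return (l, False)
    return None


def _align_to_consensus(
    consensus: str, cons_off: int, candidate: str, max_shift: int
) -> tuple[int, bool] | None:
    """Like :func:`align_shift` but against a growing consensus.

    Shift values are kept relative to the top-ranked k-mer (whose first base
    sits at absolute coordinate 0); ``cons_off`` is the absolute coordinate
    of ``consensus[0]``.
    """
    for l in range(max_shift + 1):
        if l == 0:
            if _overlap_match(consensus, candidate, -cons_off):
                return (0, False)
            continue
        neg = _overlap_match(consensus, candidate, -l - cons_off)
        pos = _overlap_match(consensus, candidate, l - cons_off)
        if neg and pos:
            return (l, True)
        if neg:
            return (-l, False)
        if pos:
            return (l, False)
    return None


def merge_kmers(
    ranked: Sequence[KmerShift],
    end: End = End.FIVE_PRIME,
    max_shift: int = 2,
) -> tuple[str, dict[str, KmerShift]]:
    """Agglomerate ranked k-mers into a consensus, assigning shifts.

    The top k-mer seeds the consensus; each remaining k-mer is aligned to
    the current consensus by the smallest shift <= ``max_shift`` and joined
    (extending the consensus where it protrudes) or deferred to the next
    pass.  Passes repeat until one joins nothing.  Shift signs follow the
    read orientation (negative = towards the 5' side); for the 3' end the
    merge runs on reversed k-mers so that shift 0 means the terminal bases
    coincide.
    """
    if not ranked:
        raise ValueError("ranked k-mer list must be non-empty")
    rev = end is End.THREE_PRIME
    oriented = [ks.kmer[::-1] if rev else ks.kmer for ks in ranked]
    by_oriented = {o: ks for o, ks in zip(oriented, ranked)}

    consensus = oriented[0]
    cons_off = 0
    shifts: dict[str, tuple[int, bool]] = {oriented[0]: (0, False)}
    pending = deque(oriented[1:])
    while pending:
        progressed = False
        deferred: list[str] = []
        for cand in pending:
            res = _align_to_consensus(consensus, cons_off, cand, max_shift)
            if res is None:
                deferred.append(cand)
                continue
            a, both = res
            shifts[cand] = (a, both)
            if not both:
                o = a - cons_off  # candidate[0] relative to consensus[0]
                left = cand[: max(0, -o)]
                right = cand[len(consensus) - o :] if len(consensus) - o < len(cand) else ""
                consensus = left + consensus + right
                if o < 0:
                    cons_off += o
            progressed = True
        pending = deque(deferred)
        if not progressed:
            break

    out: dict[str, KmerShift] = {}
    for o, (val, both) in shifts.items():
        ks = by_oriented[o]
        out[ks.kmer] = replace(ks, shift=(-val if rev else val), both=both)
    return (consensus[::-1] if rev else consensus), out


def adjust_shifts(
    assignments: Mapping[str, KmerShift], end: End
) -> dict[str, KmerShift]:
    """Shift all assignments so the 5' end has none negative (3': none positive).

    The offset is a = |min l| for the 5' end and a = -max l for the 3' end;
    the top k-mer (raw shift 0) therefore gets a as its adjusted shift.
    ±l k-mers are treated as raw shift 0.
    """
    raw = [0 if ks.both else ks.shift for ks in assignments.values()]
    if not raw:
        return {}
    a = abs(min(raw)) if end is End.FIVE_PRIME else -max(raw)
    return {
        kmer: replace(ks, shift=(0 if ks.both else ks.shift) + a)
        for kmer, ks in assignments.items()
    }


@dataclass
class FrequencyProfile:
    """Per-position base counts from one read end.

    Position 0 is the profiled end (first base for 5', last base for 3').
    Reads contributing an N at a position are excluded from that position's
    normalisation, so frequencies are over A, C, G, T only.
    """

    end: End
    counts: np.ndarray  # shape (L, 4), A/C/G/T columns

    @property
    def depth(self) -> int:
        return self.counts.shape[0]

    @property
    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def freqs(self) -> np.ndarray:
        sup = self.support
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.counts / sup[:, None]
        f[sup == 0] = 0.0
        return f

    @property
    def ranges(self) -> np.ndarray:
        f = self.freqs
        return f.max(axis=1) - f.min(axis=1)

    @property
    def medians(self) -> np.ndarray:
        return np.median(self.freqs, axis=1)


def corrected_frequencies(
    reads: Iterable[SequenceRecord],
    assignments: Mapping[str, KmerShift],
    end: End,
    k: int = 5,
    depth: int = 60,
) -> FrequencyProfile:
    """Build a shift-corrected base-frequency profile for one read end.

    A read whose terminal k-mer has an adjusted shift s contributes its base
    at end-relative position i to profile position i + s (5') or i + |s|
    (3'); reads with no assignment (or a ±l assignment) contribute
    unshifted.  With empty ``assignments`` this is the raw profile.
    """
    counts = np.zeros((depth, 4), dtype=np.int64)
    five = end is End.FIVE_PRIME
    shift_of: dict[str, int] = {
        kmer: (0 if ks.both else abs(ks.shift or 0)) for kmer, ks in assignments.items()
    }
    for r in reads:
        s = r.sequence
        if not s:
            continue
        key = s[:k] if five else s[-k:]
        sh = shift_of.get(key, 0) if len(s) >= k else 0
        span = min(len(s), depth - sh)
        if five:
            for i in range(span):
                b = _BASE_INDEX.get(s[i])
                if b is not None:
                    counts[i + sh, b] += 1
        else:
            last = len(s) - 1
            for i in range(span):
                b = _BASE_INDEX.get(s[last - i])
                if b is not None:
                    counts[i + sh, b] += 1
    return FrequencyProfile(end=end, counts=counts)


def classify_positions(
    profile: FrequencyProfile,
    variation: float = 0.05,
    min_support: int = 50,
) -> list[PositionClass]:
    """Classify each profiled position from its frequency range and median.

    range > 3*median -> SPECIFIC; range < median + variation -> BACKGROUND;
    otherwise QUASI_RANDOM.  Positions supported by fewer than
    ``min_support`` reads are background (insufficient evidence).
    ``variation`` is an absolute frequency (default 0.05).
    """
    classes: list[PositionClass] = []
    sup = profile.support
    ranges = profile.ranges
    medians = profile.medians
    for i in range(profile.depth):
        if sup[i] < min_support:
            classes.append(PositionClass.BACKGROUND)
        elif ranges[i] > 3 * medians[i]:
            classes.append(PositionClass.SPECIFIC)
        elif ranges[i] < medians[i] + variation:
            classes.append(PositionClass.BACKGROUND)
        else:
            classes.append(PositionClass.QUASI_RANDOM)
    return classes


def predict_tag(
    classes: Sequence[PositionClass],
    profile: FrequencyProfile,
    end: End,
) -> TagSpec | None:
    """Read the tag off the classified profile.

    The tag is the maximal run of non-background positions starting at the
    profiled end: specific positions emit their majority base, quasi-random
    positions emit N.  Returns None for an empty run (tag-free data).
    """
    run = 0
    while run < len(classes) and classes[run] is not PositionClass.BACKGROUND:
        run += 1
    if run == 0:
        return None
    letters = []
    for i in range(run):
        if classes[i] is PositionClass.SPECIFIC:
            letters.append(_BASES[int(np.argmax(profile.counts[i]))])
        else:
            letters.append("N")
    seq = "".join(letters)
    if end is End.THREE_PRIME:
        seq = seq[::-1]
    return TagSpec(seq, end)


@dataclass
class TagDetectionResult:
    end: End
    tag: TagSpec | None
    raw_profile: FrequencyProfile
    corrected_profile: FrequencyProfile
    classes: list[PositionClass]
    consensus: str | None
    shifts: dict[str, KmerShift]
    note: str | None = None


def detect_tag(
    reads: Sequence[SequenceRecord],
    end: End = End.FIVE_PRIME,
    k: int = 5,
    min_fraction: float = 0.10,
    max_shift: int = 2,
    variation: float = 0.05,
    min_support: int = 50,
    depth: int = 60,
) -> TagDetectionResult:
    """Full detection pipeline for one read end.

    Extracts terminal k-mers, filters/ranks them, merges them into a shift
    consensus, re-registers the frequency profile, classifies positions and
    predicts the tag.  When no k-mer clears the frequency threshold the
    result carries ``tag=None`` with an explanatory note.
    """
    if not reads:
        raise TagDetectionError("empty dataset")
    raw = corrected_frequencies(reads, {}, end, k=k, depth=depth)
    try:
        counts = extract_end_kmers(reads, k=k, end=end)
        ranked = filter_and_rank_kmers(counts, len(reads), min_fraction=min_fraction)
    except TagDetectionError as exc:
        classes = classify_positions(raw, variation=variation, min_support=min_support)
        return TagDetectionResult(end, None, raw, raw, classes, None, {}, note=str(exc))
    consensus, shifts = merge_kmers(ranked, end=end, max_shift=max_shift)
    adjusted = adjust_shifts(shifts, end)
    corrected = corrected_frequencies(reads, adjusted, end, k=k, depth=depth)
    classes = classify_positions(corrected, variation=variation, min_support=min_support)
    tag = predict_tag(classes, corrected, end)
    note = None if tag is not None else "no non-background run at the profiled end"
    return TagDetectionResult(end, tag, raw, corrected, classes, consensus, adjusted, note)


def frequency_report(result: TagDetectionResult) -> str:
    """Tab-separated per-position report (for user review of a prediction)."""
    lines = ["position\tA\tC\tG\tT\trange\tmedian\tclass"]
    prof = result.corrected_profile
    f = prof.freqs
    r = prof.ranges
    med = prof.medians
    for i in range(prof.depth):
        cls = result.classes[i].value if i < len(result.classes) else ""
        lines.append(
            f"{i}\t{f[i,0]:.4f}\t{f[i,1]:.4f}\t{f[i,2]:.4f}\t{f[i,3]:.4f}"
            f"\t{r[i]:.4f}\t{med[i]:.4f}\t{cls}"
        )
    return "\n".join(lines) + "\n"
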