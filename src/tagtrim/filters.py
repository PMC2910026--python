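"""Post-trim filtering and pipeline orchestration.

The pipeline applies, per read: 5'-end trimming (repeatedly when continuous
trimming is enabled), 3'-end trimming on the residue, junction splitting,
then the per-record filters (length, ambiguous-base content, tag
occurrence), and finally dereplication of the passing set.  Dereplication
runs after trimming so that duplicates differing only in their (noisy) tag
copies are still recognised.  Reads failing a filter are emitted untrimmed;
split fragments re-enter the filters like ordinary reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .match import continuous_trim, default_search_range, find_tag_at_end
from .records import End, SequenceRecord, TagMatch, TagSpec, ValidationError
from .split import Fragment, detect_junctions, junction_pattern, split_read

__all__ = [
    "Occurrence",
    "FilterConfig",
    "TrimReport",
    "PipelineResult",
    "resolve_mismatch_limit",
    "dereplicate",
    "filter_length",
    "filter_ambiguous",
    "filter_occurrence",
    "run_pipeline",
]


class Occurrence(Enum):
    """Which tag occurrences a read must show to be kept."""

    FIVE = "5"
    THREE = "3"
    BOTH = "both"
    EITHER = "either"
    NONE = "none"
    DONT_REMOVE = "keep"


@dataclass
class FilterConfig:
    """The full filter parameter set.

    Mismatch limits may be given as absolute counts or as percentage
    strings like ``"10%"`` of the tag length (floored).  Search ranges of
    ``"auto"`` use max{10, 3m/2} for the respective tag.  Defaults follow
    the worked WTA example configuration.
    """

    max_mm5: int | str = 3
    max_mm3: int | str = 3
    search_range5: int | str = "auto"
    search_range3: int | str = "auto"
    occurrence: Occurrence = Occurrence.DONT_REMOVE
    continuous: bool = True
    min_len: int = 50
    max_len: int | None = None
    max_n_percent: float = 5.0
    dereplicate: bool = True
    split: bool = True
    split_max_mm: int = 3

    def __post_init__(self) -> None:
        if self.max_len is not None and self.min_len > self.max_len:
            raise ValidationError("min_len must be <= max_len")
        if not (0 <= self.max_n_percent <= 100):
            raise ValidationError("max_n_percent must be in [0, 100]")
        if self.min_len < 0 or self.split_max_mm < 0:
            raise ValidationError("thresholds must be non-negative")


def resolve_mismatch_limit(value: int | str, m: int) -> int:
    """Resolve an absolute or percentage mismatch limit for a tag of length m."""
    if isinstance(value, str):
        text = value.strip()
        if not text.endswith("%"):
            raise ValidationError(f"mismatch limit {value!r} is neither a count nor a percentage")
        try:
            pct = float(text[:-1])
        except ValueError:
            raise ValidationError(f"invalid percentage {value!r}") from None
        if pct < 0:
            raise ValidationError("mismatch percentage must be non-negative")
        return math.floor(pct * m / 100.0)
    if value < 0:
        raise ValidationError("mismatch limit must be non-negative")
    return int(value)


def _resolve_range(value: int | str, m: int) -> int:
    if value == "auto":
        return default_search_range(m)
    if isinstance(value, str):
        raise ValidationError(f"invalid search range {value!r}")
    if value < 1:
        raise ValidationError("search range must be >= 1")
    return int(value)


@dataclass
class TrimReport:
    """Per-output-record provenance: lengths, trim coordinates, fates.

    ``trim5_end``/``trim3_start`` are coordinates on the original read:
    everything before ``trim5_end`` and from ``trim3_start`` on was removed
    by end trimming.  ``fate`` is "pass" or "filtered:<reason>".
    """

    read_id: str
    initial_len: int
    trimmed_len: int
    trim5_end: int
    trim3_start: int
    mm5: int | None
    mm3: int | None
    fragment_count: int
    fate: str = "pass"


@dataclass
class PipelineResult:
    passing: list[SequenceRecord]
    failing: list[SequenceRecord]
    reports: list[TrimReport]
    summary: dict
    n_input: int
    n_split: int
    n_fragments: int


def dereplicate(reads: Sequence[SequenceRecord]) -> tuple[list[SequenceRecord], int]:
    """Keep the first occurrence of each exact sequence string, in order."""
    seen: set[str] = set()
    kept: list[SequenceRecord] = []
    removed = 0
    for r in reads:
        if r.sequence in seen:
            removed += 1
        else:
            seen.add(r.sequence)
            kept.append(r)
    return kept, removed


def filter_length(length: int, min_len: int, max_len: int | None) -> bool:
    """True when min_len <= length <= max_len (inclusive bounds)."""
    return length >= min_len and (max_len is None or length <= max_len)


def filter_ambiguous(sequence: str, max_n_percent: float) -> bool:
    """True when the N content is not strictly above the threshold."""
    if not sequence:
        return False
    return 100.0 * sequence.count("N") / len(sequence) <= max_n_percent


def filter_occurrence(matched5: bool, matched3: bool, mode: Occurrence) -> bool:
    """True when the read's tag occurrences satisfy the mode."""
    if mode is Occurrence.DONT_REMOVE:
        return True
    if mode is Occurrence.FIVE:
        return matched5
    if mode is Occurrence.THREE:
        return matched3
    if mode is Occurrence.BOTH:
        return matched5 and matched3
    if mode is Occurrence.EITHER:
        return matched5 or matched3
    return not matched5 and not matched3  # NONE


def _bucket(distance: int | None) -> str:
    if distance is None or distance > 5:
        return ">5"
    return str(distance)


def run_pipeline(
    reads: Iterable[SequenceRecord],
    tag5: TagSpec | None,
    tag3: TagSpec | None,
    config: FilterConfig | None = None,
) -> PipelineResult:
    """Trim, split and filter a dataset; account for every input read.

    Every input read ends up in exactly one output stream (as itself or as
    its split fragments); reads failing a filter are emitted with their
    original, untrimmed sequence.  The summary counts reads per mismatch
    bucket (0-5, >5 including "no match") for the 5' end, the 3' end and
    the junction pattern.
    """
    config = config or FilterConfig()
    mm5 = resolve_mismatch_limit(config.max_mm5, tag5.m) if tag5 else 0
    mm3 = resolve_mismatch_limit(config.max_mm3, tag3.m) if tag3 else 0
    range5 = _resolve_range(config.search_range5, tag5.m) if tag5 else 0
    range3 = _resolve_range(config.search_range3, tag3.m) if tag3 else 0
    pattern = (
        junction_pattern(tag5, tag3) if (config.split and tag5 and tag3) else None
    )

    buckets = {
        "5'-end": {k: 0 for k in [*"012345", ">5"]},
        "3'-end": {k: 0 for k in [*"012345", ">5"]},
        "concatenated": {k: 0 for k in [*"012345"]},
    }
    passing: list[tuple[SequenceRecord, TrimReport]] = []
    failing: list[SequenceRecord] = []
    reports: list[TrimReport] = []
    n_input = 0
    n_split = 0
    n_fragments = 0

    for read in reads:
        n_input += 1
        work = read
        matches5: list[TagMatch] = []
        matches3: list[TagMatch] = []
        trim5_end = 0
        trim3_start = len(read)
        if tag5 is not None and work.sequence:
            work, matches5 = continuous_trim(
                work, tag5, mm5, range5, continuous=config.continuous
            )
            if matches5:
                trim5_end = matches5[-1].end
        if tag3 is not None and work.sequence:
            work, matches3 = continuous_trim(
                work, tag3, mm3, range3, continuous=config.continuous
            )
            if matches3:
                # coordinates of the 3' matches are on the 5'-trimmed read
                trim3_start = trim5_end + matches3[-1].start
        buckets["5'-end"][_bucket(matches5[0].distance if matches5 else None)] += 1
        buckets["3'-end"][_bucket(matches3[0].distance if matches3 else None)] += 1

        junctions = []
        if pattern is not None and work.sequence:
            junctions = detect_junctions(work, pattern, config.split_max_mm)
            for j in junctions:
                buckets["concatenated"][str(min(j.distance, 5))] += 1
        fragments = split_read(work, junctions)
        if junctions:
            n_split += 1
            n_fragments += len(fragments)

        d5 = matches5[0].distance if matches5 else None
        d3 = matches3[0].distance if matches3 else None
        tag_repeat = not work.sequence and bool(matches5 or matches3)
        for frag in fragments:
            rec_id = frag.id if frag.ordinal else frag.parent_id
            rec = SequenceRecord(rec_id, frag.sequence, read.description, frag.quality)
            report = TrimReport(
                read_id=rec_id,
                initial_len=len(read),
                trimmed_len=len(rec),
                trim5_end=trim5_end,
                trim3_start=trim3_start,
                mm5=d5,
                mm3=d3,
                fragment_count=len(fragments) if junctions else 1,
            )
            if not filter_length(len(rec), config.min_len, config.max_len):
                report.fate = "filtered:tag_repeat" if tag_repeat else "filtered:length"
            elif not filter_ambiguous(rec.sequence, config.max_n_percent):
                report.fate = "filtered:ambiguous"
            elif not filter_occurrence(bool(matches5), bool(matches3), config.occurrence):
                report.fate = "filtered:occurrence"
            reports.append(report)
            if report.fate == "pass":
                passing.append((rec, report))
            else:
                # failing reads go out untrimmed; fragments keep their sequence
                failing.append(
                    read if not junctions else SequenceRecord(rec_id, frag.sequence, read.description, frag.quality)
                )

    kept: list[SequenceRecord] = []
    if config.dereplicate:
        seen: set[str] = set()
        for rec, report in passing:
            if rec.sequence in seen:
                report.fate = "filtered:duplicate"
                failing.append(rec)
            else:
                seen.add(rec.sequence)
                kept.append(rec)
    else:
        kept = [rec for rec, _ in passing]

    summary = {
        "input": n_input,
        "passing": len(kept),
        "failing": len(failing),
        "split_reads": n_split,
        "fragments": n_fragments,
        "mismatch_buckets": buckets,
    }
    return PipelineResult(kept, failing, reports, summary, n_input, n_split, n_fragments)
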