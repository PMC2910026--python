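"""Reading and writing of sequence data and filter parameters.

FASTA and FASTQ (Sanger/Phred+33) are parsed with Biopython; the file
format and the compression layer (none, gzip, or zip) are detected from
magic bytes and content, and multi-member zip archives are concatenated in
member order.  Read sequences are normalised on ingest: upper-cased, U
mapped to T, non-N IUPAC ambiguity letters converted to N (with a logged
count), and anything outside the IUPAC alphabet rejected.
"""

from __future__ import annotations

import gzip
import io as _stdio
import json
import logging
import zipfile
from dataclasses import asdict, fields
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .filters import FilterConfig, Occurrence, PipelineResult, TrimReport
from .records import SequenceRecord, ValidationError, normalize_read_sequence

__all__ = [
    "open_dataset",
    "write_records",
    "write_report",
    "write_results",
    "config_to_file",
    "config_from_file",
]

logger = logging.getLogger(__name__)

_GZIP_MAGIC = b"\x1f\x8b"
_ZIP_MAGIC = b"PK\x03\x04"


def _sniff_format(handle: IO[str]) -> str:
    head = handle.read(1)
    handle.seek(0)
    if head == ">":
        return "fasta"
    if head == "@":
        return "fastq"
    raise ValidationError("input is neither FASTA nor FASTQ (line 1)")


def _parse_stream(handle: IO[str], source: str) -> Iterator[SequenceRecord]:
    fmt = _sniff_format(handle)
    converted_total = 0
    n = 0
    for rec in SeqIO.parse(handle, fmt):
        seq, converted = normalize_read_sequence(str(rec.seq))
        converted_total += converted
        quality = None
        if fmt == "fastq":
            quality = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
        n += 1
        yield SequenceRecord(rec.id, seq, rec.description, quality)
    if n == 0:
        raise ValidationError(f"{source}: no sequence records found")
    if converted_total:
        logger.info(
            "%s: %d non-N ambiguity letters normalised to N", source, converted_total
        )


def open_dataset(path: str | Path) -> list[SequenceRecord]:
    """Load a FASTA/FASTQ dataset, transparently decompressing gzip or zip.

    Zip archives may hold several FASTA/FASTQ members, which are joined
    into one dataset in member order.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic.startswith(_ZIP_MAGIC):
        records: list[SequenceRecord] = []
        with zipfile.ZipFile(path) as zf:
            members = [m for m in zf.namelist() if not m.endswith("/")]
            if not members:
                raise ValidationError(f"{path}: empty zip archive")
            for member in members:
                with zf.open(member) as raw:
                    text = _stdio.StringIO(raw.read().decode("ascii"))
                records.extend(_parse_stream(text, f"{path}:{member}"))
        return records
    if magic.startswith(_GZIP_MAGIC):
        with gzip.open(path, "rt") as fh:
            return list(_parse_stream(_to_seekable(fh), str(path)))
    with open(path, "rt") as fh:
        return list(_parse_stream(fh, str(path)))


def _to_seekable(handle: IO[str]) -> IO[str]:
    # gzip text handles support seek(0) but re-decompress; small sniff only
    return _stdio.StringIO(handle.read())


def _annotation(report: TrimReport) -> str:
    # 1-based inclusive coordinates of the kept region on the original read
    trim5 = report.trim5_end + 1
    trim3 = report.trim3_start
    mm5 = report.mm5 if report.mm5 is not None else "NA"
    mm3 = report.mm3 if report.mm3 is not None else "NA"
    return (
        f"init_len={report.initial_len} trim_len={report.trimmed_len} "
        f"trim5={trim5} trim3={trim3} mm5={mm5} mm3={mm3} "
        f"frags={report.fragment_count}"
    )


def write_records(
    records: Sequence[SequenceRecord],
    path: str | Path,
    out_format: str = "fasta",
    annotate: bool = False,
    reports: Sequence[TrimReport] | None = None,
) -> None:
    """Write records as FASTA (default) or FASTQ; ``.gz`` suffix gzips.

    With ``annotate``, each header gains the per-read provenance fields
    (init_len, trim_len, trim5, trim3, mm5, mm3, frags) from the matching
    report.  Output ids must be unique.
    """
    path = Path(path)
    by_id = {r.read_id: r for r in reports} if reports else {}
    seen: set[str] = set()
    out: list[SeqRecord] = []
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"duplicate output id {rec.id!r}")
        seen.add(rec.id)
        description = rec.description
        if annotate and rec.id in by_id:
            description = _annotation(by_id[rec.id])
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, description=description)
        if out_format == "fastq":
            qual = rec.quality or "I" * len(rec.sequence)
            sr.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        out.append(sr)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        SeqIO.write(out, fh, out_format)


def write_report(reports: Sequence[TrimReport], path: str | Path) -> None:
    """Per-record trimming report as TSV."""
    header = "read_id\tinit_len\ttrim_len\ttrim5_end\ttrim3_start\tmm5\tmm3\tfrags\tfate"
    lines = [header]
    for r in reports:
        mm5 = r.mm5 if r.mm5 is not None else "NA"
        mm3 = r.mm3 if r.mm3 is not None else "NA"
        lines.append(
            f"{r.read_id}\t{r.initial_len}\t{r.trimmed_len}\t{r.trim5_end}"
            f"\t{r.trim3_start}\t{mm5}\t{mm3}\t{r.fragment_count}\t{r.fate}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_results(
    result: PipelineResult,
    out_prefix: str | Path,
    out_format: str = "fasta",
    annotate: bool = False,
) -> dict[str, Path]:
    """Write passing/failing records and the report next to ``out_prefix``."""
    out_prefix = Path(out_prefix)
    ext = "fastq" if out_format == "fastq" else "fasta"
    paths = {
        "passing": out_prefix.with_name(out_prefix.name + f".pass.{ext}"),
        "failing": out_prefix.with_name(out_prefix.name + f".fail.{ext}"),
        "report": out_prefix.with_name(out_prefix.name + ".report.tsv"),
    }
    write_records(result.passing, paths["passing"], out_format, annotate, result.reports)
    write_records(result.failing, paths["failing"], out_format, False)
    write_report(result.reports, paths["report"])
    return paths


def config_to_file(config: FilterConfig, path: str | Path) -> None:
    """Export a filter configuration as flat JSON (lossless round trip)."""
    data = asdict(config)
    data["occurrence"] = config.occurrence.value
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def config_from_file(path: str | Path) -> FilterConfig:
    """Import a filter configuration; unknown or ill-typed keys are rejected."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not valid JSON ({exc})") from None
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a JSON object")
    known = {f.name for f in fields(FilterConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValidationError(f"{path}: unknown parameter keys: {', '.join(unknown)}")
    if "occurrence" in data:
        try:
            data["occurrence"] = Occurrence(data["occurrence"])
        except ValueError:
            raise ValidationError(
                f"{path}: invalid occurrence mode {data['occurrence']!r}"
            ) from None
    for key in ("min_len", "split_max_mm"):
        if key in data and not isinstance(data[key], int):
            raise ValidationError(f"{path}: {key} must be an integer")
    for key in ("continuous", "dereplicate", "split"):
        if key in data and not isinstance(data[key], bool):
            raise ValidationError(f"{path}: {key} must be a boolean")
    try:
        return FilterConfig(**data)
    except (TypeError, ValidationError) as exc:
        raise ValidationError(f"{path}: {exc}") from None
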