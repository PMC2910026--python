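"""Ground-truthed synthetic reads with WTA-style tags.

The generator emulates the artefacts the trimmer is built to remove: a
fixed-plus-quasi-random 5' primer tag, a 3' tag that is often incomplete
because the sequenced read is shorter than the amplified fragment,
homopolymer-biased indel noise in tag copies (pyrosequencing mis-calls run
lengths of repeated bases), blunt-end fragment-to-fragment concatenations
that leave an internal tag3·tag5 junction, exact duplicates, and sporadic
ambiguous bases.  Every read carries a truth record with its planted trim
coordinates, per-end edit operations and junction intervals, so recovery
can be scored exactly.

Quasi-random (N) tag positions are drawn from a skewed base distribution
(default 0.45/0.30/0.15/0.10, base order rotated per position): WTA primer
tails show preferred, not uniform, bases because primers anneal to
similar-but-not-identical template sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import IUPAC_SETS, SequenceRecord, TagSpec, ValidationError

__all__ = [
    "DEFAULT_TAG5",
    "DEFAULT_TAG3",
    "SimulationConfig",
    "TruthRecord",
    "generate",
    "write_truth",
]

#: WTA-style example tags: a 22-base fixed segment plus a 9-base
#: quasi-random tail on the 5' end; the 3' tag is the mirrored layout.
DEFAULT_TAG5 = "GTGGTGTGTTGGGTGTGTTTGG" + "N" * 9
DEFAULT_TAG3 = "N" * 9 + "CCAAACACACCCAACACACCA"

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Inserts are i.i.d. uniform A/C/G/T of uniform random length between
    ``insert_min`` and ``insert_max`` (amplified fragments of roughly
    100-1,000 bp); reads are truncated at ``read_cap`` (a 500 bp
    pyrosequencing-style cap), which leaves many 3' tags incomplete.
    ``indel_rate`` is the probability of a single indel per tag copy,
    ``substitution_rate`` a per-base probability within tag copies.
    """

    n_reads: int = 1000
    tag5: str | None = DEFAULT_TAG5
    tag3: str | None = DEFAULT_TAG3
    insert_min: int = 100
    insert_max: int = 1000
    indel_rate: float = 0.05
    substitution_rate: float = 0.01
    concat_rate: float = 0.02
    duplicate_rate: float = 0.05
    n_rate: float = 0.002
    read_cap: int | None = 500
    quasi_probs: tuple[float, float, float, float] = (0.45, 0.30, 0.15, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("indel_rate", "substitution_rate", "concat_rate", "duplicate_rate", "n_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.insert_min > self.insert_max:
            raise ValidationError("insert_min must be <= insert_max")
        if self.read_cap is not None and self.insert_min > self.read_cap:
            raise ValidationError("minimum insert length exceeds the read length cap")
        if abs(sum(self.quasi_probs) - 1.0) > 1e-9:
            raise ValidationError("quasi_probs must sum to 1")


@dataclass
class TruthRecord:
    """Planted ground truth for one synthetic read."""

    read_id: str
    trim5_end: int  # bases of (noisy) 5' tag at the read start; 0 if none
    trim3_start: int | None  # where the complete 3' tag begins; None if truncated/absent
    dist5: int | None  # edit operations applied to the 5' tag copy
    dist3: int | None
    junctions: list[tuple[int, int]] = field(default_factory=list)
    is_duplicate: bool = False


def _instantiate(tag: str, rng: np.random.Generator, quasi_probs: Sequence[float]) -> str:
    """Replace IUPAC letters with concrete bases.

    N positions draw from the skewed quasi-random distribution with the
    base order rotated by position index (so neighbouring N positions
    prefer different bases); other ambiguity codes draw uniformly from
    their sets.
    """
    out = []
    for i, letter in enumerate(tag):
        if letter in _BASES:
            out.append(letter)
        elif letter == "N":
            order = [_BASES[(i + j) % 4] for j in range(4)]
            out.append(order[rng.choice(4, p=list(quasi_probs))])
        else:
            choices = IUPAC_SETS[letter]
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _homopolymer_positions(seq: list[str]) -> list[int]:
    return [
        i
        for i in range(len(seq))
        if (i > 0 and seq[i] == seq[i - 1]) or (i + 1 < len(seq) and seq[i] == seq[i + 1])
    ]


def _noisy_tag(tag: str, rng: np.random.Generator, cfg: SimulationConfig) -> tuple[str, int]:
    """Apply substitution and (single, homopolymer-biased) indel noise."""
    seq = list(tag)
    ops = 0
    if cfg.substitution_rate > 0:
        for i in range(len(seq)):
            if rng.random() < cfg.substitution_rate:
                seq[i] = _BASES[(_BASES.index(seq[i]) + 1 + rng.integers(3)) % 4]
                ops += 1
    if cfg.indel_rate > 0 and rng.random() < cfg.indel_rate and len(seq) > 1:
        homo = _homopolymer_positions(seq)
        if homo and rng.random() < 2 / 3:
            pos = int(homo[rng.integers(len(homo))])
        else:
            pos = int(rng.integers(len(seq)))
        if rng.random() < 0.5:
            del seq[pos]
        else:
            seq.insert(pos, seq[pos])  # run-length miscall duplicates the base
        ops += 1
    return "".join(seq), ops


def _random_insert(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    length = int(rng.integers(cfg.insert_min, cfg.insert_max + 1))
    bases = rng.integers(0, 4, size=length)
    seq = "".join(_BASES[b] for b in bases)
    if cfg.n_rate > 0:
        chars = list(seq)
        for i in range(len(chars)):
            if rng.random() < cfg.n_rate:
                chars[i] = "N"
        seq = "".join(chars)
    return seq


def generate(config: SimulationConfig) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Generate a dataset plus its truth table, fully determined by the seed."""
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    truths: list[TruthRecord] = []
    cap = config.read_cap

    for idx in range(config.n_reads):
        rid = f"sim{idx:05d}"
        if records and rng.random() < config.duplicate_rate:
            src = int(rng.integers(len(records)))
            t = truths[src]
            records.append(SequenceRecord(rid, records[src].sequence))
            truths.append(
                TruthRecord(rid, t.trim5_end, t.trim3_start, t.dist5, t.dist3,
                            list(t.junctions), is_duplicate=True)
            )
            continue

        parts: list[str] = []
        junctions: list[tuple[int, int]] = []
        d5: int | None = None
        d3: int | None = None
        t5_len = 0
        if config.tag5:
            t5, d5 = _noisy_tag(_instantiate(config.tag5, rng, config.quasi_probs), rng, config)
            parts.append(t5)
            t5_len = len(t5)
        parts.append(_random_insert(rng, config))
        if config.tag5 and config.tag3 and rng.random() < config.concat_rate:
            j3, _ = _noisy_tag(_instantiate(config.tag3, rng, config.quasi_probs), rng, config)
            j5, _ = _noisy_tag(_instantiate(config.tag5, rng, config.quasi_probs), rng, config)
            j_start = sum(len(p) for p in parts)
            junctions.append((j_start, j_start + len(j3) + len(j5)))
            parts.extend([j3, j5, _random_insert(rng, config)])
        t3_len = 0
        if config.tag3:
            t3, d3 = _noisy_tag(_instantiate(config.tag3, rng, config.quasi_probs), rng, config)
            parts.append(t3)
            t3_len = len(t3)

        seq = "".join(parts)
        full_len = len(seq)
        if cap is not None and full_len > cap:
            seq = seq[:cap]
        trim3_start: int | None = None
        if config.tag3 and len(seq) == full_len:
            trim3_start = len(seq) - t3_len
        else:
            d3 = None  # 3' tag truncated away (or partially); no planted coordinate
        junctions = [(s, e) for s, e in junctions if e <= len(seq)]
        records.append(SequenceRecord(rid, seq))
        truths.append(TruthRecord(rid, t5_len, trim3_start, d5 if config.tag5 else None, d3, junctions))
    return records, truths


def write_truth(truths: Sequence[TruthRecord], path: str | Path) -> None:
    """Truth table as TSV (junction intervals as start-end;start-end)."""
    lines = ["read_id\ttrim5_end\ttrim3_start\tdist5\tdist3\tjunctions\tis_duplicate"]
    for t in truths:
        j = ";".join(f"{s}-{e}" for s, e in t.junctions)
        lines.append(
            f"{t.read_id}\t{t.trim5_end}\t"
            f"{t.trim3_start if t.trim3_start is not None else 'NA'}\t"
            f"{t.dist5 if t.dist5 is not None else 'NA'}\t"
            f"{t.dist3 if t.dist3 is not None else 'NA'}\t{j}\t{int(t.is_duplicate)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
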