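import random
from dataclasses import dataclass

import pytest

from tagtrim.filters import FilterConfig
from tagtrim.records import End, SequenceRecord, TagSpec

# The example WTA primer pair: 22 fixed + 9 quasi-random bases on the 5'
# end, the mirrored layout (21 fixed) on the 3' end.
WTA_TAG5 = "GTGGTGTGTTGGGTGTGTTTGG" + "N" * 9
WTA_TAG3 = "N" * 9 + "CCAAACACACCCAACACACCA"


@pytest.fixture
def wta_tags() -> tuple[TagSpec, TagSpec]:
    return TagSpec(WTA_TAG5, End.FIVE_PRIME), TagSpec(WTA_TAG3, End.THREE_PRIME)


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@dataclass
class ToySet:
    """An eight-read dataset with hand-enumerable fates under the default
    filter configuration (46 bp search ranges, 3 mismatches, continuous
    trimming, splitting, dereplication, min length 50, 5% N threshold)."""

    reads: list[SequenceRecord]
    config: FilterConfig
    expected_pass: dict[str, str]  # id -> trimmed sequence
    expected_fates: dict[str, str]  # id -> fate for non-passing records


@pytest.fixture
def toy_set() -> ToySet:
    rng = random.Random(42)
    t5i = "GTGGTGTGTTGGGTGTGTTTGG" + "ACGTACGTA"  # Ns instantiated
    t5i_alt = "GTGGTGTGTTGGGTGTGTTTGG" + "CCCCCCCCC"
    t3i = "TACGTACGT" + "CCAAACACACCCAACACACCA"
    i1, i2, i3 = random_dna(rng, 150), random_dna(rng, 80), random_dna(rng, 30)
    ia, ib = random_dna(rng, 120), random_dna(rng, 90)
    i4 = random_dna(rng, 46) + "N" * 8 + random_dna(rng, 46)  # 8% N
    reads = [
        SequenceRecord("r1", t5i + i1 + t3i),  # clean tagged
        SequenceRecord("r2", t5i + i2 + t3i),  # clean tagged
        SequenceRecord("r3", t5i_alt + i1 + t3i),  # trims to a duplicate of r1
        SequenceRecord("r4", t5i + i3 + t3i),  # 30 bp residue: too short
        SequenceRecord("r5", t5i + i4 + t3i),  # N-rich residue
        SequenceRecord("r6", t5i + t5i + t5i),  # pure tag repeat
        SequenceRecord("r7", t5i + ia + t3i + t5i + ib + t3i),  # concatenation
        SequenceRecord("r8", random_dna(rng, 45)),  # untagged and short
    ]
    config = FilterConfig(search_range5=46, search_range3=46)
    return ToySet(
        reads=reads,
        config=config,
        expected_pass={"r1": i1, "r2": i2, "r7.1": ia, "r7.2": ib},
        expected_fates={
            "r3": "filtered:duplicate",
            "r4": "filtered:length",
            "r5": "filtered:ambiguous",
            "r6": "filtered:tag_repeat",
            "r8": "filtered:length",
        },
    )
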