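"""Independent reference implementations used only to check the package.

The full dynamic-programming matrix is computed naively in O(nm); the
bit-parallel matcher must agree with it column by column.  IUPAC wildcards
in the pattern are expanded to zero-cost character sets, mirroring the
matcher's semantics (pattern N also accepts a read N; other pattern letters
never do).
"""

from __future__ import annotations

from tagtrim.records import IUPAC_SETS


def _accept_sets(pattern: str) -> list[set[str]]:
    out = []
    for ch in pattern:
        s = set(IUPAC_SETS[ch])
        if ch == "N":
            s.add("N")
        out.append(s)
    return out


def dp_semiglobal_scores(pattern: str, text: str) -> list[int]:
    """Bottom DP row: min edit distance of pattern to substrings ending at j."""
    m = len(pattern)
    accepts = _accept_sets(pattern)
    prev = list(range(m + 1))
    scores = []
    for c in text:
        cur = [0] * (m + 1)
        for i in range(1, m + 1):
            cost = 0 if c in accepts[i - 1] else 1
            cur[i] = min(prev[i - 1] + cost, prev[i] + 1, cur[i - 1] + 1)
        scores.append(cur[m])
        prev = cur
    return scores


def dp_semiglobal_min(pattern: str, text: str) -> int:
    return min(dp_semiglobal_scores(pattern, text))
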