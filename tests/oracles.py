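"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: exact matching is
done by position-wise slicing, and the longest-repeat oracle enumerates
copy offsets with run-length bookkeeping. They are quadratic and only
suitable for the small inputs used in tests.
"""

from __future__ import annotations

import numpy as np

COMP = str.maketrans("ACGTN", "TGCAN")


def naive_occurrences(text: str, pattern: str) -> list[int]:
    """All (overlapping) start positions of pattern in text, by slicing."""
    k = len(pattern)
    return [i for i in range(len(text) - k + 1) if text[i : i + k] == pattern]


def naive_two_strand_matches(
    records: dict[str, str], pattern: str
) -> set[tuple[str, int, str]]:
    """(seq_name, start, strand) triples for both strands, forward axis."""
    rc = pattern.translate(COMP)[::-1]
    out: set[tuple[str, int, str]] = set()
    for name, seq in records.items():
        for i in naive_occurrences(seq, pattern):
            out.add((name, i, "+"))
        for i in naive_occurrences(seq, rc):
            out.add((name, i, "-"))
    return out


def brute_longest_nonoverlapping_repeat(s: str) -> tuple[int, int, int] | None:
    """(pos_a, pos_b, length) of the maximal non-overlapping repeated pair.

    Ties broken by smallest pos_a then pos_b. Enumerates every copy offset
    d; within a maximal run of position-wise matches between s and s
    shifted by d, the best pair has length min(run, d) and starts at the
    run start.
    """
    a = np.frombuffer(s.encode(), dtype=np.uint8)
    n = len(a)
    best: tuple[int, int, int] | None = None  # (-length, pos_a, pos_b)
    for d in range(1, n):
        eq = a[: n - d] == a[d:]
        if not eq.any():
            continue
        # maximal runs of True
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for r_start, r_end in zip(starts, ends):
            length = min(int(r_end - r_start), d)
            cand = (-length, int(r_start), int(r_start) + d)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    return best[1], best[2], -best[0]


def brute_period(s: str) -> int:
    """Smallest p with s[i] == s[i+p] for all valid i."""
    for p in range(1, len(s)):
        if s[:-p] == s[p:]:
            return p
    return len(s)


def brute_tandem_candidates(unit: str, k: int) -> list[tuple[int, str, bool]]:
    """(offset, sequence, junction_spanning) from explicit rotations."""
    L = len(unit)
    tiled = unit * (k // L + 2)
    out = []
    for off in range(L):
        if unit[(off - 1) % L] == "T":
            out.append((off, tiled[off : off + k], k > L - off))
    return out
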