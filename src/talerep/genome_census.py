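"""Genome-wide exact-match census of candidate targets and feasibility calls.

Matching is exact-only on both strands: forward matches are occurrences of
the pattern itself, reverse matches are occurrences of its reverse
complement, reported on the forward coordinate axis with strand '-'.
Every start position counts (overlapping occurrences are all reported —
telomeric 8-mers recur every 6 bp, so any non-overlapping convention
would undercount tandem arrays). Matches are counted as distinct
(position, strand) pairs; self-reverse-complement patterns therefore hit
each locus twice and are flagged so callers can halve if they prefer.
N in the genome never matches any pattern base.

Copy-number feasibility follows the empirical rule that a chromatin-bound
TALE needs its target present in many copies (>1000, strict) in a ~35 Mb
genome before associated proteins can be enriched.

The multi-pattern scan is a single pass with a keyword automaton
(Aho–Corasick); its correctness contract is exact agreement with a naive
per-pattern scan, which the test suite enforces.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .sequence_io import AnnotationSet, Genome, Interval, revcomp

DEFAULT_FEASIBILITY_THRESHOLD = 1000


@dataclass(frozen=True)
class Match:
    """One exact k-mer occurrence on the forward coordinate axis."""

    interval: Interval
    strand: str
    pattern_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"match strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class CensusReport:
    """Strand-resolved counts and the specificity verdict for one pattern."""

    pattern_id: str
    pattern: str
    n_forward: int
    n_reverse: int
    n_in_class: int
    self_revcomp: bool
    target_class: str | None = None

    @property
    def n_total(self) -> int:
        return self.n_forward + self.n_reverse

    @property
    def n_off_class(self) -> int:
        return self.n_total - self.n_in_class

    @property
    def unique_to_class(self) -> bool:
        return self.n_off_class == 0 and self.n_in_class > 0


@dataclass(frozen=True)
class FeasibilityVerdict:
    """Copy-number verdict under the strict >threshold rule."""

    pattern_id: str
    n_total: int
    threshold: int = DEFAULT_FEASIBILITY_THRESHOLD
    verdict: str = "absent"


class KeywordAutomaton:
    """Aho–Corasick automaton over {A,C,G,T}; one pass, all patterns.

    Keys are opaque; several keys may share one pattern string (e.g. a
    pattern and the reverse complement of another).
    """

    def __init__(self, patterns: Mapping[object, str]):
        if not patterns:
            raise ValueError("no patterns supplied")
        self._lengths = {key: len(p) for key, p in patterns.items()}
        goto: list[dict[str, int]] = [{}]
        out: list[list[object]] = [[]]
        for key, pat in patterns.items():
            if not pat:
                raise ValueError(f"empty pattern for key {key!r}")
            node = 0
            for ch in pat:
                nxt = goto[node].get(ch)
                if nxt is None:
                    goto.append({})
                    out.append([])
                    nxt = len(goto) - 1
                    goto[node][ch] = nxt
                node = nxt
            out[node].append(key)
        fail = [0] * len(goto)
        queue: deque[int] = deque()
        for child in goto[0].values():
            queue.append(child)
        while queue:
            node = queue.popleft()
            for ch, child in goto[node].items():
                queue.append(child)
                f = fail[node]
                while f and ch not in goto[f]:
                    f = fail[f]
                fail[child] = goto[f].get(ch, 0) if goto[f].get(ch, 0) != child else 0
                out[child] = out[child] + out[fail[child]]
        self._goto = goto
        self._fail = fail
        self._out = out

    def iter_matches(self, text: str) -> Iterable[tuple[int, object]]:
        """Yield (start, key) for every occurrence, in end-position order."""
        goto, fail, out = self._goto, self._fail, self._out
        lengths = self._lengths
        node = 0
        for end, ch in enumerate(text, start=1):
            while node and ch not in goto[node]:
                node = fail[node]
            node = goto[node].get(ch, 0)
            if out[node]:
                for key in out[node]:
                    yield end - lengths[key], key


def _validate_pattern(pattern_id: str, pattern: str) -> str:
    p = pattern.upper()
    if not p:
        raise ValueError(f"pattern {pattern_id!r} is empty")
    if set(p) - set("ACGT"):
        raise ValueError(f"pattern {pattern_id!r} must be over A,C,G,T")
    return p


def count_matches(
    genome: Genome,
    patterns: Sequence[tuple[str, str]] | Mapping[str, str],
    overlapping: bool = True,
) -> list[Match]:
    """Exact both-strand occurrences of every pattern across the genome.

    With ``overlapping=False``, occurrences are thinned greedily left to
    right per (pattern, strand, sequence) so that kept matches do not
    overlap — an alternative counting convention for tandem arrays.
    """
    items = list(patterns.items()) if isinstance(patterns, Mapping) else list(patterns)
    if not items:
        raise ValueError("no patterns supplied")
    automaton_patterns: dict[tuple[str, str], str] = {}
    for pid, pat in items:
        p = _validate_pattern(pid, pat)
        automaton_patterns[(pid, "+")] = p
        automaton_patterns[(pid, "-")] = revcomp(p)
    automaton = KeywordAutomaton(automaton_patterns)
    lengths = {pid: len(_validate_pattern(pid, pat)) for pid, pat in items}
    matches: list[Match] = []
    for seq_name, seq in genome.records.items():
        found = [
            (start, key[0], key[1])
            for start, key in automaton.iter_matches(seq)
        ]
        found.sort(key=lambda t: (t[0], t[2], t[1]))
        for start, pid, strand in found:
            k = lengths[pid]
            matches.append(
                Match(Interval(seq_name, start, start + k, strand), strand, pid)
            )
    if not overlapping:
        matches = _thin_overlaps(matches)
    return matches


def _thin_overlaps(matches: list[Match]) -> list[Match]:
    last_end: dict[tuple[str, str, str], int] = {}
    kept: list[Match] = []
    for m in matches:
        key = (m.pattern_id, m.strand, m.interval.seq_name)
        if m.interval.start >= last_end.get(key, 0):
            kept.append(m)
            last_end[key] = m.interval.end
    return kept


def classify_specificity(
    matches: Iterable[Match],
    annotations: AnnotationSet,
    target_class: str,
    pattern_id: str,
    pattern: str,
) -> CensusReport:
    """Split one pattern's matches into in-class vs off-class.

    A match is in-class when its interval overlaps >= 1 bp of any interval
    of ``target_class``; the pattern is unique to the class when it has at
    least one in-class match and none off-class.
    """
    if target_class not in annotations.classes:
        raise KeyError(f"unknown class label {target_class!r}")
    pattern = _validate_pattern(pattern_id, pattern)
    trees: dict[str, IntervalTree] = {}
    for iv in annotations.intervals(target_class):
        trees.setdefault(iv.seq_name, IntervalTree()).addi(iv.start, iv.end)
    n_forward = n_reverse = n_in = 0
    for m in matches:
        if m.pattern_id != pattern_id:
            continue
        if m.strand == "+":
            n_forward += 1
        else:
            n_reverse += 1
        tree = trees.get(m.interval.seq_name)
        if tree is not None and tree.overlap(m.interval.start, m.interval.end):
            n_in += 1
    return CensusReport(
        pattern_id=pattern_id,
        pattern=pattern,
        n_forward=n_forward,
        n_reverse=n_reverse,
        n_in_class=n_in,
        self_revcomp=pattern == revcomp(pattern),
        target_class=target_class,
    )


def feasibility(
    report: CensusReport | int,
    threshold: int = DEFAULT_FEASIBILITY_THRESHOLD,
    pattern_id: str | None = None,
) -> FeasibilityVerdict:
    """Copy-number verdict: absent (0), feasible (> threshold), else low_copy."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if isinstance(report, CensusReport):
        n_total, pid = report.n_total, report.pattern_id
    else:
        n_total, pid = int(report), pattern_id or ""
    if n_total == 0:
        verdict = "absent"
    elif n_total > threshold:
        verdict = "feasible"
    else:
        verdict = "low_copy"
    return FeasibilityVerdict(pattern_id=pid, n_total=n_total, threshold=threshold, verdict=verdict)


def census(
    genome: Genome,
    patterns: Sequence[tuple[str, str]] | Mapping[str, str],
    annotations: AnnotationSet | None = None,
    target_class: str | None = None,
    threshold: int = DEFAULT_FEASIBILITY_THRESHOLD,
    overlapping: bool = True,
) -> tuple[list[Match], list[CensusReport], list[FeasibilityVerdict]]:
    """One-call census: matches, per-pattern reports, feasibility verdicts.

    Without annotations, reports carry zero in-class counts and no
    specificity verdict is meaningful (``target_class`` requires
    ``annotations``).
    """
    items = list(patterns.items()) if isinstance(patterns, Mapping) else list(patterns)
    matches = count_matches(genome, items, overlapping=overlapping)
    reports: list[CensusReport] = []
    for pid, pat in items:
        pat = _validate_pattern(pid, pat)
        if annotations is not None and target_class is not None:
            reports.append(classify_specificity(matches, annotations, target_class, pid, pat))
        else:
            mine = [m for m in matches if m.pattern_id == pid]
            reports.append(
                CensusReport(
                    pattern_id=pid,
                    pattern=pat,
                    n_forward=sum(m.strand == "+" for m in mine),
                    n_reverse=sum(m.strand == "-" for m in mine),
                    n_in_class=0,
                    self_revcomp=pat == revcomp(pat),
                )
            )
    verdicts = [feasibility(r, threshold=threshold) for r in reports]
    return matches, reports, verdicts


def matches_to_bed(matches: Iterable[Match]) -> str:
    """Matches as BED6 text (name = pattern id)."""
    lines = []
    for m in matches:
        iv = m.interval
        lines.append(f"{iv.seq_name}\t{iv.start}\t{iv.end}\t{m.pattern_id}\t0\t{m.strand}")
    return "\n".join(lines) + ("\n" if lines else "")


def reports_table(
    reports: Iterable[CensusReport],
    verdicts: Iterable[FeasibilityVerdict] | None = None,
) -> str:
    """Census reports (and optional verdicts) as a TSV table."""
    verdict_of = {v.pattern_id: v.verdict for v in verdicts or []}
    header = (
        "pattern_id\tpattern\tn_forward\tn_reverse\tn_total\tn_in_class\t"
        "n_off_class\tunique_to_class\tself_revcomp"
    )
    if verdict_of:
        header += "\tverdict"
    lines = [header]
    for r in reports:
        row = (
            f"{r.pattern_id}\t{r.pattern}\t{r.n_forward}\t{r.n_reverse}\t{r.n_total}"
            f"\t{r.n_in_class}\t{r.n_off_class}\t{int(r.unique_to_class)}\t{int(r.self_revcomp)}"
        )
        if verdict_of:
            row += f"\t{verdict_of.get(r.pattern_id, '')}"
        lines.append(row)
    return "\n".join(lines) + "\n"
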