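"""Recombination-hazard analysis of assembled TALE coding DNA.

A periodic recognition sequence translates, under a fixed module library,
into a periodic run of identical coding units: an internal direct repeat.
Two identical non-overlapping stretches in a construct can recombine and
delete the intervening DNA, shortening the RVD array and hence the
recognition sequence. For the telomere-repeat target (base period 6,
15 units x 102 bp/unit) the longest such repeat is 6 units = 612 bp, and
the recombinant actually recovered recognized only 8 of the 15 bases.

The deletion model is a single crossover between the two copies of one
direct repeat. An exactly aligned crossover removes ``unit_offset`` units;
+/- ``slippage_units`` of misalignment is allowed by default because the
observed 8-base product is one unit short of the exactly aligned 9-base
outcome. Hazard severity is reported as (repeat length in bp, unit
offset, target base period); no recombination-rate model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .target_design import BASE_OF_RVD, RvdArray, TaleDesign, module_plan

# Repeats shorter than one ~100 bp module unit are ubiquitous in any TALE
# coding sequence and not actionable, hence the default floor.
DEFAULT_MIN_REPEAT_LEN = 100
DEFAULT_SLIPPAGE_UNITS = 1


@dataclass(frozen=True)
class DirectRepeat:
    """Two identical non-overlapping stretches within one coding sequence.

    ``unit_span`` and ``unit_offset`` are filled only when length and copy
    spacing are whole numbers of module units.
    """

    pos_a: int
    pos_b: int
    length: int
    unit_span: int | None = None
    unit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.pos_a + self.length > self.pos_b:
            raise ValueError("direct repeat copies must not overlap")


@dataclass(frozen=True)
class DeletionProduct:
    """One single-crossover recombination outcome."""

    removed_units: int
    crossover_index: int
    surviving_rvds: RvdArray
    recognition: str

    @property
    def recognition_length(self) -> int:
        return len(self.recognition)


def _max_nonoverlapping_repeat_at(coding: str, length: int) -> tuple[int, int] | None:
    """Smallest (pos_a, pos_b) pair of a non-overlapping repeat of ``length``.

    For each distinct substring a valid pair exists iff its occurrence span
    reaches ``length``; the lexicographically smallest pair uses the first
    occurrence and the first occurrence at least ``length`` later.
    """
    n = len(coding)
    if length <= 0 or 2 * length > n:
        return None
    occurrences: dict[str, list[int]] = {}
    for i in range(n - length + 1):
        occurrences.setdefault(coding[i : i + length], []).append(i)
    best: tuple[int, int] | None = None
    for occ in occurrences.values():
        first = occ[0]
        if occ[-1] - first < length:
            continue
        second = next(o for o in occ if o >= first + length)
        if best is None or (first, second) < best:
            best = (first, second)
    return best


def longest_direct_repeat(
    coding: str,
    min_len: int = DEFAULT_MIN_REPEAT_LEN,
    unit_len: int | None = None,
) -> DirectRepeat | None:
    """Maximal-length non-overlapping exact repeated pair, or None.

    Ties at the maximal length are broken by smallest ``pos_a``, then
    smallest ``pos_b``. Returns None when the maximum falls below
    ``min_len``. Non-overlapping repeat existence is monotone in length
    (any repeat's prefix pair is a shorter repeat), so the maximal length
    is found by bisection; agreement with the quadratic brute-force
    oracle is enforced by the test suite.
    """
    if not coding:
        raise ValueError("coding sequence must be non-empty")
    lo, hi = 1, len(coding) // 2  # feasible lengths bracket
    if _max_nonoverlapping_repeat_at(coding, lo) is None:
        return None
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _max_nonoverlapping_repeat_at(coding, mid) is not None:
            lo = mid
        else:
            hi = mid - 1
    if lo < min_len:
        return None
    pos_a, pos_b = _max_nonoverlapping_repeat_at(coding, lo)  # type: ignore[misc]
    unit_span = unit_offset = None
    if unit_len:
        if lo % unit_len == 0:
            unit_span = lo // unit_len
        if (pos_b - pos_a) % unit_len == 0:
            unit_offset = (pos_b - pos_a) // unit_len
    return DirectRepeat(pos_a=pos_a, pos_b=pos_b, length=lo, unit_span=unit_span, unit_offset=unit_offset)


def target_period(target: str) -> int:
    """Smallest p >= 1 with target[i] == target[i+p] for all valid i.

    Equals the target length for aperiodic sequences. This is the driver
    of the coding-level hazard: base period p yields identical module
    units p apart.
    """
    if not target:
        raise ValueError("target must be non-empty")
    n = len(target)
    for p in range(1, n):
        if all(target[i] == target[i + p] for i in range(n - p)):
            return p
    return n


def scan_design(
    design: TaleDesign,
    min_len: int = DEFAULT_MIN_REPEAT_LEN,
) -> DirectRepeat | None:
    """Longest direct repeat in a design's coding DNA, in unit terms."""
    return longest_direct_repeat(design.coding, min_len=min_len, unit_len=design.unit_len)


def predict_deletion_products(
    design: TaleDesign,
    hazard: DirectRepeat,
    slippage_units: int = DEFAULT_SLIPPAGE_UNITS,
) -> list[DeletionProduct]:
    """Enumerate single-crossover deletion products of a whole-unit repeat.

    Removes m units for every m in
    ``[unit_offset - slippage_units, unit_offset + slippage_units]``
    intersected with ``[1, n_units - 1]``, at every crossover index
    ``i in [0, n_units - m]``; survivors are units ``1..i`` followed by
    units ``i+m+1..n``. Products with identical recognition sequences are
    deduplicated (first occurrence kept) and ordered by recognition length
    descending, then lexicographically.
    """
    if hazard.unit_offset is None:
        raise ValueError(
            "hazard is not a whole-unit repeat; base-pair-level crossover "
            "prediction is unsupported"
        )
    if slippage_units < 0:
        raise ValueError("slippage_units must be non-negative")
    n = design.n_units
    off = hazard.unit_offset
    seen: dict[str, DeletionProduct] = {}
    for m in range(max(1, off - slippage_units), min(n - 1, off + slippage_units) + 1):
        for i in range(0, n - m + 1):
            surviving = design.rvds.rvds[:i] + design.rvds.rvds[i + m :]
            recognition = "".join(BASE_OF_RVD[c] for c in surviving)
            if recognition in seen:
                continue
            try:
                plan = module_plan(len(surviving))
            except ValueError:
                plan = None
            seen[recognition] = DeletionProduct(
                removed_units=m,
                crossover_index=i,
                surviving_rvds=RvdArray(surviving, plan),
                recognition=recognition,
            )
    return sorted(seen.values(), key=lambda p: (-p.recognition_length, p.recognition))


def hazard_report(
    design: TaleDesign,
    min_len: int = DEFAULT_MIN_REPEAT_LEN,
    slippage_units: int = DEFAULT_SLIPPAGE_UNITS,
) -> dict:
    """JSON-ready hazard summary for one design."""
    repeat = scan_design(design, min_len=min_len)
    period = target_period(design.target.sequence)
    report = {
        "target": design.target.sequence,
        "target_period": period,
        "n_units": design.n_units,
        "unit_len": design.unit_len,
        "longest_direct_repeat_bp": repeat.length if repeat else 0,
        "unit_span": repeat.unit_span if repeat else None,
        "unit_offset": repeat.unit_offset if repeat else None,
        "pos_a": repeat.pos_a if repeat else None,
        "pos_b": repeat.pos_b if repeat else None,
        "products": [],
    }
    if repeat is not None and repeat.unit_offset is not None:
        products = predict_deletion_products(design, repeat, slippage_units=slippage_units)
        report["products"] = [
            {
                "removed_units": p.removed_units,
                "crossover_index": p.crossover_index,
                "recognition": p.recognition,
                "recognition_length": p.recognition_length,
            }
            for p in products
        ]
    return report
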