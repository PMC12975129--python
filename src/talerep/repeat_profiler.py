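"""Windowed ChIP enrichment over repeat classes.

The genome is divided into fixed windows (50 bp tiled by default; a
smaller step gives sliding windows for overview tracks). Each window is
annotated with every repeat class it overlaps by >= 1 bp; windows
overlapping nothing are "background", and windows carrying more than one
class are excluded from both background and per-class statistics (they
are reported separately), so that e.g. telomere-adjacent satellite
windows do not contaminate either class.

Per-window enrichment is log2(IP/Input) after scaling both tracks to
counts per million (CPM), with a pseudocount (default 1 CPM) added to
numerator and denominator so zero-coverage windows stay finite. When a
No-tag control track is supplied, its log2 ratio is subtracted windowwise
from each sample's to remove tag-independent background signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .sequence_io import AnnotationSet, Genome, Interval

DEFAULT_WINDOW_WIDTH = 50
DEFAULT_PSEUDOCOUNT_CPM = 1.0

BACKGROUND_LABEL = "background"
MULTI_CLASS_LABEL = "multi_class"

_SUMMARY_QUANTILES = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class WindowGrid:
    """Fixed windows per sequence, anchored at coordinate 0, half-open.

    The terminal window of each sequence may be partial (shorter than
    ``width``); it is kept and flagged.
    """

    intervals: list[Interval]
    width: int
    step: int
    seq_lengths: dict[str, int]

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def partial(self) -> np.ndarray:
        return np.array([iv.length < self.width for iv in self.intervals])

    def compatible_with(self, other: "WindowGrid") -> bool:
        return (
            self.width == other.width
            and self.step == other.step
            and self.seq_lengths == other.seq_lengths
        )


@dataclass
class CoverageTrack:
    """Per-window read counts for one sample on a fixed window grid."""

    sample_id: str
    values: np.ndarray
    window_width: int
    total_reads: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError(f"track {self.sample_id!r} has negative counts")
        if self.total_reads is None:
            self.total_reads = float(self.values.sum())
        if self.total_reads <= 0:
            raise ValueError(f"track {self.sample_id!r} has no reads")

    def cpm(self) -> np.ndarray:
        return self.values / self.total_reads * 1e6


def window_genome(
    genome: Genome,
    width: int = DEFAULT_WINDOW_WIDTH,
    step: int | None = None,
) -> WindowGrid:
    """Tile (step = width) or slide (step < width) windows over each sequence."""
    if width < 1:
        raise ValueError("window width must be >= 1")
    step = width if step is None else step
    if not (1 <= step <= width):
        raise ValueError("step must satisfy 1 <= step <= width")
    intervals: list[Interval] = []
    for name, length in genome.lengths.items():
        if width > length:
            warnings.warn(
                f"window width {width} exceeds length {length} of {name!r}; "
                "emitting a single partial window"
            )
        start = 0
        while start < length:
            intervals.append(Interval(name, start, min(start + width, length)))
            if start + width >= length:
                break
            start += step
    return WindowGrid(intervals=intervals, width=width, step=step, seq_lengths=genome.lengths)


def annotate_windows(
    grid: WindowGrid, annotations: AnnotationSet
) -> list[frozenset[str]]:
    """Class-label set per window; >= 1 bp overlap assigns the class.

    Empty set means background; multi-label windows are excluded from both
    per-class and background summaries downstream.
    """
    trees: dict[str, IntervalTree] = {}
    for label, iv in annotations.all_intervals():
        trees.setdefault(iv.seq_name, IntervalTree()).addi(iv.start, iv.end, label)
    out: list[frozenset[str]] = []
    for w in grid.intervals:
        tree = trees.get(w.seq_name)
        if tree is None:
            out.append(frozenset())
            continue
        out.append(frozenset(hit.data for hit in tree.overlap(w.start, w.end)))
    return out


def enrichment(
    ip: CoverageTrack,
    input_: CoverageTrack,
    pseudocount_cpm: float = DEFAULT_PSEUDOCOUNT_CPM,
) -> np.ndarray:
    """Per-window log2((IP_cpm + c)/(Input_cpm + c)); finite by construction."""
    if len(ip.values) != len(input_.values) or ip.window_width != input_.window_width:
        raise ValueError("IP and Input tracks are on different window grids")
    c = float(pseudocount_cpm)
    if c <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log2((ip.cpm() + c) / (input_.cpm() + c))


def normalize_to_control(
    sample_log2: np.ndarray, notag_log2: np.ndarray
) -> np.ndarray:
    """Windowwise subtraction of the No-tag control's log2 ratio."""
    sample_log2 = np.asarray(sample_log2, dtype=float)
    notag_log2 = np.asarray(notag_log2, dtype=float)
    if sample_log2.shape != notag_log2.shape:
        raise ValueError("sample and No-tag tracks are on different window grids")
    return sample_log2 - notag_log2


def class_summary(
    grid: WindowGrid,
    window_classes: Sequence[frozenset[str]],
    values: np.ndarray,
) -> pd.DataFrame:
    """Per-class summary of (normalized) enrichment values.

    Single-class windows feed their class; empty-set windows feed the
    background row; multi-class windows are counted but excluded from all
    statistics. ``delta`` is class median minus background median. Classes
    with zero single-class windows are omitted with a warning. Window
    accounting totals are attached as ``DataFrame.attrs``.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(grid) or len(window_classes) != len(grid):
        raise ValueError("values/classes do not match the window grid")
    buckets: dict[str, list[float]] = {BACKGROUND_LABEL: []}
    n_multi = 0
    for classes, v in zip(window_classes, values):
        if len(classes) == 0:
            buckets[BACKGROUND_LABEL].append(v)
        elif len(classes) == 1:
            buckets.setdefault(next(iter(classes)), []).append(v)
        else:
            n_multi += 1
    seen_labels = set().union(*window_classes) if window_classes else set()
    for label in sorted(seen_labels):
        if label not in buckets:
            warnings.warn(f"class {label!r} has no single-class windows; omitted")
    bg = np.array(buckets[BACKGROUND_LABEL], dtype=float)
    bg_median = float(np.median(bg)) if bg.size else float("nan")
    rows = []
    for label, vals in buckets.items():
        arr = np.array(vals, dtype=float)
        if arr.size == 0:
            continue
        row = {
            "class_label": label,
            "n_windows": int(arr.size),
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "delta": float(np.median(arr) - bg_median),
        }
        for q in _SUMMARY_QUANTILES:
            row[f"q{int(q * 100):02d}"] = float(np.quantile(arr, q))
        rows.append(row)
    columns = ["class_label", "n_windows", "mean", "median", "sd", "delta"] + [
        f"q{int(q * 100):02d}" for q in _SUMMARY_QUANTILES
    ]
    df = pd.DataFrame(rows, columns=columns)
    # stable order: background first, then class labels alphabetically
    if not df.empty:
        df["_key"] = (df["class_label"] != BACKGROUND_LABEL).astype(int)
        df = df.sort_values(["_key", "class_label"]).drop(columns="_key").reset_index(drop=True)
    df.attrs["n_windows_total"] = len(grid)
    df.attrs["n_background"] = len(buckets[BACKGROUND_LABEL])
    df.attrs["n_multi_class"] = n_multi
    df.attrs["n_single_class"] = len(grid) - n_multi - len(buckets[BACKGROUND_LABEL])
    return df


def profile(
    genome: Genome,
    annotations: AnnotationSet,
    ip: CoverageTrack,
    input_: CoverageTrack,
    notag_ip: CoverageTrack | None = None,
    notag_input: CoverageTrack | None = None,
    width: int = DEFAULT_WINDOW_WIDTH,
    step: int | None = None,
    pseudocount_cpm: float = DEFAULT_PSEUDOCOUNT_CPM,
) -> tuple[WindowGrid, pd.DataFrame, pd.DataFrame]:
    """Full pipeline: windows, annotation, enrichment, control normalization,
    per-class summaries.

    ``notag_ip`` (with ``notag_input``, defaulting to the sample's input)
    supplies the No-tag control; without it the raw log2 ratio is summarized
    and no ``normalized`` column is emitted.
    """
    grid = window_genome(genome, width=width, step=step)
    classes = annotate_windows(grid, annotations)
    log2_ratio = enrichment(ip, input_, pseudocount_cpm=pseudocount_cpm)
    per_window = pd.DataFrame(
        {
            "seq_name": [w.seq_name for w in grid.intervals],
            "start": [w.start for w in grid.intervals],
            "end": [w.end for w in grid.intervals],
            "classes": [",".join(sorted(c)) for c in classes],
            "log2_ratio": log2_ratio,
        }
    )
    if notag_ip is not None:
        notag_ratio = enrichment(
            notag_ip, notag_input or input_, pseudocount_cpm=pseudocount_cpm
        )
        per_window["normalized"] = normalize_to_control(log2_ratio, notag_ratio)
        summary_values = per_window["normalized"].to_numpy()
    else:
        summary_values = log2_ratio
    summary = class_summary(grid, classes, summary_values)
    return grid, per_window, summary


# ---------------------------------------------------------------------------
# bedGraph / wiggle coverage I/O
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, grid: WindowGrid, sample_id: str | None = None) -> CoverageTrack:
    """Aggregate a 4-column bedGraph (or fixedStep wiggle) onto a window grid.

    Each region's value is distributed to overlapping windows in
    proportion to overlap, so window-aligned files round-trip exactly.
    """
    path = Path(path)
    index: dict[str, list[int]] = {}
    for i, w in enumerate(grid.intervals):
        index.setdefault(w.seq_name, []).append(i)
    values = np.zeros(len(grid))
    starts = {name: [grid.intervals[i].start for i in idx] for name, idx in index.items()}
    with open(path) as fh:
        fixed_chrom, fixed_pos, fixed_span = None, 0, 1
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=") for p in line.split()[1:])
                fixed_chrom = kv["chrom"]
                fixed_pos = int(kv["start"]) - 1  # wiggle is 1-based
                fixed_span = int(kv.get("span", kv.get("step", 1)))
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) == 1 and fixed_chrom is not None:
                chrom, start, end, value = fixed_chrom, fixed_pos, fixed_pos + fixed_span, float(cols[0])
                fixed_pos += fixed_span
            elif len(cols) >= 4:
                chrom, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            else:
                raise ValueError(f"{path.name} line {lineno}: malformed coverage line")
            if chrom not in index or value == 0:
                continue
            _spread(values, index[chrom], starts[chrom], grid, start, end, value)
    return CoverageTrack(
        sample_id=sample_id or path.stem, values=values, window_width=grid.width
    )


def _spread(
    values: np.ndarray,
    window_idx: list[int],
    window_starts: list[int],
    grid: WindowGrid,
    start: int,
    end: int,
    value: float,
) -> None:
    import bisect

    region_len = end - start
    # any window starting after start - width + 1 may still overlap the region
    j = bisect.bisect_left(window_starts, start - grid.width + 1)
    j = max(j, 0)
    while j < len(window_idx):
        w = grid.intervals[window_idx[j]]
        if w.start >= end:
            break
        overlap = min(w.end, end) - max(w.start, start)
        if overlap > 0:
            values[window_idx[j]] += value * overlap / region_len
        j += 1


def write_bedgraph(
    grid: WindowGrid, values: np.ndarray, path: str | Path, precision: int = 6
) -> None:
    """Write one value per window as 4-column bedGraph (deterministic order)."""
    values = np.asarray(values)
    if len(values) != len(grid):
        raise ValueError("values do not match the window grid")
    with open(path, "w") as fh:
        for w, v in zip(grid.intervals, values):
            fh.write(f"{w.seq_name}\t{w.start}\t{w.end}\t{round(float(v), precision):g}\n")
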