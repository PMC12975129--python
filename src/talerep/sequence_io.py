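"""Genome and annotation I/O plus coordinate/strand primitives.

All internal coordinates are 0-based half-open; BED is the native annotation
dialect and GFF3 (1-based, closed) is converted on read and back on write.
Sequences are normalized to uppercase over the alphabet {A, C, G, T, N};
soft-masked (lowercase) bases are uppercased and retained, since the
exact-match census ignores masking. N never matches any pattern base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""


def normalize_sequence(seq: str, *, name: str = "sequence") -> str:
    """Uppercase, map U->T, and validate against {A,C,G,T,N}.

    Raises :class:`SequenceAlphabetError` naming the 0-based position of the
    first offending character.
    """
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        pos = next(i for i, c in enumerate(s) if c in bad)
        raise SequenceAlphabetError(
            f"invalid character {s[pos]!r} at position {pos} in {name}"
        )
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}; N maps to N."""
    s = seq.upper()
    bad = set(s) - VALID_BASES
    if bad:
        raise SequenceAlphabetError(f"invalid character {sorted(bad)[0]!r} in sequence")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Named DNA sequences; the census and simulation substrate.

    ``records`` is an ordered mapping of sequence name to normalized DNA
    string. Construction validates the alphabet; lengths are derived, never
    stored separately, so they cannot disagree with the strings.
    """

    records: dict[str, str]

    def __post_init__(self) -> None:
        normalized: dict[str, str] = {}
        for name, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence record {name!r}")
            normalized[name] = normalize_sequence(seq, name=f"record {name!r}")
        self.records = normalized

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    @property
    def names(self) -> list[str]:
        return list(self.records)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def fetch(self, interval: "Interval") -> str:
        """Sequence under ``interval`` on the forward axis (strand-aware)."""
        seq = self.records[interval.seq_name][interval.start : interval.end]
        return revcomp(seq) if interval.strand == "-" else seq


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with optional strand."""

    seq_name: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_name}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        """True when the two intervals share >= 1 bp on the same sequence."""
        return (
            self.seq_name == other.seq_name
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self) -> tuple[str, int, int]:
        return (self.seq_name, self.start, self.end)


@dataclass
class AnnotationSet:
    """Labeled intervals per repeat family plus optional per-family consensus.

    Intervals within a class are kept sorted by (seq_name, start); the
    ``tandem`` flag marks classes whose consensus forms unbounded tandem
    arrays (satellites, telomere repeats) as opposed to dispersed elements.
    """

    classes: dict[str, list[Interval]]
    consensus: dict[str, str] = field(default_factory=dict)
    tandem: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, ivs in self.classes.items():
            self.classes[label] = sorted(ivs, key=Interval.sort_key)
        for label, seq in self.consensus.items():
            self.consensus[label] = normalize_sequence(
                seq, name=f"consensus of class {label!r}"
            )

    @property
    def class_labels(self) -> list[str]:
        return list(self.classes)

    def intervals(self, label: str) -> list[Interval]:
        if label not in self.classes:
            raise KeyError(f"unknown class label {label!r}")
        return self.classes[label]

    def all_intervals(self) -> Iterator[tuple[str, Interval]]:
        for label, ivs in self.classes.items():
            for iv in ivs:
                yield label, iv

    def validate_against(self, genome: Genome) -> None:
        """Raise if any interval falls outside its genome sequence."""
        lengths = genome.lengths
        for label, iv in self.all_intervals():
            if iv.seq_name not in lengths:
                raise ValueError(
                    f"class {label!r}: interval on unknown sequence {iv.seq_name!r}"
                )
            if iv.end > lengths[iv.seq_name]:
                raise ValueError(
                    f"class {label!r}: interval [{iv.start}, {iv.end}) exceeds "
                    f"length {lengths[iv.seq_name]} of {iv.seq_name!r}"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    """Read a (possibly wrapped) multi-record FASTA into a Genome.

    Duplicate headers, empty records and non-nucleotide characters are
    errors; lowercase and U are normalized.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(records)


def write_fasta(genome: Genome, path: str | Path, line_width: int = 60) -> None:
    """Write a Genome as wrapped FASTA in record order (deterministic)."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# BED / GFF3 annotations
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int) -> tuple[str, Interval]:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 4:
        raise ValueError(f"BED line {lineno}: expected >= 4 columns, got {len(cols)}")
    try:
        start, end = int(cols[1]), int(cols[2])
    except ValueError as exc:
        raise ValueError(f"BED line {lineno}: non-integer coordinate") from exc
    if start >= end:
        raise ValueError(f"BED line {lineno}: start {start} >= end {end}")
    strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "."
    return cols[3], Interval(cols[0], start, end, strand)


_GFF_SKIP = ("#", "track", "browser")


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def _parse_gff_line(line: str, lineno: int) -> tuple[str, Interval]:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 9:
        raise ValueError(f"GFF line {lineno}: expected 9 columns, got {len(cols)}")
    try:
        start1, end1 = int(cols[3]), int(cols[4])
    except ValueError as exc:
        raise ValueError(f"GFF line {lineno}: non-integer coordinate") from exc
    if start1 < 1 or end1 < start1:
        raise ValueError(f"GFF line {lineno}: invalid 1-based range {start1}..{end1}")
    label = _gff_attr(cols[8], "Name") or _gff_attr(cols[8], "ID") or cols[2]
    strand = cols[6] if cols[6] in ("+", "-") else "."
    # GFF is 1-based closed; internal coordinates are 0-based half-open.
    return label, Interval(cols[0], start1 - 1, end1, strand)


def read_annotations(path: str | Path, format: str | None = None) -> AnnotationSet:
    """Read BED4/BED6 or GFF3 repeat-class annotations.

    The class label is BED column 4, or the GFF3 ``Name``/``ID`` attribute
    (falling back to the feature type). Malformed lines raise with their
    line number. The format is inferred from the suffix when not given.
    """
    path = Path(path)
    if format is None:
        format = "GFF" if path.suffix.lower() in (".gff", ".gff3") else "BED"
    format = format.upper()
    if format not in ("BED", "GFF"):
        raise ValueError(f"unsupported annotation format {format!r}")
    parse = _parse_bed_line if format == "BED" else _parse_gff_line
    classes: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(_GFF_SKIP):
                continue
            label, iv = parse(line, lineno)
            classes.setdefault(label, []).append(iv)
    return AnnotationSet(classes)


def write_bed(annotations: AnnotationSet, path: str | Path) -> None:
    """Write as BED6 (score 0), classes in insertion order, intervals sorted."""
    with open(path, "w") as fh:
        for label, iv in annotations.all_intervals():
            fh.write(f"{iv.seq_name}\t{iv.start}\t{iv.end}\t{label}\t0\t{iv.strand}\n")


def write_gff3(annotations: AnnotationSet, path: str | Path, source: str = "talerep") -> None:
    """Write as GFF3 ``repeat_region`` features with Name=<class label>."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for label, iv in annotations.all_intervals():
            fh.write(
                f"{iv.seq_name}\t{source}\trepeat_region\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{iv.strand}\t.\tName={label}\n"
            )
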