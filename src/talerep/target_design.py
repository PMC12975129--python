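"""TALE target enumeration, RVD design and coding-sequence assembly.

A TALE recognizes one DNA base per ~34-residue repeat through its
repeat-variable diresidue (RVD); the standard cipher is A->NI, C->HD,
G->NN, T->NG, and binding additionally requires a thymine (the T0 base)
immediately 5' of the recognition sequence. Candidate targets inside a
repeat consensus are therefore the k-mers whose preceding base is T; for
tandemly repeated consensus units the scan runs over the circularized
unit so that targets spanning unit junctions (such as the 2.5-unit
telomeric target) are found.

Arrays are assembled from pre-made tetramer and trimer RVD blocks, so a
module plan packs the array into blocks of 4 with trailing blocks of 3.
The shipped idealized module library assigns each RVD one fixed 102 bp
coding unit (34 codons, no silent variation), which makes the
recombination-hazard analysis of assembled coding DNA deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .sequence_io import normalize_sequence

RVD_OF_BASE: dict[str, str] = {"A": "NI", "C": "HD", "G": "NN", "T": "NG"}
BASE_OF_RVD: dict[str, str] = {v: k for k, v in RVD_OF_BASE.items()}
RVD_CODES = ("NI", "HD", "NN", "NG")

DEFAULT_TARGET_LENGTH = 15


@dataclass(frozen=True)
class TaleTarget:
    """A candidate recognition sequence with its T0 context.

    ``rotation_offset`` is the 0-based start of the target within the
    consensus unit; ``junction_spanning`` marks targets that wrap across a
    tandem-unit boundary (k longer than the remainder of the unit).
    """

    sequence: str
    t0_context: str = "T"
    source_class: str | None = None
    junction_spanning: bool = False
    rotation_offset: int = 0

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence, name="target sequence")
        if "N" in seq:
            raise ValueError("target sequence must not contain N")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RvdArray:
    """Ordered RVD codes plus the tetramer/trimer assembly plan.

    ``module_plan`` is None for arrays that no {4,3} block packing can
    realise (these arise only as predicted recombination products, never
    as designed arrays).
    """

    rvds: tuple[str, ...]
    module_plan: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        for code in self.rvds:
            if code not in BASE_OF_RVD:
                raise ValueError(f"unknown RVD code {code!r}")
        if self.module_plan is not None:
            if any(b not in (4, 3) for b in self.module_plan):
                raise ValueError("module plan blocks must be 4 or 3")
            if sum(self.module_plan) != len(self.rvds):
                raise ValueError("module plan does not sum to array length")

    def __len__(self) -> int:
        return len(self.rvds)

    def decode(self) -> str:
        """Recognition sequence read back through the inverse cipher."""
        return "".join(BASE_OF_RVD[c] for c in self.rvds)


@dataclass(frozen=True)
class ModuleLibrary:
    """RVD code -> fixed-length coding DNA unit."""

    unit_coding: Mapping[str, str]
    library_id: str = "custom"

    def __post_init__(self) -> None:
        missing = set(RVD_CODES) - set(self.unit_coding)
        if missing:
            raise ValueError(f"module library missing RVD codes: {sorted(missing)}")
        lengths = {len(s) for s in self.unit_coding.values()}
        if len(lengths) != 1:
            raise ValueError("all module units must have identical length")
        object.__setattr__(self, "unit_coding", dict(self.unit_coding))

    @property
    def unit_len(self) -> int:
        return len(next(iter(self.unit_coding.values())))


@dataclass(frozen=True)
class TaleDesign:
    """A designed TALE: target, RVD array, and assembled repeat-region DNA."""

    target: TaleTarget
    rvds: RvdArray
    coding: str
    library_id: str

    @property
    def n_units(self) -> int:
        return len(self.rvds)

    @property
    def unit_len(self) -> int:
        return len(self.coding) // len(self.rvds) if self.rvds.rvds else 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "target": self.target.sequence,
                "source_class": self.target.source_class,
                "rvds": list(self.rvds.rvds),
                "module_plan": list(self.rvds.module_plan or []) or None,
                "coding": self.coding,
                "library_id": self.library_id,
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "TaleDesign":
        d = json.loads(text)
        plan = tuple(d["module_plan"]) if d.get("module_plan") else None
        return TaleDesign(
            target=TaleTarget(d["target"], source_class=d.get("source_class")),
            rvds=RvdArray(tuple(d["rvds"]), plan),
            coding=d["coding"],
            library_id=d.get("library_id", "custom"),
        )


# ---------------------------------------------------------------------------
# Idealized module library
# ---------------------------------------------------------------------------
# One fixed 34-codon TALE repeat per RVD: a common scaffold (codons 1-11 and
# 14-34) around the RVD dicodon (codons 12-13). Fixed codon usage per amino
# acid; no silent variation, so identical RVDs always yield identical units.
_SCAFFOLD_PREFIX = (  # L T P E Q V V A I A S  (codons 1-11, 33 bp)
    "CTGACCCCGGAACAGGTGGTGGCCATTGCCAGC"
)
_SCAFFOLD_SUFFIX = (  # G G K Q A L E T V Q R L L P V L C Q A H G (codons 14-34, 63 bp)
    "GGCGGCAAACAGGCCCTGGAAACCGTGCAGCGTCTGCTGCCGGTGCTGTGCCAGGCCCATGGC"
)
_RVD_DICODON = {
    "NI": "AATATT",  # Asn-Ile
    "HD": "CATGAT",  # His-Asp
    "NN": "AACAAT",  # Asn-Asn
    "NG": "AATGGT",  # Asn-Gly
}

IDEALIZED_UNIT_LEN = 102


def idealized_library() -> ModuleLibrary:
    """The shipped idealized library: 102 bp per RVD unit, fixed codons."""
    units = {
        code: _SCAFFOLD_PREFIX + dicodon + _SCAFFOLD_SUFFIX
        for code, dicodon in _RVD_DICODON.items()
    }
    return ModuleLibrary(units, library_id="idealized-102")


def read_module_library(path: str | Path, library_id: str | None = None) -> ModuleLibrary:
    """Read a module library from FASTA (record name = RVD code) or 2-col TSV."""
    path = Path(path)
    units: dict[str, str] = {}
    text = path.read_text()
    if text.lstrip().startswith(">"):
        name = None
        for line in text.splitlines():
            if line.startswith(">"):
                name = line[1:].split()[0]
                units[name] = ""
            elif name is not None:
                units[name] += line.strip()
    else:
        for line in text.splitlines():
            if not line.strip():
                continue
            code, seq = line.split("\t")[:2]
            units[code] = seq
    units = {c: normalize_sequence(s, name=f"unit {c}") for c, s in units.items()}
    return ModuleLibrary(units, library_id=library_id or path.stem)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def enumerate_targets(
    consensus: str,
    tandem: bool,
    k: int = DEFAULT_TARGET_LENGTH,
    source_class: str | None = None,
) -> list[TaleTarget]:
    """Enumerate candidate k-mer targets whose immediately 5' base is T.

    Tandem mode reads candidates from the circularized (unbounded) tandem
    array of the consensus unit and emits exactly one candidate per
    distinct rotation offset in ``[0, unit_length)``; duplicate sequences
    from different offsets are all emitted. Linear mode scans the consensus
    as given (position 0 has no T0 context and is never a candidate).
    """
    if k <= 0:
        raise ValueError(f"target length k must be positive, got {k}")
    unit = normalize_sequence(consensus, name="consensus")
    if not unit:
        raise ValueError("consensus must be non-empty")
    if "N" in unit:
        raise ValueError("consensus must not contain N")
    out: list[TaleTarget] = []
    L = len(unit)
    if tandem:
        # Unbounded array: every rotation exists; wrap both the T0 lookup
        # and the k-mer read-out.
        tiled = unit * (k // L + 2)
        for off in range(L):
            if unit[(off - 1) % L] != "T":
                continue
            out.append(
                TaleTarget(
                    sequence=tiled[off : off + k],
                    source_class=source_class,
                    junction_spanning=k > L - off,
                    rotation_offset=off,
                )
            )
    else:
        for off in range(1, L - k + 1):
            if unit[off - 1] != "T":
                continue
            out.append(
                TaleTarget(
                    sequence=unit[off : off + k],
                    source_class=source_class,
                    junction_spanning=False,
                    rotation_offset=off,
                )
            )
    return out


def module_plan(n: int) -> tuple[int, ...]:
    """Pack ``n`` RVDs into tetramer blocks plus trailing trimers.

    Maximizes the number of tetramers; lengths with no {4,3} packing
    (1, 2 and 5) are an error.
    """
    if n <= 0:
        raise ValueError(f"cannot plan modules for length {n}")
    a = n // 4
    while a >= 0 and (n - 4 * a) % 3 != 0:
        a -= 1
    if a < 0:
        raise ValueError(f"no tetramer/trimer packing exists for length {n}")
    b = (n - 4 * a) // 3
    return (4,) * a + (3,) * b


def design_rvds(target: TaleTarget | str) -> RvdArray:
    """Translate a target into its RVD array via the standard cipher."""
    seq = target.sequence if isinstance(target, TaleTarget) else target
    seq = normalize_sequence(seq, name="target")
    if "N" in seq:
        raise ValueError("cannot design RVDs for a target containing N")
    rvds = tuple(RVD_OF_BASE[b] for b in seq)
    return RvdArray(rvds, module_plan(len(rvds)))


def assemble_coding(rvds: RvdArray, library: ModuleLibrary) -> str:
    """Concatenate the library's coding unit for each RVD in array order."""
    return "".join(library.unit_coding[c] for c in rvds.rvds)


def decode_coding(coding: str, library: ModuleLibrary) -> str:
    """Read a coding sequence back to its recognition sequence.

    Inverse of :func:`assemble_coding` under the library; errors on
    lengths that are not whole units or on units absent from the library.
    """
    unit_len = library.unit_len
    if len(coding) % unit_len != 0:
        raise ValueError(
            f"coding length {len(coding)} is not a multiple of unit length {unit_len}"
        )
    inverse = {seq: code for code, seq in library.unit_coding.items()}
    bases = []
    for i in range(0, len(coding), unit_len):
        unit = coding[i : i + unit_len]
        if unit not in inverse:
            raise ValueError(f"unit at offset {i} not found in library")
        bases.append(BASE_OF_RVD[inverse[unit]])
    return "".join(bases)


def design_tale(
    target: TaleTarget | str,
    library: ModuleLibrary | None = None,
) -> TaleDesign:
    """Full design: cipher translation, module plan, and coding assembly."""
    if isinstance(target, str):
        target = TaleTarget(target)
    library = library or idealized_library()
    rvds = design_rvds(target)
    coding = assemble_coding(rvds, library)
    return TaleDesign(target=target, rvds=rvds, coding=coding, library_id=library.library_id)


def candidates_table(candidates: Iterable[TaleTarget]) -> str:
    """Candidate list as TSV (sequence, rotation offset, junction flag)."""
    lines = ["sequence\trotation_offset\tjunction_spanning\tsource_class"]
    for c in candidates:
        lines.append(
            f"{c.sequence}\t{c.rotation_offset}\t{int(c.junction_spanning)}\t{c.source_class or ''}"
        )
    return "\n".join(lines) + "\n"
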