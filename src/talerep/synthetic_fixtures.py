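"""Seeded synthetic genomes, coverage tracks and intensity matrices.

The genome generator emulates the repeat landscape of a trypanosome-like
nuclear genome: chromosomes terminated by (TTAGGG)n telomere arrays,
chromosome-internal satellite arrays (147 bp- and 177 bp-like), short
subtelomeric repeat tracts (70 bp-like) and dispersed retroelement
copies, embedded in random background sequence. Arrays are exact tandem
copies by default (an optional per-unit substitution rate degrades them
to probe census robustness), and the planted ground truth for any query
pattern is recorded at build time by a naive scan of the constructed
sequence — so the truth is computed independently of the census
implementation it later validates.

Coverage simulation draws per-window read counts (Poisson or negative
binomial) around ``depth``, multiplied by a per-class fold for IP
windows only; Input and No-tag tracks use fold 1 everywhere. Intensity
simulation draws lognormal label-free intensities with bait-specific
fold effects and intensity-dependent missingness.

All generators are pure functions of (spec, seed); seeds are explicit
arguments, never global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .apms_enrichment import IntensityMatrix
from .repeat_profiler import CoverageTrack, WindowGrid, annotate_windows, window_genome
from .sequence_io import AnnotationSet, Genome, Interval, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TELOMERE_UNIT = "TTAGGG"

PLACEMENTS = ("terminal", "internal", "dispersed")
_CONDITION_STREAM = {"ip": 0, "input": 1, "notag": 2}


@dataclass(frozen=True)
class ArrayPlan:
    """One repeat family's placement plan.

    Tandem classes embed ``n_arrays`` arrays of ``units_per_array`` exact
    consensus copies; dispersed classes embed ``n_arrays`` single copies.
    """

    class_label: str
    consensus: str
    tandem: bool
    n_arrays: int
    units_per_array: int = 1
    placement: str = "internal"
    substitution_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.n_arrays < 1 or self.units_per_array < 1:
            raise ValueError("n_arrays and units_per_array must be >= 1")
        if not (0.0 <= self.substitution_rate < 1.0):
            raise ValueError("substitution_rate must be in [0, 1)")

    @property
    def array_length(self) -> int:
        n_units = self.units_per_array if self.tandem else 1
        return len(self.consensus) * n_units


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint for one synthetic genome with known planted truth."""

    chromosome_lengths: Mapping[str, int]
    plans: Sequence[ArrayPlan]
    seed: int
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    query_patterns: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")


@dataclass(frozen=True)
class CoverageSpec:
    """Blueprint for simulated per-window coverage."""

    depth: float
    fold: Mapping[str, float] = field(default_factory=dict)
    noise: str = "poisson"
    dispersion: float = 10.0
    window_width: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if any(f <= 0 for f in self.fold.values()):
            raise ValueError("folds must be positive")
        if self.noise not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def _random_background(length: int, composition: Sequence[float], rng: np.random.Generator) -> bytearray:
    idx = rng.choice(4, size=length, p=list(composition))
    return bytearray(_BASES[idx].tobytes())


def _array_sequence(plan: ArrayPlan, rng: np.random.Generator) -> str:
    if plan.tandem:
        seq = plan.consensus * plan.units_per_array
    else:
        seq = plan.consensus
    if plan.substitution_rate > 0:
        arr = bytearray(seq.encode())
        hits = np.flatnonzero(rng.random(len(arr)) < plan.substitution_rate)
        for i in hits:
            current = chr(arr[i])
            choices = [b for b in "ACGT" if b != current]
            arr[i] = ord(choices[rng.integers(3)])
        seq = arr.decode()
    return seq


def _count_occurrences(haystack: str, needle: str) -> int:
    """Overlapping occurrence count by repeated ``str.find`` (naive truth scan)."""
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def make_genome(spec: GenomeSpec) -> tuple[Genome, AnnotationSet, dict[str, dict[str, int]]]:
    """Build the genome, its truth annotations, and planted pattern counts.

    Arrays are placed terminal (flush at alternating chromosome ends),
    internal (central 60% of a chromosome) or dispersed (anywhere), never
    overlapping and separated by >= 200 bp so window-level class
    assignments stay clean. Truth counts per query pattern are taken by a
    naive scan of the finished genome on both strands. Deterministic
    given the spec (which carries the seed).
    """
    rng = np.random.default_rng(spec.seed)
    chroms = {
        name: _random_background(length, spec.base_composition, rng)
        for name, length in spec.chromosome_lengths.items()
    }
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in chroms}
    classes: dict[str, list[Interval]] = {}
    consensus: dict[str, str] = {}
    tandem: dict[str, bool] = {}
    names = list(chroms)
    margin = 200

    def _fits(name: str, start: int, end: int) -> bool:
        if start < 0 or end > len(chroms[name]):
            return False
        return all(
            end + margin <= s or e + margin <= start for s, e in occupied[name]
        )

    def _place(plan: ArrayPlan, name: str, start: int, seq: str) -> None:
        end = start + len(seq)
        chroms[name][start:end] = seq.encode()
        occupied[name].append((start, end))
        classes.setdefault(plan.class_label, []).append(Interval(name, start, end))

    terminal_slot = 0
    for plan in spec.plans:
        consensus[plan.class_label] = plan.consensus
        tandem[plan.class_label] = plan.tandem
        for _ in range(plan.n_arrays):
            seq = _array_sequence(plan, rng)
            if len(seq) > min(spec.chromosome_lengths.values()):
                raise ValueError(
                    f"array of class {plan.class_label!r} ({len(seq)} bp) exceeds "
                    "the shortest chromosome"
                )
            if plan.placement == "terminal":
                placed = False
                for _attempt in range(2 * len(names)):
                    name = names[(terminal_slot // 2) % len(names)]
                    at_end = terminal_slot % 2 == 0
                    terminal_slot += 1
                    L = len(chroms[name])
                    start = L - len(seq) if at_end else 0
                    if _fits(name, start, start + len(seq)):
                        _place(plan, name, start, seq)
                        placed = True
                        break
                if not placed:
                    raise ValueError(
                        f"no free chromosome end for class {plan.class_label!r}"
                    )
            else:
                placed = False
                for _attempt in range(200):
                    name = names[int(rng.integers(len(names)))]
                    L = len(chroms[name])
                    if plan.placement == "internal":
                        lo, hi = int(0.2 * L), int(0.8 * L) - len(seq)
                    else:
                        lo, hi = 0, L - len(seq)
                    if hi <= lo:
                        continue
                    start = int(rng.integers(lo, hi))
                    if _fits(name, start, start + len(seq)):
                        _place(plan, name, start, seq)
                        placed = True
                        break
                if not placed:
                    raise ValueError(
                        f"could not place array of class {plan.class_label!r} "
                        "without overlap"
                    )
    genome = Genome({name: chroms[name].decode() for name in names})
    annotations = AnnotationSet(classes=classes, consensus=consensus, tandem=tandem)
    annotations.validate_against(genome)
    truth: dict[str, dict[str, int]] = {}
    for pid, pattern in spec.query_patterns.items():
        fwd = sum(_count_occurrences(seq, pattern) for seq in genome.records.values())
        rc = revcomp(pattern)
        rev = sum(_count_occurrences(seq, rc) for seq in genome.records.values())
        truth[pid] = {"forward": fwd, "reverse": rev, "total": fwd + rev}
    return genome, annotations, truth


def simulate_coverage(
    genome: Genome,
    annotations: AnnotationSet,
    cov: CoverageSpec,
    condition: str,
    grid: WindowGrid | None = None,
) -> CoverageTrack:
    """Draw one per-window coverage track for ip / input / notag.

    Expected count per window is ``depth * fold(class)`` for IP windows
    overlapping a repeat class in the fold map (the largest fold wins for
    multi-class windows) and ``depth`` otherwise; Input and No-tag ignore
    the fold map entirely. Each condition draws from its own seeded
    stream, so tracks are independent but reproducible.
    """
    if condition not in _CONDITION_STREAM:
        raise ValueError(f"unknown condition {condition!r}")
    grid = grid or window_genome(genome, width=cov.window_width)
    expected = np.full(len(grid), float(cov.depth))
    if condition == "ip" and cov.fold:
        window_classes = annotate_windows(grid, annotations)
        for i, labels in enumerate(window_classes):
            folds = [cov.fold[lab] for lab in labels if lab in cov.fold]
            if folds:
                expected[i] *= max(folds)
    rng = np.random.default_rng([cov.seed, _CONDITION_STREAM[condition]])
    if cov.noise == "poisson":
        counts = rng.poisson(expected)
    else:
        r = cov.dispersion
        counts = rng.negative_binomial(r, r / (r + expected))
    return CoverageTrack(
        sample_id=condition, values=counts.astype(float), window_width=cov.window_width
    )


def simulate_intensities(
    n_proteins: int,
    n_reps: int = 3,
    effects: Mapping[str, float] | None = None,
    noise_sd_log2: float = 0.2,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> IntensityMatrix:
    """Lognormal AP-MS intensity matrix with known bait-side fold effects.

    Proteins are named ``P0000``...; ``effects`` maps protein id to the
    bait/control fold (> 0). Missingness is intensity-dependent: cells in
    the lowest quartile of log2 intensity go missing at three times the
    base rate (capped at 0.95). Deterministic given the seed.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    effects = dict(effects or {})
    if any(f <= 0 for f in effects.values()):
        raise ValueError("effect folds must be positive")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    unknown = set(effects) - set(proteins)
    if unknown:
        raise ValueError(f"effects reference unknown proteins: {sorted(unknown)}")
    base = rng.normal(25.0, 2.0, size=n_proteins)  # log2 abundance
    effect_log2 = np.array([np.log2(effects.get(p, 1.0)) for p in proteins])
    bait = base[:, None] + effect_log2[:, None] + rng.normal(
        0, noise_sd_log2, size=(n_proteins, n_reps)
    )
    ctrl = base[:, None] + rng.normal(0, noise_sd_log2, size=(n_proteins, n_reps))
    log2_matrix = np.concatenate([bait, ctrl], axis=1)
    samples = [f"bait_{i + 1}" for i in range(n_reps)] + [
        f"control_{i + 1}" for i in range(n_reps)
    ]
    values = np.power(2.0, log2_matrix)
    if missing_rate > 0:
        q25 = np.quantile(log2_matrix, 0.25)
        rate = np.where(
            log2_matrix < q25, min(3 * missing_rate, 0.95), missing_rate
        )
        values = np.where(rng.random(values.shape) < rate, np.nan, values)
    data = pd.DataFrame(values, index=proteins, columns=samples)
    design = pd.Series(
        ["bait"] * n_reps + ["control"] * n_reps, index=samples
    )
    matrix = IntensityMatrix(data=data, design=design)
    matrix.data.attrs["effects"] = effects
    return matrix


# ---------------------------------------------------------------------------
# Shipped fixture blueprints
# ---------------------------------------------------------------------------

def _stable_consensus(length: int, tag: int) -> str:
    """A fixed pseudo-random consensus per (length, tag), independent of spec seed."""
    rng = np.random.default_rng([987_654_321, length, tag])
    idx = rng.choice(4, size=length)
    return _BASES[idx].tobytes().decode()


SAT147_CONSENSUS = _stable_consensus(147, 1)
SAT177_CONSENSUS = _stable_consensus(177, 2)
SUB70_CONSENSUS = _stable_consensus(70, 3)
RETRO_CONSENSUS = _stable_consensus(400, 4)


def telomere_fixture_spec(seed: int = 0) -> GenomeSpec:
    """Small genome with terminal telomere arrays and junction-spanning queries."""
    return GenomeSpec(
        chromosome_lengths={"chr1": 40_000, "chr2": 25_000},
        plans=(
            ArrayPlan("TEL", TELOMERE_UNIT, tandem=True, n_arrays=3,
                      units_per_array=50, placement="terminal"),
            ArrayPlan("RETRO", RETRO_CONSENSUS, tandem=False, n_arrays=4,
                      placement="dispersed"),
        ),
        seed=seed,
        query_patterns={
            "TelR_truncated": "AGGGTTAG",
            # 2.5 telomere units: spans two unit junctions inside each array
            "TelR_full": "AGGGTTAGGGTTAGG",
            "Retro_probe": RETRO_CONSENSUS[101:116],
        },
    )


def study_like_spec(
    seed: int = 0,
    scale: float = 1.0,
    query_patterns: Mapping[str, str] | None = None,
) -> GenomeSpec:
    """A ~2 Mb genome with the four profiled repeat classes plus a dispersed
    retroelement, at repeat fractions (~1.5% of the genome) comparable to a
    real trypanosome-like assembly. ``scale`` shrinks everything
    proportionally for quick tests."""
    def s(x: int, lo: int = 1) -> int:
        return max(lo, int(round(x * scale)))

    return GenomeSpec(
        chromosome_lengths={"chr1": s(1_200_000, 2000), "chr2": s(800_000, 2000)},
        plans=(
            ArrayPlan("TEL", TELOMERE_UNIT, tandem=True, n_arrays=4,
                      units_per_array=s(200, 5), placement="terminal"),
            ArrayPlan("CIR147", SAT147_CONSENSUS, tandem=True, n_arrays=2,
                      units_per_array=s(20, 2), placement="internal"),
            ArrayPlan("REP177", SAT177_CONSENSUS, tandem=True, n_arrays=2,
                      units_per_array=s(35, 2), placement="internal"),
            ArrayPlan("REP70", SUB70_CONSENSUS, tandem=True, n_arrays=3,
                      units_per_array=s(15, 2), placement="internal"),
            ArrayPlan("INGI", RETRO_CONSENSUS, tandem=False, n_arrays=s(6, 1),
                      placement="dispersed"),
        ),
        seed=seed,
        query_patterns=dict(
            query_patterns
            if query_patterns is not None
            else {
                "TelR_truncated": "AGGGTTAG",
                "TelR_full": "AGGGTTAGGGTTAGG",
                "Sat147_probe": SAT147_CONSENSUS[10:25],
            }
        ),
    )


def example_genome_specs(seed: int = 0) -> dict[str, GenomeSpec]:
    """The shipped fixture blueprints, exercising every placement rule and at
    least one junction-spanning planted target."""
    return {
        "telomere_small": telomere_fixture_spec(seed),
        "study_like_mini": study_like_spec(seed, scale=0.1),
    }
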