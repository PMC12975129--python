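# Methods

This note documents the models, conventions and numerical choices behind
talerep, and what the synthetic fixtures do and do not establish about
behavior on real data.

## Coordinates, sequences, annotations

All internal coordinates are 0-based half-open; BED is the native
annotation dialect and GFF3 (1-based closed) is converted on read and
back on write, so GFF→internal→GFF is the identity. Sequences are
normalized to uppercase {A,C,G,T,N} with U→T; soft-masked (lowercase)
bases are retained rather than excluded because the census counts exact
matches irrespective of masking. N never matches any pattern base — a
conservative choice that can only undercount in gappy assemblies.

## Target enumeration and RVD design

A candidate target is a k-mer (default k = 15) whose immediately 5′ base
on its own strand is T (the T0 requirement). For tandem repeat classes
the consensus unit is treated as circular — candidates are enumerated
once per rotation offset in [0, unit length), reading through unit
junctions — because in an unbounded array every rotation exists and the
biologically relevant telomeric target spans 2.5 units. Linear
(non-tandem) consensuses are scanned as given; position 0 has no T0
context and is never a candidate. Reverse-strand candidates are obtained
by enumerating on the reverse complement, since TALE polarity is
strand-specific.

The RVD cipher is positionwise A→NI, C→HD, G→NN, T→NG. The module plan
packs the array into blocks of 4 (tetramers) with trailing blocks of 3
(trimers), maximizing tetramers; array lengths with no {4,3} packing
(1, 2, 5) are a planning error. Predicted recombination products may
have such lengths, so their RVD arrays carry no plan rather than
erroring.

## Idealized module library

The shipped library assigns each RVD one fixed 102 bp coding unit: a
common 34-codon TALE-repeat scaffold with an RVD-specific dicodon at
codons 12–13 and one fixed codon per amino acid (no silent variation).
Consequences that matter for the hazard scan:

- identical RVDs always produce identical coding units, so a target with
  base period p produces a coding sequence with period 102·p;
- different-RVD units share at most ~100 bp across unit boundaries
  (63 bp scaffold suffix + 33 bp prefix + ≤3–4 bp of shared dicodon
  prefix), which sits below the 100 bp reporting floor, so scaffold
  sharing never masquerades as a unit-level hazard.

Real assembly kits shuffle codons to suppress exactly these repeats; a
user-supplied library (FASTA or TSV, one record per RVD) replaces the
idealized one everywhere.

## Direct-repeat hazard and the deletion model

The hazard statistic is the maximal-length pair of identical,
non-overlapping substrings of the coding DNA (ties: smallest first
position, then smallest second). Existence of a non-overlapping repeat
is monotone in length (prefixes of a valid pair are valid), so the
maximum is found by bisection over length with a hash-of-substrings
check; tests enforce exact agreement with a quadratic oracle. The
default reporting floor of 100 bp ≈ one module unit, because sub-unit
repeats (the shared scaffold) occur in every TALE construct and are not
actionable.

For the telomeric target AGGGTTAGGGTTAGG (period 6, 15 units) this gives
a 612 bp repeat spanning units 1–6 and 7–12: the overlap constraint caps
the period-6 self-alignment at 6 units × 102 bp.

Deletion products model a single crossover between the two copies of a
whole-unit repeat. Exactly aligned crossover removes `unit_offset`
units; the default allows ±1 unit of slippage because the experimentally
recovered product retained 8 recognition bases where exact alignment
predicts 9 — the slippage parameter encodes that observed mechanism
ambiguity rather than resolving it, making the 8-base product a
predicted member without privileging it. Products are deduplicated by
recognition sequence and ordered by length then lexicographically. No
recombination-rate model is attempted: one observed event constrains
outcomes, not frequencies.

## Genome census conventions

Matching is exact-only on both strands; reverse-strand matches are
occurrences of the reverse complement reported on the forward axis.
Every start position counts: overlapping occurrences are all reported,
because telomeric 8-mers recur every 6 bp and any non-overlap convention
makes tandem-array copy numbers undercounted and convention-dependent
(a greedy non-overlapping mode exists as a flag for comparison).
Matches are distinct (position, strand) pairs, so self-reverse-complement
patterns count each locus twice; they are flagged so callers can halve.
A match is in-class when it overlaps ≥1 bp of any interval of the target
class; a pattern is unique to its class when it has in-class matches and
none elsewhere. Feasibility is strict: `feasible` requires count >
threshold (default 1000), count 0 is `absent`, everything else
`low_copy`.

The scanner is a hand-built Aho–Corasick keyword automaton (one pass,
all patterns, both strand variants in one trie). Its correctness
contract is exact equality with a naive per-pattern scan, which the
property tests and the 200-random-genome acceptance check enforce; the
data structure itself is an implementation detail.

## ChIP repeat profiling

Windows are fixed-width (default 50 bp), anchored at 0 per sequence,
half-open, terminal partial window kept and flagged; a smaller step
yields sliding windows for overview tracks (5 bp step mode). A window
receives every class it overlaps by ≥1 bp; windows with no class are
background; windows with ≥2 classes are excluded from both background
and per-class statistics and reported separately, preventing e.g.
telomere-adjacent satellite windows from contaminating either class.

Enrichment is log₂((IP_cpm + c)/(Input_cpm + c)) with both tracks scaled
to counts per million — a deterministic, total-count-based scaling chosen
because the upstream tooling's exact mode is tool-configuration-dependent
— and a pseudocount c = 1 CPM (configurable) keeping zero-coverage
windows finite. No-tag normalization is windowwise subtraction of the
control's log₂ ratio. Per-class summaries report n, mean, median, sd,
quantiles, and `delta` = class median − background median; `delta` is
the fold-recovery statistic because it cancels the global shift that
library-size scaling introduces when enriched classes carry extra reads.

## AP-MS statistics

Intensities are log₂-transformed; the statistic is mean(bait) −
mean(control) with a two-sided two-sample t-test. Welch's unequal-
variance form is the default for robustness at n = 3; the pooled
(classic Student) form is available and is the exactly calibrated choice
when group variances are equal — the null-calibration acceptance check
uses it for that reason. A protein is significant when p < α (default
0.05) and log₂FC > 0 with ≥2 replicates per condition; the positive-FC
gate halves the null call rate to α/2. Zero-variance-in-both-groups
rows get p = 1 (equal means) or p = 0 (different means) with a flag.
Without imputation, a tested protein needs full bait quantification and
≥2 control observations; optional imputation draws missing log₂ values
per sample from N(mean − 1.8·sd, (0.3·sd)²) of that sample's observed
values — the mainstream proteomics convention — and requires an explicit
seed. No multiple-testing correction is applied by default (matching the
p < 0.05 convention the workflow replicates); Benjamini–Hochberg is a
flag.

## Synthetic fixtures: what they emulate, what they don't

Genomes are random background (default uniform base composition) with
planted arrays: terminal arrays flush at alternating chromosome ends
(telomere-like), internal arrays in the central 60% (satellite-like),
and dispersed single copies (retroelement-like); arrays never overlap
and keep ≥200 bp spacing so window class assignments are unambiguous.
Arrays are exact tandem copies by default so truth is computable; a
substitution-rate option degrades them, making exact-match undercounting
predictable. Ground-truth pattern counts are recorded at build time by a
naive scan of the finished sequence — independent of the census
implementation they later validate. The study-like blueprint uses a 2 Mb
genome whose repeat classes total ~1.5% of sequence, mirroring the
sparseness of repeat classes in a real ~35 Mb genome; this also keeps
the CPM-scaling shift of background windows small (|background median|
< 0.05 after No-tag normalization under the planted-fold conditions).

Coverage is drawn per window (Poisson, or negative binomial with
dispersion r giving variance m + m²/r) around an expected depth of 100
reads/window, times the class fold for IP windows only; the class fold
applies uniformly to any window overlapping the class, matching the
profiler's own ≥1 bp rule. Intensity matrices are lognormal with log₂
noise sd 0.2 around per-protein abundances ~N(25, 2²) on the log₂ scale,
3 + 3 replicates, bait-side fold effects, and intensity-dependent
missingness (bottom quartile at 3× the base rate).

What passing these simulations does **not** show: real ChIP coverage has
mappability structure, fragment-length autocorrelation and copy-number
variation that per-window independent counts lack; real satellite units
diverge, so exact-match censuses undercount degenerate families (the 70
bp repeats especially); real LFQ missingness is censoring-like rather
than parametric. The fixtures validate the estimators' arithmetic and
calibration, not robustness to those artifacts.

## Problem sizes used in the test and acceptance suites

Chosen as the package's own verification scale: oracle-equivalence runs
200 random genomes of 1–100 kb; profiler recovery uses one 2 Mb
four-class genome, folds {2, 4, 8} at depth 100, three simulation seeds
plus one null seed; AP-MS calibration uses 1,000 null proteins (one
seed) and 100 seeds of a 50-protein matrix with one planted 8-fold
protein. All seeds are fixed constants in the tests; hypothesis runs
derandomized.

## Known limitations

- The census offers no approximate matching; degenerate repeat families
  need consensus-level queries per variant.
- The deletion model is single-crossover and whole-unit; base-pair-level
  (non-unit) crossovers are rejected rather than modeled.
- `longest_direct_repeat` reports one maximal pair; secondary hazards of
  equal or shorter length are not enumerated.
- The profiler averages nothing across replicates; replicate handling is
  limited to averaging normalized tracks upstream of `class_summary`.
- The 14 nt published retroelement target violates the 15 bp design rule;
  the census counts any supplied length verbatim and the CLI surfaces a
  warning rather than resolving the discrepancy.
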