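# talerep

Design and vetting of synthetic TALE DNA-binding proteins against
repetitive genomic elements, with downstream enrichment statistics for
repeat chromatin profiling.

Transcription activator-like effectors (TALEs) bind DNA through tandem
~34-residue repeats, one base per repeat, read through a two-letter
repeat-variable diresidue (RVD) cipher (A→NI, C→HD, G→NN, T→NG) with a
required thymine (T0) immediately 5′ of the recognition sequence. Because
a single TALE bound to a single-copy site yields too little material for
chromatin proteomics, TALEs aimed at repeats must hit targets present in
very many copies — empirically more than 1,000 in a ~35 Mb genome such as
*Trypanosoma brucei*'s. This package implements the computational steps of
that workflow:

- **`target_design`** — enumerate candidate k-mer targets (default 15 bp,
  T0-constrained) inside a repeat consensus, including targets that span
  tandem-unit junctions (scanned on the circularized unit); translate
  targets to RVD arrays with a tetramer/trimer module plan and assemble
  the repeat-region coding DNA from a module library.
- **`genome_census`** — exact-match, both-strand, overlap-counting census
  of candidate targets across a genome (single-pass keyword automaton,
  contract-checked against a naive scan), specificity classification
  against repeat-class annotations, and the strict >1000 copy-number
  feasibility rule.
- **`hazard_scan`** — detect internal direct repeats in the assembled
  coding DNA (a periodic target ⇒ identical coding units ⇒ a
  recombination-deletion hazard) and enumerate single-crossover deletion
  products with their truncated recognition sequences.
- **`repeat_profiler`** — 50 bp-window ChIP enrichment over repeat
  classes: log₂(IP/Input) with CPM scaling and a pseudocount, No-tag
  control subtraction, background defined as windows overlapping no
  annotated repeat, and per-class summary statistics.
- **`apms_enrichment`** — per-protein log₂ fold change and two-sample
  t-test (Welch default, pooled optional) of bait vs control label-free
  intensity matrices, significance at p < 0.05 with positive fold change,
  optional downshifted-normal imputation and Benjamini–Hochberg control.
- **`synthetic_fixtures`** — seeded generators for genomes with planted
  repeat arrays (terminal telomere-like, internal satellite-like,
  dispersed retroelement-like) and recorded ground-truth pattern counts,
  plus coverage tracks and intensity matrices with known effects.

## Worked example

The telomere repeat (TTAGGG)ₙ admits exactly two 15 bp T0-compliant
targets per unit rotation:

```python
>>> import talerep as tr
>>> for c in tr.enumerate_targets("TTAGGG", tandem=True, k=15):
...     print(c.rotation_offset, c.sequence, c.junction_spanning)
1 TAGGGTTAGGGTTAG True
2 AGGGTTAGGGTTAGG True
```

Both span unit junctions. Designing the second and scanning its coding
DNA for recombination hazards:

```python
>>> design = tr.design_tale("AGGGTTAGGGTTAGG")
>>> tr.hazard_report(design)   # products list elided
{
  "target": "AGGGTTAGGGTTAGG",
  "target_period": 6,
  "n_units": 15,
  "unit_len": 102,
  "longest_direct_repeat_bp": 612,
  "unit_span": 6,
  "unit_offset": 6,
  "pos_a": 0,
  "pos_b": 612
}
```

The target's base period of 6 makes coding units 1–6 identical to units
7–12, i.e. a 612 bp direct repeat (6 units × 102 bp) whose two copies sit
612 bp apart. A single recombination crossover between the copies deletes
6 ± 1 units; among the predicted products is the 8-base recognition
sequence `AGGGTTAG` — a TALE that survives assembly but recognizes only
8 of the intended 15 bases. Copy-number vetting uses the strict >1000
rule:

```python
>>> tr.feasibility(19164).verdict, tr.feasibility(440).verdict
('feasible', 'low_copy')
```

The same API drives the `talerep` command line (`design`, `hazard`,
`census`, `profile`, `apms`, `simulate`); every subcommand reads and
writes plain text (FASTA, BED/GFF3, bedGraph, TSV, JSON).

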