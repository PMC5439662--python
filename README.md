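# dnapartition

Multi-level retrosynthetic partitioning of large DNA designs for
overlap-based assembly.

## The problem

Building a synthetic construct of tens of kilobases to megabases means
working backwards from the final sequence to orderable parts: ~1 kb
**subblocks** that a synthesis vendor will make, joined by isothermal
in-vitro assembly into ~4 kb **blocks**, joined by yeast homologous
recombination into ~20 kb **segments**, and finally into the full design.
Each junction between adjacent units is directed by a **terminal homology
region (THR)** — a stretch of sequence duplicated on both fragments.
Assembly fails, or produces scrambled products, when a THR contains

* a direct repeat (the overlap can mis-align, causing indels),
* a hairpin stem (an inverted repeat folds and blocks annealing), or
* sequence shared with another THR of the same pool (a fragment anneals
  at the wrong junction).

`dnapartition` plans the whole tiered route for a design of up to 10 Mb:
unit counts and boundaries under size caps, THR placement, removal of THR
constraint violations by shifting junctions, nested type IIS adapter
stacks for cloning and release, diagnostic PCR primers for every
junction, and feasibility statistics for single designs or batches.

## The method in brief

* **Planning.** A stretch of length *L* at a tier with size limit *M*,
  overlap *v* and adapter load *a* is split into the least *n* with
  ⌈L/n⌉ + v + a ≤ 1.1·M; core sizes differ by ≤ 1 bp. Each tier
  re-partitions its parent's core *plus* left THR, so merging children by
  their THR duplications reproduces the parent exactly ("virtual
  assembly" — tested byte-for-byte).
* **THR screening.** Exact string kernels report the longest direct
  repeat, hairpin stem (loop ≥ 3 nt) and cross-THR shared substring (both
  strands); a feature longer than the built-in 8 bp limit is a violation.
* **Optimization.** A violating junction is shifted: candidates are
  enumerated ±1, ±2, … bp from the original position (clipped so both
  flanking units respect the 10% size caps) and scored by
  (violations, longest feature, |displacement|); the nearest
  constraint-free variant wins. Up to 20 cycles per pool, non-recurring
  search path, unresolved junctions are reported with their final state.
* **Primers.** 20-mer pairs flanking each THR within a 150 bp window,
  ΔTm ≤ 1 °C (nearest-neighbor Tm, unified Allawi–SantaLucia table,
  50 mM Na⁺ / 500 nM oligo), unique 3′ octamer, no self- or
  cross-homology; window +50 bp and ΔTm +1 °C per escalation, at most 6.

## Worked example

```python
from dnapartition import (DesignRecord, PartitionParams, build_design,
                          optimize_design, design_all_junctions, random_sequence)

record = DesignRecord("demo", random_sequence(20_000, gc=0.5, seed=1)).validate()
design = optimize_design(build_design(record, PartitionParams()))
print([len(design.units(t)) for t in ("segment", "block", "subblock")])
primers = design_all_junctions(design)
print(len(primers.tables["block"]), len(primers.tables["subblock"]))
```

prints

```
[1, 5, 20]
4 15
```

— a 20 kb design becomes one segment of five 4 kb blocks and twenty 1 kb
subblocks, with a verification primer pair for each of the 4 block
junctions and 15 subblock junctions. With empty adapters the total
synthesis effort is 20 000 + 15·35 + 4·80 = 20 845 bp (cores plus
duplicated THRs), as reported by `statistics.txt`.

The same run from the shell:

```bash
dnapartition fixture spec.yaml --out design.gb     # synthetic test input
dnapartition partition design.gb --out run/        # FASTA, GenBank, primers, stats
dnapartition feasibility design.gb --report fx.tsv # pass fractions, violations
```

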