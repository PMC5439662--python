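# Methods

## Model of the partitioning problem

An input design is a single linear A/C/G/T sequence of at most
10,000,000 bp (the cap is on sequence length, not file bytes; ambiguity
codes are rejected because overlap assembly chemistry needs exact
sequence). Circular inputs are accepted with a warning and processed as
linear: no terminal homology region (THR) ever spans the origin.
Coordinates are 0-based half-open in memory and converted to GenBank's
1-based inclusive convention only at the file boundary.

The design is decomposed into three nested tiers — segments (default
limit 20,000 bp), blocks (4,000 bp; sensible range 2,000–5,000) and
subblocks (1,000 bp; 500–2,000) — with tier overlaps of 120 / 80 / 35 bp
by default (yeast recombination needs longer homologies than isothermal
in-vitro joining, hence the decrease with tier). A unit's size is its
core sequence plus its left THR extension plus all attached adapter
sequences, and must stay within (1 + 0.10) × the tier limit; the 10%
variation allowance is fixed.

### Unit counts and boundaries

For a stretch of length L the unit count is the least n with
ceil(L/n) + overlap + adapter_load ≤ 1.1 × limit, and core sizes differ
by at most 1 bp (the first L mod n units get the extra base). The
adapter load reserved at planning time is the worst case for the tier —
a unit's own adapters plus those of every enclosing tier — because
terminal units inherit the full nested stack. Minimality is verified
exhaustively in the tests for all L ≤ 50 kb.

### THR ownership and virtual assembly

The overlap at a junction is the last `overlap` bases of the left
sibling's core, duplicated as a prefix extension of the right sibling
(the first child of any parent has no extension). Sub-partitioning at
each tier covers the parent's core *plus its own left THR*, so the
duplications survive tier transitions: stripping adapters from all
subblocks and merging consecutive regions by their exact overlaps must
reproduce the input byte for byte. This "virtual assembly" identity is
the package's structural invariant and is asserted on every fixture
class in the test suite, including optimized designs.

### Advanced (part-boundary) mode

When the input annotates biological parts (`source` features with a
note), segment boundaries are chosen by greedy left-to-right
accumulation of whole parts under the segment cap; a single part larger
than the cap becomes its own oversized segment with a logged warning.
Only segment boundaries snap to parts (block/subblock boundaries remain
size-driven), and segment-junction optimization is disabled in this mode
— shifting a boundary would detach it from the part edge it was chosen
for. Parts must tile the sequence exactly; discontinuous (join/order)
part locations are rejected.

## Constraint kernels

Three exact string kernels score a THR: longest substring occurring at
two or more distinct starts (overlaps allowed); longest hairpin stem,
i.e. substring whose reverse complement occurs downstream with a loop of
at least 3 nt (the physical minimum; no standard loop-length rule
exists, so it is configurable); and longest substring shared with
another THR of the same co-assembly pool, checked in both orientations
because overlaps anneal as duplexes. A feature is a violation iff it is
strictly longer than its threshold (built-in 8 bp, i.e. ≥ 9 bp fails):
this resolves the ambiguity between "smaller than 8 bp" and "larger than
8 bp are removed" in favor of the 8 bp size-limit table. Each kernel
binary-searches the feature length (the existence predicate is monotone)
with a hashed k-mer sweep per probe; correctness is established purely
against exhaustive diagonal-run oracles in the tests, on 1,000 random
strings up to 200 bp plus algebraic invariants (strand symmetry,
monotonicity under extension, argument symmetry). Uniqueness is compared
within the sibling pool by default (blocks against the other blocks of
their segment, subblocks within their block); `unique_scope="genome"`
switches to a whole-design comparison at quadratic cost.

## THR optimization

Per pool, junctions are processed worst-score-first (ties left to
right); each violating junction is moved at most once per cycle, for at
most 20 cycles. Candidate positions are enumerated outwards from the
*original* equidistant position (+1, −1, +2, −2, …) up to a maximal
shift of floor(0.05 × tier limit) — chosen so that no shift can push
either flanking unit past the 10% cap — and additionally clipped so the
THR stays inside the left core and the next junction's THR still fits.
Visited positions are never re-evaluated as move targets (non-recurring
search). A candidate is scored by the tuple (number of violated
constraint classes, longest feature in bp, |displacement|), compared
lexicographically; because candidates are generated smallest-shift
first, the scan accepts the first fully constraint-free candidate
immediately, which makes "least repositioning" the deciding criterion
among passing variants while the feature length still ranks variants
when none passes. Sibling THRs are always compared at their current
positions, so the pool co-evolves. Junctions still violating after the
cycle budget keep their last position and are flagged unresolved in the
log, statistics and manifest — an expected outcome on pathological
inputs such as long tandem arrays, not an error.

The whole procedure is deterministic, and `optimize_design` re-plans
from the input record, so re-optimizing an optimized design reproduces
it exactly. Segment-tier junctions are optimized with the same routine
(disable with `optimize_segments=False`).

## Adapters

Each tier owns an optional 5' prefix / 3' suffix adapter. Every unit
carries its own tier's adapters outermost; units forming a terminus of
their parent nest the parent-tier adapter inside on that side, and so on
upwards, so releasing children with their type IIS enzyme and
reassembling reconstitutes the parent with its adapters. The built-in
preset assigns the conventional enzyme roles (BbsI release for
subblocks, BspQI for blocks, PacI/PmeI for segments) with recognition
sites embedded in short neutral flanks; the flanks are synthetic
placeholders for vector homology and real cloning systems should supply
their own sequences. `check_forbidden_sites` scans the partition
sequence (cores only — adapters are supposed to contain the sites) on
both strands and warns by default; `--strict-sites` aborts.

## Primer design

Fixed 20-mers are searched in a window (initial 150 bp) on each side of
the junction THR, clipped at design boundaries. Single-primer rules: the
3'-terminal octamer must be unique on its strand within the window, and
the primer must not contain a repeat or hairpin feature longer than
4 bases (the same kernels at a 4 bp threshold). Pair rules: ΔTm ≤ 1 °C
initially; the longest complementary run between the primers ≤ 7 bp and
3'-terminal complementarity ≤ 3 bp (the printed rules quantified — the
cutoffs are configurable since no numbers are published). Pairs are
scanned forward-position ascending then reverse-position ascending and
the first passing pair is emitted, which makes output deterministic. On
failure the window grows 50 bp and the ΔTm bound relaxes 1 °C per
iteration, both applied together, at most six times; the escalation that
produced each pair is recorded, and per-rule discard counts go to the
log. The "annealing temperature range" escalation is read as relaxing
the pair ΔTm bound, the only interpretation that affects pair selection.

Tm is nearest-neighbor thermodynamics with the unified
Allawi & SantaLucia (1997) parameter table, entropy salt correction
0.368·(N−1)·ln[Na⁺] at 50 mM monovalent salt, 500 nM primer (primer in
excess, C_T term = primer concentration), self-complementary symmetry
correction included. The test suite cross-checks this hand-written
implementation against Biopython's independent implementation of the
same table to 0.1 °C.

## Feasibility analysis

A segment is "risk-free" when no THR it is responsible for — its own
junction THRs (attributed to the segment whose core physically contains
the THR, i.e. the left neighbor) and every THR of its descendant blocks
and subblocks — violates any threshold. `analyze_sequence` reports
per-tier unit counts and size ranges, violation counts per constraint
class, the risk-free segment count and fraction, mean GC of passing vs
failing segments, per-tier displacement statistics and the population
variance of block core sizes (bp²; the rendered report also shows the
standard deviation). Batch mode emits one row per sequence plus a mean
row as TSV. Database-scale genome surveys are out of scope for the
shipped metrics — they would require thousands of downloads and depend
on the exact adapter lengths of a particular cloning system — so the
desk-scale metrics are measured on seeded synthetic designs with
implanted ground truth instead.

## Synthetic fixtures

`fixtures` generates i.i.d. random sequence at a target GC (realized GC
within ±0.01 of target for ≥ 10 kb), optionally purged of forbidden
restriction sites by bounded resampling (1,000 rounds), with implantable
direct repeats, hairpins, shared motifs and homopolymers at known
positions, and part annotations serialized as GenBank `source`
features. Two stress generators build the standard stress scenarios:
`implant_block_junction_repeats` (a distinct 15 bp repeat, copies 30 bp
apart start-to-start, centered on every planned block junction) and
`implant_shared_block_motifs` (one identical 30 bp motif inside the THRs
of two block junctions per segment). One integer seed drives every
random choice; there are no unseeded paths. What the fixtures do *not*
emulate: real genomic repeat structure (rRNA operons, IS elements,
skewed k-mer composition), so passing tests demonstrate correctness of
the algorithms, not field performance on any particular genome.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use 20 kb–200 kb designs
(the documented scale for second-scale runs) and 40 kb implant fixtures;
these sizes exercise every code path — multi-segment pools, tier
transitions, escalated primers, unresolved junctions — while keeping the
whole suite around half a minute. Caps are computed as
floor(1.1 × limit) in exact integer arithmetic; ties in unit sizing give
the extra base to the leftmost units; all scans and enumerations are
ordered so byte-identical inputs give byte-identical outputs.

## Known limitations

* Secondary structure is exact-match string repeats, not a ΔG folding
  model; borderline hairpins with mismatched stems are invisible.
* Approximate (mismatched) repeats are not detected.
* Pool-scope uniqueness does not see a THR colliding with distant
  sequence elsewhere in the genome unless `unique_scope="genome"`.
* Optimization is greedy per pool; a globally coupled arrangement that
  no sequence of single-junction moves reaches will stay unresolved.
* Circular designs are linearized; a junction placed at the nominal
  origin is not treated specially.
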