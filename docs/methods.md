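# Methods

This note records the models behind each module, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
numerical and design choices made where the design was genuinely open. No
empirical claim is made here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All in-memory coordinates are 0-based half-open; GFF3 on disk is 1-based
inclusive. The conversion happens only in `core_io.read_feature_table` and
`core_io.write_primer_gff`, so no other code ever adjusts by one. Soft
masking is an interval list carried next to the sequence — masked output
FASTA is lowercased, but sequences are never destructively edited, so
masking is reversible and auditable. Only GFF3 is written (GFF2 is
obsolete). Gap features carry the N-run length as their size estimate; no
independent estimate survives assembly.

## Gap-closure primer design

**Gaps** are the maximal N-runs of a scaffold, including runs touching
sequence ends.

**Repeat detection** replaces iterative clustering-based de novo repeat
finders with exact k-mer seed-and-merge: every base covered by a canonical
(strand-folded) k-mer occurring ≥ `min_copies` times genome-wide is
masked; overlapping seed hits merge into maximal intervals, and intervals
sharing any repeated seed are linked into families by union–find. Defaults
k = 24, min_copies = 2: at k = 24 a chance repeated k-mer in megabase-scale
near-random sequence is vanishingly rare, so false masking is ≪ 1% while
exact planted copies are recovered essentially completely (interval ends
taper by k−1 bases at copy boundaries, within the ≥ 95% base-recall target).
The detect→mask loop is run to a fixed point (≤ 5 rounds); with exact
global counting one round already is the fixed point, and the loop merely
guards the contract under future detector changes. Adequacy is defined by
planted-truth recall/precision, not by equivalence to any particular
repeat finder.

**Melting temperature** is the nearest-neighbor thermodynamic Tm under the
unified dinucleotide ΔH/ΔS parameter set with the entropy-based
monovalent-salt correction, at 50 mM Na⁺ and 500 nM primer by default.
Divalent-cation corrections are unsupported. The test suite checks the
implementation against an independently hand-summed copy of the published
table to ±0.1 °C.

**Candidate gates** (config-overridable, `PrimerConstraints`): length
18–27 nt; Tm 57–63 °C, optimum 60; GC 20–80%; reject homopolymer runs ≥ 5,
3′-terminal self-complementary runs ≥ 4, and hairpin stems ≥ 6 bp with
loop ≥ 3. Penalty of an accepted candidate:
`|Tm − 60| + 2·|gc − 0.5| + 0.2·(3′ self-complementary run) +
0.2·(hairpin stem)`. The weights put ~1 °C of Tm error on par with 0.5 GC
units or five bases of sub-threshold secondary structure — mirroring the
spirit of standard primer-design software, with the product-size window
(100–1,000 bp first round, 100–3,000 bp second round) being the externally
fixed constraint.

**Pair selection** enumerates windows outward from the gap on each flank,
stopping after 80 accepted candidates per side (penalty-optimal windows in
clean flanks appear early; the cap bounds work without changing results in
practice), then picks the minimum `left.penalty + right.penalty` pair whose
product (scaffold coordinates, counting the N-run at its estimated length —
the only coherent reading of a fixed product window over a gap of unknown
true size) spans the gap inside the window, with |ΔTm| ≤ 5 °C. Ties break
by smaller product, then leftmost left primer. Masking is binary: one
masked or N base anywhere in a primer rejects it. Failures are typed:
`flanks_masked` (no clean window at all), `no_candidate_window` (clean
windows exist, none passes the gates), `product_range_unsatisfiable` (gap
plus two minimal primers exceeds the window).

## Erosion state matrix

"Score" is the raw Smith–Waterman local-alignment score under BLOSUM62
with affine gaps costing 11 + L for length L; X is tolerated and scores 0.
Raw rather than bit score because the decision statistic is the ratio to
the reference's self-score, which cancels affine scaling constants, and
the raw optimum is exactly reproducible without an external search
program. A strain's cell is *intact* if it has an annotated CDS member,
*pseudo* if its best fragment reaches relative score ≥ 0.30 against the
group's intact representative (the longest CDS member across strains), and
*absent* otherwise — erosion past the cutoff is operationally
indistinguishable from loss. Groups with any mobile-class member (IS,
phage, GIIME, TnTIR) are dropped, as are groups non-absent in fewer than
two strains. The 0.30 cutoff is inherently sharp: fragments retaining
25–35% of the reference sit in a gray zone where a few substitutions flip
the call, so synthetic truth sets sample pseudogene retained fractions
from 0.40–0.90 (detectable by construction) and recovery there is exact.

**Dollo placement.** On the fixed rooted topology ((SAp, SCt), SCc) with
an intact root, states may only degrade (intact → pseudo → absent) along
any root-to-leaf path. The single free labeling (the ingroup ancestor) is
enumerated and the minimum-event labeling chosen; a branch going intact →
absent carries both a pseudogenization and a loss event, since the pseudo
stage is obligatory under Dollo, merely unobserved. A row is flagged
*ambiguous* when the minimal labeling places an event on the internal
branch: independent terminal events could then produce the same leaf
pattern, so the shared placement is parsimony's choice, not an
observation. Two-way clustering of the matrix (heat-map ordering) is
descriptive only and not implemented; the TSV is the product.

## COG profiles

Hits are consumed from a precomputed table (running the homology search
would tie results to a database version). Per CDS, hits with e-value
≤ 1e-3 are reduced to the maximum-total-score set of mutually
nonoverlapping intervals by weighted-interval-scheduling DP, with
deterministic tie-breaking (lower e-values, then leftmost starts);
half-open intervals make touching hits compatible. A CDS with accepted
hits in m distinct categories contributes 1/m to each, keeping every
nonempty profile on the simplex — the once-per-category alternative would
not. Divergence is frequency minus the mean frequency of the designated
free-living strains, zero-filled over the union category set so the
subtraction is defined everywhere; free-living deltas therefore average to
zero per category by construction.

## Rearrangement

Shared nonmobile single-copy orthologs are indexed 1..n along genome A;
genome B's signed order lists those indices with sign +/− for
kept/flipped strand relative to A. Synteny clusters are the maximal runs
of A chained through conserved signed adjacencies in B — equivalent to
maximal blocks colinear in identical order and signs or fully reversed
with flipped signs — and partition the shared gene set. Breakpoint
distance counts non-conserved adjacencies of the 0/(n+1)-framed
permutation (adjacency (a,b) conserved iff b − a = 1); circular framing
drops the distinguished ends and closes the circle instead. Properties
relied on by the tests: the identity has distance 0; every single
inversion costs exactly 2 (its two new adjacencies (i−1, −j) and (−i,
j+1) can never satisfy b − a = 1); distance/2 is a lower bound on the
number of inversions applied; internal adjacencies are invariant under
whole-genome negate-reversal while the two linear frame adjacencies may
change, so linear distances under reversal agree only to ±2 — exact
invariance holds for the circular framing. An exact minimal inversion
distance (Hannenhalli–Pevzner) and rearrangement median trees are out of
scope; `greedy_reversal_count` provides a clearly-labelled heuristic
upper bound only. Mobile-element flank tallies count a cluster for
category c when any feature of that class starts or ends within ±3 kb of
either boundary of the cluster's span; a cluster can count in several
categories, or in "none".

## Mate-pair screen

Orientation is defined from the coordinate-leftmost mate: RF (leftmost
reverse) is the canonical outward-sequenced mate-pair; FR is short-insert
paired-end contamination; FF/RR are library errors. Insert size is the
outer distance (right.end − left.start); the default concordance window,
2,211–3,651 bp inclusive, is the empirical insert-size range of a typical
3-kb mate-pair library. The cascade order is concordant →
mobile-region → intercontig → mate-overlap, each pair receiving exactly
one disposition; disposition counts always sum to the input count and
orientation counts to the retained count. FF/RR pairs are retained through
the summary (excludable downstream) rather than hard-filtered — the
"library error" judgment is a reporting decision. Junction evidence is
single-linkage clustering of retained non-FR pairs, linking two pairs when
both mate starts co-locate within 1,000 bp on one contig; clusters with
≥ 10 supporting pairs are reported. Both parameters are declared defaults:
junction calling is density-sensitive, and the simulated screens use
library sizes and contig lengths giving a discordant-pair density per bp
comparable to a real 3-kb mate-pair screen of a ~2.5 Mb genome (50,000
pairs against 1.2 Mb), at which scatter percolation is negligible.

## Synthetic data

One global seed fans out to per-stage child generators through
`numpy.random.SeedSequence(seed, spawn_key=(stage,))` with a fixed integer
per stage, so identical configs give byte-identical outputs and stages stay
independent.

The generators emulate: i.i.d. background sequence with a GC knob (default
0.50; real *S. symbiotica* is ~0.52 — the knob exists, the neutral default
is deliberate); non-overlapping genes with ≥ 200 bp intergenic spacing
(lengths uniform 300–1,200 bp, random strands); strain derivation by block
inversions whose breakpoints fall between genes, with IS features
annotated at breakpoints; assembly gaps as in-place N-run replacements of
intergenic segments (coordinates elsewhere stay fixed, truth records the
overwritten sequence); repeat families as exact copies of a random core,
forward or reverse-complement, half of them placed flush against gap
flanks (repeats crowd gaps in real fragmented assemblies); protein decay
by truncation, premature stop, or frameshift (prefix kept, tail
garbled); and mate-pair libraries as mixtures of concordant RF pairs
(insert ~ Normal(2,931, 240) — mean at the concordance-window midpoint,
SD a sixth of its width, truncated above twice the read length),
short-insert FR contamination (uniform 200–500 bp), and FF/RR errors at
random non-overlapping positions (100 bp reads).

Not emulated — and therefore not demonstrated by passing tests: sequence
divergence between strains beyond a few substitutions in intact proteins;
inexact (diverged) repeat copies, which the exact k-mer detector would
only find given a smaller k or seed chaining; real insert-size skew,
chimeras and duplicate reads; mapping ambiguity (records are taken as
correctly and uniquely mapped); and compositional heterogeneity of real
genomes. Results on synthetic data certify the algorithms against their
definitions and planted truth, not performance on diverged biological
repeats or noisy mappings.

The four-class mate-pair mixture cannot plant *retained* discordant RF
pairs directly — in a real screen those are the tails of the concordant
insert distribution falling outside the window, which the simulation
reproduces when `frac_concordant_rf > 0`. Mixture-recovery checks
therefore compare recovered class fractions to the planted generative
fractions (binomial 3-SE bands), using a concordant-free mixture
(FR 0.9569, FF 0.0341, RR 0.0090) for the screen-negative scenario.

## Problem sizes

Chosen as comfortable desk-scale analogues of the study's data: default
simulated chromosomes 100–200 kb with 60–150 genes (the real genome is
~2.5 Mb / ~2,500 genes); repeat-recovery runs use 100 kb backgrounds with
a 3-copy 400 bp family over multiple seeds; primer-design property runs
use 50 single-gap scaffolds (the real assembly had 96 gaps); erosion
recovery uses 300 ortholog groups across 3 strains; mate-pair screens use
50,000 pairs (the real screen retained 342,088); exhaustive rearrangement
oracles cover all signed permutations to n = 7. `scripts/acceptance.py`
states each run's n in its output.

## Known limitations

- The pseudogene rule reports no confidence near the 0.30 cutoff; calls
  on fragments retaining ~25–35% of the reference are cutoff-sensitive by
  construction.
- Repeat families are linked by shared exact seeds; two diverged copies
  sharing no exact 24-mer land in different families (or are missed).
- Junction clustering reports co-locating discordant pairs; it does not
  assemble or type the underlying variant.
- The Dollo machinery is specialized to the fixed 3-leaf topology; larger
  trees would need a general small-parsimony pass.
- Ortholog inference, read mapping, homology searching and phylogeny
  reconstruction are consumed as inputs, never computed.
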