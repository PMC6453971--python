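# Methods

This note documents the models, conventions and numerical choices behind
`smacotype`, and what the synthetic-data tests do and do not establish
about behaviour on real data.

## Circular coordinates and canonical rotation

Internally every coordinate is 0-based, half-open; a feature may wrap
the linearization origin (`wraps=True`), in which case its span is
`(L − start) + end`. GFF3 output converts to 1-based inclusive
coordinates and emits wrapping features as two parts sharing one `ID`.
This arithmetic is unambiguous for wrapped features, which is why the
half-open convention was chosen over inclusive ends.

Deposited circular genomes are linearized at arbitrary points, so the
package defines a canonical rotation: when an anchor (normally the
detected origin nonanucleotide) is available the genome is rotated — and
strand-flipped for a minus-strand anchor — so the anchor starts at
position 0 on the + strand; otherwise the lexicographically minimal
rotation (Booth's algorithm) is used, which is invariant under any prior
rotation. Every rotation records an offset/flip pair; feature intervals
map bidirectionally through it, and that mapping is property-tested as a
bijection.

Input FASTA is uppercased, U→T; IUPAC ambiguity codes other than N are
coerced to N with a warning rather than rejected, because public ssDNA
records occasionally contain isolated ambiguous calls and a hard error
would block whole batches.

## ORF discovery and organization typing

ORFs are ATG-to-first-in-frame-stop on both strands, found by scanning
the doubled sequence so wrap-around ORFs appear naturally; an ORF may
not exceed one full circle. One ORF is reported per physical stop codon:
the farthest-upstream compatible ATG (the stop position on the circle
already fixes strand and frame, so this makes the ORF set rotation
invariant — a property the tests check explicitly). The default
`min_aa = 150` keeps the two real smacovirus ORFs (reported range
182–369 aa) while discarding spurious short ORFs. Alternative start
codons are off by default.

Rep is the candidate ORF whose protein carries the most Rep-motif hits,
ties broken by a Walker-A hit, then by length; CP is the longest
remaining ORF. Organization is type IV when the two sit on opposite
strands, type V when on the same strand.

## Replication origin

The nonanucleotide scan matches the degenerate pattern NAGTNTTAC on both
strands of the circle; pattern N positions match anything and up to 2
mismatches are allowed at the determined positions — the bundled study
feature table spans exactly 0, 1 and 2 mismatches, which fixed that
default. Hits are ranked by mismatch count, then (when Rep is known) by
circular distance to the Rep 3′ end; the search window for the origin is
±150 nt around the Rep 3′ end, since reported stem-loops sit near it and
both flanks are searched because "near" is not more precisely specified.

Stem-loop prediction is a pure inverted-repeat search (no thermodynamic
model, a declared non-goal): arms of 5–12 bp flanking a loop of 9–14 nt
that contains the nonanucleotide, allowing one arm mismatch; among
candidates the longest stem wins, then the shortest loop.

## Rep motif patterns

The literature prints per-genome motif strings but no consensus
definitions, so the default degenerate patterns were reverse-engineered
from the eleven reported rows and are pinned by a regression fixture
that embeds all eleven in synthetic proteins:

| motif | pattern | note |
|---|---|---|
| RCR-II | `H[WFY]Q` | anchor for RCR-I |
| RCR-III | `...Y..K` | 3 context residues + Y-x-x-K core |
| Walker-A | `G..[GH]K[TS]` | P-loop core |
| Walker-B | `[ILVW][ILV]D[ILMTV]P` | first residue distinguishes the unisense genome (L) |
| Walker-C | `[ILV][ILMT][CT]N` | |

RCR-I has no consensus of its own; it is defined positionally as the
residues immediately preceding RCR-II, anchored on the conserved
threonine at motif position 2: five residues when the T sits four before
RCR-II, six when it sits five before. This reproduces all eleven
reported strings, including the single six-residue case. Motifs are
located sequentially left-to-right, which enforces the canonical
ordering and yields at most one (leftmost) hit per motif; the column
boundaries of the reported table are ambiguous in places, so this
interpretation is pinned by the fixture but may differ from the original
annotators' in the context residues it prints.

## Pairwise identity

Identity = 100 · matches / alignment columns, computed from a global
affine-gap alignment (Biopython `PairwiseAligner`; nucleotide match +1 /
mismatch −1, protein BLOSUM62; gap open 10, extend 0.5 — recorded in all
outputs, since the original demarcation tool's parameters are not
published). Terminal-gap columns are excluded; internal gap columns
count in the denominator by default, with an `exclude-all-gap-columns`
convention available. The convention tag travels with every matrix.

Circular genomes are rotation-normalized before alignment: each genome's
anchor candidates are all of its best-scoring nonanucleotide hits (both
strands), and the reported value is the maximum identity over both
candidate sets — making the value symmetric and rotation invariant
without O(L) alignments. An exhaustive rotation search exists behind a
flag for verification on short sequences and agrees with the anchored
value in tests.

## Demarcation taxonomy

Species clustering is single linkage (connected components of the
≥ 77%-identity graph): the ICTV criterion is pairwise, and the closure
makes species well-defined groups; complete linkage is available as an
option. Threshold comparisons are inclusive (≥), fixed and tested at the
boundary. Raising the threshold only refines the partition
(property-tested).

Genus assignment is evidence-tagged per genome: **direct** when the best
reference Rep identity reaches 40% (conflicting genera resolve to the
higher percent with a logged warning); **transitive** when a
directly-assigned member of the same species cluster exists
(`same-cluster` rule), or — only if a within-study Rep identity matrix
is supplied — via the nearest directly-classified species
(`nearest-classified-species` rule); otherwise unassigned. The rule that
fired is recorded, because the verbal description of the transitive
extension admits both readings. Unisense (type V) genomes are excluded
from smacovirus demarcation and labelled "unassigned CRESS DNA virus".

## Distance-based phylogenetics

TN93 distances use the closed-form estimator (README) with pairwise
deletion of gap/N columns — 300 nt windows would otherwise lose most
sites under complete deletion — and base frequencies pooled over the
pair. A non-positive logarithm argument marks the pair saturated and
substitutes a ceiling (default 5.0 subst/site) instead of failing, so a
windowed scan never aborts on one saturated pair. No gamma-rate
correction is applied. In the equal-rate limit (P₁ = P₂ = p/6,
Q = 2p/3, equal frequencies) the estimator reduces exactly to the JC69
closed form −(3/4)ln(1 − 4p/3); the test suite verifies this to 1e-9.

Neighbor joining is the Saitou–Nei algorithm with the standard Q
criterion; ties break deterministically on the lexicographically
smallest contained-leaf label pair, so degenerate inputs give
reproducible trees. Negative branch-length estimates are clamped to
zero with the originals recorded. NJ exactly recovers additive matrices
(tested on random 5–8-taxon trees) and matches dendropy's independent NJ
on generic matrices.

Normalized RF is computed from explicitly enumerated non-trivial splits,
each canonicalized as the side containing the smallest leaf label, and
normalized by the number of splits realized in both trees — 2(n−3) for
two binary trees, and still well-defined when clamped zero-length edges
(collapsed at tolerance 1e-9) create multifurcations. Trees are
serialized as Newick with branch lengths to six decimals.

## Recombination scan

Compatibility-matrix windows start at 0, step, 2·step, …, with a final
window right-aligned to end at the alignment end if the stride would
truncate; defaults are 300/100 nt. Windows whose distance matrix cannot
be computed are masked (NaN row/column), not fatal.

The breakpoint profile counts breakpoints in 400 nt windows at 1 nt
step. The null model redistributes the same number of breakpoints
uniformly over the alignment; per-window envelopes are order statistics
of 1,000 permutation counts with the (k+1) finite-sample correction, so
envelopes are never degenerate at n_perm = 1000. Hot = observed strictly
above the 99% upper envelope; cold = strictly below the 95% lower
envelope; both are reported as maximal runs of window centers. Which
envelope defines hot vs cold is a package choice (both levels
configurable and recorded). Under a uniform null the empirical
exceedance of the 99% envelope stays within ~1–3% of window positions
(calibration test); a cluster of 30 breakpoints in a 300 nt region of a
2.5 kb alignment is called hot in ≥ 95% of seeds. Breakpoints come from
a linear MSA, so windows do not wrap.

The built-in triplet detector is convenience plumbing, not a full
recombination-detection suite (a declared non-goal): for sampled
triplets it scans informative sites with a maximum chi-square statistic
over cut points, calibrated by permuting the site pattern (199
permutations, call threshold p < 0.01), and proposes at most one
breakpoint per triplet. On planted single crossovers between divergent
parents it localizes the breakpoint within ±100 nt in ≥ 90% of
replicates while producing ≤ 1 call per 20 clonal replicates.

## Synthetic data: what it emulates and what it does not

`build_scaffold` constructs an ancestor with the real genomes' geometry:
2400–2800 nt circle, Rep of 230–290 codons carrying the six motif
strings in order (RCR-I fused immediately before RCR-II, as the
positional definition requires), CP of 270–370 codons in the configured
orientation, and a stem-loop (default 7 bp stem, 11 nt loop) holding the
nonanucleotide within 150 nt of the Rep 3′ end. Filler amino acids are
drawn from an alphabet excluding K, N, P and Q — every default motif
pattern needs at least one of those four, so filler can never complete a
spurious motif — while remaining rich in residues whose codons keep
shifted reading frames full of stop codons. Spacers carry an all-frame
stop cassette at their ends, and the whole scaffold is rejection-sampled
(up to 300 attempts) until the package's own annotator recovers exactly
the planted ORF set, origin and organization, so emitted truth is
consistent by construction.

Lineages evolve site-independently under a TN93 rate matrix
(configurable base frequencies; A↔G and C↔T rate multipliers, default 2)
normalized to one expected substitution per site per unit branch length,
down a user tree or a random ultrametric coalescent-style tree (default
root-to-tip height 0.15 subst/site, giving within-clade identities
roughly in the 75–95% band the real dataset shows). Two distortions keep
truth annotatable at high divergence and are both recorded: a protected
mask (start/stop codons, motif codons, nonanucleotide, stem arms;
~125 sites, < 5% of a 2.5 kb genome) and reversion of codons that mutate
into premature stops inside the planted ORFs. Estimator-recovery tests
therefore run on unprotected random ancestors, where the process is
exactly TN93.

Recombination events replace the acceptor's segment with the donor's in
true-alignment coordinates; no indel process is simulated (a declared
non-goal), so the true alignment is gap-free and TN93/RF arithmetic in
tests is exact. Segment edges at the sequence ends are not counted as
breakpoints.

Because of these simplifications, passing synthetic tests demonstrates
algorithmic correctness — coordinate handling, estimator exactness,
calibration, recovery power under the stated conditions — but not
robustness to indels, alignment error, rearrangements or base-composition
extremes in real data. The two acceptance checks that run on the
deposited study records (fetched once over the network) close part of
that gap: annotation of the real genomes reproduces the reported feature
table exactly, and pairwise identities match the reported values within
1 percentage point, the tolerance reflecting that the original tool's
aligner and rotation handling are unpublished.

## Problem sizes and determinism

Simulated datasets default to 8 lineages × ~2.5 kb; the property
batteries use 100 random additive trees, 200 RF oracle pairs, 50
scaffold round-trips and 20-seed calibration/power runs, which keeps the
full suite and the acceptance script to a few minutes on one CPU. Every
stochastic operation takes an explicit seed (the CLI defaults to seed 1
and logs it); identical inputs and seed reproduce byte-identical tables.
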