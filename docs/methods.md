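# Methods

## The repeat model

The package targets satellites of the CS-237 type. The monomer is a
higher-order repeat: two tandem subunits (canonically 111 bp and
126 bp, ~69–72 % mutual identity) fused into a ~237 bp unit whose
copies within an array diverge to roughly 85–94 % pairwise identity.
A derived family arises by a single internal deletion (27 bp in the
motivating case) and occupies a different genomic context: embedded,
reverse-oriented and in pairs, in the 45S rDNA intergenic spacer (IGS)
adjacent to the downstream 18S gene. Spacers between co-oriented rDNA
units are class N; the rare spacers between inverted units are class P.

## Synthetic data: what it emulates and what it does not

`simrep` plants exactly these structures. Its substitution model is
uniform random site choice with a forced change to one of the three
other bases, and no indels inside copies except through explicit
insertion lists. Consequently a copy mutated at rate *r* has expected
identity exactly 1 − *r* to its master, which makes every recovery
test analytically predictable (manifest-fidelity tests use a
1 − *r* − 3·SE floor with the binomial standard error). Defaults are
the study conditions: 3 % per-site copy divergence (the middle of the
85–94 % identity band after pairwise compounding), 20-copy desk-scale
arrays, a 3595 bp IGS carrying two reverse-oriented embedded copies
100 bp from its 18S end, and six-unit co-oriented clusters. Copy
counts are desk-scale by design; the generator does not attempt the
multi-Mbp arrays visible cytogenetically, nor sequencing-error read
simulation, nor any evolutionary history of the repeat. rRNA gene
"references" are bundled random-but-fixed surrogates of realistic
lengths (18S 1.8 kb, 5.8S 160 bp, 26S 3.4 kb, generated from a frozen
seed), so simulated-genome annotation needs no downloads; on real data
the user supplies real references. Passing tests on this generator
demonstrate algorithmic correctness under a clean substitution-only
divergence model — not robustness to assembly artifacts, nested mobile
elements, or monomer-length heterogeneity beyond what is planted.

Coordinates are 1-based inclusive everywhere in memory and in GFF3 and
JSON manifests; BED exports are 0-based half-open. A fixed (spec,
seed) pair regenerates byte-identical files.

## Alignment conventions

Scoring defaults are blastn-flavoured: match +1, mismatch −2, gap open
−5, gap extend −2 (a length-k gap costs 5 + 2k). Percent identity is
matches over all alignment columns including internal gap columns,
with end-gap columns trimmed — the convention of interactive alignment
editors, chosen so identities of length-mismatched subunits are
comparable; published identity figures computed under other
conventions can differ by a few points, which is why family-level
expectations in tests carry ±3-point bands. Dynamic programming is
delegated to `Bio.Align.PairwiseAligner`; traceback ties resolve to
the aligner's deterministic first path. No e-value statistics are
computed: a raw score floor (default half the perfect query score)
plus identity and query-coverage thresholds stand in for an e-value
cutoff, which is the binding constraint at satellite-level identities.

The local search seeds on exact words (default 10-mers), clusters
seeds into windows padded by one query length, and exhaustively
decomposes each window into disjoint local alignments by recursive
splitting around each maximal hit. On ≤5 kb subjects the resulting HSP
set matches a brute-force sliding-window Smith–Waterman oracle within
±2 bp at the ends. Cross-strand redundancy is resolved by discarding
any HSP whose subject interval is covered >50 % by a higher-scoring
one. Two presets mirror the two profiling stringencies: `relaxed`
(≥85 % identity, ≥95 % query coverage) and `strict` (≥90 % identity).

## Tandem structure

Period detection counts the distances between consecutive occurrences
of each exact 12-mer; a candidate period's support is the fraction of
the sequence covered by its voting word footprints, and candidates
longer than the word size must additionally show ≥60 % identity
between adjacent period-sized windows. Consecutive-occurrence counting
makes the fundamental period dominate its harmonics. With 12-mers the
detector is reliable down to ~85 % copy identity; at 3 % divergence
roughly half of all word positions still recur across neighbouring
copies. Periods above 2 kb are out of scope.

Segmentation tiles a region by repeatedly aligning the consensus to a
prefix of the remaining sequence (edlib, prefix mode), so copies
absorb small indels and terminal partials keep their true shorter
lengths; a remnant under a quarter monomer is dropped. Fractional copy
number is total copy length over consensus length, reported to one
decimal. Consensus building aligns every copy to the longest one and
takes per-column majorities (base beats gap on ties; bases tie-break
in A<C<G<T order); insertions relative to the anchor cannot create
columns, so the consensus never exceeds the anchor length. Array
chaining merges same-strand HSPs separated by at most two monomer
lengths — wide enough for the non-repeat insertions observed inside
real arrays, narrow enough not to fuse distinct loci — and arrays
under 2.5 copies are flagged `short` (real, but below the scale
cytogenetic detection resolves).

## HOR decomposition and indels

`decompose_subunits` scores every split point by the affine-gap global
alignment of the two resulting halves and takes the best (ties to the
smaller first subunit). The dimeric call additionally requires the
best split's inter-half identity to reach 45 % and a local off-diagonal
match of ≥20 aligned bases at ≥55 % identity; below that the monomer
is reported as a single subunit. The floor sits deliberately below the
~50–55 % subunit identities seen in derived families, and above the
~40–45 % a global alignment of unrelated sequence produces under this
scoring. Only the two-subunit model is implemented; monomers with more
internal parts decompose into their best two-way split.

Cross-family indel calls are the maximal gap runs of a global
alignment, with runs under 5 bp folded into identity rather than
called — separating a family-defining deletion from alignment jitter.
A deletion's reported position is the first deleted reference base, so
removing `reference[position-1 : position-1+length]` reconstructs the
query's gap structure exactly (a property test). When a deleted block
is flanked by repeated bases the gap can slide within the repeat;
calls are equivalent alignments, so tests pin the event length and the
reconstruction, not the exact breakpoint base. The same scanner
(30 bp event floor) powers IGS variant comparison; given only two
lengths under the collinear single-deletion model the deletion is
their difference.

## rDNA linkage

Gene hits (≥90 % identity, ≥90 % coverage) are grouped into units when
they occur in transcription order on one strand with inter-gene gaps
under 5 kb; a unit missing a gene is flagged partial. One IGS spans
each adjacent unit pair; a copy is IGS-linked when ≥90 % of its span
lies inside a spacer (near-total containment, since boundary cases are
not otherwise defined). The embedded-copy multiplicity histogram is
taken over complete spacers only, with the modal count tie-breaking
low. N/P classification uses flanking-unit orientation alone; the
protein-level evidence sometimes cited for P-configuration spacers
requires external databases and is out of scope. Embedded copies carry
their distance to the downstream 18S rather than any hard positional
filter.

## Profiling and in-silico PCR

Coverage profiles clip HSPs to fixed-size bins (10 kb default at
simulation scale; 100 kb is more natural for real chromosomes), so
summed bin coverage equals summed HSP length; array regions merge HSP
intervals with gaps of at most two monomer lengths. Genome fractions
divide the merged HSP footprint by a genome size that defaults to the
assembly's total length — an external flow-cytometry or published
genome size (e.g. 914 Mbp) is used only when explicitly supplied,
since mixing alignment coverage with an external denominator is a
reporting choice, not a computation. One fraction is reported per
named preset; strict ≤ relaxed is asserted as an invariant.

The PCR predictor requires primer sites of ≥15 bp with at most 2
mismatches and an exact 3′-terminal trio (a standard in-silico PCR
rule); every convergent site pair within the length cap yields an
amplicon spanning both primer footprints, and the ladder step is the
median difference of consecutive distinct amplicon lengths. On a clean
array with one site pair per monomer this recovers the monomer length
as the step; gel-intensity and smear modelling are out of scope.

## Problem sizes

Tests and the acceptance script run entirely on generated data:
20-copy arrays (~4.7 kb), 3–6-unit rDNA clusters (~30–60 kb
chromosomes), 1 Mb profile fixtures built directly from interval
arithmetic. These sizes exercise every code path while keeping a full
run in minutes on one CPU; the algorithms themselves have no
array-count or chromosome-count limits beyond memory.

## Known limitations

- The period detector needs exact shared words between neighbouring
  copies; below ~80 % copy identity support collapses.
- Decomposition assumes one split point; three-subunit monomers are
  approximated by their best two-way cut.
- `annotate_rdna` assembles complete gene triplets; units truncated at
  their transcription start are dropped rather than reported partial.
- Breakpoint coordinates inherit standard alignment ambiguity inside
  repeated flanking bases.
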