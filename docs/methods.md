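# Methods

`mirkit` implements an in-silico miRNA annotation study for a transcriptome
without a reference genome: known precursors from related species seed a
homology search, candidate stem-loops are excised and filtered on six
structural criteria, surviving candidates are clustered into tentative loci
and profiled, their targets are predicted by complementarity scoring in two
modes, target conservation is called against other species, and family
relationships are summarised with neighbor-joining trees.  This note
documents the models, the parameters that matter, the synthetic study the
tests run against, and the numerical choices made where the design was open.

## Candidate detection

Reference precursors are aligned against every transcript by exact local
alignment with affine gaps under BLASTN-like scoring (match +2, mismatch −3,
gap of length *k* costing 5 + 2*k*), on both strands.  Significance uses the
Karlin–Altschul expectation E = K·m·n·e^(−λS) with K = 0.41, λ = 0.625, and
hits with E > 10 are discarded.  Only the best hit per query is kept (lowest
E, ties by score then subject id), and best hits of different queries landing
on the same subject region (≥ 80% interval overlap) are collapsed to the
single best one.  The 80% overlap figure is this package's own choice for
"redundant hits"; it is exposed as a parameter.  Alignment itself is
delegated to `Bio.Align.PairwiseAligner` (exact, C-accelerated); the test
suite checks it against an independent from-scratch Smith–Waterman DP.

## Hairpin excision

A window of ±120 nt around the best hit is folded once (ViennaRNA MFE).
Every base pair whose span encloses the best-matching mature window proposes
a precursor boundary; each proposed span (capped at 300 nt, at most 8
sampled between the outermost and innermost) is refolded, and the span that
folds into a clean single stem-loop with the lowest MFEI wins.  Choosing the
boundary by folding-energy index mirrors how stem-loop excision tools trim a
pri-miRNA window to its pre-miRNA; picking e.g. the first clean hairpin
instead systematically drags decoy flanks into the precursor and dilutes its
metrics.

## The six acceptance criteria

For a folded candidate with located mature:

1. mature length 19–25 nt;
2. ≤ 2 mismatches against the closest known reference-species mature of the
   query's family (whole-length semantics: substitutions plus end overhangs,
   i.e. unit-cost edit distance, computed with edlib);
3. mature on a single arm — the terminal loop is the hairpin loop whose stem
   carries the most base pairs, and any structure in which one pair encloses
   two or more hairpin loops (a multiloop) is rejected as non-hairpin;
4. ≤ 5 mature positions unpaired or paired outside the opposite arm
   (G:U wobble counts as pairing; a switch `count_gu_as_mismatch` flips
   this, since the original convention is not documented anywhere);
5. A+U content 30–70% (inclusive on both ends);
6. MFEI ≤ −0.85, inclusive, with MFEI = AMFE / GC%, AMFE = MFE/length·100,
   GC% on the percentage scale (50, not 0.5).

The MFEI formula separates pre-miRNAs (≈ −1.0 and below) from tRNA/rRNA/mRNA
fragments (≈ −0.6); the threshold, the mismatch caps and the A+U band are
the published values and are asserted by a config self-test.  Candidates
containing ambiguity codes are rejected before folding with an explicit
reason, because mismatch counting is undefined for them.

Two folding engines share one contract: ViennaRNA MFE (default) and a
built-in Nussinov base-pair-maximisation engine (minimum loop 3, AU/GC/GU
pairs, pseudo-energy −1 per pair) used for engine-independent tests.

## Loci, names, composition

Accepted precursors differing by fewer than two whole-length mismatches are
alleles of one tentative locus.  Pairwise relations are aggregated by
single linkage — the most permissive reading of "alleles of the same
locus" — which makes the partition order-independent.  Members are named
`Ado-<reference family+variant>-<locus><allele>_<tissue initial>`
(e.g. `Ado-MIR444d-2c_b`): locus index in first-appearance order, allele
letters a, b, c… in candidate order, tissue initials b/c/l/r.  The numeric
and letter parts of this convention are an interpretation (the observed
names never come with a definition); both prefix and suffix map are
configurable.  Tissue "expression" means presence of a member in that
tissue's assembly — nothing quantitative.

Composition profiles count overall and position-specific base frequencies in
percent; positions beyond a sequence's length are excluded from that
column's denominator, so every column sums to 100.

## Target prediction

A miRNA is aligned antiparallel against candidate sites under the standard
plant penalty scheme: mismatch 1.0, G:U 0.5, indel 2.0, all doubled at
miRNA positions 2–13.  Two modes reproduce the two common predictors'
parameterisations: the windowed mode scores only the best 20-nt miRNA window
(hspsize 20) and reports sites with expectation ≤ 3.0; the full-length mode
scores the whole miRNA and reports scores < 4.0 (strict).  Sites reported by
both modes at overlapping intervals form the consensus set.  The internals
of the original programs are not published; a single auditable scorer with
two window/threshold parameterisations is this package's replacement.

Scanning a transcript pre-screens all ungapped registers with a vectorised
penalty profile (margin 3.0 above the threshold) and rescores candidates
with the exact gapped DP on a ±1-extended window.  Any reportable gapped
site carries at most one indel — two indels already cost ≥ 4.0, beyond both
thresholds — so the margin recovers them.

Inhibition type: a mismatch or gap at miRNA position 10 or 11 marks
translational inhibition, anything else transcript cleavage; G:U at those
positions counts as pairing (switchable).  The predicted cleavage point is
the transcript position paired with miRNA nt 10, the cut lying between it
and the preceding position, read off the alignment's pairing map so bulges
shift it correctly.  Target-site accessibility (UPE: energy to force the
site open, 17 nt upstream / 13 nt downstream flanks, threshold 25) is
implemented as an optional post-filter and is off by default, because the
original server's energy model is not reproducible bit-exactly.  Removal of
non-coding transcripts by protein-database search is replaced by an optional
user-supplied coding-status table (no external databases).

## Conservation calls

Each consensus target is locally aligned against per-species sets of known
target sequences; raw alignment score > 50 and query coverage > 50% (both
strict) make it a conserved homolog, otherwise novel.  The original
comparison was protein-level; this module defaults to nucleotide-level with
the same thresholds exposed as configuration, and "score" is interpreted as
the raw alignment score rather than the bit score (also configurable).

## Phylogenetics

Family members are aligned progressively: k-mer (k = 3) distances pick the
merge order, profiles are aligned by global Needleman–Wunsch with affine
gaps (open −1.0, extend −0.3, match 1, mismatch 0) so single indels stay in
one block.  An adapter loads an externally computed aligned FASTA instead.
Distances are p-distances with pairwise deletion of gap sites (the original
toolchain's distance model is unstated; p-distance is the default here).
Trees are canonical Saitou–Nei neighbor joining with ties in Q broken by
taxon label order and negative branch lengths clamped to zero.  Supports
come from column resampling with replacement (default 1000 replicates),
reported as the percentage of replicates containing each original
bipartition; rooting is by user-specified outgroup, otherwise the tree
stays unrooted.

## The synthetic study

The generator emulates the study conditions so every stage is testable
without downloads:

* **Reference set** — 14 families with a rice-like per-family locus count
  (94 loci total); family members share a base mature diverged by 1–3
  substitutions.  Mature lengths are drawn per family from the published
  catalogue distribution (20 nt 7.8%, 21 nt 85.8%, 22 nt 6.4%) and start
  with U in 85% of draws.  Three additional query species contribute
  orthologs of every locus (0–2 substitutions), emulating the multi-species
  precursor collection used for searching while one species remains the
  prediction reference — this multiplicity is what makes best-hit-per-query
  recovery of every implanted locus statistically reliable.
* **Precursors** — flank + lower stem (8–60 bp) + mature arm + loop
  (4–12 nt, A/C-rich) + star arm + complementary lower stem + flank, the
  star being the reverse complement with exactly the requested number of
  non-pairing substitutions (≤ 5 by contract).  Each construction is folded
  and must pass all six criteria; rejection sampling retries up to 100
  times and records the retry count.  Resulting lengths fall in the
  realistic 60–200 nt band.
* **Transcriptomes** — 50 implant transcripts (precursor inside random
  flanks) and 60 decoys in three classes that exercise different filters:
  uniform-random background, first-order-Markov resampled implants
  (composition kept, hairpin destroyed), and weakly folding A/U-stem
  inverted repeats.  Tissues are sampled with the published occupancy
  shares (root 32.0%, culm 26.2%, bud 22.7%, leaf 19.1%).
* **Targets** — one designed site per mRNA whose penalty equals a requested
  level exactly (verified against the scorer at 1e-9), composed from core
  mismatches (2.0), outer mismatches (1.0) and outer wobbles (0.5), with
  terminal miRNA positions left intact so both scoring modes agree;
  translation-type sites force the core mismatch onto position 10/11.
* **Homolog sets** — conserved targets receive mildly diverged (8%)
  full-length copies in four species; novel targets receive none.

What this does *not* emulate: expression levels and read sampling,
composition biases of real transcriptomes, fragmented or chimeric
assemblies, paralogous target families, and protein-level conservation.
Passing the synthetic suite therefore demonstrates the machinery is correct
and calibrated on clean signals, not that real-data recall would match.

Because family members share one mature, catalogue statistics such as the
21-nt fraction are family-correlated: with 14 families the realised fraction
in one run scatters widely around the design value.

## Problem sizes and determinism

The default synthetic study (50 implants, 60 decoys, 376 query precursors,
24 target mRNAs, 200 bootstrap replicates in the acceptance script) runs in
a few minutes on one CPU; tests use a scaled-down study (4 families, 8
implants) for everything except the full-scale recovery checks.  All
randomness flows from a single seed through `numpy.random.default_rng`;
identical config + seed reproduce identical FASTA, manifests, reports and
trees.

## Known limitations

* The seeded scan of target sites is exact for all reportable sites only
  because the thresholds cap indels at one; raising the reporting thresholds
  above 4.0 would require widening the rescoring margin.
* `whole_length_mismatches` treats every indel position as one mismatch
  (unit-cost edit distance); alignment-parameter-dependent gap placement of
  the original tools cannot be reproduced exactly.
* Bootstrap supports on families whose members are near-identical alleles
  are dominated by zero-length edges and are reported as-is.
* The multiloop rejection in criterion 3 is conservative: a genuine
  pre-miRNA inside a larger structured transcript window can be rejected if
  the chosen span retains a second hairpin.
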