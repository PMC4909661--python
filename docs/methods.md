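# Methods

## Scoring model

The sum-of-pairs score treats "aligned in the reference" as a property of
residue *identities*, never of residue letters: a residue is keyed by
(row id, 1-based position in the ungapped row). Two residues are a
reference pair when they co-occupy a scored reference column; the test
numerator counts how many of those pairs co-occupy a test column, and the
denominator is the total number of reference pairs. The defining double sum
runs over ordered pairs (j ≠ k); since the same factor of two appears in
numerator and denominator, the implementation counts unordered pairs and a
property test asserts exact rational equivalence of the two conventions.

Columns with fewer than two residues contribute zero to both sums (their
column score is zero by definition). The column score CS divides the number
of reference columns whose full residue content reappears as a single test
column by the number of scored reference columns; because the literature is
split on whether single-residue columns belong in that denominator, both
conventions are available (`ignore_single_residue_columns`, default off —
all scored columns count).

When a reference carries a core-column annotation (reliably-aligned block
ranges), the pair index and denominator are restricted to those columns by
default, matching how annotated benchmarks are normally scored; scoring the
full column range is one flag away (`use_core_mask=False`) because not all
published SPS values state which variant they used. Scoring is
case-insensitive: mixed case in curated files marks core regions, which the
explicit mask handles instead.

## Baseline aligner

The builtin aligner exists so that the sweep machinery can be exercised —
and its selection outputs validated — without external binaries. It is a
plain progressive method, deliberately minimal:

* pairwise distances: 1 − shared 3-mer fraction (normalised by the smaller
  k-mer set; k shrinks for very short sequences);
* guide tree: UPGMA with ties broken on the lexicographically smallest
  (min-label, min-label) cluster pair, so topology is deterministic;
* profile–profile alignment: three-state affine-gap dynamic programming
  (Gotoh) over expected column substitution scores `f1ᵀ S f2`, where the
  frequency vectors span residues only — gap fractions contribute nothing
  to the substitution term and are charged exclusively through the gap
  states.

Gap convention: a gap of length L costs `gop + gep·(L−1)`, terminal gaps
included. All state transitions are permitted, including a gap in one row
set directly followed by a gap in the other (two adjacent opposite gaps can
legitimately beat one very costly mismatch); tests verify the DP optimum
against exhaustive enumeration of every global alignment of short
sequences. Traceback tie-breaks prefer match/mismatch, then a gap in the
second profile, then a gap in the first, making output alignments
byte-reproducible. The DP kernel is JIT-compiled with numba; scores are
float64 throughout, and equality tie-breaks are exact comparisons on those
floats.

This aligner is *not* an emulation of MAFFT or CLUSTALW: no FFT segmenting,
no iterative refinement, no consistency objective, no weighting. Sweep
conclusions drawn with it transfer to a production aligner only in the
qualitative sense (that tuned parameters beat defaults); per-tool sweeps
should use the adapter.

## External aligner adapter

Command templates are split into argument vectors before placeholder
substitution, so no user data ever reaches a shell; templates ending in
`> {output}` have stdout captured by the adapter itself (MAFFT-style
tools). Gap penalties are formatted with their shortest round-tripping
decimal representation. Two documented caveats for MAFFT sweeps: `--ep` is
an offset, not a textbook extension penalty (values are passed verbatim),
and PAM100/PAM200 map to `--jtt 100/200` because MAFFT exposes no Dayhoff
tables — both mappings are overridable in the YAML config. Output
alignments are integrity-checked (same ids, rows ungap to the inputs)
before scoring.

## Grid and sweep

Grid values are integer multiples of the step computed in decimal
arithmetic, so combination keys are exact (`1.2`, never
`1.2000000000000002`) and serialise losslessly through the checkpoint TSV.
Default ranges are GOP ∈ [0.1, 3.0] step 0.1 and GEP ∈ [0.03, 1.50] step
0.03 with all six matrices (BLOSUM30/45/62/80, PAM100, PAM200) — wide
enough to contain every optimum reported for curated protein benchmarks,
and fully overridable. The sweep writes one record per cell as it finishes
and resumes from the checkpoint without re-invoking the aligner; failed
runs become FAILED records (excluded from means, counted per group), never
silent holes. Cells are independent, and the emitted table is always sorted
by (dataset, case, matrix, gop, gep) so artifacts do not depend on
execution order.

## Aggregation

MEAN_SPS is the unweighted mean over a dataset's cases (each reference
counts once). Argmax ties take the smallest GOP, then the smallest GEP,
then matrix list order — a deterministic preference for weaker penalties.
Reports print at 4 decimals; all comparisons happen at full precision so
rounding cannot flip a ranking. Comparison reports support two modes,
labelled in the output: *rerun* (align the cases again at each named
parameter set) and *quote* (look the cells up in an existing sweep table).

## Substitution matrices

The six canonical NCBI integer tables are loaded from biotite's matrix
database; the unit tests cross-check the BLOSUM45/62/80 tables
entry-by-entry against biopython's independently packaged copies, and all
six for symmetry, completeness and positive BLOSUM diagonals. Custom
matrices load from any NCBI-format whitespace table. Unknown residues are
normalised to X before lookup (logged once per residue), so rare codes
(U, O, J) never crash scoring.

## Synthetic families

The generator evolves a random ancestor (BLOSUM62-marginal background
frequencies) down an ultrametric balanced or caterpillar topology whose
root-to-leaf path length equals the requested divergence (expected
substitution events per site). Each event resamples the residue from the
conditional kernel `P(b|a) ∝ f_b·2^(S62(a,b)/2)`; this controls identity
bands cheaply but is explicitly not a phylogenetic rate-matrix model (no
rate heterogeneity, no codon structure, resampling may return the same
residue). Indel events are Poisson per branch (`indel_rate` × length) with
geometric lengths; insertions mint new homology columns carried only by the
inserting lineage, deletions leave gaps. Because every residue carries its
homology label through the recursion, the emitted reference alignment is
the truth by construction, and a bookkeeping test asserts each residue
occupies exactly one reference column.

The packaged presets (`RV11-like` … `RV50-like`) loosely mirror
curated-benchmark strata: the two identity-banded presets were fixed by
simulating a ladder of divergence values with the generator and choosing
the value whose mean pairwise identity lands where the stratum demands
(RV12-like: divergence 1.3, centred near 30 % identity inside the 20–40 %
band; RV11-like: divergence 2.4, below 25 %); the remaining presets vary
topology and indel-length structure (early-branching lineage for the
orphan-style set, long indels for the extension/insertion-style sets).
They are fixtures for exercising the pipeline, not reproductions of any
real benchmark — passing tests on them demonstrates the machinery, not
performance on real protein families, which additionally feature domain
architecture, conservation gradients and non-geometric indel lengths.

`perturb_alignment` degrades a reference by exiling a random fraction of
residues into fresh single-residue columns, giving scorer tests alignments
of known, monotonically controllable quality.

## Problem sizes in the shipped tests

The test suite and the acceptance script run at desk scale by choice:
families of 2–8 sequences and 30–120 ancestral sites, sweeps up to
6 cases × 18 combinations, exhaustive-enumeration oracles up to length-6
pairwise alignments, and 50-replicate calibration ensembles. The machinery
is the same at benchmark scale; only case counts and grid sizes grow.

## Known limitations

* The builtin aligner's accuracy ceiling is that of a plain progressive
  method; it exists for pipeline validation, not state-of-the-art MSA.
* MEAN_SPS over FAILED-prone external aligners depends on the failure
  convention; the default excludes failures from the mean and reports
  their count, which flatters fragile parameter combinations — inspect
  `n_failed` before trusting a winner.
* The synthetic generator's ultrametric trees make all leaves equidistant
  from the root; "orphan" behaviour is approximated by topology (an
  early-branching lineage), not by per-lineage rate variation.
* MSF output always writes 50-column interleaved blocks with GCG
  checksums; exotic MSF dialect features (weights other than 1.00,
  nucleotide types) are not emitted.
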