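# Methods

This note documents the models implemented in `bindscan`, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical conventions that matter when comparing results.

## Sliding-window ChIP enrichment

Given per-nucleotide read depth d(x) on a linear replicon, the enrichment at a
window starting at s is

    E(s) = mean(d[s, s+W)) / mean(d[B-window centered on [s, s+W)]),

sampled every `step` nucleotides. Defaults: W = 30 nt, step = 15 nt,
B = 3,000 nt. The statistic is a *local* ratio: it is exactly invariant to
rescaling the track (so libraries of different depth are comparable without
normalization) and a constant track gives E = 1 everywhere.

Conventions and edge cases:

- Coordinates are 0-based half-open, internally and in bedGraph output.
- Background windows near the replicon ends are clipped to the replicon and
  averaged over the clipped extent, rather than discarding ~1.5 kb per end.
- Windows are only emitted where the full W nucleotides fit; a trailing
  partial window is dropped.
- A window whose background mean is zero is masked (no value) rather than set
  to infinity; masks propagate through control subtraction (masked if either
  input is masked) and replicate averaging (masked only if masked in all
  inputs). Replicate enrichment tracks are averaged before the control track
  is subtracted; since both operations are window-wise means the order does
  not change the result.
- One control enrichment track may be subtracted from samples of several
  conditions or time points.
- The replicon is treated as linear; there is no wraparound.

Region calling (`call_enriched_windows`) merges maximal runs of at least
`min_consecutive` (default 2) consecutive unmasked windows at or above a
threshold into half-open regions. It is intentionally minimal — a testable
formalization of "is anything enriched here?" — not a model-based peak caller.

**Background contamination.** Because the background window is centered on the
test window, a genuine occupancy peak inflates its own background. With
fragment-scale smoothing (triangular kernel of half-width w), a site of fold f
contributes (f−1)·w extra position-units to the background integral, so the
expected peak ratio is f / (1 + (f−1)·w/B). At the defaults (w = 600,
B = 3,000) a fold-10 site reads out near 3.5, not 10. This is a property of
the statistic, not an artifact: it measures enrichment *relative to the local
neighborhood*. Recovery tests that check the planted fold is returned
numerically therefore widen the background window until the correction term
(f−1)·w/B is a few percent (B ≥ ~50·w), which is also what a user should do
when absolute fold estimates are wanted for broad peaks.

## ReDCaT SPR design and %Rmax

Test duplexes are at most 40 bp; the bottom strand carries the constant 20-nt
single-stranded capture overhang `CCTACCCTACGTCCTCCTGC` (complementary to the
chip-immobilized biotinylated linker), so designs can be loaded and stripped
serially on one chip.

Design series over a region of length L:

- **Tiling**: n oligos of fixed length placed at starts
  round(i·(L−len)/(n−1)), so the first starts at 0, the last ends at L, and
  the spacing is even. The exact historical overlap scheme for any given
  experiment is rarely printed; even placement is the natural reconstruction
  and is fully determined by (L, len, n).
- **Truncation**: member k removes k·`step` bases (default 2) from the chosen
  end, down to `min_len`; every member is a verbatim substring of the region.
- **Substitution**: for labeled repeat spans, each non-empty subset of repeats
  is kept and the remaining spans are replaced by seeded random bases of equal
  length (uniform by default, GC-matched optionally); three repeats give
  exactly 2³−1 = 7 designs of unchanged length.

Masses: ssDNA mass is the sum of average dNMP residue masses (dAMP 313.21,
dCMP 289.18, dGMP 329.21, dTMP 304.20 Da) minus 61.96 Da (5′-OH, free 3′-OH
convention); monoisotopic masses are out of scope. Protein average mass comes
from Biopython's residue tables (residues + one water). The isoelectric point
is found by bisection on the net Henderson–Hasselbalch charge under the
Bjellqvist pKa set (including residue-specific N- and C-terminal values) to a
tolerance of 0.01 pH; the in-package implementation searches the full 0–14
range, so very acidic or very basic sequences are not clamped the way some
calculators clamp them.

Normalization: for each cycle, Rmax = (MW_analyte / MW_ligand) · R_DNA · n,
where MW_ligand is the mass of the **complete captured species** — both
strands of the test duplex plus the 20-nt overhang strand — since that is what
sits on the chip; n is the assumed stoichiometry (default one analyte monomer
per duplex). %Rmax = 100 · R_protein / Rmax. Values modestly above 100 are
tolerated as noise; above 120 a warning is raised because that usually means a
wrong stoichiometry or mass. Replicate cycles are averaged per design with a
standard error (0 for a single cycle).

Footprint inference walks each truncation series from the full-length design
inward and declares binding lost at the first member whose %Rmax falls below
`loss_fraction` (default 0.2) of the full-length %Rmax; the boundary on that
side is the last-retained member's edge in region coordinates. A side on which
binding is never lost returns the region edge with a warning flag. The 20%
default makes a qualitative published "did not bind" reproducible and is
configurable; it errs by at most one truncation step per side on simulated
series.

## Repeat scanning and discovery

`scan_consensus` matches a degenerate IUPAC consensus (X accepted as a synonym
for N) at every offset. Mismatch semantics: fully degenerate columns (N/X)
always match; single-base columns count toward the `max_mismatch` budget; and
partially degenerate columns (R, Y, S, W, K, M, B, D, H, V) must be satisfied
outright — they are constraints, not soft positions. Direct repeats are
searched on the given strand by default (a direct repeat is same-strand by
definition); `both_strands=True` additionally scans the reverse complement.

`find_direct_repeats` enumerates unit lengths (default 8–14 nt), groups
non-overlapping same-strand occurrences greedily left to right (next member
within `max_span` of the previous start, Hamming distance ≤ `max_mismatch` to
every current member), suppresses low-complexity units (base-composition
Shannon entropy below 1 bit/base, so homopolymers and dinucleotide runs do not
flood the output), and removes redundant families (same-length subsets, and
families whose every member interval is contained in a longer-unit family's
members). Output order is deterministic: unit length descending, then first
start. The search is quadratic and intended for regulatory regions; sequences
over 10 kb are rejected.

`consensus_of` reduces aligned hits column-wise. Two policies: `minimal-iupac`
emits the smallest IUPAC code covering the observed bases; and
`strict-majority-else-X` emits a base only when its column frequency reaches
the `majority` threshold and `X` otherwise — the notation used when operators
are written with X placeholders. The default threshold is 0.75, so a 2-of-3
column is reported as X rather than as a weak majority call; with small member
counts (direct repeats usually have 2–4 copies) anything short of
near-unanimity is better treated as unconstrained.

## Expression readouts

Volcano classification takes DE tables (gene, log2FC, P) as input; fitting the
upstream count model is deliberately out of scope — those tables come from
dedicated tools. Thresholds follow the conventional wording: strictly
|log2FC| > 1 and inclusively P ≤ 0.01, both configurable. The P value is used
as supplied; an FDR column, if present, is passed through untouched.

For exercising the classifier on synthetic counts only, `naive_de_table`
computes log2 ratios of group-mean CPM (pseudocount 0.5) and a pooled-variance
two-sample t-test on log2 CPM. This path is labelled naive for a reason: CPM
normalization is composition-biased when many genes change in one direction
(a planted 8-fold change in 5% of genes reads out nearer 2.5 than 3 log2
units), and a t-test at n = 3 has limited power. It recovers planted signals
well enough to test the classifier (recall ≥ 0.8 at the default thresholds on
the generator's default conditions) and must not be used for real inference.

qPCR: per-primer standard curves Cq = m·log10(q) + b are fitted by ordinary
least squares to a genomic-DNA dilution series (≥3 distinct quantities);
amplification efficiency is E = 10^(−1/m) − 1, so m = −3.3219 is perfect
doubling. Technical replicates are averaged to one Cq per sample and gene
before inversion to starting quantities SQ = 10^((Cq−b)/m) (averaging in Cq
space, the scale on which replicate error is approximately symmetric). Each
sample's target SQ is divided by the mean reference-gene SQ of its group
("corresponding samples" read as per-group means; exact per-sample pairing is
available via a flag), and group means are normalized so the baseline group is
exactly 1.

## Synthetic-data generators

All generators are pure functions of their configuration including the seed
(NumPy `default_rng`), and seeds are recorded in provenance output.

- **Genomes**: i.i.d. bases at a specified GC fraction; planted motif
  instances realize degenerate positions uniformly and are recorded with their
  coordinates, so recovery is checkable exactly.
- **ChIP tracks**: control depth is Poisson(base_depth) per position; sample
  depth is Poisson(base_depth · f(x)) with f(x) = 1 + Σ (fold−1) ·
  max(0, 1 − |x−center|/w). The triangular kernel of half-width w = 600 nt
  reflects the overlap geometry of randomly sheared 300–1,000-bp fragments
  (centered near 600 bp) spanning a single bound position. Poisson noise is
  the minimal count model; overdispersion, mappability structure, GC bias and
  read-level artifacts are not emulated, so passing recovery tests demonstrate
  the statistic's correctness, not robustness to real-library pathologies.
- **SPR cycles**: each intact repeat contributes an additive ΔΔG (kcal/mol,
  negative = stabilizing) to binding, KD = KD₀ · exp(ΣΔΔG/RT) with
  RT = 0.593 kcal/mol (25 °C, the temperature SPR is run at), occupancy
  θ = c/(c+KD), analyte response θ·Rmax plus Gaussian noise, captured-DNA
  response R_DNA plus Gaussian noise. At zero noise the closed form is
  reproduced exactly, which pins the analysis path's arithmetic. The default
  analyte mass (30 kDa) is in the range of a His-tagged one-domain
  transcription factor. Repeat energies are placeholders chosen for test
  realism — no quantitative affinities are implied for any real protein.
  Mass-transport limitation, drift and regeneration artifacts are not
  modelled.
- **Counts**: per-gene baseline means are log-normal around lib_size/n_genes
  (σ = 1, mean-corrected); DE genes multiply the second group's mean by
  2^log2fc; counts are gamma-Poisson with NB dispersion 0.1 by default
  (variance = μ + φμ², a typical biological-replicate value), and dispersion 0
  is the exact Poisson limit. Library-size variation between samples and
  gene-specific dispersion trends are not emulated.

## Numerical and interface choices

- Windowed enrichment uses cumulative sums; a naive per-window loop is kept in
  the test suite as an independent oracle (agreement to 1e-9 on random tracks).
- Tiling starts use floor(x+0.5) rounding so placements are
  platform-independent; Python's banker's rounding is avoided.
- bedGraph intervals are validated on read: overlapping intervals and
  intervals past the stated replicon end are errors naming the offending line;
  uncovered positions are depth 0. Only fixed-step wiggle is read.
- TSV is the exchange format for designs, cycles, binding results, DE tables
  and Cq tables; design tables round-trip bit-identically.
- The CLI is a thin layer over the library: subcommands exit 1 on user errors
  with a one-line diagnostic and 2 on internal errors/bad usage, and simulator
  commands write a provenance JSON (config, seed, version, config digest).

## Problem sizes in the test suite

Tests run at desk scale: oracle comparisons on tracks up to 20 kb; end-to-end
ChIP recovery on a 600-kb genome with one planted site (background window
270 kb, wide relative to the 1.2-kb peak footprint, per the contamination
analysis above); replicate-convergence checks over 20 seeded simulations;
count matrices of 500–2,000 genes with 3–40 replicates per group. The full
suite completes in a few seconds.

## Known limitations

- The enrichment statistic underestimates fold for peaks whose width is not
  small relative to the background window (see above); callers wanting
  absolute fold should widen B or use an input-normalized model-based caller.
- Footprint boundaries are quantized to the truncation step and shift by one
  step when the loss threshold straddles a member's %Rmax.
- `find_direct_repeats` greedy grouping reports maximal families under a
  local rule; it is not an exhaustive maximal-clique search, and ties between
  overlapping unit lengths are resolved by preferring longer units.
- pI values depend on the pKa table; different published tables give values
  differing by a few tenths of a pH unit for the same sequence.
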