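# Methods

## Duplex thermodynamics

Duplexes are modeled with the two-state nearest-neighbor formalism: total
enthalpy and entropy are sums over adjacent base-pair doublet steps plus
initiation terms, and the melting temperature is

T_m(K) = ΔH°·1000 / (ΔS°_adj + R·ln(C_T/x)),  R = 1.9872 cal/(K·mol).

A duplex is represented as (primer, template-in-primer-frame): two equal
length 5′→3′ strings where column *i* of the frame pairs column *i* of the
primer and a Watson–Crick match is string equality. The physical bottom
strand is the frame's complement; table keys are written top-5′→3′ /
bottom-3′→5′, and lookup is symmetric under reading a step from the
opposite strand (`XY/WZ` ≡ `ZW/YX`).

Parameters (packaged in `data/nn_params.tsv`, tagged by source) are the
unified Watson–Crick set and the published single-internal-mismatch sets
for G·T, G·A, A·C, C·T and identical-base pairs. Conventions:

- **Initiation.** One general initiation term plus a per-terminal penalty
  chosen by the terminal base pair (A·T vs G·C). For a terminal *mismatch*
  no published initiation exists; the primer's terminal base class decides.
  This never gates a decision: 3′-terminal-mismatch alignments are excluded
  from specificity aggregation, and 5′-terminal mismatches contribute only
  through the (tabulated) internal-mismatch step.
- **Adjacent mismatches.** Two mismatched columns in one doublet step have
  no published parameters. In strict mode this raises an error naming the
  step and its position; in lenient mode (used for genome-wide misprime
  scoring) the step contributes (0, 0) and the position is flagged on the
  profile. Such alignments always score far below priming temperatures; the
  pseudo-step only prevents a crash, never a pass.
- **Symmetry.** A perfect self-complementary duplex receives the symmetry
  entropy term; the configuration's symmetry factor x ∈ {1, 4} covers the
  concentration side.
- **Salt.** ΔS°_adj = ΔS° + 0.368·(n_phosphates/2)·ln[Na⁺], with
  n_phosphates = 2·(length−1) per duplex (both strands, 5′-terminal
  phosphates excluded) and the sodium equivalent
  mono + 120·√(Mg − dNTP) mM (divalent term dropped when dNTPs ≥ Mg²⁺,
  since chelated magnesium is unavailable).
- **Non-physical duplexes.** If ΔH° ≥ 0 or the T_m denominator is
  non-negative there is no two-state melting solution; this raises a typed
  error (or returns a −∞ sentinel in lenient contexts), never NaN.

Default reaction conditions: 50 mM monovalent cation, 1.5 mM Mg²⁺, 0.8 mM
dNTP, C_T = 0.25 µM, x = 4. All are configurable.

### Secondary structure

Hairpin, homodimer and heterodimer stability is computed by an internal,
deliberately simple exhaustive engine rather than an external folding
library:

- **Hairpins** enumerate every stem of ≥ 3 bp with a loop of 3–30 nt; stem
  steps use the Watson–Crick table and the loop contributes a
  length-dependent closure penalty (tabulated ΔG37, interpolated between
  listed sizes, converted to an entropy). A stem must contain at least one
  G·C pair — A·T-only stems are weak nucleators and are treated as
  structureless, which also keeps the structure-poor (AT)n control at the
  no-structure sentinel. Hairpin T_m is unimolecular: ΔH·1000/ΔS, no
  strand-concentration term. A consequence worth knowing: for a perfect
  palindrome the (unimolecular) hairpin can legitimately melt above the
  (bimolecular) homodimer at 0.25 µM strands.
- **Dimers** enumerate every ungapped offset of one strand against the
  reverse of the other, trim terminal non-complementary columns, require at
  least three consecutive complementary pairs, and score with the full
  (mismatch-aware) table plus initiation. Homodimer T_m uses x = 1;
  heterodimer ΔG is evaluated at 37 °C in cal/mol and is symmetric in its
  arguments by construction.
- **Sentinels.** "No stable structure" is reported as T_m = −273.15 °C or
  ΔG = 0, far outside every filter threshold — absence of structure is a
  result, not an error.

The published heterodimer cutoff is printed as "−2000 kcal/mol" in the
source literature; the physically plausible unit is cal/mol (−2 kcal/mol).
The configuration stores the threshold in cal/mol with default −2000.

## Target region selection

Coordinates are 1-based inclusive throughout the library; BED output
converts to 0-based half-open. SNP sites are masked to 'n', indel sites to
'N' (an indel is recorded at its single POS, whatever its REF length,
matching the single-position indel encoding of dense variant resources; on
a SNP/indel collision the indel mask wins). Assembly gaps are pre-existing
runs of ≥ `gap_min` (default 100) N characters in the reference — the
conventional 100/1000-nt gap encodings — and are distinguished from
single-character variant masks. GC% excludes masked and N positions from
the denominator: masked characters are not bases. Soft-masked (lower-case)
input is uppercased on load; repeat masking plays no role in the algorithm.

## Unique oligo design

Every oligo of every length in the configured range (default 18–27 nt,
bracketing common primer lengths) is enumerated on both strands with a 1-bp
sliding window; enumeration reads the masked sequence when polymorphism
filtering is on (masked oligos then fail base composition), the raw sequence
otherwise. Filters, each a pure predicate so that the pass set is
independent of evaluation order:

- base composition: any character outside A/C/G/T;
- GC content outside 40–60 % (bounds inclusive);
- A/T at the 3′-terminal base (optional; stabilized 3′ ends prime better);
- GC clamp: more than three G/C among the last five 3′ bases (i.e. ≥ 4);
- repeats: four or more consecutive copies of a 1-nt or 2-nt unit (the
  "four units" reading of the repeat rule; the count is a setting);
- T_m outside 64–74 °C (bounds inclusive);
- hairpin or homodimer T_m above (on-target T_m − 20 °C);
- an exact occurrence of the oligo or its reverse complement anywhere in
  the genome outside its own site, found by exhaustive string search over
  both strands — a guaranteed-complete replacement for capped heuristic
  searches, which only need to find one extra match.

Oligos spanning the region's first/last base are kept; flanking-mode
enumeration restricts 3′ ends to at-or-outside a central locus within a
given flank size. Accounting is reported per category in the fixed order
sequence features → hybridization → exact match.

## Priming specificity

The scanner indexes every genomic 7-mer and, per primer and strand, seeds
windowed local alignments (match +1, mismatch −1, gap open/extend −2 — the
divergence-tolerant scoring of low-stringency searches) via Biopython's
`PairwiseAligner`; alignments with ≥ 70 % identity and a ≥ 7 consecutive
match run are kept, deduplicated, and ordered deterministically. Hits
overlapping the primer's own interval on its binding strand are discarded.
Per-subject and subject-count caps exist to emulate capped external
searches but default to off: completeness is the point at fixture scale.
An import/export path in a BLASTN-like tabular format (with aligned-row
columns) lets an external aligner substitute for the internal scanner on
genomes where exhaustive scanning is impractical.

Each hit becomes a **thermoalignment**: local alignments are truncated and
possibly gapped, so the template is re-extracted as the contiguous genomic
window of exactly primer length that anchors the primer's 3′-most *aligned*
base at its hit-assigned template coordinate, preserving strandedness.
This one rule is the net effect of the strand-specific end-filling and
gap-removal procedure (primer gaps: shift primer bases 5′ of the gap toward
the 3′ end and discard the template 5′ overhang; template gaps: shift
template bases toward the 5′ end and extend the window at the primer's 5′
side) because a maximal local alignment always ends on a matched column —
so the 3′ anchor pairing is real and unambiguous. Windows that would run
off the subject end are dropped with a logged reason. Re-extraction of the
stored window must reproduce the frame exactly; the test suite audits this
and checks the construction against an exhaustive window-enumeration oracle
with a 3′-complementarity tie-break.

Misprime T_m is computed on the full-length pair with mismatch parameters
at mismatch columns (lenient mode). Per primer, the maximum and the
90th-percentile off-target T_m are aggregated with the nearest-rank
percentile definition (ceil(0.9·n)-th order statistic; the percentile is
report-only and never filters). Thermoalignments with a mismatch at the
3′-terminal nucleotide are excluded from aggregation — such sites do not
extend under standard conditions — while mismatches at positions 2–5 from
the 3′ end are only recorded (fraction of hits). A primer passes when
on-target T_m ≥ maximum off-target T_m + threshold (default +10 °C); with
zero scoreable hits the maximum is −∞ and the primer is trivially specific.

## Primer pair selection and tiling

A pair is a forward (+ strand) and reverse (− strand) primer with
converging 3′ ends. The amplicon spans the two 5′ positions, length
stop − start + 1 (the "distance between 5′ ends" convention, inclusive).
Filters: amplicon length within range; |ΔT_m| ≤ 10 °C; the lower primer
T_m at least the misprime margin above the pair's larger off-target
maximum; heterodimer ΔG at or above the floor; optionally no assembly gap
inside the amplicon. Indel content and amplicon GC are annotated but never
filtered.

For tiling, each pair is a node; a directed edge i → j exists iff the
amplicons overlap by ≥ 1 bp, j starts after i, and j ends after i — edges
strictly increase both coordinates, so the graph is a DAG. The raw edge
weight is E = (len_i + len_j) − O_ij, the union length of the two amplicons
(the cumulative-coverage-minus-overlap reading; a union-based alternative
only shifts E by O and is not separately exposed). Within each
weakly-connected component E is transformed to W = M_g − E (M_g the
component's maximum E), making the best-covering steps the cheapest.
Per component, the W-minimal path from the minimal-start amplicons to the
maximal-stop amplicons (virtual zero-weight endpoints) is found by a
dynamic program in start order — identical to Dijkstra's relaxation order
on this DAG, and tested against networkx Dijkstra — with deterministic
tie-breaks: fewer nodes, then lexicographically smallest start tuple.
Because consecutive path amplicons overlap, every source-to-sink path
covers its component's full span; the shortest path is therefore a
maximum-coverage path and the tie-breaks select the smallest one. A
pre-pass implements the nested-amplicon exception: among amplicons sharing
a primer where one contains the others and the contained ones overlap
nothing outside the group, only the largest is kept.

Path amplicons alternate into multiplex groups A and B per subgraph; an
audit pass flips any residual intra-group overlap (possible across subgraph
boundaries) and opens additional groups with a warning only if no
two-coloring exists. Within a group no two amplicons overlap — overlapping
amplicons in one tube would yield short dominant byproducts. The minimum
set is also exported in a simple name/sequences/product-size table for
external multiplex-compatibility scoring; no compatibility scoring is done
internally.

## Synthetic study conditions

The fixture generator emulates the features of a repeat-rich, variant-dense
plant-style genome that drive every pipeline branch, at desk scale: two
25 kb chromosomes at 46 % GC; four repeat families (600 bp consensus, four
copies, 4 % per-base divergence, 20 % chance of one single-nt indel per
copy) whose first copies tile ~80 % of a 3 kb target region while sibling
copies land anywhere outside it (30 % on the minus strand); variant sites
at ~1 per 20 bp inside the target (140 SNPs, 12 two-base-REF deletions in a
VCF v4.1); and one 100-nt assembly-gap run outside the target. Repeat
coverage and variant density were chosen to match the regime the method is
for — a mostly-repetitive target where specific primers exist only in
islands — and the amplicon range used in the examples and acceptance runs
(300–1500 bp) is sized to that 3 kb target. All drawing uses a single
seeded RNG stream; output is byte-identical across runs and platforms.

What the generator does *not* emulate: real transposon structure and
nested/fragmented repeats, population haplotypes, reference assembly
errors, and genome-scale search pressure (a 50 kb genome cannot reproduce
the exact-match attrition of a multi-gigabase one). Passing tests therefore
demonstrate the correctness of the algorithms and their contracts, not
wet-lab amplification rates.

## Numerical and procedural choices

- Percentile: nearest-rank; ties in window anchoring broken by 3′-terminal-5
  complementarity, then fewer mismatches, then lower coordinate.
- T_m and GC range bounds inclusive; GC clamp strictly "more than three".
- Percent identity = identities / alignment columns (gaps count as columns),
  rounded to 3 decimals so the tabular hit format round-trips exactly.
- Scanner window pad 12 nt around a seeded placement bounds the gap shift a
  local alignment can accumulate at these identity levels.
- Problem sizes in the tests and the acceptance script (50 kb genome, 3 kb
  target, 200 random tiling instances of ≤ 12 nodes, ≥ 500 oracle-checked
  thermoalignments) are chosen so every oracle remains exhaustive.
- Determinism: fixed iteration orders, sorted outputs (coordinate, then id),
  a single RNG stream per generator; re-running a configuration reproduces
  every output file byte-for-byte (the summary's wall-clock timings aside).

## Known limitations

- No polymerase kinetics or amplification-efficiency prediction; a passing
  pair is thermodynamically sound, not guaranteed to amplify efficiently.
- No RNA or dangling-end parameters; terminal-mismatch initiation follows
  the primer-base convention described above rather than dedicated
  terminal-mismatch tables.
- The internal structure engine ignores bulges, internal loops in stems,
  and coaxial stacking; it is a screen, not a folding program.
- Single-pass selection: uncovered gaps in a tiling path do not trigger
  re-design with relaxed settings.
- Edge weights favor coverage, not amplicon-size uniformity; a size-targeted
  weighting is a noted extension point, not implemented.
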