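# amplitile

Genome-aware PCR primer design for repetitive genomes, with automated
selection of minimum amplicon tiling paths for targeted resequencing.

## The problem

Designing primers that amplify *only* their target is hard in genomes
dominated by repetitive DNA: a primer drawn from a target region typically
has many imperfect binding sites elsewhere, and counting mismatches at those
sites is a poor proxy for whether they will actually prime. `amplitile`
evaluates the *thermodynamics* of every candidate primer's binding
genome-wide. Each imperfect local alignment is first converted into a
**thermoalignment** — a full-length, ungapped pairing of the primer with a
contiguous genomic window — on which a physically meaningful melting
temperature can be computed with nearest-neighbor parameters for both
Watson–Crick pairs and single-base mismatches. A primer is accepted only if
its on-target T_m exceeds its highest off-target T_m by a margin (default
+10 °C).

For regions too large for a single amplicon, accepted primer pairs become
nodes of a directed acyclic graph whose edges join overlapping amplicons;
a shortest-path search over transformed edge weights selects the minimum
set of overlapping amplicons with maximum coverage, split into two
multiplex-compatible groups (no overlapping amplicons within a group).

## The model

Duplex stability follows the two-state nearest-neighbor model:

    ΔH°, ΔS° = Σ (doublet steps) + initiation terms
    ΔS°[Na+] = ΔS°[1 M] + 0.368 · (N/2) · ln[Na+]
    T_m(K)   = ΔH° · 1000 / (ΔS°[Na+] + R · ln(C_T / x))

with N the duplex phosphate count 2·(length−1), C_T the total strand
concentration, x = 4 for non-self-complementary duplexes, and the sodium
equivalent `[Na+] = mono + 120·√(Mg − dNTP)` (in mM) when free Mg²⁺ remains.
Doublet parameters are the published unified Watson–Crick set plus the
G·T, G·A, A·C, C·T and identical-base mismatch sets, shipped as a
tab-separated data file with per-entry source tags
(`src/amplitile/data/nn_params.tsv`).

The pipeline runs in four stages:

1. **TRS** — extract the target region; mask known variants ('n' for SNPs,
   'N' for indels) from a VCF; detect assembly-gap N runs.
2. **UOD** — enumerate every oligo of every length on both strands and apply
   the filter cascade: base composition, GC range, A/T 3′-end, GC clamp,
   short repeats, T_m range, hairpin/homodimer T_m within 20 °C of the
   on-target T_m, and genome-wide exact-match uniqueness.
3. **PSE** — seed-and-extend scan (7-mer seeds, ≥70 % identity) for
   off-target sites; thermoalignment construction; misprime T_m statistics
   (maximum and 90th percentile; 3′-terminal-mismatch sites excluded); the
   +10 °C specificity margin.
4. **PPS** — enumerate compatible pairs (amplicon size, ΔT_m ≤ 10 °C,
   misprime margin for both primers, heterodimer ΔG, optional assembly-gap
   filter), then the tiling-graph shortest path and multiplex grouping.

## Worked example

`examples/04_full_pipeline.py` generates a synthetic 50 kb two-chromosome
genome emulating a repeat-rich target: four divergent repeat families whose
first copies tile ~80 % of a 3 kb target region (their siblings, at ~4 %
divergence, create real off-target priming sites), variant sites at roughly
one per 20 bp, and an assembly gap. It then runs the full pipeline:

```
target chr1:10001-13000 GC 45.9%  140 SNPs  12 indels
enumerated oligos:            59570
after polymorphism filter:    20568
after sequence features:      4324
after Tm + self-structure:    788
genome-unique candidates:     674
pass +10 C specificity:       324
compatible primer pairs:      1458
minimum tiling path:          3 amplicons, 96.4% coverage
  multiplex group A: 2 pair(s)
  multiplex group B: 1 pair(s)
```

Reading the cascade: variant masking removes about two-thirds of the raw
oligos (any oligo touching a masked site is discarded so primers bind
monomorphic sequence); sequence-feature and hybridization filters cut to 788;
674 are exactly unique in the genome; 324 also clear the +10 °C
genome-wide specificity margin; those combine into 1,458 compatible pairs,
of which a 3-amplicon overlapping path covers 96.4 % of the target (the
residue is repeat interior where no specific primer exists — exactly the
situation the tiling search is built for).

The other examples are single-capability walkthroughs:
`01_melting_temperature.py` (duplex/mismatch T_m, salt, self-structures),
`02_offtarget_scan.py` (scanner → thermoalignment → misprime profile),
`03_tiling_path.py` (overlap graph, minimum path, multiplex groups).

A thin CLI wraps the same library code:

```bash
amplitile fixtures --outdir demo_inputs --seed 1
amplitile run config.yaml --outdir demo_run
```

where `config.yaml` holds the run parameters (target coordinates, filter
settings, reaction conditions); every setting has the study default.

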