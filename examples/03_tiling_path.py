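"""Minimum amplicon tiling: overlap graph, shortest path, multiplex groups.

Builds a toy set of candidate amplicons over a 3 kb region and selects the
minimum set of overlapping amplicons with maximum coverage.

Run:  python examples/03_tiling_path.py
"""

import math

from amplitile import pairing


def amplicon(start, stop):
    return pairing.AmpliconPair(
        fwd_id=f"F{start}", rev_id=f"R{stop}", amplicon_start=start,
        amplicon_stop=stop, tm_min_of_pair=66.0, tm_diff=1.0,
        pair_max_misprime=-math.inf, heterodimer_dg=0.0,
        contains_assembly_gap=False, contains_indel=False, amplicon_gc_pct=46.0,
    )


pairs = [
    amplicon(1, 900), amplicon(700, 1500), amplicon(800, 1900),
    amplicon(1400, 2300), amplicon(1800, 2600), amplicon(2500, 3000),
]
graph = pairing.build_tiling_graph(pairs)
print(f"{len(pairs)} candidate amplicons, "
      f"{graph.graph.number_of_edges()} overlap edges")

result = pairing.minimum_tiling_path(graph, region_interval=(1, 3000))
result = pairing.split_multiplex_groups(result)
for i, path in enumerate(result.paths, 1):
    print(f"subgraph {i} minimum path:")
    for pid in path:
        p = result.pairs[pid]
        print(f"  {pid}: {p.amplicon_start}-{p.amplicon_stop} "
              f"({p.amplicon_length} bp)")
print(f"coverage: {100 * result.coverage_fraction:.1f}% of the region")
print(f"uncovered gaps: {result.uncovered or 'none'}")
for name, members in result.multiplex_groups.items():
    print(f"multiplex group {name}: {members}")
print("\nEach group contains only non-overlapping amplicons, so its pairs can")
print("share one PCR tube without short overlap products dominating.")
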