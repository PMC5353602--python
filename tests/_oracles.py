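"""Independent oracles used by the test suite.

These deliberately do not share code paths with the package: the Tm oracle
is Biopython's nearest-neighbor implementation of the same published model;
the thermoalignment oracle enumerates every candidate genomic window; the
tiling oracle enumerates every source-to-sink path of a graph.
"""

from __future__ import annotations

import itertools

import networkx as nx
from Bio.SeqUtils import MeltingTemp as mt

_COMP = str.maketrans("ACGTN", "TGCAN")


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def tm_oracle(primer: str, frame: str) -> float:
    """Tm via Biopython's independently coded summation of the published
    tables, at the study conditions (50 mM monovalent, 1.5 mM Mg, 0.8 mM
    dNTP, C_T = 0.25 uM split between two strands)."""
    return mt.Tm_NN(
        primer,
        c_seq=complement(frame),
        nn_table=mt.DNA_NN4,
        imm_table=mt.DNA_IMM1,
        Na=50,
        Mg=1.5,
        dNTPs=0.8,
        saltcorr=5,
        dnac1=125,
        dnac2=125,
    )


def anchor_from_alignment(hit) -> tuple[int, int]:
    """(primer_pos, +strand coord) of the 3'-most aligned primer base,
    found by walking the gapped alignment columns from the 3' end."""
    qpos = hit.primer_aln_stop + 1
    # count real subject bases consumed, walking from the right
    consumed = 0
    anchor_offset = None
    for a, b in zip(reversed(hit.aligned_primer), reversed(hit.aligned_subject)):
        if a != "-":
            qpos -= 1
        if b != "-":
            consumed += 1
        if a != "-" and b != "-":
            anchor_offset = consumed  # subject bases from the 3' end, inclusive
            break
    assert anchor_offset is not None
    if hit.subject_strand == "+":
        coord = hit.subject_stop - (anchor_offset - 1)
    else:
        coord = hit.subject_start + (anchor_offset - 1)
    return qpos, coord


def thermoalignment_window_oracle(hit, primer_seq: str, genome) -> tuple[int, int] | None:
    """Exhaustive window enumeration: every full-length genomic window
    overlapping the hit, scored by (anchor satisfied, 3'-terminal-5
    complementarity, fewer mismatches, lower start coordinate)."""
    L = len(primer_seq)
    chrom_len = genome.length(hit.subject_name)
    qpos, coord = anchor_from_alignment(hit)
    lo = max(1, hit.subject_start - 2 * L)
    hi = min(chrom_len, hit.subject_stop + 2 * L)
    best = None
    for start in range(lo, hi - L + 2):
        stop = start + L - 1
        if stop < hit.subject_start or start > hit.subject_stop:
            continue  # must overlap the hit
        window = genome.slice(hit.subject_name, start, stop)
        frame = window if hit.subject_strand == "+" else revcomp(window)
        # position of primer base `qpos` in this window, orientation-aware
        if hit.subject_strand == "+":
            anchored = start + qpos - 1 == coord
        else:
            anchored = stop - qpos + 1 == coord
        comp5 = sum(1 for a, b in zip(primer_seq[-5:], frame[-5:]) if a == b)
        mism = sum(1 for a, b in zip(primer_seq, frame) if a != b)
        key = (not anchored, -comp5, mism, start)
        if best is None or key < best[0]:
            best = (key, (start, stop))
    if best is None or best[0][0]:  # no anchored window (boundary case)
        return None
    return best[1]


def brute_force_paths(graph: nx.DiGraph, pairs: dict):
    """All source-to-sink simple paths per weakly-connected component,
    with their total transformed weight, coverage and node count."""
    results = []
    for comp in nx.weakly_connected_components(graph):
        sub = graph.subgraph(comp)
        min_start = min(pairs[n][0] for n in comp)
        max_stop = max(pairs[n][1] for n in comp)
        sources = [n for n in comp if pairs[n][0] == min_start]
        sinks = [n for n in comp if pairs[n][1] == max_stop]
        paths = []
        for s, t in itertools.product(sources, sinks):
            if s == t:
                paths.append([s])
            else:
                paths.extend(nx.all_simple_paths(sub, s, t))
        entries = []
        for p in paths:
            w = sum(sub[u][v]["W"] for u, v in zip(p, p[1:]))
            covered = coverage_of(p, pairs)
            entries.append({"path": p, "W": w, "n": len(p), "coverage": covered})
        results.append(entries)
    return results


def coverage_of(path, pairs: dict) -> int:
    ivs = sorted(pairs[n] for n in path)
    total = 0
    cur_lo, cur_hi = ivs[0]
    for lo, hi in ivs[1:]:
        if lo <= cur_hi + 1:
            cur_hi = max(cur_hi, hi)
        else:
            total += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
    total += cur_hi - cur_lo + 1
    return total
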