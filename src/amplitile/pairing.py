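"""Primer-pair selection (PPS): compatible pairs, tiling graph, minimum path.

Compatible forward/reverse pairs are annotated as expected amplicons
(amplicon span = the two primers' 5' positions, inclusive). For regions too
large for one amplicon, pairs become nodes of a directed graph: an edge
i -> j joins overlapping amplicons where j starts after and ends after i.
Raw edge weight E = (len_i + len_j) - O_ij (the union length of the pair);
within each weakly-connected component E is flipped to W = M_g - E with M_g
the component's maximum E, so that the best-covering, least-overlapping
steps carry the smallest weights and a shortest-path search (Dijkstra on the
DAG, here an equivalent dynamic program with deterministic tie-breaks)
yields the minimum amplicon tiling path. The path is finally alternated into
two multiplex candidate groups with no intra-group amplicon overlap.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import networkx as nx

from . import thermo
from ._dna import gc_percent
from .design import CandidateOligo
from .genome import TargetRegion
from .specificity import MisprimeProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PPSSettings:
    amplicon_len_min: int = 300
    amplicon_len_max: int = 2000
    tm_diff_max: float = 10.0
    misprime_margin: float = 10.0
    heterodimer_floor: float = -2000.0  # cal/mol; pairs below are dropped
    gap_filter_enabled: bool = True


@dataclass
class AmpliconPair:
    """A forward/reverse primer pair with expected-amplicon annotations."""

    fwd_id: str
    rev_id: str
    amplicon_start: int  # forward primer 5' position
    amplicon_stop: int   # reverse primer 5' position
    tm_min_of_pair: float
    tm_diff: float
    pair_max_misprime: float
    heterodimer_dg: float
    contains_assembly_gap: bool
    contains_indel: bool
    amplicon_gc_pct: float

    @property
    def pair_id(self) -> str:
        return f"{self.fwd_id}|{self.rev_id}"

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_stop - self.amplicon_start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return self.amplicon_start, self.amplicon_stop


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def enumerate_pairs(
    candidates: list[CandidateOligo],
    profiles: dict[str, MisprimeProfile],
    region: TargetRegion,
    settings: PPSSettings = PPSSettings(),
    conditions: thermo.ReactionConditions = thermo.DEFAULT_CONDITIONS,
    table: thermo.NNParameterTable | None = None,
) -> list[AmpliconPair]:
    """All compatible forward/reverse pairs.

    A pair passes when: amplicon length in range; |Tm_f - Tm_r| <= tm_diff_max;
    min(Tm_f, Tm_r) >= max misprime Tm of both primers + misprime_margin;
    heterodimer dG >= floor; and (when the gap filter is on) no assembly gap
    inside the amplicon. Indel content is annotated, never filtered.
    """
    table = table or thermo.default_table()
    fwd = sorted(
        (c for c in candidates if c.strand == "F"), key=lambda c: c.five_prime_pos
    )
    rev = sorted(
        (c for c in candidates if c.strand == "R"), key=lambda c: c.five_prime_pos
    )
    rev_pos = [r.five_prime_pos for r in rev]
    mask_indels = [
        p for p in range(region.start, region.stop + 1)
        if region.masked_seq[p - region.start] == "N"
        and not any(lo <= p <= hi for lo, hi in region.summary.gap_runs)
    ]
    pairs: list[AmpliconPair] = []
    for f in fwd:
        if f.id not in profiles or f.tm_on_target is None:
            raise ValueError(f"candidate {f.id} lacks a misprime profile")
        lo = bisect_left(rev_pos, f.five_prime_pos + settings.amplicon_len_min - 1)
        hi = bisect_right(rev_pos, f.five_prime_pos + settings.amplicon_len_max - 1)
        for r in rev[lo:hi]:
            if r.three_prime_pos <= f.three_prime_pos:
                continue  # primers must converge
            tm_f, tm_r = f.tm_on_target, r.tm_on_target
            if abs(tm_f - tm_r) > settings.tm_diff_max:
                continue
            pair_max_mis = max(
                profiles[f.id].tm_offtarget_max, profiles[r.id].tm_offtarget_max
            )
            if min(tm_f, tm_r) < pair_max_mis + settings.misprime_margin:
                continue
            start, stop = f.five_prime_pos, r.five_prime_pos
            has_gap = any(
                _overlap((start, stop), run) for run in region.summary.gap_runs
            )
            if settings.gap_filter_enabled and has_gap:
                continue
            dg = thermo.heterodimer_dg(f.sequence, r.sequence, conditions, table)
            if dg < settings.heterodimer_floor:
                continue
            has_indel = any(start <= p <= stop for p in mask_indels)
            amplicon_seq = region.masked_seq[
                start - region.start : stop - region.start + 1
            ]
            pairs.append(
                AmpliconPair(
                    fwd_id=f.id,
                    rev_id=r.id,
                    amplicon_start=start,
                    amplicon_stop=stop,
                    tm_min_of_pair=min(tm_f, tm_r),
                    tm_diff=abs(tm_f - tm_r),
                    pair_max_misprime=pair_max_mis,
                    heterodimer_dg=dg,
                    contains_assembly_gap=has_gap,
                    contains_indel=has_indel,
                    amplicon_gc_pct=gc_percent(amplicon_seq),
                )
            )
    pairs.sort(key=lambda p: (p.amplicon_start, p.amplicon_stop, p.pair_id))
    return pairs


@dataclass
class TilingGraph:
    """Directed amplicon-overlap graph with transformed edge weights.

    Nodes are pair ids carrying their AmpliconPair; edge i -> j exists iff
    the amplicons overlap by >= 1 bp, start_i < start_j and stop_j > stop_i
    (edges strictly increase both coordinates, so the graph is acyclic).
    E = union length of the two amplicons; W = M_g - E with M_g the maximum
    E within the edge's weakly-connected component.
    """

    graph: nx.DiGraph
    pairs: dict[str, AmpliconPair]

    @property
    def components(self) -> list[set[str]]:
        comps = list(nx.weakly_connected_components(self.graph))
        return sorted(
            comps, key=lambda c: min(self.pairs[n].amplicon_start for n in c)
        )


def build_tiling_graph(pairs: list[AmpliconPair]) -> TilingGraph:
    if not pairs:
        raise ValueError("no pairs to build a tiling graph from")
    g = nx.DiGraph()
    by_id = {p.pair_id: p for p in pairs}
    ordered = sorted(pairs, key=lambda p: (p.amplicon_start, p.amplicon_stop, p.pair_id))
    for p in ordered:
        g.add_node(p.pair_id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if b.amplicon_start > a.amplicon_stop:
                break  # sorted by start: no further overlaps with a
            if a.amplicon_start < b.amplicon_start and b.amplicon_stop > a.amplicon_stop:
                o = _overlap(a.interval, b.interval)
                e = a.amplicon_length + b.amplicon_length - o
                g.add_edge(a.pair_id, b.pair_id, E=e)
    for comp in nx.weakly_connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges():
            m_g = max(d["E"] for _, _, d in sub.edges(data=True))
            for u, v, d in sub.edges(data=True):
                g[u][v]["W"] = m_g - d["E"]
    return TilingGraph(g, by_id)


@dataclass
class TilingResult:
    """Minimum tiling paths per subgraph, coverage accounting, multiplex groups."""

    paths: list[list[str]]  # ordered pair ids per subgraph
    covered: list[tuple[int, int]]  # merged genomic intervals
    coverage_fraction: float
    uncovered: list[tuple[int, int]]
    multiplex_groups: dict[str, list[str]] = field(default_factory=dict)
    pairs: dict[str, AmpliconPair] = field(default_factory=dict)


def prune_nested_shared_primer(tg: TilingGraph) -> list[str]:
    """The single-amplicon exception: among amplicons sharing a primer where
    one contains the others and the contained ones overlap nothing outside
    the shared-primer group, only the maximum-coverage amplicon is retained.
    Returns the dropped pair ids."""
    pairs = list(tg.pairs.values())
    dropped: set[str] = set()
    for key in ("fwd_id", "rev_id"):
        groups: dict[str, list[AmpliconPair]] = {}
        for p in pairs:
            groups.setdefault(getattr(p, key), []).append(p)
        for members in groups.values():
            if len(members) < 2:
                continue
            members = [m for m in members if m.pair_id not in dropped]
            if len(members) < 2:
                continue
            best = max(members, key=lambda p: (p.amplicon_length, p.pair_id))
            outside = [
                q for q in pairs
                if q.pair_id not in {m.pair_id for m in members}
                and q.pair_id not in dropped
            ]
            for m in members:
                if m.pair_id == best.pair_id:
                    continue
                nested = (
                    best.amplicon_start <= m.amplicon_start
                    and m.amplicon_stop <= best.amplicon_stop
                )
                external = any(_overlap(m.interval, q.interval) for q in outside)
                if nested and not external:
                    dropped.add(m.pair_id)
    for pid in dropped:
        tg.graph.remove_node(pid)
        del tg.pairs[pid]
    return sorted(dropped)


def _component_path(tg: TilingGraph, comp: set[str]) -> list[str]:
    """W-minimal source-to-sink path in one component.

    Sources are the amplicons with the component's minimal start, sinks those
    with its maximal stop (virtual zero-weight endpoints). Tie-breaks: fewer
    nodes, then lexicographically smallest start-coordinate tuple. Implemented
    as a dynamic program over the DAG (nodes in start order), which for
    non-negative W is exactly Dijkstra's relaxation order.
    """
    pairs = tg.pairs
    nodes = sorted(
        comp, key=lambda n: (pairs[n].amplicon_start, pairs[n].amplicon_stop, n)
    )
    min_start = min(pairs[n].amplicon_start for n in comp)
    max_stop = max(pairs[n].amplicon_stop for n in comp)
    sources = {n for n in comp if pairs[n].amplicon_start == min_start}
    sinks = {n for n in comp if pairs[n].amplicon_stop == max_stop}
    # cost: (total W, node count, starts tuple)
    best: dict[str, tuple] = {}
    back: dict[str, str | None] = {}
    for n in nodes:
        if n in sources:
            best[n] = (0.0, 1, (pairs[n].amplicon_start,))
            back[n] = None
        for pred in tg.graph.predecessors(n):
            if pred not in best:
                continue
            w = tg.graph[pred][n]["W"]
            c = best[pred]
            cand = (c[0] + w, c[1] + 1, c[2] + (pairs[n].amplicon_start,))
            if n not in best or cand < best[n]:
                best[n] = cand
                back[n] = pred
    finish = min((best[n], n) for n in sinks if n in best)[1]
    path = [finish]
    while back[path[-1]] is not None:
        path.append(back[path[-1]])
    return path[::-1]


def minimum_tiling_path(
    tg: TilingGraph,
    region_interval: tuple[int, int] | None = None,
    apply_exception: bool = True,
) -> TilingResult:
    """Minimum amplicon tiling path per subgraph plus coverage accounting.

    Every source-to-sink path in a component covers the component's full
    span (consecutive path amplicons overlap), so the W-shortest path is a
    maximum-coverage path; the tie-breaks make the output deterministic.
    An isolated node is its own path.
    """
    if apply_exception:
        dropped = prune_nested_shared_primer(tg)
        if dropped:
            logger.info("single-amplicon exception dropped %d pairs", len(dropped))
    paths = [_component_path(tg, comp) for comp in tg.components]
    intervals = sorted(
        tg.pairs[n].interval for path in paths for n in path
    )
    covered: list[list[int]] = []
    for lo, hi in intervals:
        if covered and lo <= covered[-1][1] + 1:
            covered[-1][1] = max(covered[-1][1], hi)
        else:
            covered.append([lo, hi])
    covered_t = [tuple(c) for c in covered]
    uncovered: list[tuple[int, int]] = []
    frac = math.nan
    if region_interval is not None:
        rlo, rhi = region_interval
        cursor = rlo
        n_cov = 0
        for lo, hi in covered_t:
            lo, hi = max(lo, rlo), min(hi, rhi)
            if hi < lo:
                continue
            if lo > cursor:
                uncovered.append((cursor, lo - 1))
            n_cov += hi - lo + 1
            cursor = max(cursor, hi + 1)
        if cursor <= rhi:
            uncovered.append((cursor, rhi))
        frac = n_cov / (rhi - rlo + 1)
    return TilingResult(
        paths=paths,
        covered=covered_t,
        coverage_fraction=frac,
        uncovered=uncovered,
        pairs=dict(tg.pairs),
    )


def split_multiplex_groups(result: TilingResult) -> TilingResult:
    """Assign path amplicons alternately to groups A and B per subgraph, then
    audit: any residual intra-group overlap (possible across subgraph
    boundaries) flips the later amplicon; if a conflict survives both groups,
    extra groups are opened with a warning rather than failing."""
    assignment: dict[str, str] = {}
    for path in result.paths:
        for i, pid in enumerate(path):
            assignment[pid] = "A" if i % 2 == 0 else "B"
    ordered = sorted(
        assignment, key=lambda pid: result.pairs[pid].interval
    )

    def conflicts(pid: str, group: str) -> bool:
        iv = result.pairs[pid].interval
        return any(
            other != pid
            and assignment.get(other) == group
            and _overlap(iv, result.pairs[other].interval)
            for other in placed
        )

    placed: list[str] = []
    extra = 0
    for pid in ordered:
        g = assignment[pid]
        if conflicts(pid, g):
            flipped = "B" if g == "A" else "A"
            if not conflicts(pid, flipped):
                assignment[pid] = flipped
            else:
                extra += 1
                new = f"extra_{extra}"
                logger.warning(
                    "no 2-coloring without overlap: %s placed in group %s", pid, new
                )
                assignment[pid] = new
        placed.append(pid)
    groups: dict[str, list[str]] = {"A": [], "B": []}
    for pid in ordered:
        groups.setdefault(assignment[pid], []).append(pid)
    result.multiplex_groups = groups
    return result
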