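"""Pair enumeration, the tiling graph, minimum paths and multiplex groups."""

from __future__ import annotations

import math
import random

import networkx as nx
import pytest

from amplitile import genome as gmod, pairing, specificity
from amplitile.design import CandidateOligo, oligo_id

from ._oracles import brute_force_paths, coverage_of


def make_candidate(chrom, five, length, strand, tm):
    three = five + length - 1 if strand == "F" else five - length + 1
    # purine-only placeholder: two A/G strands cannot base-pair, so the
    # heterodimer screen is inert in these rule-arithmetic tests
    seq = ("AGGAGAGGAAGAGGAGAAGGAGAGGAG")[:length]
    o = CandidateOligo(
        id=oligo_id(chrom, five, length, strand), sequence=seq, strand=strand,
        five_prime_pos=five, three_prime_pos=three, chrom=chrom, gc_pct=50.0,
    )
    o.tm_on_target = tm
    return o


def make_profile(oid, on, off=-math.inf):
    return specificity.MisprimeProfile(
        primer_id=oid, tm_on_target=on, n_hits_scored=0,
        tm_offtarget_max=off, tm_offtarget_p90=off,
        frac_hits_with_last5_mismatch=0.0, pass_specificity=True,
    )


def pair_at(start, stop, fwd=None, rev=None):
    return pairing.AmpliconPair(
        fwd_id=fwd or f"F{start}", rev_id=rev or f"R{stop}",
        amplicon_start=start, amplicon_stop=stop, tm_min_of_pair=65.0,
        tm_diff=1.0, pair_max_misprime=-math.inf, heterodimer_dg=0.0,
        contains_assembly_gap=False, contains_indel=False, amplicon_gc_pct=50.0,
    )


def toy_region(length=2000, gap=None, indel=None):
    rng = random.Random(0)
    seq = list("".join(rng.choice("ACGT") for _ in range(length)))
    if gap:
        lo, n = gap
        seq[lo - 1 : lo - 1 + n] = ["N"] * n
    g = gmod.ReferenceGenome({"c": "".join(seq)})
    mask = gmod.VariantMask()
    if indel:
        mask.add("c", indel, "indel")
    return gmod.extract_masked_region(g, "c", 1, length, mask=mask)


class TestEnumeratePairs:
    def _inputs(self, region, pairs_spec):
        cands, profiles = [], {}
        for five, length, strand, tm in pairs_spec:
            c = make_candidate("c", five, length, strand, tm)
            cands.append(c)
            profiles[c.id] = make_profile(c.id, tm)
        return cands, profiles

    def test_amplicon_length_is_five_prime_distance_inclusive(self):
        region = toy_region()
        cands, profiles = self._inputs(
            region, [(100, 20, "F", 65.0), (599, 20, "R", 66.0)]
        )
        (pair,) = pairing.enumerate_pairs(
            cands, profiles, region,
            pairing.PPSSettings(amplicon_len_min=100, amplicon_len_max=1000),
        )
        assert pair.amplicon_length == 500
        assert (pair.amplicon_start, pair.amplicon_stop) == (100, 599)

    def test_tm_difference_and_misprime_margin_rules(self):
        region = toy_region()
        settings = pairing.PPSSettings(amplicon_len_min=100, amplicon_len_max=1000)
        # tm diff 9 with margins satisfied (misprime max 50): passes
        cands, profiles = self._inputs(
            region, [(100, 20, "F", 65.0), (599, 20, "R", 74.0)]
        )
        for p in profiles.values():
            p.tm_offtarget_max = 50.0
        assert len(pairing.enumerate_pairs(cands, profiles, region, settings)) == 1
        # tm diff 11: fails
        cands, profiles = self._inputs(
            region, [(100, 20, "F", 63.0), (599, 20, "R", 74.0)]
        )
        assert pairing.enumerate_pairs(cands, profiles, region, settings) == []
        # margin violated: min tm 65 < misprime 58 + 10
        cands, profiles = self._inputs(
            region, [(100, 20, "F", 65.0), (599, 20, "R", 66.0)]
        )
        profiles[cands[0].id].tm_offtarget_max = 58.0
        assert pairing.enumerate_pairs(cands, profiles, region, settings) == []

    def test_gap_filter_excludes_spanning_amplicons_and_annotates(self):
        region = toy_region(gap=(300, 100))
        cands, profiles = self._inputs(
            region, [(100, 20, "F", 65.0), (599, 20, "R", 66.0)]
        )
        on = pairing.PPSSettings(amplicon_len_min=100, amplicon_len_max=1000,
                                 gap_filter_enabled=True)
        off = pairing.PPSSettings(amplicon_len_min=100, amplicon_len_max=1000,
                                  gap_filter_enabled=False)
        assert pairing.enumerate_pairs(cands, profiles, region, on) == []
        (pair,) = pairing.enumerate_pairs(cands, profiles, region, off)
        assert pair.contains_assembly_gap

    def test_indel_annotated_but_not_filtered(self):
        region = toy_region(indel=400)
        cands, profiles = self._inputs(
            region, [(100, 20, "F", 65.0), (599, 20, "R", 66.0)]
        )
        (pair,) = pairing.enumerate_pairs(
            cands, profiles, region,
            pairing.PPSSettings(amplicon_len_min=100, amplicon_len_max=1000),
        )
        assert pair.contains_indel

    def test_primers_must_converge(self):
        region = toy_region()
        # reverse primer 3' end inside/behind the forward primer: rejected
        cands, profiles = self._inputs(
            region, [(100, 20, "F", 65.0), (130, 20, "R", 66.0)]
        )
        assert pairing.enumerate_pairs(
            cands, profiles, region,
            pairing.PPSSettings(amplicon_len_min=10, amplicon_len_max=100),
        ) == []


class TestTilingGraph:
    def test_edge_weight_is_union_length(self):
        tg = pairing.build_tiling_graph([pair_at(1, 600), pair_at(400, 1000)])
        (edge,) = tg.graph.edges(data=True)
        assert edge[2]["E"] == 1000  # union of [1,600] and [400,1000]
        assert edge[2]["W"] == 0  # single edge: M_g == E

    def test_disjoint_amplicons_form_two_subgraphs(self):
        tg = pairing.build_tiling_graph([pair_at(1, 600), pair_at(700, 1200)])
        assert tg.graph.number_of_edges() == 0
        assert len(tg.components) == 2

    def test_ordering_condition_is_strict(self):
        # same stop: neither direction satisfies "ends after"
        tg = pairing.build_tiling_graph([pair_at(400, 1000), pair_at(350, 1000)])
        assert tg.graph.number_of_edges() == 0
        # containment: no edge either way
        tg = pairing.build_tiling_graph([pair_at(300, 900), pair_at(400, 800)])
        assert tg.graph.number_of_edges() == 0

    def test_graph_is_acyclic(self):
        rng = random.Random(1)
        pairs = [
            pair_at(s, s + rng.randint(200, 900))
            for s in sorted(rng.sample(range(1, 3000), 15))
        ]
        tg = pairing.build_tiling_graph(pairs)
        assert nx.is_directed_acyclic_graph(tg.graph)


class TestMinimumTilingPath:
    def test_unique_chain_is_returned(self):
        pairs = [pair_at(1, 600), pair_at(400, 1000), pair_at(900, 1500)]
        tg = pairing.build_tiling_graph(pairs)
        result = pairing.minimum_tiling_path(tg, (1, 1500))
        assert [p for path in result.paths for p in path] == [
            pairs[0].pair_id, pairs[1].pair_id, pairs[2].pair_id
        ]
        assert result.coverage_fraction == 1.0
        assert result.uncovered == []

    def test_isolated_node_is_its_own_path(self):
        tg = pairing.build_tiling_graph([pair_at(100, 500)])
        result = pairing.minimum_tiling_path(tg, (1, 1000))
        assert result.paths == [[pair_at(100, 500).pair_id]]
        assert result.uncovered == [(1, 99), (501, 1000)]
        assert result.coverage_fraction == pytest.approx(401 / 1000)

    def test_shared_primer_nested_exception_keeps_largest(self):
        shared_f = "Fshared"
        pairs = [
            pair_at(100, 600, fwd=shared_f),
            pair_at(100, 900, fwd=shared_f),  # same forward primer, larger
        ]
        tg = pairing.build_tiling_graph(pairs)
        result = pairing.minimum_tiling_path(tg, (100, 900))
        kept = [p for path in result.paths for p in path]
        assert kept == [pairs[1].pair_id]

    def test_nested_pair_with_external_overlap_is_retained(self):
        shared_f = "Fshared"
        pairs = [
            pair_at(100, 600, fwd=shared_f),
            pair_at(100, 900, fwd=shared_f),
            pair_at(500, 1400),  # overlaps the smaller nested amplicon too
        ]
        tg = pairing.build_tiling_graph(pairs)
        pairing.prune_nested_shared_primer(tg)
        assert len(tg.pairs) == 3

    def test_random_graphs_reach_brute_force_coverage_with_minimal_nodes(self):
        rng = random.Random(42)
        for _ in range(200):
            n = rng.randint(3, 12)
            pairs = []
            seen = set()
            for _k in range(n):
                s = rng.randint(1, 3000)
                e = s + rng.randint(200, 1500)
                if (s, e) in seen:
                    continue
                seen.add((s, e))
                pairs.append(pair_at(s, e))
            tg = pairing.build_tiling_graph(pairs)
            iv = {p.pair_id: p.interval for p in pairs}
            oracle = brute_force_paths(tg.graph, iv)
            result = pairing.minimum_tiling_path(
                tg, apply_exception=False
            )
            by_comp = {}
            for path in result.paths:
                by_comp[frozenset(
                    c for comp in tg.components for c in comp
                    if path[0] in comp
                )] = path
            for comp, entries in zip(tg.components, oracle):
                path = next(p for p in result.paths if p[0] in comp)
                best_cov = max(e["coverage"] for e in entries)
                cov_max = [e for e in entries if e["coverage"] == best_cov]
                min_nodes = min(e["n"] for e in cov_max)
                got_cov = coverage_of(path, iv)
                assert got_cov == best_cov
                assert len(path) == min_nodes

    def test_dijkstra_agrees_with_dag_dynamic_program(self):
        """Total transformed weight of the selected path equals the true
        shortest-path weight through virtual source/sink by Dijkstra."""
        rng = random.Random(43)
        for _ in range(100):
            n = rng.randint(3, 12)
            pairs = [
                pair_at(s, s + rng.randint(200, 1500))
                for s in rng.sample(range(1, 3000), n)
            ]
            pairs = list({p.pair_id: p for p in pairs}.values())
            tg = pairing.build_tiling_graph(pairs)
            result = pairing.minimum_tiling_path(tg, apply_exception=False)
            for comp, path in zip(tg.components, result.paths):
                sub = tg.graph.subgraph(comp)
                aug = nx.DiGraph()
                aug.add_edges_from(
                    (u, v, {"W": d["W"]}) for u, v, d in sub.edges(data=True)
                )
                min_start = min(tg.pairs[x].amplicon_start for x in comp)
                max_stop = max(tg.pairs[x].amplicon_stop for x in comp)
                for x in comp:
                    if tg.pairs[x].amplicon_start == min_start:
                        aug.add_edge("SRC", x, W=0)
                    if tg.pairs[x].amplicon_stop == max_stop:
                        aug.add_edge(x, "SNK", W=0)
                ref = nx.dijkstra_path_length(aug, "SRC", "SNK", weight="W")
                got = sum(
                    tg.graph[u][v]["W"] for u, v in zip(path, path[1:])
                )
                assert got == ref

    def test_widening_amplicon_range_never_reduces_coverage(self):
        rng = random.Random(44)
        for _ in range(30):
            spots = sorted(rng.sample(range(1, 4000), 14))
            all_pairs = [
                pair_at(s, s + rng.randint(100, 2000)) for s in spots
            ]
            covs = []
            for max_len in (600, 1200, 2400):
                subset = [
                    p for p in all_pairs if p.amplicon_length <= max_len
                ]
                if not subset:
                    covs.append(0)
                    continue
                tg = pairing.build_tiling_graph(subset)
                res = pairing.minimum_tiling_path(tg, (1, 6000))
                covs.append(res.coverage_fraction)
            assert covs == sorted(covs)


class TestMultiplexGroups:
    def test_five_amplicon_path_splits_three_two(self):
        pairs = [
            pair_at(1, 600), pair_at(500, 1100), pair_at(1000, 1600),
            pair_at(1500, 2100), pair_at(2000, 2600),
        ]
        tg = pairing.build_tiling_graph(pairs)
        result = pairing.split_multiplex_groups(
            pairing.minimum_tiling_path(tg, (1, 2600))
        )
        groups = result.multiplex_groups
        assert sorted(len(v) for v in (groups["A"], groups["B"])) == [2, 3]
        for members in groups.values():
            ivs = sorted(result.pairs[p].interval for p in members)
            for (a1, a2), (b1, b2) in zip(ivs, ivs[1:]):
                assert a2 < b1  # no intra-group overlap

    def test_single_amplicon_goes_to_group_a(self):
        tg = pairing.build_tiling_graph([pair_at(100, 500)])
        result = pairing.split_multiplex_groups(
            pairing.minimum_tiling_path(tg, (100, 500))
        )
        assert len(result.multiplex_groups["A"]) == 1
        assert result.multiplex_groups["B"] == []

    def test_cross_subgraph_conflicts_resolved_by_audit(self):
        # two disjoint subgraphs; alternation restarts per subgraph, and the
        # audit must still leave both groups overlap-free
        pairs = [
            pair_at(1, 600), pair_at(500, 1100),
            pair_at(2000, 2600), pair_at(2500, 3100),
        ]
        tg = pairing.build_tiling_graph(pairs)
        result = pairing.split_multiplex_groups(
            pairing.minimum_tiling_path(tg, (1, 3100))
        )
        for members in result.multiplex_groups.values():
            ivs = sorted(result.pairs[p].interval for p in members)
            for (a1, a2), (b1, b2) in zip(ivs, ivs[1:]):
                assert a2 < b1
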