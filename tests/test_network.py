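import math
import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haploweb.network import (
    FFR,
    HaploNet,
    add_arcs,
    build_haploweb,
    build_msn,
    conspecificity,
    consensus_clusters,
    find_ffrs,
    msn_clades,
    p_distance,
    pairwise_diffs,
)
from haploweb.phasing import PhasedGenotype, PhaseStatus, phase_all
from haploweb.simdata import SimConfig, make_cohort

from conftest import brute_force_msn, make_aln, make_haps, random_haplotype


def _pg(sid, a, b, locus="L"):
    status = PhaseStatus.HOMOZYGOUS if a == b else PhaseStatus.PHASED_BY_REFERENCE
    return PhasedGenotype(sid, locus, a, b, status)


class TestDistances:
    def test_identical(self):
        assert pairwise_diffs("ACGT", "ACGT") == 0
        assert p_distance("ACGT", "ACGT") == 0.0

    def test_two_diffs(self):
        assert pairwise_diffs("AAAA", "AATT") == 2

    def test_n_sites_skipped(self):
        assert pairwise_diffs("ANAT", "AAAA") == 1
        assert p_distance("ANTT", "AAAA") == pytest.approx(2 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pairwise_diffs("ACG", "AC")

    def test_three_diffs_over_970_rounds_to_0003(self):
        a = "A" * 970
        b = "T" * 3 + "A" * 967
        assert round(p_distance(a, b), 3) == 0.003

    def test_no_comparable_sites_is_missing(self):
        assert p_distance("NNN", "AAA") is None

    @given(st.integers(0, 2**32 - 1), st.integers(1, 60))
    @settings(max_examples=80, deadline=None)
    def test_brute_force_and_symmetry(self, seed, length):
        rng = random.Random(seed)
        a = "".join(rng.choice("ACGTN-") for _ in range(length))
        b = "".join(rng.choice("ACGTN-") for _ in range(length))
        expected = sum(
            1 for x, y in zip(a, b) if x in "ACGT" and y in "ACGT" and x != y
        )
        assert pairwise_diffs(a, b) == expected == pairwise_diffs(b, a)
        assert p_distance(a, b) == p_distance(b, a)


class TestBuildMsn:
    def test_single_node(self):
        assert build_msn(make_haps({"h1": "AAAA"})) == []

    def test_triangle_drops_heavy_edge(self):
        haps = make_haps({"h1": "AAAA", "h2": "AAAT", "h3": "AATT"})
        edges = {(u, v) for u, v, _ in build_msn(haps)}
        assert edges == {("h1", "h2"), ("h2", "h3")}

    def test_tied_edges_all_kept(self):
        # equilateral triangle: every edge is in some MST
        haps = make_haps({"h1": "AAT", "h2": "ATA", "h3": "TAA"})
        edges = {(u, v) for u, v, _ in build_msn(haps)}
        assert edges == {("h1", "h2"), ("h1", "h3"), ("h2", "h3")}

    def test_edge_steps_equal_pairwise_diffs(self):
        haps = make_haps({"h1": "AAAA", "h2": "ATTT", "h3": "AATT"})
        for u, v, w in build_msn(haps):
            assert w == pairwise_diffs(haps[u].seq, haps[v].seq)

    @pytest.mark.parametrize("trial", range(25))
    def test_exhaustive_oracle(self, trial):
        rng = random.Random(1000 + trial)
        n = rng.randint(2, 7)
        # short sequences over 2 letters force plenty of ties
        seqs = {f"h{i}": "".join(rng.choice("AT") for _ in range(6))
                for i in range(n)}
        # deduplicate identical sequences (nodes are unique haplotypes)
        uniq = {}
        for hid, s in seqs.items():
            if s not in uniq.values():
                uniq[hid] = s
        got = {(u, v) for u, v, _ in build_msn(make_haps(uniq))}
        assert got == brute_force_msn(uniq)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_connected_with_mst_weight(self, seed):
        rng = random.Random(seed)
        n = rng.randint(1, 7)
        uniq = {}
        while len(uniq) < n:
            s = random_haplotype(rng, 8)
            uniq[f"h{len(uniq)}"] = s if s not in uniq.values() else s
        haps = make_haps(uniq)
        edges = build_msn(haps)
        G = nx.Graph()
        G.add_nodes_from(uniq)
        G.add_weighted_edges_from(edges)
        assert nx.is_connected(G)
        if n > 1:
            K = nx.Graph()
            for i, a in enumerate(sorted(uniq)):
                for b in sorted(uniq)[i + 1:]:
                    K.add_edge(a, b, weight=pairwise_diffs(uniq[a], uniq[b]))
            mst_w = sum(d["weight"] for _, _, d in
                        nx.minimum_spanning_tree(K).edges(data=True))
            msn_tree_w = sum(d["weight"] for _, _, d in
                             nx.minimum_spanning_tree(G).edges(data=True))
            assert msn_tree_w == mst_w


class TestArcs:
    def _net(self, seqs):
        haps = make_haps(seqs)
        for h in haps.values():
            h.hom_carriers = [f"hom_{h.hap_id}"]
        return HaploNet(locus="L", nodes=haps, edges=build_msn(haps))

    def test_all_homozygous_no_arcs(self):
        net = self._net({"h1": "AAAA", "h2": "AATT"})
        add_arcs(net, [_pg("s1", "h1", "h1"), _pg("s2", "h2", "h2")])
        assert net.arcs == {}

    def test_shared_pair_weight_two(self):
        net = self._net({"h1": "AAAA", "h2": "AATT"})
        add_arcs(net, [_pg("s1", "h1", "h2"), _pg("s2", "h1", "h2")])
        assert net.arc_weight("h1", "h2") == 2

    def test_unknown_hap_errors(self):
        net = self._net({"h1": "AAAA"})
        with pytest.raises(KeyError):
            add_arcs(net, [_pg("s1", "h1", "hX")])

    def test_unresolved_adds_nothing(self):
        net = self._net({"h1": "AAAA"})
        add_arcs(net, [PhasedGenotype("s1", "L", "", "", PhaseStatus.UNRESOLVED)])
        assert net.arcs == {}

    def test_arc_weights_sum_to_het_count(self):
        net = self._net({"h1": "AAAA", "h2": "AATT", "h3": "TTTT"})
        phased = [_pg("s1", "h1", "h2"), _pg("s2", "h1", "h2"),
                  _pg("s3", "h2", "h3"), _pg("s4", "h1", "h1")]
        add_arcs(net, phased)
        n_het = sum(1 for p in phased if p.hap_a != p.hap_b)
        assert sum(len(c) for c in net.arcs.values()) == n_het


class TestFindFfrs:
    def _net(self, seqs, phased, hom=()):
        haps = make_haps(seqs)
        for pg in phased:
            for hid in (pg.hap_a, pg.hap_b):
                h = haps[hid]
                if pg.hap_a == pg.hap_b:
                    if pg.specimen_id not in h.hom_carriers:
                        h.hom_carriers.append(pg.specimen_id)
                elif pg.specimen_id not in h.carriers:
                    h.carriers.append(pg.specimen_id)
        net = HaploNet(locus="L", nodes=haps, edges=build_msn(haps))
        return add_arcs(net, phased)

    def test_no_heterozygotes_singletons(self):
        phased = [_pg("s1", "h1", "h1"), _pg("s2", "h2", "h2"),
                  _pg("s3", "h3", "h3")]
        net = self._net({"h1": "AAAA", "h2": "AATT", "h3": "TTTT"}, phased)
        ffrs = find_ffrs(net)
        assert len(ffrs) == 3
        assert all(len(f.haplotypes) == 1 for f in ffrs)

    def test_chain_transitive_closure(self):
        # A-het-B and B-het-C link all three into one FFR
        phased = [_pg("s1", "hA", "hB"), _pg("s2", "hB", "hC")]
        net = self._net({"hA": "AAAA", "hB": "AATT", "hC": "TTTT"}, phased)
        ffrs = find_ffrs(net)
        assert len(ffrs) == 1
        assert ffrs[0].haplotypes == ["hA", "hB", "hC"]
        assert ffrs[0].members == ["s1", "s2"]

    def test_hybrid_bridge_split_and_flagged_in_both(self):
        # two homozygote-backed pools joined by a single het -> split,
        # with the bridging specimen listed in both FFRs
        phased = [_pg("a1", "hA", "hA"), _pg("a2", "hA", "hA"),
                  _pg("b1", "hB", "hB"), _pg("f1", "hA", "hB")]
        net = self._net({"hA": "AAAA", "hB": "TTTT"}, phased)
        ffrs = find_ffrs(net)
        assert len(ffrs) == 2
        assert all("f1" in f.members for f in ffrs)

    def test_private_variant_attaches_to_pool(self):
        # a het linking a pool to an allele seen nowhere else is not a
        # hybrid bridge: the lone allele has no independent evidence
        phased = [_pg("a1", "hA", "hA"), _pg("s1", "hA", "hX")]
        net = self._net({"hA": "AAAA", "hX": "AAAT"}, phased)
        ffrs = find_ffrs(net)
        assert len(ffrs) == 1
        assert ffrs[0].haplotypes == ["hA", "hX"]

    def test_partition_property(self):
        rng = random.Random(99)
        for _ in range(20):
            n = rng.randint(1, 6)
            seqs = {f"h{i}": random_haplotype(rng, 10) for i in range(n)}
            phased = []
            for s in range(rng.randint(1, 8)):
                a, b = rng.choice(sorted(seqs)), rng.choice(sorted(seqs))
                phased.append(_pg(f"s{s}", a, b))
            net = self._net(seqs, phased)
            ffrs = find_ffrs(net)
            carried = {h for f in ffrs for h in f.haplotypes}
            wanted = {h for p in phased for h in (p.hap_a, p.hap_b)}
            assert carried == set(seqs)  # nodes passed in are all carried here
            counts = {}
            for f in ffrs:
                for h in f.haplotypes:
                    counts[h] = counts.get(h, 0) + 1
            assert all(c == 1 for c in counts.values())  # disjoint

    def test_simulated_two_species_two_ffrs(self):
        cfg = SimConfig(seed=77)
        cohort = make_cohort(cfg)
        res = phase_all(cohort.alignments["nuc1"], cohort.metadata)
        net = build_haploweb(res, "nuc1")
        assert len(find_ffrs(net)) == 2


class TestMsnClades:
    def test_threshold_cuts_long_edges(self):
        phased = [_pg("s1", "h1", "h1"), _pg("s2", "h2", "h2")]
        haps = {"h1": "A" * 20, "h2": "T" * 10 + "A" * 10}
        net = HaploNet(locus="mt", nodes=make_haps(haps), edges=build_msn(make_haps(haps)))
        for pg in phased:
            net.nodes[pg.hap_a].hom_carriers.append(pg.specimen_id)
        assert len(msn_clades(net, max_steps=5)) == 2
        assert len(msn_clades(net, max_steps=10)) == 1


class TestConspecificity:
    def _ffr(self, ffr_id, locus, members):
        return FFR(ffr_id=ffr_id, locus=locus, haplotypes=[], members=members)

    def test_single_locus_entries(self):
        ffrs = {"L1": [self._ffr("L1_F1", "L1", ["s1", "s2"]),
                       self._ffr("L1_F2", "L1", ["s3"])]}
        m = conspecificity(ffrs, ["s1", "s2", "s3"])
        assert m.counts.loc["s1", "s2"] == 1
        assert m.counts.loc["s1", "s3"] == 0
        assert (m.counts.values.diagonal() == m.loci_scored.values.diagonal()).all()
        assert consensus_clusters(m) == [["s1", "s2"], ["s3"]]

    def test_two_loci_conflicting_membership(self):
        # s2 groups with s1 at locus A but with s3 at locus B
        ffrs = {
            "A": [self._ffr("A_F1", "A", ["s1", "s2"]),
                  self._ffr("A_F2", "A", ["s3", "s4"])],
            "B": [self._ffr("B_F1", "B", ["s1"]),
                  self._ffr("B_F2", "B", ["s2", "s3", "s4"])],
        }
        m = conspecificity(ffrs, ["s1", "s2", "s3", "s4"])
        assert m.counts.loc["s1", "s2"] == 1
        assert m.counts.loc["s2", "s3"] == 1
        assert m.counts.loc["s1", "s3"] == 0
        assert m.counts.loc["s3", "s4"] == 2
        # majority threshold ceil(2/2)=1 links s1-s2-s3-s4 by single linkage
        assert consensus_clusters(m) == [["s1", "s2", "s3", "s4"]]

    def test_three_loci_with_haploid_clades(self):
        ffrs = {
            "A": [self._ffr("A_F1", "A", ["s1", "s2"]),
                  self._ffr("A_F2", "A", ["s3", "s4"])],
            "B": [self._ffr("B_F1", "B", ["s1", "s2"]),
                  self._ffr("B_F2", "B", ["s3", "s4"])],
            "mt": [self._ffr("mt_c1", "mt", ["s1", "s3"]),
                   self._ffr("mt_c2", "mt", ["s2", "s4"])],
        }
        m = conspecificity(ffrs, ["s1", "s2", "s3", "s4"])
        assert m.counts.loc["s1", "s2"] == 2  # nuclear only
        assert m.counts.loc["s1", "s3"] == 1  # mt only
        assert m.loci_scored.loc["s1", "s2"] == 3
        # ceil(3/2)=2 -> mt alone cannot join groups
        assert consensus_clusters(m) == [["s1", "s2"], ["s3", "s4"]]

    def test_absent_specimen_not_scored(self):
        ffrs = {
            "A": [self._ffr("A_F1", "A", ["s1", "s2"])],
            "B": [self._ffr("B_F1", "B", ["s1"])],
        }
        m = conspecificity(ffrs, ["s1", "s2"])
        assert m.loci_scored.loc["s1", "s2"] == 1
        assert m.loci_scored.loc["s1", "s1"] == 2

    def test_symmetry_and_bounds(self):
        rng = random.Random(5)
        sids = [f"s{i}" for i in range(6)]
        ffrs = {}
        for locus in ("A", "B", "C"):
            k = rng.randint(1, 3)
            groups = [[] for _ in range(k)]
            for s in sids:
                if rng.random() < 0.8:
                    groups[rng.randrange(k)].append(s)
            ffrs[locus] = [
                self._ffr(f"{locus}_F{i}", locus, g)
                for i, g in enumerate(groups) if g
            ]
        m = conspecificity(ffrs, sids)
        assert (m.counts.values == m.counts.values.T).all()
        assert (m.counts.values <= m.loci_scored.values).all()
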