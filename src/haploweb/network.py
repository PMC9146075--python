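"""Haplotype networks with heterozygote arcs and fields-for-recombination.

Nodes are resolved haplotypes; mutational edges form an epsilon-0
minimum-spanning network (every edge of every minimum spanning tree);
arcs connect the two alleles of each heterozygous specimen.  Connected
components of the arc graph delimit fields for recombination (FFRs) —
exclusive allele pools — except that a lone arc whose removal separates
two independently-evidenced pools is treated as a hybrid bridge: it does
not merge the pools and its carriers are flagged as FFR-bridging
heterozygotes, listed in both.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .phasing import Haplotype, PhasedGenotype, PhaseResult, PhaseStatus
from .seqio import BASES, SpecimenRecord

__all__ = [
    "HaploNet",
    "FFR",
    "ConspecificityMatrix",
    "pairwise_diffs",
    "p_distance",
    "build_msn",
    "add_arcs",
    "build_haploweb",
    "find_ffrs",
    "msn_clades",
    "conspecificity",
    "consensus_clusters",
    "to_graphml",
    "to_dot",
]


def pairwise_diffs(h1: str | Haplotype, h2: str | Haplotype) -> int:
    """Number of sites where both sequences carry plain bases and differ."""
    s1 = h1.seq if isinstance(h1, Haplotype) else h1
    s2 = h2.seq if isinstance(h2, Haplotype) else h2
    if len(s1) != len(s2):
        raise ValueError("sequence length mismatch")
    return sum(1 for a, b in zip(s1, s2) if a != b and a in BASES and b in BASES)


def p_distance(h1: str | Haplotype, h2: str | Haplotype) -> Optional[float]:
    """Uncorrected distance: differing sites over comparable sites.

    Sites where either sequence is not a plain base are excluded
    (pairwise deletion).  ``None`` when no site is comparable.
    """
    s1 = h1.seq if isinstance(h1, Haplotype) else h1
    s2 = h2.seq if isinstance(h2, Haplotype) else h2
    if len(s1) != len(s2):
        raise ValueError("sequence length mismatch")
    comparable = sum(1 for a, b in zip(s1, s2) if a in BASES and b in BASES)
    if comparable == 0:
        return None
    return pairwise_diffs(s1, s2) / comparable


@dataclass
class HaploNet:
    """Haplotype nodes + mutational-step edges + heterozygote arcs."""

    locus: str
    nodes: dict[str, Haplotype]
    edges: list[tuple[str, str, int]] = field(default_factory=list)
    # unordered hap-id pair -> carrier specimen ids
    arcs: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def arc_weight(self, u: str, v: str) -> int:
        return len(self.arcs.get(_norm(u, v), ()))


def _norm(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def build_msn(nodes: Mapping[str, Haplotype] | Sequence[Haplotype]) -> list[tuple[str, str, int]]:
    """Epsilon-0 minimum-spanning network over pairwise difference counts.

    Returns the union of all minimum spanning trees: processing weight
    classes in ascending order, an edge is kept iff its endpoints are in
    different components of the graph built from strictly lighter edges.
    """
    haps = list(nodes.values()) if isinstance(nodes, Mapping) else list(nodes)
    if not haps:
        return []
    by_weight: dict[int, list[tuple[str, str]]] = {}
    for i, a in enumerate(haps):
        for b in haps[i + 1:]:
            w = pairwise_diffs(a.seq, b.seq)
            by_weight.setdefault(w, []).append(_norm(a.hap_id, b.hap_id))
    uf = nx.utils.UnionFind(h.hap_id for h in haps)
    out: list[tuple[str, str, int]] = []
    for w in sorted(by_weight):
        kept = [(u, v) for u, v in by_weight[w] if uf[u] != uf[v]]
        out.extend((u, v, w) for u, v in sorted(kept))
        for u, v in kept:
            uf.union(u, v)
    return out


def add_arcs(net: HaploNet, phased: Sequence[PhasedGenotype]) -> HaploNet:
    """One arc per unordered heterozygous allele pair, weighted by carriers."""
    for pg in phased:
        if pg.status is PhaseStatus.UNRESOLVED or pg.hap_a == pg.hap_b:
            continue
        for hid in (pg.hap_a, pg.hap_b):
            if hid not in net.nodes:
                raise KeyError(f"unknown haplotype id {hid} in phased genotypes")
        net.arcs.setdefault(_norm(pg.hap_a, pg.hap_b), []).append(pg.specimen_id)
    return net


def build_haploweb(result: PhaseResult, locus: str) -> HaploNet:
    """Network over carried haplotypes with MSN edges and heterozygote arcs."""
    carried = {
        hid: h for hid, h in result.haplotypes.items()
        if h.locus == locus and (h.carriers or h.hom_carriers)
    }
    net = HaploNet(locus=locus, nodes=carried, edges=build_msn(carried))
    return add_arcs(net, [pg for pg in result.genotypes if pg.locus == locus])


@dataclass
class FFR:
    """Field for recombination: an exclusive allele pool and its carriers."""

    ffr_id: str
    locus: str
    haplotypes: list[str]
    members: list[str]
    species_composition: dict[str, int] = field(default_factory=dict)


def _evidenced(side: set[str], net: HaploNet) -> bool:
    # a pool stands on its own if it shows recombination (>= 2 arc-linked
    # alleles) or a homozygous carrier of one of its alleles
    if len(side) > 1:
        return True
    (hid,) = side
    return bool(net.nodes[hid].hom_carriers)


def find_ffrs(net: HaploNet) -> list[FFR]:
    """Delimit FFRs from the arc graph, splitting at hybrid bridges.

    A bridge arc is removed when each side it separates has independent
    evidence of being a recombining pool (another arc, or a homozygous
    carrier); carriers of removed arcs become FFR-bridging heterozygotes
    and appear in both resulting FFRs.
    """
    G = nx.Graph()
    G.add_nodes_from(net.nodes)
    G.add_edges_from(net.arcs)
    bridging_arcs: list[tuple[str, str]] = []
    while True:
        removed = []
        for u, v in sorted(nx.bridges(G)):
            H = G.copy()
            H.remove_edge(u, v)
            side_u = nx.node_connected_component(H, u)
            side_v = nx.node_connected_component(H, v)
            if _evidenced(side_u, net) and _evidenced(side_v, net):
                removed.append((u, v))
        if not removed:
            break
        G.remove_edges_from(removed)
        bridging_arcs.extend(_norm(u, v) for u, v in removed)

    comps = sorted(nx.connected_components(G), key=lambda c: sorted(c)[0])
    hap_ffr: dict[str, int] = {}
    ffrs = []
    for i, comp in enumerate(comps):
        for hid in comp:
            hap_ffr[hid] = i
        members: set[str] = set()
        for hid in comp:
            members.update(net.nodes[hid].carriers)
            members.update(net.nodes[hid].hom_carriers)
        ffrs.append(
            FFR(
                ffr_id=f"{net.locus}_FFR{i + 1}",
                locus=net.locus,
                haplotypes=sorted(comp),
                members=sorted(members),
            )
        )
    # bridging carriers belong to the FFRs on both sides of their arc
    for u, v in bridging_arcs:
        for sid in net.arcs[_norm(u, v)]:
            for hid in (u, v):
                ffr = ffrs[hap_ffr[hid]]
                if sid not in ffr.members:
                    ffr.members.append(sid)
                    ffr.members.sort()
    return ffrs


def msn_clades(net: HaploNet, max_steps: int = 5) -> list[FFR]:
    """Haploid stand-in for FFRs: MSN components after cutting long edges.

    Used to pool a haploid locus into multilocus consensus: clade
    membership plays the role of shared-FFR membership.
    """
    G = nx.Graph()
    G.add_nodes_from(net.nodes)
    G.add_edges_from((u, v) for u, v, w in net.edges if w <= max_steps)
    comps = sorted(nx.connected_components(G), key=lambda c: sorted(c)[0])
    out = []
    for i, comp in enumerate(comps):
        members: set[str] = set()
        for hid in comp:
            members.update(net.nodes[hid].carriers)
            members.update(net.nodes[hid].hom_carriers)
        out.append(
            FFR(
                ffr_id=f"{net.locus}_clade{i + 1}",
                locus=net.locus,
                haplotypes=sorted(comp),
                members=sorted(members),
            )
        )
    return out


@dataclass
class ConspecificityMatrix:
    """Specimen-pair counts of loci sharing an FFR."""

    specimen_ids: list[str]
    counts: pd.DataFrame       # int loci where the pair shares an FFR
    loci_scored: pd.DataFrame  # int loci scored for the pair


def conspecificity(
    ffrs_by_locus: Mapping[str, Sequence[FFR]],
    specimens: Sequence[str],
) -> ConspecificityMatrix:
    """Count, per specimen pair, the loci at which they share an FFR.

    A locus is scored for a pair only when both specimens appear in some
    FFR of that locus; FFR-bridging specimens share a locus with members
    of either side.  The diagonal equals loci_scored.
    """
    ids = sorted(specimens)
    counts = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    scored = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for locus, ffrs in sorted(ffrs_by_locus.items()):
        membership: dict[str, set[str]] = {}
        for ffr in ffrs:
            for sid in ffr.members:
                membership.setdefault(sid, set()).add(ffr.ffr_id)
        present = [sid for sid in ids if sid in membership]
        for i, a in enumerate(present):
            for b in present[i:]:
                scored.loc[a, b] += 1
                if a != b:
                    scored.loc[b, a] += 1
                if membership[a] & membership[b]:
                    counts.loc[a, b] += 1
                    if a != b:
                        counts.loc[b, a] += 1
    return ConspecificityMatrix(specimen_ids=ids, counts=counts, loci_scored=scored)


def consensus_clusters(matrix: ConspecificityMatrix) -> list[list[str]]:
    """Single-linkage grouping of pairs conspecific at a majority of loci.

    Specimens are linked when they share an FFR at >= ceil(L/2) of the L
    loci scored for the pair; components are returned sorted by their
    lexicographically first member.
    """
    G = nx.Graph()
    G.add_nodes_from(matrix.specimen_ids)
    ids = matrix.specimen_ids
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            L = int(matrix.loci_scored.loc[a, b])
            if L > 0 and int(matrix.counts.loc[a, b]) >= math.ceil(L / 2):
                G.add_edge(a, b)
    comps = sorted(nx.connected_components(G), key=lambda c: sorted(c)[0])
    return [sorted(c) for c in comps]


def to_graphml(net: HaploNet, path) -> None:
    G = nx.Graph(locus=net.locus)
    for hid, h in sorted(net.nodes.items()):
        G.add_node(hid, seq=h.seq, frequency=h.frequency,
                   carriers=",".join(sorted(h.carriers or h.hom_carriers)),
                   provenance=h.provenance.value)
    for u, v, w in net.edges:
        G.add_edge(u, v, steps=w, kind="mutation")
    for (u, v), carriers in sorted(net.arcs.items()):
        if G.has_edge(u, v):
            G[u][v]["arc_weight"] = len(carriers)
        else:
            G.add_edge(u, v, kind="arc", arc_weight=len(carriers))
    nx.write_graphml(G, path)


def to_dot(net: HaploNet, path) -> None:
    """Minimal DOT export: nodes sized by frequency, arcs dashed."""
    lines = [f'graph "{net.locus}" {{']
    for hid, h in sorted(net.nodes.items()):
        size = 0.3 + 0.1 * max(h.frequency, 1)
        lines.append(f'  "{hid}" [width={size:.2f}, label="{hid} ({h.frequency})"];')
    for u, v, w in net.edges:
        lines.append(f'  "{u}" -- "{v}" [label="{w}"];')
    for (u, v), carriers in sorted(net.arcs.items()):
        lines.append(
            f'  "{u}" -- "{v}" [style=dashed, penwidth={len(carriers)}, '
            f'label="n={len(carriers)}"];'
        )
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
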