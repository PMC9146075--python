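import itertools
import random

import pytest

from haploweb.phasing import Haplotype
from haploweb.seqio import AMBIG, GenotypeSequence, LocusAlignment, Ploidy


def make_aln(seqs: dict[str, str], locus: str = "L",
             ploidy: Ploidy = Ploidy.DIPLOID, codon_framed: bool = False) -> LocusAlignment:
    return LocusAlignment(
        locus=locus,
        ploidy=ploidy,
        sequences=tuple(
            GenotypeSequence(sid, locus, seq, ploidy) for sid, seq in seqs.items()
        ),
        codon_framed=codon_framed,
    )


def make_haps(seqs: dict[str, str], locus: str = "L") -> dict[str, Haplotype]:
    return {
        hid: Haplotype(hap_id=hid, locus=locus, seq=seq)
        for hid, seq in seqs.items()
    }


def random_haplotype(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def enumerate_decompositions(genotype: str) -> list[tuple[str, str]]:
    """Brute-force oracle: all 2^k haplotype pairs consistent with a genotype."""
    het_positions = [i for i, ch in enumerate(genotype) if ch in AMBIG]
    options = [sorted(AMBIG[genotype[i]]) for i in het_positions]
    pairs = set()
    for combo in itertools.product(*options) if het_positions else [()]:
        a = list(genotype)
        b = list(genotype)
        for pos, base in zip(het_positions, combo):
            pair = AMBIG[genotype[pos]]
            a[pos] = base
            (b[pos],) = pair - {base}
        pairs.add(tuple(sorted(("".join(a), "".join(b)))))
    return sorted(pairs)


def brute_force_msn(haps: dict[str, str]) -> set[tuple[str, str]]:
    """Union of all minimum spanning trees by exhaustive enumeration."""
    from haploweb.network import pairwise_diffs

    ids = sorted(haps)
    n = len(ids)
    if n <= 1:
        return set()
    edges = [
        (a, b, pairwise_diffs(haps[a], haps[b]))
        for i, a in enumerate(ids) for b in ids[i + 1:]
    ]
    best = None
    trees: list[list[tuple[str, str, int]]] = []
    for combo in itertools.combinations(edges, n - 1):
        # spanning check via union-find
        parent = {v: v for v in ids}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        ok = True
        for u, v, _ in combo:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if not ok:
            continue
        w = sum(e[2] for e in combo)
        if best is None or w < best:
            best = w
            trees = [list(combo)]
        elif w == best:
            trees.append(list(combo))
    return {(u, v) for tree in trees for u, v, _ in tree}


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240501)
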