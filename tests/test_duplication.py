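"""Tandem rules, transitive clustering and collinearity chaining."""

import pytest

from prolaminkit import synthgen as sg
from prolaminkit.duplication import (PairStats, SyntenyBlock, align_identity,
                                     chain_collinear, cluster_tandem,
                                     genomic_distance, is_tandem_pair,
                                     reciprocal_best_anchors,
                                     tandem_proportion)
from prolaminkit.errors import InputError
from prolaminkit.homology import ScanParams, glocal_align
from prolaminkit.seqio import GeneModel


def _model(gid, chrom, start, end):
    return GeneModel(gid, chrom, "+", start, end, ((start, end),))


# ---------------------------------------------------------------------------
# pairwise statistics


def test_identical_sequences_full_identity(rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 900))
    identity, coverage = align_identity(seq, seq)
    assert identity == 100.0 and coverage == 100.0


def test_prefix_coverage(rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
    identity, coverage = align_identity(seq[:400], seq)
    assert identity == 100.0
    assert coverage == pytest.approx(50.0, abs=0.5)


def test_diverged_pair_identity_matches_dp_oracle(rng):
    """~10% synonymous divergence: identity near 90, and consistent with
    an independently computed DP alignment identity."""
    cds, _ = sg.generate_gene("gamma", rng)
    other = sg.diverge_synonymous(cds, rng, 0.10)
    identity, _cov = align_identity(cds, other)
    assert identity == pytest.approx(90.0, abs=1.5)
    # independent route: glocal DP (hand-written numpy, not Biopython)
    _score, _js, _je, matches, columns = glocal_align(cds, other, ScanParams())
    assert identity == pytest.approx(100.0 * matches / columns, abs=1.0)


def test_align_identity_rejects_empty():
    with pytest.raises(InputError):
        align_identity("", "ACGT")


def test_genomic_distance_inner_gap():
    a = _model("a", "c", 1000, 2000)
    assert genomic_distance(a, _model("b", "c", 2001, 2500)) == 0
    assert genomic_distance(a, _model("b", "c", 2101, 2500)) == 100
    assert genomic_distance(a, _model("b", "c", 1500, 2500)) == 0
    assert genomic_distance(_model("b", "c", 2101, 2500), a) == 100  # symmetric


# ---------------------------------------------------------------------------
# tandem rules


def _stats(dist=10_000, cov=90.0, ident=90.0, same=True):
    return PairStats("a", "b", ident, cov, dist, same)


@pytest.mark.parametrize("stats,expected", [
    (_stats(), True),
    (_stats(same=False), False),
    (_stats(dist=100_000), False),       # strict less-than
    (_stats(dist=99_999), True),
    (_stats(cov=70.0), False),           # strict greater-than
    (_stats(ident=70.0), False),
    (_stats(ident=70.1), True),
])
def test_is_tandem_pair_rules(stats, expected):
    assert is_tandem_pair(stats) is expected


def test_transitive_clustering():
    """AB and BC tandem but AC not: one cluster {A, B, C}."""
    models = [_model("A", "c", 1, 1000), _model("B", "c", 50_000, 51_000),
              _model("C", "c", 99_000, 100_000), _model("D", "c", 500_000, 501_000)]
    pairs = [
        PairStats("A", "B", 90, 90, 48_999, True),
        PairStats("B", "C", 90, 90, 47_999, True),
        PairStats("A", "C", 60, 90, 97_999, True),   # fails identity
    ]
    clusters = cluster_tandem(models, pairs)
    assert len(clusters) == 1
    assert clusters[0].members == ("A", "B", "C")
    num, den, pct = tandem_proportion(clusters, ["A", "B", "C", "D"])
    assert (num, den, pct) == (3, 4, 75.0)


def test_no_qualifying_pairs_no_clusters():
    models = [_model("A", "c", 1, 1000), _model("B", "c", 500_000, 501_000)]
    assert cluster_tandem(models, [PairStats("A", "B", 90, 90, 498_999, True)]) == []


def test_planted_arrays_recovered_exactly(e_genome):
    """Every planted tandem array comes back as one cluster with exactly
    its planted membership, at the default intra-array divergence."""
    truth_clusters = {
        frozenset(group.gene_id)
        for _, group in e_genome.truth[e_genome.truth.cluster_id != ""]
        .groupby("cluster_id")
    }
    found = {frozenset(c.members) for c in e_genome.clusters}
    assert found == truth_clusters


# ---------------------------------------------------------------------------
# collinearity chaining


def test_forward_chain():
    blocks, isolated = chain_collinear([(1, 1, 90.0), (2, 2, 90.0), (3, 3, 90.0)])
    assert len(blocks) == 1 and blocks[0].orientation == "forward"
    assert len(blocks[0]) == 3 and isolated == []


def test_inverted_chain():
    blocks, _ = chain_collinear([(1, 3, 90.0), (2, 2, 90.0), (3, 1, 90.0)])
    assert len(blocks) == 1 and blocks[0].orientation == "inverted"


def _brute_force_decomposition(anchors):
    """Exhaustive reference: repeatedly take the maximum-length strictly
    monotone chain (forward preferred, then lexicographically smallest)."""

    def monotone_chains(pool, inverted):
        best = []
        pool = sorted(pool)
        n = len(pool)
        for mask in range(1, 1 << n):
            chain = [pool[i] for i in range(n) if mask >> i & 1]
            ok = all(
                b[0] > a[0] and (b[1] < a[1] if inverted else b[1] > a[1])
                for a, b in zip(chain, chain[1:])
            )
            if ok and (len(chain), ) > (len(best), ):
                best = chain
            elif ok and len(chain) == len(best) and tuple(chain) < tuple(best):
                best = chain
        return best

    remaining = list(anchors)
    blocks = []
    while True:
        fwd = monotone_chains(remaining, False)
        inv = monotone_chains(remaining, True)
        chain, orient = (fwd, "forward") if len(fwd) >= len(inv) else (inv, "inverted")
        if len(chain) < 2:
            break
        blocks.append(SyntenyBlock(tuple(chain), orient))
        taken = set(chain)
        remaining = [a for a in remaining if a not in taken]
    return blocks, sorted(remaining)


def test_chain_decomposition_equals_brute_force(rng):
    """Greedy chaining equals exhaustive search over chain partitions for
    n <= 10 anchors."""
    for _ in range(25):
        n = int(rng.integers(2, 11))
        xs = rng.permutation(20)[:n]
        ys = rng.permutation(20)[:n]
        anchors = sorted((int(x), int(y), 80.0) for x, y in zip(xs, ys))
        got = chain_collinear(anchors)
        expected = _brute_force_decomposition(anchors)
        assert got == expected


def test_orientation_duality():
    """Reversing the second genome's order flips block orientation."""
    anchors = [(1, 1, 90.0), (2, 2, 90.0), (3, 3, 90.0), (4, 4, 90.0)]
    nmax = 5
    flipped = [(a, nmax - b, s) for a, b, s in anchors]
    blocks, _ = chain_collinear(anchors)
    flipped_blocks, _ = chain_collinear(flipped)
    assert [b.orientation for b in blocks] == ["forward"]
    assert [b.orientation for b in flipped_blocks] == ["inverted"]
    assert [len(b) for b in blocks] == [len(b) for b in flipped_blocks]


def test_region_pair_inversion_and_isolated_gene(rng):
    """Cross-genome region comparison recovers the planted inversion and
    the transplanted isolated gene."""
    genes1, genes2 = sg.generate_region_pair(rng)
    anchors = reciprocal_best_anchors([c for _, c in genes1],
                                      [c for _, c in genes2])
    assert len(anchors) == len(genes1)        # every gene anchored 1:1
    blocks, isolated = chain_collinear(anchors)
    orientations = sorted(b.orientation for b in blocks)
    assert "inverted" in orientations
    assert len(isolated) == 1                  # the transplanted gene
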