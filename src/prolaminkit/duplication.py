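"""Tandem-duplication clustering and micro-collinearity chaining.

Two genes form a tandem pair when all three rules hold strictly:

  (a) they sit on the same chromosome less than 100 kb apart,
  (b) the aligned region covers more than 70% of the longer sequence,
  (c) the aligned sequences are more than 70% identical.

The relation is extended transitively: if A-B and B-C are tandem pairs,
A and C belong to one tandem cluster even if the A-C pair fails the rules.
Clusters are therefore connected components of the tandem-pair graph.

Micro-collinearity between two ordered gene lists is modelled on
reciprocal-best similarity anchors: maximal strictly monotone chains are
peeled off greedily (longest first), each labeled forward (both indices
increasing) or inverted (second index decreasing), until no chain of two
or more anchors remains. Left-over anchors are reported as isolated genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx
from Bio import Align

from .annotate import round_pct
from .errors import InputError
from .seqio import CodingSequence, GeneModel

TANDEM_MAX_DISTANCE = 100_000
TANDEM_MIN_COVERAGE = 70.0
TANDEM_MIN_IDENTITY = 70.0


@dataclass(frozen=True)
class PairStats:
    gene_a: str
    gene_b: str
    identity_pct: float
    coverage_pct: float
    genomic_distance_bp: int
    same_chrom: bool


@dataclass(frozen=True)
class TandemCluster:
    chrom: str
    members: tuple[str, ...]  # gene ids ordered by coordinate

    def __len__(self) -> int:
        return len(self.members)


def _aligner(match: float = 1, mismatch: float = -2,
             gap_open: float = -5, gap_extend: float = -2) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    al.end_insertion_score = 0.0   # free end gaps on both sequences
    al.end_deletion_score = 0.0
    return al


def align_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(identity_pct, coverage_pct) of a free-end-gap global alignment.

    Identity counts matches over all alignment columns including internal
    gaps; coverage is the aligned span on the longer sequence over its
    full length. Terminal overhangs are free and excluded from both.
    """
    if not seq_a or not seq_b:
        raise InputError("cannot align an empty sequence")
    aln = _aligner().align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return 0.0, 0.0
    matches = 0
    aligned_len = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned_len += a1 - a0
        matches += sum(x == y for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]))
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    columns = span_a + span_b - aligned_len  # pairs + internal gap columns
    identity = 100.0 * matches / columns
    longer = max(len(seq_a), len(seq_b))
    span_longer = span_a if len(seq_a) >= len(seq_b) else span_b
    coverage = 100.0 * span_longer / longer
    return identity, coverage


def genomic_distance(model_a: GeneModel, model_b: GeneModel) -> int:
    """Inner gap between feature boundaries; 0 when the spans overlap."""
    if model_a.start > model_b.start:
        model_a, model_b = model_b, model_a
    return max(0, model_b.start - model_a.end - 1)


def pair_stats(seq_a: CodingSequence | str, seq_b: CodingSequence | str,
               model_a: GeneModel, model_b: GeneModel) -> PairStats:
    sa = seq_a.nucleotides if isinstance(seq_a, CodingSequence) else seq_a
    sb = seq_b.nucleotides if isinstance(seq_b, CodingSequence) else seq_b
    identity, coverage = align_identity(sa, sb)
    return PairStats(
        gene_a=model_a.gene_id, gene_b=model_b.gene_id,
        identity_pct=identity, coverage_pct=coverage,
        genomic_distance_bp=genomic_distance(model_a, model_b),
        same_chrom=model_a.chrom == model_b.chrom,
    )


def is_tandem_pair(stats: PairStats,
                   max_distance: int = TANDEM_MAX_DISTANCE,
                   min_coverage: float = TANDEM_MIN_COVERAGE,
                   min_identity: float = TANDEM_MIN_IDENTITY) -> bool:
    """All three rules, with strict inequalities."""
    return (
        stats.same_chrom
        and stats.genomic_distance_bp < max_distance
        and stats.coverage_pct > min_coverage
        and stats.identity_pct > min_identity
    )


def tandem_pairs(models: Sequence[GeneModel],
                 cds_by_gene: dict[str, str | CodingSequence],
                 max_distance: int = TANDEM_MAX_DISTANCE) -> list[PairStats]:
    """PairStats for every same-chromosome pair within the distance window.

    Pairs further apart are never tandem, so their alignment is skipped.
    """
    out: list[PairStats] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom_models in by_chrom.values():
        chrom_models.sort(key=lambda m: m.start)
        for i, a in enumerate(chrom_models):
            for b in chrom_models[i + 1:]:
                if genomic_distance(a, b) >= max_distance:
                    break  # sorted by start: all later genes are farther
                out.append(pair_stats(cds_by_gene[a.gene_id],
                                      cds_by_gene[b.gene_id], a, b))
    return out


def cluster_tandem(models: Sequence[GeneModel],
                   pairs: Iterable[PairStats],
                   predicate: Callable[[PairStats], bool] = is_tandem_pair
                   ) -> list[TandemCluster]:
    """Connected components of the tandem-pair graph; singletons excluded."""
    pos = {m.gene_id: (m.chrom, m.start) for m in models}
    g = nx.Graph()
    for p in pairs:
        if predicate(p):
            g.add_edge(p.gene_a, p.gene_b)
    clusters = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda gid: pos[gid][1])
        clusters.append(TandemCluster(pos[members[0]][0], tuple(members)))
    clusters.sort(key=lambda c: (c.chrom, pos[c.members[0]][1]))
    return clusters


def tandem_proportion(clusters: Sequence[TandemCluster],
                      subfamily_gene_ids: Sequence[str]
                      ) -> tuple[int, int, float]:
    """(numerator, denominator, pct): genes in clusters of size >= 2 over
    the subfamily gene count. Numerator and denominator are reported
    explicitly because printed proportions can hide the denominator choice.
    """
    if not subfamily_gene_ids:
        raise InputError("tandem proportion over an empty gene set")
    in_cluster = {gid for c in clusters if len(c) >= 2 for gid in c.members}
    num = sum(1 for gid in subfamily_gene_ids if gid in in_cluster)
    den = len(subfamily_gene_ids)
    return num, den, round_pct(num / den)


# ---------------------------------------------------------------------------
# micro-collinearity

Anchor = tuple[int, int, float]  # (index in genome 1, index in genome 2, similarity)


@dataclass(frozen=True)
class SyntenyBlock:
    anchors: tuple[Anchor, ...]   # ordered by first index ascending
    orientation: str              # "forward" | "inverted"

    def __len__(self) -> int:
        return len(self.anchors)


def _longest_chain(anchors: list[Anchor], inverted: bool) -> list[Anchor]:
    """Lexicographically smallest maximum-length strictly monotone chain.

    Forward chains increase in both indices; inverted chains increase in
    the first and decrease in the second. O(n^2) suffix DP, then greedy
    front construction, which yields the lexicographically smallest
    maximum chain deterministically.
    """
    items = sorted(anchors, key=lambda a: (a[0], a[1]))
    n = len(items)
    if n == 0:
        return []

    def follows(a: Anchor, b: Anchor) -> bool:
        if b[0] <= a[0]:
            return False
        return b[1] < a[1] if inverted else b[1] > a[1]

    suffix = [1] * n  # longest chain starting at i
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if follows(items[i], items[j]):
                suffix[i] = max(suffix[i], 1 + suffix[j])
    best_len = max(suffix)
    chain: list[Anchor] = []
    need = best_len
    prev: Anchor | None = None
    for i in range(n):
        if suffix[i] == need and (prev is None or follows(prev, items[i])):
            chain.append(items[i])
            prev = items[i]
            need -= 1
            if need == 0:
                break
    return chain


def chain_collinear(anchors: Sequence[Anchor]
                    ) -> tuple[list[SyntenyBlock], list[Anchor]]:
    """Greedy decomposition into syntenic blocks.

    Repeatedly extracts the longest strictly monotone chain over the
    remaining anchors (forward preferred on ties) until only chains of
    length < 2 remain; returns (blocks, isolated_anchors).
    """
    remaining = list(anchors)
    blocks: list[SyntenyBlock] = []
    while True:
        fwd = _longest_chain(remaining, inverted=False)
        inv = _longest_chain(remaining, inverted=True)
        best, orient = (fwd, "forward") if len(fwd) >= len(inv) else (inv, "inverted")
        if len(best) < 2:
            break
        blocks.append(SyntenyBlock(tuple(best), orient))
        taken = set(best)
        remaining = [a for a in remaining if a not in taken]
    return blocks, sorted(remaining)


def reciprocal_best_anchors(cds_a: Sequence[str], cds_b: Sequence[str],
                            min_identity: float = 50.0) -> list[Anchor]:
    """Reciprocal-best-identity anchors between two ordered gene lists.

    The identity floor screens out spurious cross-subfamily pairings, a
    stand-in for the score filters of whole-genome collinearity tools.
    """
    na, nb = len(cds_a), len(cds_b)
    ident = [[0.0] * nb for _ in range(na)]
    for i, sa in enumerate(cds_a):
        for j, sb in enumerate(cds_b):
            identity, coverage = align_identity(sa, sb)
            if coverage > 50.0:
                ident[i][j] = identity
    anchors: list[Anchor] = []
    for i in range(na):
        j = max(range(nb), key=lambda jj: ident[i][jj], default=None)
        if j is None or ident[i][j] < min_identity:
            continue
        if max(range(na), key=lambda ii: ident[ii][j]) == i:
            anchors.append((i, j, ident[i][j]))
    return anchors
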