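"""Nucleotide homology search: seed -> chain -> banded extension.

Candidate prolamin loci are discovered by a blastn-like strategy at desk
scale: exact k-mer seeds are looked up in a genome index, seeds sharing a
diagonal band are chained, and each chain is extended by a glocal
(query-global, target-local) affine-gap alignment over the chained window.
Hits are filtered by a Karlin-Altschul expected-count surrogate

    E = K * m * n * exp(-lambda * S)

with lambda fit to the scoring scheme over uniform base frequencies, m the
query length and n the total genome length. The default cutoff of 1e-10
mirrors the conventional stringent blastn filter for cross-species gene
family searches.

Scoring defaults (match +1, mismatch -2, gap open -5, gap extend -2,
band 32) are blastn-like. The gap open penalty applies to the first gapped
column and the extend penalty to each subsequent one. Direct transitions
between insertion and deletion states are not modelled; with any sensible
scheme (mismatch cheaper than two gap opens) they are never optimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import InputError, ParameterError
from .seqio import GenomeSequence, STOP_CODONS, reverse_complement

NEG = np.float32(-1e9)


@dataclass(frozen=True)
class ScanParams:
    k: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    band: int = 32
    evalue_cutoff: float = 1e-10
    ka_k: float = 0.3            # Karlin-Altschul K (order-of-magnitude constant)
    chain_gap: int = 500         # max query-offset gap between chained seeds
    #: chance seed pairs are common in composition-matched background;
    #: four co-linear seeds essentially never are
    min_chain_seeds: int = 4
    max_chains_per_strand: int = 100
    #: k-mers with more genomic occurrences than this are ignored as
    #: low-complexity repeats (polyglutamine / proline-rich codon runs
    #: would otherwise seed every prolamin locus against every query)
    max_kmer_occurrences: int = 150


@dataclass(frozen=True)
class QuerySet:
    """Named query CDSs with an optional subfamily hint each."""

    records: tuple[tuple[str, str, str], ...]  # (query_id, sequence, hint)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise InputError("query ids must be unique")
        for qid, seq, _hint in self.records:
            if len(seq) < 60:
                raise InputError(f"query {qid}: shorter than 60 nt")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    chrom: str
    strand: str
    start: int                   # 1-based inclusive genomic
    end: int
    score: float
    identity_pct: float          # matches / alignment columns * 100
    evalue_surrogate: float


@dataclass(frozen=True)
class CandidateLocus:
    chrom: str
    strand: str
    start: int
    end: int
    hits: tuple[HomologyHit, ...]
    orf_span: tuple[int, int] | None = None  # genomic, incl. stop codon

    @property
    def best_hit(self) -> HomologyHit:
        return max(self.hits, key=lambda h: h.score)


# ---------------------------------------------------------------------------
# k-mer index


_BASE_CODE = np.full(256, 4, dtype=np.uint8)  # N and anything else -> 4
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_ids(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer id of each k-mer window; windows containing N get -1."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    ids = windows.astype(np.int64) @ powers
    has_n = np.convolve((codes == 4).astype(np.int64), np.ones(k, np.int64),
                        mode="valid") > 0
    ids[has_n] = -1
    return ids


class KmerIndex:
    """Sorted-array index of exact k-mer positions over a set of
    chromosomes. Plus-strand occurrences are stored; minus-strand queries
    are answered by looking up the reverse complement at mirrored (i.e.
    identical genomic) coordinates. N-containing k-mers are skipped.

    Internally 2-bit-encodes the genome, assigns every window an integer
    id and argsorts once; lookups are binary searches.
    """

    def __init__(self, genome: Sequence[GenomeSequence], k: int = 11) -> None:
        if not 8 <= k <= 16:
            raise ParameterError(f"k={k} outside [8, 16]")
        self.k = k
        self.total_length = sum(len(g) for g in genome)
        self.chroms = {g.chrom_id: g for g in genome}
        self.chrom_names = [g.chrom_id for g in genome]
        offsets = np.cumsum([0] + [len(g) for g in genome])
        self.chrom_starts = offsets[:-1]
        ids_parts, pos_parts = [], []
        for g, off in zip(genome, self.chrom_starts):
            ids = _kmer_ids(_encode(g.sequence), k)
            keep = ids >= 0
            ids_parts.append(ids[keep])
            pos_parts.append(np.nonzero(keep)[0].astype(np.int64) + off)
        all_ids = np.concatenate(ids_parts) if ids_parts else np.empty(0, np.int64)
        all_pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        order = np.argsort(all_ids, kind="stable")
        self._ids_sorted = all_ids[order]
        self._pos_sorted = all_pos[order]

    def _lookup_id(self, kmer_id: int) -> np.ndarray:
        """Global 0-based positions of one k-mer id."""
        lo = np.searchsorted(self._ids_sorted, kmer_id, side="left")
        hi = np.searchsorted(self._ids_sorted, kmer_id, side="right")
        return self._pos_sorted[lo:hi]

    def _split_global(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.chrom_starts, gpos, side="right")) - 1
        return self.chrom_names[ci], int(gpos - self.chrom_starts[ci]) + 1

    def positions(self, kmer: str, strand: str = "+") -> list[tuple[str, int]]:
        """(chrom, 1-based start) occurrences of ``kmer`` on a strand."""
        if strand == "-":
            kmer = reverse_complement(kmer)
        codes = _encode(kmer)
        if len(codes) != self.k or (codes == 4).any():
            return []
        powers = 4 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)
        kmer_id = int(codes.astype(np.int64) @ powers)
        return [self._split_global(int(p)) for p in self._lookup_id(kmer_id)]


def build_kmer_index(genome: Sequence[GenomeSequence], k: int = 11) -> KmerIndex:
    return KmerIndex(genome, k)


# ---------------------------------------------------------------------------
# Karlin-Altschul lambda


def karlin_lambda(match: int, mismatch: int) -> float:
    """Positive root of sum_ij p_i p_j exp(lambda * s_ij) = 1 (uniform p)."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


# ---------------------------------------------------------------------------
# glocal affine alignment (query fully aligned, target substring free)


def glocal_align(query: str, target: str, params: ScanParams
                 ) -> tuple[float, int, int, int, int]:
    """Align all of ``query`` against a substring of ``target``.

    Returns (score, target_start0, target_end0, matches, columns) where the
    target span is 0-based half-open and columns counts aligned pairs plus
    internal gap columns (terminal free target overhang excluded).

    Row-vectorized affine DP; three states per cell (pair, query-consuming
    gap, target-consuming gap). Integer scores are exact in float32.
    """
    m, n = len(query), len(target)
    if m == 0 or n == 0:
        raise InputError("empty sequence in alignment")
    go, ge = np.float32(params.gap_open), np.float32(params.gap_extend)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    sub = np.where(
        (q[:, None] == t[None, :]) & (q[:, None] != ord("N")),
        np.float32(params.match), np.float32(params.mismatch),
    )

    M = np.full((m + 1, n + 1), NEG, dtype=np.float32)
    Ix = np.full((m + 1, n + 1), NEG, dtype=np.float32)
    Iy = np.full((m + 1, n + 1), NEG, dtype=np.float32)
    M[0, :] = 0.0  # free leading target overhang / fresh start
    js = np.arange(n + 1, dtype=np.float32)
    for i in range(1, m + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = best_prev[:-1] + sub[i - 1]
        Ix[i, :] = np.maximum(M[i - 1] + go, Ix[i - 1] + ge)
        # target-consuming gap: running-max scan within the row
        a = M[i] - ge * js
        prefix = np.maximum.accumulate(a)
        Iy[i, 1:] = go + ge * (js[1:] - 1.0) + prefix[:-1]

    ends = np.maximum(M[m], Ix[m])
    j_end = int(np.argmax(ends))
    score = float(ends[j_end])

    # traceback (scalar comparisons: the matrices hold exact integers in
    # float32, so >= tie-breaks are deterministic)
    ql, tl = list(query), list(target)
    i, j = m, j_end
    state = "M" if M[m, j_end] >= Ix[m, j_end] else "X"
    gof, gef = float(go), float(ge)
    matches = columns = 0
    while i > 0:
        if state == "M":
            if ql[i - 1] == tl[j - 1] and ql[i - 1] != "N":
                matches += 1
            columns += 1
            i, j = i - 1, j - 1
            if i == 0:
                break
            vm, vx, vy = M[i, j], Ix[i, j], Iy[i, j]
            state = "M" if vm >= vx and vm >= vy else ("X" if vx >= vy else "Y")
        elif state == "X":
            columns += 1
            state = "M" if M[i - 1, j] + gof >= Ix[i - 1, j] + gef else "X"
            i -= 1
        else:  # Y
            columns += 1
            state = "M" if M[i, j - 1] + gof >= Iy[i, j - 1] + gef else "Y"
            j -= 1
    return score, j, j_end, matches, columns


# ---------------------------------------------------------------------------
# seeding and chaining


def _chains(seeds: list[tuple[int, int]], params: ScanParams
            ) -> list[list[tuple[int, int]]]:
    """Group (diagonal, query_offset) seeds into diagonal-band chains."""
    if not seeds:
        return []
    seeds = sorted(seeds)
    groups: list[list[tuple[int, int]]] = [[seeds[0]]]
    for s in seeds[1:]:
        if s[0] - groups[-1][-1][0] <= params.band:
            groups[-1].append(s)
        else:
            groups.append([s])
    chains: list[list[tuple[int, int]]] = []
    for grp in groups:
        grp.sort(key=lambda s: s[1])
        cur = [grp[0]]
        for s in grp[1:]:
            if s[1] - cur[-1][1] <= params.chain_gap:
                cur.append(s)
            else:
                chains.append(cur)
                cur = [s]
        chains.append(cur)
    return [c for c in chains if len(c) >= params.min_chain_seeds]


def _merge_cochained(chains: list[list[tuple[int, int]]], m: int,
                     margin: int) -> list[list[tuple[int, int]]]:
    """Union chains whose approximate target spans overlap.

    Off-register repeat matches and indels split one locus into several
    partial chains on nearby diagonals; extending a partial chain clips
    the alignment window and under-scores the locus, so co-located chains
    are pooled and the locus is extended once over its full window.
    """
    if not chains:
        return []
    spans = sorted(
        (min(d for d, _ in c), max(d for d, _ in c) + m, c) for c in chains
    )
    merged: list[tuple[int, int, list[tuple[int, int]]]] = []
    for lo, hi, chain in spans:
        if merged and lo <= merged[-1][1] + margin:
            prev_lo, prev_hi, prev_chain = merged[-1]
            merged[-1] = (prev_lo, max(prev_hi, hi), prev_chain + chain)
        else:
            merged.append((lo, hi, list(chain)))
    return [c for _lo, _hi, c in merged]


def scan(query_id: str, query_seq: str, index: KmerIndex,
         params: ScanParams = ScanParams()) -> list[HomologyHit]:
    """Find homologous loci of one query; hits sorted by score descending."""
    k = index.k
    lam = karlin_lambda(params.match, params.mismatch)
    hits: list[HomologyHit] = []
    for strand in "+-":
        q = query_seq if strand == "+" else reverse_complement(query_seq)
        m = len(q)
        # seeds per chromosome: (diagonal, query offset)
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        q_ids = _kmer_ids(_encode(q), k)
        lo = np.searchsorted(index._ids_sorted, q_ids, side="left")
        hi = np.searchsorted(index._ids_sorted, q_ids, side="right")
        counts = hi - lo
        hits_at = np.nonzero((q_ids >= 0) & (counts > 0)
                             & (counts <= params.max_kmer_occurrences))[0]
        starts = index.chrom_starts
        names = index.chrom_names
        for i in hits_at:
            for gpos in index._pos_sorted[lo[i]:hi[i]]:
                ci = int(np.searchsorted(starts, gpos, side="right")) - 1
                local0 = int(gpos - starts[ci])
                per_chrom.setdefault(names[ci], []).append((local0 - int(i), int(i)))
        for chrom, seeds in per_chrom.items():
            genome = index.chroms[chrom]
            chains = _merge_cochained(_chains(seeds, params), m, params.band)
            chains.sort(key=len, reverse=True)
            worklist = chains[: params.max_chains_per_strand]
            seen_spans: list[tuple[int, int]] = []
            extensions = 0
            while worklist and extensions < 4 * params.max_chains_per_strand:
                chain = worklist.pop(0)
                # off-register repeat chains re-describe an already-aligned
                # locus; skip any chain centered inside an accepted span
                mid = sorted(d + i for d, i in chain)[len(chain) // 2]
                if any(a <= mid <= b for a, b in seen_spans):
                    continue
                dmin = min(s[0] for s in chain)
                dmax = max(s[0] for s in chain)
                t0 = max(0, dmin - params.band)
                t1 = min(len(genome), dmax + m + params.band)
                if t1 - t0 < k:
                    continue
                extensions += 1
                region = genome.sequence[t0:t1]
                score, js, je, matches, columns = glocal_align(q, region, params)
                if columns == 0:
                    continue
                start1, end1 = t0 + js + 1, t0 + je
                dup = any(min(end1, b) - max(start1, a) > 0.5 * (end1 - start1)
                          for a, b in seen_spans)
                if not dup:
                    # remember the span even when the hit is rejected, so
                    # weak loci are not re-extended chain after chain
                    seen_spans.append((start1, end1))
                # a chain (especially over tandem repeat arrays) can span
                # several gene copies: the alignment claims one copy, the
                # leftover seeds on either side go back on the worklist
                left = [s for s in chain if s[0] + s[1] < start1 - k]
                right = [s for s in chain if s[0] + s[1] > end1 + k]
                for part in (left, right):
                    if params.min_chain_seeds <= len(part) < len(chain):
                        worklist.append(part)
                if dup or score <= 0:
                    continue
                evalue = params.ka_k * m * index.total_length * math.exp(-lam * score)
                if evalue > params.evalue_cutoff:
                    continue
                hits.append(HomologyHit(
                    query_id=query_id, chrom=chrom, strand=strand,
                    start=start1, end=end1, score=score,
                    identity_pct=100.0 * matches / columns,
                    evalue_surrogate=evalue,
                ))
    hits.sort(key=lambda h: h.score, reverse=True)
    return hits


def scan_queries(queries: QuerySet, index: KmerIndex,
                 params: ScanParams = ScanParams()) -> list[HomologyHit]:
    out: list[HomologyHit] = []
    for qid, seq, _hint in queries.records:
        out.extend(scan(qid, seq, index, params))
    return out


# ---------------------------------------------------------------------------
# locus merging and ORF extraction


def _longest_orf(oriented: str) -> tuple[int, int] | None:
    """Longest ATG..stop span (0-based half-open, stop included) over the
    three reading frames of an oriented sequence."""
    best: tuple[int, int] | None = None
    n = len(oriented)
    for frame in range(3):
        open_start: int | None = None
        for p in range(frame, n - 2, 3):
            codon = oriented[p : p + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    span = (open_start, p + 3)
                    if best is None or span[1] - span[0] > best[1] - best[0]:
                        best = span
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = p
    return best


def merge_to_loci(hits: Sequence[HomologyHit],
                  genome: Sequence[GenomeSequence] | None = None,
                  merge_gap: int = 2000,
                  orf_flank: int = 1000) -> list[CandidateLocus]:
    """Union hits on one chromosome/strand whose spans lie within
    ``merge_gap``; report the longest complete ORF near each locus.

    Loci without any complete ORF (e.g. over a pseudogene) are retained
    with an empty ORF span — that absence is itself pseudogene evidence.
    """
    chrom_map = {g.chrom_id: g for g in genome} if genome else {}
    by_key: dict[tuple[str, str], list[HomologyHit]] = {}
    for h in hits:
        by_key.setdefault((h.chrom, h.strand), []).append(h)
    loci: list[CandidateLocus] = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: (h.start, h.end))
        cluster: list[HomologyHit] = [group[0]]
        clusters: list[list[HomologyHit]] = [cluster]
        for h in group[1:]:
            if h.start - max(x.end for x in cluster) <= merge_gap:
                cluster.append(h)
            else:
                cluster = [h]
                clusters.append(cluster)
        for cl in clusters:
            start = min(h.start for h in cl)
            end = max(h.end for h in cl)
            orf_span = None
            g = chrom_map.get(chrom)
            if g is not None:
                w0 = max(1, start - orf_flank)
                w1 = min(len(g), end + orf_flank)
                window = g.slice1(w0, w1)
                oriented = window if strand == "+" else reverse_complement(window)
                span = _longest_orf(oriented)
                if span is not None:
                    if strand == "+":
                        orf_span = (w0 + span[0], w0 + span[1] - 1)
                    else:
                        orf_span = (w1 - span[1] + 1, w1 - span[0])
            loci.append(CandidateLocus(chrom, strand, start, end, tuple(cl), orf_span))
    return loci
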