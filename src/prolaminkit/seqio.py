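"""FASTA / GFF3 input-output and gene-model materialization.

Prolamin genes are intronless, so gene models here are thin: a strand, a
span and one or a few CDS segments. Coordinates are GFF3-style 1-based
inclusive everywhere; no half-open representation is ever exposed.

Nucleotide ambiguity codes other than N are coerced to N on input, and any
codon containing an N translates to X. This keeps downstream pseudogene
calling conservative: an ambiguous codon is never allowed to fake a stop
codon or rescue one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import CoordinateError, FormatError, InputError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> residue for the standard genetic code; stops map to "*"
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})

_NON_ACGTN = re.compile(r"[^ACGTN]")


def clean_nucleotides(seq: str) -> str:
    """Uppercase and coerce every non-ACGTN symbol to N."""
    return _NON_ACGTN.sub("N", seq.upper())


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome / scaffold of a genome assembly."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"empty sequence for {self.chrom_id!r}")
        object.__setattr__(self, "sequence", clean_nucleotides(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    def slice1(self, start: int, end: int) -> str:
        """Subsequence by 1-based inclusive coordinates."""
        if start < 1 or end > len(self.sequence) or start > end:
            raise CoordinateError(
                f"span {start}-{end} outside {self.chrom_id!r} (length {len(self.sequence)})"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class GeneModel:
    """A located gene with strand and CDS segments on one chromosome.

    ``cds_segments`` are (start, end) pairs, 1-based inclusive, stored in
    genomic order regardless of strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_segments: tuple[tuple[int, int], ...]
    subgenome_or_genome: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise InputError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.start > self.end:
            raise InputError(f"{self.gene_id}: start {self.start} > end {self.end}")
        segs = tuple(sorted((int(a), int(b)) for a, b in self.cds_segments))
        if not segs:
            raise InputError(f"{self.gene_id}: no CDS segments")
        prev_end = None
        for a, b in segs:
            if a > b:
                raise InputError(f"{self.gene_id}: CDS segment {a}-{b} reversed")
            if a < self.start or b > self.end:
                raise InputError(
                    f"{self.gene_id}: CDS segment {a}-{b} outside gene span "
                    f"{self.start}-{self.end}"
                )
            if prev_end is not None and a <= prev_end:
                raise InputError(f"{self.gene_id}: overlapping CDS segments at {a}-{b}")
            prev_end = b
        object.__setattr__(self, "cds_segments", segs)

    @property
    def spliced_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_segments)


@dataclass(frozen=True)
class CodingSequence:
    """Spliced, strand-oriented CDS nucleotides of one gene."""

    gene_id: str
    nucleotides: str
    complete_flag: bool  # terminal stop codon present, in frame

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass(frozen=True)
class ProteinRecord:
    """Translation of a CDS.

    Premature stops are rendered as X in ``residues`` and their 1-based
    codon indices recorded, so a pseudogene translation keeps its full
    length and stays scannable for residual motif evidence.
    """

    gene_id: str
    residues: str
    internal_stop_positions: tuple[int, ...] = ()
    trailing_partial_codon: bool = False

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA file, preserving record order."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: not FASTA (no '>' header)")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        records.append(GenomeSequence(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[GenomeSequence | tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomeSequence):
                name, seq = rec.chrom_id, rec.sequence
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _attr(feature: gffutils.Feature, key: str) -> str | None:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def _infer_genome_label(chrom: str) -> str:
    """Default genome/subgenome label: trailing letter of the chromosome
    name (``6E`` -> ``E``, ``chr1A`` -> ``A``), empty if none."""
    m = re.search(r"([A-Za-z])$", chrom)
    return m.group(1).upper() if m else ""


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Materialize gene models from a GFF3 file.

    Supports the gene/mRNA/CDS subset with ID/Parent attributes. A CDS may
    also be a direct child of a gene (intronless prolamin genes are often
    annotated without an mRNA line).
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"{path}: cannot parse GFF3 ({exc})") from exc

    ids = {f.id for f in db.all_features()}
    # index CDS by parent, validating parent resolution
    cds_by_parent: dict[str, list[gffutils.Feature]] = {}
    for cds in db.features_of_type("CDS"):
        parent = _attr(cds, "Parent")
        if parent is None or parent not in ids:
            raise FormatError(
                f"{path}: CDS without resolvable Parent: {str(cds).strip()}"
            )
        cds_by_parent.setdefault(parent, []).append(cds)

    models = []
    for gene in db.features_of_type("gene"):
        segs: list[tuple[int, int]] = []
        for holder in [gene] + list(db.children(gene, featuretype="mRNA")):
            for cds in cds_by_parent.get(holder.id, []):
                segs.append((cds.start, cds.end))
        if not segs:
            continue
        genome = _attr(gene, "genome") or _infer_genome_label(gene.seqid)
        try:
            models.append(
                GeneModel(
                    gene_id=gene.id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    start=gene.start,
                    end=gene.end,
                    cds_segments=tuple(sorted(set(segs))),
                    subgenome_or_genome=genome,
                )
            )
        except InputError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal gene + CDS GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda x: (x.chrom, x.start)):
            attrs = f"ID={m.gene_id}"
            if m.subgenome_or_genome:
                attrs += f";genome={m.subgenome_or_genome}"
            fh.write(
                f"{m.chrom}\tprolaminkit\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for i, (a, b) in enumerate(m.cds_segments, 1):
                fh.write(
                    f"{m.chrom}\tprolaminkit\tCDS\t{a}\t{b}\t.\t{m.strand}\t0\t"
                    f"ID={m.gene_id}.cds{i};Parent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# CDS extraction and translation


def extract_cds(model: GeneModel, genome: GenomeSequence) -> CodingSequence:
    """Splice CDS segments 5'->3' in transcription order.

    Minus-strand genes are reverse-complemented after concatenation in
    genomic order, which is equivalent to concatenating reverse-complemented
    segments in reverse genomic order.
    """
    if model.chrom != genome.chrom_id:
        raise InputError(
            f"{model.gene_id}: model on {model.chrom!r} but genome is {genome.chrom_id!r}"
        )
    spliced = "".join(genome.slice1(a, b) for a, b in model.cds_segments)
    if model.strand == "-":
        spliced = reverse_complement(spliced)
    complete = (
        len(spliced) >= 3
        and len(spliced) % 3 == 0
        and spliced[-3:] in STOP_CODONS
    )
    return CodingSequence(model.gene_id, spliced, complete)


def translate(cds: CodingSequence) -> ProteinRecord:
    """Translate a CDS with the standard genetic code.

    A terminal stop codon is dropped; premature stops become X with their
    codon index recorded; a trailing partial codon is dropped and flagged.
    """
    seq = cds.nucleotides
    if len(seq) < 3:
        raise InputError(f"{cds.gene_id}: CDS shorter than one codon")
    trailing = len(seq) % 3 != 0
    n_codons = len(seq) // 3
    residues = []
    stops: list[int] = []
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        aa = CODON_TO_AA.get(codon, "X")  # any N-containing codon -> X
        if aa == "*":
            if i == n_codons - 1 and not trailing:
                break  # terminal stop: dropped
            stops.append(i + 1)
            aa = "X"
        residues.append(aa)
    return ProteinRecord(
        gene_id=cds.gene_id,
        residues="".join(residues),
        internal_stop_positions=tuple(stops),
        trailing_partial_codon=trailing,
    )
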