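"""Celiac-disease epitope scanning of deduced functional prolamin proteins.

The scan is a literal, overlap-aware substring count: every start position
of an exact occurrence counts once, so the proteolysis-resistant 33-mer
(LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF) contributes one DQ2.5-glia-a1a, two
DQ2.5-glia-a1b and three DQ2.5-glia-a2 occurrences by itself. No
mismatches or deamidation are modelled.

Only putative functional proteins are scanned by default — pseudogene
translations are not part of the expressed epitope repertoire — but an
override flag allows scanning them anyway.

Two spellings of DQ2.5-glia-a3 circulate (a 9-mer FRPQQPYPQ and a 10-mer
FRPQQQPYPQ); both ship in the default definition table, the 9-mer active,
the alternative selectable by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .annotate import round_pct
from .errors import InputError
from .seqio import ProteinRecord

GLIA_A1A = "DQ2.5-glia-a1a"
GLIA_A1B = "DQ2.5-glia-a1b"
GLIA_A2 = "DQ2.5-glia-a2"
GLIA_A3 = "DQ2.5-glia-a3"
DQ8 = "DQ8-glia-a1/DQ8.5-glia-a1"
MER33 = "33-mer"

#: alternative 10-mer spelling of DQ2.5-glia-a3, selectable by config
GLIA_A3_ALT_PEPTIDE = "FRPQQQPYPQ"


@dataclass(frozen=True)
class EpitopeDef:
    name: str
    peptide: str

    def __post_init__(self) -> None:
        if len(self.peptide) < 9:
            raise InputError(f"epitope {self.name}: peptide shorter than 9 aa")


DEFAULT_EPITOPES: tuple[EpitopeDef, ...] = (
    EpitopeDef(GLIA_A1A, "PFPQPQLPY"),
    EpitopeDef(GLIA_A1B, "PYPQPQLPY"),
    EpitopeDef(GLIA_A2, "PQPQLPYPQ"),
    EpitopeDef(GLIA_A3, "FRPQQPYPQ"),
    EpitopeDef(DQ8, "QGSFQPSQQ"),
    EpitopeDef(MER33, "LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF"),
)


def count_overlapping(text: str, pattern: str) -> int:
    """Occurrences of ``pattern`` in ``text``, counting every start site."""
    count = 0
    pos = text.find(pattern)
    while pos != -1:
        count += 1
        pos = text.find(pattern, pos + 1)
    return count


def multiplicity_class(count: int) -> str:
    if count == 0:
        return "absent"
    return "single" if count == 1 else "multiple"


@dataclass(frozen=True)
class EpitopeProfile:
    gene_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def carries(self, name: str) -> bool:
        return self.counts.get(name, 0) > 0

    def classes(self) -> dict[str, str]:
        return {name: multiplicity_class(c) for name, c in self.counts.items()}


def scan_epitopes(protein: ProteinRecord | str,
                  defs: Sequence[EpitopeDef] = DEFAULT_EPITOPES,
                  *, functional: bool = True,
                  allow_pseudogenes: bool = False) -> EpitopeProfile:
    """Overlap-aware exact occurrence counts of each epitope.

    Refuses pseudogene input unless ``allow_pseudogenes`` is set, because
    the repertoire is defined over deduced functional proteins.
    """
    if not functional and not allow_pseudogenes:
        raise InputError(
            "refusing to scan a pseudogene translation "
            "(set allow_pseudogenes=True to override)"
        )
    if isinstance(protein, ProteinRecord):
        gene_id, residues = protein.gene_id, protein.residues
    else:
        gene_id, residues = "", protein
    counts = {d.name: count_overlapping(residues, d.peptide) for d in defs}
    return EpitopeProfile(gene_id, counts)


@dataclass(frozen=True)
class GenomeEpitopeSummary:
    genome: str
    n_functional_alpha: int
    carrier_pct: dict[str, float]          # per-epitope carrier fraction, %
    union_a1a_a3_pct: float                # carries a1a or a3
    dq8_only_pct: float                    # carries DQ8 and nothing else
    epitope_types_present: tuple[str, ...]


def summarize_genome(profiles: Sequence[EpitopeProfile], genome_label: str,
                     defs: Sequence[EpitopeDef] = DEFAULT_EPITOPES
                     ) -> GenomeEpitopeSummary:
    """Per-genome carrier fractions over functional alpha-gliadins.

    Reports, at one-decimal precision: the carrier fraction of each
    epitope, of the {a1a or a3} union, and of proteins whose only epitope
    is DQ8-glia-a1/DQ8.5-glia-a1.
    """
    if not profiles:
        raise InputError(f"no functional alpha-gliadin profiles for {genome_label!r}")
    n = len(profiles)
    names = [d.name for d in defs]
    carrier_pct = {
        name: round_pct(sum(p.carries(name) for p in profiles) / n)
        for name in names
    }
    union = sum(p.carries(GLIA_A1A) or p.carries(GLIA_A3) for p in profiles)
    dq8_only = sum(
        p.carries(DQ8) and not any(p.carries(x) for x in names if x != DQ8)
        for p in profiles
    )
    present = tuple(name for name in names if any(p.carries(name) for p in profiles))
    return GenomeEpitopeSummary(
        genome=genome_label,
        n_functional_alpha=n,
        carrier_pct=carrier_pct,
        union_a1a_a3_pct=round_pct(union / n),
        dq8_only_pct=round_pct(dq8_only / n),
        epitope_types_present=present,
    )


# ---------------------------------------------------------------------------
# definition table IO (2-column TSV: name <tab> peptide)


def read_epitope_table(path: str | Path) -> tuple[EpitopeDef, ...]:
    defs = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputError(f"{path}:{line_no}: expected 2 tab-separated columns")
        defs.append(EpitopeDef(parts[0], parts[1].upper()))
    if not defs:
        raise InputError(f"{path}: no epitope definitions")
    return tuple(defs)


def write_epitope_table(defs: Iterable[EpitopeDef], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# name\tpeptide\n")
        for d in defs:
            fh.write(f"{d.name}\t{d.peptide}\n")
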