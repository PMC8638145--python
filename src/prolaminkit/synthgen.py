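"""Synthetic genomes, gene panels and count matrices with known truth.

Every pipeline stage is testable offline against data whose ground truth
is planted, not inferred. The generator emulates the structure of a
Triticeae prolamin complement:

* per-subfamily gene grammars (signal peptide + repetitive domain +
  cysteine-bearing unique domains) whose translations satisfy the
  subfamily classifier by construction;
* tandem arrays on one chromosome (members < 100 kb apart, controlled
  intra-array nucleotide divergence via synonymous codon churn) and
  dispersed singletons (> 100 kb apart);
* exact-count pseudogenization (round(p * n) defects) so printed rates
  are reproduced deterministically, with premature-stop, frameshift and
  lost-start defect modes;
* celiac epitopes inserted into chosen functional alpha-gliadins,
  giving each genome its own repertoire;
* intergenic background drawn from an order-2 Markov chain fitted to the
  gene set, so homology-scan specificity is non-trivial;
* negative-binomial count matrices over six developmental stages with
  three replicates and per-sample library-size factors.

The default genome emulates a diploid wheatgrass E genome: 19 alpha-
(16 pseudo, including an isolated cluster of four pseudogenes on a
second chromosome), 9 gamma- (7 pseudo), 19 omega-gliadins, 2 HMW and
5 LMW glutenins, with tandem arrays sized so that 14/19 alpha, 8/9
gamma and 13/19 omega genes are tandem-duplicated.

All generators are pure functions of (spec, rng seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import epitopes as ep
from .errors import InputError, ParameterError, SpecError
from .expression import STAGES, CountMatrix
from .seqio import CODON_TO_AA, GeneModel, GenomeSequence, reverse_complement

#: residue -> synonymous codons, standard code
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for codon, aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(aa, ())
AA_TO_CODONS = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in set(CODON_TO_AA.values())
}
STOP_CHOICES = AA_TO_CODONS["*"]

PSEUDO_MODES = ("internal_stop", "frameshift", "no_start")

#: relative per-stage expression shapes (young spike ... grain), peak = 100
PATTERN_SHAPES: dict[str, tuple[float, ...]] = {
    "rise_then_fall": (1.0, 2.0, 8.0, 30.0, 100.0, 40.0),
    "rising": (1.0, 2.0, 5.0, 12.0, 40.0, 100.0),
    "flat": (100.0, 100.0, 100.0, 100.0, 100.0, 100.0),
}

EPITOPE_PEPTIDES = {d.name: d.peptide for d in ep.DEFAULT_EPITOPES}


# ---------------------------------------------------------------------------
# protein grammars

_SIG_ALPHA = "MKTFLILALLAIVATTA"
_ALPHA_U1 = "SGQGVSFGVPSRLPWL"
_ALPHA_CYS1 = "NIQVDPSGQVQWCQQWLCQTNPRAC"
_ALPHA_CYS2 = "ILHQQQKQQLVETIRSLVLQTLPSMCNVYIPPYCSTTIAPFC"
_ALPHA_TAIL = "GIFGTNRSDAHSIQAPLQ"

_SIG_GAMMA = "MKTLLILTILAMATNIA"
_GAMMA_NTERM = "NMQVDPSGQVQWPQQQPFP"
_GAMMA_CYS = ("VSQQQAQDVVSGC" "STIAAPFASIVAGIGGQC" "QAPTTLQHNC" "CHVMQQQC"
              "DRELQGLQRC" "SNIATTNNQC" "QTLPTMC" "SVNVPLW")
_GAMMA_TAIL = "FDSPVLQSLQGIIQPHQPAQL"

_SIG_OMEGA = "MKTFLIFALLAMAMSIA"
_OMEGA_NTERM = "ARELNPSNKELQSPHQSF"
_OMEGA_TAIL = "SGSDARTIPHMTSPLVSG"

_SIG_LMW = "MKTFLVFALLAVAATSA"
_LMW_NTERM = "SHIPGLERPSQQQPLPPHQ"
_LMW_CYS = ("QIPEQSRC" "QAIHNVVHAIC" "IMQEQQEGVQILRPLFC" "C" "QLAQGLGIIC"
            "QPHQELQTASC" "RVDQQLVGQLC" "EWSTNPMTMAC" "RNLALQTLPAM")
_LMW_TAIL = "SQQQSYQLLQQLAQGQGIQGE"

_SIG_HMW = "MAKRLVLFAAVVVALVALTAA"
_HMW_NTERM_X = ("EGEASEQLQC" "ERELQELQERELKAC" "QQVMDQQLRDISPEC"
                "HPVVVSPVAGQYEQQIVVPPKGGSFYPGETTPPQQLQQRIFWGIPALLKRYV")
_HMW_NTERM_Y = ("EGEASRQLQC" "ERELQEC" "RQVVDQQLAGRLPWC"
                "STNPQAVGQYEQQVVVPPKGGSFC" "YPGETTPPQQLQQSIFWGIPALLRRYVC")
_HMW_TAIL = "AMSQMSLQCNMGQIPEQAKSPLPS"

_SIG_DELTA = "MKIFLIFALLAMAVNMA"
_DELTA_CYS = "TIPQNPCANQLSHCDTIAPFCCQPLQTSCLVPSHAC"
_DELTA_TAIL = "QVGQGTFLQPHQIAQLEVMTSIALRTLPTM"


def _units(rng: np.random.Generator, pattern: Sequence[str],
           lo: int, hi: int) -> str:
    """A repeat domain of n units (n drawn from [lo, hi]) cycling through
    ``pattern`` deterministically — repeat domains within a subfamily are
    homogeneous across genes, as in real prolamins, so cross-gene
    nucleotide divergence comes from codon choice and unit count only."""
    n = int(rng.integers(lo, hi + 1))
    return "".join(pattern[i % len(pattern)] for i in range(n))


def build_protein(subfamily: str, rng: np.random.Generator,
                  epitope_names: Sequence[str] = ()) -> str:
    """Mature protein (with signal peptide, without stop) for one subfamily.

    Epitope peptides, given by name, are inserted directly after the
    signal peptide of an alpha-gliadin; planting into other subfamilies
    is not modelled.
    """
    if epitope_names and subfamily != "alpha":
        raise SpecError("epitope planting is defined for alpha-gliadins only")
    # the serine spacer keeps an epitope's tail from combining with the
    # repeat domain into an unplanned second epitope
    insert = "".join(EPITOPE_PEPTIDES[name] + "S" for name in epitope_names)
    if subfamily == "alpha":
        rep = _units(rng, ("PQPQPF", "PQPQPF", "PQPQPY"), 20, 24)
        q1 = "Q" * int(rng.integers(8, 13))
        q2 = "Q" * int(rng.integers(8, 13))
        return (_SIG_ALPHA + insert + rep + q1 + _ALPHA_U1 + _ALPHA_CYS1
                + q2 + _ALPHA_CYS2 + _ALPHA_TAIL)
    if subfamily == "gamma":
        rep = _units(rng, ("PQQPFPQ", "PQQPFPQ", "PQQPYPQ"), 16, 19)
        return _SIG_GAMMA + _GAMMA_NTERM + rep + _GAMMA_CYS + _GAMMA_TAIL
    if subfamily == "omega":
        rep = _units(rng, ("PQQPF", "PQQPF", "PQQPY"), 56, 68)
        return _SIG_OMEGA + _OMEGA_NTERM + rep + _OMEGA_TAIL
    if subfamily == "LMW":
        rep = _units(rng, ("QQQPPFS", "PQQPPFS"), 20, 26)
        return _SIG_LMW + _LMW_NTERM + rep + _LMW_CYS + _LMW_TAIL
    if subfamily in ("HMW_x", "HMW_y"):
        rep = _units(rng, ("PGQGQQ", "PGQGQQ", "GYYPTS"), 82, 92)
        nterm = _HMW_NTERM_X if subfamily == "HMW_x" else _HMW_NTERM_Y
        return _SIG_HMW + nterm + rep + _HMW_TAIL
    if subfamily == "delta":
        rep = _units(rng, ("QQPQQPF",), 10, 13)
        return _SIG_DELTA + rep + _DELTA_CYS + _DELTA_TAIL
    raise SpecError(f"unknown subfamily {subfamily!r}")


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous codon choice per residue (no stop appended)."""
    return "".join(
        AA_TO_CODONS[aa][int(rng.integers(0, len(AA_TO_CODONS[aa])))]
        for aa in protein
    )


def generate_gene(subfamily: str, rng: np.random.Generator,
                  epitope_names: Sequence[str] = ()) -> tuple[str, str]:
    """(CDS nucleotides incl. stop codon, protein residues)."""
    protein = build_protein(subfamily, rng, epitope_names)
    cds = reverse_translate(protein, rng) + STOP_CHOICES[int(rng.integers(0, 3))]
    return cds, protein


def diverge_synonymous(cds: str, rng: np.random.Generator,
                       target_frac: float) -> str:
    """Mutate codons to synonymous alternatives until roughly
    ``target_frac`` of nucleotides differ. The protein is unchanged, so
    planted classifications and epitopes survive divergence."""
    if not 0 <= target_frac <= 0.5:
        raise ParameterError("divergence fraction outside [0, 0.5]")
    codons = [cds[i:i + 3] for i in range(0, len(cds) - 2, 3)]
    target = target_frac * len(cds)
    changed = 0
    order = rng.permutation(len(codons))
    for idx in order:
        if changed >= target:
            break
        old = codons[int(idx)]
        aa = CODON_TO_AA.get(old)
        if aa is None:
            continue
        alts = [c for c in AA_TO_CODONS[aa] if c != old]
        if not alts:
            continue
        new = alts[int(rng.integers(0, len(alts)))]
        changed += sum(a != b for a, b in zip(old, new))
        codons[int(idx)] = new
    return "".join(codons) + cds[len(codons) * 3:]


def insert_epitopes_cds(cds: str, epitope_names: Sequence[str],
                        rng: np.random.Generator,
                        after_codon: int = len(_SIG_ALPHA)) -> str:
    """Splice epitope peptide codons into a CDS right after the signal
    peptide, leaving the rest of the sequence untouched. A serine spacer
    after each peptide prevents unplanned epitopes at the junctions."""
    peptide = "".join(EPITOPE_PEPTIDES[name] + "S" for name in epitope_names)
    pos = 3 * after_codon
    return cds[:pos] + reverse_translate(peptide, rng) + cds[pos:]


def pseudogenize(cds: str, rng: np.random.Generator, mode: str) -> str:
    """Introduce exactly one defect of the requested mode.

    internal_stop replaces a middle codon with a stop; frameshift deletes
    one nucleotide in the middle; no_start mutates the initial ATG.
    """
    if mode not in PSEUDO_MODES:
        raise ParameterError(f"unknown pseudogenization mode {mode!r}")
    n_codons = len(cds) // 3
    if n_codons < 12:
        raise InputError("sequence too short to host a defect")
    if mode == "internal_stop":
        pos = int(rng.integers(n_codons // 4, 3 * n_codons // 4))
        stop = STOP_CHOICES[int(rng.integers(0, 3))]
        return cds[: 3 * pos] + stop + cds[3 * pos + 3:]
    if mode == "frameshift":
        pos = int(rng.integers(len(cds) // 4, 3 * len(cds) // 4))
        return cds[:pos] + cds[pos + 1:]
    first = ("CTG", "GTG", "ATA")[int(rng.integers(0, 3))]
    return first + cds[3:]


# ---------------------------------------------------------------------------
# genome assembly


@dataclass(frozen=True)
class ArraySpec:
    """One placement unit: a tandem array (size >= 2) or a singleton."""

    chrom: str
    subfamily: str
    size: int
    n_pseudo: int = 0
    divergence_pct: float = 5.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.size < 1 or not 0 <= self.n_pseudo <= self.size:
            raise SpecError(f"bad array spec {self.name or self.subfamily}")
        if not 0 <= self.divergence_pct <= 50:
            raise SpecError("divergence_pct outside [0, 50]")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    genome_label: str
    arrays: tuple[ArraySpec, ...]
    #: epitope-name tuples cycled over functional alpha-gliadins in
    #: gene-id order (the genome's planted repertoire)
    alpha_epitope_plan: tuple[tuple[str, ...], ...] = ()
    chromosome_lengths: dict[str, int] | None = None
    array_spacing: tuple[int, int] = (2_500, 6_000)       # within arrays, bp
    unit_spacing: tuple[int, int] = (101_000, 126_000)    # between units, bp
    margin: int = 10_000
    #: per-subfamily expression base (mean TPM-scale at peak) for
    #: functional genes; pseudogenes share one low flat base
    expr_base: dict[str, float] = field(default_factory=lambda: {
        "alpha": 40.0, "gamma": 66.0, "omega": 15.0,
        "LMW": 50.0, "HMW_x": 60.0, "HMW_y": 45.0, "delta": 10.0,
    })
    #: pseudogenes are transcribed at a low, stage-constant level — well
    #: below every functional base but out of the Poisson-zero regime
    pseudo_expr_base: float = 4.0
    #: functional-gene expression pattern per subfamily; the storage-
    #: protein burst peaks at half grain except for the late subfamilies
    expr_pattern: dict[str, str] = field(default_factory=lambda: {
        "alpha": "rise_then_fall", "gamma": "rising", "omega": "rise_then_fall",
        "LMW": "rise_then_fall", "HMW_x": "rise_then_fall", "HMW_y": "rising",
        "delta": "rise_then_fall",
    })
    #: second functional gamma-gliadin is expressed this much lower than
    #: the first (a planted within-subfamily fold difference)
    gamma_fold: float = 5.5


def thinopyrum_e_spec() -> SyntheticGenomeSpec:
    """Default diploid E-genome layout.

    19 alpha (16 pseudo; a 10-array and 5 singletons on chromosome 6E
    plus an all-pseudogene 4-array on 7E), 9 gamma (7 pseudo; 8-array +
    singleton), 19 omega (8-array + 5-array + 6 singletons), 5 LMW
    (2-array + 3 singletons) and one x- plus one y-type HMW glutenin on
    chromosome 1E. Tandem fractions follow: alpha 14/19, gamma 8/9,
    omega 13/19, LMW 2/5. Functional alpha-gliadins carry the DQ8
    epitope in two of three cases and nothing else.
    """
    arrays = (
        # 1E short arm: omega / gamma / LMW region, then HMW on the long arm
        ArraySpec("1E", "omega", 8, n_pseudo=3),
        ArraySpec("1E", "omega", 5, n_pseudo=2),
        ArraySpec("1E", "omega", 1, n_pseudo=1),
        ArraySpec("1E", "omega", 1, n_pseudo=1),
        ArraySpec("1E", "omega", 1, n_pseudo=1),
        ArraySpec("1E", "omega", 1, n_pseudo=1),
        ArraySpec("1E", "omega", 1, n_pseudo=1),
        ArraySpec("1E", "omega", 1, n_pseudo=0),
        ArraySpec("1E", "gamma", 8, n_pseudo=6),
        ArraySpec("1E", "gamma", 1, n_pseudo=1),
        ArraySpec("1E", "LMW", 2, n_pseudo=0),
        ArraySpec("1E", "LMW", 1, n_pseudo=0),
        ArraySpec("1E", "LMW", 1, n_pseudo=1),
        ArraySpec("1E", "LMW", 1, n_pseudo=0),
        ArraySpec("1E", "HMW_x", 1, n_pseudo=0),
        ArraySpec("1E", "HMW_y", 1, n_pseudo=0),
        # 6E: the main alpha-gliadin locus
        ArraySpec("6E", "alpha", 10, n_pseudo=8),
        ArraySpec("6E", "alpha", 1, n_pseudo=1),
        ArraySpec("6E", "alpha", 1, n_pseudo=1),
        ArraySpec("6E", "alpha", 1, n_pseudo=0),
        ArraySpec("6E", "alpha", 1, n_pseudo=1),
        ArraySpec("6E", "alpha", 1, n_pseudo=1),
        # 7E: the isolated all-pseudogene alpha cluster
        ArraySpec("7E", "alpha", 4, n_pseudo=4),
    )
    return SyntheticGenomeSpec(
        genome_label="E",
        arrays=arrays,
        alpha_epitope_plan=((ep.DQ8,), (ep.DQ8,), ()),
    )


def small_demo_spec() -> SyntheticGenomeSpec:
    """A minimal one-chromosome genome (one alpha tandem array plus two
    singletons) for quick demonstrations and fast tests."""
    return SyntheticGenomeSpec(
        genome_label="T",
        arrays=(
            ArraySpec("1T", "alpha", 3, n_pseudo=1),
            ArraySpec("1T", "gamma", 1, n_pseudo=0),
            ArraySpec("1T", "omega", 1, n_pseudo=1),
        ),
        alpha_epitope_plan=((ep.GLIA_A1A,), ()),
    )


def _subfamily_token(subfamily: str) -> str:
    return {"alpha": "alpha_gliadin", "gamma": "gamma_gliadin",
            "omega": "omega_gliadin", "delta": "delta_gliadin",
            "LMW": "LMW_glutenin", "HMW_x": "hmw_glutenin_x",
            "HMW_y": "hmw_glutenin_y"}[subfamily]


def fit_markov_background(gene_seqs: Sequence[str]) -> np.ndarray:
    """Order-2 transition matrix (16 contexts x 4 bases, +1 pseudocount)
    fitted to the gene set, so intergenic background shares its
    GC/dinucleotide flavor."""
    idx = {b: i for i, b in enumerate("ACGT")}
    counts = np.ones((16, 4))
    for seq in gene_seqs:
        codes = [idx[b] for b in seq if b in idx]
        for i in range(2, len(codes)):
            counts[codes[i - 2] * 4 + codes[i - 1], codes[i]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def markov_background(length: int, transition: np.ndarray,
                      rng: np.random.Generator) -> str:
    cum = np.cumsum(transition, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    a, b = rng.integers(0, 4), rng.integers(0, 4)
    for i in range(length):
        ctx = a * 4 + b
        c = int(np.searchsorted(cum[ctx], u[i], side="right"))
        c = min(c, 3)
        out[i] = c
        a, b = b, c
    return "".join("ACGT"[c] for c in out)


def assemble_genome(spec: SyntheticGenomeSpec, rng: np.random.Generator
                    ) -> tuple[list[GenomeSequence], list[GeneModel], pd.DataFrame]:
    """Place planned genes on chromosomes and emit FASTA-able sequences,
    gene models and a truth table (one row per planted gene)."""
    counters: dict[tuple[str, str], int] = {}
    rows: list[dict] = []
    gene_seq: dict[str, str] = {}

    cluster_no = 0
    for unit in spec.arrays:
        cluster_no += 1
        cluster_id = f"cluster_{cluster_no}" if unit.size >= 2 else ""
        base_protein = build_protein(unit.subfamily, rng)
        base_cds = reverse_translate(base_protein, rng) \
            + STOP_CHOICES[int(rng.integers(0, 3))]
        pseudo_members = set(rng.permutation(unit.size)[: unit.n_pseudo].tolist())
        modes_cycle = ("internal_stop", "internal_stop", "frameshift", "no_start")
        mode_i = 0
        for member in range(unit.size):
            key = (unit.chrom, unit.subfamily)
            counters[key] = counters.get(key, 0) + 1
            gid = f"Tel_{_subfamily_token(unit.subfamily)}_{unit.chrom}_{counters[key]}"
            if unit.size >= 2:
                cds = diverge_synonymous(base_cds, rng, unit.divergence_pct / 100)
            else:
                prot = build_protein(unit.subfamily, rng)
                cds = reverse_translate(prot, rng) + STOP_CHOICES[int(rng.integers(0, 3))]
            defect = ""
            status = "functional"
            if member in pseudo_members:
                defect = modes_cycle[mode_i % len(modes_cycle)]
                mode_i += 1
                cds = pseudogenize(cds, rng, defect)
                status = "pseudogene"
            rows.append({
                "gene_id": gid, "chrom": unit.chrom,
                "subfamily": unit.subfamily, "status": status,
                "defect": defect, "cluster_id": cluster_id,
                "epitopes": "", "genome": spec.genome_label,
            })
            gene_seq[gid] = cds

    # epitope planting: cycle the plan over functional alpha-gliadins,
    # splicing epitope codons in after the signal peptide so array
    # relatedness is preserved
    if spec.alpha_epitope_plan:
        functional_alpha = [r for r in rows
                            if r["subfamily"] == "alpha" and r["status"] == "functional"]
        for i, row in enumerate(sorted(functional_alpha, key=lambda r: r["gene_id"])):
            names = spec.alpha_epitope_plan[i % len(spec.alpha_epitope_plan)]
            if not names:
                continue
            gene_seq[row["gene_id"]] = insert_epitopes_cds(
                gene_seq[row["gene_id"]], names, rng)
            row["epitopes"] = ";".join(names)

    # expression truth
    gamma_rank = 0
    for row in rows:
        if row["status"] == "pseudogene":
            row["pattern"], row["expr_base"] = "flat", spec.pseudo_expr_base
            continue
        sf = row["subfamily"]
        row["pattern"] = spec.expr_pattern[sf]
        base = spec.expr_base[sf]
        if sf == "gamma":
            gamma_rank += 1
            if gamma_rank == 2:
                base = base / spec.gamma_fold
        row["expr_base"] = base

    # placement
    transition = fit_markov_background(list(gene_seq.values()))
    chrom_order = list(dict.fromkeys(u.chrom for u in spec.arrays))
    genomes: list[GenomeSequence] = []
    models: list[GeneModel] = []
    unit_rows: dict[int, list[dict]] = {}
    i = 0
    for no, unit in enumerate(spec.arrays):
        unit_rows[no] = rows[i: i + unit.size]
        i += unit.size
    for chrom in chrom_order:
        parts: list[str] = []
        cursor = 0

        def emit_background(n: int) -> None:
            nonlocal cursor
            parts.append(markov_background(n, transition, rng))
            cursor += n

        emit_background(spec.margin)
        for no, unit in enumerate(spec.arrays):
            if unit.chrom != chrom:
                continue
            for j, row in enumerate(unit_rows[no]):
                if j > 0:
                    emit_background(int(rng.integers(*spec.array_spacing)))
                cds = gene_seq[row["gene_id"]]
                strand = "+" if rng.random() < 0.5 else "-"
                placed = cds if strand == "+" else reverse_complement(cds)
                start = cursor + 1
                parts.append(placed)
                cursor += len(placed)
                end = cursor
                row.update(strand=strand, start=start, end=end)
                models.append(GeneModel(
                    gene_id=row["gene_id"], chrom=chrom, strand=strand,
                    start=start, end=end, cds_segments=((start, end),),
                    subgenome_or_genome=spec.genome_label,
                ))
            emit_background(int(rng.integers(*spec.unit_spacing)))
        emit_background(max(0, spec.margin - spec.unit_spacing[0]))
        sequence = "".join(parts)
        wanted = (spec.chromosome_lengths or {}).get(chrom)
        if wanted is not None:
            if wanted < len(sequence):
                raise SpecError(
                    f"{chrom}: requested length {wanted} cannot hold "
                    f"{len(sequence)} bp of placed genes"
                )
            sequence += markov_background(wanted - len(sequence), transition, rng)
        genomes.append(GenomeSequence(chrom, sequence))

    truth = pd.DataFrame(rows)[
        ["gene_id", "chrom", "strand", "start", "end", "genome", "subfamily",
         "status", "defect", "cluster_id", "epitopes", "pattern", "expr_base"]
    ]
    return genomes, models, truth


# ---------------------------------------------------------------------------
# count matrices


def planted_stage_means(truth: pd.DataFrame) -> pd.DataFrame:
    """Gene x stage planted mean expression (TPM-scale units)."""
    mat = {
        row.gene_id: [row.expr_base * s / 100.0 for s in PATTERN_SHAPES[row.pattern]]
        for row in truth.itertuples()
    }
    return pd.DataFrame.from_dict(mat, orient="index", columns=list(STAGES))


def generate_counts(truth: pd.DataFrame, lengths: pd.Series,
                    rng: np.random.Generator, *, reps: int = 3,
                    dispersion: float = 0.1, depth_scale: float = 30.0,
                    lib_size_range: tuple[float, float] = (0.8, 1.2),
                    n_background: int = 400, background_base: float = 40.0,
                    background_length: int = 1200) -> CountMatrix:
    """Negative-binomial counts from the planted stage means.

    Expected count = mean * (length/1000) * depth * library factor;
    variance = m + dispersion * m^2. A dispersion below 1e-8 degrades to
    Poisson (the NB small-dispersion limit).

    Besides the prolamin genes, ``n_background`` stage-constant genes
    emulate the rest of the transcriptome. Without them the TPM
    denominator would be dominated by the storage-protein burst itself
    and every within-sample-normalized profile would flatten — the same
    reason real TPM values are computed genome-wide, not on a gene
    family alone.
    """
    if dispersion <= 0:
        raise ParameterError("dispersion must be > 0")
    means = planted_stage_means(truth)
    if n_background:
        bg_index = [f"background_{i + 1}" for i in range(n_background)]
        bg = pd.DataFrame(background_base, index=bg_index,
                          columns=list(STAGES))
        means = pd.concat([means, bg])
        lengths = pd.concat([
            lengths,
            pd.Series(background_length, index=bg_index, name=lengths.name),
        ])
    genes = list(means.index)
    samples, stages_meta, rep_meta = [], [], []
    cols = {}
    for stage in STAGES:
        for rep in range(1, reps + 1):
            sample = f"{stage}_r{rep}"
            lib = rng.uniform(*lib_size_range)
            m = (means[stage].values
                 * lengths.loc[genes].values / 1000.0
                 * depth_scale * lib)
            if dispersion < 1e-8:
                counts = rng.poisson(m)
            else:
                size = 1.0 / dispersion
                p = size / (size + np.maximum(m, 1e-12))
                counts = rng.negative_binomial(size, p)
                counts = np.where(m <= 0, 0, counts)
            cols[sample] = counts.astype(int)
            samples.append(sample)
            stages_meta.append(stage)
            rep_meta.append(rep)
    counts_df = pd.DataFrame(cols, index=genes)
    metadata = pd.DataFrame(
        {"stage": stages_meta, "replicate": rep_meta},
        index=pd.Index(samples, name="sample"),
    )
    return CountMatrix(counts_df, lengths.loc[genes], metadata)


# ---------------------------------------------------------------------------
# query sets and cross-genome panels


def generate_query_set(rng: np.random.Generator,
                       subfamilies: Sequence[str] = ("alpha", "gamma", "omega",
                                                     "delta", "LMW", "HMW_x",
                                                     "HMW_y")) -> list[tuple[str, str, str]]:
    """One independently drawn reference CDS per subfamily, standing in
    for the cross-species query genes of a homology search."""
    out = []
    for sf in subfamilies:
        cds, _ = generate_gene(sf, rng)
        out.append((f"query_{sf}", cds, sf))
    return out


#: per-genome alpha-gliadin epitope plans for the four-species comparison:
#: (number of functional genes, epitope names cycled per gene)
ALPHA_PANEL_PLANS: dict[str, tuple[int, tuple[tuple[str, ...], ...]]] = {
    # 14 of 15 carry DQ2.5-glia-a1a or -a3
    "A": (15, ((ep.GLIA_A1A,),) * 10 + ((ep.GLIA_A3,),) * 4 + ((),)),
    # 2 of 7 carry the DQ8 epitope and nothing else
    "B": (7, ((ep.DQ8,), (ep.DQ8,), (), (), (), (), ())),
    # all six types present; the 33-mer brings a1a/a1b/a2 with it
    "D": (10, ((ep.MER33,), (ep.MER33,), (ep.MER33,), (ep.GLIA_A1A,),
               (ep.GLIA_A1A,), (ep.GLIA_A3,), (ep.GLIA_A3,), (ep.DQ8,),
               (ep.DQ8,), ())),
}


def generate_alpha_panel(genome_label: str, rng: np.random.Generator
                         ) -> list[tuple[str, str, tuple[str, ...]]]:
    """(gene_id, protein, planted epitope names) for the functional
    alpha-gliadins of one genome."""
    if genome_label not in ALPHA_PANEL_PLANS:
        raise SpecError(f"no alpha panel plan for genome {genome_label!r}")
    n, plan = ALPHA_PANEL_PLANS[genome_label]
    out = []
    for i in range(n):
        names = plan[i % len(plan)]
        protein = build_protein("alpha", rng, names)
        out.append((f"{genome_label}_alpha_{i + 1}", protein, names))
    return out


def generate_hmw_panel(rng: np.random.Generator
                       ) -> list[tuple[str, str, str, str]]:
    """(gene_id, species, cds, expected subfamily) for the twelve HMW
    glutenins of four species: one x and one y per diploid genome, three
    genomes in hexaploid wheat."""
    species_genomes = (("Tel", ("E",)), ("Tu", ("A",)), ("Aet", ("D",)),
                       ("Ta", ("A", "B", "D")))
    out = []
    for species, genomes in species_genomes:
        for g in genomes:
            for sub in ("HMW_x", "HMW_y"):
                cds, _ = generate_gene(sub, rng)
                out.append((f"{species}_hmw_1{g}_{sub[-1]}", species, cds, sub))
    return out


def generate_region_pair(rng: np.random.Generator, *,
                         divergence_pct: float = 10.0,
                         inversion: tuple[int, int] = (8, 13),
                         isolated_move: tuple[int, int] = (2, 5)
                         ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Two ordered gene lists emulating the short-arm prolamin interval
    of two related genomes.

    The second genome carries the same genes (synonymously diverged) with
    the slice ``inversion`` reversed, and one gene displaced out of
    register (``isolated_move`` = (from, to) positions) so its anchor can
    extend neither the forward nor the inverted chains — the 'isolated
    gene' pattern of cross-genome comparisons.
    """
    subfams = (["omega"] * 6 + ["gamma"] * 5 + ["LMW"] * 4)
    genes1 = []
    for i, sf in enumerate(subfams):
        cds, _ = generate_gene(sf, rng)
        genes1.append((f"g1_{sf}_{i + 1}", cds))
    diverged = [(gid.replace("g1_", "g2_"),
                 diverge_synonymous(cds, rng, divergence_pct / 100))
                for gid, cds in genes1]
    a, b = inversion
    order = list(range(len(diverged)))
    order[a:b] = order[a:b][::-1]
    src, dst = isolated_move
    order.insert(dst, order.pop(src))
    genes2 = [diverged[i] for i in order]
    return genes1, genes2
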