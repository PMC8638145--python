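"""Subfamily classification, pseudogene calling and physicochemical traits.

Prolamin subfamilies are recognized by their repeat-motif grammar, cysteine
count and mature length:

* alpha-gliadin   — P(QP)2[FY]-type repeat units plus two polyglutamine
                    tracts; 6 conserved cysteines; ~250-350 aa
* gamma-gliadin   — PQQP[FY]PQ repeat units; 8-9 cysteines; ~250-350 aa
* omega-gliadin   — PQQP[FY] units dominating the protein, at most one
                    cysteine; ~300-450 aa
* LMW glutenin    — MKTF... signal peptide followed by the SHIPGL mature
                    N-terminus; 7-9 cysteines; ~280-400 aa
* HMW glutenin    — long (>=600 aa) central repeat of GYYPTS/PGQGQQ-type
                    units; x- vs y-type split by cysteines in the first
                    120 residues (y >= 5, x < 5)
* delta-gliadin   — short QQPQQ-rich gliadin with 6-7 cysteines and no
                    alpha-type repeat region

Every threshold lives in :class:`SubfamilyRule` and can be overridden from
configuration; the defaults are an explicit, reproducible stand-in for
manual curation by homology.

A gene is called a pseudogene when its coding sequence cannot produce a
structurally complete protein: missing ATG start, premature stop codon,
missing terminal stop, a frame-breaking length, or repeat-domain evidence
below the subfamily's structural minimum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from scipy.optimize import brentq

from .errors import InputError
from .seqio import CodingSequence, ProteinRecord

SUBFAMILIES = ("alpha", "gamma", "omega", "delta", "LMW", "HMW_x", "HMW_y")

DEFECTS = ("no_start", "internal_stop", "no_terminal_stop", "frameshift",
           "structure_incomplete")


def round_pct(fraction: float, ndigits: int = 1) -> float:
    """Percentage at fixed precision, round-half-up (97.25% -> 97.3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Subfamily rule set


@dataclass(frozen=True)
class SubfamilyRule:
    """Motif / length / cysteine criteria for one subfamily."""

    name: str
    motif: str                      # regex for the repeat unit
    min_motif_count: int
    length_range: tuple[int, int]   # residues, inclusive
    cys_range: tuple[int, int]      # whole-protein cysteine count, inclusive
    min_polyq_tracts: int = 0       # tracts of >= polyq_len consecutive Q
    polyq_len: int = 6
    nterm_prefix: str = ""          # required residue prefix (signal peptide)
    nterm_motif: str = ""           # regex required within the first 60 aa
    max_cys: int | None = None      # cysteines in first 120 aa strictly below
    min_cys_nterm: int | None = None  # cysteines in first 120 aa at least
    forbid_motif: str = ""          # regex whose count must stay below its min
    forbid_count: int = 0

    def motif_count(self, residues: str) -> int:
        return count_overlapping_regex(self.motif, residues)


def count_overlapping_regex(pattern: str, text: str) -> int:
    """Number of (possibly overlapping) regex matches, one per start site."""
    return len(re.findall(f"(?=({pattern}))", text))


def _polyq_tracts(residues: str, min_len: int) -> int:
    return len(re.findall("Q{%d,}" % min_len, residues))


DEFAULT_RULES: dict[str, SubfamilyRule] = {
    "alpha": SubfamilyRule(
        name="alpha", motif="PQPQP[FY]", min_motif_count=5,
        length_range=(250, 350), cys_range=(5, 7),
        min_polyq_tracts=2, polyq_len=6,
    ),
    "gamma": SubfamilyRule(
        name="gamma", motif="PQQP[FY]PQ", min_motif_count=5,
        length_range=(250, 350), cys_range=(8, 9),
    ),
    "omega": SubfamilyRule(
        name="omega", motif="PQQP[FY]", min_motif_count=8,
        length_range=(300, 450), cys_range=(0, 1),
    ),
    "LMW": SubfamilyRule(
        name="LMW", motif="QQQPPFS|PQQPPFS", min_motif_count=3,
        length_range=(280, 400), cys_range=(7, 9),
        nterm_prefix="MKTF", nterm_motif="SHIPGL",
    ),
    "HMW_x": SubfamilyRule(
        name="HMW_x", motif="GYYPTS|PGQGQQ", min_motif_count=15,
        length_range=(600, 900), cys_range=(3, 5), max_cys=5,
    ),
    "HMW_y": SubfamilyRule(
        name="HMW_y", motif="GYYPTS|PGQGQQ", min_motif_count=15,
        length_range=(600, 900), cys_range=(5, 8), min_cys_nterm=5,
    ),
    "delta": SubfamilyRule(
        name="delta", motif="QQPQQ", min_motif_count=3,
        length_range=(150, 280), cys_range=(6, 7),
        forbid_motif="PQPQP[FY]", forbid_count=5,
    ),
}


def dump_rules(rules: Mapping[str, SubfamilyRule], path) -> None:
    """Write a rule set as plain-text YAML (every threshold overridable)."""
    import yaml
    from dataclasses import asdict
    data = {name: asdict(rule) for name, rule in rules.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_rules(path) -> dict[str, SubfamilyRule]:
    """Read a rule set written by :func:`dump_rules`."""
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh)
    rules = {}
    for name, kw in data.items():
        for key in ("length_range", "cys_range"):
            kw[key] = tuple(kw[key])
        rules[name] = SubfamilyRule(**kw)
    return rules


def load_pka(path) -> dict[str, float]:
    """Read an alternative pKa set (plain-text ``key: value`` YAML);
    missing keys fall back to the Bjellqvist defaults."""
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    merged = dict(BJELLQVIST_PKA)
    unknown = set(data) - set(merged)
    if unknown:
        raise InputError(f"unknown pKa keys: {sorted(unknown)}")
    merged.update({k: float(v) for k, v in data.items()})
    return merged


@dataclass(frozen=True)
class ClassificationResult:
    subfamily: str                  # one of SUBFAMILIES or "unclassified"
    evidence: dict[str, float] = field(default_factory=dict)


def _rule_satisfied(rule: SubfamilyRule, residues: str) -> tuple[bool, float]:
    """Check one subfamily's criteria; score = motif count / required."""
    n = len(residues)
    if not rule.length_range[0] <= n <= rule.length_range[1]:
        return False, 0.0
    cys = residues.count("C")
    if not rule.cys_range[0] <= cys <= rule.cys_range[1]:
        return False, 0.0
    head = residues[:120]
    if rule.max_cys is not None and head.count("C") >= rule.max_cys:
        return False, 0.0
    if rule.min_cys_nterm is not None and head.count("C") < rule.min_cys_nterm:
        return False, 0.0
    if rule.nterm_prefix and not residues.startswith(rule.nterm_prefix):
        return False, 0.0
    if rule.nterm_motif and not re.search(rule.nterm_motif, residues[:60]):
        return False, 0.0
    if rule.min_polyq_tracts and _polyq_tracts(residues, rule.polyq_len) < rule.min_polyq_tracts:
        return False, 0.0
    if rule.forbid_motif and count_overlapping_regex(rule.forbid_motif, residues) >= rule.forbid_count:
        return False, 0.0
    count = rule.motif_count(residues)
    if count < rule.min_motif_count:
        return False, 0.0
    return True, count / rule.min_motif_count


def classify_subfamily(
    protein: ProteinRecord | str,
    rules: Mapping[str, SubfamilyRule] = DEFAULT_RULES,
) -> ClassificationResult:
    """Assign the highest-scoring subfamily whose criteria are all met.

    Score is motif-count enrichment over the subfamily's minimum; ties are
    broken by the fixed subfamily order, keeping classification
    deterministic. Proteins meeting no rule are "unclassified".
    """
    residues = protein if isinstance(protein, str) else protein.residues
    if len(residues) < 30:
        raise InputError("protein shorter than 30 residues cannot be classified")
    best, best_score = "unclassified", 0.0
    evidence: dict[str, float] = {}
    for name in SUBFAMILIES:
        rule = rules.get(name)
        if rule is None:
            continue
        ok, score = _rule_satisfied(rule, residues)
        evidence[name] = rule.motif_count(residues)
        if ok and score > best_score:
            best, best_score = name, score
    return ClassificationResult(best, evidence)


# ---------------------------------------------------------------------------
# Functional status


@dataclass(frozen=True)
class ProlaminCall:
    """Subfamily + functional status + defect list for one gene."""

    gene_id: str
    subfamily: str
    status: str                     # "functional" | "pseudogene"
    defects: tuple[str, ...]
    evidence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = "pseudogene" if self.defects else "functional"
        if self.status != expected:
            raise InputError(
                f"{self.gene_id}: status {self.status!r} inconsistent with defects"
            )


def call_status(
    cds: CodingSequence,
    protein: ProteinRecord,
    subfamily: str,
    rules: Mapping[str, SubfamilyRule] = DEFAULT_RULES,
) -> ProlaminCall:
    """Functional iff the CDS yields a structurally complete protein.

    Defects checked: missing ATG start, internal stop codon, missing
    in-frame terminal stop, frame-breaking length, and — when the claimed
    subfamily's rule is available — repeat-motif evidence below the
    structural minimum.
    """
    if cds.gene_id != protein.gene_id:
        raise InputError(f"mismatched records: {cds.gene_id} vs {protein.gene_id}")
    defects: list[str] = []
    if not cds.nucleotides.startswith("ATG"):
        defects.append("no_start")
    if protein.internal_stop_positions:
        defects.append("internal_stop")
    if not cds.complete_flag:
        defects.append("no_terminal_stop")
    if len(cds.nucleotides) % 3 != 0:
        defects.append("frameshift")
    rule = rules.get(subfamily)
    if rule is not None and rule.motif_count(protein.residues) < rule.min_motif_count:
        defects.append("structure_incomplete")
    status = "pseudogene" if defects else "functional"
    return ProlaminCall(cds.gene_id, subfamily, status, tuple(defects))


def pseudogene_rate(calls: Sequence[ProlaminCall]) -> float:
    """Fraction of pseudogenes among all calls (0..1)."""
    if not calls:
        raise InputError("pseudogene_rate of an empty call list is undefined")
    n_pseudo = sum(1 for c in calls if c.status == "pseudogene")
    return n_pseudo / len(calls)


# ---------------------------------------------------------------------------
# Molecular weight and isoelectric point

#: average (isotope-weighted) residue masses, Da
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

#: Bjellqvist pKa set (the one behind the familiar web pI calculator).
#: N-terminal pKa depends on the first residue; C-terminal carboxyl has
#: residue-specific exceptions for D and E.
BJELLQVIST_PKA: dict[str, float] = {
    "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,  # acidic side chains
    "H": 5.98, "K": 10.0, "R": 12.0,            # basic side chains
    "Cterm": 3.55, "Cterm_D": 4.55, "Cterm_E": 4.75,
    "Nterm": 7.5, "Nterm_A": 7.59, "Nterm_M": 7.0, "Nterm_S": 6.93,
    "Nterm_P": 8.36, "Nterm_T": 6.82, "Nterm_V": 7.44, "Nterm_E": 7.7,
    "Nterm_G": 7.5,
}

_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")


def _check_residues(residues: str) -> None:
    if not residues:
        raise InputError("empty protein sequence")
    bad = set(residues) - set(AVERAGE_RESIDUE_MASS)
    if bad:
        raise InputError(
            f"non-standard residues {sorted(bad)}: MW/pI undefined "
            "(pseudogene translations contain X)"
        )


def compute_mw(protein: ProteinRecord | str) -> float:
    """Average molecular mass in Daltons (residue masses + one water)."""
    residues = protein if isinstance(protein, str) else protein.residues
    _check_residues(residues)
    return sum(AVERAGE_RESIDUE_MASS[r] for r in residues) + WATER_MASS


def net_charge(residues: str, ph: float,
               pka: Mapping[str, float] = BJELLQVIST_PKA) -> float:
    """Henderson-Hasselbalch net charge of a peptide with free termini."""
    pos = 10 ** -ph / (10 ** -ph + 10 ** -pka.get(f"Nterm_{residues[0]}", pka["Nterm"]))
    for aa in _BASIC:
        k = 10 ** -pka[aa]
        pos += residues.count(aa) * (10 ** -ph) / (10 ** -ph + k)
    ct_key = f"Cterm_{residues[-1]}"
    ct = pka.get(ct_key, pka["Cterm"])
    neg = 10 ** -ct / (10 ** -ph + 10 ** -ct)
    for aa in _ACIDIC:
        k = 10 ** -pka[aa]
        neg += residues.count(aa) * k / (10 ** -ph + k)
    return pos - neg


def compute_pi(protein: ProteinRecord | str, tol: float = 0.01,
               pka: Mapping[str, float] = BJELLQVIST_PKA) -> float:
    """Theoretical isoelectric point by bisection on the net-charge curve.

    The net charge is strictly decreasing in pH, positive at pH 0 and
    negative at pH 14 for any peptide with free termini, so the bracket is
    always valid.
    """
    residues = protein if isinstance(protein, str) else protein.residues
    _check_residues(residues)
    return float(brentq(lambda ph: net_charge(residues, ph, pka),
                        0.0, 14.0, xtol=tol / 2))


@dataclass(frozen=True)
class PhysChem:
    gene_id: str
    mw_da: float
    pi: float


def physchem(protein: ProteinRecord) -> PhysChem:
    return PhysChem(protein.gene_id, compute_mw(protein), compute_pi(protein))
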