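"""End-to-end orchestration: discovery -> annotation -> family analyses.

The stages mirror how a prolamin complement is characterized in practice:
known prolamin CDSs are used as nucleotide queries against the genome;
candidate loci are matched to gene models; coding sequences are extracted,
translated, classified into subfamilies and called functional or
pseudogene; then the family-level analyses (pseudogene rates, tandem
clusters, collinearity, epitope repertoires, expression profiles) run on
the per-gene table.

Subfamily assignment is motif-based where the translation still supports
it; heavily degraded pseudogenes that no longer satisfy any subfamily
rule inherit the subfamily of their best-scoring homology query — the
same homology-first logic a manual curation applies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import annotate as ann
from . import duplication as dup
from . import epitopes as ep
from . import expression as expr
from . import homology as hom
from .errors import InputError
from .seqio import CodingSequence, GeneModel, GenomeSequence, extract_cds, translate


@dataclass
class GeneRecord:
    """Everything the downstream analyses need about one gene."""

    model: GeneModel
    cds: CodingSequence
    protein_residues: str
    call: ann.ProlaminCall
    locus: hom.CandidateLocus | None = None
    physchem: ann.PhysChem | None = None


def discover_loci(genomes: Sequence[GenomeSequence], queries: hom.QuerySet,
                  params: hom.ScanParams = hom.ScanParams(),
                  merge_gap: int = 2000, orf_flank: int = 1000
                  ) -> tuple[list[hom.CandidateLocus], dict[str, str]]:
    """Scan all queries and merge hits into candidate loci.

    Returns the loci plus a query_id -> subfamily-hint map for later
    homology-based subfamily fallback.
    """
    index = hom.build_kmer_index(genomes, params.k)
    hits = hom.scan_queries(queries, index, params)
    loci = hom.merge_to_loci(hits, genomes, merge_gap=merge_gap,
                             orf_flank=orf_flank)
    hints = {qid: hint for qid, _seq, hint in queries.records}
    return loci, hints


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0) + 1)


def match_loci_to_models(loci: Sequence[hom.CandidateLocus],
                         models: Sequence[GeneModel],
                         min_frac: float = 0.5) -> dict[str, hom.CandidateLocus]:
    """Assign each gene model the locus covering most of it (if more than
    ``min_frac`` of the model span is covered)."""
    out: dict[str, hom.CandidateLocus] = {}
    for m in models:
        best, best_cov = None, 0
        for l in loci:
            if l.chrom != m.chrom:
                continue
            cov = _overlap(l.start, l.end, m.start, m.end)
            if cov > best_cov:
                best, best_cov = l, cov
        if best is not None and best_cov > min_frac * (m.end - m.start + 1):
            out[m.gene_id] = best
    return out


def annotate_genes(models: Sequence[GeneModel],
                   genomes: Sequence[GenomeSequence],
                   rules: Mapping[str, ann.SubfamilyRule] = ann.DEFAULT_RULES,
                   loci_by_gene: Mapping[str, hom.CandidateLocus] | None = None,
                   hints: Mapping[str, str] | None = None) -> list[GeneRecord]:
    """Extract, translate, classify and status-call every gene model.

    When a translation satisfies no subfamily rule (typical for badly
    degraded pseudogenes) and homology evidence is available, the
    subfamily hint of the best-scoring supporting query is used instead.
    """
    chrom_map = {g.chrom_id: g for g in genomes}
    records: list[GeneRecord] = []
    for m in models:
        genome = chrom_map.get(m.chrom)
        if genome is None:
            raise InputError(f"{m.gene_id}: chromosome {m.chrom!r} not in genome")
        cds = extract_cds(m, genome)
        protein = translate(cds)
        result = ann.classify_subfamily(protein, rules)
        subfamily = result.subfamily
        locus = (loci_by_gene or {}).get(m.gene_id)
        if subfamily == "unclassified" and locus is not None and hints:
            subfamily = hints.get(locus.best_hit.query_id, subfamily)
        call = ann.call_status(cds, protein, subfamily, rules)
        pc = None
        if call.status == "functional":
            pc = ann.physchem(protein)
        records.append(GeneRecord(m, cds, protein.residues, call, locus, pc))
    return records


def calls_table(records: Sequence[GeneRecord]) -> pd.DataFrame:
    """Flat per-gene TSV-able table of the annotation stage."""
    rows = []
    for r in records:
        rows.append({
            "gene_id": r.model.gene_id,
            "chrom": r.model.chrom,
            "strand": r.model.strand,
            "start": r.model.start,
            "end": r.model.end,
            "genome": r.model.subgenome_or_genome,
            "subfamily": r.call.subfamily,
            "status": r.call.status,
            "defects": ";".join(r.call.defects),
            "mw_da": round(r.physchem.mw_da, 2) if r.physchem else float("nan"),
            "pi": round(r.physchem.pi, 2) if r.physchem else float("nan"),
            "length_aa": len(r.protein_residues),
        })
    return pd.DataFrame(rows)


def subfamily_counts(records: Sequence[GeneRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in records:
        counts[r.call.subfamily] = counts.get(r.call.subfamily, 0) + 1
    return counts


def pseudogene_rates(records: Sequence[GeneRecord]) -> dict[str, dict]:
    """Per-subfamily pseudogene rate with explicit numerator/denominator.

    Records whose CDS length is not a multiple of three are sequences
    that cannot be complete as extracted; because it is a judgment call
    whether such records belong in the denominator, the rate is also
    reported with them excluded.
    """
    out: dict[str, dict] = {}
    for sf in sorted({r.call.subfamily for r in records}):
        group = [r for r in records if r.call.subfamily == sf]
        calls = [r.call for r in group]
        n_pseudo = sum(1 for c in calls if c.status == "pseudogene")
        complete = [r.call for r in group if len(r.cds.nucleotides) % 3 == 0]
        entry = {
            "pseudogenes": n_pseudo,
            "genes": len(calls),
            "rate_pct": ann.round_pct(ann.pseudogene_rate(calls)),
        }
        if complete:
            entry["genes_frame_complete"] = len(complete)
            entry["rate_pct_frame_complete"] = ann.round_pct(
                ann.pseudogene_rate(complete))
        out[sf] = entry
    return out


def tandem_analysis(records: Sequence[GeneRecord],
                    max_distance: int = dup.TANDEM_MAX_DISTANCE,
                    min_coverage: float = dup.TANDEM_MIN_COVERAGE,
                    min_identity: float = dup.TANDEM_MIN_IDENTITY
                    ) -> tuple[list[dup.TandemCluster], dict[str, dict]]:
    """Tandem clusters over all genes plus per-subfamily proportions."""
    models = [r.model for r in records]
    cds_map = {r.model.gene_id: r.cds for r in records}
    pairs = dup.tandem_pairs(models, cds_map, max_distance)

    def predicate(p: dup.PairStats) -> bool:
        return dup.is_tandem_pair(p, max_distance, min_coverage, min_identity)

    clusters = dup.cluster_tandem(models, pairs, predicate)
    proportions: dict[str, dict] = {}
    for sf in sorted({r.call.subfamily for r in records}):
        ids = [r.model.gene_id for r in records if r.call.subfamily == sf]
        num, den, pct = dup.tandem_proportion(clusters, ids)
        proportions[sf] = {"tandem_genes": num, "genes": den, "pct": pct}
    return clusters, proportions


def epitope_analysis(records: Sequence[GeneRecord], genome_label: str,
                     defs: Sequence[ep.EpitopeDef] = ep.DEFAULT_EPITOPES
                     ) -> tuple[list[ep.EpitopeProfile], ep.GenomeEpitopeSummary]:
    """Scan the functional alpha-gliadins of one genome."""
    profiles = [
        ep.scan_epitopes(
            # ProteinRecord-free path: residues plus id via EpitopeProfile
            r.protein_residues, defs)
        for r in records
        if r.call.subfamily == "alpha" and r.call.status == "functional"
    ]
    profiles = [
        ep.EpitopeProfile(rec.model.gene_id, prof.counts)
        for rec, prof in zip(
            [r for r in records
             if r.call.subfamily == "alpha" and r.call.status == "functional"],
            profiles)
    ]
    summary = ep.summarize_genome(profiles, genome_label, defs)
    return profiles, summary


def expression_analysis(tpm: pd.DataFrame, metadata: pd.DataFrame,
                        **pattern_kwargs) -> pd.DataFrame:
    profiles = expr.profile_stages(tpm, metadata, **pattern_kwargs)
    rows = []
    for p in profiles:
        row = {"gene_id": p.gene_id, "peak_stage": p.peak_stage,
               "pattern": p.pattern}
        row.update({f"tpm_{s}": round(v, 3) for s, v in p.stage_means.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report bundle

#: structural schema of the JSON report: required keys and their types
REPORT_SCHEMA: dict[str, type] = {
    "subfamily_counts": dict,
    "pseudogene_rates": dict,
    "tandem": dict,
    "epitopes": dict,
    "thresholds": dict,
}


def validate_report(report: Mapping) -> bool:
    """Structural validation against :data:`REPORT_SCHEMA`."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report or not isinstance(report[key], typ):
            return False
    return True


def build_report(records: Sequence[GeneRecord], genome_label: str,
                 thresholds: Mapping[str, float],
                 clusters: Sequence[dup.TandemCluster] | None = None,
                 proportions: Mapping[str, dict] | None = None,
                 epitope_summary: ep.GenomeEpitopeSummary | None = None,
                 expression_table: pd.DataFrame | None = None) -> dict:
    if clusters is None or proportions is None:
        clusters, proportions = tandem_analysis(records)
    if epitope_summary is None:
        _profiles, epitope_summary = epitope_analysis(records, genome_label)
    report = {
        "genome": genome_label,
        "subfamily_counts": subfamily_counts(records),
        "pseudogene_rates": pseudogene_rates(records),
        "tandem": {
            "clusters": [
                {"chrom": c.chrom, "members": list(c.members)} for c in clusters
            ],
            "proportions": dict(proportions),
        },
        "epitopes": {
            "n_functional_alpha": epitope_summary.n_functional_alpha,
            "carrier_pct": epitope_summary.carrier_pct,
            "union_a1a_a3_pct": epitope_summary.union_a1a_a3_pct,
            "dq8_only_pct": epitope_summary.dq8_only_pct,
            "types_present": list(epitope_summary.epitope_types_present),
        },
        "thresholds": dict(thresholds),
    }
    if expression_table is not None:
        report["expression_patterns"] = (
            expression_table["pattern"].value_counts().to_dict()
        )
    return report


def write_report(report: dict, out_dir: str | Path,
                 tables: Mapping[str, pd.DataFrame] | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    for name, df in (tables or {}).items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    return path
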