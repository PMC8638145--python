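"""Synthetic generator: determinism, planted-truth closed loops."""

import numpy as np
import pandas as pd
import pytest

from prolaminkit import synthgen as sg
from prolaminkit.annotate import call_status, classify_subfamily, round_pct
from prolaminkit.epitopes import scan_epitopes
from prolaminkit.errors import ParameterError, SpecError
from prolaminkit.expression import STAGES
from prolaminkit.seqio import CodingSequence, STOP_CODONS, translate


def _cs(nt, gene="g"):
    return CodingSequence(gene, nt, len(nt) % 3 == 0 and nt[-3:] in STOP_CODONS)


# ---------------------------------------------------------------------------
# gene generation


def test_generated_gene_structure(rng):
    cds, protein = sg.generate_gene("alpha", rng)
    assert cds.startswith("ATG") and cds[-3:] in STOP_CODONS
    assert len(cds) == 3 * len(protein) + 3
    assert classify_subfamily(protein).subfamily == "alpha"


def test_hmw_y_cysteine_signature(rng):
    for _ in range(5):
        _, protein = sg.generate_gene("HMW_y", rng)
        assert protein[:120].count("C") >= 5
        _, protein_x = sg.generate_gene("HMW_x", rng)
        assert protein_x[:120].count("C") < 5


def test_generation_is_deterministic():
    a = sg.generate_gene("gamma", np.random.default_rng(11))
    b = sg.generate_gene("gamma", np.random.default_rng(11))
    assert a == b


def test_unknown_subfamily_rejected(rng):
    with pytest.raises(SpecError):
        sg.build_protein("beta", rng)


def test_synonymous_divergence_preserves_protein(rng):
    cds, protein = sg.generate_gene("omega", rng)
    moved = sg.diverge_synonymous(cds, rng, 0.10)
    assert translate(_cs(moved)).residues == protein
    frac = sum(a != b for a, b in zip(cds, moved)) / len(cds)
    assert 0.06 <= frac <= 0.14
    with pytest.raises(ParameterError):
        sg.diverge_synonymous(cds, rng, 0.9)


# ---------------------------------------------------------------------------
# pseudogenization


@pytest.mark.parametrize("mode", sg.PSEUDO_MODES)
def test_pseudogenize_detectable(mode, rng):
    for _ in range(5):
        cds, _ = sg.generate_gene("gamma", rng)
        mutated = sg.pseudogenize(cds, rng, mode)
        cs = _cs(mutated)
        call = call_status(cs, translate(cs), "gamma")
        assert call.status == "pseudogene"
        assert mode in call.defects
        if mode == "frameshift":
            assert len(mutated) % 3 == 2
        if mode == "no_start":
            assert not mutated.startswith("ATG")


def test_pseudogenize_bad_mode(rng):
    with pytest.raises(ParameterError):
        sg.pseudogenize("ATG" * 40, rng, "inversion")


# ---------------------------------------------------------------------------
# genome assembly


def test_assembly_deterministic():
    spec = sg.small_demo_spec()
    g1, m1, t1 = sg.assemble_genome(spec, np.random.default_rng(3))
    g2, m2, t2 = sg.assemble_genome(spec, np.random.default_rng(3))
    assert [x.sequence for x in g1] == [x.sequence for x in g2]
    assert m1 == m2
    pd.testing.assert_frame_equal(t1, t2)


def test_assembly_matches_truth_coordinates(demo_genome):
    chrom_map = {g.chrom_id: g for g in demo_genome.genomes}
    models = {m.gene_id: m for m in demo_genome.models}
    for row in demo_genome.truth.itertuples():
        m = models[row.gene_id]
        assert (m.chrom, m.strand, m.start, m.end) == \
            (row.chrom, row.strand, row.start, row.end)
        assert m.end <= len(chrom_map[m.chrom])


def test_exact_count_planting_reproduces_printed_rate():
    """16 planted defects among 19 alpha genes give 84.2% exactly."""
    rng = np.random.default_rng(0)
    truth = sg.thinopyrum_e_spec()
    _g, _m, table = sg.assemble_genome(
        sg.SyntheticGenomeSpec("E", tuple(
            a for a in truth.arrays if a.subfamily == "alpha")), rng)
    assert (table.status == "pseudogene").sum() == 16
    assert len(table) == 19
    assert round_pct(16 / 19) == 84.2


def test_chromosome_length_spec_error():
    spec = sg.SyntheticGenomeSpec(
        "E", (sg.ArraySpec("1E", "alpha", 3),),
        chromosome_lengths={"1E": 1000})
    with pytest.raises(SpecError):
        sg.assemble_genome(spec, np.random.default_rng(0))


def test_bad_array_spec():
    with pytest.raises(SpecError):
        sg.ArraySpec("1E", "alpha", 2, n_pseudo=3)
    with pytest.raises(SpecError):
        sg.ArraySpec("1E", "alpha", 2, divergence_pct=80)


def test_background_is_nucleotide_only(rng):
    trans = sg.fit_markov_background(["ATGCATGCAAGG"])
    bg = sg.markov_background(500, trans, rng)
    assert len(bg) == 500 and set(bg) <= set("ACGT")


def test_epitope_planting_in_assembled_genome(demo_genome):
    """The demo plan alternates (a1a,) and () over functional alphas."""
    truth = demo_genome.truth
    by_id = {r.model.gene_id: r for r in demo_genome.records}
    planted = truth[truth.epitopes != ""]
    assert len(planted) >= 1
    for row in planted.itertuples():
        profile = scan_epitopes(by_id[row.gene_id].protein_residues)
        for name in row.epitopes.split(";"):
            assert profile.carries(name)


# ---------------------------------------------------------------------------
# counts


def test_counts_deterministic(e_genome):
    a = sg.generate_counts(e_genome.truth, e_genome.lengths,
                           np.random.default_rng(5))
    b = sg.generate_counts(e_genome.truth, e_genome.lengths,
                           np.random.default_rng(5))
    pd.testing.assert_frame_equal(a.counts, b.counts)


def test_counts_shape_and_metadata(e_genome):
    cm = sg.generate_counts(e_genome.truth, e_genome.lengths,
                            np.random.default_rng(5), reps=3)
    assert cm.counts.shape[1] == 18
    assert set(cm.metadata["stage"]) == set(STAGES)
    assert (cm.counts.values >= 0).all()
    # prolamin genes plus the background transcriptome
    assert len(cm.counts) == len(e_genome.truth) + 400


def test_counts_poisson_limit(e_genome):
    """At vanishing dispersion counts sit within Poisson-like 5-sigma of
    the planted expectation."""
    cm = sg.generate_counts(e_genome.truth, e_genome.lengths,
                            np.random.default_rng(5), dispersion=1e-12,
                            lib_size_range=(1.0, 1.0))
    means = sg.planted_stage_means(e_genome.truth)
    gene = e_genome.truth[e_genome.truth.status == "functional"].gene_id.iloc[0]
    length = e_genome.lengths[gene]
    for stage in STAGES:
        expected = means.loc[gene, stage] * length / 1000 * 30.0
        for rep in (1, 2, 3):
            got = cm.counts.loc[gene, f"{stage}_r{rep}"]
            assert abs(got - expected) <= 5 * np.sqrt(expected) + 1


def test_counts_bad_dispersion(e_genome):
    with pytest.raises(ParameterError):
        sg.generate_counts(e_genome.truth, e_genome.lengths,
                           np.random.default_rng(5), dispersion=0)


def test_hmw_panel_composition(rng):
    panel = sg.generate_hmw_panel(rng)
    assert len(panel) == 12
    labels = [classify_subfamily(translate(_cs(cds)).residues).subfamily
              for _gid, _species, cds, _expected in panel]
    assert labels == [expected for *_rest, expected in panel]
    assert sum(1 for l in labels if l == "HMW_x") == 6
    assert sum(1 for l in labels if l == "HMW_y") == 6
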