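"""TPM normalization, stage profiling and fold recovery."""

import numpy as np
import pandas as pd
import pytest

from prolaminkit import synthgen as sg
from prolaminkit.errors import InputError
from prolaminkit.expression import (STAGES, CountMatrix, classify_pattern,
                                    compute_tpm, fold_between, profile_stages,
                                    read_counts, write_counts)


def _cm(counts: dict, lengths: dict, stages=None):
    counts_df = pd.DataFrame(counts)
    n = counts_df.shape[1]
    stages = stages or [STAGES[i % 6] for i in range(n)]
    meta = pd.DataFrame({"stage": stages, "replicate": [1] * n},
                        index=counts_df.columns)
    return CountMatrix(counts_df, pd.Series(lengths), meta)


# ---------------------------------------------------------------------------
# TPM


def test_equal_genes_split_the_million():
    cm = _cm({"s1": [100, 100]}, {0: 1000, 1: 1000})
    tpm = compute_tpm(cm)
    assert tpm["s1"].tolist() == [500_000.0, 500_000.0]


def test_length_normalization():
    cm = _cm({"s1": [100, 100]}, {0: 2000, 1: 1000})
    tpm = compute_tpm(cm)
    assert tpm.loc[1, "s1"] == pytest.approx(2 * tpm.loc[0, "s1"])


def test_tpm_sums_to_one_million(rng):
    counts = rng.integers(0, 500, size=(30, 6)) + 1
    cm = _cm({f"s{i}": counts[:, i] for i in range(6)},
             dict(enumerate(rng.integers(300, 3000, 30))))
    tpm = compute_tpm(cm)
    assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)


def test_tpm_scaling_invariance(rng):
    counts = rng.integers(1, 500, size=(10, 1))
    lengths = dict(enumerate(rng.integers(300, 3000, 10)))
    a = compute_tpm(_cm({"s1": counts[:, 0]}, lengths))
    b = compute_tpm(_cm({"s1": counts[:, 0] * 7}, lengths))
    assert np.allclose(a.values, b.values)


def test_all_zero_sample_errors():
    cm = _cm({"s1": [5, 5], "s2": [0, 0]}, {0: 1000, 1: 1000})
    with pytest.raises(InputError, match="s2"):
        compute_tpm(cm)


def test_unknown_stage_rejected():
    counts_df = pd.DataFrame({"s1": [1]})
    meta = pd.DataFrame({"stage": ["seedling"], "replicate": [1]},
                        index=["s1"])
    with pytest.raises(InputError):
        CountMatrix(counts_df, pd.Series({0: 1000}), meta)


# ---------------------------------------------------------------------------
# pattern classification


@pytest.mark.parametrize("means,expected", [
    ([1, 2, 10, 5, 2, 1], ("rise_then_fall", 2)),
    ([0, 0, 1, 2, 5, 9], ("rising", 5)),
    ([3, 3, 3, 3, 3, 3], ("flat", 0)),
    ([1, 2, 8, 30, 100, 40], ("rise_then_fall", 4)),
    ([10, 1, 10, 1, 10, 1], ("other", 0)),
])
def test_classify_pattern(means, expected):
    assert classify_pattern(means) == expected


def test_profile_replicate_order_invariance(rng):
    genes = [f"g{i}" for i in range(5)]
    samples = [f"{s}_r{r}" for s in STAGES for r in (1, 2, 3)]
    counts = pd.DataFrame(rng.integers(1, 400, (5, 18)), index=genes,
                          columns=samples)
    meta = pd.DataFrame({"stage": [s for s in STAGES for _ in range(3)],
                         "replicate": [1, 2, 3] * 6}, index=samples)
    cm = CountMatrix(counts, pd.Series(1000, index=genes), meta)
    tpm = compute_tpm(cm)
    shuffled = samples[::-1]
    profiles_a = profile_stages(tpm, meta)
    profiles_b = profile_stages(tpm[shuffled], meta.loc[shuffled])
    for a, b in zip(profiles_a, profiles_b):
        assert (a.gene_id, a.peak_stage, a.pattern) == \
            (b.gene_id, b.peak_stage, b.pattern)
        assert a.stage_means == pytest.approx(b.stage_means, rel=1e-12)


# ---------------------------------------------------------------------------
# folds


def test_fold_between_values():
    genes = ["a", "b"]
    samples = ["grain_r1", "grain_r2"]
    tpm = pd.DataFrame([[600, 600], [100, 100]], index=genes, columns=samples)
    meta = pd.DataFrame({"stage": ["grain", "grain"], "replicate": [1, 2]},
                        index=samples)
    assert fold_between(tpm, meta, "a", "b", "grain") == pytest.approx(6.0)
    assert fold_between(tpm, meta, "a", "a", "grain") == pytest.approx(1.0)
    zero = tpm.copy()
    zero.loc["b"] = 0
    with pytest.raises(InputError):
        fold_between(zero, meta, "a", "b", "grain")


def test_planted_gamma_fold_recovered(e_genome):
    """The two functional gamma-gliadins are planted at a 5.5x expression
    ratio; with NB dispersion 0.1 and 3 replicates the estimate over
    repeated simulations centers on 5.5."""
    truth = e_genome.truth
    functional_gamma = truth[(truth.subfamily == "gamma")
                             & (truth.status == "functional")]
    hi, lo = functional_gamma.sort_values("expr_base", ascending=False).gene_id
    folds = []
    for seed in range(10):
        counts_rng = np.random.default_rng(900 + seed)
        cm = sg.generate_counts(truth, e_genome.lengths, counts_rng)
        tpm = compute_tpm(cm)
        folds.append(fold_between(tpm, cm.metadata, hi, lo, "grain"))
    assert np.mean(folds) == pytest.approx(5.5, abs=1.0)


# ---------------------------------------------------------------------------
# planted pattern recovery


def test_planted_patterns_recovered(e_genome):
    """At low NB dispersion, >= 95% of genes get their planted stage
    pattern back (functional bursts and pseudogene flats alike)."""
    truth = e_genome.truth
    counts_rng = np.random.default_rng(31)
    cm = sg.generate_counts(truth, e_genome.lengths, counts_rng,
                            dispersion=0.01)
    tpm = compute_tpm(cm)
    profiles = {p.gene_id: p.pattern for p in profile_stages(tpm, cm.metadata)}
    hits = sum(profiles[row.gene_id] == row.pattern
               for row in truth.itertuples())
    assert hits / len(truth) >= 0.95


def test_functional_patterns_recovered_at_study_dispersion(e_genome):
    """The subfamily expression patterns (alpha/LMW burst peaking at half
    grain, gamma rising) survive the study-level noise (dispersion 0.1)."""
    truth = e_genome.truth
    counts_rng = np.random.default_rng(17)
    cm = sg.generate_counts(truth, e_genome.lengths, counts_rng)
    tpm = compute_tpm(cm)
    profiles = {p.gene_id: p for p in profile_stages(tpm, cm.metadata)}
    functional = truth[truth.status == "functional"]
    hits = sum(profiles[row.gene_id].pattern == row.pattern
               for row in functional.itertuples())
    assert hits / len(functional) >= 0.9
    # the alpha burst peaks at half grain, above the mature-grain level
    for row in functional[functional.subfamily == "alpha"].itertuples():
        means = profiles[row.gene_id].stage_means
        assert means["half_grain"] > means["grain"]


# ---------------------------------------------------------------------------
# IO


def test_counts_round_trip(tmp_path, rng):
    genes = ["g1", "g2"]
    samples = [f"{s}_r1" for s in STAGES]
    counts = pd.DataFrame(rng.integers(0, 100, (2, 6)), index=genes,
                          columns=samples)
    meta = pd.DataFrame({"stage": list(STAGES), "replicate": [1] * 6},
                        index=pd.Index(samples, name="sample"))
    cm = CountMatrix(counts, pd.Series([900, 1200], index=genes), meta)
    paths = [tmp_path / n for n in ("c.tsv", "l.tsv", "s.tsv")]
    write_counts(cm, *paths)
    back = read_counts(*paths)
    pd.testing.assert_frame_equal(back.counts, cm.counts)
    assert back.lengths.tolist() == cm.lengths.tolist()
    pd.testing.assert_frame_equal(back.metadata, cm.metadata)
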