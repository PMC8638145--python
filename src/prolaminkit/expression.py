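"""TPM normalization and developmental stage profiling.

Expression starts from a gene x sample count matrix (read alignment and
quantification are upstream of this package). TPM divides each count by
the gene's effective length in kilobases and rescales each sample to sum
to one million, making values comparable across genes and samples. For
intronless prolamin genes the effective length is the spliced CDS length.

Stage profiles average replicate TPMs per developmental stage (six stages
from young spike to mature grain) and label the trajectory:

* ``rise_then_fall`` — interior peak with both neighbors >= 20% below it
  (the classic storage-protein burst peaking around the half-grain stage)
* ``rising``         — non-decreasing to the last stage within tolerance
* ``flat``           — max/min ratio <= 1.5
* ``other``          — anything else

The neighbor-drop and flatness thresholds are configuration values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError

STAGES = ("young_spike", "pre_flowering", "flowering",
          "ovary_expansion", "half_grain", "grain")


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer counts with sample metadata and gene lengths."""

    counts: pd.DataFrame          # genes x samples
    lengths: pd.Series            # effective length per gene, nt
    metadata: pd.DataFrame        # index = sample, columns: stage, replicate

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise InputError("negative counts")
        missing = set(self.counts.index) - set(self.lengths.index)
        if missing:
            raise InputError(f"genes without length: {sorted(missing)[:5]}")
        if (self.lengths.loc[self.counts.index] <= 0).any():
            raise InputError("gene lengths must be positive")
        bad = set(self.metadata["stage"]) - set(STAGES)
        if bad:
            raise InputError(f"unknown stage labels: {sorted(bad)}")
        if list(self.metadata.index) != list(self.counts.columns):
            raise InputError("metadata rows must match count matrix columns")


@dataclass(frozen=True)
class StageExpressionProfile:
    gene_id: str
    stage_means: dict[str, float]  # mean TPM per stage, stage order preserved
    peak_stage: str
    pattern: str                   # rise_then_fall | rising | flat | other


def compute_tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: rate_i = count_i / length_i, scaled so each
    sample sums to 1e6."""
    lengths = cm.lengths.loc[cm.counts.index].astype(float)
    rates = cm.counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise InputError(f"all-zero sample(s): {list(zero.index)}")
    return rates.div(totals, axis=1) * 1e6


def classify_pattern(means: Sequence[float], *, drop_frac: float = 0.2,
                     flat_ratio: float = 1.5, rise_tol: float = 0.05) -> tuple[str, int]:
    """(pattern, peak index) for one vector of per-stage means.

    ``rise_then_fall`` needs an interior peak with both neighbors at least
    ``drop_frac`` below it; ``rising`` tolerates per-step dips up to
    ``rise_tol`` of the running level; ``flat`` caps max/min at
    ``flat_ratio``.
    """
    x = np.asarray(means, dtype=float)
    if len(x) < 3:
        raise InputError("need at least 3 stages to classify a pattern")
    peak = int(np.argmax(x))
    mx, mn = float(x.max()), float(x.min())
    if mx == 0:
        return "flat", peak
    if mn > 0 and mx / mn <= flat_ratio:
        return "flat", peak
    if 0 < peak < len(x) - 1:
        if x[peak - 1] <= (1 - drop_frac) * x[peak] and x[peak + 1] <= (1 - drop_frac) * x[peak]:
            return "rise_then_fall", peak
    rising = all(x[i + 1] >= x[i] * (1 - rise_tol) for i in range(len(x) - 1))
    if rising and peak >= len(x) - 2 and mx > mn:
        return "rising", peak
    return "other", peak


def profile_stages(tpm: pd.DataFrame, metadata: pd.DataFrame, *,
                   drop_frac: float = 0.2, flat_ratio: float = 1.5
                   ) -> list[StageExpressionProfile]:
    """Replicate-mean stage profiles with trajectory labels.

    Replicates are averaged per stage first; the pattern is assessed on
    the stage means, so it is invariant to replicate order.
    """
    bad = set(metadata["stage"]) - set(STAGES)
    if bad:
        raise InputError(f"unknown stage labels: {sorted(bad)}")
    stages = [s for s in STAGES if s in set(metadata["stage"])]
    if len(stages) < 3:
        raise InputError("need at least 3 stages for profiling")
    stage_of = metadata["stage"]
    means = tpm.T.groupby(stage_of).mean().T  # genes x stages
    profiles = []
    for gene_id, row in means.iterrows():
        vec = [float(row[s]) for s in stages]
        pattern, peak = classify_pattern(vec, drop_frac=drop_frac,
                                         flat_ratio=flat_ratio)
        profiles.append(StageExpressionProfile(
            gene_id=str(gene_id),
            stage_means=dict(zip(stages, vec)),
            peak_stage=stages[peak],
            pattern=pattern,
        ))
    return profiles


def fold_between(tpm: pd.DataFrame, metadata: pd.DataFrame,
                 gene_a: str, gene_b: str, stage: str) -> float:
    """Mean TPM ratio of gene_a over gene_b at one stage."""
    if stage not in set(metadata["stage"]):
        raise InputError(f"stage {stage!r} not present")
    for g in (gene_a, gene_b):
        if g not in tpm.index:
            raise InputError(f"gene {g!r} not in TPM matrix")
    samples = metadata.index[metadata["stage"] == stage]
    a = float(tpm.loc[gene_a, samples].mean())
    b = float(tpm.loc[gene_b, samples].mean())
    if b == 0:
        raise InputError(f"zero mean TPM for {gene_b!r} at {stage!r}: ratio undefined")
    return a / b


# ---------------------------------------------------------------------------
# TSV IO


def read_counts(counts_path, lengths_path, metadata_path) -> CountMatrix:
    """Counts as TSV (gene rows, sample columns, one-line header); lengths
    as 2-column TSV; sample sheet as 3-column TSV (sample, stage, replicate)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return CountMatrix(counts, lengths, metadata)


def write_counts(cm: CountMatrix, counts_path, lengths_path, metadata_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.lengths.rename("length_nt").to_csv(lengths_path, sep="\t")
    cm.metadata.to_csv(metadata_path, sep="\t")
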