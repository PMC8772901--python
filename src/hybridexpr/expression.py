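"""Expression-level profiling: RPKM normalization, per-type aggregation,
the expressed-gene universe, and rank correlation between transcriptomes.

The analysis operates on a gene x sample matrix of raw read counts from
four genetic types -- the two parental species (PC: channel catfish,
PB: blue catfish) and their reciprocal F1 hybrids (F1BC: blue female x
channel male, F1CB: channel female x blue male).  Counts are normalized
to RPKM (reads per kilobase of transcript per million mapped reads),
replicates are averaged within each genetic type, and a gene is
considered expressed when its type-mean RPKM exceeds 1.0 in at least
one genetic type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENETIC_TYPES",
    "CountMatrix",
    "TypeMeans",
    "compute_rpkm",
    "aggregate_by_type",
    "filter_expressed",
    "spearman_correlation",
]

#: The four genome configurations of the reciprocal-cross design.
GENETIC_TYPES = ("PC", "PB", "F1BC", "F1CB")


class ValidationError(ValueError):
    """Raised when an input table violates the contracts of the pipeline."""


@dataclass
class CountMatrix:
    """Integer read counts per gene x sample with gene lengths and sample types.

    Parameters
    ----------
    counts
        Gene x sample DataFrame of non-negative integers. The index holds
        gene identifiers, columns hold sample identifiers.
    lengths
        Transcript length in bp per gene (index aligned with ``counts``).
    type_map
        Genetic type per sample, values in :data:`GENETIC_TYPES`.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    type_map: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if (np.asarray(self.counts) < 0).any():
            bad = self.counts.index[(self.counts < 0).any(axis=1)]
            raise ValidationError(f"negative counts for genes: {list(bad[:5])}")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.counts.index[self.lengths.isna()]
            raise ValidationError(f"genes without a length: {list(missing[:5])}")
        if (self.lengths <= 0).any():
            raise ValidationError("gene lengths must be positive")
        self.type_map = self.type_map.reindex(self.counts.columns)
        if self.type_map.isna().any():
            missing = self.counts.columns[self.type_map.isna()]
            raise ValidationError(f"samples without a genetic type: {list(missing)}")
        unknown = set(self.type_map) - set(GENETIC_TYPES)
        if unknown:
            raise ValidationError(f"unknown genetic-type tokens: {sorted(unknown)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        """Per-sample column sums, the default RPKM denominator."""
        return self.counts.sum(axis=0)


@dataclass
class TypeMeans:
    """Per-gene mean RPKM within each genetic type.

    ``means`` is gene x genetic-type; ``n_replicates`` records how many
    samples were averaged per type.
    """

    means: pd.DataFrame
    n_replicates: pd.Series = field(default=None)  # type: ignore[assignment]


def compute_rpkm(
    count_matrix: CountMatrix, library_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """Normalize counts to RPKM.

    RPKM = count * 1e9 / (length_bp * library_size).  When ``library_sizes``
    is not given, the per-sample column sums of the count matrix are used
    as the "million mapped reads" denominator.
    """
    counts = count_matrix.counts
    if library_sizes is None:
        library_sizes = count_matrix.library_sizes()
    else:
        library_sizes = pd.Series(library_sizes).reindex(counts.columns)
        if library_sizes.isna().any():
            raise ValidationError("library size missing for some samples")
    if (library_sizes <= 0).any():
        bad = library_sizes.index[library_sizes <= 0]
        raise ValidationError(f"non-positive library size for samples: {list(bad)}")
    lengths = count_matrix.lengths.to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    scale = 1e9 / np.outer(lengths, library_sizes.to_numpy(dtype=float))
    rpkm = counts.to_numpy(dtype=float) * scale
    return pd.DataFrame(rpkm, index=counts.index, columns=counts.columns)


def aggregate_by_type(rpkm: pd.DataFrame, type_map: pd.Series) -> TypeMeans:
    """Average replicate RPKM columns within each genetic type."""
    type_map = type_map.reindex(rpkm.columns)
    if type_map.isna().any():
        raise ValidationError("samples without a genetic type in aggregation")
    present = set(type_map)
    absent = [t for t in GENETIC_TYPES if t not in present]
    if absent:
        raise ValidationError(f"genetic types with zero samples: {absent}")
    means = rpkm.T.groupby(type_map).mean().T
    means = means[[t for t in GENETIC_TYPES if t in means.columns]]
    n_rep = type_map.value_counts().reindex(means.columns)
    return TypeMeans(means=means, n_replicates=n_rep)


def filter_expressed(type_means: TypeMeans, threshold: float = 1.0) -> pd.Index:
    """Genes with type-mean RPKM strictly above ``threshold`` in >= 1 type.

    The default of 1.0 with a strict inequality defines the expressed-gene
    universe on which differential expression and transgressive
    classification operate.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    keep = (type_means.means > threshold).any(axis=1)
    return type_means.means.index[keep]


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Raises :class:`ValidationError` for constant input, where the rank
    correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("rank correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
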