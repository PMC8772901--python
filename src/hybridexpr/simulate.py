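"""Synthetic count matrices with planted inheritance modes, and phenotype
tables with the four-genetic-type group structure.

Each simulated gene is assigned one inheritance mode that fixes its
expected RPKM-scale expression in the two parents (PC, PB) and the two
reciprocal hybrids (F1BC, F1CB):

``null``
    all four types at the baseline.
``additive``
    parents separated by the effect size; hybrids at the mid-parent.
``dominant_PC`` / ``dominant_PB``
    parents separated; hybrids at the named parent's level.
``concordant_up`` / ``concordant_down``
    parents at baseline; both hybrids beyond the parental envelope by
    the effect size (above or below).
``discordant_I``
    transgressive-up in F1BC only (the hybrid choice is arbitrary but
    fixed; the truth table records the per-type expectations).
``discordant_II``
    transgressive-up in F1BC, transgressive-down in F1CB.

Expected counts are expression x (length/1000) x (library_size/1e6), so
RPKM normalization inverts the construction in expectation and the
generator is self-verifying.  Counts are drawn NB with variance
mu + phi*mu^2; phi = 0 is exact Poisson sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .expression import GENETIC_TYPES, CountMatrix, ValidationError

__all__ = ["MODES", "SimConfig", "mode_expectations", "generate_counts", "generate_phenotypes"]

MODES = (
    "null",
    "additive",
    "dominant_PC",
    "dominant_PB",
    "concordant_up",
    "concordant_down",
    "discordant_I",
    "discordant_II",
)

#: Default gene-count mix: the study-scale transcriptome (13,420 expressed
#: genes) with the transgressive classes at their reported sizes, a modest
#: additive/dominant contingent, and the remainder null.
DEFAULT_MODE_MIX = {
    "null": 11680,
    "additive": 300,
    "dominant_PC": 150,
    "dominant_PB": 150,
    "concordant_up": 60,
    "concordant_down": 925,
    "discordant_I": 106,
    "discordant_II": 49,
}


@dataclass
class SimConfig:
    """Parameters of the count simulation.

    Defaults emulate the study design: 2 biological replicates per
    genetic type, ~13k genes, 5 million reads per sample, and a
    baseline expression of 50 on the RPKM scale.
    """

    n_genes_per_mode: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MODE_MIX)
    )
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    effect_size: float = 2.0
    replicates_per_type: int = 2
    library_sizes: Sequence[int] | None = None  # default 5e6 per sample
    gene_length_range: tuple[int, int] = (500, 3000)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_genes_per_mode) - set(MODES)
        if unknown:
            raise ValidationError(f"unknown modes: {sorted(unknown)}")
        if any(n < 0 for n in self.n_genes_per_mode.values()):
            raise ValidationError("gene counts per mode must be >= 0")
        if sum(self.n_genes_per_mode.values()) <= 0:
            raise ValidationError("at least one gene must be simulated")
        if self.baseline_mean <= 0:
            raise ValidationError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.effect_size <= 1:
            raise ValidationError("effect_size must exceed 1")
        if self.replicates_per_type < 1:
            raise ValidationError("need >= 1 replicate per type")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValidationError("gene_length_range must be positive and ordered")
        n_samples = 4 * self.replicates_per_type
        if self.library_sizes is None:
            self.library_sizes = [5_000_000] * n_samples
        self.library_sizes = list(self.library_sizes)
        if len(self.library_sizes) != n_samples:
            raise ValidationError(
                f"need {n_samples} library sizes, got {len(self.library_sizes)}"
            )
        if any(ls <= 0 for ls in self.library_sizes):
            raise ValidationError("library sizes must be positive")

    @property
    def n_genes(self) -> int:
        return sum(self.n_genes_per_mode.values())

    @property
    def sample_ids(self) -> list[str]:
        return [f"{t}_{r + 1}" for t in GENETIC_TYPES for r in range(self.replicates_per_type)]


def mode_expectations(mode: str, baseline: float, effect: float) -> dict[str, float]:
    """Expected RPKM-scale expression per genetic type for one mode."""
    b, e = baseline, effect
    if mode == "null":
        return {t: b for t in GENETIC_TYPES}
    if mode == "additive":
        return {"PC": b * e, "PB": b, "F1BC": b * (1 + e) / 2, "F1CB": b * (1 + e) / 2}
    if mode == "dominant_PC":
        return {"PC": b * e, "PB": b, "F1BC": b * e, "F1CB": b * e}
    if mode == "dominant_PB":
        return {"PC": b * e, "PB": b, "F1BC": b, "F1CB": b}
    if mode == "concordant_up":
        return {"PC": b, "PB": b, "F1BC": b * e, "F1CB": b * e}
    if mode == "concordant_down":
        return {"PC": b, "PB": b, "F1BC": b / e, "F1CB": b / e}
    if mode == "discordant_I":
        return {"PC": b, "PB": b, "F1BC": b * e, "F1CB": b}
    if mode == "discordant_II":
        return {"PC": b, "PB": b, "F1BC": b * e, "F1CB": b / e}
    raise ValidationError(f"unknown mode: {mode!r}")


def generate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a seeded NB count matrix and its truth table.

    Returns the CountMatrix (with lengths and sample-to-type map) and a
    gene-indexed truth table holding each gene's planted mode and its
    expected expression in every genetic type.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = max(5, len(str(n)))
    gene_ids = pd.Index([f"g{i + 1:0{width}d}" for i in range(n)], name="gene_id")
    lo, hi = config.gene_length_range
    lengths = pd.Series(
        rng.integers(lo, hi + 1, size=n), index=gene_ids, name="length_bp"
    )

    modes = np.concatenate(
        [
            np.repeat(m, k)
            for m, k in config.n_genes_per_mode.items()
            if k > 0
        ]
    )
    # expected expression per gene x type
    expect = np.empty((n, 4), dtype=float)
    for m in np.unique(modes):
        exp_map = mode_expectations(m, config.baseline_mean, config.effect_size)
        expect[modes == m] = [exp_map[t] for t in GENETIC_TYPES]

    sample_ids = config.sample_ids
    type_map = pd.Series(
        [s.rsplit("_", 1)[0] for s in sample_ids], index=pd.Index(sample_ids, name="sample_id"),
        name="genetic_type",
    )
    lib = np.asarray(config.library_sizes, dtype=float)
    type_idx = np.array([GENETIC_TYPES.index(t) for t in type_map])
    # mu[g, s] = expression * (length/1e3) * (lib/1e6)
    mu = (
        expect[:, type_idx]
        * (lengths.to_numpy(float)[:, None] / 1e3)
        * (lib[None, :] / 1e6)
    )
    phi = config.dispersion
    if phi == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=sample_ids)

    truth = pd.DataFrame({"mode": modes}, index=gene_ids)
    for j, t in enumerate(GENETIC_TYPES):
        truth[f"expected_{t}"] = expect[:, j]
    return CountMatrix(counts=counts, lengths=lengths, type_map=type_map), truth


def generate_phenotypes(
    group_means: pd.DataFrame,
    group_sds: pd.DataFrame,
    n_per_type: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a phenotype table: normal draws truncated at zero.

    ``group_means`` and ``group_sds`` are trait x genetic-type tables of
    the same shape.  Each genetic type receives ``n_per_type``
    individuals (the study measured six fish per type).  Values are
    truncated at 0 because morphometric and plasma traits are
    non-negative; sd = 0 yields the group mean exactly.
    """
    if group_means.shape != group_sds.shape or list(group_means.columns) != list(
        group_sds.columns
    ):
        raise ValidationError("means and sds must have identical shape and labels")
    if (group_sds.to_numpy(float) < 0).any():
        raise ValidationError("standard deviations must be >= 0")
    if n_per_type < 1:
        raise ValidationError("n_per_type must be >= 1")
    missing = [t for t in GENETIC_TYPES if t not in group_means.columns]
    if missing:
        raise ValidationError(f"missing genetic types in group means: {missing}")
    rng = np.random.default_rng(seed)
    rows = []
    for t in GENETIC_TYPES:
        for i in range(n_per_type):
            row = {"individual_id": f"{t}_{i + 1:02d}", "genetic_type": t}
            for trait in group_means.index:
                mu = float(group_means.loc[trait, t])
                sd = float(group_sds.loc[trait, t])
                if sd == 0:
                    row[trait] = mu
                else:
                    a = (0.0 - mu) / sd  # truncate at zero
                    row[trait] = float(
                        truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng)
                    )
            rows.append(row)
    return pd.DataFrame(rows)
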