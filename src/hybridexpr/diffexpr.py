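"""Pairwise differential expression with a negative-binomial exact test.

Counts within each genetic type are modelled as NB with mean mu and
variance mu + phi*mu^2 (edgeR-style dispersion phi).  A single common
dispersion is estimated by maximizing the exact conditional likelihood
given per-gene group totals (qCML) on library-size-equalized counts.
Per gene, a two-sided exact p-value is computed by conditioning on the
total count of the two groups and summing the probabilities of all
splits no more likely than the observed one.  Benjamini-Hochberg
correction and the DEG thresholds (|log2FC| > 1.5, adjusted p < 0.05)
follow.

At phi = 0 the model is Poisson and the conditional split distribution
is Binomial(total, n_a / (n_a + n_b)), so the test reduces to the exact
conditional Poisson (binomial) test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import binom, nbinom
from statsmodels.stats.multitest import multipletests

from .expression import (
    GENETIC_TYPES,
    CountMatrix,
    ValidationError,
    aggregate_by_type,
    compute_rpkm,
)

__all__ = [
    "DispersionEstimate",
    "estimate_common_dispersion",
    "equalize_library_sizes",
    "nb_exact_test",
    "bh_adjust",
    "log2_fold_change",
    "call_degs",
    "de_table",
    "all_pairwise_de",
    "PAIRS",
]

#: The six pairwise comparisons between the four genetic types.
PAIRS = tuple(itertools.combinations(GENETIC_TYPES, 2))


@dataclass(frozen=True)
class DispersionEstimate:
    """A common NB dispersion phi (variance = mu + phi*mu^2) and how it was fit."""

    phi: float
    method: str = "qCML-common"

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValidationError("dispersion must be >= 0")


def equalize_library_sizes(counts: pd.DataFrame) -> pd.DataFrame:
    """Rescale each sample's counts to the geometric-mean library size.

    The conditional (exact-test) argument requires exchangeable samples;
    rescaling to a common depth and rounding to the nearest integer is a
    simple surrogate for edgeR's quantile adjustment.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValidationError("cannot equalize: some samples have zero total count")
    target = float(np.exp(np.mean(np.log(lib))))
    scaled = counts.to_numpy(dtype=float) * (target / lib)
    return pd.DataFrame(
        np.rint(scaled).astype(np.int64), index=counts.index, columns=counts.columns
    )


def _cond_loglik(y: np.ndarray, r: float) -> float:
    """Exact conditional NB log-likelihood given per-gene totals.

    ``y`` is genes x replicates with equalized library sizes; ``r`` = 1/phi
    is the NB size.  Terms constant in r are dropped.  Groups with a single
    replicate contribute a constant and thus vanish here by construction.
    """
    n = y.shape[1]
    t = y.sum(axis=1)
    ll = gammaln(y + r).sum() - y.size * gammaln(r)
    ll -= gammaln(t + n * r).sum() - t.size * gammaln(n * r)
    return float(ll)


def estimate_common_dispersion(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    equalize: bool = True,
) -> DispersionEstimate:
    """Estimate one shared phi across genes from two replicate groups (qCML).

    Maximizes the sum over genes and groups of the conditional NB
    log-likelihood given each gene's group total, over log10(phi); the
    estimate is floored at 0 (exact Poisson).
    """
    if counts_a.shape[1] < 2 and counts_b.shape[1] < 2:
        raise ValidationError("need >= 2 replicates in at least one group")
    mats = []
    for c in (counts_a, counts_b):
        if c.shape[1] >= 2:
            mats.append(
                (equalize_library_sizes(c) if equalize else c).to_numpy(dtype=np.int64)
            )
    if all((m.sum() == 0) for m in mats):
        raise ValidationError("all-zero count matrix")

    def neg_ll(log10_phi: float) -> float:
        r = 1.0 / 10.0**log10_phi
        return -sum(_cond_loglik(m, r) for m in mats)

    res = minimize_scalar(neg_ll, bounds=(-8.0, 1.5), method="bounded")
    phi = float(10.0**res.x)
    # Flat likelihood toward phi -> 0 means the Poisson floor is the MLE.
    if phi < 1e-6 or neg_ll(-8.0) <= res.fun + 1e-9:
        phi = 0.0
    return DispersionEstimate(phi=phi, method="qCML-common")


def nb_exact_test(
    sum_a: int, n_a: int, sum_b: int, n_b: int, phi: float, mean: float | None = None
) -> float:
    """Two-sided exact NB test for a difference between two count groups.

    Conditions on the total ``sum_a + sum_b``: each split (k, total - k)
    has probability proportional to NB(n_a*mean, phi/n_a) x NB(n_b*mean,
    phi/n_b) evaluated at (k, total - k).  The two-sided p-value is the
    total conditional probability of all splits no more likely than the
    observed one (ties included, conservative).

    ``mean`` is the per-sample mean under the null; it defaults to
    ``total / (n_a + n_b)``.  At phi = 0 the conditional distribution is
    Binomial(total, n_a/(n_a+n_b)) regardless of ``mean``.
    """
    if min(sum_a, sum_b) < 0 or min(n_a, n_b) < 1 or phi < 0:
        raise ValidationError("sums must be >= 0, group sizes >= 1, phi >= 0")
    total = int(sum_a) + int(sum_b)
    if total == 0:
        return 1.0
    k = np.arange(total + 1)
    if phi < 1e-8:  # numerically Poisson; the NB pmf overflows for huge size r
        logp = binom.logpmf(k, total, n_a / (n_a + n_b))
    else:
        if mean is None:
            mean = total / (n_a + n_b)
        if mean <= 0:
            raise ValidationError("mean must be positive for phi > 0")
        r_a, r_b = n_a / phi, n_b / phi
        mu_a, mu_b = n_a * mean, n_b * mean
        logp = nbinom.logpmf(k, r_a, r_a / (r_a + mu_a)) + nbinom.logpmf(
            total - k, r_b, r_b / (r_b + mu_b)
        )
        logp = logp - logsumexp(logp)
    log_obs = logp[int(sum_a)]
    keep = logp <= log_obs + 1e-10
    p = float(np.exp(logsumexp(logp[keep])))
    return min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(mean_a, mean_b, pseudocount: float = 1.0):
    """log2((mean_b + pseudocount) / (mean_a + pseudocount)), B over A."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    out = np.log2((b + pseudocount) / (a + pseudocount))
    return float(out) if out.ndim == 0 else out


def call_degs(
    records: pd.DataFrame, lfc_threshold: float = 1.5, fdr_threshold: float = 0.05
) -> pd.Index:
    """Genes with |log2fc| strictly above and adjusted p strictly below threshold."""
    flag = (records["log2fc"].abs() > lfc_threshold) & (
        records["p_adj"] < fdr_threshold
    )
    return records.index[flag]


def de_table(
    count_matrix: CountMatrix,
    type_a: str,
    type_b: str,
    genes: pd.Index | None = None,
    pseudocount: float = 1.0,
    lfc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """One pairwise DE comparison: per-gene means, log2FC, exact p, BH, DEG flag.

    Fold changes are computed from type-mean RPKM with a pseudocount; the
    exact test runs on library-size-equalized raw counts restricted to
    ``genes`` (the expressed universe) when given.  ``dispersion``
    overrides the qCML estimate (used for phi = 0 simulations).
    """
    for t in (type_a, type_b):
        if t not in set(count_matrix.type_map):
            raise ValidationError(f"genetic type {t!r} has no samples")
    rpkm = compute_rpkm(count_matrix)
    means = aggregate_by_type(rpkm, count_matrix.type_map).means
    sub = count_matrix.counts
    if genes is not None:
        sub = sub.loc[sub.index.intersection(genes)]
        means = means.loc[sub.index]
    cols_a = count_matrix.sample_ids[count_matrix.type_map == type_a]
    cols_b = count_matrix.sample_ids[count_matrix.type_map == type_b]
    ca, cb = sub[cols_a], sub[cols_b]
    if dispersion is None:
        phi = estimate_common_dispersion(ca, cb).phi
    else:
        phi = float(dispersion)
    eq = equalize_library_sizes(sub[list(cols_a) + list(cols_b)])
    sa = eq[cols_a].sum(axis=1).to_numpy()
    sb = eq[cols_b].sum(axis=1).to_numpy()
    n_a, n_b = len(cols_a), len(cols_b)
    p_raw = np.array(
        [
            nb_exact_test(int(a), n_a, int(b), n_b, phi)
            for a, b in zip(sa, sb, strict=True)
        ]
    )
    table = pd.DataFrame(
        {
            "mean_a": means[type_a],
            "mean_b": means[type_b],
            "log2fc": log2_fold_change(means[type_a], means[type_b], pseudocount),
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
        },
        index=sub.index,
    )
    table.index.name = "gene_id"
    table["is_deg"] = (table["log2fc"].abs() > lfc_threshold) & (
        table["p_adj"] < fdr_threshold
    )
    table.attrs["comparison"] = (type_a, type_b)
    table.attrs["dispersion"] = phi
    return table


def all_pairwise_de(
    count_matrix: CountMatrix, genes: pd.Index | None = None, **kwargs
) -> dict[tuple[str, str], pd.DataFrame]:
    """DE tables for all six pairs of genetic types."""
    return {
        (a, b): de_table(count_matrix, a, b, genes=genes, **kwargs) for a, b in PAIRS
    }
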