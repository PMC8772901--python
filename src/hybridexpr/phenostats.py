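"""Phenotype statistics: heterosis, heterobeltiosis, trait standardization,
and exact Mann-Whitney U tests for the small group sizes of the design.

Heterosis is the deviation of the reciprocal-F1 average from the
mid-parent value, as a percentage of the mid-parent value:

    heterosis% = 100 * (mean(F1BC, F1CB) - (PC + PB)/2) / ((PC + PB)/2)

Heterobeltiosis compares the F1 average with the best-performing parent
instead of the mid-parent; the hybrids exhibit heterobeltiosis for a
trait only when that percentage is strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .expression import GENETIC_TYPES, ValidationError

__all__ = [
    "HeterosisResult",
    "heterosis",
    "heterobeltiosis",
    "standardize_by_length",
    "MWUResult",
    "mann_whitney_exact",
    "group_means",
    "pairwise_mwu",
]


@dataclass(frozen=True)
class HeterosisResult:
    trait: str
    means: dict
    midparent: float
    f1_mean: float
    heterosis_pct: float
    best_parent: str
    heterobeltiosis_pct: float
    exceeds_best: bool


def heterosis(means: Mapping[str, float], trait: str = "", larger_is_better: bool = True) -> HeterosisResult:
    """Mid-parent heterosis and best-parent heterobeltiosis from type means.

    ``means`` maps each of PC, PB, F1BC, F1CB to a trait mean.  The
    mid-parent value must be positive.  ``larger_is_better`` selects the
    direction in which a parent counts as "best" (growth traits: larger).
    """
    missing = [t for t in GENETIC_TYPES if t not in means]
    if missing:
        raise ValidationError(f"missing type means: {missing}")
    pc, pb = float(means["PC"]), float(means["PB"])
    midparent = (pc + pb) / 2.0
    if midparent <= 0:
        raise ValidationError("mid-parent value must be positive")
    f1_mean = (float(means["F1BC"]) + float(means["F1CB"])) / 2.0
    het = 100.0 * (f1_mean - midparent) / midparent
    if larger_is_better:
        best_parent = "PC" if pc >= pb else "PB"
    else:
        best_parent = "PC" if pc <= pb else "PB"
    best = float(means[best_parent])
    if best <= 0:
        raise ValidationError("best-parent mean must be positive")
    hb = 100.0 * (f1_mean - best) / best
    if not larger_is_better:
        hb = -hb  # improvement means moving below the best (lowest) parent
    return HeterosisResult(
        trait=trait,
        means={t: float(means[t]) for t in GENETIC_TYPES},
        midparent=midparent,
        f1_mean=f1_mean,
        heterosis_pct=het,
        best_parent=best_parent,
        heterobeltiosis_pct=hb,
        exceeds_best=hb > 0,
    )


def heterobeltiosis(means: Mapping[str, float], larger_is_better: bool = True):
    """(best_parent, heterobeltiosis_pct, exceeds_best) for one trait."""
    r = heterosis(means, larger_is_better=larger_is_better)
    return r.best_parent, r.heterobeltiosis_pct, r.exceeds_best


def standardize_by_length(
    table: pd.DataFrame, denominator_trait: str = "total_length"
) -> pd.DataFrame:
    """Divide every trait column (body weight included) by total length per fish.

    Removes the overall size axis so that shape differences between the
    genetic types can be compared.  The denominator column itself is kept
    unchanged; non-trait columns (individual_id, genetic_type) pass through.
    """
    if denominator_trait not in table.columns:
        raise ValidationError(f"denominator trait {denominator_trait!r} absent")
    denom = table[denominator_trait].astype(float)
    if (denom <= 0).any():
        bad = table.index[denom <= 0]
        raise ValidationError(f"non-positive {denominator_trait} for rows: {list(bad[:5])}")
    out = table.copy()
    trait_cols = [
        c
        for c in table.columns
        if c not in ("individual_id", "genetic_type", denominator_trait)
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    for c in trait_cols:
        out[c] = table[c].astype(float) / denom
    return out


@dataclass(frozen=True)
class MWUResult:
    U: float
    p_two_sided: float
    method: str  # "exact" or "normal-approx"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for group x via mid-ranks (ties count half)."""
    n1 = len(x)
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_exact(
    x,
    y,
    alternative: str = "two-sided",
    exact_cap: int = 200_000,
) -> MWUResult:
    """Mann-Whitney U test with exact enumeration for small samples.

    When C(n1+n2, n1) <= ``exact_cap`` (covers the design's 6 vs 6 with
    924 assignments) the full permutation distribution of U over all
    group assignments of the pooled values is enumerated; tied
    permutations contribute their whole probability to the tail
    (conservative) and the two-sided p is min(1, 2 * smaller one-sided
    tail).  Larger problems fall back to the tie-corrected normal
    approximation, labelled in ``method``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValidationError(f"unknown alternative: {alternative!r}")
    n1, n2 = len(x), len(y)
    u_obs = _u_statistic(x, y)
    n_assign = comb(n1 + n2, n1)
    if n_assign > exact_cap:
        p = float(
            mannwhitneyu(x, y, alternative=alternative, method="asymptotic").pvalue
        )
        return MWUResult(U=u_obs, p_two_sided=p, method="normal-approx")

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    n_le = n_ge = 0
    tol = 1e-9
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        if u <= u_obs + tol:
            n_le += 1
        if u >= u_obs - tol:
            n_ge += 1
    p_less = n_le / n_assign
    p_greater = n_ge / n_assign
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return MWUResult(U=u_obs, p_two_sided=p, method="exact")


def group_means(phenotypes: pd.DataFrame, trait: str) -> dict[str, float]:
    """Per-genetic-type mean of one trait column."""
    if trait not in phenotypes.columns:
        raise ValidationError(f"trait {trait!r} absent from phenotype table")
    g = phenotypes.groupby("genetic_type")[trait].mean()
    return {t: float(g[t]) for t in GENETIC_TYPES if t in g.index}


def pairwise_mwu(
    phenotypes: pd.DataFrame, trait: str, adjust: bool = False
) -> pd.DataFrame:
    """Exact Mann-Whitney p-values for all six pairs of genetic types.

    ``adjust=True`` appends a Benjamini-Hochberg column across the six
    comparisons.
    """
    from .diffexpr import bh_adjust  # local import to avoid cycle

    rows = []
    for a, b in combinations(GENETIC_TYPES, 2):
        xa = phenotypes.loc[phenotypes["genetic_type"] == a, trait].to_numpy(float)
        xb = phenotypes.loc[phenotypes["genetic_type"] == b, trait].to_numpy(float)
        res = mann_whitney_exact(xa, xb)
        rows.append(
            {"type_a": a, "type_b": b, "U": res.U, "p": res.p_two_sided, "method": res.method}
        )
    out = pd.DataFrame(rows)
    if adjust:
        out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out
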