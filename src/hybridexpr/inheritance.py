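"""Transgressive-gene classification from parental and hybrid type means.

A gene is transgressive in a hybrid when its expression lies at least a
margin (default 20%) beyond the envelope spanned by the two parental
species: "up" when the hybrid type-mean is >= 1.2x the higher parent,
"down" when it is <= 0.8x the lower parent.  Combining the calls in the
two reciprocal hybrids yields the inheritance class:

===========  ===========  =================
call in BC   call in CB   class
===========  ===========  =================
up           up           concordant_up
down         down         concordant_down
up/down      down/up      discordant_II
one of up/down, other none  discordant_I
none         none         non_transgressive
===========  ===========  =================

Concordant genes are transgressive in the same direction in both
reciprocal hybrids; discordant I genes are transgressive in exactly one
hybrid; discordant II genes flip direction between the hybrids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ValidationError, TypeMeans

__all__ = [
    "CALLS",
    "CLASSES",
    "TRANSGRESSIVE_CLASSES",
    "call_transgressive_per_hybrid",
    "classify_gene",
    "classify_all",
    "ClassSummary",
    "summarize_classes",
    "hybrid_overlap",
    "pct",
]

CALLS = ("up", "down", "none")
TRANSGRESSIVE_CLASSES = (
    "concordant_up",
    "concordant_down",
    "discordant_I",
    "discordant_II",
)
CLASSES = ("non_transgressive",) + TRANSGRESSIVE_CLASSES


def call_transgressive_per_hybrid(
    mean_pc: float, mean_pb: float, mean_f1: float, margin: float = 0.2
) -> str:
    """Directional transgressive call for one hybrid against both parents.

    ``up`` iff f1 >= (1 + margin) * max(parents) and f1 > 0;
    ``down`` iff min(parents) > 0 and f1 <= (1 - margin) * min(parents);
    else ``none``.  Boundaries are inclusive ("at least" the margin).
    A gene silent in both parents can only be called up (any positive
    hybrid expression exceeds a zero envelope); it can never be called
    down.
    """
    if not 0 <= margin < 1:
        raise ValidationError("margin must lie in [0, 1)")
    if min(mean_pc, mean_pb, mean_f1) < 0:
        raise ValidationError("expression means must be >= 0")
    hi = max(mean_pc, mean_pb)
    lo = min(mean_pc, mean_pb)
    if mean_f1 > 0 and mean_f1 >= (1 + margin) * hi:
        return "up"
    if lo > 0 and mean_f1 <= (1 - margin) * lo:
        return "down"
    return "none"


def classify_gene(call_bc: str, call_cb: str) -> str:
    """Map the pair of per-hybrid calls to the inheritance class."""
    for c in (call_bc, call_cb):
        if c not in CALLS:
            raise ValidationError(f"unknown call token: {c!r}")
    if call_bc == "none" and call_cb == "none":
        return "non_transgressive"
    if call_bc == call_cb:
        return f"concordant_{call_bc}"
    if "none" in (call_bc, call_cb):
        return "discordant_I"
    return "discordant_II"


def classify_all(
    type_means: TypeMeans, expressed: pd.Index, margin: float = 0.2
) -> pd.DataFrame:
    """Classify every expressed gene; returns gene_id-indexed calls + class.

    Only the expressed universe is classified (the transgressive fraction
    is reported relative to expressed genes).
    """
    expressed = pd.Index(expressed)
    if len(expressed) == 0:
        raise ValidationError("expressed gene set is empty")
    missing = expressed.difference(type_means.means.index)
    if len(missing):
        raise ValidationError(f"expressed genes absent from type means: {list(missing[:5])}")
    m = type_means.means.loc[expressed]
    pc = m["PC"].to_numpy(float)
    pb = m["PB"].to_numpy(float)
    hi = np.maximum(pc, pb)
    lo = np.minimum(pc, pb)

    def _calls(f1: np.ndarray) -> np.ndarray:
        up = (f1 > 0) & (f1 >= (1 + margin) * hi)
        down = (lo > 0) & (f1 <= (1 - margin) * lo) & ~up
        out = np.where(up, "up", np.where(down, "down", "none"))
        return out

    call_bc = _calls(m["F1BC"].to_numpy(float))
    call_cb = _calls(m["F1CB"].to_numpy(float))
    klass = np.array(
        [classify_gene(b, c) for b, c in zip(call_bc, call_cb, strict=True)]
    )
    out = pd.DataFrame(
        {"call_BC": call_bc, "call_CB": call_cb, "klass": klass}, index=expressed
    )
    out.index.name = "gene_id"
    return out


def pct(count: int, universe: int, decimals: int = 1) -> float:
    """Percentage of ``count`` within ``universe``, recomputed from integers."""
    if universe <= 0:
        raise ValidationError("universe must be positive")
    return round(100.0 * count / universe, decimals)


@dataclass(frozen=True)
class ClassSummary:
    """Integer class counts over the expressed universe.

    Percentages are always recomputed from the integer counts, never
    stored rounded, so fraction arithmetic stays reproducible.
    """

    concordant_up: int
    concordant_down: int
    discordant_I: int
    discordant_II: int
    universe: int

    def __post_init__(self) -> None:
        if self.universe < self.total_transgressive:
            raise ValidationError("universe smaller than transgressive total")

    @classmethod
    def from_counts(
        cls,
        concordant_up: int,
        concordant_down: int,
        discordant_I: int,
        discordant_II: int,
        universe: int,
    ) -> "ClassSummary":
        return cls(concordant_up, concordant_down, discordant_I, discordant_II, universe)

    @property
    def concordant(self) -> int:
        return self.concordant_up + self.concordant_down

    @property
    def total_transgressive(self) -> int:
        return self.concordant + self.discordant_I + self.discordant_II

    @property
    def non_transgressive(self) -> int:
        return self.universe - self.total_transgressive

    def counts(self) -> dict[str, int]:
        return {
            "non_transgressive": self.non_transgressive,
            "concordant_up": self.concordant_up,
            "concordant_down": self.concordant_down,
            "discordant_I": self.discordant_I,
            "discordant_II": self.discordant_II,
        }

    def transgressive_pct_of_universe(self) -> float:
        """Transgressive genes as % of expressed genes, one decimal."""
        return pct(self.total_transgressive, self.universe, 1)

    def concordant_down_pct(self) -> float:
        """Downregulated share of concordant genes, nearest integer %."""
        if self.concordant == 0:
            raise ValidationError("no concordant genes")
        return pct(self.concordant_down, self.concordant, 0)

    def discordant_I_pct_of_transgressive(self) -> float:
        return pct(self.discordant_I, self.total_transgressive, 1)

    def discordant_II_pct_of_transgressive(self) -> float:
        return pct(self.discordant_II, self.total_transgressive, 1)

    def to_dict(self) -> dict:
        d: dict = {"universe": self.universe, **self.counts()}
        d["total_transgressive"] = self.total_transgressive
        d["transgressive_pct_of_universe"] = self.transgressive_pct_of_universe()
        if self.concordant:
            d["concordant_down_pct"] = self.concordant_down_pct()
        if self.total_transgressive:
            d["discordant_I_pct_of_transgressive"] = (
                self.discordant_I_pct_of_transgressive()
            )
            d["discordant_II_pct_of_transgressive"] = (
                self.discordant_II_pct_of_transgressive()
            )
            d["hybrid_overlap"] = hybrid_overlap(self)
        return d


def summarize_classes(calls: pd.DataFrame, universe: int) -> ClassSummary:
    """Tally the class column of :func:`classify_all` over a stated universe."""
    if universe <= 0:
        raise ValidationError("universe must be positive")
    counts = calls["klass"].value_counts()
    return ClassSummary(
        concordant_up=int(counts.get("concordant_up", 0)),
        concordant_down=int(counts.get("concordant_down", 0)),
        discordant_I=int(counts.get("discordant_I", 0)),
        discordant_II=int(counts.get("discordant_II", 0)),
        universe=universe,
    )


def hybrid_overlap(summary: ClassSummary | pd.DataFrame) -> float:
    """Fraction of transgressive genes shared by the reciprocal hybrids.

    |transgressive in both hybrids| / |transgressive in at least one|.
    Concordant and discordant II genes are transgressive in both hybrids;
    discordant I genes in exactly one, so the ratio equals
    (concordant + discordant_II) / all transgressive.
    """
    if isinstance(summary, pd.DataFrame):
        summary = summarize_classes(summary, universe=len(summary))
    total = summary.total_transgressive
    if total == 0:
        raise ValidationError("no transgressive genes; overlap undefined")
    return (summary.concordant + summary.discordant_II) / total
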