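"""Rank aggregation of stability methods (RefFinder-style) and top-k comparison.

Each stability method produces one value per gene with a known orientation
(lower-is-better for all four methods used here).  Genes are ranked with
competition (min-tie) ranking, and a comprehensive ranking is obtained as the
geometric mean of the per-method ranks — the aggregation RefFinder applies to
geNorm, NormFinder, BestKeeper and the comparative ΔCt method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "competition_ranks",
    "StabilityTable",
    "ComprehensiveRanking",
    "reffinder_aggregate",
    "compare_top_k",
    "TopKOverlap",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for display (1.315 -> 1.32)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def competition_ranks(
    values: Sequence[float], orientation: str = "lower_better"
) -> np.ndarray:
    """Competition (min-tie) ranks: rank = 1 + number of strictly better values.

    Tied values share the minimal applicable rank, so e.g. stability values
    {0.077, 0.077, 0.146} rank {1, 1, 3}.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("cannot rank an empty value list")
    if not np.isfinite(v).all():
        raise ValueError("ranks require finite values")
    if orientation == "higher_better":
        v = -v
    elif orientation != "lower_better":
        raise ValueError(f"unknown orientation {orientation!r}")
    return (v[:, None] > v[None, :]).sum(axis=1).astype(int) + 1


@dataclass
class StabilityTable:
    """One method's per-gene stability values with competition ranks."""

    method: str
    genes: list[str]
    values: np.ndarray
    orientation: str = "lower_better"
    ranks: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.values = np.asarray(self.values, float)
        if len(self.genes) != self.values.size:
            raise ValueError("genes and values length mismatch")
        if self.ranks is None:
            self.ranks = competition_ranks(self.values, self.orientation)
        else:
            self.ranks = np.asarray(self.ranks, int)
            if self.ranks.size != self.values.size:
                raise ValueError("genes and ranks length mismatch")

    @classmethod
    def from_values(
        cls,
        method: str,
        values: Mapping[str, float] | pd.Series,
        orientation: str = "lower_better",
    ) -> "StabilityTable":
        series = pd.Series(values)
        return cls(method, list(series.index), series.to_numpy(float), orientation)

    @classmethod
    def from_ranks(
        cls, method: str, ranks: Mapping[str, int] | pd.Series
    ) -> "StabilityTable":
        """Build a table from externally supplied ranks (values carry the ranks)."""
        series = pd.Series(ranks)
        return cls(
            method,
            list(series.index),
            series.to_numpy(float),
            "lower_better",
            ranks=series.to_numpy(int),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": self.values, "rank": self.ranks},
            index=pd.Index(self.genes, name="gene"),
        )


@dataclass
class ComprehensiveRanking:
    """Geometric-mean-of-ranks aggregate across stability methods.

    ``table`` is indexed by gene with one ``<method>_rank`` column per input
    method, the full-precision ``geomean``, its 2-decimal half-up display
    value, and the competition ``final_rank`` of the geomean (ascending).
    """

    table: pd.DataFrame
    methods: list[str]

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def top_genes(self, k: int) -> tuple[list[str], bool]:
        """Genes with final rank <= k; ties at the k-th position all included.

        Returns (genes, tie_flag); tie_flag is True when ties made the set
        larger than k.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        sel = self.table[self.table["final_rank"] <= k]
        genes = list(sel.sort_values(["final_rank", "geomean"]).index)
        return genes, len(genes) != k

    def ordered_genes(self) -> list[str]:
        return list(self.table.sort_values(["geomean"], kind="stable").index)


def reffinder_aggregate(tables: Sequence[StabilityTable]) -> ComprehensiveRanking:
    """Aggregate per-method ranks by their geometric mean.

    All tables must cover the same gene set.  The geometric mean
    (Π ranks)^(1/m) is reported at full precision and half-up rounded to two
    decimals for display; the final ordering uses full precision with
    competition ranking.
    """
    if len(tables) < 2:
        raise ValueError("aggregation needs at least two method tables")
    ref = set(tables[0].genes)
    for t in tables[1:]:
        if set(t.genes) != ref:
            diff = sorted(ref.symmetric_difference(t.genes))
            raise ValueError(
                f"gene sets differ between method tables ({tables[0].method} vs "
                f"{t.method}): {diff}"
            )
    genes = list(tables[0].genes)
    rank_cols = {
        f"{t.method}_rank": pd.Series(t.ranks, index=t.genes).loc[genes].to_numpy()
        for t in tables
    }
    ranks = np.column_stack(list(rank_cols.values())).astype(float)
    geomean = np.exp(np.log(ranks).mean(axis=1))
    out = pd.DataFrame(rank_cols, index=pd.Index(genes, name="gene"))
    out["geomean"] = geomean
    out["geomean_2dp"] = [round_half_up(g, 2) for g in geomean]
    out["final_rank"] = competition_ranks(geomean, "lower_better")
    return ComprehensiveRanking(out, [t.method for t in tables])


@dataclass
class TopKOverlap:
    """Top-k gene sets per condition plus their pairwise and global overlaps."""

    k: int
    sets: dict[str, list[str]]
    tie_flags: dict[str, bool]
    pairwise: dict[tuple[str, str], set[str]]
    global_intersection: set[str]


def _top_set(ranking, k: int) -> tuple[list[str], bool]:
    if isinstance(ranking, ComprehensiveRanking):
        return ranking.top_genes(k)
    genes = list(ranking)
    return genes[:k], len(genes[:k]) != k


def compare_top_k(
    rankings: Mapping[str, "ComprehensiveRanking | Iterable[str]"], k: int = 3
) -> TopKOverlap:
    """Compare top-k reference-gene sets across named conditions.

    ``rankings`` maps a condition name to either a
    :class:`ComprehensiveRanking` or an already-selected ordered gene list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(rankings) < 2:
        raise ValueError("need at least two rankings to compare")
    sets: dict[str, list[str]] = {}
    ties: dict[str, bool] = {}
    for name, ranking in rankings.items():
        genes, tie = _top_set(ranking, k)
        sets[name] = genes
        ties[name] = tie
    names = list(sets)
    pairwise = {
        (a, b): set(sets[a]) & set(sets[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    global_intersection = set(sets[names[0]])
    for name in names[1:]:
        global_intersection &= set(sets[name])
    return TopKOverlap(k, sets, ties, pairwise, global_intersection)
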