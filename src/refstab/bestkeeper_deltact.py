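"""BestKeeper descriptive/index statistics and the comparative ΔCt method.

BestKeeper works directly on Cq: each gene is described by its mean Cq, its
dispersion SD[±Cq] (defined by the BestKeeper applet as the *mean absolute
deviation* about the mean, not the root-mean-square SD), the derived CV%, and
the Pearson correlation of the gene's Cq profile with the BestKeeper index —
the per-sample geometric mean of Cq across all candidates.  Genes are ranked
ascending by dispersion by default (|r| descending is available).

The comparative ΔCt method scores a gene by the average sample SD of its
pairwise Cq differences with every other candidate; with all efficiencies at
2 it coincides exactly with first-round geNorm M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import gmean

from .cq_data import CqDataset, DataError
from .reffinder import StabilityTable, competition_ranks

__all__ = ["BestkeeperResult", "bestkeeper", "DeltaCtResult", "deltact_stability"]


@dataclass
class BestkeeperResult:
    """Per-gene BestKeeper descriptives plus the per-sample index."""

    table: pd.DataFrame  # gene-indexed: mean_cq, mad_cq, cv_percent, r_index, rank
    index: pd.Series  # per-sample geometric mean of Cq
    ranking_basis: str  # "mad" | "abs_r"

    @property
    def ranking(self) -> StabilityTable:
        if self.ranking_basis == "mad":
            return StabilityTable(
                "bestkeeper",
                list(self.table.index),
                self.table["mad_cq"].to_numpy(),
                "lower_better",
                ranks=self.table["rank"].to_numpy(),
            )
        return StabilityTable(
            "bestkeeper",
            list(self.table.index),
            self.table["r_index"].abs().to_numpy(),
            "higher_better",
            ranks=self.table["rank"].to_numpy(),
        )


def bestkeeper(
    d: CqDataset, ranking_basis: str = "mad", include_self: bool = True
) -> BestkeeperResult:
    """BestKeeper statistics for a collapsed, complete dataset (≥ 2 genes).

    ``include_self=False`` correlates each gene against the index computed
    from the *other* candidates only (the applet includes the gene itself).
    Zero-variance genes have undefined r (NaN) and are ranked by dispersion.
    """
    if ranking_basis not in ("mad", "abs_r"):
        raise ValueError(f"unknown ranking basis {ranking_basis!r}")
    wide = d.to_wide()
    genes = list(wide.index)
    if len(genes) < 2:
        raise DataError("BestKeeper needs at least 2 genes")
    cq = wide.to_numpy(float)
    mean = cq.mean(axis=1)
    mad = np.abs(cq - mean[:, None]).mean(axis=1)
    cv = 100.0 * mad / mean
    index = gmean(cq, axis=0)
    r = np.full(len(genes), np.nan)
    for i in range(len(genes)):
        base = index if include_self else gmean(np.delete(cq, i, axis=0), axis=0)
        if cq[i].std() > 0 and base.std() > 0:
            r[i] = stats.pearsonr(cq[i], base).statistic
    if ranking_basis == "mad":
        ranks = competition_ranks(mad, "lower_better")
    else:
        if np.isnan(r).any():
            raise DataError(
                "abs_r ranking unavailable: undefined correlation for zero-variance gene(s)"
            )
        ranks = competition_ranks(np.abs(r), "higher_better")
    table = pd.DataFrame(
        {"mean_cq": mean, "mad_cq": mad, "cv_percent": cv, "r_index": r, "rank": ranks},
        index=pd.Index(genes, name="gene"),
    )
    return BestkeeperResult(table, pd.Series(index, index=wide.columns, name="bk_index"),
                            ranking_basis)


@dataclass
class DeltaCtResult:
    """Mean pairwise-SD stability per gene and the symmetric pair-SD table."""

    stability: pd.Series
    pair_sd: pd.DataFrame

    @property
    def ranking(self) -> StabilityTable:
        return StabilityTable.from_values(
            "deltact", self.stability, "lower_better"
        )


def deltact_stability(d: CqDataset) -> DeltaCtResult:
    """Comparative ΔCt stability: mean over partners of SD(Cq_i − Cq_l).

    Pair SDs use the n−1 denominator.  Identical to first-round geNorm M when
    every efficiency is 2 (log2 ratios of relative quantities are then plain
    Cq differences up to a constant).
    """
    wide = d.to_wide()
    genes = list(wide.index)
    if len(genes) < 2:
        raise DataError("comparative deltaCt needs at least 2 genes")
    cq = wide.to_numpy(float)
    diff = cq[:, None, :] - cq[None, :, :]
    sd = diff.std(axis=2, ddof=1)
    stability = sd.sum(axis=1) / (len(genes) - 1)
    return DeltaCtResult(
        pd.Series(stability, index=genes, name="stability"),
        pd.DataFrame(sd, index=genes, columns=genes),
    )
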