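"""geNorm: M-value stability, iterative-exclusion ranking, pairwise variation.

geNorm judges a candidate reference gene by the average standard deviation of
its log2 expression ratios with every other candidate (the M value; smaller =
more stable).  Repeatedly discarding the least stable gene yields a stability
ordering ending in an inseparable best pair.  The pairwise-variation analysis
V(n/n+1) then asks how many references are enough: once adding the (n+1)-th
ranked gene changes the normalization factor by less than a cutoff
(conventionally 0.15), n references suffice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .cq_data import CqDataset, DataError
from .reffinder import StabilityTable

__all__ = [
    "QuantityMatrix",
    "relative_quantities",
    "genorm_m",
    "GenormResult",
    "genorm_rank",
    "PairwiseVariationResult",
    "pairwise_variation",
]


@dataclass
class QuantityMatrix:
    """Relative expression quantities per gene × sample.

    q(i, j) = E_i^(min_j' Cq(i, j') − Cq(i, j)): each gene is scaled to its
    highest-expressed sample, so every row's maximum is 1 and all entries lie
    in (0, 1].  E is the amplification efficiency as fold change per cycle
    (2.0 = perfect doubling).
    """

    genes: list[str]
    samples: list[str]
    q: np.ndarray
    efficiencies: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        self.efficiencies = np.asarray(self.efficiencies, float)
        if self.q.shape != (len(self.genes), len(self.samples)):
            raise ValueError("q must be genes x samples")
        if (self.q <= 0).any():
            raise ValueError("relative quantities must be positive")

    def subset(self, genes: Sequence[str]) -> "QuantityMatrix":
        idx = [self.genes.index(g) for g in genes]
        return QuantityMatrix(
            list(genes), self.samples, self.q[idx], self.efficiencies[idx]
        )

    def log2q(self) -> np.ndarray:
        return np.log2(self.q)


def _efficiency_vector(
    genes: Sequence[str], eff: Mapping[str, float] | float | None
) -> np.ndarray:
    if eff is None:
        e = np.full(len(genes), 2.0)
    elif np.isscalar(eff):
        e = np.full(len(genes), float(eff))  # type: ignore[arg-type]
    else:
        missing = [g for g in genes if g not in eff]  # type: ignore[operator]
        if missing:
            raise DataError(f"no efficiency supplied for gene(s): {missing}")
        e = np.array([float(eff[g]) for g in genes])  # type: ignore[index]
    if (e <= 1.0).any():
        raise DataError("amplification efficiency must exceed 1 fold per cycle")
    return e


def relative_quantities(
    d: CqDataset, eff: Mapping[str, float] | float | None = None
) -> QuantityMatrix:
    """Transform a collapsed, complete Cq dataset to relative quantities.

    ``eff`` maps gene id to fold-per-cycle efficiency (default 2.0 for every
    gene, i.e. 100% efficiency, the spreadsheet-geNorm convention).
    """
    wide = d.to_wide()
    genes = list(wide.index)
    e = _efficiency_vector(genes, eff)
    cq = wide.to_numpy(float)
    q = e[:, None] ** (cq.min(axis=1, keepdims=True) - cq)
    return QuantityMatrix(genes, list(wide.columns), q, e)


def genorm_m(
    qm: QuantityMatrix, subset: Sequence[str] | None = None
) -> pd.Series:
    """geNorm M value for each gene (optionally within a gene subset).

    For genes j, k the pairwise variation V_jk is the sample SD (n−1) over
    samples of log2(q_j / q_k); M_j is the mean of V_jk over all k ≠ j.
    """
    sub = qm if subset is None else qm.subset(list(subset))
    k, n = sub.q.shape
    if k < 2:
        raise DataError("M undefined for fewer than 2 genes")
    if n < 2:
        raise DataError("M requires at least 2 samples")
    a = sub.log2q()
    # pair SD matrix: sd over samples of (a_j - a_k)
    diff = a[:, None, :] - a[None, :, :]
    v = diff.std(axis=2, ddof=1)
    m = v.sum(axis=1) / (k - 1)  # diagonal is 0
    return pd.Series(m, index=sub.genes, name="m_value")


@dataclass
class GenormResult:
    """Iterative-exclusion geNorm output.

    ``initial_m`` is the first-round M on the full panel; ``stepwise_m`` the
    M each gene had in the round it was excluded (the final pair share the
    two-gene-round M).  The ranking gives the final pair joint rank 1 and the
    remaining genes ranks 3, 4, … in reverse exclusion order (competition
    convention: two genes at rank 1, the next at rank 3).
    """

    initial_m: pd.Series
    exclusion_order: list[str]
    final_pair: tuple[str, str]
    stepwise_m: pd.Series
    ranking: StabilityTable
    mean_m_path: list[float]

    def ordered_genes(self) -> list[str]:
        """All genes, most stable first (final pair in input order)."""
        return list(self.final_pair) + list(reversed(self.exclusion_order))


def genorm_rank(qm: QuantityMatrix) -> GenormResult:
    """Rank genes by iterative exclusion of the least stable candidate.

    Each round recomputes M on the surviving subset and removes the gene
    with the largest M; ties remove the gene later in input order (a
    deterministic, documented rule).  Stops when two genes remain; those
    share rank 1 with identical M.
    """
    genes = list(qm.genes)
    if len(genes) < 3:
        raise DataError("iterative exclusion needs at least 3 genes")
    initial_m = genorm_m(qm)
    surviving = list(genes)
    exclusion: list[str] = []
    stepwise: dict[str, float] = {}
    mean_m_path: list[float] = []
    while len(surviving) > 2:
        m = genorm_m(qm, surviving)
        mean_m_path.append(float(m.mean()))
        worst_value = m.max()
        # tie -> remove the later gene in input order
        worst = [g for g in surviving if m[g] == worst_value][-1]
        stepwise[worst] = float(m[worst])
        exclusion.append(worst)
        surviving.remove(worst)
    final_m = genorm_m(qm, surviving)
    mean_m_path.append(float(final_m.mean()))
    for g in surviving:
        stepwise[g] = float(final_m[g])
    final_pair = (surviving[0], surviving[1])
    ordered = list(final_pair) + list(reversed(exclusion))
    ranks = {ordered[0]: 1, ordered[1]: 1}
    for pos, g in enumerate(ordered[2:], start=3):
        ranks[g] = pos
    stepwise_m = pd.Series({g: stepwise[g] for g in genes}, name="m_value")
    table = StabilityTable(
        "genorm",
        genes,
        stepwise_m.loc[genes].to_numpy(),
        "lower_better",
        ranks=np.array([ranks[g] for g in genes]),
    )
    return GenormResult(
        initial_m=initial_m,
        exclusion_order=exclusion,
        final_pair=final_pair,
        stepwise_m=stepwise_m,
        ranking=table,
        mean_m_path=mean_m_path,
    )


@dataclass
class PairwiseVariationResult:
    """V(n/n+1) series and the smallest adequate number of references."""

    v: list[tuple[int, float]]
    threshold: float
    recommended_n: int | None  # None = "not reached"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": [n for n, _ in self.v],
                "v_value": [v for _, v in self.v],
                "below_threshold": [v < self.threshold for _, v in self.v],
            }
        )


def pairwise_variation(
    qm: QuantityMatrix,
    ranking: Sequence[str] | None = None,
    threshold: float = 0.15,
) -> PairwiseVariationResult:
    """Pairwise variation V_n between normalization factors NF_n and NF_{n+1}.

    NF_n(sample) is the geometric mean of the relative quantities of the
    top-n ranked genes; V_n is the sample SD (n−1 denominator) of
    log2(NF_n / NF_{n+1}) across samples, for n = 2 … k−1.  The recommended
    number of references is the smallest n with V_n below the cutoff.
    """
    k = len(qm.genes)
    if k < 3:
        raise DataError("pairwise variation needs at least 3 genes")
    if ranking is None:
        ranking = genorm_rank(qm).ordered_genes()
    ranking = list(ranking)
    if sorted(ranking) != sorted(qm.genes):
        raise DataError("ranking must cover exactly the genes of the matrix")
    ordered = qm.subset(ranking)
    v_list: list[tuple[int, float]] = []
    recommended: int | None = None
    for n in range(2, k):
        nf_n = gmean(ordered.q[:n], axis=0)
        nf_n1 = gmean(ordered.q[: n + 1], axis=0)
        v = float(np.std(np.log2(nf_n / nf_n1), ddof=1))
        v_list.append((n, v))
        if recommended is None and v < threshold:
            recommended = n
    return PairwiseVariationResult(v_list, threshold, recommended)
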