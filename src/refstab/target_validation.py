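"""Target-gene normalization under alternative reference schemes.

To check that a recommended reference set actually matters, a target gene
with a known expression pattern is normalized seven ways — by the single
most stable reference, the top two, the top three, the single least stable,
the two least stable, the three least stable, and all candidates — and group
differences (e.g. across tissues) are assessed with one-way ANOVA plus a
compact letter display from pairwise Welch tests with Holm correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import gmean
from statsmodels.stats.multitest import multipletests

from .cq_data import CqDataset, DataError
from .genorm import relative_quantities
from .reffinder import ComprehensiveRanking

__all__ = [
    "NormalizationScheme",
    "SCHEME_NAMES",
    "build_schemes",
    "normalization_factor",
    "RelativeExpressionResult",
    "relative_expression",
    "scheme_panel",
]

SCHEME_NAMES = ("top1", "top2", "top3", "worst1", "worst2", "worst3", "all")


@dataclass(frozen=True)
class NormalizationScheme:
    """A named reference-gene set drawn from one comprehensive ranking."""

    name: str
    refs: tuple[str, ...]


def build_schemes(ranking: ComprehensiveRanking) -> list[NormalizationScheme]:
    """The seven standard schemes from a comprehensive ranking (best first)."""
    ordered = ranking.ordered_genes()
    if len(ordered) < 3:
        raise DataError("scheme construction needs at least 3 ranked candidates")
    return [
        NormalizationScheme("top1", tuple(ordered[:1])),
        NormalizationScheme("top2", tuple(ordered[:2])),
        NormalizationScheme("top3", tuple(ordered[:3])),
        NormalizationScheme("worst1", tuple(ordered[-1:])),
        NormalizationScheme("worst2", tuple(ordered[-2:])),
        NormalizationScheme("worst3", tuple(ordered[-3:])),
        NormalizationScheme("all", tuple(ordered)),
    ]


def normalization_factor(
    d: CqDataset,
    refs: Sequence[str],
    eff: Mapping[str, float] | float | None = None,
) -> pd.Series:
    """Per-sample normalization factor: geometric mean of the references'
    relative quantities (duplicated references are collapsed first)."""
    refs = list(dict.fromkeys(refs))
    if not refs:
        raise DataError("empty reference list")
    missing = [g for g in refs if g not in d.genes]
    if missing:
        raise DataError(f"reference gene(s) not in dataset: {missing}")
    qm = relative_quantities(d, eff)
    sub = qm.subset(refs)
    return pd.Series(gmean(sub.q, axis=0), index=sub.samples, name="nf")


@dataclass
class RelativeExpressionResult:
    """Normalized target expression with per-group statistics.

    ``expression`` is scaled so the maximum group mean equals 1 (levels read
    as fractions of the peak group).  ``group_stats`` has one row per group
    with mean, standard error over biological replicates, replicate count and
    the compact-letter-display letter; groups sharing no letter differ at the
    chosen alpha.
    """

    scheme: str
    refs: tuple[str, ...]
    expression: pd.Series
    groups: pd.Series
    group_stats: pd.DataFrame
    anova_f: float
    anova_p: float


def _compact_letters(
    names: Sequence[str], different: Mapping[tuple[str, str], bool]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``different[(a, b)]`` is True when groups a and b are significantly
    different; such groups must share no letter, while non-different groups
    share at least one.
    """
    columns: list[set[str]] = [set(names)]
    for (a, b), diff in different.items():
        if not diff:
            continue
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend(({g for g in col if g != b}, {g for g in col if g != a}))
        # absorb duplicated/contained columns
        columns = [
            c
            for i, c in enumerate(columns)
            if c and not any(c < o or (c == o and i > j) for j, o in enumerate(columns))
        ]
    columns.sort(key=lambda c: min(names.index(g) for g in c))
    letters = {g: "" for g in names}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in names:
            if g in col:
                letters[g] += letter
    return letters


def relative_expression(
    d: CqDataset,
    target: str,
    refs: Sequence[str],
    eff: Mapping[str, float] | float | None = None,
    group_factor: str = "tissue",
    alpha: float = 0.05,
    scheme_name: str = "custom",
) -> RelativeExpressionResult:
    """Normalize ``target`` by a reference set and test group differences.

    expr(sample) = q_target(sample) / NF(sample), rescaled so the largest
    group mean is 1.  A one-way ANOVA runs across the groups of
    ``group_factor``; letters come from all-pairs Welch t-tests with Holm
    correction at ``alpha``.
    """
    if target in refs:
        raise DataError("target cannot normalize itself")
    if target not in d.genes:
        raise DataError(f"target gene {target!r} not in dataset")
    qm = relative_quantities(d, eff)
    q_target = pd.Series(
        qm.subset([target]).q[0], index=qm.samples, name=target
    )
    nf = normalization_factor(d, refs, eff)
    expr = (q_target / nf).rename("expression")
    groups = d.groups(group_factor).loc[expr.index]
    group_means = expr.groupby(groups).mean()
    expr = expr / group_means.max()

    by_group = {g: expr[groups == g].to_numpy() for g in pd.unique(groups)}
    names = list(by_group)
    arrays = list(by_group.values())
    if len(names) < 2:
        raise DataError("group comparison needs at least 2 groups")
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    means = np.array([a.mean() for a in arrays])
    if ss_within == 0 and np.allclose(means, means[0]):
        f_stat, p_val = 0.0, 1.0  # fully constant expression
    else:
        f_stat, p_val = stats.f_oneway(*arrays)

    pairs = list(combinations(names, 2))
    raw_p = []
    for a, b in pairs:
        if by_group[a].std() == 0 and by_group[b].std() == 0:
            raw_p.append(0.0 if by_group[a].mean() != by_group[b].mean() else 1.0)
        else:
            raw_p.append(
                float(stats.ttest_ind(by_group[a], by_group[b], equal_var=False).pvalue)
            )
    if pairs:
        reject = multipletests(raw_p, alpha=alpha, method="holm")[0]
    else:
        reject = []
    different = {pair: bool(rej) for pair, rej in zip(pairs, reject)}
    letters = _compact_letters(names, different)

    stats_rows = []
    for g in names:
        vals = by_group[g]
        se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        stats_rows.append((g, vals.size, float(vals.mean()), float(se), letters[g]))
    group_stats = pd.DataFrame(
        stats_rows, columns=["group", "n", "mean", "se", "letter"]
    ).set_index("group")
    return RelativeExpressionResult(
        scheme=scheme_name,
        refs=tuple(refs),
        expression=expr,
        groups=groups,
        group_stats=group_stats,
        anova_f=float(f_stat),
        anova_p=float(p_val),
    )


def scheme_panel(
    d: CqDataset,
    target: str,
    ranking: ComprehensiveRanking,
    eff: Mapping[str, float] | float | None = None,
    group_factor: str = "tissue",
    alpha: float = 0.05,
) -> dict[str, RelativeExpressionResult]:
    """Run :func:`relative_expression` for each of the seven schemes."""
    if target in ranking.genes:
        raise DataError("target gene must not be part of the candidate ranking")
    results = {}
    for scheme in build_schemes(ranking):
        results[scheme.name] = relative_expression(
            d,
            target,
            scheme.refs,
            eff=eff,
            group_factor=group_factor,
            alpha=alpha,
            scheme_name=scheme.name,
        )
    return results
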