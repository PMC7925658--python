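"""NormFinder: model-based stability (SV values), ungrouped and grouped.

NormFinder models the log2 relative expression of gene i in sample j as a
gene effect plus a sample effect plus gene-specific noise.  The stability
value of a gene is driven by its own noise variance, estimated after removing
gene and sample means; because the subtracted sample mean leaks a little of
every gene's noise into every residual, a small-panel bias correction is
applied before taking the square root.  The grouped variant additionally
estimates a systematic gene × group effect (e.g. a gene drifting in one
tissue), shrinks it toward zero in proportion to its sampling noise, and
reports SV as the average absolute shrunken group bias plus its posterior
uncertainty — so a gene is penalised both for noisiness and for consistent
group-dependent expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cq_data import CqDataset, DataError
from .genorm import _efficiency_vector

__all__ = ["NormfinderResult", "normfinder_stability"]


@dataclass
class NormfinderResult:
    """Per-gene stability values (lower = more stable).

    ``group_table`` (grouped mode only) reports, per gene × group, the
    within-group variance estimate, the raw intergroup deviation and its
    shrunken counterpart.
    """

    sv: pd.Series
    mode: str  # "grouped" | "ungrouped"
    group_by: str | None = None
    group_table: pd.DataFrame | None = None
    gamma2: float | None = None  # intergroup variance component (grouped)
    #: unclamped per-gene variance estimate (ungrouped mode); the bias
    #: correction is exactly unbiased only before clamping at zero
    sigma2_raw: pd.Series | None = None


def _sigma2_hat(x: np.ndarray, clamp: bool = True) -> np.ndarray:
    """Bias-corrected per-gene noise variance from a k × n log2 expression block.

    Residuals are double-centered (gene and sample means removed); with
    v_i = sum_j r_ij^2 / (n-1), the correction
    sigma2_i = max((k/(k-2)) (v_i - v_bar/(k-1)), 0) removes the leakage of
    the other genes' noise through the per-sample means (E[v_i] =
    sigma2_i (1-2/k) + mean(sigma2)/k holds exactly, so the estimator is
    unbiased before clamping).
    """
    k, n = x.shape
    if k < 3:
        raise DataError("NormFinder bias correction needs at least 3 genes")
    if n < 2:
        raise DataError("NormFinder needs at least 2 samples")
    r = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
    v = (r**2).sum(axis=1) / (n - 1)
    raw = (k / (k - 2)) * (v - v.mean() / (k - 1))
    return np.clip(raw, 0.0, None) if clamp else raw


def normfinder_stability(
    d: CqDataset,
    group_by: str | None = None,
    eff: Mapping[str, float] | float | None = None,
) -> NormfinderResult:
    """NormFinder stability values for a collapsed, complete dataset.

    ``group_by`` selects the design factor defining sample groups
    (``"tissue"``, ``"stage"`` or ``"tissue:stage"``); with ``None`` the
    ungrouped estimator is used and SV is simply the bias-corrected noise SD.
    The working scale is x(i, j) = log2(E_i) · (mean_j Cq(i, ·) − Cq(i, j)),
    i.e. centered log2 relative expression (with E = 2 this is centered
    negative Cq).
    """
    wide = d.to_wide()
    genes = list(wide.index)
    if len(genes) < 3:
        raise DataError("NormFinder needs at least 3 genes")
    e = _efficiency_vector(genes, eff)
    cq = wide.to_numpy(float)
    x = np.log2(e)[:, None] * (cq.mean(axis=1, keepdims=True) - cq)

    if group_by is None:
        raw = _sigma2_hat(x, clamp=False)
        sv = np.sqrt(np.clip(raw, 0.0, None))
        return NormfinderResult(
            pd.Series(sv, index=genes, name="sv"),
            mode="ungrouped",
            sigma2_raw=pd.Series(raw, index=genes, name="sigma2_raw"),
        )

    labels = d.groups(group_by).loc[list(wide.columns)]
    group_names = list(pd.unique(labels))
    if len(group_names) < 2:
        raise DataError("grouped NormFinder needs at least 2 groups")
    cols = {g: np.flatnonzero((labels == g).to_numpy()) for g in group_names}
    for g, idx in cols.items():
        if idx.size < 2:
            raise DataError(f"group {g!r} has fewer than 2 samples")

    k = len(genes)
    G = len(group_names)
    sigma2 = np.column_stack([_sigma2_hat(x[:, cols[g]]) for g in group_names])
    n_g = np.array([cols[g].size for g in group_names], float)
    means = np.column_stack([x[:, cols[g]].mean(axis=1) for g in group_names])
    dev = (
        means
        - means.mean(axis=1, keepdims=True)
        - means.mean(axis=0, keepdims=True)
        + means.mean()
    )
    noise = sigma2 / n_g[None, :]
    gamma2 = max(float((dev**2).sum() / ((k - 1) * (G - 1)) - noise.mean()), 0.0)
    denom = gamma2 + noise
    with np.errstate(invalid="ignore", divide="ignore"):
        shrunk = np.where(denom > 0, dev * gamma2 / denom, 0.0)
        posterior_sd = np.sqrt(np.where(denom > 0, gamma2 * noise / denom, 0.0))
    sv = (np.abs(shrunk) + posterior_sd).mean(axis=1)

    group_table = pd.DataFrame(
        {
            "gene": np.repeat(genes, G),
            "group": group_names * k,
            "intragroup_var": sigma2.ravel(),
            "intergroup_dev": dev.ravel(),
            "shrunken_dev": shrunk.ravel(),
        }
    )
    return NormfinderResult(
        pd.Series(sv, index=genes, name="sv"),
        mode="grouped",
        group_by=group_by,
        group_table=group_table,
        gamma2=gamma2,
    )
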