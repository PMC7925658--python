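"""Data model, I/O and descriptive statistics for RT-qPCR Cq measurements.

The quantification cycle (Cq) is the PCR cycle at which a reaction's
fluorescence crosses the detection threshold; it is a log2-scale proxy for
template abundance (lower Cq = more template).  This module holds the single
input object the whole stability pipeline consumes (:class:`CqDataset`),
long-format TSV/CSV readers and writers, technical-replicate collapsing,
per-gene summary statistics, and amplification-efficiency estimation from
standard-curve dilution series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DataError",
    "SchemaError",
    "CqValueError",
    "DesignError",
    "CqDataset",
    "DilutionSeries",
    "GeneEfficiency",
    "read_cq_long",
    "write_cq_long",
    "read_design",
    "read_dilution_series",
    "collapse_technical_replicates",
    "cq_summary",
    "amplification_efficiency",
    "check_efficiency_range",
]

#: Valid Cq window in cycles.  Values above 45 are treated as non-detects
#: (beyond common cycler limits) and rejected at read time.
CQ_MIN, CQ_MAX = 0.0, 45.0

RECORD_COLUMNS = ("sample", "gene", "bio_rep", "tech_rep", "cq")
DESIGN_COLUMNS = ("sample", "tissue", "stage")


class DataError(ValueError):
    """Base class for input-validation failures."""


class SchemaError(DataError):
    """A required column is missing from an input table."""


class CqValueError(DataError):
    """A Cq value is non-numeric, non-finite or outside (0, 45]."""


class DesignError(DataError):
    """A sample has no design entry, or the design table is malformed."""


@dataclass
class CqDataset:
    """Long-format Cq measurements plus per-sample design factors.

    Parameters
    ----------
    data
        DataFrame with columns ``sample, gene, bio_rep, tech_rep, cq``;
        one row per technical measurement (or per biological sample once
        technical replicates have been collapsed).
    design
        DataFrame indexed by sample id with columns ``tissue`` and
        ``stage``.
    species_label
        Optional free-text label carried through to reports.
    """

    data: pd.DataFrame
    design: pd.DataFrame
    species_label: str | None = None

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        missing = [c for c in RECORD_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing column(s) in Cq table: {', '.join(missing)}")
        if "sample" in self.design.columns:
            self.design = self.design.set_index("sample")
        for col in ("tissue", "stage"):
            if col not in self.design.columns:
                raise SchemaError(f"missing column in design table: {col}")
        if self.design.index.has_duplicates:
            dups = self.design.index[self.design.index.duplicated()].unique().tolist()
            raise DesignError(f"duplicate design entries for sample(s): {dups}")
        cq = pd.to_numeric(self.data["cq"], errors="coerce").to_numpy(float)
        bad = ~np.isfinite(cq) | (cq <= CQ_MIN) | (cq > CQ_MAX)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1  # 1-based data row
            raise CqValueError(
                f"invalid cq value {self.data['cq'].iloc[row - 1]!r} on data row {row}: "
                f"cq must be a finite number in ({CQ_MIN:g}, {CQ_MAX:g}]"
            )
        self.data["cq"] = cq
        for col in ("bio_rep", "tech_rep"):
            reps = pd.to_numeric(self.data[col], errors="coerce")
            if reps.isna().any() or (reps < 1).any() or (reps % 1 != 0).any():
                raise CqValueError(f"column {col} must contain positive integers")
            self.data[col] = reps.astype(int)
        undesigned = set(self.data["sample"]) - set(self.design.index)
        if undesigned:
            raise DesignError(f"sample(s) without design entry: {sorted(undesigned)}")

    # -- basic introspection -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.data["gene"]))

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data["sample"]))

    @property
    def is_collapsed(self) -> bool:
        return not self.data.duplicated(subset=["sample", "gene"]).any()

    def groups(self, factor: str) -> pd.Series:
        """Per-sample group labels for ``tissue``, ``stage`` or their cross.

        ``tissue:stage`` (also accepted as ``tissue x stage``) returns the
        interaction labels ``<tissue>:<stage>``.
        """
        key = factor.replace("×", ":").replace(" x ", ":").strip()
        design = self.design.loc[self.samples]
        if key in ("tissue", "stage"):
            return design[key].astype(str)
        if key in ("tissue:stage", "stage:tissue"):
            return design["tissue"].astype(str) + ":" + design["stage"].astype(str)
        raise ValueError(f"unknown design factor {factor!r}")

    def to_wide(self, drop_incomplete: bool = False) -> pd.DataFrame:
        """Gene × sample Cq matrix for a collapsed dataset.

        Missing (gene, sample) cells are a hard error by default so that all
        pairwise statistics stay balanced; ``drop_incomplete=True`` instead
        drops every sample with any missing gene.
        """
        if not self.is_collapsed:
            raise DataError(
                "dataset has uncollapsed technical replicates; "
                "call collapse_technical_replicates first"
            )
        wide = self.data.pivot(index="gene", columns="sample", values="cq")
        wide = wide.loc[self.genes, self.samples]
        if wide.isna().any().any():
            if drop_incomplete:
                wide = wide.dropna(axis=1)
                if wide.shape[1] < 2:
                    raise DataError("fewer than 2 complete samples remain")
            else:
                cells = [
                    (g, s)
                    for g, row in wide.iterrows()
                    for s in wide.columns[row.isna()]
                ]
                raise DataError(f"missing (gene, sample) cells: {cells[:10]}")
        return wide

    def subset_genes(self, genes: Sequence[str]) -> "CqDataset":
        keep = self.data[self.data["gene"].isin(set(genes))]
        return replace(self, data=keep.reset_index(drop=True))


@dataclass(frozen=True)
class DilutionSeries:
    """Standard-curve points for one gene: (log10 relative concentration, Cq)."""

    gene_id: str
    points: tuple[tuple[float, float], ...]

    def __init__(self, gene_id: str, points: Iterable[tuple[float, float]]):
        object.__setattr__(self, "gene_id", gene_id)
        object.__setattr__(
            self, "points", tuple((float(x), float(y)) for x, y in points)
        )


@dataclass(frozen=True)
class GeneEfficiency:
    """Fitted amplification efficiency of one primer pair.

    ``slope`` is the standard-curve slope in cycles per log10 dilution unit;
    ``e_percent`` is the per-cycle amplification efficiency
    (10^(−1/slope) − 1) × 100, so a perfect doubling gives 100%.
    """

    gene_id: str
    slope: float
    e_percent: float
    r_squared: float


# ---------------------------------------------------------------------------
# I/O


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV with case-insensitive headers (delimiter sniffed)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) in design table: {', '.join(missing)}")
    return df[list(DESIGN_COLUMNS)].set_index("sample")


def read_cq_long(
    path: str | Path, design_path: str | Path, species_label: str | None = None
) -> CqDataset:
    """Read a long-format Cq table plus its sample design table.

    The Cq table needs columns ``sample, gene, bio_rep, tech_rep, cq``
    (case-insensitive), the design table ``sample, tissue, stage``.  Row
    order is preserved.  Malformed Cq values raise :class:`CqValueError`
    naming the offending 1-based data row.
    """
    df = _read_table(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) in Cq table: {', '.join(missing)}")
    return CqDataset(df[list(RECORD_COLUMNS)], read_design(design_path), species_label)


def write_cq_long(
    d: CqDataset, path: str | Path, design_path: str | Path | None = None
) -> None:
    """Write the canonical tab-separated long format (and optionally the design)."""
    d.data[list(RECORD_COLUMNS)].to_csv(path, sep="\t", index=False)
    if design_path is not None:
        d.design.reset_index().rename(columns={"index": "sample"}).to_csv(
            design_path, sep="\t", index=False
        )


def read_dilution_series(path: str | Path) -> dict[str, DilutionSeries]:
    """Read a dilution-series table (``gene, log10_dilution, cq``) into one
    :class:`DilutionSeries` per gene, in file order."""
    df = _read_table(path)
    missing = [c for c in ("gene", "log10_dilution", "cq") if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing column(s) in dilution table: {', '.join(missing)}"
        )
    out: dict[str, DilutionSeries] = {}
    for gene, sub in df.groupby("gene", sort=False):
        pts = list(
            zip(sub["log10_dilution"].astype(float), sub["cq"].astype(float))
        )
        out[str(gene)] = DilutionSeries(str(gene), pts)
    return out


# ---------------------------------------------------------------------------
# Operations


def collapse_technical_replicates(d: CqDataset, policy: str = "mean") -> CqDataset:
    """Collapse technical repeats to one record per (gene, biological sample).

    Cq is already on a log scale, so the arithmetic mean of Cq (the community
    convention) is the default; ``policy="median"`` is available for outlier
    robustness.  Singleton groups pass through unchanged.
    """
    if policy not in ("mean", "median"):
        raise ValueError(f"unknown collapsing policy {policy!r}")
    agg = (
        d.data.groupby(["sample", "gene"], sort=False)
        .agg(bio_rep=("bio_rep", "first"), cq=("cq", policy))
        .reset_index()
    )
    agg["tech_rep"] = 1
    return replace(d, data=agg[list(RECORD_COLUMNS)])


def cq_summary(d: CqDataset) -> pd.DataFrame:
    """Per-gene descriptive statistics of Cq.

    Returns a DataFrame indexed by gene with ``n, mean_cq, sd_cq, cv_percent,
    min_cq, max_cq, sd_defined``.  SD uses the n−1 denominator; CV% is
    100·sd/mean.  Genes observed fewer than twice are reported with
    ``sd_defined=False`` and NaN dispersion.
    """
    rows = []
    for gene, sub in d.data.groupby("gene", sort=False):
        cq = sub["cq"].to_numpy(float)
        n = cq.size
        mean = float(cq.mean())
        if n >= 2:
            sd = float(cq.std(ddof=1))
            rows.append((gene, n, mean, sd, 100.0 * sd / mean, cq.min(), cq.max(), True))
        else:
            rows.append((gene, n, mean, np.nan, np.nan, cq.min(), cq.max(), False))
    return pd.DataFrame(
        rows,
        columns=["gene", "n", "mean_cq", "sd_cq", "cv_percent", "min_cq", "max_cq", "sd_defined"],
    ).set_index("gene")


def amplification_efficiency(s: DilutionSeries) -> GeneEfficiency:
    """Estimate amplification efficiency from a dilution standard curve.

    An ordinary least-squares fit of Cq on log10 relative concentration gives
    the slope; efficiency is E% = (10^(−1/slope) − 1) × 100.  A tenfold
    dilution series with perfect doubling has slope −1/log10(2) ≈ −3.32 and
    E = 100%.
    """
    x = np.array([p[0] for p in s.points], float)
    y = np.array([p[1] for p in s.points], float)
    if np.unique(x).size < 3:
        raise DataError(
            f"dilution series for {s.gene_id} needs >= 3 distinct dilution levels"
        )
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise DataError(
            f"standard curve has non-negative slope for {s.gene_id}"
        )
    e_percent = (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0
    return GeneEfficiency(
        gene_id=s.gene_id,
        slope=float(fit.slope),
        e_percent=float(e_percent),
        r_squared=float(fit.rvalue**2),
    )


def check_efficiency_range(
    e: GeneEfficiency, low: float = 90.0, high: float = 110.0
) -> bool:
    """Gate a fitted efficiency against the conventional window (boundaries pass)."""
    return low <= e.e_percent <= high
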