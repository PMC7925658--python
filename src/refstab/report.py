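"""End-to-end stability analysis and table-style report assembly.

Runs all four stability methods on one dataset, aggregates them into the
comprehensive ranking, computes the pairwise-variation series, and lays the
results out as a combined per-gene table (method value + rank columns plus
the comprehensive geomean and final rank), mirroring how reference-gene
studies print their results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .bestkeeper_deltact import bestkeeper, deltact_stability
from .cq_data import CqDataset
from .genorm import (
    GenormResult,
    PairwiseVariationResult,
    genorm_rank,
    pairwise_variation,
    relative_quantities,
)
from .normfinder import normfinder_stability
from .reffinder import ComprehensiveRanking, StabilityTable, reffinder_aggregate

__all__ = ["StabilityReport", "run_stability", "combined_table", "provenance"]

METHODS = ("genorm", "normfinder", "bestkeeper", "deltact")


@dataclass
class StabilityReport:
    """All per-method outputs plus the aggregate for one condition."""

    condition: str
    tables: dict[str, StabilityTable]
    ranking: ComprehensiveRanking
    genorm_detail: GenormResult
    pairwise: PairwiseVariationResult
    combined: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "condition": self.condition,
            "genes": self.ranking.genes,
            "methods": {
                name: {
                    g: {"value": float(v), "rank": int(r)}
                    for g, v, r in zip(t.genes, t.values, t.ranks)
                }
                for name, t in self.tables.items()
            },
            "comprehensive": {
                g: {
                    "geomean": float(row["geomean"]),
                    "geomean_2dp": float(row["geomean_2dp"]),
                    "final_rank": int(row["final_rank"]),
                }
                for g, row in self.ranking.table.iterrows()
            },
            "pairwise_variation": {
                "threshold": self.pairwise.threshold,
                "v": [{"n": n, "v_value": v} for n, v in self.pairwise.v],
                "recommended_n": self.pairwise.recommended_n,
            },
            "genorm_initial_m": {
                g: float(v) for g, v in self.genorm_detail.initial_m.items()
            },
        }


def combined_table(
    tables: Mapping[str, StabilityTable], ranking: ComprehensiveRanking
) -> pd.DataFrame:
    """Per-gene wide table: each method's value and rank, then the aggregate."""
    genes = ranking.genes
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for name, t in tables.items():
        frame = t.to_frame().loc[genes]
        out[f"{name}_value"] = frame["value"]
        out[f"{name}_rank"] = frame["rank"]
    out["reffinder_value"] = ranking.table.loc[genes, "geomean_2dp"]
    out["reffinder_rank"] = ranking.table.loc[genes, "final_rank"]
    return out


def run_stability(
    d: CqDataset,
    group_by: str | None = None,
    eff: Mapping[str, float] | float | None = None,
    v_threshold: float = 0.15,
    condition: str | None = None,
) -> StabilityReport:
    """Run geNorm, NormFinder, BestKeeper and ΔCt and aggregate their ranks.

    ``group_by`` is forwarded to NormFinder (``None`` = ungrouped); all
    methods see the same pooled sample set.
    """
    qm = relative_quantities(d, eff)
    gn = genorm_rank(qm)
    nf = normfinder_stability(d, group_by=group_by, eff=eff)
    bk = bestkeeper(d)
    dc = deltact_stability(d)
    tables = {
        "genorm": gn.ranking,
        "normfinder": StabilityTable.from_values("normfinder", nf.sv),
        "bestkeeper": bk.ranking,
        "deltact": dc.ranking,
    }
    ranking = reffinder_aggregate([tables[m] for m in METHODS])
    pv = pairwise_variation(qm, gn.ordered_genes(), threshold=v_threshold)
    return StabilityReport(
        condition=condition or (group_by or "pooled"),
        tables=tables,
        ranking=ranking,
        genorm_detail=gn,
        pairwise=pv,
        combined=combined_table(tables, ranking),
    )


def provenance(config: Mapping, seed: int | None = None) -> dict:
    """Provenance block recorded verbatim in every output."""
    payload = json.dumps(
        {k: config[k] for k in sorted(config)}, sort_keys=True, default=str
    )
    return {
        "tool": "refstab",
        "version": __version__,
        "config": dict(config),
        "config_hash": hashlib.sha1(payload.encode()).hexdigest()[:12],
        "seed": seed,
    }


def write_tsv_with_provenance(
    frame: pd.DataFrame, path: str | Path, prov: Mapping
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# refstab {prov['version']} config={prov['config_hash']} "
            f"seed={prov['seed']}\n"
        )
        frame.to_csv(fh, sep="\t")
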