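"""Synthetic spatio-temporal RT-qPCR Cq data with known ground truth.

The generator emulates a factorial sampling design common in plant
reference-gene studies: a panel of candidate genes measured across tissues
and developmental stages with biological and technical replication.  Each
gene's Cq is a baseline plus fixed tissue, stage and tissue × stage effects
(in cycles), a shared per-sample loading effect, biological noise and
technical noise — Gaussian on the Cq (log2) scale, matching the
multiplicative error model of qPCR.  Because the condition effects are known,
every downstream stability statistic can be checked against designed truth.

The bundled preset mirrors a two-species licorice study design: 14 candidate
genes across root/rhizome/leaf in April, May, July and October with 3
biological × 3 technical replicates, baselines spread over 19–27 cycles,
three designed-stable genes, eight moderate, three designed-unstable, plus a
target gene expressed in roots and rhizomes but ~16-fold lower in leaves
(the expression pattern of a glycyrrhizin-pathway gene such as β-amyrin
synthase).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cq_data import CqDataset, DataError, DilutionSeries

__all__ = [
    "GeneSpec",
    "SyntheticSpec",
    "TruthRecord",
    "generate_cq",
    "paper_like_preset",
    "generate_dilution",
    "TARGET_GENE",
]

#: Gene id of the preset's validation target.
TARGET_GENE = "BAS"

_STRUCTURE_SEED = 20210302  # fixes the preset's effect patterns, not the noise


@dataclass(frozen=True)
class GeneSpec:
    """Generative truth for one gene (all effects in Cq cycles)."""

    gene_id: str
    baseline_cq: float
    tissue_effects: Mapping[str, float] = field(default_factory=dict)
    stage_effects: Mapping[str, float] = field(default_factory=dict)
    interaction_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    residual_sd: float = 0.25
    e_true: float = 2.0
    stability_class: str = "moderate"  # stable | moderate | unstable | target

    def cell_effect(self, tissue: str, stage: str) -> float:
        return (
            self.tissue_effects.get(tissue, 0.0)
            + self.stage_effects.get(stage, 0.0)
            + self.interaction_effects.get((tissue, stage), 0.0)
        )


@dataclass
class SyntheticSpec:
    """Design and noise parameters of one synthetic experiment."""

    genes: list[GeneSpec]
    tissues: list[str]
    stages: list[str]
    n_bio: int = 3
    n_tech: int = 3
    sample_effect_sd: float = 0.5
    tech_sd: float = 0.15
    seed: int = 0
    species_label: str | None = None

    def validate(self) -> None:
        if self.sample_effect_sd < 0 or self.tech_sd < 0:
            raise DataError("noise SDs must be non-negative")
        cells = {(t, s) for t in self.tissues for s in self.stages}
        for g in self.genes:
            if g.residual_sd < 0:
                raise DataError(f"negative residual_sd for {g.gene_id}")
            if not 0 < g.baseline_cq < 45:
                raise DataError(f"baseline Cq out of range for {g.gene_id}")
            unknown = set(g.tissue_effects) - set(self.tissues)
            unknown |= set(g.stage_effects) - set(self.stages)
            unknown |= {
                f"{t}:{s}" for (t, s) in g.interaction_effects if (t, s) not in cells
            }
            if unknown:
                raise DataError(
                    f"effects of {g.gene_id} reference unknown design levels: "
                    f"{sorted(map(str, unknown))}"
                )


@dataclass
class TruthRecord:
    """Designed ground truth written alongside every generated dataset."""

    dispersion: pd.Series  # per gene: SD over design cells of the condition effects
    classes: dict[str, str]
    target_profiles: dict[str, dict[str, float]]  # gene -> tissue -> relative expr

    def to_dict(self) -> dict:
        return {
            "dispersion": {g: float(v) for g, v in self.dispersion.items()},
            "classes": dict(self.classes),
            "target_profiles": {
                g: {t: float(v) for t, v in prof.items()}
                for g, prof in self.target_profiles.items()
            },
        }


def generate_cq(spec: SyntheticSpec) -> tuple[CqDataset, TruthRecord]:
    """Simulate a long-format Cq dataset from a :class:`SyntheticSpec`.

    Cq(gene, sample, tech) = baseline + tissue + stage + interaction
    + sample effect + N(0, residual_sd²) + N(0, tech_sd²); byte-identical
    under a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    samples = [
        (f"{t}_{s}_b{b}", t, s, b)
        for t in spec.tissues
        for s in spec.stages
        for b in range(1, spec.n_bio + 1)
    ]
    sample_effect = {
        sid: rng.normal(0.0, spec.sample_effect_sd) for sid, _, _, _ in samples
    }
    rows = []
    for g in spec.genes:
        for sid, t, s, b in samples:
            mu = g.baseline_cq + g.cell_effect(t, s) + sample_effect[sid]
            mu += rng.normal(0.0, g.residual_sd)
            for tech in range(1, spec.n_tech + 1):
                rows.append(
                    (sid, g.gene_id, b, tech, mu + rng.normal(0.0, spec.tech_sd))
                )
    data = pd.DataFrame(rows, columns=["sample", "gene", "bio_rep", "tech_rep", "cq"])
    data["cq"] = data["cq"].round(4).clip(0.01, 45.0)
    design = pd.DataFrame(
        [(sid, t, s) for sid, t, s, _ in samples],
        columns=["sample", "tissue", "stage"],
    )
    dataset = CqDataset(data, design, species_label=spec.species_label)

    cells = [(t, s) for t in spec.tissues for s in spec.stages]
    dispersion = pd.Series(
        {
            g.gene_id: float(np.std([g.cell_effect(t, s) for t, s in cells]))
            for g in spec.genes
        },
        name="dispersion",
    )
    profiles = {}
    for g in spec.genes:
        if g.stability_class == "target":
            per_tissue = {
                t: float(
                    np.mean(
                        [g.e_true ** (-g.cell_effect(t, s)) for s in spec.stages]
                    )
                )
                for t in spec.tissues
            }
            peak = max(per_tissue.values())
            profiles[g.gene_id] = {t: v / peak for t, v in per_tissue.items()}
    truth = TruthRecord(
        dispersion=dispersion,
        classes={g.gene_id: g.stability_class for g in spec.genes},
        target_profiles=profiles,
    )
    return dataset, truth


def _spread(levels: list[str], amplitude: float, rng: np.random.Generator) -> dict:
    """Centered effects evenly spanning ±amplitude, assigned in random order."""
    if amplitude == 0 or len(levels) < 2:
        return {lv: 0.0 for lv in levels}
    vals = np.linspace(-amplitude, amplitude, len(levels))
    vals -= vals.mean()
    return dict(zip(levels, rng.permutation(vals)))


def paper_like_preset(seed: int = 0) -> SyntheticSpec:
    """The licorice-style factorial preset with designed stability classes.

    14 candidates + 1 target across 3 tissues × 4 stages × 3 biological × 3
    technical replicates.  Condition-effect amplitudes: designed-stable
    ≤ 0.1 cycles, moderate 0.3–0.8, designed-unstable up to 1.5; baselines
    span 19–27 cycles so the per-gene CV of Cq brackets the range reported
    for real licorice panels (stable genes ≲ 3%, unstable ≳ 8%).
    """
    tissues = ["root", "rhizome", "leaf"]
    stages = ["April", "May", "July", "October"]
    cells = [(t, s) for t in tissues for s in stages]
    rng = np.random.default_rng(_STRUCTURE_SEED)

    def make(gene_id, baseline, amplitude, klass, inter_frac=0.5) -> GeneSpec:
        # interaction: spread values double-centered over the tissue x stage
        # grid so they are orthogonal to the main effects (pure interaction)
        raw = _spread([f"{t}:{s}" for t, s in cells], amplitude * inter_frac, rng)
        grid = np.array([[raw[f"{t}:{s}"] for s in stages] for t in tissues])
        grid = (
            grid
            - grid.mean(axis=1, keepdims=True)
            - grid.mean(axis=0, keepdims=True)
            + grid.mean()
        )
        return GeneSpec(
            gene_id=gene_id,
            baseline_cq=baseline,
            tissue_effects=_spread(tissues, amplitude, rng),
            stage_effects=_spread(stages, amplitude, rng),
            interaction_effects={
                (t, s): float(grid[i, j])
                for i, t in enumerate(tissues)
                for j, s in enumerate(stages)
            },
            stability_class=klass,
        )

    genes = [
        make("STB1", 23.5, 0.06, "stable"),
        make("STB2", 24.4, 0.06, "stable"),
        make("STB3", 25.2, 0.06, "stable"),
    ]
    moderate_base = [21.2, 21.9, 22.6, 23.3, 24.1, 24.9, 25.8, 26.6]
    moderate_amp = [0.30, 0.38, 0.45, 0.52, 0.59, 0.66, 0.73, 0.80]
    for i, (b, a) in enumerate(zip(moderate_base, moderate_amp), start=1):
        genes.append(make(f"MID{i}", b, a, "moderate"))
    genes += [
        make("VAR1", 19.4, 1.5, "unstable", inter_frac=1.0),
        make("VAR2", 20.1, 1.5, "unstable", inter_frac=1.0),
        make("VAR3", 20.8, 1.5, "unstable", inter_frac=1.0),
    ]
    # validation target: root ≈ rhizome, leaf 4 cycles higher (~16-fold lower)
    genes.append(
        GeneSpec(
            gene_id=TARGET_GENE,
            baseline_cq=22.5,
            tissue_effects={"root": 0.0, "rhizome": 0.2, "leaf": 4.0},
            stage_effects=_spread(stages, 0.3, rng),
            stability_class="target",
        )
    )
    return SyntheticSpec(
        genes=genes,
        tissues=tissues,
        stages=stages,
        n_bio=3,
        n_tech=3,
        sample_effect_sd=0.5,
        tech_sd=0.15,
        seed=seed,
        species_label="synthetic licorice-like panel",
    )


def generate_dilution(
    gene_id: str,
    e_true: float,
    levels: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
    c0: float = 20.0,
) -> DilutionSeries:
    """Tenfold dilution series with known true efficiency.

    Cq = c0 + slope · log10_dilution with slope = −1/log10(e_true), plus
    N(0, noise_sd²); log10_dilution runs 0, −1, …, −(levels−1).
    """
    if e_true <= 1.0:
        raise DataError("true efficiency must exceed 1 fold per cycle")
    if levels < 3:
        raise DataError("dilution series needs at least 3 levels")
    rng = np.random.default_rng(seed)
    slope = -1.0 / np.log10(e_true)
    points = []
    for lv in range(levels):
        x = -float(lv)
        points.append((x, c0 + slope * x + rng.normal(0.0, noise_sd)))
    return DilutionSeries(gene_id, points)
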