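# Methods

`refstab` implements the standard toolbox for choosing RT-qPCR reference
(housekeeping) genes: four stability algorithms, their rank-based
aggregation, the geNorm criterion for how many references to use,
amplification-efficiency QC, and a target-gene validation step.  This note
records the models, the numerical choices, and what the synthetic benchmark
does and does not demonstrate.

## Data model

The quantification cycle Cq is treated as a log2-scale abundance proxy: one
PCR cycle ≈ one doubling of template, so differences in Cq are log2 fold
changes up to the amplification efficiency.  Input is a long-format table
(sample, gene, biological replicate, technical replicate, Cq) plus a design
table mapping each sample to a tissue and a developmental stage.  Cq must be
finite and in (0, 45]; values beyond 45 cycles are treated as non-detects
and rejected rather than imputed.

Technical replicates are collapsed by the arithmetic mean of Cq (median
available): Cq is already a log quantity, so mean-of-Cq corresponds to a
geometric mean of abundances, the community convention.  After collapsing,
all stability statistics require a *complete* gene × sample matrix; missing
cells are a hard error by default (an opt-in flag drops affected samples)
because every method below compares genes pairwise on the same samples.
Wherever a statistic is called an SD it uses the n−1 denominator, with one
deliberate exception in BestKeeper (below).

## Amplification efficiency

A tenfold dilution standard curve is fit by ordinary least squares of Cq on
log10 relative concentration.  Efficiency is

    E% = (10^(−1/slope) − 1) × 100,

so perfect doubling (slope −1/log10 2 ≈ −3.32) gives 100%.  Curves need at
least three distinct dilution levels and a negative slope.  The conventional
acceptance window 90–110% is applied inclusively at both boundaries; both
bounds are parameters.

## Relative quantities

Stability methods that work on expression rather than Cq use the transform
q(i, j) = E_i^(Cq_min,i − Cq(i, j)), scaling each gene to its most abundant
sample (row maximum 1).  The default efficiency is E = 2 for every gene,
matching the spreadsheet-geNorm convention; per-gene fitted efficiencies can
be supplied instead.  All stability statistics are invariant to this
per-gene rescaling by construction.

## geNorm

For genes j, k the pairwise variation V_jk is the SD over samples of
log2(q_j/q_k); the M value of a gene is the mean of V_jk over all partners.
Ranking proceeds by iterative exclusion: recompute M on the surviving set,
drop the gene with the largest M, repeat until two genes remain.  The final
pair is inseparable (their M values are identical by definition) and both
receive rank 1; the next gene receives rank 3 and so on (competition
ranking).  Ties in the exclusion step remove the gene that appears later in
input order — an arbitrary but deterministic and documented rule.  Both the
first-round M and the exclusion-path M (the value a gene had when removed)
are reported; the combined table shows the exclusion-path values because
only those make the final pair's printed values identical.

The pairwise-variation analysis builds normalization factors NF_n as
geometric means of the top-n genes' quantities and reports
V_n = SD(log2(NF_n/NF_{n+1})) for n = 2 … k−1.  The recommended number of
references is the smallest n with V_n below the threshold (default 0.15, the
conventional cutoff); if no V_n passes, the recommendation is "not reached"
(`None`).

## NormFinder

The working scale is x(i, j) = log2(E_i)(mean_j Cq(i,·) − Cq(i, j)), i.e.
log2 relative expression.  The model is x = gene effect + sample effect +
noise with gene-specific noise variance σ²_i.  After double-centering, the
per-gene residual mean square v_i is a biased mix of all genes' variances,
E[v_i] = σ²_i (1 − 2/k) + mean(σ²)/k; inverting this linear system gives the
estimator σ̂²_i = (k/(k−2))(v_i − v̄/(k−1)), which is exactly unbiased (we
verified the expectation algebraically and by simulation).  Negative
estimates are clamped to zero before SV = σ̂ is reported; the unclamped
estimate is also exposed because the clamp necessarily inflates the mean for
genes whose true variance is near zero.

In grouped mode (groups = tissue, stage, or their interaction) the same
estimator runs within each group; the gene × group mean table is
double-centered to give intergroup deviations d_ig, and the intergroup
variance component γ² is estimated by moment matching with the sampling
noise σ̂²_ig/n_g subtracted and clamped at zero.  Each deviation is shrunk,
d̃ = d·γ²/(γ² + σ̂²/n_g), and

    SV_i = mean_g( |d̃_ig| + sqrt( γ² (σ̂²_ig/n_g) / (γ² + σ̂²_ig/n_g) ) ),

the absolute shrunken group bias plus its posterior SD.  A gene is thus
penalised both for noise and for systematic group-dependent expression.
When groups are exchangeable γ̂² hits its clamp at zero in most replicates
and all SV collapse toward zero — a property, not a bug, checked by
simulation.  Grouped mode requires ≥ 2 groups with ≥ 2 samples each and
≥ 3 genes (the bias correction divides by k − 2).

## BestKeeper and comparative ΔCt

BestKeeper works on raw Cq.  Its "SD [±Cq]" is the mean absolute deviation
about the mean (the definition used by the original spreadsheet tool), and
CV% = 100·MAD/mean.  The BestKeeper index is the per-sample geometric mean
of Cq over all candidates; each gene's Pearson r against the index is
reported (optionally excluding the gene from its own index).  The default
stability ranking is ascending MAD — dispersion values, unlike correlations,
are what published BestKeeper columns actually order — with |r|-descending
available as an alternative basis.  Zero-variance genes have undefined r and
are ranked by dispersion only.

The comparative ΔCt method scores gene i by the mean over partners l of
SD(Cq_i − Cq_l).  With all efficiencies at 2 this is *identical* to
first-round geNorm M (log2 ratios of quantities are Cq differences up to a
constant); the test suite asserts this equality to 1e−10 on random data, and
it serves as a strong cross-implementation check of both engines.

## Comprehensive ranking (RefFinder-style)

Each method contributes competition (min-tie) ranks: tied values share the
smallest applicable rank and the next distinct value's rank is 1 + the
number of strictly better genes.  The comprehensive stability value of a
gene is the geometric mean of its four method ranks, displayed half-up
rounded to 2 decimals; the final ordering uses full precision.  Plain
unweighted ranks reproduce every published comprehensive value we checked to
the printed precision (e.g. ranks (1,1,3,1) → 1.32), which is why no
additional weighting is applied.  Top-k sets keep all genes tied at the k-th
value and flag the tie.

## Target-gene validation

A target gene is normalized as expr = q_target / NF, where NF is the
geometric mean of the chosen references' quantities.  Seven schemes are
built from the comprehensive ranking: top1/top2/top3, worst1/worst2/worst3,
and all candidates.  Expressions are rescaled so the maximum group mean is
1 (levels read as fractions of the peak tissue).  Group differences use
one-way ANOVA; the compact letter display comes from all-pairs Welch t-tests
with Holm correction at α = 0.05 via the insert-and-absorb algorithm.  Welch
+ Holm was chosen because group variances differ strongly under bad
normalization schemes — published studies rarely state their post-hoc
method, so letters (not F values) are the part most likely to differ from
any specific study.  Fully constant expression is reported as F = 0, p = 1.

## Synthetic data generator

Cq(gene, sample, tech) = baseline + tissue effect + stage effect +
interaction + sample loading effect + biological noise + technical noise,
all Gaussian on the Cq scale (multiplicative on abundance).  Interaction
effects are double-centered over the tissue × stage grid so they are
orthogonal to the main effects — each gene's designed condition dispersion
is then a deterministic function of its amplitudes.  Sample loading effects
are shared by all genes and must cancel in every stability statistic; an
end-to-end invariance test asserts this.

The preset emulates a licorice-style design: 14 candidates + 1 target ×
3 tissues (root, rhizome, leaf) × 4 stages (April, May, July, October) ×
3 biological × 3 technical replicates.  Defaults: technical SD 0.15 cycles,
biological residual SD 0.25, sample loading SD 0.5; baselines span
19–27 cycles; condition-effect amplitudes ≤ 0.06 cycles for the three
designed-stable genes, 0.30–0.80 for the eight moderate genes, 1.5 for the
three designed-unstable genes (with full-amplitude interactions).  These
amplitudes were calibrated once so that the per-gene CV of Cq brackets the
extremes reported for real licorice panels — stable genes < 5% (real panels:
≈ 2.9–6.7% for the best gene), unstable > 8% (≈ 10.5% for the worst) — and
were not revisited.  The target gene is expressed equally in root and
rhizome and 4 cycles (≈ 16-fold) lower in leaf, with mild stage effects,
mimicking a root/rhizome-specific biosynthetic gene.  The effect *patterns*
are frozen by an internal structure seed; the user seed controls only the
noise, so datasets are reproducible and the truth record is constant.

What the generator does **not** emulate: non-detects and censoring at high
Cq, inhibitor-driven efficiency shifts between samples, heavy-tailed or
correlated technical error, plate/batch effects, and imbalanced designs.
Passing the recovery tests therefore shows the pipeline is correct and
well-powered under a clean factorial model, not that any particular real
panel will rank identically.

## Problem sizes and determinism

The simulation-based checks use 500 replicates (estimator bias), 200
replicates (grouped detection power), and 20 seeds of the full preset
pipeline — sizes at which the Monte-Carlo error is comfortably below the
asserted margins while the whole suite runs in seconds.  All randomness
flows through `numpy.random.default_rng` seeded explicitly; the
acceptance script derives every stream from its `--seed` argument.

## Known limitations

- Absolute M/SV/MAD/ΔCt values from published studies cannot be reproduced
  without their raw Cq tables; correctness of the engines is instead
  established by closed-form examples, brute-force oracles, the exact
  geNorm/ΔCt identity, and simulation recovery.
- The grouped NormFinder SV follows the variance-decomposition structure
  described above; other implementations differ in small constants (e.g.
  how they pool σ̂² across groups), so grouped SV values are comparable
  within a run, not across tools.
- The compact-letter display is one of several valid letterings when the
  significance relation is non-transitive; only the sharing/separation
  pattern is contractual.
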