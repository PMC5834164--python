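# Methods

This note records the statistical definitions the package implements, the
defaults it ships, and the choices made where the methods literature leaves
room — in enough detail that every number the code produces can be derived
by hand.

## Data model

A qRT-PCR experiment is a table of quantification cycles Cq(g, s) for gene
g and sample s, where each sample carries a condition label and a replicate
index (replicates are treated as independent samples throughout; for the
bundled scenario that is 8 conditions × 3 replicates = 24 samples).  Cq is
a log2-scale quantity: at perfect amplification efficiency (E = 2) a
difference of one cycle is a two-fold difference in template.  Per-gene
efficiencies E ∈ (1, 2] may be supplied; they enter the pairwise kernel as
a rescaling of Cq by log2(E).  All methods default to E = 2, which is also
the assumption under which published Cq-based rankings are computed.

Missing Cq cells are recorded as a mask; each method applies its own
policy: pairwise-complete samples for the ΔCt kernel (geNorm, comparative
ΔCt), listwise-complete samples for BestKeeper and NormFinder (both need a
per-sample quantity defined over all genes).

## Stability statistics

**Pairwise variation kernel.**  For genes j, k:
V_jk = SD over samples of (log2(E_j)·Cq_j − log2(E_k)·Cq_k), with the
sample (n − 1) denominator.  V is symmetric with zero diagonal and is
invariant to any per-sample additive offset — the loading variation that
reference-gene normalization exists to remove.

**geNorm.**  M_j = mean over k ≠ j of V_jk on the current candidate set.
The gene with the highest M is removed (an exact tie removes the
alphabetically last gene — deterministic and documented) and M is
recomputed until two genes remain.  Those two are inseparable by the
method (their M values are identical by construction), so they share rank
1 and the next gene takes rank 3: competition ranking, matching how tied
best pairs are printed in published tables.  The reported value per gene
is its M at the iteration it was excluded; for the final pair it is V_AB.

**Comparative ΔCt.**  The same mean pairwise SD without iteration; exact
ties get fractional (average) ranks.  By construction the first geNorm
pass equals this statistic for every gene (asserted to 1e−9 in the tests).

**BestKeeper.**  Per gene: SD of raw Cq about the arithmetic mean and
CV% = 100·SD/mean.  The BestKeeper index is the per-sample geometric mean
of all candidates' Cq; each gene's Pearson r with the index is reported.
Ranking is by SD ascending, ties broken by higher r, then gene name.  The
sample (n − 1) SD convention is used.  Note two deliberate deviations from
the original BestKeeper software: the original reports mean absolute
deviation rather than SD, and a coefficient-of-correlation significance
test; here the SD/CV/r triple is defined as above because only ranks are
ever consumed downstream.  BestKeeper operates on raw Cq, so it is *not*
invariant to per-sample loading offsets — a known asymmetry of the method
that the tests document rather than hide.

**NormFinder.**  Expression is y = −Cq (log2 scale up to a constant).
Step 1 removes the per-sample effect: u_gs = y_gs − mean over genes of
y_·s.  Step 2, per gene and condition group: intergroup bias d = group
mean of u minus the gene's average of group means (Σ_groups d = 0).
Step 3: intragroup variance s² = sample variance of u within the group.
The stability value is ρ = mean over groups of (|d| + s); lower is more
stable.  This is the simplified bias-plus-variance form; the exact
small-sample shrinkage corrections of the original model-based estimator
are intentionally not reproduced, so ρ's absolute scale is not comparable
across tools — every assertion in this package depends only on ranks or on
planted ground truth.  A single group is allowed (d ≡ 0, with a warning);
groups of fewer than two samples are an error.

**Raw Cq spread.**  Box-plot five-number summaries per gene: quartiles by
linear interpolation, whiskers at the most extreme observation within
1.5·IQR of the quartiles, points beyond listed as outliers, plus the plain
max − min range in cycles.

## Comprehensive ranking

Each method contributes a rank vector (competition ranking "1223" for
exact ties; the geNorm tied pair contributes 1, 1, 3, …).  Per gene the
geometric mean of its ranks is computed as (Π ranks)^(1/M) — product
before root, so exact ties stay exact in floating point — and genes are
sorted ascending.  Exact geometric-mean ties are broken by the arithmetic
mean of ranks, then by gene name, and annotated.  Two comprehensive
rankings over the same genes (e.g. an RNA-Seq based and a qPCR based one)
can be combined by summing their geometric-mean values per gene.

This aggregation, applied to the published per-method rank columns for the
11 *G. rostochiensis* candidates, reproduces both published comprehensive
orders exactly — which is how the tie conventions above were fixed.  For
the 10-gene *G. pallida* table the same aggregation reproduces the top
(AMA-1) and bottom (Act-1) positions but permutes the published middle
order; since no tie convention recovers the printed middle, the package
asserts only the extremes for that dataset and records the discrepancy
here rather than special-casing it.

## RNA-Seq candidate screen

Counts are normalized per sample by a size factor — the library total
(default) or the upper quartile of nonzero counts — scaled by the
geometric mean of all factors so values stay on a count-like scale, then
transformed as log2(x + 1).  The zero-expression filter runs on *raw*
counts: a gene is excluded iff its summed counts within any single
condition are zero (a zero in one replicate alone does not exclude), so
the pseudocount can never mask absence.  Kept genes are scored by the SD
of log2 expression across all samples (replicate-level, not
condition-mean — both are computed, the ranking uses the former), with the
range of per-condition mean log2 expression as tie-breaker, then gene
name; the top k (default 4) are flagged as candidates.

One caveat follows from the pseudocount: rescaling a sample's counts is
removed exactly by total-count normalization up to the global
geometric-mean factor, and that global rescale shifts values through the
log2(x + 1) pseudocount, so ranks and selection are exactly invariant
while absolute scores move by a fraction of a percent.

## Relative quantification (2^−ΔΔCt)

Per sample, the reference index is the arithmetic mean of the reference
genes' Cq — the Cq-scale equivalent of a geometric mean of linear-scale
quantities at E = 2.  ΔCt = Cq_target − index per replicate;
ΔΔCt = ΔCt − mean ΔCt over the calibrator condition's replicates;
per-replicate fold change FC = 2^−ΔΔCt.  The reported per-condition
`fold_change` is the geometric mean of replicate FCs (equivalently
2^−mean ΔΔCt), which makes the calibrator's value exactly 1 by
construction and coincides with the arithmetic mean at zero noise; the
arithmetic mean is reported alongside (`fold_change_amean`), and the SEM
is SD/√n of the replicate FCs, matching how error bars are drawn on
linear-scale charts.  An efficiency-corrected (per-gene-base) ratio is
available as an option and reduces to the classic form at E = 2.

Significance between conditions is assessed per target gene on the
replicate-level ΔCt values — log-scale residuals are closer to
homoscedastic normal than fold changes — with a one-way ANOVA followed by
Tukey's HSD at α = 0.05 on all condition pairs, summarised as a compact
letter display built by the insert-and-absorb algorithm: two conditions
share a letter iff not significantly different.  Letters are assigned
deterministically, 'a' to the condition with the highest mean fold
change.  If the pooled within-group variance is exactly zero, every pair
with unequal means is declared different (all-distinct letters) without
numerical failure.

## Synthetic data

The generator emulates the hatching time-course design: 8 conditions
(dry cyst, hydrated cyst, 1 h/8 h/24 h/48 h/7 d of potato-root-diffusate
exposure, hatched J2 larvae), 3 qPCR replicates and 2 RNA-Seq replicates
per condition.  On the Cq scale,

    Cq(g, s) = μ_g − Δ_g(condition(s)) + L_s + ε,
    L_s ~ N(0, σ_load),  ε ~ N(0, √(σ_tech² + extra_sd_g²)),

with Δ_g the role-defined log2 effect.  Counts are negative binomial with
mean libsize_s · q_g / Σq_g, q_g = mean_expression_g · 2^Δ_g, dispersion
0.05 by default (0 = Poisson), and designated dropout genes forced to
zero counts in their conditions.  Fixed seeds give bit-reproducible
tables.

Default scenario (14 genes): three stable references (aaRS, PMP-3, GR);
six mildly variable candidates with fixed per-condition shifts of
0.3–0.5 log2 units; one drifting unstable gene (Act-1) with a 2.0-cycle
linear trend across the condition order *and* 1.2 cycles of extra
replicate noise; one high-variance gene (EIF-3, 1.5 cycles); and three
pulse targets — NEP-1 (log2 10 at 8 h), cht-2 (log2 6 / log2 7 at
24 h/48 h, with zero RNA-Seq counts in dry cysts), eng (log2 4 at 48 h).
Noise defaults are σ_tech = 0.15 and σ_load = 0.3 cycles — values typical
of replicated SYBR-green assays; the unstable genes' replicate SDs were
chosen so their raw Cq values span several cycles over the 24 samples,
the signature of an unusable reference.  Library sizes are uniform on
0.8–1.2 M reads.

What the generator does *not* emulate: amplification-efficiency
heterogeneity (effects are written directly in cycles), count
distributions of any real library beyond the NB family, correlated
technical noise between genes, and real hatching-gene identities beyond
the qualitative pulse patterns.  Passing the planted-truth tests
therefore shows the pipeline recovers the structure this model encodes —
stable-vs-unstable separation under loading offsets — not that it would
rank any particular real dataset identically.

With these defaults, across 20 seeds the three planted references occupy
the top 4 comprehensive ranks and the drift gene the bottom 2 in 20/20
runs, and the single-unstable-reference failure mode (normalizing the
4-fold pulse target by the drifting gene alone leaves the induced
condition letter-inseparable from the calibrator, while the 3-reference
set separates it cleanly) reproduces in 19–20/20 runs — the acceptance
suite asserts ≥ 18, ≥ 18, ≥ 15 and ≥ 15 of 20 respectively.  "Letter
separation" is measured between the pulse condition and the calibrator,
the scientifically reported contrast; demanding that *no* pair among all
28 be significant is a strictly stronger event that no realistic noise
level makes reliable.

## Numerical conventions and degenerate inputs

- All SDs use the sample (n − 1) denominator unless noted.
- Quartiles: linear interpolation (numpy default).
- Sorting is stable (mergesort) everywhere a tie-break chain ends in gene
  name, so output order is deterministic.
- geNorm needs ≥ 3 genes; the pairwise kernel needs ≥ 3 complete samples
  per gene pair; BestKeeper needs positive Cq (geometric mean) and ≥ 3
  complete samples; NormFinder groups need ≥ 2 samples.
- Result tables are written as TSV with 6-significant-digit floats;
  re-reading reproduces values exactly at that precision.

## Limitations

- NormFinder's exact variance-component estimator (with small-sample
  corrections) is not implemented; rank agreement, not value agreement,
  is the contract.
- The geNorm V(n/n+1) pairwise-variation statistic for choosing *how
  many* references to use is out of scope; the recommended-set size
  defaults to 3 and is configurable.
- No vendor plate-export parsing, no Excel I/O, no primer design or
  fluorescence-curve efficiency estimation; efficiencies are input
  metadata.
- Orthologue searching is not performed; which genes enter the candidate
  set is input metadata.
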