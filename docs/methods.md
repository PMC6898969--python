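# Methods

## Scope and model

`cortexdiff` reimplements the expression-analysis machinery of a five-group
post-mortem cortex microarray design: non-neurological controls (CTRL) and
two groups of secondary progressive MS cases — with (F+) and without (F−)
lymphoid-like meningeal follicles — each case contributing one grey matter
lesion (GML) and one normal-appearing grey matter (NAGM) array. Every
statistical stage consumes a log2 expression matrix (genes × samples) that
is assumed already normalised; probe-level processing, array QC and
normalisation are out of scope, and row identifiers are treated as opaque
(probe- or gene-level).

## Random variance model (RVM)

With only 10 arrays per group, per-gene variance estimates are noisy. The
RVM shares variance information across genes: gene-specific inverse
variances are modelled as Gamma(a, scale b), which implies that the pooled
two-group residual variance satisfies s²·a·b ~ F(d, 2a) with d = nₐ+n_b−2
across genes. The hyperparameters (a, b) are fitted by maximising the
corresponding marginal likelihood with Nelder–Mead on (log a, log b),
started from a = 2 and b = 1/mean(s²). The moderated test replaces s² with
the posterior compromise

    σ̃² = (d·s² + 2a·τ) / (d + 2a),   τ = 1/(a·b),

and refers t = (x̄ₐ − x̄_b)/√(σ̃²(1/nₐ + 1/n_b)) to a t distribution with
d + 2a degrees of freedom. The calibration of that reference distribution —
not a formula citation — is the testable contract: the test suite verifies
that under the generator's global null the rejection rate at α = 0.01 lands
inside the 99% binomial band, and that (a, b) = (3, 1) are recovered from
20 000 simulated variances in each of 20 seeds.

Numerical choices: zero pooled variances are floored at the 1st percentile
of the positive variances before fitting (configurable); an all-equal
variance vector makes the likelihood unbounded in a and raises an error, or
returns a capped a = 10⁶ (with b matching the common variance) when cap
mode is requested — in that limit the moderated statistic equals the pooled
t statistic and its p-value approaches the known-variance normal limit.
Optimiser tolerances (xatol 1e-10, fatol 1e-12) make refits reproducible to
1e-8.

## Differential-expression calls

Fold change is 2^(difference of group means of log2 values), reported
signed (−2^|log2fc| for down-regulation). A gene is significant when its
two-sided p-value is below the p threshold (default 0.01, strict) and its
absolute fold change reaches the FC threshold (default 1.5, inclusive). No
gene-level multiple-testing adjustment is applied; error control is
delegated to the permutation FDR stage. Comparisons are unpaired (each MS
condition vs CTRL); case pairing is carried in the sample sheet but unused
by the tests. Venn-style accounting reports, for every non-empty subset of
comparisons, the count of genes significant in exactly that subset.

## Balanced-permutation FDR and stringency scan

For one comparison at thresholds (p, FC), the samples of both groups are
split into two pseudo-groups containing exactly half of each group's
arrays, so real group differences cancel; the full pipeline (RVM refit
included, by default — a flag freezes the observed fit) is rerun on the
pseudo-labels and significant genes are counted. Ten distinct splits are
drawn by default (rejection on collision), and

    FDR% = 100 · median(null counts) / experimental count,

reported as NA with a warning when the experimental count is zero. The
stringency scan evaluates the default grid {0.05, 0.01} × {1.5, 2.0}
reusing the same splits across grid points, which makes null counts
monotone non-increasing in stringency within each permutation. Odd group
sizes are rejected unless a parity argument assigns the extra sample
(alternating parity across permutations is the caller's contract); the
target design (10+10) never hits this case. A pooled "overall" FDR across
the four comparisons is the ratio of summed medians to summed experimental
counts. Because the moderated test is calibrated, the null count at
p < 0.01 is ≈1% of genes; FDR% therefore approaches 100% on fully-null data
and falls as planted signal increases — the behaviour the acceptance tests
pin down quantitatively.

## Gene-set testing and consensus

Per-gene p-values and moderated t scores come from a single RVM fit on the
true labels. For a set of k resolved members:

- **LS** = mean of −ln p over members; **KS** = maxᵢ (i/k − p₍ᵢ₎) on the
  sorted member p-values. Both are referred to an empirical null of random
  gene sets of size k drawn uniformly from all genes, with the add-one rule
  p = (1 + #{null ≥ observed})/(n_null + 1), so empirical p-values are
  never zero. Natural log in LS is a documented convention (any base is
  monotone-equivalent under a permutation null).
- **maxmean** scores the set by the larger of the mean positive part and
  mean negative part of member t scores; the null permutes sample labels
  uniformly over assignments preserving group sizes, reusing the observed
  variance hyperparameters. With restandardization (default on) the
  positive- and negative-part set means are centred and scaled by the
  genome-wide moments of the corresponding per-gene part scores in the same
  permutation before taking the max, protecting against genome-wide score
  shifts.

A set is a consensus hit when at least 2 of the 3 tests have p < α
(strict; default 0.05). Sets resolving below the minimum size (default 3)
are reported as skipped, never silently dropped. The choice of a random-set
null for LS/KS versus a label-permutation null for maxmean mirrors the
distinct constructions of the two test families; it is a semantic choice,
flagged as such.

## TNF balance index

The pro-death panel (RIPK1, RIPK3, MLKL, RNF11, CYLD, LOX, HSP70, TNFAIP3,
CASP3, CASP7, TNFR1) and pro-survival panel (TNFR2, CASP8, TRADD, FADD,
CFLAR, IKK-B, NFKB, RELA, AKT, XIAP) are stored under their informal
symbols with a user-editable alias map for resolution against platform row
ids. The balance index is the difference of equally weighted panel means of
log2 fold change; verdicts use a dead-band δ (default 0.2 log2 units).
Heatmap row order keeps the panels contiguous (death first), each ordered
by the leaf order of an average-linkage dendrogram on uncentered-Pearson
distance. The index is a deliberately simple formalisation of a
qualitative contrast; it attaches no significance weighting.

## Hierarchical clustering

Distance is 1 − r_u with r_u the uncentered correlation (cosine
similarity); all-zero rows are rejected by name. Agglomeration is
unweighted average linkage via Lance–Williams updates with a deterministic
tie-break (lowest-index cluster pair first); distances within 1e-12 of zero
are snapped to zero so proportional rows tie exactly. The implementation is
validated against both a pure-Python O(n³) re-computation and scipy's
cosine/average linkage on tie-free data, and is practical up to a few
thousand rows.

## qPCR quantification

ΔCt = Ct_target − Ct_reference with relative expression 2^−ΔCt (PCR
efficiency fixed at 2). Group fold change defaults to the ΔΔCt-of-means
convention 2^−(ΔCt̄ₐ − ΔCt̄_b) — the ratio of geometric means — with the
ratio-of-arithmetic-means convention behind a flag. Group comparisons use
the two-sided Mann-Whitney U test: exact null for combined n ≤ 20 without
ties, normal approximation with tie correction otherwise; all-identical
input returns p = 1 with a warning.

## Synthetic-data generator

The generator emulates the target design's statistical structure, not its
biology: x_gs = μ_g + effect(g, group(s)) + case(g, case(s)) + ε_gs with
μ_g ~ N(8, 1) on the log2 scale (typical microarray range), ε_gs ~
N(0, σ_g²) and 1/σ_g² ~ Gamma(a_true = 3, scale b_true = 1). The per-(gene,
case) random effect correlating a donor's GML and NAGM arrays has SD 0.2 ×
the gene's noise SD; making it proportional (rather than additive-constant)
keeps the marginal per-gene variance inverse-gamma, so the variance model
the moderated test assumes holds exactly on generator output. Default
planted effects are the two TNF panels at the percentage changes the
verification experiments report (e.g. RIPK1 +88%, RIPK3 +160%, MLKL +135%
in the F+ lesion condition; TRADD +173%, NFKB +250% in F−), with CASP8
halved in F+ and raised +60% in F− (unquantified in the source; a generator
default), NAGM effects attenuated ×0.5, plus optionally n random effects
per condition with |log2FC| uniform on [0.58, 2]. Gene sets comprise the
two TNF panels and decoy sets drawn uniformly from non-planted genes.
The qPCR simulator plants per-group expression ratios (defaults: the
reported TNFR1/TNFR2 fold changes) as Ct_target = baseline − log2(ratio) +
N(0, 0.3²) against a near-constant reference (SD 0.05); the noise SD is
interpreted as target-Ct noise.

What the generator does **not** emulate: probe-level intensity structure,
batch/chip spatial artefacts, correlated gene modules beyond the planted
sets, heavy-tailed or outlying arrays, and annotation ambiguity. Passing
tests therefore demonstrate correctness of the statistical machinery under
its own model assumptions, not robustness to real-data pathologies.

## Problem sizes and determinism

Test and acceptance runs use deliberately scaled problems: 8000 genes for
calibration, 2000 for the FDR regimes (20 seeds × 10 permutations), 800
genes / 300 permutations × 50 seeds for gene-set power, 500 replicates at
n_null = 1000 for gene-set calibration, ≤8-row fixtures for brute-force
oracle equality. All randomness flows through numpy Generators seeded from
explicit integers; identical config + seed reproduce outputs byte-for-byte.

## Known limitations

- The LS/KS null samples random gene sets; tools in this family sometimes
  permute sample labels instead, and the two nulls answer subtly different
  questions (self-contained vs competitive).
- The pooled "overall" FDR definition (ratio of sums) is one of several
  defensible poolings.
- Fold changes are differences of group means of log2 values; median-based
  or per-sample-ratio conventions would differ on skewed data.
- The balance index treats panels as unstructured gene lists; no pathway
  topology, no cell-type deconvolution.
- Dendrograms above a few thousand rows become slow (O(n³) worst case).
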