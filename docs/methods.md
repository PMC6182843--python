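# Methods

## Data model

Cq values live in a genes × samples matrix paired with per-sample
metadata (assay, accession, control/treated group, time in minutes,
biological and technical replicate). The canonical on-disk form is a
long CSV with one row per well; a matrix is valid when gene and sample
ids are unique, the replicate key (accession, group, time, bio, tech)
is unique within an assay, every retained sample has at least one
observed Cq, and all present values are finite. Technical replicates
are arithmetic means on the Cq scale when collapsed (`tech_rep = 0`
marks collapsed columns); biological replicates are never averaged,
because every stability statistic needs biological variation to
measure. All four stability methods assume a complete matrix, so
samples with any missing gene are dropped (complete-case) with a
logged count before analysis.

## Efficiency calibration

`fit_standard_curve` is ordinary least squares of Cq on log10 relative
concentration. The amplification base is E = 10^(−1/slope) (E = 2 is
perfect per-cycle doubling) and percent efficiency (E − 1)·100. The
acceptance window is the slope interval [−3.58, −3.10], inclusive at
both ends. The window is usually glossed as 90–110 % efficiency, but
the two statements are not identical (−3.58 ⇒ 90.26 %, −3.10 ⇒
110.17 %); the slope window is treated as the operative rule. r² is
reported as the squared Pearson correlation (always ≥ 0) with the
signed correlation kept separately, since some reports print the
correlation with the slope's sign. Degenerate designs (fewer than
three points, or a single concentration) are rejected.

## Stability statistics

All methods consume either raw Cq or relative quantities
Q = E^(minCq − Cq), calibrated so each gene's lowest-Cq sample has
Q = 1. Gene-specific E from calibration is used when available,
otherwise E = 2; both modes are exposed because published panels often
do not state which was used.

**geNorm.** V_jk is the ddof-1 SD over samples of log2(Q_j/Q_k);
M_j is the mean of V_jk over the other remaining candidates. Each
round removes the argmax-M gene (ties broken by input order, with a
warning) until two remain; the survivors are reported as an unordered
pair, because a ratio-based statistic cannot order its last two genes.
V_n/n+1 is the SD over samples of log2(NF_n/NF_{n+1}), where NF_n is
the per-sample geometric mean of the n best genes' quantities taken
along the ranking; the optimal panel size is the smallest n with
V < 0.15 (configurable), flagged when no n qualifies. M is invariant
to per-gene additive Cq shifts by construction.

**NormFinder-style model-based value.** Log2 expression
x = (minCq − Cq)·log2(E) is centered per sample across genes, removing
loading effects exactly. Within each group g of n_g samples the
per-gene mean z̄ and ddof-1 variance s² are formed; because centering
across G genes biases the naive variance, the intragroup variance is
estimated as γ̂² = max(0, (s² − Σs²/(G(G−1)))·G/(G−2)) — the constants
follow from E[s²_i] = σ²_i(1 − 2/G) + Σ_k σ²_k/G². Intergroup deviations
d = z̄_ig − z̄_i· (gene mean weighted by n_g) are shrunk toward zero by
τ̂²/(τ̂² + γ̂²/n_g) with τ̂² the ddof-1 variance of the raw d across
genes in that group. The stability value is
ρ_i = mean_g(|d̃_ig| + sqrt(γ̂²_ig/n_g)); with a single group it
reduces to sqrt(γ̂²). Lower is more stable; ties keep input order and
are flagged. Three genes and two samples per group are the minima (the
bias correction needs G ≥ 3).

**BestKeeper.** Statistics are computed on raw Cq: geometric and
arithmetic means, extremes, a dispersion statistic (ddof-1 SD about
the arithmetic mean by default; the original tool's mean absolute
deviation via `sd_mode="mad"`), CV, and x-fold deviations
E^|Cq − GM| signed negative when the extreme lies below GM
(over-expression). The per-sample index is the geometric mean of all
candidates' Cq; each gene is scored by Pearson correlation with the
index (two-sided t-based p, n − 2 df). Genes with dispersion above one
cycle are flagged inconsistent and, by default, demoted below all
consistent genes in the ranking. Note a small-panel artifact: each
gene contributes 1/G of the index, so a high-variance gene partly
correlates with the index through itself; the consistency flag is what
keeps such genes out of the top ranks.

**ΔCt method.** pair_sd[i,k] is the ddof-1 SD over samples of
Cq_i − Cq_k; a gene's score is its mean over partners, ranked
ascending. Per-sample constants cancel inside the difference and
per-gene constants shift it by a constant, so the statistic is
invariant to both — at equal efficiencies it coincides exactly with
the geNorm pairwise-variation matrix (asserted to 1e−12 in the suite).

**Consensus.** The rank table assigns each method's ranking 1..G, with
the geNorm pair sharing rank 1.5. The aggregate is the geometric mean
of ranks per gene (a RefFinder-style device, not itself a published
statistic of the validation literature, and labelled as such); the
report also keeps each method's raw top-4 list for qualitative
comparison, plus pairwise top-k overlap counts. The selected reference
set is the top 3 by aggregate rank by default — three genes being the
conventional minimum for a normalization factor.

## Relative expression and the randomization test

The expression ratio is R = E_t^ΔCq_t / geomean_r(E_r^ΔCq_r) with
ΔCq = mean(control Cq) − mean(treated Cq) per gene; with equal
efficiencies a per-sample loading constant cancels exactly through the
reference geometric mean. Significance uses a fixed reallocation
randomization test on per-sample normalized log quantities
(log2 q = −Cq_t·log2 E_t + mean_r Cq_r·log2 E_r): samples are
reallocated between groups preserving sizes, the statistic is
|log R|, and p is the fraction of allocations at least as extreme,
observed allocation included (so p > 0 always). All C(n1+n2, n1)
allocations are enumerated when at most 100,000, otherwise a seeded
Monte-Carlo sample of 2,000 reallocations (configurable) is drawn with
an add-one correction. Whole-sample reallocation means a 3v3 design
has a minimum two-sided p of 2/20 = 0.1; the pipeline therefore
randomizes over all replicate wells (9v9 for a 3×3 design), matching
the granularity the original randomization software works at, while
the library accepts any grouping the caller passes. Calls are UR
(R > 1, p < α), DR (R < 1, p < α), else ns, with α = 0.05 by default;
signed fold change is FC = R for R ≥ 1 and −1/R otherwise. Per-time
analyses compare each treated time against the control group at time 0
within an accession. A cross-platform comparison is validated when the
qPCR call at any time point equals the sequencing call; ns counts as a
call. The published call grid bundled in `refstab.datasets` yields
9 validated comparisons of 16 (56 %).

## Tag-count differential expression

For a tag counted x and y in libraries totalling N1 and N2, the
conditional null of y given x is negative binomial with size x + 1 and
success probability N1/(N1 + N2) — algebraically identical to the
conditional Poisson form p(y|x) = (N2/N1)^y (x+y)! / (x! y!
(1+N2/N1)^(x+y+1)), whose normalization over y is verified in the
suite. Tails are evaluated through scipy's regularized
incomplete-beta implementation (log-gamma space), and the two-sided p
doubles the smaller inclusive tail, capped at 1. The exact symmetry of
the test is tail complementarity, P(Y≤y|x; N1,N2) + P(X≤x|y; N2,N1)
= 1; the doubled two-sided p from the two viewpoints can differ by up
to the observed point's mass, which the suite bounds explicitly.
Singlets (total count 1 across the pair; per-library reading via
`singlet_mode`) are excluded, as are sequences that are not 26 bases
anchored on CATG. Fold changes replace zero counts by one, form
tags-per-million frequencies, and report R = g/f with FC = R or −1/R.
No multiple-testing correction is applied by default (matching the
per-tag p < 0.05 convention of the source workflow); Benjamini–
Hochberg adjustment is available with `bh=True`.

## Synthetic data: what it emulates, and what it does not

`simulate_cq` draws Cq = μ_gene + δ(group, time) + s_sample + e_bio +
t_tech, all Gaussian on the cycle scale: s_sample is a loading effect
shared by every gene of one RNA sample (SD 0.4 cycles by default),
e_bio is per-gene biological noise shared by a biological replicate's
technical wells, and t_tech is per-well noise (SD 0.2). The design is
fully crossed (groups × times × 3 biological × 3 technical replicates
by default). The seven-gene preset places baselines at 15.6–21.6
cycles; residual noise is chosen so the six stable genes' realized
marginal dispersions land near the 0.45–0.60-cycle band typical of
well-behaved reference candidates, while `EF1a` carries a 1.5-cycle
treated-group effect plus elevated noise, landing near 1.4 cycles —
the designed unstable role. `simulate_dilution_series` and
`simulate_tags` (Poisson counts at rates per million × library depth)
complete the chain; ground-truth tables label every gene/tag.

The generator captures exactly the error structure the normalization
methods assume: additive Gaussian noise on the log-quantity scale and
a shared loading effect that induces inter-gene correlation. It does
not emulate co-regulated candidate pairs, efficiency heterogeneity
between wells, pipetting outliers, or non-Gaussian heavy tails — so
passing recovery tests show the methods separate a designed unstable
gene under the assumed model, not robustness to those violations.

One empirical finding from the recovery simulations is worth stating:
with realistic, similar dispersions among stable genes, the
model-based (NormFinder-style) ranking *within* the stable set is
dominated by sampling noise of the group-mean deviations — the
lowest-noise gene wins on average (best mean rank across 100 seeds)
but is not reliably in the top 2 of any single run. Rankings of
near-equivalent stable candidates should be read as a set, not an
order; the unstable gene, by contrast, is ranked last by all four
methods in ≥ 95 of 100 seeded runs and never enters the consensus
selection.

## Numerical choices and degenerate inputs

Ties in every ranking are broken deterministically by input gene order
with a warning. Variance estimates use ddof 1 throughout; the
NormFinder variance estimate and shrinkage denominator are floored at
zero. Quantities must be strictly positive before logs; non-positive
Cq is rejected where geometric means are formed. The randomization
test refuses designs with a single sample on both sides; exact
enumeration uses a tolerance of 1e−12 when comparing statistics so
ties count as "at least as extreme". Monte-Carlo p-values use the
(h+1)/(m+1) convention. The BestKeeper index of a single-gene panel
is that gene's Cq (guarded with a warning); panels above ten genes
warn, as the index was designed for small candidate sets. All
randomness flows through numpy Generators seeded from a single
configuration seed (spawned per stage in the pipeline), making every
report byte-reproducible.

## Problem sizes

Default verification runs use the preset's 7 genes × 72 wells
(24 biological samples), 100-seed recovery loops, 1,000-replicate null
calibration for the randomization test (6v6 samples, 924 exact
allocations each), and 10,000 simulated null tags at 100 counts
expected per library; the whole suite completes in well under a
minute of compute on a single core.

## Known limitations

The original NormFinder and BestKeeper tools leave parts of their
arithmetic unpublished (grouping conventions, dispersion statistic);
where the literature leaves latitude the choices above are fixed,
documented, and verified against independently coded oracles rather
than against binary tool output. The geNorm V-rule and the three-gene
selection are conventions, not tests; the consensus aggregate is a
pragmatic device. Tag libraries are compared pairwise as given;
pooling of stress times into bulked libraries happens upstream of this
package and is not modelled.
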