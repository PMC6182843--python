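# refstab

Reference-gene selection and expression analysis for qPCR experiments,
with Poisson tag-count differential expression for sequencing-based
cross-validation.

Relative quantification by qPCR stands or falls with its normalizers: a
reference gene must be uniformly expressed across every condition being
compared, and that has to be demonstrated, not assumed. `refstab`
implements the complete computational chain such a validation study
needs — from raw quantification-cycle (Cq) tables to a statistically
validated reference set and efficiency-corrected expression calls — for
experiments like stress time-courses in plant roots (the bundled
synthetic preset mimics a seven-candidate cowpea panel under root
dehydration and salt stress).

## What it computes

**Efficiency calibration.** From a 5-point, 10-fold dilution series,
ordinary least squares of Cq on log10 concentration gives the slope *s*;
the amplification base is E = 10^(−1/s) and percent efficiency
(E − 1)·100. Slopes in the inclusive window [−3.58, −3.10]
(≈ 90–110 %) are accepted.

**Dispersion screen.** Per-gene Cq standard deviation and CV across an
assay; candidates with SD ≥ 1 cycle are flagged.

**Four stability statistics**, each authored here and checked against
independent brute-force oracles:

* *geNorm*: M_j = mean over partners k of SD(log2 Q_j/Q_k), stepwise
  exclusion of the highest M, and the pairwise variation
  V_n/n+1 = SD(log2 NF_n/NF_{n+1}) between normalization factors, with
  the conventional V < 0.15 rule for the optimal number of references.
* *NormFinder*: a model-based stability value ρ combining bias-corrected
  intragroup variance with shrunk intergroup deviations.
* *BestKeeper*: descriptive Cq statistics, signed x-fold deviations, and
  each gene's Pearson correlation with the per-sample geometric-mean
  index; SD > 1 marks a gene inconsistent.
* *ΔCt method*: a gene's average pairwise SD of per-sample Cq
  differences. At equal efficiencies this equals the geNorm pairwise
  variation matrix exactly.

**Consensus.** Per-method rank table (the geNorm best pair ties at 1.5),
top-k overlaps, geometric-mean aggregate rank, and a selected reference
set (default 3 genes).

**Relative expression.** Efficiency-corrected ratio
R = E_t^ΔCq_t / geomean_r(E_r^ΔCq_r) with ΔCq = mean control − mean
treated, a fixed reallocation randomization test (exact enumeration when
feasible), UR/DR/ns calls at α = 0.05, signed fold change
(FC = R, or −1/R when R < 1), and the cross-platform agreement rule
(validated when any qPCR time point repeats the sequencing call).

**Tag-count differential expression.** For 26-bp CATG-anchored tags
counted x and y in libraries of N1 and N2 total tags, the conditional
Poisson (Audic–Claverie) null p(y|x) ∝ (N2/N1)^y (x+y)! / (x! y!) is
evaluated through stable log-gamma tails; singlets are excluded, zero
counts are replaced by one before forming tags-per-million ratios.

A seeded synthetic-data module generates Cq matrices, dilution series
and tag libraries with known ground truth, so every stage is testable
without any external data.

## Worked example

```python
from refstab import (
    simulate_cq, default_panel, collapse_technical_reps, complete_case,
    cq_dispersion, cq_to_quantity, genorm_rank, normfinder_stability,
    bestkeeper, rank_bestkeeper, delta_ct_method, build_consensus, method_ranks,
)

m, truth = simulate_cq(default_panel(seed=1))      # 7 genes x 72 wells
collapsed, _ = complete_case(collapse_technical_reps(m))
print(cq_dispersion(collapsed).round(2).to_string(index=False))
```

```
           assay  gene  mean_cq   sd  cv_pct  passes_screen
root_dehydration   UNK    19.99 0.44    2.18           True
root_dehydration   TUB    19.72 0.44    2.25           True
root_dehydration  FBOX    21.44 0.42    1.98           True
root_dehydration UE21D    18.32 0.49    2.66           True
root_dehydration UBQ10    15.58 0.37    2.34           True
root_dehydration   ACT    20.22 0.44    2.18           True
root_dehydration  EF1a    16.93 1.15    6.80          False
```

The screen already flags `EF1a`, the gene the generator designed to be
unstable (a 1.5-cycle treatment effect). The four methods agree:

```python
gn = genorm_rank(cq_to_quantity(collapsed))
nf = normfinder_stability(collapsed)
bk = bestkeeper(collapsed)
dc = delta_ct_method(collapsed)
rep = build_consensus(method_ranks(
    genorm=gn, normfinder=nf,
    bestkeeper_order=rank_bestkeeper(bk.stats), delta_ct=dc))
print(gn.final_pair, gn.exclusion_order[0], rep.selected)
```

```
('FBOX', 'UBQ10') EF1a ['UBQ10', 'ACT', 'FBOX']
```

geNorm's unordered most-stable pair is (`FBOX`, `UBQ10`), `EF1a` is
excluded first (M = highest), and the consensus selects a three-gene
reference set that never contains the designed unstable gene. The same
chain is available from the shell:

```sh
refstab pipeline --seed 5 --out out/
```

which writes per-stage CSV/JSON (calibration, screen, four stability
methods, consensus, expression calls, tag differential expression and
the agreement summary) plus a combined `report.json`, byte-identical
for a fixed seed.

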