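# tdgbh — two-dimensional group Benjamini–Hochberg FDR control

Modern omics experiments often produce a **matrix** of p-values rather than a
vector: single-cell studies test every gene in every cell type; microbiome
multi-omics studies test every taxon against every metabolite. Such a matrix
has a *two-way grouping structure* — each p-value belongs simultaneously to a
feature (row) group and an outcome (column) group — and true signals are
usually concentrated in a few rows, a few columns, or both. Classic FDR
procedures either ignore this structure (BH, Storey's q-value) or can exploit
only one direction of it (adaptive group BH, stratified BH/ST), and the
stratified variants can badly inflate the false discovery rate when strata are
many and signals sparse.

`tdgbh` implements the **two-dimensional group Benjamini–Hochberg (2dGBH)
procedure**, which adapts to the signal structure in *both* directions at
once, together with the standard comparators, a two-way signal-enrichment
simulator, and a Monte-Carlo benchmark harness.

## The procedure

Given p-values P_ij (i = 1..n features, j = 1..m outcomes) and a target FDR
level α:

1. Estimate the overall null proportion π̂₀ from all n·m p-values (Storey's
   tail estimator by default; least-slope and two-stage estimators are also
   available).
2. Estimate per-row proportions π̂₀ᵢ₁ (from each row's m p-values) and
   per-column proportions π̂₀ⱼ₂ (from each column's n p-values).
3. Shrink toward the global estimate to tame small-group noise:
   π̃₀ᵢ₁ = (1−S)·π̂₀ᵢ₁ + S·π̂₀ (and likewise for columns), with S = 0.1 by
   default.
4. Combine the two directions per cell through a balance factor
   R = (σ̂₂/m) / (σ̂₁/n + σ̂₂/m), where σ̂₁, σ̂₂ are the standard deviations of
   the shrunken row and column estimates:
   π̂₀ᵢⱼ = (π̃₀ᵢ₁)^(1−R) · (π̃₀ⱼ₂)^R.
   A direction whose group estimates vary more (more informative grouping)
   and whose groups are larger (better estimated) receives more weight; at
   R = 0 or 1 only one direction contributes.
5. Weight the p-values: W_ij = (1−π̂₀ᵢⱼ)/π̂₀ᵢⱼ and
   P_ij^w = P_ij / W_ij · (1−π̂₀^w), with π̂₀^w the mean of the per-cell
   estimates. Cells estimated as pure null (W = 0) can never be rejected.
6. Apply the classic BH step-up to the weighted p-values at level α.

With full shrinkage (S = 1) the procedure reduces exactly to BH at level
α/π̂₀; forcing R to 0 or 1 reduces it to one-way adaptive GBH.

## Worked example

```python
import numpy as np
from tdgbh import SimulationScenario, simulate_dataset, two_d_gbh, bh_adjust, score_run

# 1000 genes x 20 cell types; 5% of cells carry signal z ~ N(2, 1),
# confined to 4 of the 20 cell types
scenario = SimulationScenario(n=1000, m=20, theta=0.05, p_i=1.0, p_j=0.2,
                              mu=2.0, seed=7)
data = simulate_dataset(scenario)

result, surface = two_d_gbh(data.p, alpha=0.05, return_surface=True)
print(f"global pi0 estimate : {surface.pi0_global:.3f}")
print(f"balance factor R    : {surface.R:.3f}")
print(f"rejections (2dGBH)  : {result.n_rejected}")
print(f"rejections (BH)     : {int((bh_adjust(data.p) <= 0.05).sum())}")
m = score_run(result.rejected, data.truth)
print(f"realised FDP        : {m.fdp:.3f}")
print(f"realised TPR        : {m.tpr:.3f}")
```

prints

```
global pi0 estimate : 0.953
balance factor R    : 0.973
rejections (2dGBH)  : 252
rejections (BH)     : 44
realised FDP        : 0.052
realised TPR        : 0.239
```

The balance factor sits near 1 because with only 20 outcomes the column
groups (1000 p-values each) are far better estimated than the row groups (20
p-values each), and the signal really is structured by outcome. 2dGBH finds
252 of the 1000 planted signals' cells versus 44 for plain BH, while the
realised false discovery proportion stays at the 5% target.

## Command line

```bash
# adjust a matrix (rows = features, columns = outcomes, TSV or CSV)
tdgbh adjust --input P.tsv --alpha 0.05 --output adjusted.tsv \
             --long --surface surface.tsv

# comparator methods: bh, st, gbh-o/-g, stratbh-o/-g, stratst-o/-g
tdgbh adjust --input P.tsv --method stratbh-o --output out.tsv

# simulate matrices, or run the full benchmark grid
tdgbh simulate --scenario scenario.yaml --out data/ --runs 100 --seed 42
tdgbh benchmark --grid paper --methods all --runs 100 --seed 42 --out results.tsv
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch with the package's own
simulator: the global-null any-discovery rate of 2dGBH over 1000 replicate
1000×20 matrices; the any-discovery rate of outcome-wise stratified BH over
100 replicate 1000×500 null matrices (which is ~100% — the reason stratified
FDR control is dangerous with many strata); and the mean false discovery
proportion of 2dGBH in the outcome-enriched signal setting over 100 runs.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model details, numerical conventions and known
limitations.
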