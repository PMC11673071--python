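# npvuln

Neuropeptide co-expression scoring and neuronal vulnerability analysis
for brain transcriptomics.

## The problem

Neurons that co-express many neuropeptides (NPs) carry a heavy
secretory and metabolic load, and there is converging evidence that
these high-NP (HNP) neurons — particularly those producing the subset
of NPs disrupted in Alzheimer's disease (ADNPs) — are selectively
depleted in affected brains and in aging. Testing that idea requires a
chain of analyses spanning three data modalities: single-cell RNA-seq
(are high-NP neurons depleted in disease, and what distinguishes them
functionally?), bulk RNA-seq across donor ages (does cumulative ADNP
expression decline with age, region by region?), and atlas cluster
annotations (where in the brain do high-ADNP neuronal populations
physically live?).

`npvuln` packages that chain as a tested Python library for
computational neuroscientists and transcriptomics analysts:

* **Per-cell NP co-expression scoring** — the count of distinct NP
  genes with nonzero expression, `c_i = |{g ∈ NP : x_{gi} > 0}|`, used
  as a proxy for the cell's NP transcript load, with cell QC (200–2500
  expressed genes, <5% mitochondrial reads), CPM normalization, and
  stratification into low (0–1), mid (2–5) and high (6+) groups.
* **Depletion testing** — donor-level stratum proportions compared
  across conditions by a one-tailed Wilcoxon rank-sum test (exact
  enumeration for ≤10 donors per group).
* **Differential expression** — two-sided Wilcoxon rank-sum DGE with
  detection/fold-change pre-filters and Benjamini–Hochberg FDR, plus
  per-gene OLS of expression on the co-expression count ranked by
  slope and R².
* **Gene-set overlap** — the hypergeometric upper tail
  P(X ≥ x) for an overlap of x genes between a k-gene sample and m
  population successes in an (m+n)-gene universe, computed in log
  space.
* **Aging association** — cumulative ADNP expression
  `Σ_g log2(TPM_g + 1)` per sample, conservative exclusion gates
  (metadata completeness, Hardy 3–4, RIN ≤ 6, ages 20–29), and a
  partial Spearman correlation with age adjusting for RIN and Hardy
  score, per brain region.
* **Regional abundance** — classification of atlas neuronal clusters
  as AHNP (≥6 ADNP tags, <3 other NP tags), proportional attribution
  of cluster cells to microdissections, and region ranking.
* **Synthetic cohorts** — seeded generators for all three modalities
  with planted effects and truth records, so every stage is testable
  without downloading the original datasets.

## Worked example

```python
import npvuln as nv

params = nv.SCGeneratorParams(seed=42)          # 16 donors, 9,600 cells
matrix, meta, _ = nv.generate_sc_dataset(params)
profiles = nv.stratify(nv.count_np_coexpression(matrix, params.np_panel))
print(profiles["stratum"].value_counts().to_dict())
corr = nv.np_count_abundance_correlation(profiles)
print(f"rho = {corr.estimate:.4f}")

props = nv.stratum_proportions(profiles, meta)
res = nv.compare_stratum_proportions(props, "CT", "AD", "high", "greater")
print(f"one-tailed p = {res.p_value:.4f}")
```

prints

```
{'low': 6652, 'mid': 2548, 'high': 400}
rho = 0.9899
one-tailed p = 0.0001
```

The rho near 0.99 confirms the co-expression count tracks total NP
transcript abundance (the premise of using the count as a proxy); the
one-tailed p-value shows the planted 50% depletion of high-NP cells in
the affected condition is detected from eight donors per group.

Each capability also has a short narrative script under `examples/`,
and a thin CLI mirrors the library:

```bash
npvuln simulate sc --seed 1 --out syn/
npvuln overlap --sample up.txt --success down.txt --universe all.txt
npvuln run function --config config.json
```

## Layout

```
src/npvuln/        io, profiling, diffexp, overlap, aging, regional,
                   synthetic, pipeline, cli
tests/             unit + property tests and end-to-end acceptance checks
examples/          one narrative script per capability
docs/methods.md    models, parameters, numerical choices, limitations
```
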