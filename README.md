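# tpghallmarks

Statistical characterization of **translocation partner genes (TPGs)** in
hematological cancer.  A reciprocal chromosomal translocation fuses the
promoter-proximal part of a 5' partner gene to the downstream part of a 3'
partner; which genes end up in such fusions, and in which combinations, is
non-random.  This package provides tested, reusable implementations of the
analyses used to characterize that non-randomness, for computational
biologists studying gene fusions:

- **Expression & regulation** — tissue/lineage expression aggregation,
  paired 5'-3' contrasts, promoter Pol2 peak frequency with per-group
  z-normalization, H3K4me3 promoter meta-profiles, 3'-UTR length and
  regulatory-element counts.
- **Fusion domain analysis** — breakpoint-relative retention of InterPro-style
  domains and protein interaction interfaces (a feature is retained only if
  it lies *entirely* on the contributed side of the breakpoint),
  categorization into D/P/H/K/O functional classes, a permutation test for
  domain-category co-occurrence with BH-FDR, partner-type dependence
  (Fisher), EM clustering of 10-bit fusion functional profiles with
  cross-validated model selection, and fusion/interactor network export.
- **Nuclear position** — Hi-C pair-proximity permutation tests under four
  schemes (pair shuffling, one- and two-sided gene replacement), k-means
  central/peripheral compartment partition, locus centrality,
  lineage-specific contact contrasts, chromosome-pair closeness.
- **Replication timing** — LOESS smoothing, per-gene RT, early/late
  enrichment (early = RT > 0.5) with exact binomial p-values.
- **Clinical recurrence** — rare (one report) vs frequent (more than one)
  comparisons of contact, expression and interface counts.
- **Synthetic data** — a first-class generator that emulates every input
  (gene models, domains, translocation tables, expression matrices, peak
  and signal tracks, contact matrices, RT profiles, report counts) with
  known planted effects, so the entire pipeline runs and is verified
  offline.

The central statistic: for translocations with 5' category set S5 and 3'
set S3 (categories D = DNA-binding, P = protein interaction, H = histone
modification, K = kinase, O = other, N = none retained), the co-occurrence
count of cell (c5, c3) is `#{t : c5 in S5(t), c3 in S3(t)}`.  Its null
distribution comes from permuting the 3' sets across translocations;
per cell the test reports fold = observed/mean-permuted, an add-one
two-sided empirical p, and BH q-values at q = 0.10.

## Worked example

```sh
tpg-hallmarks simulate --outdir demo/bundle --seed 4
tpg-hallmarks rt --bundle demo/bundle --outdir demo/out --seed 4
```

prints

```
bundle written to demo/bundle
summary written to demo/out/summary.json
  rt: {'pct_early_tpg': 11.910112359550562, 'pct_early_background': 9.849246231155778,
       'early_enrichment_fold': 1.209240999770695, 'early_enrichment_p': 0.08651138701798963,
       'direction': 'over'}
```

meaning: on this seed's synthetic genome, 11.9% of partner genes fall in
early-replicating regions versus 9.8% of all genes — a 1.21-fold
over-representation whose exact binomial p-value (0.087) does not reach
significance at this sample size.  `demo/out/gene_rt.tsv` holds the
per-gene smoothed RT values and early flags.  The same pattern at the
library level:

```python
from tpghallmarks import SimulationConfig, simulate_bundle
from tpghallmarks.domains import fusion_profiles, cooccurrence_permutation_test

bundle = simulate_bundle(SimulationConfig(seed=1, cooccurrence_folds={"O,K": 3.0}))
by_gene = {}
for a in bundle.annotations:
    by_gene.setdefault(a.gene_id, []).append(a)
cds = {g: m.cds_start_nt for g, m in bundle.catalog.items()}
profiles, _ = fusion_profiles(bundle.translocations, by_gene, cds, bundle.cmap)
res = cooccurrence_permutation_test([p.set5 for p in profiles],
                                    [p.set3 for p in profiles],
                                    n_perm=100_000, seed=1)
print(res.cell("O", "K"))
```

```
EnrichmentResult(observed=40.0, null_mean=13.94097, fold=2.8692408060558194,
                 p_value=1.999980000199998e-05, direction='over',
                 q_value=0.0007199928000719993)
```

— the planted 3-fold (O,K) co-occurrence is recovered (40 observed fusions
against a permuted mean of 13.9, fold 2.87) and flagged well below the
q = 0.10 FDR cutoff.

Other subcommands: `expression`, `domains`, `spatial`, `recurrence`,
`run-all`; all accept `--bundle`, `--outdir`, `--seed` and permutation-count
flags, write per-stage TSV tables plus a machine-readable `summary.json`,
and are byte-reproducible for a fixed seed.

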