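# mirreg

Integrated analysis of a transcription factor's miRNA response program.

When a pluripotency factor such as SOX2 is silenced in stem-like cells, the
response is visible on three layers at once: the miRNAs whose expression
shifts, the genes those miRNAs post-transcriptionally repress, and the
promoters the factor binds directly. `mirreg` turns that joint readout into
a tested, reusable pipeline for systems-biology and stem-cell labs:

1. **Differential-expression filtering** — inclusive thresholds on
   per-cell-line DE tables (miRNA: *p* ≤ 0.05; gene: ≥ 2-fold, *p* ≤ 0.01,
   FDR ≤ 0.05), fold changes accepted as signed linear values or log2, and
   cross-cell-line concordance classification.
2. **Consensus target catalog** — TargetScan-style 3′UTR sites matched for
   conservation with their miRNAs, then filtered to pairs supported by
   TargetScan plus at least one co-predictor (microT-CDS ≥ 0.4 or mirSVR
   magnitude ≥ 0.1); pairs supported by all three tools form the
   high-confidence tier.
3. **Monte Carlo master-regulator test** — for each deregulated miRNA,
   random gene sets the size of the *inversely* deregulated gene group are
   drawn from the universe of genes with ≥ 1 TargetScan site. With observed
   statistic *T* (targets hit in the group, or a weighted site score), null
   draws *T*₁…*T*_B, and mean 3′UTR lengths L̄_bg and L̄_group, the test
   reports

   *T*\* = *T* · L̄_bg / L̄_group,  *p* = (1 + #{*T*_b ≥ *T*\*}) / (B + 1),

   with Benjamini–Hochberg adjustment across miRNAs per cell line and
   direction. The weighted score sums per-site seed-match weights
   (8mer 1.0, 7mer-m8 0.75, 7mer-A1 0.5, 6mer 0.25) plus a +0.2 bonus per
   cooperatively spaced site pair (13–46 nt gap).
4. **Promoter proximity** — miRNA and host-gene TSSs compiled and
   deduplicated, ChIP peaks intersected with ±5 kb windows, signed
   distances reported in the direction of transcription.
5. **Network assembly** — TF→miRNA edges (sign inferred from the knockdown
   response), miRNA→gene repression edges for master regulators with
   inversely deregulated consensus targets, validated-interaction flags,
   interaction summaries with merged-group counting, and feedback-loop
   classification for miRNAs known to repress the TF.

A first-class synthetic-data generator (`mirreg.simulate`) produces complete
input bundles with planted ground truth — enriched master miRNAs and
promoter-proximal peaks — so every stage is testable without downloads.

## Worked example

Plant three master regulators among 30 miRNAs and recover them:

```python
from mirreg import (SyntheticConfig, generate_bundle, Thresholds,
                    filter_mirna_de, filter_gene_de, identify_master_regulators)

cfg = SyntheticConfig(n_genes=2000, n_mirnas=30, seed=42,
                      planted_masters=("miR-n001", "miR-n002", "miR-n003"),
                      enrichment_factor=5.0)
bundle = generate_bundle(cfg)
thr = Thresholds(mc_iterations=2000)
sig_mirnas = filter_mirna_de(list(bundle.mirna_de), thr)
sig_genes = filter_gene_de(list(bundle.gene_de), thr)
results = identify_master_regulators(sig_mirnas, sig_genes, bundle.catalog,
                                     thr, rng_seed=1)
for r in sorted(results, key=lambda r: r.adjusted_p)[:5]:
    print(f"{r.mature_id:10s} {r.direction:22s} observed={r.observed_raw:4.0f} "
          f"norm={r.observed_normalised:6.1f} p={r.empirical_p:.2e} "
          f"q={r.adjusted_p:.2e} master={r.is_master}")
```

```
miR-n001   mirna_down_genes_up    observed=  43 norm=  39.5 p=5.00e-04 q=3.33e-03 master=True
miR-n002   mirna_down_genes_up    observed=  46 norm=  42.3 p=5.00e-04 q=3.33e-03 master=True
miR-n003   mirna_down_genes_up    observed=  46 norm=  42.2 p=5.00e-04 q=3.33e-03 master=True
miR-n004   mirna_up_genes_down    observed=   8 norm=   9.1 p=3.17e-01 q=6.38e-01 master=False
miR-n009   mirna_up_genes_down    observed=  10 norm=  11.3 p=3.83e-01 q=6.38e-01 master=False
```

Each planted down-regulated miRNA hits ~43–46 of the 200 up-regulated genes
against a null expectation near 9; after 3′UTR-length normalisation its
empirical p-value sits at the Monte Carlo floor 1/(B+1) and survives FDR
adjustment, while unplanted miRNAs stay near uniform p. The same analysis is
available from the shell:

```bash
mirreg simulate --outdir sim --seed 42 --n-planted-masters 3 --enrichment-factor 5
mirreg run --config run.yaml --outdir results --seed 1
```

`mirreg fixtures --outdir example/` emits a curated example bundle from the
SOX2-knockdown embryonal-carcinoma study of two hECC lines (2102Ep,
NTera-2): the consensus miRNA–target table with confidence tiers, the
promoter-proximity inputs realising the published peak-to-TSS distances,
and the validated-interaction list.

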