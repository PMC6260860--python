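# ribote

Integrated analysis of paired RNA-Seq and ribosome-profiling (Ribo-Seq)
data from a two-condition bacterial growth experiment — the design used to
ask how an acetogen such as *Eubacterium limosum* reallocates translation
between heterotrophic (sugar) and autotrophic (H₂/CO₂) growth.

Given raw per-gene counts for mRNA and ribosome-protected-fragment (RPF)
libraries in both conditions, plus gene annotation with transcription
start sites, the package computes:

- **Differential expression** — a re-implemented DESeq2-style core:
  median-of-ratios size factors, per-gene NB dispersion (method of moments
  shrunk toward a mean–dispersion trend), a negative-binomial GLM Wald
  test per gene, Benjamini–Hochberg adjustment, and DEG calling at
  |log₂FC| ≥ 1 with adjusted *p* < 0.05. RPKM and a PCA QC are included.
- **Translation efficiency (TE)** — per condition,
  TE_g = (mean normalized RPF) / (mean normalized mRNA); the TE fold
  change is tested as the condition × assay interaction of an NB GLM
  (a ratio-of-ratios Wald test). Translational buffering is quantified as
  the Spearman correlation between mRNA log₂FC and TE log₂FC.
- **Reporter relative TE** — for promoter–5′UTR *lacZ* constructs:
  relative TE = (protein-level fold change from the β-galactosidase
  assay) / (mRNA-level fold change), rounded half-up to two decimals.
- **Subunit stoichiometry** — Pearson correlation of log₁₀ RPF between
  first and second genes of operons encoding 1:1 complex subunits, and
  mean-RPF ratios between named gene groups (e.g. the methyl vs carbonyl
  branch of the Wood–Ljungdahl pathway) with an equimolar flag.
- **5′UTR secondary structure** — strand-aware UTR extraction and a
  self-contained minimum-free-energy folder (Zuker-style dynamic program
  over a simplified nearest-neighbor model), with a Wilcoxon rank-sum
  comparison of ΔG between TE classes.
- **Metagene footprint profiles** — CDS-mean-normalized coverage binned
  across 5′UTR/CDS/3′UTR with per-region condition tests.
- **Functional enrichment** — hypergeometric term enrichment with BH
  correction and grouping of enriched terms by Cohen's kappa (≥ 0.4) over
  shared gene membership.
- **A synthetic-data generator** that emulates the study's statistical
  structure (NB counts with condition/assay/interaction effects,
  buffering, operon pairs, structured UTRs, footprint coverage), so every
  stage is testable without sequencing data.

## Worked example

Reporter relative TE from measured fold changes (autotrophic over
heterotrophic):

```python
>>> from ribote.te import reporter_relative_te
>>> for m in reporter_relative_te([("ELIM_c1647", 1.01, 0.62),
...                                ("ELIM_c1650", 20.91, 0.99),
...                                ("ELIM_c1491", 2.75, 3.90)]):
...     print(m.construct_id, m.relative_te)
ELIM_c1647 0.61
ELIM_c1650 0.05
ELIM_c1491 1.42
```

A relative TE well below 1 (0.61, 0.05) means the construct's 5′UTR
represses translation under autotrophy even when its mRNA is abundant;
1.42 means translation is activated.

End-to-end on synthetic data:

```sh
ribote simulate --seed 1 --out data/
ribote run --config pipeline.yaml
```

or from Python:

```python
from ribote.simulate import SimConfig
from ribote.pipeline import simulate_dataset, PipelineConfig, run_pipeline

paths = simulate_dataset(SimConfig(n_genes=500, n_operons=25,
                                   frac_te=0.3, seed=1), "data")
cfg = PipelineConfig(out_dir="out", annotation=paths["annotation"],
                     counts=paths["counts"], samples=paths["samples"],
                     genome=paths["genome"], coverage=paths["coverage"],
                     terms=paths["terms"])
run_pipeline(cfg)
```

The run writes TSV tables (`de_mrna`, `de_rpf`, `te`, `stoich_pairs`,
`utr_folds`, `metagene_profiles`, `enrichment_up/down`), a `summary.json`
and a `manifest.json` with a config hash and output checksums. For the
configuration above the summary reads (numbers from the run):

- 61 of 500 genes called differentially expressed at the two-fold /
  adjusted-*p* < 0.05 criterion;
- translational buffering: Spearman ρ = −0.444 (*p* ≈ 2.2 × 10⁻²⁵)
  between mRNA and TE fold changes — the generator plants ρ = −0.5;
- operon-pair stoichiometry: Pearson r = 0.986 (heterotrophic) and 0.972
  (autotrophic) across subunit pairs sharing expression;
- 5′UTR folding: median ΔG −5.75 kcal/mol for TE-up genes vs
  −23.45 kcal/mol for TE-down genes, whose UTRs carry planted hairpins;
- metagene: 5′UTR footprint coverage differs between conditions
  (Wilcoxon *p* = 1.5 × 10⁻⁷) while CDS coverage does not (*p* = 0.55),
  matching the planted TE-down 5′UTR enrichment.

A rerun with the same config and seed is bit-identical (checksums in the
manifest).

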