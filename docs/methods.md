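# Methods

## Data model and conventions

All coordinates are 0-based half-open internally; GFF3's 1-based
inclusive convention is converted only at the parsing boundary. The TSS
is carried as a dedicated `TSS` feature with `Parent=<gene>`; a gene
without one keeps an empty 5′UTR and is flagged, so it is excluded from
UTR analyses but never from count analyses. On the + strand the 5′UTR is
`[tss, cds_start)`; on the − strand it is `[cds_end, tss+1)` and is
reverse-complemented on extraction so sequences always read 5′→3′.
Count matrices must contain raw integers — normalized input is rejected,
because size-factor estimation assumes raw counts.

## Differential expression

**Size factors.** Median-of-ratios: the reference is the per-gene
geometric mean across samples (genes with any zero excluded);
`sf_s = median_g(count_gs / ref_g)`, then rescaled so the geometric mean
of the factors is 1. The convention leaves all fold changes invariant; it
only fixes a representation. A poscounts-style pseudo-reference is
available for matrices where no gene is positive everywhere.

**Dispersion.** NB2 throughout: Var = μ + αμ². Per gene, a method-of-
moments estimate `(s² − m)/m²` is pooled across the four
condition × assay groups (weighted by degrees of freedom), then shrunk in
log space with weight 0.5 toward a trend `α(μ) = a₀ + a₁/μ` fitted by
bounded least squares with one outlier-trimming pass. Two guards matter
at two replicates per group: genes whose moment estimate is non-positive
fall back to the trend value (only genes with zero within-group variance
keep the floor of 1e-4), and no non-constant gene is reported below the
trend. Without these guards the Wald test is sharply anti-conservative,
because half the moment estimates fall below the truth by chance at 4 df.
This is a deliberate simplification of DESeq2's empirical-Bayes
machinery; it trades some power for calibration and is documented as
such.

**Wald test.** Per gene, an NB GLM with log link, the condition factor as
a two-level design within one assay, `log(sf)` as offset and fixed
dispersion, fitted by Fisher scoring with step damping and a linear-
predictor clip at ±30 (which bounds estimates for separated designs). The
two-sided Wald p-value comes from the interaction-free contrast
coefficient; log₂FC is reported autotrophic over heterotrophic. Genes
with all-zero counts get p = 1, log₂FC = 0 and are excluded from BH;
genes with one all-zero group keep the GLM test statistic but report an
Anscombe (+0.5) offset point estimate. DEG calling: |log₂FC| ≥ 1 and
BH-adjusted p < 0.05. No independent filtering, LFC shrinkage or
outlier replacement is applied.

**Calibration.** With the generating dispersions supplied, the null
rejection rate at p < 0.05 is 0.052 (Wald) and 0.051 (interaction) over
4000 simulated genes, and the empirical FDR at adjusted-p < 0.05 with 10%
planted effects is ≈ 0.03. With dispersions *estimated* at two replicates
the 5% level is still calibrated (≈ 0.047) but the far tail is
anti-conservative for high-dispersion genes, so FDR under strong effect
mixtures can exceed the nominal level — an inherent limit of per-gene
moment estimation at 4 df, and the main reason more replicates help.

## Translation efficiency

TE per condition is the ratio of replicate-averaged normalized RPF to
replicate-averaged normalized mRNA. Genes whose mean normalized mRNA
falls below `mrna_floor` (default 1 normalized count) in either condition
are flagged and excluded from ratios rather than dropped. By algebra the
TE log₂ fold change equals RPF log₂FC − mRNA log₂FC for the point
estimates.

Significance of a TE change is the Wald test on the condition × assay
interaction of an NB GLM over all eight libraries (intercept, condition,
assay, interaction; shared per-gene dispersion across assays). This is
the ratio-of-ratios construction: a condition effect common to both
assays — translational buffering at the transcript level — does not load
on the interaction, which the confound-control test verifies. TE classes
mirror the DEG thresholds (|log₂FC| ≥ 1, adjusted p < 0.05).

Buffering is the Spearman correlation between mRNA log₂FC and TE log₂FC
over shared genes; the reporter relative TE is protein fold change over
mRNA fold change with two-decimal half-up rounding, matching how bench
reporter assays are tabulated.

## Stoichiometry

The synthesis-rate proxy for a gene is its mean normalized RPF count (no
codon-level correction). Operon subunit pairs (indices 1 and 2) are kept
when both members exceed an expression floor in both conditions; the
per-condition statistic is the Pearson correlation of log₁₀ RPF between
first and second subunits. Named gene groups are compared by the ratio of
group means, flagged equimolar within [1/1.5, 1.5] by default.

## 5′UTR folding

The folder is a self-contained Zuker-style dynamic program:

- stacking energies for the six canonical pairs (AU, UA, GC, CG, GU, UG)
  from a packaged 6 × 6 nearest-neighbor table (kcal/mol);
- hairpin loops: 5.0 + 0.15·(L−3) kcal/mol, minimum L = 3;
- interior loops/bulges: 3.0 + 0.3·(unpaired) kcal/mol, at most 10
  unpaired nt per loop;
- multiloops: linear model 4.6 + 0.4·branch + 0.1·unpaired;
- exterior bases free; no pseudoknots, dangles or temperature dependence.

The traceback is deterministic (fixed scan order; at the exterior level a
pair is introduced only when it strictly lowers the energy, so ΔG = 0
exactly when the structure is empty). The DP equals exhaustive
enumeration of all valid structures for every tested sequence up to
16 nt. Absolute ΔG values are **not** comparable to full Turner-model
folders (the parameter table is intentionally simple and pluggable);
only relative comparisons between sequence classes are meaningful here.
UTRs shorter than 8 nt are folded but flagged trivially unstructured.

Class comparisons use the two-sided Wilcoxon rank-sum test: the exact
null distribution when there are no ties and both n ≤ 25, otherwise the
tie-corrected normal approximation with continuity correction; a pooled
sample with zero rank variance returns p = 1. A paired signed-rank
variant is available where the same genes appear in both conditions, but
rank-sum is the default.

## Metagene profiles

Per gene, coverage is oriented 5′→3′, divided by the mean CDS coverage
(genes with zero CDS coverage are excluded), and resampled onto a
20/50/20 bin grid for 5′UTR/CDS/3′UTR. Regions at least as long as their
grid average the bases mapped to each bin (base b → bin ⌊b·nbins/L⌋);
shorter regions are resampled per base onto the grid. Aggregation reports
the per-bin median across genes; the per-region condition test applies
the Wilcoxon rank-sum to per-gene mean normalized region coverage.
Normalization makes profiles invariant to scaling a track by any positive
constant.

## Enrichment and kappa grouping

Term enrichment is the upper tail of the hypergeometric distribution with
the annotated-gene universe (not the genome — avoids unannotated-gene
bias), BH-corrected across terms; terms annotating fewer than 3 universe
genes are excluded. Enriched terms are grouped by Cohen's kappa between
binary gene-membership vectors restricted to the DEG universe: edges at
κ ≥ 0.4, groups = connected components (singletons allowed). A term that
is an articulation point of its component is additionally reported with
the number of parts it bridges — the analogue of a node shared between
two groups in a term-network figure.

## Synthetic data

The generator emulates a two-condition, two-assay bacterial expression
study with biological duplicates:

```
count[g,s] ~ NB(mean = q_g · sf_s · 2^(x_cond·β_g + x_assay·γ_g + x_cond·x_assay·δ_g),  α_g)
```

with x_cond = 1 for autotrophic and x_assay = 1 for RPF, so the TE log₂FC
truth is exactly δ_g. Defaults (chosen once as a realistic desk-scale
design): 2000 genes; 2 replicates; base means log₁₀-uniform in
[0.5, 3.5]; dispersions log-uniform in [0.01, 0.5] (a modeling choice —
true per-gene dispersions of the emulated study are unknown); 30% of
genes carry a condition effect (β ~ N(0, 2²)) and 15% a TE effect
(δ ~ N(0, 1²)); a baseline assay offset γ ~ N(0, 0.5²) models
gene-specific ribosome loading. Buffering is induced by drawing (β, δ)
from a bivariate normal with correlation −0.5 before masking by the
effect indicators. Operon pairs share expression up to 10% log-normal
noise and share all effects. Each operation draws from its own RNG
stream seeded from (seed, operation tag), so stages are independently
reproducible.

UTR sequences are i.i.d. uniform ACGU; TE-down genes receive a planted
GC-biased complementary stem (length from the upper half of [4, 10],
4-nt loop), which the folder provably pairs. The genome is assembled by
writing planted UTRs (strand-aware) into a random background, so
extraction is exactly invertible. Coverage is Poisson per base with CDS
rate proportional to the RPF group mean, 5′UTR rate a configurable
fraction of it (0.2 baseline, 1.0 for TE-down genes under autotrophy —
the altered footprint distribution the metagene stage detects) and a
3′UTR fraction of 0.1. The emulated library-preparation read-length
filter (reads < 20 bp removed) is recorded as a config parameter;
read-level artifacts (MNase bias, rRNA contamination, mapping ambiguity)
are **not** modeled. Passing tests on these data therefore validate the
statistical machinery, not robustness to alignment- or protocol-level
artifacts in real libraries.

## Pipeline

Stages run in dependency order (`de` → `te` → `stoich`/`utr`/`metagene`/
`enrich`) on one input bundle; required inputs are validated before any
computation. Every result table carries a header comment with the package
version and a config hash (computed over the analysis configuration,
excluding the output directory). The manifest records output SHA-256
checksums and no timestamps, so identical config + seed reproduce
bit-identical outputs. Thresholds default to the two-fold / 5% FDR DEG
criterion, κ ≥ 0.4, mRNA floor 1, ratio tolerance 1.5.

## Problem sizes used in tests

The suite runs simulations of 300–5000 genes (type-I calibration at
4000; FDR at 5000; recovery over 20 replicates of 300), folds sequences
to 16 nt against exhaustive enumeration and 1000 random sequences ≤ 12 nt,
and executes the full pipeline twice on a 100–120-gene dataset for
determinism — sizes chosen so each check is statistically informative
while the whole suite stays interactive.

## Known limitations

- Per-gene dispersion at two replicates is weakly identified; the far
  tail of the Wald test is anti-conservative for high-dispersion genes
  (see Calibration above).
- The folding energy table is simplified; absolute ΔG values differ from
  Turner-parameter folders, and published ΔG medians for real UTR sets
  are not reproducible with it.
- The interaction test assumes a shared per-gene dispersion across
  assays.
- Counting rules for RPF reads (e.g. CDS-restriction) are the data
  producer's responsibility; the generator documents its own rule (counts
  are whole-gene NB draws, coverage tracks are separate).
- Reported DEG/TE-class counts depend on replicate number and power and
  are not comparable across datasets of different depth.
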