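"""Translation efficiency: per-gene TE, interaction significance, buffering,
and the reporter-assay relative TE.

TE of a gene in one condition is the replicate-averaged normalized RPF
abundance divided by the replicate-averaged normalized mRNA abundance.
Significance of a TE change between conditions comes from an NB GLM with
condition, assay and condition x assay terms and a Wald test on the
interaction coefficient -- the ratio-of-ratios definition made testable.
The reporter relative TE mirrors the bench assay: a protein-level fold
change (beta-galactosidase activity) divided by the matching mRNA-level
fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._glm import nb_glm_fit, wald_test
from .de import LOG2, SizeFactorSet, benjamini_hochberg, normalized_counts
from .io_formats import ASSAYS, CONDITIONS, CountMatrix, ValidationError

TE_LFC_THRESHOLD = 1.0
TE_ALPHA = 0.05
DEFAULT_MRNA_FLOOR = 1.0


def compute_te(counts: CountMatrix, sf: SizeFactorSet,
               mrna_floor: float = DEFAULT_MRNA_FLOOR) -> pd.DataFrame:
    """Per-gene, per-condition TE point estimates and TE log2 fold change.

    Genes with mean normalized mRNA below ``mrna_floor`` in either condition
    are excluded (TE set to NaN, ``excluded=True``) rather than dropped.
    """
    for assay in ASSAYS:
        if not counts.sample_mask(assay=assay).any():
            raise ValidationError(f"count matrix lacks assay {assay!r}")
    norm = normalized_counts(counts, sf)
    het, auto = CONDITIONS
    means = {}
    for cond in CONDITIONS:
        for assay in ASSAYS:
            mask = counts.sample_mask(condition=cond, assay=assay)
            if not mask.any():
                raise ValidationError(f"no samples for ({cond}, {assay})")
            means[(cond, assay)] = norm[:, mask].mean(axis=1)
    excluded = (means[(het, "mRNA")] < mrna_floor) | \
               (means[(auto, "mRNA")] < mrna_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        te_het = means[(het, "RPF")] / means[(het, "mRNA")]
        te_auto = means[(auto, "RPF")] / means[(auto, "mRNA")]
        lfc = np.log2(te_auto / te_het)
    te_het = np.where(excluded, np.nan, te_het)
    te_auto = np.where(excluded, np.nan, te_auto)
    lfc = np.where(excluded, np.nan, lfc)
    return pd.DataFrame({
        "gene_id": counts.gene_ids,
        "mrna_het": means[(het, "mRNA")], "mrna_auto": means[(auto, "mRNA")],
        "rpf_het": means[(het, "RPF")], "rpf_auto": means[(auto, "RPF")],
        "te_het": te_het, "te_auto": te_auto,
        "te_log2fc": lfc, "excluded": excluded,
    })


def te_interaction_test(counts: CountMatrix, sf: SizeFactorSet,
                        dispersions: np.ndarray) -> pd.DataFrame:
    """Wald test on the condition x assay interaction of an NB GLM.

    The design has intercept, condition (autotrophic), assay (RPF) and
    their interaction; a shared per-gene dispersion is used across assays.
    The interaction estimate on the log2 scale is the TE log2 fold change.
    Genes with all-zero counts are flagged and get p = 1.
    """
    conds = np.array([s.condition for s in counts.samples])
    assays = np.array([s.assay for s in counts.samples])
    x_cond = (conds == CONDITIONS[1]).astype(float)
    x_assay = (assays == "RPF").astype(float)
    for c in CONDITIONS:
        for a in ASSAYS:
            if ((conds == c) & (assays == a)).sum() < 2:
                raise ValidationError(
                    f"interaction test needs >= 2 replicates in ({c}, {a})")
    X = np.column_stack([np.ones_like(x_cond), x_cond, x_assay,
                         x_cond * x_assay])
    offset = np.log(sf.factors)
    rows = []
    for i, gid in enumerate(counts.gene_ids):
        y = counts.counts[i].astype(float)
        if y.sum() == 0:
            rows.append((gid, 0.0, np.nan, 0.0, 1.0, "all_zero"))
            continue
        beta, cov = nb_glm_fit(y, X, offset, float(dispersions[i]))
        est, se, z, p = wald_test(beta, cov, 3)
        rows.append((gid, est / LOG2, se / LOG2, z, p, "ok"))
    df = pd.DataFrame(rows, columns=["gene_id", "interaction_log2fc", "se",
                                     "wald_z", "p", "status"])
    tested = (df["status"] == "ok").to_numpy()
    padj = np.full(len(df), 1.0)
    padj[tested] = benjamini_hochberg(df.loc[tested, "p"])
    df["p_adj"] = padj
    return df


def classify_te(te_table: pd.DataFrame, test_table: pd.DataFrame,
                lfc_threshold: float = TE_LFC_THRESHOLD,
                sig_alpha: float = TE_ALPHA) -> pd.DataFrame:
    """Merge TE point estimates with interaction significance; assign classes.

    ``up``: te_log2fc >= threshold and adjusted p < alpha; ``down``
    symmetric; otherwise ``unchanged`` (excluded genes get ``excluded``).
    """
    df = te_table.merge(
        test_table[["gene_id", "p", "p_adj", "status"]], on="gene_id",
        how="left")
    cls = np.full(len(df), "unchanged", dtype=object)
    up = (df["te_log2fc"] >= lfc_threshold) & (df["p_adj"] < sig_alpha)
    down = (df["te_log2fc"] <= -lfc_threshold) & (df["p_adj"] < sig_alpha)
    cls[up.to_numpy(na_value=False)] = "up"
    cls[down.to_numpy(na_value=False)] = "down"
    cls[df["excluded"].to_numpy()] = "excluded"
    df["te_class"] = cls
    return df


def buffering_correlation(de_mrna: pd.DataFrame,
                          te: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation between mRNA log2FC and TE log2FC over shared genes.

    A negative value is the translational-buffering signature: transcript
    increases are damped at the ribosome-loading level.
    """
    merged = de_mrna[["gene_id", "log2fc"]].merge(
        te[["gene_id", "te_log2fc"]], on="gene_id")
    merged = merged.dropna()
    if len(merged) < 3:
        raise ValidationError("need >= 3 shared genes for buffering correlation")
    rho, p = sps.spearmanr(merged["log2fc"], merged["te_log2fc"])
    return float(rho), float(p)


@dataclass(frozen=True)
class ReporterMeasurement:
    construct_id: str
    mrna_fc: float
    protein_fc: float
    relative_te: float


def reporter_relative_te(measurements) -> list[ReporterMeasurement]:
    """Relative TE of reporter constructs: protein FC / mRNA FC.

    Fold changes are autotrophic over heterotrophic; the ratio is reported
    rounded half-up to two decimals, matching how bench reporter assays are
    tabulated.
    """
    out = []
    for construct_id, mrna_fc, protein_fc in measurements:
        if mrna_fc <= 0 or protein_fc <= 0:
            raise ValidationError(
                f"{construct_id}: fold changes must be positive")
        ratio = Decimal(str(protein_fc)) / Decimal(str(mrna_fc))
        rel = float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
        out.append(ReporterMeasurement(str(construct_id), float(mrna_fc),
                                       float(protein_fc), rel))
    return out


def read_reporter_tsv(path) -> list[tuple[str, float, float]]:
    """Read a 3-column reporter TSV: construct_id, mrna_fc, protein_fc."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns[:3])
    return [(str(r[cols[0]]), float(r[cols[1]]), float(r[cols[2]]))
            for _, r in df.iterrows()]
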