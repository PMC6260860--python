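"""DESeq2-style differential-expression core, re-implemented.

The chain is: median-of-ratios size factors -> per-gene NB dispersion
(method of moments within groups, shrunk toward a fitted mean-dispersion
trend) -> per-gene NB GLM Wald test on the condition contrast ->
Benjamini-Hochberg adjustment -> DEG calling at |log2FC| >= 1 and
adjusted p < 0.05 (a two-fold change at 5% FDR).

This is a documented simplification of DESeq2's empirical-Bayes machinery:
no Cook's-distance outlier handling, no independent filtering, no LFC
shrinkage. Size factors follow the convention that their geometric mean
is 1, which leaves all fold changes invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from ._glm import nb_glm_fit, wald_test
from .io_formats import CountMatrix, ValidationError

LOG2 = np.log(2.0)

DEG_LFC_THRESHOLD = 1.0
DEG_ALPHA = 0.05
ALPHA_FLOOR = 1e-4


@dataclass
class SizeFactorSet:
    factors: np.ndarray            # per sample, geometric mean 1
    sample_ids: list[str]
    log_reference: np.ndarray      # per-gene log geometric mean; -inf where excluded

    def as_series(self) -> pd.Series:
        return pd.Series(self.factors, index=self.sample_ids)


def estimate_size_factors(counts: CountMatrix,
                          pseudo_reference: bool = False) -> SizeFactorSet:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean across samples; genes with
    a zero in any sample are excluded from the reference. ``sf_s`` is the
    median of count/reference over reference genes, then the factor vector
    is rescaled so its geometric mean is 1.

    With ``pseudo_reference=True`` the geometric mean is taken over the
    positive counts of each gene (a poscounts-style fallback for sparse
    matrices where no gene is positive everywhere).
    """
    k = counts.counts.astype(float)
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    if pseudo_reference:
        pos = k > 0
        ngood = pos.sum(axis=1)
        usable = ngood > 0
        logref = np.full(k.shape[0], -np.inf)
        logref[usable] = np.where(pos[usable], logk[usable], 0.0).sum(axis=1) \
            / ngood[usable]
    else:
        usable = (k > 0).all(axis=1)
        logref = np.full(k.shape[0], -np.inf)
        logref[usable] = logk[usable].mean(axis=1)
    if not usable.any():
        raise ValidationError(
            "no gene has nonzero counts in every sample; rerun with "
            "pseudo_reference=True to use a positive-count pseudo-reference")
    ratios = logk[usable] - logref[usable, None]
    if pseudo_reference:
        # median over finite ratios per sample
        sf_log = np.array([np.median(col[np.isfinite(col)])
                           for col in ratios.T])
    else:
        sf_log = np.median(ratios, axis=0)
    sf_log = sf_log - sf_log.mean()   # geometric-mean-1 convention
    return SizeFactorSet(np.exp(sf_log), counts.sample_ids, logref)


def normalized_counts(counts: CountMatrix, sf: SizeFactorSet) -> np.ndarray:
    return counts.counts / sf.factors[None, :]


def estimate_dispersions(counts: CountMatrix, sf: SizeFactorSet,
                         groups: list[str], alpha_floor: float = ALPHA_FLOOR,
                         shrink_weight: float = 0.5,
                         alpha_cap: float = 10.0) -> np.ndarray:
    """Per-gene NB dispersion alpha (Var = mu + alpha mu^2).

    Method of moments within each group of ``groups`` (one label per
    sample), pooled across groups, then shrunk in log space toward a fitted
    trend ``alpha(mu) = a0 + a1/mu``. With few replicates the moment
    estimate is frequently non-positive even for overdispersed genes, so
    such genes fall back to the trend value; only genes with zero
    within-group variance (constant counts) keep the floor.
    """
    labels = np.asarray(groups)
    if len(labels) != len(counts.samples):
        raise ValueError("groups must give one label per sample")
    norm = normalized_counts(counts, sf)
    uniq = np.unique(labels)
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    totvar = np.zeros(norm.shape[0])
    base_mean = norm.mean(axis=1)
    for g in uniq:
        cols = norm[:, labels == g]
        r = cols.shape[1]
        if r < 2:
            raise ValidationError(
                f"dispersion estimation needs >= 2 replicates in group {g!r}")
        m = cols.mean(axis=1)
        v = cols.var(axis=1, ddof=1)
        totvar += v
        # (v - m) / m^2, pooled over groups weighted by df
        ok = m > 0
        num[ok] += (r - 1) * (v[ok] - m[ok]) / m[ok] ** 2
        den += (r - 1)
    alpha_mom = num / den
    # mean-dispersion trend on genes with informative moment estimates
    fit_mask = (alpha_mom > alpha_floor) & (base_mean > 0)
    alpha_trend = np.full(norm.shape[0], alpha_floor)
    if fit_mask.sum() >= 10:
        a = _fit_trend(base_mean[fit_mask], alpha_mom[fit_mask])
        with np.errstate(divide="ignore"):
            alpha_trend = a[0] + a[1] / np.maximum(base_mean, 1e-8)
        alpha_trend = np.maximum(alpha_trend, alpha_floor)
    out = np.where(totvar > 0, alpha_trend, alpha_floor)
    pos = fit_mask
    out[pos] = np.exp((1 - shrink_weight) * np.log(alpha_mom[pos])
                      + shrink_weight * np.log(alpha_trend[pos]))
    # never report less dispersion than the trend for a non-constant gene:
    # with few replicates, downward-noisy moment estimates otherwise make
    # the Wald test sharply anti-conservative
    out = np.where(totvar > 0, np.maximum(out, alpha_trend), out)
    return np.clip(out, alpha_floor, alpha_cap)


def _fit_trend(mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha ~ a0 + a1/mean with one trimming pass."""
    X = np.column_stack([np.ones_like(mean), 1.0 / mean])
    res = lsq_linear(X, alpha, bounds=(0.0, np.inf))
    a = res.x
    pred = np.maximum(X @ a, 1e-8)
    ratio = alpha / pred
    keep = (ratio > 1e-2) & (ratio < 1e2)
    if keep.sum() >= 10 and keep.sum() < len(alpha):
        res = lsq_linear(X[keep], alpha[keep], bounds=(0.0, np.inf))
        a = res.x
    return a


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-stable)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def nb_wald_test(counts: CountMatrix, sf: SizeFactorSet,
                 dispersions: np.ndarray,
                 contrast: tuple[str, str] = ("heterotrophic", "autotrophic"),
                 assay: str = "mRNA",
                 lfc_threshold: float = DEG_LFC_THRESHOLD,
                 sig_alpha: float = DEG_ALPHA) -> pd.DataFrame:
    """Per-gene NB GLM Wald test of the condition effect within one assay.

    log2FC is the second condition of ``contrast`` over the first
    (autotrophic over heterotrophic by default). Genes with all-zero counts
    in the tested samples get p = 1, log2FC = 0 and ``status='all_zero'``;
    genes with one all-zero group get an Anscombe 0.5-count offset for the
    reported point estimate only (the test statistic comes from the GLM).
    """
    ref, alt = contrast
    mask = counts.sample_mask(assay=assay)
    sub = counts.subset_samples(mask)
    sf_sub = sf.factors[mask]
    conds = np.array([s.condition for s in sub.samples])
    for c in contrast:
        if (conds == c).sum() < 2:
            raise ValidationError(
                f"need >= 2 replicates of condition {c!r} in assay {assay!r}")
    x = (conds == alt).astype(float)
    X = np.column_stack([np.ones_like(x), x])
    offset = np.log(sf_sub)
    norm = sub.counts / sf_sub[None, :]

    rows = []
    for i, gid in enumerate(sub.gene_ids):
        y = sub.counts[i].astype(float)
        m_ref = norm[i, conds == ref].mean()
        m_alt = norm[i, conds == alt].mean()
        if y.sum() == 0:
            rows.append((gid, 0.0, 0.0, 0.0, np.nan, 0.0, 1.0, "all_zero"))
            continue
        beta, cov = nb_glm_fit(y, X, offset, float(dispersions[i]))
        est, se, z, p = wald_test(beta, cov, 1)
        lfc = est / LOG2
        if m_ref == 0.0 or m_alt == 0.0:
            lfc = float(np.log2((m_alt + 0.5) / (m_ref + 0.5)))
            status = "zero_group"
        else:
            status = "ok"
        rows.append((gid, m_ref, m_alt, lfc, se / LOG2, z, p, status))

    df = pd.DataFrame(rows, columns=["gene_id", f"mean_{ref}", f"mean_{alt}",
                                     "log2fc", "se", "wald_z", "p", "status"])
    tested = df["status"] != "all_zero"
    padj = np.full(len(df), 1.0)
    padj[tested.to_numpy()] = benjamini_hochberg(df.loc[tested, "p"])
    df["p_adj"] = padj
    df["is_deg"] = (df["log2fc"].abs() >= lfc_threshold) & (df["p_adj"] < sig_alpha) \
        & tested
    return df


def compute_rpkm(counts: CountMatrix, gene_lengths) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads: 1e9 * k / (L * total)."""
    lengths = np.asarray([gene_lengths[g] for g in counts.gene_ids], dtype=float)
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    totals = counts.counts.sum(axis=0).astype(float)
    totals[totals == 0] = np.nan
    rpkm = 1e9 * counts.counts / (lengths[:, None] * totals[None, :])
    return pd.DataFrame(np.nan_to_num(rpkm), index=counts.gene_ids,
                        columns=counts.sample_ids)


def pca_qc(counts: CountMatrix, sf: SizeFactorSet):
    """PCA of log2(normalized + 1), gene-centered, via SVD.

    Returns ``(coords, var_frac)``: sample coordinates (samples x PCs) and
    the fraction of variance per component (sums to 1, or all zeros for a
    constant matrix).
    """
    logn = np.log2(normalized_counts(counts, sf) + 1.0)
    centered = logn - logn.mean(axis=1, keepdims=True)
    # samples as observations
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    total = float((s ** 2).sum())
    if total <= 1e-12:
        ncomp = len(counts.samples)
        coords = pd.DataFrame(np.zeros((ncomp, ncomp)), index=counts.sample_ids,
                              columns=[f"PC{i+1}" for i in range(ncomp)])
        return coords, np.zeros(ncomp)
    var_frac = s ** 2 / total
    coords = pd.DataFrame(u * s, index=counts.sample_ids,
                          columns=[f"PC{i+1}" for i in range(len(s))])
    return coords, var_frac
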