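"""Stoichiometric synthesis of protein-complex subunits from RPF levels.

Operon gene pairs encoding 1:1 complex subunits should show near-identical
ribosome-footprint synthesis rates; the per-condition Pearson correlation
of log10 RPF means across pairs quantifies this.  Named gene groups
(e.g. the methyl vs carbonyl branch of the Wood-Ljungdahl pathway) are
compared by the ratio of their mean normalized RPF, flagged "equimolar"
within a tolerance band.  The synthesis-rate proxy is the mean normalized
RPF count — no codon-level correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .de import SizeFactorSet, normalized_counts
from .io_formats import CONDITIONS, CountMatrix, GeneModel, ValidationError

DEFAULT_RATIO_TOL = 1.5
DEFAULT_EXPRESSION_FLOOR = 1.0


def rpf_condition_means(counts: CountMatrix, sf: SizeFactorSet) -> pd.DataFrame:
    """Per-gene mean normalized RPF count per condition."""
    norm = normalized_counts(counts, sf)
    data = {"gene_id": counts.gene_ids}
    for cond in CONDITIONS:
        mask = counts.sample_mask(condition=cond, assay="RPF")
        if not mask.any():
            raise ValidationError(f"no RPF samples for condition {cond!r}")
        data[cond] = norm[:, mask].mean(axis=1)
    return pd.DataFrame(data).set_index("gene_id")


def operon_pair_stats(annotation: list[GeneModel], counts: CountMatrix,
                      sf: SizeFactorSet,
                      floor: float = DEFAULT_EXPRESSION_FLOOR) -> pd.DataFrame:
    """RPF means and per-condition log ratios for subunit pairs (1, 2).

    Pairs are kept only when both members pass the expression floor in
    both conditions.
    """
    means = rpf_condition_means(counts, sf)
    by_operon: dict[str, dict[int, str]] = {}
    for g in annotation:
        if g.operon_id is not None:
            by_operon.setdefault(g.operon_id, {})[g.subunit_index] = g.gene_id
    rows = []
    for operon_id in sorted(by_operon):
        sub = by_operon[operon_id]
        if 1 not in sub or 2 not in sub:
            continue
        g1, g2 = sub[1], sub[2]
        if g1 not in means.index or g2 not in means.index:
            continue
        row = {"operon_id": operon_id, "gene1": g1, "gene2": g2}
        ok = True
        for cond in CONDITIONS:
            r1 = float(means.loc[g1, cond])
            r2 = float(means.loc[g2, cond])
            if r1 < floor or r2 < floor:
                ok = False
                break
            row[f"rpf1_{cond}"] = r1
            row[f"rpf2_{cond}"] = r2
            row[f"log_ratio_{cond}"] = float(np.log10(r1 / r2))
        if ok:
            rows.append(row)
    return pd.DataFrame(rows)


def pair_correlation(pairs: pd.DataFrame, condition: str) -> tuple[float, float]:
    """Pearson r (and p) of log10 RPF between first and second subunits."""
    if condition not in CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}")
    if len(pairs) < 3:
        raise ValidationError("need >= 3 operon pairs for a correlation")
    x = np.log10(pairs[f"rpf1_{condition}"].to_numpy(dtype=float))
    y = np.log10(pairs[f"rpf2_{condition}"].to_numpy(dtype=float))
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def complex_ratio(groups: dict[str, set], counts: CountMatrix,
                  sf: SizeFactorSet, condition: str,
                  ratio_tol: float = DEFAULT_RATIO_TOL):
    """Group synthesis rates (mean member RPF) and pairwise ratio matrix.

    Returns ``(group_means, ratios, equimolar)``: a Series of per-group
    mean normalized RPF, a DataFrame of ratios (row / column), and a
    boolean DataFrame flagging ratios within [1/ratio_tol, ratio_tol].
    """
    if ratio_tol < 1.0:
        raise ValidationError("ratio_tol must be >= 1")
    means = rpf_condition_means(counts, sf)[condition]
    group_means = {}
    for name in sorted(groups):
        members = [g for g in groups[name] if g in means.index]
        if not members:
            raise ValidationError(f"group {name!r} has no genes in the matrix")
        group_means[name] = float(means.loc[members].mean())
    gm = pd.Series(group_means)
    ratios = pd.DataFrame(gm.to_numpy()[:, None] / gm.to_numpy()[None, :],
                          index=gm.index, columns=gm.index)
    equimolar = (ratios >= 1.0 / ratio_tol) & (ratios <= ratio_tol)
    return gm, ratios, equimolar


def read_groups_tsv(path) -> dict[str, set]:
    """Two-column TSV (group, gene_id) -> group -> gene set."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["group", "gene_id"], dtype=str)
    out: dict[str, set] = {}
    for r in df.itertuples():
        out.setdefault(r.group, set()).add(r.gene_id)
    return out
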