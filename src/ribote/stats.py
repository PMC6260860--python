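"""Shared rank statistics used by the UTR and metagene comparisons."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def wilcoxon_rank_sum(x, y, paired: bool = False) -> tuple[float, float]:
    """Two-sided Wilcoxon test between two samples.

    Unpaired (rank-sum / Mann-Whitney): the exact null distribution is used
    when there are no ties and both samples have at most 25 observations;
    otherwise the normal approximation with tie correction.  A pooled sample
    with zero rank variance (all values identical) gives p = 1 by convention.

    Paired (signed-rank) is offered for designs where the same genes are
    measured in both conditions.

    Returns ``(statistic, p)`` where the statistic is the rank-sum of ``x``
    for the unpaired test and the signed-rank statistic for the paired one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired test requires equal-length samples")
        d = x - y
        nz = d[d != 0]
        if nz.size == 0:
            return 0.0, 1.0
        res = sps.wilcoxon(x, y, zero_method="wilcox", correction=False,
                           alternative="two-sided")
        return float(res.statistic), float(res.pvalue)

    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        n1 = x.size
        return float(n1 * (n1 + pooled.size - n1 + 1) / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size <= 25 and y.size <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=(method == "asymptotic"))
    # convert U to the rank-sum W of x
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return w, float(res.pvalue)
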