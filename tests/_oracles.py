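"""Independent brute-force oracles shared by the statistics tests."""

from itertools import product

import numpy as np
from scipy import stats as sps


def rank_pearson_oracle(x, y):
    """Spearman via Pearson on ranks."""
    return sps.pearsonr(sps.rankdata(x), sps.rankdata(y))[0]


def icc_anova_oracle(x, y):
    """ICC(A,1) via explicit two-way sums of squares."""
    scores = np.column_stack([x, y])
    n, k = scores.shape
    grand = scores.mean()
    ss_rows = k * sum((scores[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((scores[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((scores - grand) ** 2).sum()
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def wilcoxon_enumeration_oracle(d):
    """Two-sided exact signed-rank p over all 2^n sign patterns."""
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in product((0, 1), repeat=d.size)
        ]
    )
    p = 2 * min((w_all <= w_obs + 1e-12).mean(), (w_all >= w_obs - 1e-12).mean())
    return min(p, 1.0)
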