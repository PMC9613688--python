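"""Independent brute-force oracles used by unit and acceptance tests."""

import itertools

import numpy as np
from scipy.stats import rankdata


def enumerate_signed_rank_p(d: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p by full 2^n enumeration.

    Zero differences are dropped; |d| midranked; every sign pattern is
    enumerated and the two-sided p is twice the smaller tail of the
    permutation distribution of W+ (capped at 1).
    """
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ])
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def spearman_rho_by_definition(x, y) -> float:
    """Spearman rho from mid-ranks via the Pearson formula (tie-safe)."""
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))
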