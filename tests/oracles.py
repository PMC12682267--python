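"""Independent brute-force oracles for the nonparametric tests."""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def wilcoxon_exact_p(diffs) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    n = d.size
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        sum(r for j, r in enumerate(ranks) if (mask >> j) & 1)
        for mask in range(2 ** n)
    ])
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


def mwu_exact_p(a, b) -> float:
    """Two-sided Mann-Whitney p by enumerating all group assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    na = a.size
    ranks = rankdata(pooled)

    def u_stat(idx):
        return ranks[list(idx)].sum() - na * (na + 1) / 2

    u_obs = u_stat(range(na))
    us = np.array([u_stat(c) for c in combinations(range(pooled.size), na)])
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
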