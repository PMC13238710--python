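"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: brute-force
all-pairs distances for mask expansion, exhaustive rank-assignment
enumeration for the Mann-Whitney test, and direct hypergeometric
enumeration for Fisher's exact test.
"""

from itertools import combinations
from math import comb

import numpy as np


def brute_expand(grid: np.ndarray, radius_px: float) -> np.ndarray:
    """O(N^2) all-pairs pixel-center distance oracle for closed-ball dilation."""
    fg = np.argwhere(grid)
    out = np.zeros_like(grid, dtype=bool)
    if fg.size == 0:
        return out
    coords = np.argwhere(np.ones_like(grid, dtype=bool))
    d2 = ((coords[:, None, :] - fg[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    out[coords[:, 0], coords[:, 1]] = np.sqrt(d2) <= radius_px
    return out


def enumerate_mw_p(x, y) -> float:
    """Exact two-tailed Mann-Whitney p by enumerating every rank assignment."""
    x, y = list(x), list(y)
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "oracle assumes no ties"
    n1, n2 = len(x), len(y)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    center = n1 * n2 / 2.0
    dev = abs(u_obs - center)
    total = hits = 0
    for idx in combinations(range(n1 + n2), n1):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(n1 + n2) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - center) >= dev - 1e-12:
            hits += 1
    return hits / total


def enumerate_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p: sum of hypergeometric tables no more probable."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(aa):
        cc = c1 - aa
        if cc < 0 or cc > r2 or aa > r1:
            return 0.0
        return comb(r1, aa) * comb(r2, cc) / comb(n, c1)

    p_obs = prob(a)
    return sum(p for aa in range(0, min(r1, c1) + 1)
               if (p := prob(aa)) <= p_obs * (1 + 1e-9))
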