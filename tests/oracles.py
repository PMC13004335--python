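"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: set comparison by
explicit element loops, the signed-rank null by full sign enumeration, and
one-dimensional two-group clustering by enumerating every bipartition.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def naive_compare(l_ref, l_cmp):
    """Element-loop computation of C/G/PL/GR/PLR and the semantic SE."""
    consensus = {x for x in l_ref if x in l_cmp}
    gain = {x for x in l_cmp if x not in l_ref}
    loss = {x for x in l_ref if x not in l_cmp}
    n1, n2, ni = len(l_ref), len(l_cmp), len(consensus)
    gr = len(gain) / n2 if n2 else float("nan")
    plr = len(loss) / n1 if n1 else float("nan")
    if n1 == 0:
        se = 1.0
    elif n2 == 0:
        se = -1.0
    else:
        se = ni / n1 - ni / n2
    return {
        "consensus": consensus, "gain": gain, "potential_loss": loss,
        "gain_ratio": gr, "potential_loss_ratio": plr, "se": se,
    }


def signed_rank_two_sided_p(diffs):
    """Exact two-sided signed-rank p-value by enumerating all 2^n sign
    assignments (requires non-zero differences with distinct magnitudes)."""
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    w_all = []
    for mask in range(2 ** n):
        signs = np.array([(mask >> i) & 1 for i in range(n)])
        w_all.append(ranks[signs == 1].sum())
    w_all = np.asarray(w_all)
    p_low = np.mean(w_all <= w_obs)
    p_high = np.mean(w_all >= w_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


def best_bipartition_ss(values):
    """Minimum within-group sum of squares over every 2-group partition."""
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    idx = range(n)
    best = np.inf
    for size in range(1, n):
        for group in combinations(idx, size):
            g = np.array(group)
            mask = np.zeros(n, dtype=bool)
            mask[g] = True
            a, b = vals[mask], vals[~mask]
            ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            best = min(best, ss)
    return best


def within_group_ss(values, high_idx, low_idx):
    vals = np.asarray(values, dtype=float)
    ss = 0.0
    for group in (high_idx, low_idx):
        if group:
            g = vals[list(group)]
            ss += ((g - g.mean()) ** 2).sum()
    return ss
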