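"""Brute-force oracles for the small-sample statistics, independent of the
package's code paths: the observed statistics come from scipy, and the
permutation distributions are enumerated from scratch."""

import itertools

import numpy as np
from scipy.stats import rankdata, spearmanr


def spearman_oracle(x, y):
    """(r_s, two-tailed exact p) by full enumeration of pairings."""
    r_obs = spearmanr(x, y).statistic
    rx, ry = rankdata(x), rankdata(y)
    perms = np.array(list(itertools.permutations(ry)))
    xc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    r_all = (pc @ xc) / np.sqrt((pc**2).sum(axis=1) * (xc**2).sum())
    p = np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12)
    return float(r_obs), float(p)


def _u_stat(a, b):
    a = np.asarray(a)[:, None]
    b = np.asarray(b)[None, :]
    return float(np.sum(a > b) + 0.5 * np.sum(a == b))


def mann_whitney_oracle(a, b):
    """(U of first sample, two-tailed exact p) by assignment enumeration."""
    n1 = len(a)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    u_obs = _u_stat(a, b)
    center = n1 * (n - n1) / 2.0
    u_all = []
    for idx in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        u_all.append(_u_stat(pooled[mask], pooled[~mask]))
    u_all = np.array(u_all)
    p = np.mean(np.abs(u_all - center) >= abs(u_obs - center) - 1e-9)
    return u_obs, float(p)
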