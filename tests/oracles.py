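"""Independent brute-force / closed-form oracles used across the test suite.

These deliberately avoid the algorithms used by the package: repeats and
self-complements are found by explicit all-pairs extension, regression by
the normal equations, ANOVA by hand-computed sums of squares, and Pearson r
by the textbook formula.
"""

import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_longest_repeat(seq: str) -> int:
    """All-pairs longest common extension: O(n^2) pairs, naive matching."""
    n = len(seq)
    best = 0
    for i in range(n):
        for j in range(i + 1, n):
            k = 0
            while j + k < n and seq[i + k] == seq[j + k]:
                k += 1
            if k > best:
                best = k
    return best


def brute_longest_self_complement(seq: str) -> int:
    """Pair every substring end with every candidate rc start and extend."""
    n = len(seq)
    best = 0
    for end in range(n):          # last index of the forward substring
        for j in range(n):        # start of its reverse complement
            k = 0
            while end - k >= 0 and j + k < n and seq[j + k] == _COMP[seq[end - k]]:
                k += 1
            if k > best:
                best = k
    return best


def normal_equations_fit(x, y):
    """(slope, intercept) by the closed-form least-squares solution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    n = x.size
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def hand_anova(groups):
    """(F, df_between, df_within) from hand-computed sums of squares."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_b = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = all_vals.size - len(arrays)
    return (ss_b / df_b) / (ss_w / df_w), df_b, df_w


def textbook_pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = math.sqrt(n * (x * x).sum() - x.sum() ** 2) * math.sqrt(
        n * (y * y).sum() - y.sum() ** 2)
    return num / den
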