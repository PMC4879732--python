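"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — O(n^2) pair enumeration, explicit
branch walks, exhaustive permutation — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def kendall_tau_b(x, y) -> float:
    """Tau-b by explicit concordant/discordant pair counting."""
    x = list(x)
    y = list(y)
    n = len(x)
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = (x[i] - x[j]) * (y[i] - y[j])
            if s > 0:
                conc += 1
            elif s < 0:
                disc += 1
    n0 = n * (n - 1) // 2

    def tie_term(v):
        counts = {}
        for val in v:
            counts[val] = counts.get(val, 0) + 1
        return sum(c * (c - 1) // 2 for c in counts.values())

    n1, n2 = tie_term(x), tie_term(y)
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    return (conc - disc) / denom if denom else float("nan")


def _branches(tree):
    """(length, set of descendant tip names) for every non-root edge."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        out.append((node.length or 0.0, tips))
    return out


def faith_pd(tree, present: set) -> float:
    """Sum of branch lengths with at least one present descendant tip."""
    return sum(b for b, tips in _branches(tree) if tips & present)


def unweighted_unifrac(tree, present_a: set, present_b: set) -> float:
    shared = unique = 0.0
    for b, tips in _branches(tree):
        in_a, in_b = bool(tips & present_a), bool(tips & present_b)
        if in_a and in_b:
            shared += b
        elif in_a or in_b:
            unique += b
    total = shared + unique
    return unique / total if total else 0.0


def weighted_unifrac(tree, counts_a: dict, counts_b: dict, normalized: bool) -> float:
    ta, tb = sum(counts_a.values()), sum(counts_b.values())
    num = den = 0.0
    for b, tips in _branches(tree):
        pa = sum(counts_a.get(t, 0) for t in tips) / ta
        pb = sum(counts_b.get(t, 0) for t in tips) / tb
        num += b * abs(pa - pb)
        den += b * (pa + pb)
    if not normalized:
        return num
    return num / den if den else 0.0


def bh_adjust(p):
    """Step-up Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def permanova_f(d: np.ndarray, labels) -> float:
    """Pseudo-F from explicit within/between sums of squared distances."""
    labels = list(labels)
    n = len(labels)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    groups = sorted(set(labels))
    ss_within = 0.0
    for g in groups:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        ss_g = sum(
            d[i, j] ** 2 for ii, i in enumerate(idx) for j in idx[ii + 1:]
        )
        ss_within += ss_g / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova_exhaustive_p(d: np.ndarray, labels) -> float:
    """Exact permutation p over all distinct label arrangements."""
    labels = list(labels)
    f_obs = permanova_f(d, labels)
    seen = set()
    hits = total = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if permanova_f(d, list(perm)) >= f_obs - 1e-12:
            hits += 1
    return hits / total
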