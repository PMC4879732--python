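"""Permutational MANOVA (one-way PERMANOVA) on a distance matrix.

Pseudo-F from within/between-group squared distances, significance from
random label permutations with the +1 correction, so the smallest
attainable p with 999 permutations is 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

try:  # accepted as input, not required
    from skbio import DistanceMatrix as _SkbioDM
except ImportError:  # pragma: no cover
    _SkbioDM = None

__all__ = ["PermanovaResult", "permanova"]


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int
    n_samples: int
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "pseudo_F": self.pseudo_f,
            "p": self.p_value,
            "n_permutations": self.n_permutations,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "n": self.n_samples,
            "seed": self.seed,
        }


def _coerce_distances(dist) -> tuple[np.ndarray, list]:
    if _SkbioDM is not None and isinstance(dist, _SkbioDM):
        return dist.data.astype(float), list(dist.ids)
    if isinstance(dist, pd.DataFrame):
        return dist.to_numpy(dtype=float), list(dist.index)
    d = np.asarray(dist, dtype=float)
    return d, list(range(d.shape[0]))


def _ss_within(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    total = 0.0
    for idx in groups:
        sub = d2[np.ix_(idx, idx)]
        total += sub.sum() / (2.0 * idx.size)  # sum over i<j = sum/2
    return total


def permanova(
    dist,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA.

    ``SS_total = (1/N) sum_{i<j} d_ij^2``; ``SS_within`` sums the analogous
    per-group terms; ``pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a))``.
    The p-value is ``(#{F_perm >= F_obs} + 1) / (n_permutations + 1)``.

    Degenerate case: when every distance is zero there is no variation to
    partition; pseudo-F is NaN and p is 1.
    """
    d, ids = _coerce_distances(dist)
    n = d.shape[0]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    labels = pd.Series(np.asarray(labels), index=ids)
    if len(labels) != n:
        raise ValueError("label length does not match distance matrix")
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")

    codes, uniques = pd.factorize(labels)
    a = len(uniques)
    if a < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = uniques[int(np.argmin(sizes))]
        raise ValueError(f"group {small!r} has fewer than 2 members")

    d2 = d**2
    ss_total = d2.sum() / (2.0 * n)
    groups = [np.flatnonzero(codes == g) for g in range(a)]
    ss_within = _ss_within(d2, groups)
    ss_between = ss_total - ss_within
    df_between, df_within = a - 1, n - a

    if ss_total <= 1e-12:
        return PermanovaResult(
            pseudo_f=float("nan"),
            p_value=1.0,
            n_permutations=n_permutations,
            df_between=df_between,
            df_within=df_within,
            n_samples=n,
            seed=seed,
        )

    f_obs = (ss_between / df_between) / (ss_within / df_within)

    rng = np.random.default_rng(seed)
    perm = np.arange(n)
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(perm)
        perm_groups = [perm[idx] for idx in groups]
        ssw = _ss_within(d2, perm_groups)
        ssb = ss_total - ssw
        if ssw <= 1e-12:
            hits += 1  # infinite F ties or beats anything
            continue
        f_perm = (ssb / df_between) / (ssw / df_within)
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        df_between=df_between,
        df_within=df_within,
        n_samples=n,
        seed=seed,
    )
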