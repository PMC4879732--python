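"""Alpha diversity, UniFrac beta diversity, PCoA and trend fitting.

Alpha metrics (Shannon, Chao1, observed species, Faith's PD) and the two
UniFrac variants are computed per sample with scikit-bio; PCoA is a direct
eigendecomposition of the double-centred squared-distance matrix with a
deterministic sign convention and explicit negative-eigenvalue handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1, faith_pd, shannon

from .io_prep import GenusAbundanceTable

__all__ = [
    "alpha_diversity",
    "unifrac",
    "pcoa",
    "OrdinationResult",
    "polynomial_trend",
    "PolynomialTrend",
    "rarefy",
]

ALPHA_METRICS = ("shannon", "chao1", "observed_species", "pd_whole_tree")


def _check_tree_covers(tree: TreeNode, taxa: list[str]) -> None:
    leaves = {t.name for t in tree.tips()}
    missing = [t for t in taxa if t not in leaves]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing[:5]}")


def rarefy(
    table: GenusAbundanceTable, depth: int, seed: int | None = None
) -> GenusAbundanceTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    """
    if table.mode != "counts":
        raise ValueError("rarefaction needs a counts table")
    rng = np.random.default_rng(seed)
    counts = table.data.to_numpy(dtype=int)
    keep_rows, rare = [], []
    for i, row in enumerate(counts):
        total = row.sum()
        if total < depth:
            continue
        pool = np.repeat(np.arange(row.size), row)
        sub = rng.choice(pool, size=depth, replace=False)
        rare.append(np.bincount(sub, minlength=row.size))
        keep_rows.append(i)
    if len(keep_rows) < table.n_samples:
        warnings.warn(
            f"dropped {table.n_samples - len(keep_rows)} samples below "
            f"rarefaction depth {depth}",
            stacklevel=2,
        )
    df = pd.DataFrame(
        np.asarray(rare, dtype=int).reshape(len(keep_rows), -1),
        index=table.data.index[keep_rows],
        columns=table.data.columns,
    )
    return GenusAbundanceTable(df, "counts")


def alpha_diversity(
    table: GenusAbundanceTable,
    tree: TreeNode | None = None,
    metrics: tuple[str, ...] = ALPHA_METRICS,
    shannon_base: float = 2.0,
    rarefy_depth: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-sample alpha diversity.

    Shannon entropy is in bits by default (``shannon_base=2``); Chao1 uses
    the bias-corrected singleton/doubleton estimator
    ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))``; PD (whole tree) is the branch
    length of the minimal subtree spanning the root and the observed taxa
    and requires ``tree``.  Optional rarefaction is applied first.
    """
    if table.mode != "counts":
        raise ValueError("alpha diversity needs a counts table")
    unknown = [m for m in metrics if m not in ALPHA_METRICS]
    if unknown:
        raise ValueError(f"unknown metrics {unknown}")
    if "pd_whole_tree" in metrics and tree is None:
        raise ValueError("pd_whole_tree requested but no tree supplied")
    if rarefy_depth is not None:
        table = rarefy(table, rarefy_depth, seed=seed)
    taxa = table.taxon_ids
    if tree is not None:
        _check_tree_covers(tree, taxa)

    out = pd.DataFrame(index=table.data.index, columns=list(metrics), dtype=float)
    counts = table.data.to_numpy()
    for i, sid in enumerate(table.data.index):
        row = counts[i]
        if "shannon" in metrics:
            out.at[sid, "shannon"] = shannon(row, base=shannon_base)
        if "chao1" in metrics:
            out.at[sid, "chao1"] = chao1(row, bias_corrected=True)
        if "observed_species" in metrics:
            out.at[sid, "observed_species"] = float(np.count_nonzero(row))
        if "pd_whole_tree" in metrics:
            out.at[sid, "pd_whole_tree"] = faith_pd(row, taxa, tree)
    return out


def unifrac(
    table: GenusAbundanceTable,
    tree: TreeNode,
    weighted: bool = False,
    normalized: bool = True,
) -> DistanceMatrix:
    """Pairwise UniFrac distances between all samples.

    Unweighted UniFrac is the unshared fraction of observed branch length;
    weighted UniFrac sums branch-length-weighted abundance differences,
    normalised (by default) so distances lie in [0, 1].
    """
    if table.mode != "counts":
        raise ValueError("unifrac needs a counts table")
    totals = table.data.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    _check_tree_covers(tree, table.taxon_ids)
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": normalized} if weighted else {}
    return beta_diversity(
        metric,
        table.data.to_numpy(),
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree,
        **kwargs,
    )


@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates, eigenvalues, proportion explained."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dist: DistanceMatrix | pd.DataFrame | np.ndarray, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Eigendecomposition of the double-centred ``-D**2 / 2`` matrix.  Axes
    are ordered by descending eigenvalue; only positive-eigenvalue axes get
    coordinates.  Negative eigenvalues are reported but excluded from the
    proportion-explained denominator.  Sign convention: on each axis the
    largest-magnitude loading is positive.
    """
    if isinstance(dist, DistanceMatrix):
        ids = list(dist.ids)
        d = dist.data
    elif isinstance(dist, pd.DataFrame):
        ids = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        ids = [f"s{i}" for i in range(d.shape[0])]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals[np.abs(evals) < 1e-10 * max(1.0, np.abs(evals).max(initial=0.0))] = 0.0

    pos = evals > 0
    coords = np.zeros((n, int(pos.sum())))
    coords[:, :] = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    if n_axes is not None:
        coords = coords[:, :n_axes]
    denom = evals[pos].sum()
    prop = np.where(evals > 0, evals, 0.0) / denom if denom > 0 else np.zeros_like(evals)
    axis_names = [f"PC{k + 1}" for k in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=pd.Index(ids, name="sample_id"), columns=axis_names),
        eigenvalues=evals,
        proportion_explained=prop,
    )


@dataclass
class PolynomialTrend:
    """Least-squares polynomial fit of an alpha metric against age."""

    coefficients: np.ndarray  # highest power first
    r_squared: float
    degree: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(x, dtype=float))


def polynomial_trend(x, y, degree: int) -> PolynomialTrend:
    """Fit ``y ~ poly(x, degree)`` by least squares; returns fit and R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < degree + 1:
        raise ValueError("need at least degree+1 points")
    if degree >= 1 and np.unique(x).size < degree + 1:
        raise ValueError("degenerate design: too few distinct x values")
    coeffs = np.polyfit(x, y, degree)
    fitted = np.polyval(coeffs, x)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PolynomialTrend(coefficients=coeffs, r_squared=r2, degree=degree)
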