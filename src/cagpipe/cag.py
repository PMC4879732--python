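"""Co-abundance groups (CAGs): correlation, FDR, clustering, networks.

The core procedure: a genus x genus Kendall tau-b correlation matrix over
relative abundances, Storey q-value FDR control of the pairwise tests,
Ward clustering of genera (on 1 - Pearson correlation between their
tau-profile rows) into K CAGs, per-subject transition profiles (sums of
member-genus z-scores, summarised per age group), and the significant-edge
network retained at q < 0.05 and |tau| > 0.3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_prep import GenusAbundanceTable, prevalence

__all__ = [
    "CorrelationMatrix",
    "kendall_matrix",
    "estimate_qvalues",
    "CAGPartition",
    "cluster_genera",
    "label_cags",
    "TransitionProfile",
    "transition_profiles",
    "build_network",
    "NetworkResult",
]


@dataclass
class CorrelationMatrix:
    """Symmetric Kendall tau-b matrix with p- and q-values.

    ``excluded`` lists genera whose correlation is undefined (constant
    across samples); they carry NaN rows/columns and are skipped by the
    clustering step.
    """

    tau: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.tau.index)

    def defined_taxa(self) -> list[str]:
        return [t for t in self.tau.index if t not in set(self.excluded)]


def kendall_matrix(
    table: GenusAbundanceTable, exclude: tuple[str, ...] = ()
) -> CorrelationMatrix:
    """All-pairs Kendall tau-b over genera of a relative-abundance table.

    Tau-b applies the tie correction; p-values are two-sided, from the
    tie-corrected normal approximation (exact enumeration for n <= 9 and
    tie-free data, scipy's default switch).  Constant genera have no
    defined correlation: they are recorded in ``excluded`` with NaN
    entries and a warning.  ``exclude`` removes taxa (e.g. an unidentified
    catch-all group) before computing.
    """
    if table.mode != "relative":
        raise ValueError("kendall_matrix expects a relative-abundance table")
    data = table.data.drop(columns=list(exclude), errors="ignore")
    n, g = data.shape
    if n < 10:
        warnings.warn(
            f"only {n} samples: Kendall p-values will be unstable", stacklevel=2
        )
    cols = list(data.columns)
    x = data.to_numpy()
    constant = [c for i, c in enumerate(cols) if np.all(x[:, i] == x[0, i])]
    if constant:
        warnings.warn(
            f"{len(constant)} constant genera excluded from correlation: "
            f"{constant[:5]}",
            stacklevel=2,
        )
    const_set = set(constant)

    tau = np.full((g, g), np.nan)
    pval = np.full((g, g), np.nan)
    for i in range(g):
        if cols[i] in const_set:
            continue
        tau[i, i], pval[i, i] = 1.0, 0.0
        for j in range(i + 1, g):
            if cols[j] in const_set:
                continue
            res = stats.kendalltau(x[:, i], x[:, j])
            tau[i, j] = tau[j, i] = res.statistic
            pval[i, j] = pval[j, i] = res.pvalue

    tau_df = pd.DataFrame(tau, index=cols, columns=cols)
    p_df = pd.DataFrame(pval, index=cols, columns=cols)

    iu = np.triu_indices(g, k=1)
    flat_p = p_df.to_numpy()[iu]
    ok = ~np.isnan(flat_p)
    flat_q = np.full_like(flat_p, np.nan)
    if ok.any():
        flat_q[ok] = estimate_qvalues(flat_p[ok])
    qmat = np.full((g, g), np.nan)
    qmat[iu] = flat_q
    qmat.T[iu] = flat_q
    np.fill_diagonal(qmat, 0.0)
    for c in constant:
        k = cols.index(c)
        qmat[k, :] = qmat[:, k] = np.nan
    q_df = pd.DataFrame(qmat, index=cols, columns=cols)
    return CorrelationMatrix(tau=tau_df, p=p_df, q=q_df, excluded=constant)


def _pi0_smoother(p: np.ndarray) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a lambda grid, then a
    cubic smoothing spline evaluated at the largest lambda.
    """
    m = p.size
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0s = np.array(
        [np.count_nonzero(p > lam) / (m * (1.0 - lam)) for lam in lambdas]
    )
    try:
        spline = interpolate.UnivariateSpline(lambdas, pi0s, k=3)
        pi0 = float(spline(lambdas[-1]))
    except Exception:
        return 1.0
    return pi0


def estimate_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Storey q-values with smoother-based pi0 and a BH fallback.

    When the pi0 estimate falls outside (0, 1] it is reset to 1, which
    makes the q-values identical to Benjamini-Hochberg step-up adjusted
    p-values.  Monotonicity in p is enforced.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = _pi0_smoother(p) if m >= 100 else 1.0
    if not 0 < pi0 <= 1:
        pi0 = 1.0

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # enforce monotone in p
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


@dataclass
class CAGPartition:
    """Assignment of every (correlation-defined) genus to one CAG."""

    assignment: pd.Series  # genus -> cag id (1..K)
    k: int
    names: dict[int, str] = field(default_factory=dict)

    def members(self, cag_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cag_id])

    def display_name(self, cag_id: int) -> str:
        return self.names.get(cag_id, f"CAG {cag_id}")


def _pearson_of_tau_rows(tau: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between tau rows, self-entries excluded.

    For genera i, j the correlation is computed over all other genera's
    columns (i and j removed), vectorised via full-row sums minus the
    excluded terms.
    """
    g = tau.shape[0]
    if g < 3:
        raise ValueError("need at least 3 genera for tau-profile distances")
    s1 = tau.sum(axis=1)  # full row sums
    s2 = (tau**2).sum(axis=1)
    cross = tau @ tau.T
    n = g - 2

    tii = np.diag(tau)
    sx = s1[:, None] - tii[:, None] - tau  # row i minus cols i, j
    sy = s1[None, :] - tii[None, :] - tau
    sxx = s2[:, None] - tii[:, None] ** 2 - tau**2
    syy = s2[None, :] - tii[None, :] ** 2 - tau**2
    sxy = cross - tau * tii[None, :] - tau.T * tii[:, None]
    # subtract the (i,j)/(j,i) cross terms: rows are symmetric so tau works
    # cross[i,j] includes k=i: tau[i,i]*tau[j,i] and k=j: tau[i,j]*tau[j,j]
    num = n * sxy - sx * sy
    den = np.sqrt(np.maximum(n * sxx - sx**2, 0.0) * np.maximum(n * syy - sy**2, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def cluster_genera(
    corr: CorrelationMatrix, k: int, profile_distance: bool = True
) -> CAGPartition:
    """Ward clustering of genera into k CAGs.

    Distance between two genera defaults to ``1 - Pearson`` correlation of
    their tau-profile rows (self-entries excluded); ``profile_distance=False``
    uses ``1 - tau`` directly.  Ward linkage; the tree is cut to exactly k
    clusters and cluster ids are renumbered by first appearance in input
    order so the result is deterministic.
    """
    taxa = corr.defined_taxa()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(taxa):
        raise ValueError(f"k={k} exceeds the {len(taxa)} usable genera")
    tau = corr.tau.loc[taxa, taxa].to_numpy()
    if profile_distance:
        r = _pearson_of_tau_rows(tau)
        dist = 1.0 - r
    else:
        dist = 1.0 - tau
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    # renumber by first appearance for determinism
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    assignment = pd.Series(
        [remap[lab] for lab in raw], index=pd.Index(taxa, name="taxon_id"),
        name="cag_id",
    )
    return CAGPartition(assignment=assignment, k=k)


def label_cags(
    partition: CAGPartition, table: GenusAbundanceTable
) -> CAGPartition:
    """Name each CAG after its most abundant member genus.

    The member with the highest cohort-mean relative abundance lends its
    name ("<genus> CAG"); duplicates get a numeric suffix.
    """
    if table.mode != "relative":
        raise ValueError("label_cags expects a relative-abundance table")
    means = table.data.mean(axis=0)
    names: dict[int, str] = {}
    used: dict[str, int] = {}
    for cag_id in sorted(partition.assignment.unique()):
        members = partition.members(cag_id)
        dominant = means.loc[members].idxmax()
        base = f"{dominant} CAG"
        if base in used:
            used[base] += 1
            names[cag_id] = f"{base} ({used[base]})"
        else:
            used[base] = 1
            names[cag_id] = base
    return CAGPartition(
        assignment=partition.assignment, k=partition.k, names=names
    )


@dataclass
class TransitionProfile:
    """Per-subject CAG z-score sums and their per-age-group summaries."""

    profile: pd.DataFrame  # subjects x CAGs, summed member z-scores
    group_summary: pd.DataFrame  # age_group x cag: n, median, q1, q3
    outliers: pd.DataFrame  # sample, cag, age_group, value, severity


def transition_profiles(
    zscores: pd.DataFrame,
    partition: CAGPartition,
    metadata: pd.DataFrame,
) -> TransitionProfile:
    """Sum member-genus z-scores per subject per CAG; summarise by age group.

    Group summaries report median and quartiles; values outside
    ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`` are flagged mild outliers and outside
    the 3 IQR bounds extreme outliers, per age group and CAG.
    """
    missing = [g for g in partition.assignment.index if g not in zscores.columns]
    if missing:
        raise ValueError(f"z-score table lacks partition genera: {missing[:5]}")
    if "age_group" not in metadata.columns:
        raise ValueError("metadata lacks an age_group column")
    if not zscores.index.isin(metadata.index).all():
        raise ValueError("metadata missing for some profiled samples")

    cag_ids = sorted(partition.assignment.unique())
    cols = {}
    for cag_id in cag_ids:
        cols[partition.display_name(cag_id)] = zscores[
            partition.members(cag_id)
        ].sum(axis=1)
    profile = pd.DataFrame(cols, index=zscores.index)

    groups = metadata.loc[profile.index, "age_group"]
    rows, outlier_rows = [], []
    for grp, idx in profile.groupby(groups).groups.items():
        sub = profile.loc[idx]
        for cag_name in profile.columns:
            vals = sub[cag_name]
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            rows.append(
                {
                    "age_group": grp,
                    "cag": cag_name,
                    "n": len(vals),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                }
            )
            lo_m, hi_m = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            lo_x, hi_x = q1 - 3.0 * iqr, q3 + 3.0 * iqr
            for sid, v in vals.items():
                if v < lo_x or v > hi_x:
                    sev = "extreme"
                elif v < lo_m or v > hi_m:
                    sev = "mild"
                else:
                    continue
                outlier_rows.append(
                    {
                        "sample_id": sid,
                        "cag": cag_name,
                        "age_group": grp,
                        "value": v,
                        "severity": sev,
                    }
                )
    summary = pd.DataFrame(rows)
    outliers = pd.DataFrame(
        outlier_rows,
        columns=["sample_id", "cag", "age_group", "value", "severity"],
    )
    return TransitionProfile(
        profile=profile, group_summary=summary, outliers=outliers
    )


@dataclass
class NetworkResult:
    """Significant-correlation network: edges, node attributes, census."""

    edges: pd.DataFrame  # source, target, tau, q, sign
    nodes: pd.DataFrame  # taxon: mean_rel_abundance, prevalence, cag, displayed
    summary: dict


def build_network(
    corr: CorrelationMatrix,
    table: GenusAbundanceTable,
    partition: CAGPartition | None = None,
    q_threshold: float = 0.05,
    tau_cutoff: float = 0.3,
    prevalence_threshold: float = 0.5,
) -> NetworkResult:
    """Edge list of genus pairs with q < 0.05 and |tau| strictly > 0.3.

    Node attributes carry cohort-mean relative abundance (node size),
    prevalence, CAG membership, and a ``displayed`` flag restricted to taxa
    found in more than half of the subjects.  The summary counts connected
    genera and positive/negative edges.
    """
    if table.mode != "relative":
        raise ValueError("build_network expects a relative-abundance table")
    taxa = corr.defined_taxa()
    tau = corr.tau.loc[taxa, taxa].to_numpy()
    q = corr.q.loc[taxa, taxa].to_numpy()
    iu = np.triu_indices(len(taxa), k=1)
    keep = (q[iu] < q_threshold) & (np.abs(tau[iu]) > tau_cutoff)
    rows = []
    for a, b in zip(iu[0][keep], iu[1][keep]):
        t = tau[a, b]
        rows.append(
            {
                "source": taxa[a],
                "target": taxa[b],
                "tau": t,
                "q": q[a, b],
                "sign": "positive" if t > 0 else "negative",
            }
        )
    edges = pd.DataFrame(rows, columns=["source", "target", "tau", "q", "sign"])

    prev = prevalence(table)
    nodes = pd.DataFrame(
        {
            "mean_rel_abundance": table.data.mean(axis=0),
            "prevalence": prev,
            "displayed": prev > prevalence_threshold,
        }
    )
    nodes.index.name = "taxon_id"
    if partition is not None:
        nodes["cag_id"] = partition.assignment.reindex(nodes.index)
    connected = (
        set(edges["source"]).union(edges["target"]) if len(edges) else set()
    )
    summary = {
        "n_connected_genera": len(connected),
        "n_edges": int(len(edges)),
        "n_positive_edges": int((edges["sign"] == "positive").sum()),
        "n_negative_edges": int((edges["sign"] == "negative").sum()),
    }
    return NetworkResult(edges=edges, nodes=nodes, summary=summary)
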