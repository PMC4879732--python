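"""Ward clustering of subjects and the intergroup statistics around it.

Subjects are clustered on their (z-scored) genus abundance profiles with
Ward's method on squared Euclidean distances, cut into k clusters (3 and 5
are the interesting solutions), labelled by life stage from cluster median
ages, and screened for mismatched-age members.  Per-genus Mann-Whitney
tests and an exact / Monte-Carlo Fisher test on the sex x group table
round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import gammaln

__all__ = [
    "SubjectPartition",
    "cluster_subjects",
    "life_stage_of_age",
    "cluster_age_summary",
    "detect_mismatches",
    "intergroup_genus_tests",
    "kruskal_screen",
    "gender_distribution_test",
]

#: Life-stage age boundaries (years): below 20 infant/maturing, 70 and
#: above elderly.  These are the cohort's observed transition points.
INFANT_BELOW = 20.0
ELDERLY_FROM = 70.0


def life_stage_of_age(age_years: float) -> str:
    if age_years < INFANT_BELOW:
        return "infant"
    if age_years >= ELDERLY_FROM:
        return "elderly"
    return "adult"


@dataclass
class SubjectPartition:
    """Sample -> cluster assignment with per-cluster life-stage labels."""

    assignment: pd.Series  # sample -> cluster id (1..k)
    k: int
    stage_labels: dict[int, str] = field(default_factory=dict)
    linkage: np.ndarray | None = None

    def members(self, cluster_id: int) -> pd.Index:
        return self.assignment.index[self.assignment == cluster_id]

    def stage_of(self, cluster_id: int) -> str:
        return self.stage_labels.get(cluster_id, f"cluster {cluster_id}")


def subject_linkage(data: pd.DataFrame) -> np.ndarray:
    """Ward merge tree over subjects (squared-Euclidean objective).

    The same tree serves every k, so the 3- and 5-cluster solutions are
    nested cuts of one dendrogram.
    """
    x = np.ascontiguousarray(data.to_numpy(dtype=float))
    return hierarchy.linkage(x, method="ward")


def cluster_subjects(
    data: pd.DataFrame,
    k: int,
    metadata: pd.DataFrame | None = None,
    linkage: np.ndarray | None = None,
) -> SubjectPartition:
    """Cut the subject Ward tree into k clusters.

    ``data`` is a subjects x genera matrix (z-scored relative abundances
    by default upstream).  Cluster ids are renumbered by first appearance
    in sample order.  When metadata with ages is given, clusters get
    life-stage labels from their median age (< 20 infant, 20-69 adult,
    >= 70 elderly), with Roman-numeral suffixes when a stage repeats
    (ordered by median age).
    """
    n = data.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} subjects")
    if linkage is None:
        linkage = subject_linkage(data)
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    assignment = pd.Series(
        [remap[lab] for lab in raw],
        index=data.index.rename("sample_id"),
        name="cluster_id",
    )
    stage_labels: dict[int, str] = {}
    if metadata is not None:
        ages = metadata.loc[assignment.index, "age_years"]
        medians = {
            cid: float(ages[assignment == cid].median())
            for cid in sorted(assignment.unique())
        }
        stages = {cid: life_stage_of_age(m) for cid, m in medians.items()}
        for stage in ("infant", "adult", "elderly"):
            cids = sorted(
                (c for c, s in stages.items() if s == stage),
                key=lambda c: medians[c],
            )
            if len(cids) == 1:
                stage_labels[cids[0]] = stage
            else:
                numerals = ["I", "II", "III", "IV", "V", "VI"]
                for rank, cid in enumerate(cids):
                    stage_labels[cid] = f"{stage} {numerals[rank]}"
    return SubjectPartition(
        assignment=assignment, k=k, stage_labels=stage_labels, linkage=linkage
    )


def cluster_age_summary(
    partition: SubjectPartition, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster n, median age and interquartile range.

    Quartiles use the linear-interpolation convention, which yields
    fractional values like 24.75 on even-sized clusters.
    """
    ages = metadata.loc[partition.assignment.index, "age_years"]
    rows = []
    for cid in sorted(partition.assignment.unique()):
        a = ages[partition.assignment == cid].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(a, [25, 50, 75])
        rows.append(
            {
                "cluster_id": cid,
                "stage": partition.stage_of(cid),
                "n": a.size,
                "median_age": med,
                "q1": q1,
                "q3": q3,
            }
        )
    return pd.DataFrame(rows).set_index("cluster_id")


def detect_mismatches(
    partition: SubjectPartition, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subjects whose own life stage differs from their cluster's label.

    Returns ``(mismatches, per_cluster_counts)``.  A cluster labelled e.g.
    "adult II" counts as the "adult" stage.
    """
    if not partition.stage_labels:
        raise ValueError("partition has no life-stage labels; pass metadata to cluster_subjects")
    rows = []
    for sid, cid in partition.assignment.items():
        age = float(metadata.loc[sid, "age_years"])
        own = life_stage_of_age(age)
        cluster_stage = partition.stage_of(cid).split()[0]
        if own != cluster_stage:
            rows.append(
                {
                    "sample_id": sid,
                    "age_years": age,
                    "age_group": metadata.loc[sid].get("age_group", ""),
                    "life_stage": own,
                    "cluster_id": cid,
                    "cluster_stage": partition.stage_of(cid),
                }
            )
    mism = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "age_years", "age_group", "life_stage",
            "cluster_id", "cluster_stage",
        ],
    )
    counts = (
        mism.groupby("cluster_id").size()
        if len(mism)
        else pd.Series(dtype=int)
    )
    per_cluster = pd.DataFrame(
        {
            "n_members": partition.assignment.value_counts().sort_index(),
            "n_mismatched": counts.reindex(
                sorted(partition.assignment.unique()), fill_value=0
            ),
        }
    )
    per_cluster.index.name = "cluster_id"
    return mism, per_cluster


def intergroup_genus_tests(
    table,
    partition: SubjectPartition,
    pair: tuple[int, int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per genus between two subject clusters.

    Uses the tie-corrected normal approximation; reports raw p and
    BH-adjusted q, flagging significance at ``alpha`` on the raw p (the
    historical convention) with the adjusted call alongside.
    """
    a_idx = partition.members(pair[0])
    b_idx = partition.members(pair[1])
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("each cluster needs at least 2 members")
    data = table.data if hasattr(table, "data") else table
    rows = []
    for genus in data.columns:
        x = data.loc[a_idx, genus].to_numpy(dtype=float)
        y = data.loc[b_idx, genus].to_numpy(dtype=float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            u, p = len(x) * len(y) / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
        rows.append({"taxon_id": genus, "U": u, "p": p})
    out = pd.DataFrame(rows).set_index("taxon_id")
    out["q_bh"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    out["significant"] = out["p"] < alpha
    return out


def kruskal_screen(table, partition: SubjectPartition) -> pd.DataFrame:
    """Kruskal-Wallis screen of each genus across all clusters.

    Convenience alternative to effect-size-based taxon screening; not a
    discriminant analysis.
    """
    data = table.data if hasattr(table, "data") else table
    groups = [
        data.loc[partition.members(cid)] for cid in sorted(partition.assignment.unique())
    ]
    rows = []
    for genus in data.columns:
        samples = [g[genus].to_numpy(dtype=float) for g in groups]
        if all(np.all(s == samples[0][0]) for s in samples):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
        rows.append({"taxon_id": genus, "H": h, "p": p})
    out = pd.DataFrame(rows).set_index("taxon_id")
    out["q_bh"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out


def _log_table_prob(males: np.ndarray, totals: np.ndarray, m_total: int) -> float:
    """Log probability of an R x 2 table under fixed margins.

    P = prod_r C(n_r, m_r) / C(N, M) — the multivariate hypergeometric of
    the male column conditioned on all margins.
    """
    n = int(totals.sum())

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return float(np.sum(logc(totals, males)) - logc(n, m_total))


def gender_distribution_test(
    metadata: pd.DataFrame,
    grouping: str = "age_group",
    n_replicates: int = 10000,
    seed: int | None = None,
) -> dict:
    """Fisher test of sex distribution across groups.

    2 x 2 tables use the exact test; R x 2 tables use a Monte-Carlo Fisher
    test conditional on both margins with the probability-ordering
    criterion (a table counts as at least as extreme when its conditional
    probability does not exceed the observed one).  The estimate comes
    with its binomial standard error.
    """
    tab = pd.crosstab(metadata[grouping], metadata["sex"])
    for col in ("male", "female"):
        if col not in tab.columns:
            tab[col] = 0
    tab = tab[["male", "female"]]
    zero = tab.sum(axis=1) == 0
    if zero.any():
        import warnings

        warnings.warn(f"dropping zero-margin groups {list(tab.index[zero])}", stacklevel=2)
        tab = tab[~zero]
    if tab.shape[0] < 2:
        raise ValueError("need at least two groups with members")
    if tab.shape[0] == 2:
        _, p = stats.fisher_exact(tab.to_numpy(), alternative="two-sided")
        return {"p": float(p), "se": 0.0, "method": "exact", "table": tab}

    totals = tab.sum(axis=1).to_numpy()
    males = tab["male"].to_numpy()
    m_total = int(males.sum())
    obs_logp = _log_table_prob(males, totals, m_total)

    rng = np.random.default_rng(seed)
    pool = np.zeros(int(totals.sum()), dtype=np.int8)
    pool[:m_total] = 1
    starts = np.concatenate([[0], np.cumsum(totals)])
    hits = 0
    for _ in range(n_replicates):
        rng.shuffle(pool)
        sim_males = np.array(
            [pool[starts[r]: starts[r + 1]].sum() for r in range(len(totals))]
        )
        if _log_table_prob(sim_males, totals, m_total) <= obs_logp + 1e-9:
            hits += 1
    p = (hits + 1) / (n_replicates + 1)
    se = float(np.sqrt(p * (1 - p) / n_replicates))
    return {"p": float(p), "se": se, "method": "monte_carlo", "table": tab}
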