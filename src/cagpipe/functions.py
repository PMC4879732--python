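"""Simplified gene-content (transporter) projection.

A database-free analogue of 16S-based function prediction: taxon counts
are corrected by 16S rRNA copy number, projected through a taxon x
function gene-content matrix, and the predicted transporter profiles are
renormalised per sample.  Functions are then Ward-clustered into
age-associated groups and the drug-transporter census per group reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io_prep import GenusAbundanceTable
from .subjects import life_stage_of_age

__all__ = [
    "normalize_by_copy_number",
    "project_functions",
    "FunctionProfile",
    "cluster_function_profiles",
    "FunctionClustering",
]


def normalize_by_copy_number(
    table: GenusAbundanceTable, copy_numbers: pd.Series
) -> GenusAbundanceTable:
    """Divide each taxon's counts by its 16S copy number."""
    if table.mode != "counts":
        raise ValueError("copy-number correction applies to counts")
    missing = [t for t in table.taxon_ids if t not in copy_numbers.index]
    if missing:
        raise ValueError(f"missing copy number for taxa: {missing[:5]}")
    cn = copy_numbers.loc[table.taxon_ids].astype(float)
    if (cn <= 0).any():
        bad = cn.index[cn <= 0][0]
        raise ValueError(f"non-positive copy number for taxon {bad!r}")
    return GenusAbundanceTable(table.data / cn, "counts")


@dataclass
class FunctionProfile:
    """Predicted function abundances per sample.

    ``raw`` is the plain projection; ``relative`` renormalises each sample
    over the transporter subset so rows sum to 1.
    """

    raw: pd.DataFrame
    relative: pd.DataFrame
    catalog: pd.DataFrame


def project_functions(
    table: GenusAbundanceTable,
    content: pd.DataFrame,
    catalog: pd.DataFrame | None = None,
) -> FunctionProfile:
    """Project (copy-number-corrected) taxon abundances to functions.

    The raw profile is the matrix product (samples x taxa)(taxa x
    functions).  The relative profile renormalises over the transporter
    functions (all functions whose catalog category mentions
    "transporter"; everything, when no catalog is given).
    """
    missing = [t for t in table.taxon_ids if t not in content.index]
    if missing:
        raise ValueError(f"content matrix lacks taxa: {missing[:5]}")
    c = content.loc[table.taxon_ids]
    if (c.to_numpy() < 0).any():
        raise ValueError("gene-content matrix has negative entries")
    raw = table.data.to_numpy() @ c.to_numpy(dtype=float)
    raw_df = pd.DataFrame(raw, index=table.data.index, columns=content.columns)

    if catalog is not None:
        transporter = catalog["category"].str.contains("transporter", case=False)
        subset = list(catalog.index[transporter])
    else:
        subset = list(content.columns)
    sub = raw_df[subset]
    sums = sub.sum(axis=1)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(f"sample {bad!r} has zero predicted transporter content")
    rel = sub.div(sums, axis=0)
    cat = (
        catalog.loc[subset]
        if catalog is not None
        else pd.DataFrame(index=pd.Index(subset, name="function_id"))
    )
    return FunctionProfile(raw=raw_df, relative=rel, catalog=cat)


@dataclass
class FunctionClustering:
    """Ward clustering of functions plus enrichment and drug census."""

    assignment: pd.Series  # function -> cluster id
    cluster_enrichment: pd.DataFrame  # per cluster: enriched stratum + label
    drug_census: pd.DataFrame  # per cluster: n_functions, n_drug, fraction


def cluster_function_profiles(
    profile: FunctionProfile,
    metadata: pd.DataFrame,
    k: int = 2,
) -> FunctionClustering:
    """Ward-cluster functions by their across-sample z-score profiles.

    Each function's relative abundance is z-scored across samples; the
    function x sample rows are Ward-clustered into k groups.  Per cluster,
    mean z-scores within the infant / adult / elderly strata decide the
    enrichment label ("adult-enriched" when the adult stratum leads,
    otherwise "infant/elderly-enriched"), and the census reports how many
    drug-transporter-flagged functions land in each cluster.
    """
    rel = profile.relative
    n_fun = rel.shape[1]
    if k < 1 or k > n_fun:
        raise ValueError(f"k={k} out of range for {n_fun} functions")
    mean = rel.mean(axis=0)
    sd = rel.std(axis=0, ddof=1).replace(0, 1.0)
    z = (rel - mean) / sd  # samples x functions

    x = np.ascontiguousarray(z.to_numpy().T)  # functions as observations
    if k == n_fun:
        raw = np.arange(1, n_fun + 1)
    elif k == 1:
        raw = np.ones(n_fun, dtype=int)
    else:
        linkage = hierarchy.linkage(x, method="ward")
        raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    assignment = pd.Series(
        [remap[lab] for lab in raw],
        index=rel.columns.rename("function_id"),
        name="cluster_id",
    )

    stages = metadata.loc[rel.index, "age_years"].map(life_stage_of_age)
    rows, census_rows = [], []
    is_drug = (
        profile.catalog["is_drug_transporter"]
        if "is_drug_transporter" in profile.catalog.columns
        else pd.Series(False, index=rel.columns)
    )
    for cid in sorted(assignment.unique()):
        funcs = assignment.index[assignment == cid]
        zc = z[funcs].mean(axis=1)  # per-sample mean z over cluster functions
        stage_means = zc.groupby(stages).mean()
        infant = float(stage_means.get("infant", np.nan))
        adult = float(stage_means.get("adult", np.nan))
        elderly = float(stage_means.get("elderly", np.nan))
        ie = np.nanmean([infant, elderly])
        label = "adult-enriched" if adult > ie else "infant/elderly-enriched"
        rows.append(
            {
                "cluster_id": cid,
                "mean_z_infant": infant,
                "mean_z_adult": adult,
                "mean_z_elderly": elderly,
                "label": label,
            }
        )
        n_drug = int(is_drug.reindex(funcs).fillna(False).sum())
        census_rows.append(
            {
                "cluster_id": cid,
                "n_functions": len(funcs),
                "n_drug_transporters": n_drug,
            }
        )
    enrichment = pd.DataFrame(rows).set_index("cluster_id")
    census = pd.DataFrame(census_rows).set_index("cluster_id")
    total_drug = census["n_drug_transporters"].sum()
    census["fraction_of_drug_transporters"] = (
        census["n_drug_transporters"] / total_drug if total_drug else 0.0
    )
    return FunctionClustering(
        assignment=assignment, cluster_enrichment=enrichment, drug_census=census
    )
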