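"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes prep -> diversity -> CAG -> subject clustering ->
PERMANOVA -> function projection on a cohort (real or simulated), writes
every stage artifact as TSV into one output directory together with the
effective config, and returns a JSON-able summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from . import cag as cagmod
from . import diversity as divmod_
from . import functions as funmod
from . import io_prep, synthetic
from .permanova import permanova
from .subjects import (
    cluster_age_summary,
    cluster_subjects,
    detect_mismatches,
    gender_distribution_test,
    intergroup_genus_tests,
    subject_linkage,
)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_cohort"]


@dataclass
class PipelineConfig:
    """All stage parameters of a pipeline run."""

    # inputs; None means simulate
    table_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    gene_content_path: str | None = None
    copy_number_path: str | None = None
    catalog_path: str | None = None
    # simulation
    simulate: bool = True
    n_genera: int = 186
    n_blocks: int = 9
    rho_within: float = 0.8
    effect_size: float = 2.0
    n_functions: int = 64
    # stage parameters
    k_cag: int = 9
    k_subjects: tuple[int, ...] = (3, 5)
    edge_tau_cutoff: float = 0.3
    edge_q_threshold: float = 0.05
    prevalence_threshold: float = 0.5
    n_permutations: int = 999
    exclude_taxa: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.k_subjects, list):
            cfg.k_subjects = tuple(cfg.k_subjects)
        if isinstance(cfg.exclude_taxa, list):
            cfg.exclude_taxa = tuple(cfg.exclude_taxa)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["k_subjects"] = list(self.k_subjects)
        d["exclude_taxa"] = list(self.exclude_taxa)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def simulate_cohort(config: PipelineConfig):
    """Generate the synthetic cohort a config describes."""
    design = synthetic.default_design()
    gen = synthetic.GeneratorConfig(
        n_genera=config.n_genera,
        design=design,
        blocks=None,
        seed=config.seed,
    )
    genus_ids = gen.genus_ids()
    blocks = synthetic.default_blocks(
        genus_ids,
        n_blocks=config.n_blocks,
        rho_within=config.rho_within,
        effect_size=config.effect_size,
    )
    gen = synthetic.GeneratorConfig(
        n_genera=config.n_genera, design=design, blocks=blocks, seed=config.seed
    )
    metadata = synthetic.sample_metadata(design, seed=config.seed)
    table = synthetic.sample_genus_counts(gen, metadata)
    tree = synthetic.sample_tree(genus_ids, seed=config.seed + 1)
    content, copy_numbers, catalog = synthetic.sample_gene_content(
        genus_ids, config.n_functions, seed=config.seed + 2, blocks=blocks
    )
    return table, metadata, tree, content, copy_numbers, catalog


def _load_inputs(config: PipelineConfig):
    table = io_prep.read_table(config.table_path)
    metadata = io_prep.read_metadata(config.metadata_path)
    tree = content = copy_numbers = catalog = None
    if config.tree_path:
        tree = TreeNode.read(config.tree_path)
    if config.gene_content_path:
        content = pd.read_csv(config.gene_content_path, sep="\t", index_col=0)
    if config.copy_number_path:
        copy_numbers = pd.read_csv(
            config.copy_number_path, sep="\t", index_col=0
        ).iloc[:, 0]
    if config.catalog_path:
        catalog = pd.read_csv(config.catalog_path, sep="\t", index_col=0)
    return table, metadata, tree, content, copy_numbers, catalog


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage; write artifacts and a JSON summary to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    stage = "inputs"
    try:
        if config.simulate:
            (table, metadata, tree, content, copy_numbers, catalog) = (
                simulate_cohort(config)
            )
        else:
            (table, metadata, tree, content, copy_numbers, catalog) = (
                _load_inputs(config)
            )
        io_prep.write_table(table, outdir / "genus_counts.tsv")
        io_prep.write_metadata(metadata, outdir / "metadata.tsv")
        if tree is not None:
            tree.write(str(outdir / "genus_tree.nwk"))

        stage = "prep"
        rel = io_prep.to_relative(table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            zs = io_prep.zscore_table(rel)

        stage = "diversity"
        alpha_metrics = (
            ("shannon", "chao1", "observed_species", "pd_whole_tree")
            if tree is not None
            else ("shannon", "chao1", "observed_species")
        )
        alpha = divmod_.alpha_diversity(table, tree=tree, metrics=alpha_metrics)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        trend = divmod_.polynomial_trend(
            metadata.loc[alpha.index, "age_years"], alpha["shannon"], degree=3
        )
        ordination = None
        if tree is not None:
            dm = divmod_.unifrac(table, tree, weighted=True, normalized=True)
            pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
                outdir / "weighted_unifrac.tsv", sep="\t"
            )
            ordination = divmod_.pcoa(dm)
            ordination.coordinates.iloc[:, :10].to_csv(
                outdir / "pcoa_coordinates.tsv", sep="\t"
            )

        stage = "cag"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = cagmod.kendall_matrix(rel, exclude=config.exclude_taxa)
        long = corr.tau.where(np.triu(np.ones(corr.tau.shape, dtype=bool), k=1))
        long = long.stack().rename("tau").reset_index()
        long.columns = ["taxon_a", "taxon_b", "tau"]
        long["p"] = [
            corr.p.at[a, b] for a, b in zip(long["taxon_a"], long["taxon_b"])
        ]
        long["q"] = [
            corr.q.at[a, b] for a, b in zip(long["taxon_a"], long["taxon_b"])
        ]
        long.to_csv(outdir / "kendall_correlations.tsv", sep="\t", index=False)

        partition = cagmod.cluster_genera(corr, k=config.k_cag)
        partition = cagmod.label_cags(partition, rel)
        partition.assignment.to_frame().assign(
            cag_name=[
                partition.display_name(c) for c in partition.assignment
            ]
        ).to_csv(outdir / "cag_partition.tsv", sep="\t")

        profile = cagmod.transition_profiles(zs, partition, metadata)
        profile.profile.to_csv(outdir / "transition_profiles.tsv", sep="\t")
        profile.group_summary.to_csv(
            outdir / "transition_group_summary.tsv", sep="\t", index=False
        )
        network = cagmod.build_network(
            corr,
            rel,
            partition,
            q_threshold=config.edge_q_threshold,
            tau_cutoff=config.edge_tau_cutoff,
            prevalence_threshold=config.prevalence_threshold,
        )
        network.edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        network.nodes.to_csv(outdir / "network_nodes.tsv", sep="\t")

        stage = "subject_clustering"
        linkage = subject_linkage(zs)
        cluster_results = {}
        for k in config.k_subjects:
            part = cluster_subjects(zs, k, metadata=metadata, linkage=linkage)
            summary_k = cluster_age_summary(part, metadata)
            mism, per_cluster = detect_mismatches(part, metadata)
            part.assignment.to_frame().to_csv(
                outdir / f"subject_clusters_k{k}.tsv", sep="\t"
            )
            summary_k.to_csv(outdir / f"cluster_age_summary_k{k}.tsv", sep="\t")
            mism.to_csv(outdir / f"mismatched_subjects_k{k}.tsv", sep="\t", index=False)
            cluster_results[k] = {
                "age_summary": {
                    str(cid): {
                        "stage": row["stage"],
                        "n": int(row["n"]),
                        "median_age": float(row["median_age"]),
                        "q1": float(row["q1"]),
                        "q3": float(row["q3"]),
                    }
                    for cid, row in summary_k.iterrows()
                },
                "n_mismatched": int(len(mism)),
            }
        gender = gender_distribution_test(
            metadata, grouping="age_group", seed=config.seed
        )

        stage = "permanova"
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(profile.profile.to_numpy()))
        perm = permanova(
            pd.DataFrame(d, index=profile.profile.index, columns=profile.profile.index),
            metadata.loc[profile.profile.index, "age_group"],
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        with open(outdir / "permanova.json", "w") as fh:
            json.dump(perm.as_dict(), fh, indent=2)

        stage = "functions"
        functions_summary = None
        if content is not None:
            corrected = funmod.normalize_by_copy_number(table, copy_numbers)
            fprofile = funmod.project_functions(corrected, content, catalog)
            fprofile.relative.to_csv(outdir / "function_profiles.tsv", sep="\t")
            fclust = funmod.cluster_function_profiles(fprofile, metadata, k=2)
            fclust.assignment.to_frame().to_csv(
                outdir / "function_clusters.tsv", sep="\t"
            )
            fclust.drug_census.to_csv(outdir / "drug_census.tsv", sep="\t")
            census = fclust.drug_census
            enr = fclust.cluster_enrichment
            functions_summary = {
                "cluster_labels": {
                    str(c): enr.at[c, "label"] for c in enr.index
                },
                "drug_census": {
                    str(c): int(census.at[c, "n_drug_transporters"])
                    for c in census.index
                },
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "n_samples": table.n_samples,
        "n_genera": table.n_taxa,
        "n_cags": int(partition.k),
        "cag_names": {
            str(c): partition.display_name(c)
            for c in sorted(partition.assignment.unique())
        },
        "network": network.summary,
        "shannon_trend_r2": round(trend.r_squared, 6),
        "gender_test_p": round(gender["p"], 6),
        "subject_clusters": cluster_results,
        "permanova": {
            "pseudo_F": round(perm.pseudo_f, 6),
            "p": perm.p_value,
            "n_permutations": perm.n_permutations,
        },
        "functions": functions_summary,
        "seed": config.seed,
    }
    if ordination is not None:
        summary["pcoa_pc1_fraction"] = round(
            float(ordination.proportion_explained[0]), 6
        )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
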