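"""Synthetic age-structured gut-microbiota cohorts.

Generates cohorts with the statistical structure the downstream analysis
assumes: a 14-group cross-sectional age design spanning preweaning infants
to centenarians, genus abundances with block-diagonal latent correlation
(the planted co-abundance groups), life-stage trends in block means, and
realistic per-sample sequencing depth.  Also produces a random genus
phylogeny and a toy transporter gene-content matrix so that phylogenetic
diversity and function-projection stages are testable without any external
reference data.

Model
-----
Per sample with age ``a``, a latent Gaussian vector over genera is drawn:

    z_g = b_g + effect_size * t_{block(g)}(a) + sqrt(rho) * u_{block(g)}
          + sqrt(1 - rho) * eps_g

with ``b_g`` a fixed per-genus baseline (log-scale rank-abundance),
``t_k`` a piecewise-linear life-stage trend with knots at ages 3, 20 and
70 years, ``u_k`` a shared block factor and ``eps_g`` independent noise.
The composition is ``softmax(z)`` and counts are multinomial at a depth
drawn from a truncated normal.  This logistic-normal / multinomial scheme
yields both the compositional constraint and tunable within-block Kendall
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .io_prep import GenusAbundanceTable

__all__ = [
    "AgeGroup",
    "AgeGroupDesign",
    "CAGBlockSpec",
    "DepthModel",
    "GeneratorConfig",
    "default_design",
    "default_blocks",
    "sample_metadata",
    "sample_genus_counts",
    "sample_tree",
    "sample_gene_content",
    "life_stage_weights",
    "TREND_TYPES",
]

TREND_TYPES = (
    "infant_high",
    "adult_high",
    "elderly_high",
    "infant_and_elderly_high",
    "flat",
)


@dataclass(frozen=True)
class AgeGroup:
    label: str
    age_low: float
    age_high: float
    n_male: int
    n_female: int
    feeding_stage: str = "n/a"

    def __post_init__(self) -> None:
        if self.age_low > self.age_high:
            raise ValueError(f"group {self.label!r}: age_low > age_high")
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError(f"group {self.label!r}: negative sample count")


@dataclass(frozen=True)
class AgeGroupDesign:
    """Ordered age-group layout of a cross-sectional cohort."""

    groups: tuple[AgeGroup, ...]

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels in design")

    @property
    def n_samples(self) -> int:
        return sum(g.n_male + g.n_female for g in self.groups)

    @property
    def n_male(self) -> int:
        return sum(g.n_male for g in self.groups)

    @property
    def n_female(self) -> int:
        return sum(g.n_female for g in self.groups)


def default_design() -> AgeGroupDesign:
    """The 371-subject, 14-group design (158 male / 213 female).

    Infant groups are defined by weaning status, not age alone; later
    groups are decade bins with all subjects >= 100 pooled.
    """
    rows = [
        # label, lo, hi, male, female, feeding
        ("1", 0.1, 0.6, 7, 7, "preweaning"),
        ("2", 0.4, 1.5, 6, 6, "weaning"),
        ("3", 1.5, 3.9, 10, 8, "weaned"),
        ("4", 4.0, 9.9, 6, 8, "n/a"),
        ("10", 10.0, 19.9, 7, 3, "n/a"),
        ("20", 20.0, 29.9, 16, 24, "n/a"),
        ("30", 30.0, 39.9, 45, 43, "n/a"),
        ("40", 40.0, 49.9, 13, 21, "n/a"),
        ("50", 50.0, 59.9, 12, 13, "n/a"),
        ("60", 60.0, 69.9, 11, 17, "n/a"),
        ("70", 70.0, 79.9, 5, 10, "n/a"),
        ("80", 80.0, 89.9, 16, 32, "n/a"),
        ("90", 90.0, 99.9, 4, 15, "n/a"),
        ("100", 100.0, 104.0, 0, 6, "n/a"),
    ]
    return AgeGroupDesign(tuple(AgeGroup(*r) for r in rows))


@dataclass(frozen=True)
class CAGBlockSpec:
    """Planted co-abundance block structure over genera.

    ``block_of`` maps each genus id to a block id in 1..K; ``trend_of``
    assigns each block one of the life-stage trend archetypes; genera in
    the same block share a latent factor with correlation ``rho_within``.
    """

    block_of: dict[str, int]
    rho_within: float = 0.8
    trend_of: dict[int, str] = field(default_factory=dict)
    effect_size: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.rho_within < 1:
            raise ValueError("rho_within must be in [0, 1)")
        for b, t in self.trend_of.items():
            if t not in TREND_TYPES:
                raise ValueError(f"unknown trend {t!r} for block {b}")

    @property
    def n_blocks(self) -> int:
        return len(set(self.block_of.values()))

    def validate_covers(self, genus_ids: list[str]) -> None:
        missing = [g for g in genus_ids if g not in self.block_of]
        if missing:
            raise ValueError(
                f"{len(missing)} genera missing from block map, e.g. "
                f"{missing[:3]}"
            )


#: Default trend archetypes for the 9-block layout: three elderly-associated
#: blocks, one infant+elderly, one infant/child, one adult, two further
#: elderly-leaning blocks and one flat block.
_DEFAULT_TRENDS_9 = (
    "elderly_high",
    "elderly_high",
    "elderly_high",
    "infant_and_elderly_high",
    "infant_high",
    "adult_high",
    "elderly_high",
    "elderly_high",
    "flat",
)


def default_blocks(
    genus_ids: list[str],
    n_blocks: int = 9,
    rho_within: float = 0.8,
    effect_size: float = 2.0,
    trends: tuple[str, ...] | None = None,
) -> CAGBlockSpec:
    """Split genera into contiguous blocks with cycling trend archetypes."""
    if n_blocks < 1:
        raise ValueError("need at least one block")
    if trends is None:
        trends = (
            _DEFAULT_TRENDS_9
            if n_blocks == 9
            else tuple(TREND_TYPES[i % len(TREND_TYPES)] for i in range(n_blocks))
        )
    chunks = np.array_split(np.asarray(genus_ids, dtype=object), n_blocks)
    block_of = {g: b + 1 for b, chunk in enumerate(chunks) for g in chunk}
    trend_of = {b + 1: trends[b % len(trends)] for b in range(n_blocks)}
    return CAGBlockSpec(block_of, rho_within, trend_of, effect_size)


@dataclass(frozen=True)
class DepthModel:
    """Truncated-normal model of per-sample read depth."""

    mean: float = 4959.0
    sd: float = 1813.0
    floor: int = 500

    def __post_init__(self) -> None:
        if self.floor < 1:
            raise ValueError("depth floor must be >= 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.floor - self.mean) / self.sd
        depths = stats.truncnorm.rvs(
            a, np.inf, loc=self.mean, scale=self.sd, size=n, random_state=rng
        )
        return np.maximum(np.round(depths).astype(int), self.floor)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort."""

    n_genera: int = 186
    design: AgeGroupDesign = field(default_factory=default_design)
    blocks: CAGBlockSpec | None = None
    depth: DepthModel = field(default_factory=DepthModel)
    seed: int = 0
    baseline_sd: float = 1.5

    def genus_ids(self) -> list[str]:
        return [f"g{i:03d}" for i in range(1, self.n_genera + 1)]

    def resolved_blocks(self) -> CAGBlockSpec:
        if self.blocks is not None:
            return self.blocks
        return default_blocks(self.genus_ids())


def life_stage_weights(age: np.ndarray) -> dict[str, np.ndarray]:
    """Piecewise-linear life-stage weights with knots at 3, 20 and 70 years.

    The infant weight is 1 up to age 3 then ramps to 0 at 20; the adult
    weight mirrors it and stays 1 through age 70, after which the elderly
    weight ramps in (full by 100).
    """
    age = np.asarray(age, dtype=float)
    infant = np.clip((20.0 - age) / 17.0, 0.0, 1.0)
    elderly = np.clip((age - 70.0) / 30.0, 0.0, 1.0)
    adult = 1.0 - infant - elderly
    return {"infant": infant, "adult": adult, "elderly": elderly}


#: Within-block grading of the infant-stage effect: multiplier
#: ``peak * decay**rank`` (floored) over block members.  Infant communities
#: are dominated by one or two genera (a Bifidobacterium-like profile), so
#: the infant elevation concentrates mass instead of spreading it evenly —
#: this is what makes infant alpha diversity lower than adult diversity.
INFANT_DOMINANCE = (3.5, 0.55, 0.25)  # peak, decay, floor


def _infant_profile(block_size: int) -> np.ndarray:
    peak, decay, floor = INFANT_DOMINANCE
    return np.maximum(peak * decay ** np.arange(block_size), floor)


def _stage_components(trend: str) -> tuple[str, ...]:
    if trend == "infant_high":
        return ("infant",)
    if trend == "adult_high":
        return ("adult",)
    if trend == "elderly_high":
        return ("elderly",)
    if trend == "infant_and_elderly_high":
        return ("infant", "elderly")
    return ()  # flat


def sample_metadata(design: AgeGroupDesign, seed: int) -> pd.DataFrame:
    """Draw per-sample metadata for a design.

    Ages are uniform within each group's range; sex counts match the design
    exactly; sample ids are stable ("S0001", ...).  An empty design yields
    an empty frame.
    """
    rng = np.random.default_rng(seed)
    records = []
    for group in design.groups:
        sexes = ["male"] * group.n_male + ["female"] * group.n_female
        for sex in sexes:
            age = float(rng.uniform(group.age_low, group.age_high))
            records.append(
                {
                    "age_years": round(age, 2),
                    "sex": sex,
                    "feeding_stage": group.feeding_stage,
                    "age_group": group.label,
                }
            )
    md = pd.DataFrame.from_records(
        records, columns=["age_years", "sex", "feeding_stage", "age_group"]
    )
    md.index = pd.Index(
        [f"S{i + 1:04d}" for i in range(len(md))], name="sample_id"
    )
    return md


def sample_genus_counts(
    config: GeneratorConfig, metadata: pd.DataFrame
) -> GenusAbundanceTable:
    """Draw the genus count table for a cohort.

    Row sums equal the sampled sequencing depths; within-block latent
    correlation is ``rho_within`` and block means follow their life-stage
    trend evaluated at each subject's age.
    """
    if metadata.empty:
        raise ValueError("metadata is empty; nothing to simulate")
    genus_ids = config.genus_ids()
    blocks = config.resolved_blocks()
    blocks.validate_covers(genus_ids)

    rng = np.random.default_rng(config.seed)
    n, g = len(metadata), len(genus_ids)
    block_ids = np.array([blocks.block_of[x] for x in genus_ids])
    uniq_blocks = np.unique(block_ids)

    # Fixed per-genus baseline: the cohort-level rank-abundance curve.
    baseline = rng.normal(0.0, config.baseline_sd, size=g)

    weights = life_stage_weights(metadata["age_years"].to_numpy())
    mu = np.tile(baseline, (n, 1))

    # Infant dominance is graded over ALL infant-trending genera at once
    # (infant_high blocks first), so the cohort has a single
    # Bifidobacterium-like dominant rather than one per block.
    infant_blocks = sorted(
        (
            int(b)
            for b in uniq_blocks
            if "infant" in _stage_components(blocks.trend_of.get(int(b), "flat"))
        ),
        key=lambda b: (blocks.trend_of.get(b) != "infant_high", b),
    )
    infant_cols = np.concatenate(
        [np.flatnonzero(block_ids == b) for b in infant_blocks]
    ) if infant_blocks else np.array([], dtype=int)
    infant_mult = np.zeros(g)
    infant_mult[infant_cols] = _infant_profile(infant_cols.size)

    for b in uniq_blocks:
        trend = blocks.trend_of.get(int(b), "flat")
        cols = np.flatnonzero(block_ids == b)
        for stage in _stage_components(trend):
            mult = infant_mult[cols] if stage == "infant" else np.ones(cols.size)
            mu[:, cols] += (
                blocks.effect_size * weights[stage][:, None] * mult[None, :]
            )

    rho = blocks.rho_within
    shared = rng.standard_normal((n, len(uniq_blocks)))
    noise = rng.standard_normal((n, g))
    block_col = {b: j for j, b in enumerate(uniq_blocks)}
    z = mu + np.sqrt(rho) * shared[:, [block_col[b] for b in block_ids]]
    z += np.sqrt(1.0 - rho) * noise

    # softmax per sample -> composition
    z -= z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)

    depths = config.depth.sample(n, rng)
    counts = np.empty((n, g), dtype=int)
    for i in range(n):
        counts[i] = rng.multinomial(depths[i], p[i])
    df = pd.DataFrame(counts, index=metadata.index, columns=genus_ids)
    return GenusAbundanceTable(df, "counts")


def sample_tree(genus_ids: list[str], seed: int) -> TreeNode:
    """Random bifurcating genus tree with exponential branch lengths.

    Lineages are joined in a coalescent-style random order; every branch
    gets a positive length, so Faith's PD and UniFrac are well defined.
    """
    if len(genus_ids) < 2:
        raise ValueError("need at least 2 genera to build a tree")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=str(gid)) for gid in genus_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.exponential(0.5) + 1e-3)
        right.length = float(rng.exponential(0.5) + 1e-3)
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def sample_gene_content(
    genus_ids: list[str],
    n_functions: int,
    seed: int,
    blocks: CAGBlockSpec | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Toy transporter gene-content matrix, 16S copy numbers and catalog.

    Returns ``(content, copy_numbers, catalog)``: a nonnegative integer
    genus x function matrix, integer copy numbers in [1, 15], and a catalog
    labelling each function with a transporter category plus a
    ``is_drug_transporter`` flag for a designated subset.

    When a block spec is given, drug-transporter content is concentrated on
    genera whose blocks carry infant/elderly trends while half of the other
    functions load on adult/flat-trend genera — mimicking the age-related
    split of transporter repertoires.
    """
    if n_functions < 1:
        raise ValueError("need at least one function")
    rng = np.random.default_rng(seed)
    g = len(genus_ids)
    function_ids = [f"K{i:05d}" for i in range(1, n_functions + 1)]

    n_drug = max(1, n_functions // 8)
    categories = []
    base_cats = (
        "carbohydrate transporter",
        "amino acid transporter",
        "metal transporter",
        "other transporter",
    )
    for i in range(n_functions):
        if i < n_drug:
            categories.append("drug transporter")
        else:
            categories.append(base_cats[i % len(base_cats)])
    catalog = pd.DataFrame(
        {
            "category": categories,
            "is_drug_transporter": [c == "drug transporter" for c in categories],
        },
        index=pd.Index(function_ids, name="function_id"),
    )

    infant_elderly_trends = {
        "infant_high",
        "elderly_high",
        "infant_and_elderly_high",
    }
    if blocks is not None:
        blocks.validate_covers(list(genus_ids))
        ie_mask = np.array(
            [
                blocks.trend_of.get(blocks.block_of[gid], "flat")
                in infant_elderly_trends
                for gid in genus_ids
            ]
        )
    else:
        ie_mask = rng.random(g) < 0.5

    content = np.zeros((g, n_functions), dtype=int)
    for j in range(n_functions):
        if catalog["is_drug_transporter"].iloc[j]:
            host = ie_mask
        elif blocks is not None:
            # alternate the remaining functions between the two strata
            host = ie_mask if j % 2 == 0 else ~ie_mask
        else:
            host = rng.random(g) < 0.4
        lam = np.where(host, 5.0, 0.05)
        content[:, j] = rng.poisson(lam)

    content_df = pd.DataFrame(
        content, index=pd.Index(genus_ids, name="taxon_id"), columns=function_ids
    )
    copy_numbers = pd.Series(
        rng.integers(1, 16, size=g),
        index=content_df.index,
        name="copy_number",
    )
    return content_df, copy_numbers, catalog
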