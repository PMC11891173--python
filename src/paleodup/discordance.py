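"""Gene-tree / species-tree discordance machinery.

Robinson-Foulds distances on the shared leaf set, empirical-vs-simulated
distance distributions with a Pearson chi-square test (Cochran pooling),
per-node concordance/conflict/uninformative counts in the PhyParts sense,
and selection of genes whose trees match the species topology exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

from .trees import bipartitions, leaf_labels

__all__ = [
    "DistanceDistribution",
    "ChiSquareReport",
    "DiscordanceSummary",
    "NodeConcordance",
    "rf_distance",
    "distance_distribution",
    "chi_square_compare",
    "count_concordance",
    "filter_concordant_genes",
]


@dataclass
class DistanceDistribution:
    counts: dict[int, int]
    n: int
    label: str = "empirical"

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be >= 0")
        if sum(self.counts.values()) != self.n:
            raise ValueError("counts must sum to n")

    def proportions(self) -> dict[int, float]:
        return {d: c / self.n for d, c in self.counts.items()}


@dataclass
class ChiSquareReport:
    statistic: float
    df: int
    p_value: float
    bin_edges: list          # list of tuples of pooled distance values
    pooled: bool


@dataclass
class NodeConcordance:
    bipartition: frozenset[str]
    concordant: int
    conflicting: int
    uninformative: int

    @property
    def percent_concordant(self) -> float:
        total = self.concordant + self.conflicting + self.uninformative
        return round(100.0 * self.concordant / total, 1) if total else 0.0


@dataclass
class DiscordanceSummary:
    nodes: list[NodeConcordance]
    n_gene_trees: int


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

def _shared_bipartitions(t1, t2):
    s1, s2 = set(leaf_labels(t1)), set(leaf_labels(t2))
    shared = s1 & s2
    if len(shared) < 4:
        raise ValueError(
            f"only {len(shared)} shared leaves; RF needs at least 4"
        )
    return bipartitions(t1, shared), bipartitions(t2, shared), shared


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance on the shared leaf set.

    Both trees are restricted to their common leaves; the distance is the
    size of the symmetric difference of their non-trivial bipartition
    sets.
    """
    b1, b2, _ = _shared_bipartitions(t1, t2)
    return len(b1 ^ b2)


def distance_distribution(
    gene_trees, species_tree: dendropy.Tree, label: str = "empirical"
) -> DistanceDistribution:
    """Histogram of RF distances from each gene tree to the species tree."""
    gene_trees = list(gene_trees)
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    sp_bip_cache: dict[frozenset[str], set] = {}
    counts: Counter[int] = Counter()
    for gt in gene_trees:
        shared = frozenset(leaf_labels(gt)) & frozenset(leaf_labels(species_tree))
        if len(shared) < 4:
            raise ValueError("gene tree shares fewer than 4 leaves with species tree")
        if shared not in sp_bip_cache:
            sp_bip_cache[shared] = bipartitions(species_tree, shared)
        d = len(bipartitions(gt, shared) ^ sp_bip_cache[shared])
        counts[d] += 1
    return DistanceDistribution(dict(counts), n=len(gene_trees), label=label)


# ---------------------------------------------------------------------------
# chi-square comparison
# ---------------------------------------------------------------------------

def chi_square_compare(
    empirical: DistanceDistribution,
    simulated: DistanceDistribution,
    min_expected: float = 5.0,
) -> ChiSquareReport:
    """Pearson chi-square of the empirical distance histogram against
    expectations from the simulated one.

    Expected counts are the simulated proportions rescaled to the
    empirical sample size over the union of observed distance values;
    adjacent bins are pooled (Cochran's rule) until every expected count
    reaches ``min_expected``; df = #bins - 1.
    """
    values = sorted(set(empirical.counts) | set(simulated.counts))
    obs = np.array([empirical.counts.get(v, 0) for v in values], dtype=float)
    sim_p = np.array([simulated.proportions().get(v, 0.0) for v in values])
    exp = sim_p * empirical.n

    # pool adjacent bins until each expected count >= min_expected
    bins: list[list[int]] = []
    cur_vals: list[int] = []
    cur_obs = cur_exp = 0.0
    pooled_obs, pooled_exp = [], []
    for v, o, e in zip(values, obs, exp):
        cur_vals.append(v)
        cur_obs += o
        cur_exp += e
        if cur_exp >= min_expected:
            bins.append(cur_vals)
            pooled_obs.append(cur_obs)
            pooled_exp.append(cur_exp)
            cur_vals, cur_obs, cur_exp = [], 0.0, 0.0
    if cur_vals:
        if bins:
            bins[-1].extend(cur_vals)
            pooled_obs[-1] += cur_obs
            pooled_exp[-1] += cur_exp
        else:
            bins.append(cur_vals)
            pooled_obs.append(cur_obs)
            pooled_exp.append(cur_exp)
    if len(bins) < 2:
        raise ValueError("distributions degenerate: fewer than 2 bins after pooling")

    pooled_obs = np.array(pooled_obs)
    pooled_exp = np.array(pooled_exp)
    # renormalize expectations to the observed total (guards rounding)
    pooled_exp *= pooled_obs.sum() / pooled_exp.sum()
    statistic = float(((pooled_obs - pooled_exp) ** 2 / pooled_exp).sum())
    df = len(bins) - 1
    p = float(stats.chi2.sf(statistic, df))
    return ChiSquareReport(
        statistic=statistic,
        df=df,
        p_value=p,
        bin_edges=[tuple(b) for b in bins],
        pooled=any(len(b) > 1 for b in bins),
    )


# ---------------------------------------------------------------------------
# per-node concordance (PhyParts-style trichotomy)
# ---------------------------------------------------------------------------

def _compatible(side_a: frozenset, side_b: frozenset, universe: frozenset) -> bool:
    comp_a = universe - side_a
    comp_b = universe - side_b
    return (
        not (side_a & side_b)
        or not (side_a & comp_b)
        or not (comp_a & side_b)
        or not (comp_a & comp_b)
    )


def count_concordance(gene_trees, species_tree: dendropy.Tree) -> DiscordanceSummary:
    """Concordant / conflicting / uninformative gene-tree counts per node.

    For every non-trivial species-tree bipartition, a gene tree restricted
    to the shared taxa is *concordant* if it contains the (restricted)
    bipartition, *conflicting* if it contains an incompatible one, else
    *uninformative*.  Percentages are reported to one decimal.
    """
    gene_trees = list(gene_trees)
    sp_taxa = frozenset(leaf_labels(species_tree))
    sp_bips = sorted(bipartitions(species_tree, sp_taxa), key=sorted)
    tallies = {b: [0, 0, 0] for b in sp_bips}

    for gt in gene_trees:
        gt_taxa = frozenset(leaf_labels(gt))
        shared = gt_taxa & sp_taxa
        gt_bips = bipartitions(gt, shared) if len(shared) >= 4 else set()
        anchor = min(shared) if shared else None
        for b in sp_bips:
            restricted = frozenset(b & shared)
            if anchor in restricted:
                restricted = frozenset(shared - restricted)
            if len(restricted) < 2 or len(shared - restricted) < 2:
                tallies[b][2] += 1  # restriction trivial: uninformative
                continue
            if restricted in gt_bips:
                tallies[b][0] += 1
            elif any(not _compatible(restricted, g, shared) for g in gt_bips):
                tallies[b][1] += 1
            else:
                tallies[b][2] += 1

    nodes = [
        NodeConcordance(b, c, x, u) for b, (c, x, u) in tallies.items()
    ]
    return DiscordanceSummary(nodes=nodes, n_gene_trees=len(gene_trees))


def filter_concordant_genes(gene_trees, species_tree: dendropy.Tree):
    """Gene trees whose RF distance to the species tree (on shared taxa) is 0."""
    out = []
    for gt in gene_trees:
        if rf_distance(gt, species_tree) == 0:
            out.append(gt)
    return out
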