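"""Synthetic-data generators with known ground truth.

Everything the downstream pipeline consumes can be produced here:

* a fixed Pandanales-like reference chronogram (17 ingroup taxa, five
  family clades, crown age 107.9 Mya);
* dated gene-family trees grown along a chronogram under a per-lineage
  birth-death (duplication-loss) process with episodic whole-genome
  duplication pulses;
* gene trees under the contained (censored) multispecies coalescent;
* triplet internal-branch-length draws from an exponential /
  shifted-exponential mixture;
* Proteinortho-dialect orthogroup tables and HyDe-style result tables.

All generators are bit-reproducible: a single root seed, with per-family
substreams derived from ``(seed, family_index)`` so each family can be
regenerated independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .trees import node_ages, read_newick

__all__ = [
    "WGDPulse",
    "SimulationConfig",
    "make_reference_chronogram",
    "REFERENCE_FAMILIES",
    "simulate_gene_family",
    "simulate_gene_families",
    "simulate_msc_gene_trees",
    "simulate_triplet_lengths",
    "make_orthogroup_table",
    "write_orthogroup_table",
    "make_hyde_table",
    "write_hyde_table",
]


# ---------------------------------------------------------------------------
# reference chronogram
# ---------------------------------------------------------------------------

#: family clades of the reference chronogram (five monophyletic families).
REFERENCE_FAMILIES: dict[str, tuple[str, ...]] = {
    "Velloziaceae": (
        "Acanthochlamys_bracteata",
        "Xerophyta_retinervis",
        "Xerophyta_viscosa",
        "Xerophyta_elegans",
    ),
    "Triuridaceae": (
        "Lacandonia_schismatica",
        "Sciaphila_secundiflora",
        "Sciaphila_densiflora",
    ),
    "Stemonaceae": (
        "Croomia_japonica",
        "Stemona_sessilifolia",
        "Stemona_japonica",
    ),
    "Cyclanthaceae": (
        "Asplundia_insignis",
        "Carludovica_palmata",
        "Dicranopygium_yacu",
    ),
    "Pandanaceae": (
        "Pandanus_dubius",
        "Pandanus_unipapillatus",
        "Freycinetia_excelsa",
        "Benstonea_copelandii",
    ),
}

def _node(age: float, *children):
    return (age, children)


# crown of the order at 107.9 Mya, family stems all Cretaceous.
# Velloziaceae is sister to the rest, then Triuridaceae, then
# Stemonaceae, then Cyclanthaceae + Pandanaceae.
_REF_TOPOLOGY = _node(
    107.9,
    _node(
        32.0,
        "Acanthochlamys_bracteata",
        _node(12.0, "Xerophyta_retinervis",
              _node(6.0, "Xerophyta_viscosa", "Xerophyta_elegans")),
    ),
    _node(
        100.9,
        _node(25.0, "Lacandonia_schismatica",
              _node(10.0, "Sciaphila_secundiflora", "Sciaphila_densiflora")),
        _node(
            94.4,
            _node(45.0, "Croomia_japonica",
                  _node(18.0, "Stemona_sessilifolia", "Stemona_japonica")),
            _node(
                82.7,
                _node(38.0, "Asplundia_insignis",
                      _node(22.0, "Carludovica_palmata", "Dicranopygium_yacu")),
                _node(
                    55.0,
                    _node(20.0, "Pandanus_dubius", "Pandanus_unipapillatus"),
                    _node(35.0, "Freycinetia_excelsa", "Benstonea_copelandii"),
                ),
            ),
        ),
    ),
)


def _spec_to_newick(spec, parent_age: float) -> str:
    if isinstance(spec, str):
        return f"{spec}:{parent_age:.10g}"
    age, children = spec
    inner = ",".join(_spec_to_newick(ch, age) for ch in children)
    return f"({inner}):{parent_age - age:.10g}"


def make_reference_chronogram() -> dendropy.Tree:
    """Fixed 17-taxon Pandanales-like chronogram, crown age 107.9 Mya.

    Five monophyletic family clades (:data:`REFERENCE_FAMILIES`), family
    stem lineages originating in the Cretaceous.  Deterministic.
    """
    age, children = _REF_TOPOLOGY
    inner = ",".join(_spec_to_newick(ch, age) for ch in children)
    return read_newick(f"({inner});")


# ---------------------------------------------------------------------------
# gene-family birth-death simulator with WGD pulses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WGDPulse:
    """Episodic duplication pulse on one species-tree branch.

    ``branch`` identifies the edge by the leaf set of the node below it
    (a single label for a terminal branch).  ``time`` (Mya) must lie
    strictly inside the edge's age interval; ``retention_prob`` is the
    probability that any gene lineage alive on the branch at that time
    retains the duplicate.
    """

    branch: frozenset[str]
    time: float
    retention_prob: float

    def __init__(self, branch, time: float, retention_prob: float):
        if isinstance(branch, str):
            branch = frozenset({branch})
        object.__setattr__(self, "branch", frozenset(branch))
        object.__setattr__(self, "time", float(time))
        object.__setattr__(self, "retention_prob", float(retention_prob))
        if not (0.0 <= self.retention_prob <= 1.0):
            raise ValueError("retention_prob must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Rates and pulses for the gene-family simulator.

    Rates are events per gene lineage per My.  Identical seed + config
    gives bit-identical output.
    """

    dup_rate: float = 0.0
    loss_rate: float = 0.0
    wgd_pulses: list[WGDPulse] = field(default_factory=list)
    n_families: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")


class _GNode:
    __slots__ = ("age", "children", "sample")

    def __init__(self, age, children=None, sample=None):
        self.age = age
        self.children = children or []
        self.sample = sample


def _family_rng(seed: int, family_id) -> np.random.Generator:
    if isinstance(family_id, (int, np.integer)):
        sub = int(family_id)
    else:
        sub = zlib.crc32(str(family_id).encode())
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, sub & 0x7FFFFFFF])


def _validate_pulses(chrono, pulses: Sequence[WGDPulse]):
    ages = node_ages(chrono)
    clades: dict[frozenset[str], tuple[float, float]] = {}
    for nd in chrono.postorder_node_iter():
        if nd.parent_node is None:
            continue
        leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        clades[leaves] = (ages[nd], ages[nd.parent_node])
    by_branch: dict[frozenset[str], list[WGDPulse]] = {}
    for p in pulses:
        if p.branch not in clades:
            raise ValueError(f"pulse branch {sorted(p.branch)} is not a chronogram edge")
        lo, hi = clades[p.branch]
        if not (lo < p.time < hi):
            raise ValueError(
                f"pulse time {p.time} outside edge interval ({lo}, {hi}) "
                f"for branch {sorted(p.branch)}"
            )
        by_branch.setdefault(p.branch, []).append(p)
    for v in by_branch.values():
        v.sort(key=lambda p: -p.time)  # oldest first going down the branch
    return by_branch


def simulate_gene_family(
    chronogram: dendropy.Tree,
    config: SimulationConfig,
    family_id,
) -> dendropy.Tree | None:
    """Grow one dated gene-family tree along the chronogram.

    A single ancestral gene enters at the crown; lineages duplicate at
    ``dup_rate`` and die at ``loss_rate`` (continuous time, per lineage);
    at each WGD pulse every lineage alive on the pulse branch duplicates
    independently with probability ``retention_prob``; speciation nodes
    copy all surviving lineages into both daughters.  Leaves are labelled
    ``sample|copy`` in left-to-right traversal order; the returned tree
    is ultrametric in Mya with extinct subtrees pruned.

    Returns ``None`` (the explicit empty-family marker) when every
    lineage is lost before the present.
    """
    rng = _family_rng(config.seed, family_id)
    by_branch = _validate_pulses(chronogram, config.wgd_pulses)
    ages = node_ages(chronogram)
    lam, mu = config.dup_rate, config.loss_rate
    total = lam + mu

    def along_branch(sp_node, t_start: float, pulses: list[WGDPulse]):
        """One gene lineage entering the branch above ``sp_node`` at t_start."""
        t_end = ages[sp_node]
        t = t_start
        remaining = [p for p in pulses if p.time < t_start]
        i = 0
        while True:
            t_event = t - rng.exponential(1.0 / total) if total > 0 else -np.inf
            next_pulse = remaining[i] if i < len(remaining) else None
            if next_pulse is not None and next_pulse.time > max(t_event, t_end):
                # pulse fires before any background event / branch end
                t = next_pulse.time
                i += 1
                if rng.random() < next_pulse.retention_prob:
                    kids = [
                        along_branch_from(sp_node, t, remaining[i:]),
                        along_branch_from(sp_node, t, remaining[i:]),
                    ]
                    return _join(kids, t)
                continue
            if t_event > t_end:
                t = t_event
                if rng.random() < (lam / total):
                    kids = [
                        along_branch_from(sp_node, t, remaining[i:]),
                        along_branch_from(sp_node, t, remaining[i:]),
                    ]
                    return _join(kids, t)
                return None  # loss
            break
        # survived to the bottom of the branch
        if sp_node.is_leaf():
            return _GNode(0.0, sample=sp_node.taxon.label)
        kids = [
            along_branch(ch, t_end, branch_pulses(ch)) for ch in sp_node.child_nodes()
        ]
        return _join(kids, t_end)

    def along_branch_from(sp_node, t_start, pulses):
        return along_branch(sp_node, t_start, pulses)

    def branch_pulses(sp_node) -> list[WGDPulse]:
        leaves = frozenset(lf.taxon.label for lf in sp_node.leaf_iter())
        return by_branch.get(leaves, [])

    def _join(kids, age):
        alive = [k for k in kids if k is not None]
        if not alive:
            return None
        if len(alive) == 1:
            return alive[0]
        return _GNode(age, children=alive)

    root = chronogram.seed_node
    top = _join(
        [along_branch(ch, ages[root], branch_pulses(ch)) for ch in root.child_nodes()],
        ages[root],
    )
    if top is None:
        return None
    return _gnode_to_tree(top, family_id)


def _build_dendropy(root: _GNode, leaf_label) -> dendropy.Tree:
    """Construct a dendropy tree from a _GNode hierarchy without a
    round-trip through Newick text (which dominates runtime otherwise)."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True

    def build(gn: _GNode, dn) -> None:
        if not gn.children:
            dn.taxon = tns.new_taxon(leaf_label(gn))
            return
        for ch in gn.children:
            cn = dn.new_child()
            cn.edge.length = gn.age - ch.age
            build(ch, cn)

    if not root.children:
        leaf = tree.seed_node.new_child()
        leaf.edge.length = root.age
        leaf.taxon = tns.new_taxon(leaf_label(root))
    else:
        build(root, tree.seed_node)
    return tree


def _gnode_to_tree(root: _GNode, family_id) -> dendropy.Tree:
    counters: dict[str, int] = {}

    def label(gn: _GNode) -> str:
        counters[gn.sample] = counters.get(gn.sample, 0) + 1
        return f"{gn.sample}|{counters[gn.sample]}"

    tree = _build_dendropy(root, label)
    tree.label = str(family_id)
    return tree


def simulate_gene_families(
    chronogram: dendropy.Tree, config: SimulationConfig
) -> list[dendropy.Tree | None]:
    """All ``config.n_families`` families; ``None`` entries mark extinct ones."""
    return [
        simulate_gene_family(chronogram, config, fid)
        for fid in range(config.n_families)
    ]


# ---------------------------------------------------------------------------
# multispecies coalescent (contained/censored coalescent)
# ---------------------------------------------------------------------------

def simulate_msc_gene_trees(
    ctree: dendropy.Tree, n: int, seed: int
) -> list[dendropy.Tree]:
    """Sample ``n`` gene trees under the contained coalescent.

    ``ctree`` carries branch lengths in coalescent units (2N generations);
    one allele is sampled per leaf species.  Within a species-tree branch
    holding k gene lineages, coalescence occurs at rate k(k-1)/2 per
    coalescent unit; lineages surviving to the root coalesce without
    bound.  Gene-tree branch lengths are in coalescent units.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for edge in ctree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in coalescent species tree")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x6D5C])
    ages = node_ages(ctree)
    # fixed postorder so the draw sequence is reproducible
    post = list(ctree.postorder_node_iter())

    out = []
    for _ in range(n):
        pool: dict[int, list[_GNode]] = {}
        for nd in post:
            if nd.is_leaf():
                lineages = [_GNode(ages[nd], sample=nd.taxon.label)]
            else:
                lineages = []
                for ch in nd.child_nodes():
                    lineages.extend(
                        _coalesce_in_branch(pool.pop(id(ch)), ages[ch], ages[nd], rng)
                    )
            pool[id(nd)] = lineages
        lineages = pool.pop(id(ctree.seed_node))
        root_lineage = _coalesce_in_branch(
            lineages, ages[ctree.seed_node], np.inf, rng
        )[0]
        out.append(_msc_to_tree(root_lineage))
    return out


def _coalesce_in_branch(lineages, a0: float, a1: float, rng) -> list[_GNode]:
    t = a0
    lineages = list(lineages)
    while len(lineages) >= 2:
        k = len(lineages)
        t = t + rng.exponential(2.0 / (k * (k - 1)))
        if t >= a1:
            break
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        merged = _GNode(t, children=[lineages[i], lineages[j]])
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    return lineages


def _msc_to_tree(root: _GNode) -> dendropy.Tree:
    return _build_dendropy(root, lambda gn: gn.sample)


def triplet_species_tree(t: float, t_root: float = None) -> dendropy.Tree:
    """Rooted triplet ((A,B),C) with internal branch ``t`` coalescent units."""
    if t_root is None:
        t_root = t + 10.0
    return read_newick(f"((A:1,B:1):{t:.10g},C:{1 + t:.10g}):{t_root:.10g};")


# ---------------------------------------------------------------------------
# triplet internal-branch-length mixture draws
# ---------------------------------------------------------------------------

def simulate_triplet_lengths(
    pi2: float, lam: float, shift_c: float, n: int, seed: int
) -> np.ndarray:
    """Draws from (1-pi2)*Exp(lam) + pi2*(shift_c + Exp(lam)).

    The first component models internal branches produced by incomplete
    lineage sorting; the second, shifted by ``shift_c``, those produced
    by speciation or gene flow.
    """
    if not (0.0 <= pi2 <= 1.0):
        raise ValueError("pi2 must be in [0, 1]")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if shift_c < 0:
        raise ValueError("shift_c must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x7A1])
    base = rng.exponential(1.0 / lam, size=n)
    shifted = rng.random(n) < pi2
    return base + shift_c * shifted


# ---------------------------------------------------------------------------
# orthogroup tables (Proteinortho dialect)
# ---------------------------------------------------------------------------

def make_orthogroup_table(
    n_samples: int,
    n_families: int,
    copy_number_spec="single_copy_complete",
    seed: int = 0,
) -> pd.DataFrame:
    """Proteinortho-dialect orthogroup table with controlled copy numbers.

    ``copy_number_spec`` is either a preset name —
    ``"single_copy_complete"`` (every cell one gene) or
    ``"coverage_ladder"`` (cluster k present in exactly min(k+1, n_samples)
    samples) — or an explicit list of ``(n_present, n_multi)`` tuples, one
    per cluster, where ``n_multi`` of the present cells hold two genes.
    Absent cells are serialized as ``"*"``.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x0F0])
    samples = [f"sample{i:02d}" for i in range(n_samples)]

    if copy_number_spec == "single_copy_complete":
        spec = [(n_samples, 0)] * n_families
    elif copy_number_spec == "coverage_ladder":
        spec = [(min(k + 1, n_samples), 0) for k in range(n_families)]
    else:
        spec = list(copy_number_spec)
        if len(spec) != n_families:
            raise ValueError("copy_number_spec length must equal n_families")

    rows = []
    for fam, (n_present, n_multi) in enumerate(spec):
        present = sorted(rng.choice(n_samples, size=n_present, replace=False))
        multi = set(present[:n_multi])
        cells = []
        for i in range(n_samples):
            if i not in present:
                cells.append("*")
            elif i in multi:
                cells.append(f"{samples[i]}_g{fam}a,{samples[i]}_g{fam}b")
            else:
                cells.append(f"{samples[i]}_g{fam}")
        n_genes = sum(2 if i in multi else 1 for i in present)
        rows.append([n_present, n_genes, 1.0] + cells)
    return pd.DataFrame(
        rows, columns=["# Species", "Genes", "Alg.-Conn."] + samples
    )


def write_orthogroup_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# HyDe-style tables
# ---------------------------------------------------------------------------

_HYDE_COLUMNS = ["P1", "Hybrid", "P2", "Zscore", "Pvalue", "Gamma"]


def make_hyde_table(records_spec, seed: int = 0) -> pd.DataFrame:
    """HyDe-style table: P1/Hybrid/P2/Zscore/Pvalue/Gamma rows.

    ``records_spec`` is either a list of dicts (echoed verbatim; no
    filtering — that is downstream's job) or an integer n for n random
    rows over placeholder taxa, reproducible under ``seed``.
    """
    if isinstance(records_spec, int):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x47D])
        taxa = [f"t{i}" for i in range(8)]
        rows = []
        for _ in range(records_spec):
            p1, h, p2 = rng.choice(len(taxa), size=3, replace=False)
            rows.append(
                {
                    "P1": taxa[int(p1)],
                    "Hybrid": taxa[int(h)],
                    "P2": taxa[int(p2)],
                    "Zscore": float(np.round(rng.normal(2, 4), 4)),
                    "Pvalue": float(np.round(rng.random(), 6)),
                    "Gamma": float(np.round(rng.normal(0.3, 0.4), 4)),
                }
            )
        return pd.DataFrame(rows, columns=_HYDE_COLUMNS)
    df = pd.DataFrame(list(records_spec))
    missing = [c for c in _HYDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records_spec missing fields: {missing}")
    return df[_HYDE_COLUMNS]


def write_hyde_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
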