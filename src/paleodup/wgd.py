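"""Whole-genome-duplication detection from dated paralog-bearing gene trees.

The method: in gene-family trees whose leaves are individual gene copies
(``sample|copy``), a node is a *duplication* when its child subtrees share
at least one sample (species-overlap rule).  Each duplication node
contributes its age once per sample present on both sides, building a
per-sample distribution of paralog origin times.  A whole-genome
duplication leaves a tight, heavy cluster in those distributions; the
cluster is located by a 1-D Gaussian mixture selected by BIC, and
clusters shared by all members of a species-tree clade are merged into a
single dated WGD call on that clade's stem branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .trees import clade_sets, is_ultrametric, node_ages

__all__ = [
    "DuplicationRecord",
    "GMMResult",
    "WGDCall",
    "InsufficientDataError",
    "rescale_to_root_age",
    "label_duplications",
    "extract_duplication_ages",
    "fit_gmm",
    "WGDDetector",
    "call_wgd",
]


class InsufficientDataError(ValueError):
    """Too few duplication ages to support a mixture fit."""


def sample_of(leaf_label: str) -> str:
    """Sample identifier from a ``sample|copy`` leaf label."""
    return leaf_label.split("|", 1)[0]


@dataclass(frozen=True)
class DuplicationRecord:
    """One paralog-origin observation: a sample's copy pair diverging at ``age``."""

    sample: str
    age: float
    family_id: str
    node_id: int
    spanned_species: frozenset[str]

    def __post_init__(self):
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.sample not in self.spanned_species:
            raise ValueError("sample must belong to spanned_species")


@dataclass
class GMMResult:
    """BIC-selected 1-D Gaussian mixture over duplication ages."""

    k: int
    means: np.ndarray         # Mya, per component
    sds: np.ndarray           # Mya
    weights: np.ndarray
    support: np.ndarray       # hard-assignment counts per component
    bic: dict[int, float]     # candidate k -> BIC
    n: int


@dataclass
class WGDCall:
    branch: frozenset[str]        # clade below the assigned branch
    age: float                    # Mya
    age_sd: float
    samples: frozenset[str]
    n_duplications: int
    weight: float                 # mean mixture weight of merged peaks
    assignment: str               # "clade" | "terminal" | "approximate"
    age_branch_conflict: bool = False


# ---------------------------------------------------------------------------
# tree-level operations
# ---------------------------------------------------------------------------

def rescale_to_root_age(
    tree: dendropy.Tree, root_age: float, rel_tol: float = 0.05
) -> dendropy.Tree:
    """Linearly rescale a near-ultrametric dated tree to a fixed root age.

    Every node age is multiplied by ``root_age / current root depth``;
    leaf depths are renormalized to zero, so the output is exactly
    ultrametric.  Trees that violate the clock beyond ``rel_tol``
    (relative) are rejected: they need genuine rate-aware dating, which
    this package does not perform.
    """
    if not is_ultrametric(tree, rel_tol=rel_tol):
        raise ValueError(
            "tree is non-ultrametric beyond tolerance; date it with an "
            "external molecular-clock method before rescaling"
        )
    clone = dendropy.Tree(tree)
    ages = node_ages(clone)
    current = ages[clone.seed_node]
    if current <= 0:
        raise ValueError("root depth must be positive")
    factor = root_age / current
    for nd in clone.preorder_node_iter():
        if nd.parent_node is None:
            continue
        child_age = 0.0 if nd.is_leaf() else ages[nd] * factor
        nd.edge.length = ages[nd.parent_node] * factor - child_age
    return clone


def _child_sample_sets(node) -> list[set[str]]:
    return [
        {sample_of(lf.taxon.label) for lf in ch.leaf_iter()}
        for ch in node.child_nodes()
    ]


def _check_rooted(tree: dendropy.Tree) -> None:
    if len(tree.seed_node.child_nodes()) > 2:
        raise ValueError(
            "tree appears unrooted (basal polytomy); root it before "
            "duplication labeling"
        )


def label_duplications(tree: dendropy.Tree) -> set[int]:
    """Ids of nodes whose child subtrees share a sample (species overlap)."""
    _check_rooted(tree)
    dups: set[int] = set()
    for nd in tree.preorder_internal_node_iter():
        sets = _child_sample_sets(nd)
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    dups.add(id(nd))
                    break
    return dups


def extract_duplication_ages(tree: dendropy.Tree) -> list[DuplicationRecord]:
    """Paralog-origin records from a dated gene-family tree.

    For each duplication node, one record per sample present in at least
    two child subtrees, with the node's age and the union of the
    children's sample sets.  Undated trees are rejected.
    """
    _check_rooted(tree)
    if any(
        nd.edge.length is None
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None
    ):
        raise ValueError("tree has no branch lengths; duplication dating needs a dated tree")
    ages = node_ages(tree)
    family_id = tree.label or ""
    records: list[DuplicationRecord] = []
    for nd in tree.preorder_internal_node_iter():
        sets = _child_sample_sets(nd)
        counts: dict[str, int] = {}
        for s in sets:
            for smp in s:
                counts[smp] = counts.get(smp, 0) + 1
        overlapping = sorted(s for s, c in counts.items() if c >= 2)
        if not overlapping:
            continue
        spanned = frozenset().union(*[frozenset(s) for s in sets])
        for smp in overlapping:
            records.append(
                DuplicationRecord(
                    sample=smp,
                    age=float(ages[nd]),
                    family_id=str(family_id),
                    node_id=id(nd),
                    spanned_species=spanned,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Gaussian-mixture dating
# ---------------------------------------------------------------------------

def fit_gmm(
    ages,
    k_candidates=range(1, 7),
    random_state: int = 0,
    n_init: int = 5,
) -> GMMResult:
    """Fit 1-D Gaussian mixtures over paralog ages; select k by minimum BIC.

    Five EM restarts per k with a deterministic seed; BIC ties break
    toward the smaller k.  Fewer than 10 ages is an
    :class:`InsufficientDataError` — no fit is attempted.
    """
    x = np.sort(np.asarray(list(ages), dtype=float))
    if x.size < 10:
        raise InsufficientDataError(
            f"need >= 10 duplication ages, got {x.size}"
        )
    X = x.reshape(-1, 1)
    bic: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in k_candidates:
        if k > x.size:
            continue
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=random_state,
            reg_covar=1e-6,
        ).fit(X)
        bic[k] = float(gm.bic(X))
        fits[k] = gm
    best_k = min(bic, key=lambda k: (round(bic[k], 9), k))
    gm = fits[best_k]
    order = np.argsort(gm.means_.ravel())
    labels = gm.predict(X)
    support = np.array([(labels == c).sum() for c in order])
    return GMMResult(
        k=best_k,
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.ravel()[order]),
        weights=gm.weights_[order],
        support=support,
        bic=bic,
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# WGD calling
# ---------------------------------------------------------------------------

@dataclass
class _Peak:
    sample: str
    mean: float
    sd: float
    weight: float
    support: int


class WGDDetector(BaseEstimator):
    """Call dated WGD events from duplication records on a chronogram.

    Per-sample age distributions are fitted with BIC-selected Gaussian
    mixtures; a component is a candidate peak when its weight reaches
    ``min_weight`` and its spread stays under ``max_sd``; peaks within
    ``merge_window`` of each other whose supporting samples exactly form
    a chronogram clade are merged into one event on that clade's stem
    branch.  Single-sample peaks land on the sample's terminal branch;
    non-clade supporting sets fall back to their MRCA branch, flagged
    ``"approximate"``.

    Parameters
    ----------
    min_weight : minimum mixture weight for a candidate peak (default 0.10).
    max_sd : maximum component standard deviation in My (default 15).
    merge_window : peak means within this many My merge (default 5).
    min_age : ages below this (My) are discarded before fitting, damping
        assembly-isoform artifacts (default 1).
    min_records : minimum ages per sample to attempt a fit (default 10).
    min_peak_support : minimum duplications assigned to a component for it
        to count as a peak (default 15) — a genome-wide duplication
        recruits many gene families, while a burst of records from a
        single deep family duplication (one same-aged record per spanned
        sample) does not.
    """

    def __init__(
        self,
        min_weight: float = 0.10,
        max_sd: float = 15.0,
        merge_window: float = 5.0,
        min_age: float = 1.0,
        min_records: int = 10,
        min_peak_support: int = 15,
        k_candidates: tuple = (1, 2, 3, 4, 5, 6),
        random_state: int = 0,
    ):
        self.min_weight = min_weight
        self.max_sd = max_sd
        self.merge_window = merge_window
        self.min_age = min_age
        self.min_records = min_records
        self.min_peak_support = min_peak_support
        self.k_candidates = k_candidates
        self.random_state = random_state

    def fit(self, records, chronogram: dendropy.Tree):
        """Fit per-sample mixtures and derive WGD calls.

        ``records`` is an iterable of :class:`DuplicationRecord`;
        ``chronogram`` supplies the clades and branch age intervals.
        Order of ``records`` is irrelevant.
        """
        records = list(records)
        if not records:
            raise ValueError("records must be non-empty")
        clades = clade_sets(chronogram)
        ages = node_ages(chronogram)
        clade_interval: dict[frozenset[str], tuple[float, float]] = {}
        for cl, nd in clades.items():
            lo = ages[nd]
            hi = ages[nd.parent_node] if nd.parent_node is not None else np.inf
            clade_interval[cl] = (lo, hi)

        by_sample: dict[str, list[float]] = {}
        for r in records:
            if r.age >= self.min_age:
                by_sample.setdefault(r.sample, []).append(r.age)

        self.gmm_: dict[str, GMMResult] = {}
        peaks: list[_Peak] = []
        for sample in sorted(by_sample):
            vals = sorted(by_sample[sample])
            if len(vals) < self.min_records:
                continue
            res = fit_gmm(
                vals,
                k_candidates=self.k_candidates,
                random_state=self.random_state,
            )
            self.gmm_[sample] = res
            for m, s, w, sup in zip(res.means, res.sds, res.weights, res.support):
                if (
                    w >= self.min_weight
                    and s <= self.max_sd
                    and sup >= self.min_peak_support
                ):
                    peaks.append(_Peak(sample, float(m), float(s), float(w), int(sup)))

        self.peaks_ = sorted(peaks, key=lambda p: (p.mean, p.sample))
        self.calls_ = self._merge_peaks(self.peaks_, clades, clade_interval)
        return self

    def _merge_peaks(self, peaks, clades, clade_interval) -> list[WGDCall]:
        groups: list[list[_Peak]] = []
        for p in peaks:  # single-linkage chaining over sorted means
            if groups and p.mean - groups[-1][-1].mean <= self.merge_window:
                groups[-1].append(p)
            else:
                groups.append([p])
        calls = []
        for grp in groups:
            samples = frozenset(p.sample for p in grp)
            support = sum(p.support for p in grp)
            wsum = sum(p.support for p in grp) or len(grp)
            age = sum(p.mean * p.support for p in grp) / wsum
            sd = sum(p.sd * p.support for p in grp) / wsum
            weight = float(np.mean([p.weight for p in grp]))
            if samples in clades:
                branch = samples
                assignment = "terminal" if len(samples) == 1 else "clade"
            else:
                branch = self._mrca_clade(samples, clades)
                assignment = "approximate"
            lo, hi = clade_interval[branch]
            conflict = not (lo <= age <= hi)
            calls.append(
                WGDCall(
                    branch=branch,
                    age=float(age),
                    age_sd=float(sd),
                    samples=samples,
                    n_duplications=int(support),
                    weight=weight,
                    assignment=assignment,
                    age_branch_conflict=conflict,
                )
            )
        return calls

    @staticmethod
    def _mrca_clade(samples: frozenset[str], clades) -> frozenset[str]:
        candidates = [cl for cl in clades if samples <= cl]
        return min(candidates, key=len)


def call_wgd(records, chronogram: dendropy.Tree, **params) -> list[WGDCall]:
    """Functional wrapper over :class:`WGDDetector`.

    Returns an empty list when there are no duplication records at all or
    no candidate peak survives the weight and spread thresholds (that is
    an answer, not an error).
    """
    records = list(records)
    if not records:
        return []
    try:
        det = WGDDetector(**params).fit(records, chronogram)
    except InsufficientDataError:
        return []
    return det.calls_
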