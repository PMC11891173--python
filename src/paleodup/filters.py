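"""Ortholog-table and alignment filters.

Covers single-copy-orthogroup (SCOG) extraction from Proteinortho-style
tables, alignment column stripping at a missing-data threshold,
parsimony-informative-site counting, and selection of gene trees backed
by sufficiently informative, taxon-complete alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import leaf_labels

__all__ = [
    "OrthogroupTable",
    "FilterConfig",
    "read_orthogroup_table",
    "extract_scogs",
    "alignment_from_dict",
    "strip_columns",
    "count_parsimony_informative",
    "filter_informative_trees",
]

#: characters treated as missing data in alignments
DEFAULT_MISSING = frozenset({"-", "?", "N"})


@dataclass
class OrthogroupTable:
    """Parsed orthogroup membership: one gene-id list per sample per cluster."""

    sample_ids: list[str]
    clusters: list[list[list[str]]]  # clusters[i][j] = gene ids of sample j

    def __post_init__(self):
        for i, row in enumerate(self.clusters):
            if len(row) != len(self.sample_ids):
                raise ValueError(
                    f"cluster row {i}: {len(row)} cells for "
                    f"{len(self.sample_ids)} samples"
                )


@dataclass
class FilterConfig:
    min_taxa: int = 12
    strip_threshold: float = 0.20
    min_informative_sites: int = 600
    require_complete_taxa: bool = True
    missing_chars: frozenset = field(default_factory=lambda: DEFAULT_MISSING)

    def __post_init__(self):
        if not (0.0 <= self.strip_threshold <= 1.0):
            raise ValueError("strip_threshold must be in [0, 1]")
        if self.min_taxa < 1:
            raise ValueError("min_taxa must be >= 1")


def read_orthogroup_table(path) -> OrthogroupTable:
    """Parse a Proteinortho-dialect TSV (header ``# Species / Genes / Alg.-Conn.``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta = [c for c in df.columns if c in ("# Species", "Species", "Genes", "Alg.-Conn.")]
    samples = [c for c in df.columns if c not in meta]
    clusters = []
    for i, row in enumerate(df[samples].itertuples(index=False)):
        cells = []
        for cell in row:
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ValueError(f"line {i + 2}: empty cell (expected '*')")
            cell = str(cell)
            cells.append([] if cell == "*" else cell.split(","))
        clusters.append(cells)
    return OrthogroupTable(sample_ids=samples, clusters=clusters)


def extract_scogs(table: OrthogroupTable, min_taxa: int = 12) -> list[int]:
    """Indices of single-copy orthogroups covered by >= ``min_taxa`` samples.

    A cluster qualifies when every non-empty cell holds exactly one gene
    and the number of non-empty cells reaches ``min_taxa``; input order
    is preserved.
    """
    kept = []
    for i, row in enumerate(table.clusters):
        n_present = sum(1 for cell in row if cell)
        single = all(len(cell) <= 1 for cell in row)
        if single and n_present >= min_taxa:
            kept.append(i)
    return kept


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def alignment_from_dict(seqs: dict[str, str]) -> MultipleSeqAlignment:
    """Build a Biopython alignment from ``{id: row}`` (rows equal length)."""
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    return MultipleSeqAlignment(
        SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()
    )


def _aln_matrix(aln: MultipleSeqAlignment) -> np.ndarray:
    return np.array([list(str(rec.seq)) for rec in aln])


def strip_columns(
    aln: MultipleSeqAlignment,
    threshold: float = 0.20,
    missing_chars=DEFAULT_MISSING,
) -> tuple[MultipleSeqAlignment, list[int]]:
    """Drop columns whose missing-data fraction strictly exceeds ``threshold``.

    Missing characters default to ``{'-', '?', 'N'}``.  Returns the
    stripped alignment (row order and ids unchanged) and the list of
    retained original column indices.
    """
    if len(aln) == 0 or aln.get_alignment_length() == 0:
        raise ValueError("empty alignment")
    mat = _aln_matrix(aln)
    missing = np.isin(mat, sorted(missing_chars))
    frac = missing.mean(axis=0)
    keep = np.flatnonzero(frac <= threshold)
    records = [
        SeqRecord(Seq("".join(mat[i, keep])), id=rec.id, description="")
        for i, rec in enumerate(aln)
    ]
    return MultipleSeqAlignment(records), [int(j) for j in keep]


def count_parsimony_informative(
    aln: MultipleSeqAlignment, missing_chars=DEFAULT_MISSING
) -> int:
    """Columns with >= 2 distinct non-missing states each in >= 2 sequences."""
    mat = _aln_matrix(aln)
    count = 0
    for j in range(mat.shape[1]):
        col = [c for c in mat[:, j] if c not in missing_chars]
        states, freqs = np.unique(col, return_counts=True)
        if np.sum(freqs >= 2) >= 2:
            count += 1
    return count


def filter_informative_trees(
    pairs,
    config: FilterConfig,
    full_taxon_set=None,
):
    """Keep (tree, alignment) pairs that are informative and taxon-complete.

    A pair survives when its alignment has strictly more than
    ``config.min_informative_sites`` parsimony-informative sites and —
    if ``config.require_complete_taxa`` — the tree's leaf set equals
    ``full_taxon_set`` (default: union over all pairs).  Tree and
    alignment of a pair must agree on their taxa.
    """
    pairs = list(pairs)
    if not pairs:
        return []
    if full_taxon_set is None:
        full_taxon_set = set()
        for tree, _ in pairs:
            full_taxon_set |= set(leaf_labels(tree))
    full_taxon_set = set(full_taxon_set)

    kept = []
    for k, (tree, aln) in enumerate(pairs):
        tree_taxa = set(leaf_labels(tree))
        aln_taxa = {rec.id for rec in aln}
        if tree_taxa != aln_taxa:
            raise ValueError(
                f"pair {k}: tree/alignment leaf mismatch "
                f"(tree-only={sorted(tree_taxa - aln_taxa)}, "
                f"alignment-only={sorted(aln_taxa - tree_taxa)})"
            )
        if config.require_complete_taxa and tree_taxa != full_taxon_set:
            continue
        n_inf = count_parsimony_informative(aln, config.missing_chars)
        if n_inf > config.min_informative_sites:
            kept.append((tree, aln))
    return kept


def read_fasta_alignment(path) -> MultipleSeqAlignment:
    return AlignIO.read(path, "fasta")


def write_fasta_alignment(aln: MultipleSeqAlignment, path) -> None:
    AlignIO.write(aln, path, "fasta")
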