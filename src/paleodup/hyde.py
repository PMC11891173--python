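"""Filtering and clade-level aggregation of hybridization-test tables.

HyDe-style rows test a rooted quartet (((P1, H), P2), O): a significant
row estimates the inheritance probability gamma — the fraction of the
hybrid taxon H's genome contributed by P2.  This module applies the
standard significance filter (0 < gamma < 1, p < 0.05, Z > 1, all
strict) and then groups per-sample signals into donor-to-recipient
blocks when the recipients form a monophyletic clade in a reference
tree and their gamma values agree, mirroring how heat-map blocks of
similar intensity are read as a single ancestral gene-flow event.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .trees import is_monophyletic, leaf_labels, mrca_clade

__all__ = [
    "HyDeRecord",
    "IntrogressionBlock",
    "HydeThresholds",
    "parse_and_filter_hyde",
    "aggregate_blocks",
    "block_matrix",
]

_REQUIRED = ["P1", "Hybrid", "P2", "Zscore", "Pvalue", "Gamma"]


@dataclass(frozen=True)
class HyDeRecord:
    P1: str
    Hybrid: str
    P2: str
    Zscore: float
    Pvalue: float
    Gamma: float

    def __post_init__(self):
        if len({self.P1, self.Hybrid, self.P2}) != 3:
            raise ValueError("P1, Hybrid, P2 must be distinct")
        if not (0.0 <= self.Pvalue <= 1.0):
            raise ValueError("Pvalue must be in [0, 1]")


@dataclass
class HydeThresholds:
    """Retention rule: 0 < gamma < 1 AND p < 0.05 AND Z > 1 (all strict)."""

    max_pvalue: float = 0.05
    min_zscore: float = 1.0

    def keep(self, rec: HyDeRecord) -> bool:
        return (
            0.0 < rec.Gamma < 1.0
            and rec.Pvalue < self.max_pvalue
            and rec.Zscore > self.min_zscore
        )


@dataclass
class IntrogressionBlock:
    donor: frozenset[str]       # donor-side taxa (P2)
    recipient: frozenset[str]   # hybrid taxa receiving the material
    mean_gamma: float
    records: list[HyDeRecord]
    recipient_monophyletic: bool
    ancestral_donor: bool = False

    @property
    def count(self) -> int:
        return len(self.records)


def parse_and_filter_hyde(
    source, thresholds: HydeThresholds | None = None
) -> list[HyDeRecord]:
    """Read a HyDe TSV (or DataFrame) and apply the significance filter.

    Input order is preserved.  A missing column or a non-numeric cell is
    reported by name / line number.
    """
    thresholds = thresholds or HydeThresholds()
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    records = []
    for i, row in df.iterrows():
        vals = {}
        for col in ("Zscore", "Pvalue", "Gamma"):
            try:
                vals[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"line {int(i) + 2}: non-numeric {col} value {row[col]!r}"
                ) from exc
        rec = HyDeRecord(
            P1=str(row["P1"]), Hybrid=str(row["Hybrid"]), P2=str(row["P2"]),
            Zscore=vals["Zscore"], Pvalue=vals["Pvalue"], Gamma=vals["Gamma"],
        )
        if thresholds.keep(rec):
            records.append(rec)
    return records


def aggregate_blocks(
    records,
    reference_tree: dendropy.Tree,
    gamma_window: float = 0.10,
) -> list[IntrogressionBlock]:
    """Group filtered records into clade-level donor-to-recipient blocks.

    Records sharing a donor (P2) are merged greedily, in input order,
    whenever the pooled recipient taxa stay monophyletic in the
    reference tree and every member's gamma lies within ``gamma_window``
    of the running group mean.  Records that fit no group pass through
    as singleton blocks, so every input record lands in exactly one
    block.  A final pass joins blocks with identical recipient clades
    whose donors themselves form a monophyletic clade (compatible mean
    gamma), flagging the result as an ancestral-donor event.
    """
    records = list(records)
    tree_taxa = set(leaf_labels(reference_tree))
    for rec in records:
        unknown = {rec.P1, rec.Hybrid, rec.P2} - tree_taxa
        if unknown:
            raise ValueError(f"record taxa absent from reference tree: {sorted(unknown)}")

    groups: list[dict] = []
    for rec in records:
        placed = False
        for g in groups:
            if g["donor"] != frozenset({rec.P2}):
                continue
            cand_recip = g["recipients"] | {rec.Hybrid}
            gammas = [r.Gamma for r in g["records"]] + [rec.Gamma]
            mean = float(np.mean(gammas))
            if not is_monophyletic(reference_tree, cand_recip):
                continue
            if any(abs(x - mean) > gamma_window for x in gammas):
                continue
            g["recipients"] = cand_recip
            g["records"].append(rec)
            placed = True
            break
        if not placed:
            groups.append(
                {
                    "donor": frozenset({rec.P2}),
                    "recipients": frozenset({rec.Hybrid}),
                    "records": [rec],
                }
            )

    # fixpoint pass: sibling groups under one donor can union into a
    # larger clade (a singleton plus a cherry completing a 3-taxon clade)
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                if a["donor"] != b["donor"]:
                    continue
                union = a["recipients"] | b["recipients"]
                gammas = [r.Gamma for r in a["records"] + b["records"]]
                mean = float(np.mean(gammas))
                if not is_monophyletic(reference_tree, union):
                    continue
                if any(abs(x - mean) > gamma_window for x in gammas):
                    continue
                a["recipients"] = union
                a["records"] += b["records"]
                del groups[j]
                changed = True
                break
            if changed:
                break

    blocks = [
        IntrogressionBlock(
            donor=g["donor"],
            recipient=g["recipients"],
            mean_gamma=float(np.mean([r.Gamma for r in g["records"]])),
            records=g["records"],
            recipient_monophyletic=is_monophyletic(reference_tree, g["recipients"]),
        )
        for g in groups
    ]
    return _merge_ancestral_donors(blocks, reference_tree, gamma_window)


def _merge_ancestral_donors(blocks, reference_tree, gamma_window):
    merged: list[IntrogressionBlock] = []
    used = [False] * len(blocks)
    for i, b in enumerate(blocks):
        if used[i]:
            continue
        group = [b]
        used[i] = True
        for j in range(i + 1, len(blocks)):
            if used[j]:
                continue
            other = blocks[j]
            if other.recipient != b.recipient:
                continue
            donors = frozenset().union(*(g.donor for g in group)) | other.donor
            gammas = [r.Gamma for g in group + [other] for r in g.records]
            mean = float(np.mean(gammas))
            if not is_monophyletic(reference_tree, donors):
                continue
            if any(abs(x - mean) > gamma_window for x in gammas):
                continue
            group.append(other)
            used[j] = True
        if len(group) == 1:
            merged.append(b)
        else:
            donors = frozenset().union(*(g.donor for g in group))
            donor_clade = frozenset(mrca_clade(reference_tree, donors))
            recs = [r for g in group for r in g.records]
            merged.append(
                IntrogressionBlock(
                    donor=donor_clade,
                    recipient=b.recipient,
                    mean_gamma=float(np.mean([r.Gamma for r in recs])),
                    records=recs,
                    recipient_monophyletic=b.recipient_monophyletic,
                    ancestral_donor=True,
                )
            )
    return merged


def block_matrix(blocks, taxa=None) -> pd.DataFrame:
    """Donor-by-recipient mean-gamma matrix (heat-map analog)."""
    if taxa is None:
        taxa = sorted(
            {t for b in blocks for t in b.donor} | {t for b in blocks for t in b.recipient}
        )
    mat = pd.DataFrame(0.0, index=list(taxa), columns=list(taxa))
    for b in blocks:
        for d in b.donor:
            for r in b.recipient:
                if d in mat.index and r in mat.columns:
                    mat.loc[d, r] = b.mean_gamma
    return mat
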