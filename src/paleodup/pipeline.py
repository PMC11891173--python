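"""End-to-end pipeline driver: simulation -> filtering -> WGD detection ->
discordance -> triplet mixture -> introgression summary.

Everything is driven by a JSON-serializable :class:`PipelineConfig`; a
given config + seed produces a byte-identical output bundle, and every
output file records the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .discordance import chi_square_compare, count_concordance, distance_distribution
from .filters import extract_scogs, read_orthogroup_table
from .hyde import HydeThresholds, aggregate_blocks, parse_and_filter_hyde
from .simulate import (
    SimulationConfig,
    WGDPulse,
    make_hyde_table,
    make_orthogroup_table,
    make_reference_chronogram,
    simulate_gene_families,
    simulate_msc_gene_trees,
    write_hyde_table,
    write_orthogroup_table,
)
from .trees import leaf_labels, node_ages, write_newick
from .triplets import MixtureFitParams, fit_triplet, significant_geneflow
from .wgd import call_wgd, extract_duplication_ages

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Constants of the analysis plus simulation settings for the demo run.

    Defaults carry the canonical study constants (12-sample SCOG rule,
    20% stripping threshold, >600 informative sites, 10,000 simulated
    gene trees, delta-BIC < -30, HyDe thresholds); the ``demo`` preset
    shrinks the simulation sizes for a fast smoke run.
    """

    # filter constants
    min_taxa: int = 12
    strip_threshold: float = 0.20
    min_informative_sites: int = 600
    # discordance
    n_sim_gene_trees: int = 10000
    n_empirical_gene_trees: int = 114
    coalescent_units_per_my: float = 0.02
    # triplet mixture
    delta_bic_threshold: float = -30.0
    # hyde
    hyde_max_pvalue: float = 0.05
    hyde_min_zscore: float = 1.0
    gamma_window: float = 0.10
    # gmm / wgd
    gmm_k_max: int = 6
    wgd_min_weight: float = 0.10
    wgd_max_sd: float = 15.0
    wgd_merge_window: float = 5.0
    wgd_min_age: float = 1.0
    # gene-family simulation
    n_families: int = 300
    dup_rate: float = 0.0005
    loss_rate: float = 0.0005
    pulses: list[dict] = field(default_factory=list)
    # orthogroups / hyde demo tables
    n_table_samples: int = 17
    n_table_families: int = 50
    seed: int = 1

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    @classmethod
    def demo(cls, seed: int = 1) -> "PipelineConfig":
        """Small, fast configuration exercising every stage."""
        return cls(
            n_families=120,
            n_sim_gene_trees=1500,
            n_empirical_gene_trees=114,
            pulses=[
                {
                    "branch": [
                        "Pandanus_dubius", "Pandanus_unipapillatus",
                        "Freycinetia_excelsa", "Benstonea_copelandii",
                    ],
                    "time": 80.0,
                    "retention_prob": 0.8,
                }
            ],
            seed=seed,
        )

    def wgd_pulses(self) -> list[WGDPulse]:
        return [
            WGDPulse(frozenset(p["branch"]), p["time"], p["retention_prob"])
            for p in self.pulses
        ]


def _coalescent_tree(chronogram: dendropy.Tree, units_per_my: float) -> dendropy.Tree:
    ct = dendropy.Tree(chronogram)
    for edge in ct.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * units_per_my
    return ct


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on simulated data; write the report bundle.

    Returns a dict with the in-memory results; files (TSV/JSON plus a
    run log) land under ``out_dir``.  ``n_families == 0`` is a clean
    no-op.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log_lines = [
        f"paleodup {__version__} (python {platform.python_version()})",
        f"config_hash={chash}",
        f"seed={config.seed}",
    ]
    if config.n_families == 0:
        (out / "run.log").write_text("\n".join(log_lines + ["nothing to do"]) + "\n")
        return {"status": "nothing to do", "config_hash": chash}

    chrono = make_reference_chronogram()
    write_newick(chrono, out / "chronogram.nwk", units="Mya")

    # --- stage 1: gene families + WGD detection -------------------------
    sim_cfg = SimulationConfig(
        dup_rate=config.dup_rate,
        loss_rate=config.loss_rate,
        wgd_pulses=config.wgd_pulses(),
        n_families=config.n_families,
        seed=config.seed,
    )
    families = [t for t in simulate_gene_families(chrono, sim_cfg) if t is not None]
    records = [r for t in families for r in extract_duplication_ages(t)]
    calls = call_wgd(
        records,
        chrono,
        min_weight=config.wgd_min_weight,
        max_sd=config.wgd_max_sd,
        merge_window=config.wgd_merge_window,
        min_age=config.wgd_min_age,
        k_candidates=tuple(range(1, config.gmm_k_max + 1)),
    )
    rec_df = pd.DataFrame(
        [
            {
                "sample": r.sample,
                "age_mya": round(r.age, 2),
                "family": r.family_id,
                "spanned_species": ",".join(sorted(r.spanned_species)),
            }
            for r in records
        ]
    )
    rec_df.to_csv(out / "duplication_records.tsv", sep="\t", index=False)
    call_rows = [
        {
            "branch": ",".join(sorted(c.branch)),
            "age_mya": round(c.age, 2),
            "age_sd": round(c.age_sd, 2),
            "n_samples": len(c.samples),
            "n_duplications": c.n_duplications,
            "weight": round(c.weight, 3),
            "assignment": c.assignment,
            "age_branch_conflict": c.age_branch_conflict,
        }
        for c in calls
    ]
    pd.DataFrame(call_rows).to_csv(out / "wgd_calls.tsv", sep="\t", index=False)
    (out / "wgd_calls.json").write_text(
        json.dumps({"config_hash": chash, "calls": call_rows}, indent=2)
    )

    # --- stage 2: orthogroup table + SCOG filter ------------------------
    table = make_orthogroup_table(
        config.n_table_samples, config.n_table_families,
        "coverage_ladder", seed=config.seed,
    )
    write_orthogroup_table(table, out / "orthogroups.tsv")
    scogs = extract_scogs(read_orthogroup_table(out / "orthogroups.tsv"), config.min_taxa)
    pd.DataFrame({"cluster_index": scogs}).to_csv(
        out / "scog_clusters.tsv", sep="\t", index=False
    )

    # --- stage 3: MSC discordance + chi-square --------------------------
    ctree = _coalescent_tree(chrono, config.coalescent_units_per_my)
    empirical = simulate_msc_gene_trees(
        ctree, config.n_empirical_gene_trees, seed=config.seed * 2 + 1
    )
    simulated = simulate_msc_gene_trees(
        ctree, config.n_sim_gene_trees, seed=config.seed * 2 + 2
    )
    emp_dist = distance_distribution(empirical, chrono, label="empirical")
    sim_dist = distance_distribution(simulated, chrono, label="simulated")
    report = chi_square_compare(emp_dist, sim_dist)
    dist_df = pd.DataFrame(
        sorted(
            [("empirical", d, c) for d, c in emp_dist.counts.items()]
            + [("simulated", d, c) for d, c in sim_dist.counts.items()]
        ),
        columns=["label", "rf_distance", "count"],
    )
    dist_df.to_csv(out / "distance_distributions.tsv", sep="\t", index=False)
    (out / "chi_square.json").write_text(
        json.dumps(
            {
                "config_hash": chash,
                "statistic": report.statistic,
                "df": report.df,
                "p_value": report.p_value,
                "bins": [list(b) for b in report.bin_edges],
            },
            indent=2,
        )
    )
    summary = count_concordance(empirical, chrono)
    conc_rows = [
        {
            "clade": ",".join(sorted(nc.bipartition)),
            "concordant": nc.concordant,
            "conflicting": nc.conflicting,
            "uninformative": nc.uninformative,
            "percent_concordant": nc.percent_concordant,
        }
        for nc in summary.nodes
    ]
    pd.DataFrame(sorted(conc_rows, key=lambda r: r["clade"])).to_csv(
        out / "concordance.tsv", sep="\t", index=False
    )

    # --- stage 4: triplet mixture ---------------------------------------
    params = MixtureFitParams(delta_bic_threshold=config.delta_bic_threshold)
    taxa = leaf_labels(chrono)
    ages = node_ages(chrono)
    # one representative per family clade keeps the triplet scan small
    triplet = (taxa[0], taxa[4], taxa[7])
    trip_result = fit_triplet(empirical + simulated, triplet, params)
    trip_rows = [
        {
            "triplet": "|".join(trip_result.triplet),
            "topology": ",".join(sorted(f.topology)),
            "count": f.count,
            "pi1": round(f.pi1, 4),
            "pi2": round(f.pi2, 4),
            "lam": round(f.lam, 4),
            "shift": round(f.shift, 4),
            "bic1": round(f.bic1, 2),
            "bic2": round(f.bic2, 2),
            "delta_bic": round(f.delta_bic, 2),
        }
        for f in trip_result.fits.values()
    ]
    pd.DataFrame(trip_rows).to_csv(out / "triplet_mixture.tsv", sep="\t", index=False)
    pi2_matrix = significant_geneflow([trip_result], chrono, params)
    pi2_matrix.to_csv(out / "pi2_matrix.tsv", sep="\t")

    # --- stage 5: HyDe filtering + blocks -------------------------------
    # demo table: a Velloziaceae -> Triuridaceae donor signal plus one
    # insignificant row that the filter must drop
    hyde_df = make_hyde_table(
        [
            {"P1": taxa[7], "Hybrid": t, "P2": taxa[0],
             "Zscore": 12.3, "Pvalue": 1e-6, "Gamma": g}
            for t, g in zip(taxa[4:7], (0.18, 0.20, 0.19))
        ]
        + [
            {"P1": taxa[7], "Hybrid": taxa[8], "P2": taxa[0],
             "Zscore": 0.4, "Pvalue": 0.2, "Gamma": 0.5}
        ],
        seed=config.seed,
    )
    write_hyde_table(hyde_df, out / "hyde_input.tsv")
    kept = parse_and_filter_hyde(
        out / "hyde_input.tsv",
        HydeThresholds(config.hyde_max_pvalue, config.hyde_min_zscore),
    )
    blocks = aggregate_blocks(kept, chrono, config.gamma_window)
    pd.DataFrame(
        [
            {
                "donor": ",".join(sorted(b.donor)),
                "recipient": ",".join(sorted(b.recipient)),
                "mean_gamma": round(b.mean_gamma, 4),
                "n_records": b.count,
                "ancestral_donor": b.ancestral_donor,
            }
            for b in blocks
        ]
    ).to_csv(out / "introgression_blocks.tsv", sep="\t", index=False)

    log_lines += [
        f"families_simulated={len(families)}",
        f"duplication_records={len(records)}",
        f"wgd_calls={len(calls)}",
        f"scog_clusters={len(scogs)}",
        f"chi_square_p={report.p_value:.6g}",
        f"introgression_blocks={len(blocks)}",
    ]
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "status": "ok",
        "config_hash": chash,
        "wgd_calls": calls,
        "scogs": scogs,
        "chi_square": report,
        "triplet_result": trip_result,
        "blocks": blocks,
        "n_families": len(families),
        "root_age": ages[chrono.seed_node],
    }
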