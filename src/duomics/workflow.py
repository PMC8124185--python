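"""End-to-end pipeline orchestration.

Stages communicate through files in a run directory so any stage can be
re-run from its predecessors' outputs:

    01_inputs/     generated or copied pipeline inputs
    02_de/         per-layer classified DE tables
    03_integration/ integrated gene table + per-group reports
    04_uorf/       per-gene uORF features + Monte-Carlo reports
    05_enrichment/ term enrichment with kappa groups
    06_network/    cliques and first-neighbour subnetworks
    summary.json   machine-readable run summary

A "fixture mode" accepts a pre-computed signed fold-change table and
bypasses the DE stage, so published FC tables can be pushed through the
integration, uORF and network stages directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, enrichment, integration, netgraph, synthetic, uorf

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "duomics_run"
    seed: int = 0
    # synthetic-input generation; set generate=False and fill input paths instead
    generate: bool = True
    synthetic: synthetic.SyntheticConfig | None = None
    # externally supplied inputs (used when generate=False)
    transcript_tsv: str | None = None
    protein_tsv: str | None = None
    id_map_tsv: str | None = None
    utr_fasta: str | None = None
    network_tsv: str | None = None
    terms_gmt: str | None = None
    # fixture mode: pre-computed signed-FC table, DE stage bypassed
    fc_table_tsv: str | None = None
    # analysis parameters
    fc_cut: float = 1.6
    fdr_cut: float = 0.05
    mc_n_sims: int = 1000
    mc_draws_per_sim: int = 100
    mc_alpha: float = 0.05
    enrich_alpha: float = 0.05
    kappa_threshold: float = 0.4
    score_cut: float = 0.4
    inflation_schedule: tuple = netgraph.DEFAULT_INFLATION_SCHEDULE

    @property
    def thresholds(self) -> diffexpr.AnalysisThresholds:
        return diffexpr.AnalysisThresholds(fc_cut=self.fc_cut, fdr_cut=self.fdr_cut)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if "utr_length_range" in syn:
                syn["utr_length_range"] = tuple(syn["utr_length_range"])
            for key in ("clique_size_range", "term_size_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            cfg.synthetic = synthetic.SyntheticConfig(**syn)
        if isinstance(cfg.inflation_schedule, list):
            cfg.inflation_schedule = tuple(cfg.inflation_schedule)
        return cfg


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Consistency checks on externally supplied inputs; returns an
    itemized problem list (empty = valid).  Report-only, never raises."""
    problems: list[str] = []
    if config.generate:
        return problems
    paths = {
        "transcript_tsv": config.transcript_tsv,
        "protein_tsv": config.protein_tsv,
        "id_map_tsv": config.id_map_tsv,
    }
    for name, p in paths.items():
        if p is None:
            problems.append(f"{name} not set")
        elif not Path(p).exists():
            problems.append(f"{name} does not exist: {p}")
    if problems:
        return problems

    id_map = synthetic.read_id_map_tsv(config.id_map_tsv)
    for col in ("transcript_id", "protein_id", "gene_id"):
        if col not in id_map.columns:
            problems.append(f"id map missing column {col!r}")
            return problems

    for name, p in (("transcript", config.transcript_tsv), ("protein", config.protein_tsv)):
        try:
            m = diffexpr.read_expression_tsv(p)
        except Exception as exc:  # malformed header / duplicates
            problems.append(f"{name} matrix: {exc}")
            continue
        col = f"{name}_id"
        known = set(id_map[col].dropna())
        unmapped = [f for f in m.feature_ids if f not in known]
        if unmapped:
            problems.append(f"{name} matrix: {len(unmapped)} features missing from id map (e.g. {unmapped[0]!r})")

    if config.utr_fasta:
        if not Path(config.utr_fasta).exists():
            problems.append(f"utr_fasta does not exist: {config.utr_fasta}")
        else:
            from Bio import SeqIO

            utr_ids = {rec.id for rec in SeqIO.parse(config.utr_fasta, "fasta")}
            for tid in id_map["transcript_id"].dropna():
                if tid not in utr_ids:
                    problems.append(f"UTR FASTA missing mapped transcript {tid!r}")
    return problems


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the summary dict (also written to
    ``<outdir>/summary.json``).  A stage failure raises :class:`StageError`
    with partial outputs left in place."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # ---- stage 1: inputs -------------------------------------------------
    stage = "inputs"
    try:
        d = out / "01_inputs"
        d.mkdir(exist_ok=True)
        if config.generate:
            scfg = config.synthetic or synthetic.SyntheticConfig(seed=config.seed)
            transcript, protein, id_map, truth = synthetic.generate_omics_dataset(scfg)
            utrs = synthetic.generate_utr_set(scfg, truth)
            background = synthetic.generate_background_network(scfg, truth)
            terms = synthetic.generate_annotation_sets(scfg, truth)
            diffexpr.write_expression_tsv(
                diffexpr.ExpressionMatrix(transcript, _conds(transcript.columns)), d / "transcript.tsv"
            )
            diffexpr.write_expression_tsv(
                diffexpr.ExpressionMatrix(protein, _conds(protein.columns)), d / "protein.tsv"
            )
            synthetic.write_id_map_tsv(id_map, d / "id_map.tsv")
            synthetic.write_utr_fasta(utrs, d / "utrs.fasta")
            netgraph.write_edge_list_tsv(background, d / "network.tsv")
            enrichment.write_gmt(terms, d / "terms.gmt")
            synthetic.write_truth_tsv(truth, d / "truth.tsv")
            t_mat = diffexpr.read_expression_tsv(d / "transcript.tsv")
            p_mat = diffexpr.read_expression_tsv(d / "protein.tsv")
        else:
            t_mat = diffexpr.read_expression_tsv(config.transcript_tsv) if config.transcript_tsv else None
            p_mat = diffexpr.read_expression_tsv(config.protein_tsv) if config.protein_tsv else None
            id_map = synthetic.read_id_map_tsv(config.id_map_tsv) if config.id_map_tsv else None
            utrs = None
            if config.utr_fasta:
                from Bio import SeqIO

                utrs = {r.id: str(r.seq) for r in SeqIO.parse(config.utr_fasta, "fasta")}
            background = netgraph.read_edge_list_tsv(config.network_tsv) if config.network_tsv else None
            terms = enrichment.read_gmt(config.terms_gmt) if config.terms_gmt else None
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 2: differential expression --------------------------------
    stage = "diffexpr"
    try:
        d = out / "02_de"
        d.mkdir(exist_ok=True)
        if config.fc_table_tsv:
            integrated = integration.classify_fc_table(
                pd.read_csv(config.fc_table_tsv, sep="\t", index_col="gene_id"),
                config.thresholds,
            )
            summary["de"] = {"mode": "fixture (DE bypassed)"}
        else:
            t_de = diffexpr.run_de(t_mat, config.thresholds)
            p_de = diffexpr.run_de(p_mat, config.thresholds)
            diffexpr.write_de_tsv(t_de, d / "transcript_de.tsv")
            diffexpr.write_de_tsv(p_de, d / "protein_de.tsv")
            summary["de"] = {
                layer: {
                    s: int((de["status"] == s).sum())
                    for s in (diffexpr.STATUS_UP, diffexpr.STATUS_DOWN, diffexpr.STATUS_NS)
                }
                for layer, de in (("transcript", t_de), ("protein", p_de))
            }
            integrated = None
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 3: integration --------------------------------------------
    stage = "integration"
    try:
        d = out / "03_integration"
        d.mkdir(exist_ok=True)
        if integrated is None:
            integrated = integration.assign_groups(
                integration.match_layers(t_de, p_de, id_map)
            )
        integration.write_integrated_tsv(integrated, d / "integrated.tsv")
        for grp in (integration.GROUP1, integration.GROUP2, integration.GROUP3):
            integration.group_report(integrated, grp).to_csv(
                d / f"group{grp}_report.tsv", sep="\t", index=False
            )
        summary["groups"] = integration.group_sizes(integrated)
        try:
            r, p, n = integration.correlate_fold_changes(integrated)
            summary["fold_change_correlation"] = {"pearson_r": r, "p_value": p, "n": n}
        except ValueError:
            summary["fold_change_correlation"] = None
    except Exception as exc:
        raise StageError(stage, exc) from exc

    gene_of_transcript = None
    if "id_map" in locals() and id_map is not None:
        gene_of_transcript = id_map.set_index("transcript_id")["gene_id"]

    # ---- stage 4: uORFs ---------------------------------------------------
    stage = "uorf"
    if utrs is not None and gene_of_transcript is not None:
        try:
            d = out / "04_uorf"
            d.mkdir(exist_ok=True)
            annotations = {tid: uorf.find_uorfs(seq, tid) for tid, seq in utrs.items()}
            feats = uorf.uorf_gene_features(annotations, gene_of_transcript)
            feats.drop(columns=["lengths"]).to_csv(d / "gene_uorf_features.tsv", sep="\t")
            carriers = set(feats.index[feats["carrier"]])
            bg_freq = len(carriers) / len(feats)
            mc: dict = {}
            for grp in (integration.GROUP1, integration.GROUP2):
                members = set(integrated.index[integrated["group"] == grp])
                observed = len(members & carriers)
                if members and 0 < bg_freq < 1:
                    res = uorf.monte_carlo_enrichment(
                        observed,
                        len(members),
                        bg_freq,
                        n_sims=config.mc_n_sims,
                        draws_per_sim=config.mc_draws_per_sim,
                        alpha=config.mc_alpha,
                        seed=config.seed + int(grp),
                    )
                    mc[f"group{grp}"] = res.to_dict()
            g1 = feats.loc[feats.index.intersection(integrated.index[integrated["group"] == integration.GROUP1])]
            g2 = feats.loc[feats.index.intersection(integrated.index[integrated["group"] == integration.GROUP2])]
            wilcoxon = {}
            if len(g1) and len(g2):
                wilcoxon = {
                    "n_uorfs_p": uorf.compare_uorf_features(g1["n_uorfs"], g2["n_uorfs"]),
                    "mean_length_p": uorf.compare_uorf_features(
                        g1["mean_length"].dropna(), g2["mean_length"].dropna()
                    )
                    if g1["mean_length"].notna().any() and g2["mean_length"].notna().any()
                    else None,
                }
            summary["uorf"] = {
                "n_genes": int(len(feats)),
                "n_carriers": int(len(carriers)),
                "carrier_percentage": uorf.carrier_percentage(len(carriers), len(feats)),
                "monte_carlo": mc,
                "wilcoxon": wilcoxon,
            }
            _write_json(summary["uorf"], d / "monte_carlo_report.json")
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # ---- stage 5: enrichment ----------------------------------------------
    stage = "enrichment"
    if terms is not None:
        try:
            d = out / "05_enrichment"
            d.mkdir(exist_ok=True)
            universe = list(integrated.index)
            query = list(integrated.index[integrated["group"] == integration.GROUP2])
            if query:
                res = enrichment.enrich_terms(query, terms, universe, alpha=config.enrich_alpha)
                res = enrichment.group_terms(res, terms, universe, config.kappa_threshold)
                res.to_csv(d / "group2_enrichment.tsv", sep="\t", index=False)
                enrichment.barchart_table(res).to_csv(d / "group2_barchart.tsv", sep="\t", index=False)
                summary["enrichment"] = {
                    "n_terms_tested": int(len(res)),
                    "n_significant": int(res["significant"].sum()),
                    "n_groups": int(res["group_id"].nunique()) if len(res) else 0,
                    "leading_terms": sorted(res.loc[res["is_leading"] & res["significant"], "term_id"]),
                }
            else:
                summary["enrichment"] = {"n_terms_tested": 0, "n_significant": 0, "n_groups": 0, "leading_terms": []}
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # ---- stage 6: network --------------------------------------------------
    stage = "network"
    if background is not None:
        try:
            d = out / "06_network"
            d.mkdir(exist_ok=True)
            group2 = set(integrated.index[integrated["group"] == integration.GROUP2])
            sub = netgraph.build_subnetwork(group2, background, config.score_cut)
            cliques, unresolved = netgraph.clique_refine(sub, config.inflation_schedule)
            netgraph.write_clusters_tsv(cliques, unresolved, d / "clusters.tsv")
            node_status = integrated["node_class"].to_dict()
            inventory = []
            for i, cl in enumerate(sorted(cliques, key=lambda c: sorted(map(str, c)))):
                expanded = netgraph.expand_first_neighbours(cl, background, node_status)
                netgraph.write_subnetwork_tsv(
                    expanded, d / f"clique{i}_edges.tsv", d / f"clique{i}_nodes.tsv"
                )
                inventory.append(
                    {
                        "clique": sorted(map(str, cl)),
                        "size": len(cl),
                        "n_neighbours": len(expanded.neighbours),
                    }
                )
            summary["network"] = {
                "group2_nodes": len(group2),
                "n_cliques": len(cliques),
                "n_unresolved": len(unresolved),
                "cliques": inventory,
            }
        except Exception as exc:
            raise StageError(stage, exc) from exc

    _write_json(summary, out / "summary.json")
    return summary


def _conds(columns) -> pd.Series:
    return pd.Series({c: str(c).rsplit("_", 1)[0] for c in columns})
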