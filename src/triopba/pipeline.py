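"""End-to-end orchestration: simulate (or load) -> QC -> TDT -> gene
scoring -> pathway association (pooled FDR) -> size-bias check ->
network scan -> cross-population overlap, with a JSON run manifest.

Every stage is deterministic given the global seed, and no output embeds
a timestamp, so rerunning an identical config reproduces every file
byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .crosspop import overlap_curves
from .gene_scoring import best_p_per_gene, map_snps_to_genes, write_gene_scores
from .io import (
    read_bed,
    read_gmt,
    read_hierarchy,
    read_interactome,
    read_ped_map,
    write_bed,
    write_gmt,
    write_hierarchy,
    write_interactome,
    write_ped_map,
)
from .network import NetworkScanConfig, scan
from .pba import PbaConfig, pool_fdr, run_pba, write_enrichment
from .qc import QcThresholds, run_qc
from .sim import SimConfig, simulate_study
from .size_bias import bias_report
from .tdt import run_tdt, write_tdt

logger = logging.getLogger("triopba")

STAGES = ["simulate", "qc", "tdt", "score_genes", "pba", "bias", "network", "crosspop"]


@dataclass
class RunConfig:
    """One human-editable document driving the whole pipeline."""

    out_dir: str
    seed: int = 0
    populations: list[str] = field(default_factory=lambda: ["pop1"])
    simulate: bool = True
    sim: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # when simulate is False
    qc: dict = field(default_factory=dict)
    pba: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    crosspop: dict = field(default_factory=dict)
    flank_bp: int = 500
    run_network: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def validate(self) -> None:
        if not self.populations:
            raise ValueError("at least one population label is required")
        SimConfig(**{**self.sim, "seed": self.seed})
        QcThresholds(**self.qc)
        PbaConfig(**self.pba)
        NetworkScanConfig(**{**self.network, "seed": self.seed})
        if not self.simulate:
            for pop in self.populations:
                ped_map = self.inputs.get("cohorts", {}).get(pop)
                if not ped_map or not Path(ped_map["ped"]).exists() or not Path(ped_map["map"]).exists():
                    raise ValueError(f"missing PED/MAP input for population {pop!r}")
            for key in ("bed", "gmt", "hierarchy"):
                p = self.inputs.get(key)
                if not p or not Path(p).exists():
                    raise ValueError(f"missing input file for {key!r}")
            if self.run_network:
                p = self.inputs.get("interactome")
                if not p or not Path(p).exists():
                    raise ValueError(
                        "network stage enabled but no interactome input given"
                    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "triopba_version": __version__,
        "seed": config.seed,
        "populations": list(config.populations),
        "stages": {},
    }

    stage = "simulate"
    try:
        if config.simulate:
            sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
            annotation, cohorts, interactome = simulate_study(
                sim_cfg, populations=config.populations
            )
            write_bed(annotation.genes, out / "genes.bed")
            write_gmt(annotation.collection, out / "terms.gmt")
            write_hierarchy(annotation.collection, out / "hierarchy.tsv")
            write_interactome(interactome, out / "interactome.tsv")
            truths = {}
            for pop, (cohort, truth) in cohorts.items():
                write_ped_map(cohort, out / f"{pop}.ped", out / f"{pop}.map")
                truths[pop] = truth.to_dict()
            with open(out / "truth.json", "w") as fh:
                json.dump(truths, fh, indent=2, sort_keys=True)
                fh.write("\n")
            genes = annotation.genes
            collection = annotation.collection
            raw_cohorts = {pop: cohort for pop, (cohort, _t) in cohorts.items()}
            manifest["stages"][stage] = {
                "outputs": ["genes.bed", "terms.gmt", "hierarchy.tsv",
                            "interactome.tsv", "truth.json"]
                + [f"{p}.ped" for p in config.populations]
                + [f"{p}.map" for p in config.populations],
            }
        else:
            genes = read_bed(config.inputs["bed"])
            collection = read_hierarchy(
                config.inputs["hierarchy"], read_gmt(config.inputs["gmt"])
            )
            collection.propagate_up()
            interactome = (
                read_interactome(config.inputs["interactome"])
                if config.run_network
                else None
            )
            raw_cohorts = {
                pop: read_ped_map(
                    config.inputs["cohorts"][pop]["ped"],
                    config.inputs["cohorts"][pop]["map"],
                )
                for pop in config.populations
            }
            manifest["stages"][stage] = {"outputs": [], "note": "inputs loaded from disk"}

        gene_lengths = {
            g: int(e - s)
            for g, s, e in zip(genes["gene_id"], genes["start"], genes["end"])
        }

        stage = "qc"
        clean, tdt_tables, score_tables = {}, {}, {}
        thresholds = QcThresholds(**config.qc)
        qc_counts = {}
        for pop in config.populations:
            cohort, report = run_qc(raw_cohorts[pop], thresholds)
            report.write_tsv(out / f"{pop}.qc_report.tsv")
            clean[pop] = cohort
            qc_counts[pop] = report.to_frame().to_dict("records")
        manifest["stages"][stage] = {
            "outputs": [f"{p}.qc_report.tsv" for p in config.populations],
            "attrition": qc_counts,
        }

        stage = "tdt"
        for pop in config.populations:
            tdt_tables[pop] = run_tdt(clean[pop])
            write_tdt(tdt_tables[pop], out / f"{pop}.tdt.tsv")
        manifest["stages"][stage] = {
            "outputs": [f"{p}.tdt.tsv" for p in config.populations]
        }

        stage = "score_genes"
        snp_maps = {}
        for pop in config.populations:
            mapping, extra = map_snps_to_genes(
                clean[pop].snps, genes, flank_bp=config.flank_bp
            )
            snp_maps[pop] = mapping
            score_tables[pop] = best_p_per_gene(tdt_tables[pop], mapping, gene_lengths)
            write_gene_scores(score_tables[pop], out / f"{pop}.gene_scores.tsv")
            with open(out / f"{pop}.extragenic_snps.tsv", "w") as fh:
                fh.write("snp_id\n")
                fh.writelines(f"{s}\n" for s in extra)
        manifest["stages"][stage] = {
            "outputs": [f"{p}.gene_scores.tsv" for p in config.populations]
            + [f"{p}.extragenic_snps.tsv" for p in config.populations]
        }

        stage = "pba"
        pba_cfg = PbaConfig(**config.pba)
        raw_tables = {
            pop: run_pba(score_tables[pop], collection, pba_cfg, adjust=False)
            for pop in config.populations
        }
        pooled = pool_fdr(raw_tables)  # every individual test in one adjustment
        for pop, table in pooled.items():
            write_enrichment(table, out / f"{pop}.enrichment.tsv")
        manifest["stages"][stage] = {
            "outputs": [f"{p}.enrichment.tsv" for p in config.populations],
            "fdr_pooling": "all populations adjusted jointly",
        }

        stage = "bias"
        for pop in config.populations:
            rep = bias_report(
                pooled[pop],
                collection,
                gene_lengths,
                scored_genes=score_tables[pop]["gene_id"],
                alpha=pba_cfg.alpha_fdr,
            )
            rep.write_tsv(out / f"{pop}.size_bias.tsv")
        manifest["stages"][stage] = {
            "outputs": [f"{p}.size_bias.tsv" for p in config.populations]
        }

        stage = "network"
        if config.run_network:
            net_cfg = NetworkScanConfig(**{**config.network, "seed": config.seed})
            net_summary = {}
            for pop in config.populations:
                ranked = score_tables[pop]["gene_id"].tolist()
                result = scan(ranked, interactome, net_cfg)
                result.write_json(out / f"{pop}.network.json")
                result.write_edges_tsv(out / f"{pop}.network_edges.tsv")
                net_summary[pop] = {
                    "n_final": result.n_final,
                    "empirical_p": result.empirical_p,
                    "significant": result.significant,
                }
            manifest["stages"][stage] = {
                "outputs": [f"{p}.network.json" for p in config.populations]
                + [f"{p}.network_edges.tsv" for p in config.populations],
                "summary": net_summary,
            }
        else:
            manifest["stages"][stage] = {"outputs": [], "note": "disabled"}

        stage = "crosspop"
        if len(config.populations) >= 2:
            union_map: dict[str, set[str]] = {}
            for mapping in snp_maps.values():
                for sid, gids in mapping.items():
                    union_map.setdefault(sid, set()).update(gids)
            tested_terms = sorted(
                {t for tab in raw_tables.values() for t in tab["term_id"]}
            )
            ranked_snps = {
                pop: tdt_tables[pop]["snp_id"].tolist() for pop in config.populations
            }
            curve = overlap_curves(
                ranked_snps,
                union_map,
                collection,
                cutoffs=config.crosspop.get("cutoffs"),
                term_universe=tested_terms,
            )
            curve.write_tsv(out / "crosspop_overlap.tsv")
            manifest["stages"][stage] = {"outputs": ["crosspop_overlap.tsv"]}
        else:
            manifest["stages"][stage] = {
                "outputs": [],
                "note": "needs at least 2 populations",
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
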