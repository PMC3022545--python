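"""End-to-end orchestration: simulate -> normalize -> match -> agree -> DE
-> concordance -> network, with a machine-readable report bundle.

Every stage writes its outputs as the TSV dialects from
:mod:`panelconcord.io_formats` into the configured output directory, and
``report.json`` lists the emitted files along with the seed, a config hash
and library versions. A fixed seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import agreement_table, interpanel_agreement, replicate_agreement
from .differential import differential_expression, fold_change_concordance
from .exceptions import ConfigurationError, StageError
from .io_formats import (
    write_expression_matrix,
    write_interaction_edges,
    write_probe_manifest,
    write_sample_metadata,
)
from .matching import match_genes, match_probe_sequences, summarize_gene_level
from .network import hub_summary, shortest_path_subnetwork
from .normalization import fastlo_normalize, log2_floor
from .synthetic import PANEL_A, PANEL_B, SimulationConfig, generate_dataset

logger = logging.getLogger("panelconcord")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "panelconcord_out"
    floor: float = 1.0
    span: float = 0.6
    max_iter: int = 5
    tol: float = 1e-3
    thresholds: list = field(default_factory=lambda: [round(0.05 * i, 2) for i in range(21)])
    max_steps: int = 2
    seed: int | None = None  # overrides simulation.seed when set

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if self.seed is not None:
            self.simulation.seed = int(self.seed)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls(**data)


@dataclass
class ReportBundle:
    out_dir: Path
    manifest: dict  # logical name -> relative file path
    metadata: dict  # seed, config hash, versions

    def path(self, name: str) -> Path:
        return self.out_dir / self.manifest[name]


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {**config.simulation.to_dict(), "floor": config.floor, "span": config.span,
         "max_iter": config.max_iter, "tol": config.tol,
         "thresholds": list(config.thresholds), "max_steps": config.max_steps},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage on a simulated two-panel dataset; see module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _emit(name: str, filename: str, writer) -> None:
        writer(out / filename)
        manifest[name] = filename

    stage = "simulate"
    try:
        truth, (mat_a, man_a), (mat_b, man_b), meta, graph = generate_dataset(config.simulation)
        logger.info("simulate: %d genes, %d + %d probes, %d samples",
                    config.simulation.n_genes, len(man_a), len(man_b), mat_a.values.shape[1])
        _emit("raw_a", "raw_1.5K.tsv", lambda p: write_expression_matrix(mat_a, p))
        _emit("raw_b", "raw_24K.tsv", lambda p: write_expression_matrix(mat_b, p))
        _emit("manifest_a", "manifest_1.5K.tsv", lambda p: write_probe_manifest(man_a, p))
        _emit("manifest_b", "manifest_24K.tsv", lambda p: write_probe_manifest(man_b, p))
        _emit("metadata", "metadata.tsv", lambda p: write_sample_metadata(meta, p))
        _emit("edges", "edges.tsv", lambda p: write_interaction_edges(graph, p))

        stage = "normalize"
        norm = {}
        for panel, mat in ((PANEL_A, mat_a), (PANEL_B, mat_b)):
            res = fastlo_normalize(
                log2_floor(mat, config.floor),
                span=config.span, max_iter=config.max_iter, tol=config.tol,
            )
            logger.info("normalize %s: %d iterations, converged=%s",
                        panel, res.iterations, res.converged)
            norm[panel] = res.matrix
        _emit("norm_a", "norm_1.5K.tsv", lambda p: write_expression_matrix(norm[PANEL_A], p))
        _emit("norm_b", "norm_24K.tsv", lambda p: write_expression_matrix(norm[PANEL_B], p))

        stage = "match"
        matches = match_genes(man_a, man_b)
        seq_matches = match_probe_sequences(man_a, man_b)
        logger.info("match: %d genes (tiers %s), %d sequence-matched probe pairs",
                    len(matches), matches["tier"].value_counts().to_dict(), len(seq_matches))
        _emit("matches", "gene_matches.tsv",
              lambda p: matches.to_csv(p, sep="\t", index=False))
        _emit("seq_matches", "seq_matches.tsv",
              lambda p: seq_matches.to_csv(p, sep="\t", index=False))
        gene_a = summarize_gene_level(norm[PANEL_A], matches, "A")
        gene_b = summarize_gene_level(norm[PANEL_B], matches, "B")
        _emit("gene_a", "gene_1.5K.tsv", lambda p: write_expression_matrix(gene_a, p))
        _emit("gene_b", "gene_24K.tsv", lambda p: write_expression_matrix(gene_b, p))

        stage = "agree"
        agree_frames = []
        for panel, gm in (("1.5K", gene_a), ("24K", gene_b)):
            for mode in ("technical", "extract"):
                tab = agreement_table(replicate_agreement(gm, meta, mode, span=config.span))
                if not tab.empty:
                    tab.insert(0, "panel", panel)
                    tab.insert(1, "mode", mode)
                    agree_frames.append(tab)
        inter = agreement_table(
            interpanel_agreement(gene_a, gene_b, units="genes", span=config.span)
        )
        inter.insert(0, "panel", "both")
        inter.insert(1, "mode", "interpanel_genes")
        agree_frames.append(inter)
        inter_seq = agreement_table(
            interpanel_agreement(norm[PANEL_A], norm[PANEL_B], units="seq_probes",
                                 seq_matches=seq_matches, span=config.span)
        ) if len(seq_matches) >= 3 else pd.DataFrame()
        if not inter_seq.empty:
            inter_seq.insert(0, "panel", "both")
            inter_seq.insert(1, "mode", "interpanel_seq_probes")
            agree_frames.append(inter_seq)
        agree_all = pd.concat(agree_frames, ignore_index=True)
        _emit("agreement", "agreement.tsv",
              lambda p: agree_all.to_csv(p, sep="\t", index=False, float_format="%.12g"))

        stage = "differential"
        de_tables = {}
        for panel, probe_mat, gene_mat in (
            ("1.5K", norm[PANEL_A], gene_a),
            ("24K", norm[PANEL_B], gene_b),
        ):
            for level, mat in (("probe", probe_mat), ("gene", gene_mat)):
                de = differential_expression(mat, meta, level)
                de_tables[(panel, level)] = de
                _emit(f"de_{panel}_{level}", f"de_{panel}_{level}.tsv",
                      lambda p, de=de: de.to_csv(p, sep="\t", index=False, float_format="%.12g"))

        stage = "concordance"
        curve = fold_change_concordance(
            de_tables[("1.5K", "gene")], de_tables[("24K", "gene")],
            thresholds=np.asarray(config.thresholds, dtype=float),
        )
        _emit("concordance", "concordance.tsv",
              lambda p: curve.to_csv(p, sep="\t", index=False, float_format="%.12g"))

        stage = "network"
        de_a = de_tables[("1.5K", "gene")]
        de_b = de_tables[("24K", "gene")]
        cand_a = set(de_a.loc[de_a["candidate"], "unit_id"])
        cand_b = set(de_b.loc[de_b["candidate"], "unit_id"])
        seeds = sorted(cand_a & cand_b) or sorted(cand_a | cand_b)
        logger.info("network: %d seed genes", len(seeds))
        sub = shortest_path_subnetwork(graph, seeds, max_steps=config.max_steps)
        _emit("subnetwork", "subnetwork.tsv",
              lambda p: write_interaction_edges(sub.graph, p))
        hubs = hub_summary(sub)
        _emit("hubs", "hubs.tsv", lambda p: hubs.to_csv(p, sep="\t", index=False))

        stage = "report"
        metadata = {
            "seed": config.simulation.seed,
            "config_hash": _config_hash(config),
            "package_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "networkx_version": nx.__version__,
            "seeds_network": seeds,
            "unplaced_seeds": sub.unplaced,
        }
        bundle = ReportBundle(out_dir=out, manifest=manifest, metadata=metadata)
        with open(out / "report.json", "w") as fh:
            json.dump({"manifest": manifest, "metadata": metadata}, fh, indent=2, sort_keys=True)
        return bundle
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, str(exc)) from exc
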