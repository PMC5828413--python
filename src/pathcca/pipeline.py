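"""End-to-end run: load or simulate a compendium, screen pathways, build
the gene-pair network baseline, test enrichment, and write all artifacts.

A run is described by a :class:`PipelineConfig` (parsed from a YAML file by
:func:`load_config`) naming either three input files (expression TSV,
pathway GMT, disease gene list) or a simulation block; identical config and
seed always reproduce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .io import (
    GeneList,
    read_expression_matrix,
    read_gene_list,
    read_gmt,
    write_edge_list,
    write_enrichment_table,
    write_expression_matrix,
    write_gene_list,
    write_gmt,
    write_screen_table,
)
from .network import (
    bipartite_pearson_network,
    connected_components,
    hub_nodes,
    hypergeometric_enrichment,
)
from .screen import PathwayScreen, ScreenThresholds, get_preset
from .simulate import SimParams, generate_compendium

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Exactly one of (expression+pathways+disease paths) or ``simulation``
    must be given.
    """

    expression: str | None = None
    pathways: str | None = None
    disease: str | None = None
    simulation: SimParams | None = None
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    network_r_min: float = 0.6
    network_mode: str = "signed"
    output_dir: str = "pathcca_out"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        has_files = all(x is not None for x in (self.expression, self.pathways, self.disease))
        some_files = any(x is not None for x in (self.expression, self.pathways, self.disease))
        if self.simulation is not None and some_files:
            raise ValueError("give input paths or a simulation block, not both")
        if self.simulation is None and not has_files:
            raise ValueError(
                "config needs either expression+pathways+disease paths "
                "or a simulation block"
            )


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML config file into a :class:`PipelineConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulation", None)
    thr = raw.pop("thresholds", None)
    cfg = PipelineConfig(
        simulation=SimParams(**sim) if sim is not None else None,
        thresholds=_parse_thresholds(thr),
        **raw,
    )
    return cfg


def _parse_thresholds(thr) -> ScreenThresholds:
    if thr is None:
        return ScreenThresholds()
    if isinstance(thr, str):
        return get_preset(thr)
    if isinstance(thr, dict):
        preset = thr.pop("preset", None)
        base = get_preset(preset) if preset else ScreenThresholds()
        return dataclasses.replace(base, **thr)
    if isinstance(thr, ScreenThresholds):
        return thr
    raise ValueError(f"cannot parse thresholds from {thr!r}")


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulation is not None:
        sim = dataclasses.replace(cfg.simulation, seed=cfg.simulation.seed or cfg.seed)
        expr, pathways, disease, truth = generate_compendium(sim)
        return expr, pathways, disease, truth
    for path in (cfg.expression, cfg.pathways, cfg.disease):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    return (
        read_expression_matrix(cfg.expression),
        read_gmt(cfg.pathways),
        read_gene_list(cfg.disease),
        None,
    )


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute simulate/load -> screen -> network -> enrichment -> report.

    Returns a name -> path mapping of the written artifacts:
    screen_table.tsv, network_edges.tsv, enrichment.tsv, run_log.txt.
    """
    expr, pathways, disease, truth = _load_inputs(cfg)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    n_before = expr.n_genes
    expr = expr.drop_missing_genes()
    n_dropped_missing = n_before - expr.n_genes

    screen = PathwayScreen(thresholds=cfg.thresholds).fit(expr, pathways, disease)
    screen_path = outdir / "screen_table.tsv"
    write_screen_table(screen.records_, screen_path)

    measured = set(expr.gene_ids)
    pathway_union = [g for g in pathways.all_genes() if g in measured]
    metabolic = GeneList(pathway_union)
    net = bipartite_pearson_network(
        expr, disease, metabolic, r_min=cfg.network_r_min, mode=cfg.network_mode
    )
    edges_path = outdir / "network_edges.tsv"
    write_edge_list(net, edges_path)

    connected_met = [g for g in net.connected_nodes() if net.node_class(g) == "metabolic"]
    enrich_path = outdir / "enrichment.tsv"
    if connected_met:
        rows = hypergeometric_enrichment(GeneList(connected_met), pathways, metabolic)
    else:
        rows = []
    write_enrichment_table(rows, enrich_path)

    comps = connected_components(net)
    log_path = outdir / "run_log.txt"
    with log_path.open("w") as fh:
        fh.write(f"pathcca {__version__}\n")
        fh.write(f"seed\t{cfg.seed}\n")
        cfg_dict = dataclasses.asdict(cfg)
        for key in sorted(cfg_dict):
            fh.write(f"config.{key}\t{cfg_dict[key]!r}\n")
        fh.write(f"genes_dropped_missing\t{n_dropped_missing}\n")
        fh.write(f"disease_genes_used\t{screen.n_disease_genes_used_}\n")
        fh.write(f"pathways_screened\t{len(screen.records_)}\n")
        fh.write(f"pathways_passed\t{sum(r.passed for r in screen.records_)}\n")
        fh.write(f"network_nodes\t{net.n_nodes}\tnetwork_edges\t{net.n_edges}\n")
        fh.write(f"connected_disease_genes\t"
                 f"{sum(1 for g in net.connected_nodes() if net.node_class(g) == 'disease')}\n")
        fh.write(f"connected_metabolic_genes\t{len(connected_met)}\n")
        for i, comp in enumerate(comps, start=1):
            fh.write(f"component_{i}\tsize={comp.n_nodes}\thubs={','.join(hub_nodes(comp))}\n")
        if truth is not None:
            fh.write(f"truth.linked_pathways\t{truth.linked_pathways}\n")
            fh.write(f"truth.rho_canonical\t{truth.rho_canonical}\n")

    return {
        "screen_table": screen_path,
        "network_edges": edges_path,
        "enrichment": enrich_path,
        "run_log": log_path,
    }


def write_simulated_inputs(params: SimParams, outdir: str | Path) -> dict[str, Path]:
    """Generate a compendium and write it in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, pathways, disease, truth = generate_compendium(params)
    paths = {
        "expression": outdir / "expression.tsv",
        "pathways": outdir / "pathways.gmt",
        "disease": outdir / "disease_genes.txt",
        "truth": outdir / "truth.txt",
    }
    write_expression_matrix(expr, paths["expression"])
    write_gmt(pathways, paths["pathways"])
    write_gene_list(disease, paths["disease"])
    with paths["truth"].open("w") as fh:
        fh.write(f"linked_pathways\t{','.join(map(str, truth.linked_pathways))}\n")
        fh.write(f"rho_gene\t{truth.rho_gene:.6f}\n")
        for j, rho in sorted(truth.rho_canonical.items()):
            fh.write(f"rho_canonical[{j}]\t{rho:.6f}\n")
        fh.write(f"seed\t{truth.seed}\n")
    return paths
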