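"""Config-driven orchestration: simulate -> score -> network -> enrichment.

A run is fully described by a :class:`PipelineConfig` (usually loaded
from YAML).  The default configuration simulates a coherent study over
one gene namespace: a planted-partition interactome over ``n_genes``
genes, a chemical-genomic growth screen whose planted sensitive and
resistant strains sit inside the first block, a per-cell microscopy
table with planted abundance shifts on genes of the same block, and a
gene-set collection whose first set is that block.  Downstream stages
then recover the planted structure: hit calls -> merged seed list ->
high-confidence subnetwork -> communities and their significance ->
per-community pathway enrichment.

Every stage writes plain TSV/JSON outputs; a manifest records the
config echo, the master seed, package version, and SHA-256 checksums
of every output, so two runs of the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io, microscopy, network, screen, synthetic
from .enrichment import enrich_communities
from .mapeq import detect_communities

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "merge_gene_lists", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run (defaults define the simulated study)."""

    seed: int = 1
    out_dir: str = "chemnet_run"
    stages: tuple[str, ...] = ("simulate", "screens", "microscopy",
                               "network", "enrichment")

    # simulated study shape
    n_genes: int = 100
    n_blocks: int = 4
    p_in: float = 0.5
    p_out: float = 0.02
    frac_high_confidence: float = 0.7
    frac_experimental: float = 0.9
    n_sensitive: int = 8
    n_resistant: int = 2
    sensitive_multiplier: float = 0.5
    resistant_multiplier: float = 1.5
    noise_sd: float = 0.05
    replicates: int = 3
    n_screens: int = 3
    n_cells: int = 200
    abundance_shift_pct: float = 50.0
    n_shifted_proteins: int = 4
    n_gene_sets: int = 20
    gene_set_size: int = 12

    # thresholds
    validation_lower: float = 75.0
    validation_upper: float = 130.0
    alpha: float = 0.05
    min_screens: int = 2
    abundance_cutoff: float = 20.0
    min_cells: int = 50

    # network / enrichment
    min_combined: int = 900
    require_experimental: bool = True
    network_mode: str = "first-order"  # or "minimum"
    n_null: int = 199
    fdr: float = 0.05

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if self.validation_lower >= self.validation_upper:
            raise ValueError("validation thresholds: lower must be < upper")
        if self.network_mode not in ("first-order", "minimum"):
            raise ValueError(f"unknown network mode {self.network_mode!r}")
        unknown = set(self.stages) - {"simulate", "screens", "microscopy",
                                      "network", "enrichment"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def merge_gene_lists(**lists: list[str]) -> pd.DataFrame:
    """Union of per-source hit lists with provenance flags.

    Keyword arguments name the sources (e.g. ``chemgen=..., sga=...,
    microscopy=...``).  Gene ids are case-normalized; duplicates
    collapse.  Raises when the union is empty (the network stage would
    have no seeds).
    """
    genes: dict[str, set[str]] = {}
    for source, ids in lists.items():
        for gid in ids:
            genes.setdefault(network.normalize_id(gid), set()).add(source)
    if not genes:
        raise ValueError("zero hits across all sources: nothing to seed the network")
    rows = [(g, *(src in genes[g] for src in lists)) for g in sorted(genes)]
    return pd.DataFrame(rows, columns=["gene", *lists])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write all outputs.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    outputs: list[Path] = []
    summary: dict = {}

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    block_size = cfg.n_genes // cfg.n_blocks
    block0 = genes[:block_size]

    # ---- simulate ---------------------------------------------------------
    if "simulate" in cfg.stages:
        try:
            sens = block0[:cfg.n_sensitive]
            resist = block0[cfg.n_sensitive:cfg.n_sensitive + cfg.n_resistant]
            mult = {g: cfg.sensitive_multiplier for g in sens}
            mult.update({g: cfg.resistant_multiplier for g in resist})
            truth = synthetic.ScreenTruth(tuple(genes), mult, cfg.noise_sd,
                                          cfg.replicates, cfg.seed)
            scores = synthetic.gen_screen_scores(truth, cfg.n_screens)
            scores.to_csv(out / "screen_scores.tsv", sep="\t", index=False)

            blocks = {g: i // block_size for i, g in enumerate(genes)}
            net_truth = synthetic.NetworkTruth(
                blocks, cfg.p_in, cfg.p_out,
                frac_high_confidence=cfg.frac_high_confidence,
                frac_experimental=cfg.frac_experimental, seed=cfg.seed)
            edges, net_truth_d = synthetic.gen_interactome(
                cfg.n_genes, "planted_partition", truth=net_truth, seed=cfg.seed)
            io.write_edge_tsv(edges, out / "interactome.tsv")

            shifted = block0[cfg.n_sensitive + cfg.n_resistant:][:cfg.n_shifted_proteins]
            cells, mic_truth = synthetic.gen_microscopy_table(
                n_strains=cfg.n_genes, n_cells=cfg.n_cells,
                abundance_shifts={}, seed=cfg.seed)
            # strain ids in the shared gene namespace, shifts on block-0 genes
            cells["strain"] = cells["strain"].map(
                dict(zip(sorted(cells["strain"].unique()), genes)))
            shift_map = {g: cfg.abundance_shift_pct for g in shifted}
            treated = cells["condition"] == "treated"
            factor = cells["strain"].map(shift_map).fillna(0.0) / 100.0 + 1.0
            cells.loc[treated, "gfp"] *= factor[treated]
            mic_truth["abundance_shifts"] = shift_map
            io.write_cell_tsv(cells, out / "cells.tsv")

            sets = {}
            for i in range(cfg.n_gene_sets):
                rng = synthetic.substream(cfg.seed, "pipeline_sets", i)
                if i == 0:
                    sets["set000"] = set(block0[:cfg.gene_set_size])
                else:
                    sets[f"set{i:03d}"] = set(rng.choice(genes, cfg.gene_set_size,
                                                         replace=False))
            io.write_gmt(sets, out / "genesets.gmt")
            io.write_json({"screen": truth.as_dict(), "network": net_truth_d,
                           "microscopy": mic_truth,
                           "planted_set": "set000"}, out / "truth.json")
            outputs += [out / f for f in ("screen_scores.tsv", "interactome.tsv",
                                          "cells.tsv", "genesets.gmt", "truth.json")]
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    # ---- screens ----------------------------------------------------------
    hit_genes: list[str] = []
    if "screens" in cfg.stages:
        try:
            scores = pd.read_csv(out / "screen_scores.tsv", sep="\t")
            calls = screen.call_hits(
                scores, stage="screen",
                thresholds=(cfg.validation_lower, cfg.validation_upper),
                alpha=cfg.alpha, min_screens=cfg.min_screens)
            calls.to_csv(out / "screen_calls.tsv", sep="\t", index=False)
            outputs.append(out / "screen_calls.tsv")
            hit_genes = calls.loc[calls["call"].isin(["sensitive", "resistant"]),
                                  "strain"].tolist()
            summary["screen_hits"] = len(hit_genes)
        except Exception as exc:
            raise RuntimeError(f"stage 'screens' failed: {exc}") from exc

    # ---- microscopy -------------------------------------------------------
    mic_genes: list[str] = []
    if "microscopy" in cfg.stages:
        try:
            cells = io.read_cell_tsv(out / "cells.tsv")
            mic = microscopy.score_microscopy(cells, cutoff=cfg.abundance_cutoff,
                                              min_cells=cfg.min_cells)
            mic.to_csv(out / "microscopy_calls.tsv", sep="\t", index=False)
            outputs.append(out / "microscopy_calls.tsv")
            mic_genes = mic.loc[mic["flagged"] | mic["shifted"], "strain"].tolist()
            summary["microscopy_hits"] = len(mic_genes)
        except Exception as exc:
            raise RuntimeError(f"stage 'microscopy' failed: {exc}") from exc

    # ---- network ----------------------------------------------------------
    subnet = None
    if "network" in cfg.stages:
        try:
            seeds_df = merge_gene_lists(chemgen=hit_genes, microscopy=mic_genes)
            seeds_df.to_csv(out / "seeds.tsv", sep="\t", index=False)
            io.write_gene_list(seeds_df["gene"], out / "seeds.txt")
            g = network.load_interactome(out / "interactome.tsv",
                                         cfg.min_combined, cfg.require_experimental)
            extract = (network.first_order_network if cfg.network_mode == "first-order"
                       else network.minimum_network)
            subnet = extract(g, seeds_df["gene"].tolist())
            subnet.partition = detect_communities(subnet.graph, seed=cfg.seed)
            subnet.community_p = network.community_significance(
                subnet, subnet.partition, n_null=cfg.n_null, seed=cfg.seed)
            subnet.node_table().to_csv(out / "network_nodes.tsv", sep="\t",
                                       index=False)
            edge_rows = [(u, v, d["experimental"], d["combined_score"])
                         for u, v, d in sorted(subnet.graph.edges(data=True))]
            pd.DataFrame(edge_rows, columns=io.EDGE_COLUMNS).to_csv(
                out / "network_edges.tsv", sep="\t", index=False)
            outputs += [out / f for f in ("seeds.tsv", "seeds.txt",
                                          "network_nodes.tsv", "network_edges.tsv")]
            summary["n_seeds"] = len(seeds_df)
            summary["n_network_nodes"] = subnet.graph.number_of_nodes()
            summary["n_communities"] = subnet.partition.n_communities
            summary["significant_communities"] = sorted(
                c for c, p in subnet.community_p.items() if p < 0.05)
        except Exception as exc:
            raise RuntimeError(f"stage 'network' failed: {exc}") from exc

    # ---- enrichment -------------------------------------------------------
    if "enrichment" in cfg.stages:
        try:
            if subnet is None or subnet.partition is None:
                raise ValueError("enrichment stage requires the network stage")
            collection = io.read_gmt(out / "genesets.gmt")
            collection = {name: {network.normalize_id(g) for g in members}
                          for name, members in collection.items()}
            res = enrich_communities(subnet.partition, collection,
                                     universe=[network.normalize_id(g) for g in genes])
            res.to_csv(out / "community_enrichment.tsv", sep="\t", index=False)
            outputs.append(out / "community_enrichment.tsv")
            sig = res[(res["status"] == "tested") & (res["p_adj"] < cfg.fdr)]
            summary["enriched"] = [
                {"community": int(r.community), "set": r.set,
                 "p_adj": float(r.p_adj)} for r in sig.itertuples()]
        except Exception as exc:
            raise RuntimeError(f"stage 'enrichment' failed: {exc}") from exc

    manifest = {
        "package": "chemnet",
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "outputs": {p.name: _sha256(p) for p in sorted(set(outputs))},
        "summary": summary,
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
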