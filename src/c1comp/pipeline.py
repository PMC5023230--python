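"""End-to-end pipeline: AAI -> inventory -> islands, with reporting.

Glue only: every computation lives in the stage modules.  Outputs are
plain TSV/JSON so each stage can be rerun independently, and a manifest
records every parameter value and input checksum; a rerun on identical
inputs and parameters is byte-identical.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aai as aai_mod
from . import inventory as inv_mod
from . import islands as isl_mod
from .seqio import GenomeBundle, ReferencePanel, load_genome_dir, read_panel, write_report

log = logging.getLogger("c1comp")


@dataclass
class PipelineConfig:
    """All stage parameters for one pipeline run.

    ``genome_dirs`` lists per-genome directories (proteins.faa +
    features.tsv/gff3 + optional contigs.fna); ``panel_fasta`` /
    ``panel_meta`` point at the reference panel.  Stage parameters carry
    the module defaults unless overridden.
    """

    genome_dirs: list[str] = field(default_factory=list)
    panel_fasta: str | None = None
    panel_meta: str | None = None
    outdir: str = "c1c_out"
    # alignment / hit filtering
    min_identity_pct: float = 30.0
    min_short_coverage: float = 0.7
    min_length: int = 50
    prescreen_k: int | None = 8
    # inventory
    inventory_min_ref_coverage: float = 0.4
    partial_threshold: float = 0.5
    type_linkage_pct: float = 50.0
    fragment_functions: list[str] = field(default_factory=list)
    # islands
    max_gap: int = 3
    min_size: int = 3
    lateral_margin: float = 15.0
    vertical_band: float = 10.0
    groups: dict = field(default_factory=dict)
    # simulation passthrough
    seed: int | None = None

    def validate(self) -> None:
        if not self.genome_dirs:
            raise ValueError("no genome directories configured")
        if (self.panel_fasta is None) != (self.panel_meta is None):
            raise ValueError("panel_fasta and panel_meta must be given together")
        if self.min_identity_pct < 0 or self.min_short_coverage < 0:
            raise ValueError("thresholds must be non-negative")
        if self.max_gap < 0 or self.min_size < 1:
            raise ValueError("invalid cluster parameters")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _aai_stage(genomes: list[GenomeBundle], cfg: PipelineConfig, outdir: Path):
    filt = aai_mod.HitFilter(cfg.min_identity_pct, cfg.min_short_coverage,
                             cfg.min_length)
    matrix = aai_mod.aai_matrix(genomes, filter=filt, prescreen_k=cfg.prescreen_k)
    mat = matrix.values.round(1)
    mat.index.name = "genome"
    mat.reset_index().to_csv(outdir / "aai.tsv", sep="\t", index=False,
                             float_format="%.1f")
    pair_rows = []
    for key, rbh in sorted(matrix.rbh.items(),
                           key=lambda kv: sorted(kv[0])):
        for p in rbh.pairs:
            pair_rows.append({
                "genome_a": rbh.genome_a, "genome_b": rbh.genome_b,
                "locus_a": p.query_tag, "locus_b": p.subject_tag,
                "identity_pct": p.identity_pct, "score": p.score,
            })
    write_report(pd.DataFrame(
        pair_rows, columns=["genome_a", "genome_b", "locus_a", "locus_b",
                            "identity_pct", "score"]),
        outdir / "rbh_pairs.tsv")

    markers = []
    for ga, gb in itertools.combinations(genomes, 2):
        try:
            markers.append(aai_mod.marker_identity(ga, gb))
        except aai_mod.AAIError as exc:
            log.warning("marker identity skipped: %s", exc)
    fig1 = aai_mod.fig1_table(matrix, markers)
    write_report(fig1, outdir / "fig1_table.tsv")
    log.info("stage=aai genomes=%d pairs=%d rbh_total=%d", len(genomes),
             len(matrix.results), sum(len(r) for r in matrix.rbh.values()))
    return matrix


def _inventory_stage(genomes, panel: ReferencePanel, cfg: PipelineConfig,
                     outdir: Path):
    th = inv_mod.InventoryThresholds(
        min_identity_pct=cfg.min_identity_pct,
        min_ref_coverage=cfg.inventory_min_ref_coverage,
        partial_threshold=cfg.partial_threshold,
        type_linkage_pct=cfg.type_linkage_pct,
    )
    matrix = inv_mod.build_inventory(genomes, panel, th,
                                     fragment_functions=cfg.fragment_functions)
    frame = matrix.to_frame()
    frame.reset_index().to_csv(outdir / "inventory.tsv", sep="\t", index=False)
    log.info("stage=inventory genomes=%d functions=%d hits=%d",
             len(genomes), len(matrix.functions), len(matrix.hits))
    return matrix


def _island_stage(genomes, inv_matrix, aai_matrix, cfg: PipelineConfig,
                  outdir: Path):
    hits_by_genome: dict[str, list] = {g.label: [] for g in genomes}
    for h in inv_matrix.hits:
        hits_by_genome[h.genome].append(h)
    report = isl_mod.island_report(
        genomes, hits_by_genome, aai_matrix,
        max_gap=cfg.max_gap, min_size=cfg.min_size,
        margins=isl_mod.TransferMargins(cfg.lateral_margin, cfg.vertical_band),
        groups=cfg.groups or None,
    )
    write_report(report.clusters, outdir / "clusters.tsv")
    write_report(report.transfer_calls, outdir / "transfer_calls.tsv")
    write_report(report.cluster_verdicts, outdir / "cluster_verdicts.tsv")
    log.info("stage=islands clusters=%d calls=%d",
             report.clusters["cluster_id"].nunique() if len(report.clusters) else 0,
             len(report.transfer_calls))
    return report


def run_pipeline(config: PipelineConfig):
    """Run aai -> inventory -> islands and write the report bundle.

    Returns (aai_matrix | None, inventory_matrix | None, island_report).
    A single-genome input skips the AAI stage with a warning; a missing
    panel skips inventory and islands.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes = [load_genome_dir(d) for d in config.genome_dirs]
    genomes.sort(key=lambda g: g.label)

    manifest: dict = {"parameters": {
        k: v for k, v in vars(config).items() if k != "genome_dirs"}}
    manifest["inputs"] = {}
    for d in config.genome_dirs:
        for f in sorted(Path(d).glob("*")):
            if f.is_file():
                manifest["inputs"][str(f)] = _checksum(f)
    for p in (config.panel_fasta, config.panel_meta):
        if p:
            manifest["inputs"][p] = _checksum(Path(p))

    aai_matrix = None
    if len(genomes) >= 2:
        aai_matrix = _aai_stage(genomes, config, outdir)
    else:
        log.warning("single genome: AAI stage skipped")

    inv_matrix = None
    report = None
    if config.panel_fasta:
        panel = read_panel(config.panel_fasta, config.panel_meta)
        inv_matrix = _inventory_stage(genomes, panel, config, outdir)
        report = _island_stage(genomes, inv_matrix, aai_matrix, config, outdir)
    else:
        log.warning("no reference panel: inventory and island stages skipped")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return aai_matrix, inv_matrix, report
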