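"""End-to-end orchestration: counts in, network artifacts and key genes out.

``run_pipeline`` executes the stages in order — size-factor normalization,
variance-stabilizing transform, variance filtering, soft-threshold
selection, global network + TOM + modules, module eigengenes and
module-trait relationships, the two condition-specific networks with their
statistics and centralities, the centrality-change table and key hub genes,
and (when a GMT is supplied) per-module over-representation analysis. Every
artifact is written as TSV under the output directory and a JSON manifest
records the configuration hash plus a SHA-256 checksum per file, so
re-running an identical configuration is byte-verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from coexnet import enrichment as enr
from coexnet import io, netstats, preprocess, two_state, wgcna

log = logging.getLogger("coexnet")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of the analysis, with the workflow's published defaults."""

    counts: str
    sample_sheet: str
    out_dir: str
    gmt: str | None = None
    variance_percentile: float = 95.0
    powers: tuple[int, ...] = tuple(range(1, 21))
    r2_cut: float = 0.9
    power: int | None = None  # fixed soft threshold; None = auto-select
    min_module_size: int = 35
    cut_height: float | None = None
    edge_threshold: float = 0.1
    key_threshold: float = 80.0
    allow_real_counts: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.variance_percentile < 100:
            raise ValueError("variance_percentile must be in [0, 100)")
        if not 0 < self.edge_threshold <= 1:
            raise ValueError("edge_threshold must be in (0, 1]")
        if not 0 < self.key_threshold <= 100:
            raise ValueError("key_threshold must be in (0, 100]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if isinstance(raw.get("powers"), list):
            raw["powers"] = tuple(raw["powers"])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _state_network(x: pd.DataFrame, beta: int, threshold: float):
    """Correlation -> |r|^beta -> TOM -> thresholded graph for one state.

    Genes flat across this state's samples are dropped first (they cannot
    carry edges and would make the correlation undefined).
    """
    variances = x.var(axis=1, ddof=1)
    x = x.loc[variances > 0]
    r = wgcna.pearson_correlation(x)
    a = wgcna.soft_adjacency(r, beta)
    t = wgcna.tom_similarity(a)
    return netstats.build_network(t, min_weight=threshold), t


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, write artifacts under ``cfg.out_dir``, return the
    manifest (also written as ``manifest.json``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    t0 = time.monotonic()

    def stage(name):
        log.info("stage %-18s (t=%.1fs)", name, time.monotonic() - t0)
        return name

    current = "setup"
    try:
        current = stage("read_counts")
        counts = io.read_counts(cfg.counts, allow_real=cfg.allow_real_counts)

        current = stage("read_sample_sheet")
        sheet = io.read_sample_sheet(cfg.sample_sheet, counts=counts)

        current = stage("size_factors")
        s = preprocess.estimate_size_factors(counts)
        files["size_factors"] = out / "size_factors.tsv"
        s.rename_axis("sample_id").to_frame().to_csv(files["size_factors"], sep="\t")

        current = stage("vst")
        x = preprocess.vst_transform(counts, s)

        current = stage("variance_filter")
        x = preprocess.filter_by_variance(x, percentile=cfg.variance_percentile)
        files["expression_filtered"] = out / "expression_filtered.tsv"
        x.rename_axis("gene_id").to_csv(
            files["expression_filtered"], sep="\t", float_format="%.6g"
        )

        current = stage("pick_soft_threshold")
        report = wgcna.pick_soft_threshold(x, powers=cfg.powers, r2_cut=cfg.r2_cut)
        beta = cfg.power if cfg.power is not None else report.power
        files["soft_threshold_report"] = out / "soft_threshold_report.tsv"
        report.to_tsv(files["soft_threshold_report"])
        if not report.reached_cut and cfg.power is None:
            log.warning(
                "no candidate power reached signed R^2 >= %.2f; using best (%d)",
                cfg.r2_cut, beta,
            )

        current = stage("global_network")
        r = wgcna.pearson_correlation(x)
        a = wgcna.soft_adjacency(r, beta)
        tom = wgcna.tom_similarity(a)
        g_global = netstats.build_network(tom, min_weight=cfg.edge_threshold)

        current = stage("modules")
        modules = wgcna.cluster_modules(
            tom, min_module_size=cfg.min_module_size, cut_height=cfg.cut_height
        )
        files["module_assignment"] = out / "module_assignment.tsv"
        modules.rename_axis("gene_id").to_frame().to_csv(
            files["module_assignment"], sep="\t"
        )

        current = stage("eigengenes")
        eigengenes = wgcna.module_eigengenes(x, modules)
        files["eigengenes"] = out / "eigengenes.tsv"
        eigengenes.rename_axis("sample_id").to_csv(
            files["eigengenes"], sep="\t", float_format="%.6g"
        )

        current = stage("mtr")
        design = wgcna.trait_design(sheet)
        mtr = wgcna.module_trait_relationships(eigengenes, design)
        files["mtr"] = out / "mtr.tsv"
        mtr.to_csv(files["mtr"], sep="\t", index=False, float_format="%.6g")

        current = stage("state_networks")
        graphs = {"global": g_global}
        for state, cond in (("normal", "control"), ("saline", "salt")):
            cols = sheet.loc[sheet["condition"] == cond, "sample_id"]
            graphs[state], _ = _state_network(
                x[cols], beta, cfg.edge_threshold
            )

        current = stage("network_stats")
        stats_rows = []
        for name, g in graphs.items():
            files[f"edges_{name}"] = out / f"edges_{name}.tsv"
            netstats.write_edge_list(g, files[f"edges_{name}"])
            row = netstats.network_properties(g).to_frame()
            row.insert(0, "network", name)
            stats_rows.append(row)
        files["network_stats"] = out / "network_stats.tsv"
        pd.concat(stats_rows, ignore_index=True).to_csv(
            files["network_stats"], sep="\t", index=False, float_format="%.6g"
        )

        current = stage("centralities")
        centralities = {}
        for name, g in graphs.items():
            tab = netstats.node_centralities(g)
            centralities[name] = tab
            files[f"centrality_{name}"] = out / f"centrality_{name}.tsv"
            annotated = tab.copy()
            annotated.insert(0, "module", modules.reindex(tab.index).fillna("grey"))
            annotated.to_csv(
                files[f"centrality_{name}"], sep="\t", float_format="%.6g"
            )

        current = stage("centrality_change")
        norm_n = (
            two_state.normalize_centrality(centralities["normal"])
            if len(centralities["normal"])
            else centralities["normal"]
        )
        norm_s = (
            two_state.normalize_centrality(centralities["saline"])
            if len(centralities["saline"])
            else centralities["saline"]
        )
        changes = two_state.centrality_change(norm_n, norm_s)
        files["centrality_change"] = out / "centrality_change.tsv"
        changes_out = changes.copy()
        changes_out["in_global"] = changes_out.index.isin(graphs["global"].nodes)
        changes_out.to_csv(
            files["centrality_change"], sep="\t", float_format="%.6g"
        )

        current = stage("key_genes")
        keys = two_state.identify_key_genes(
            changes, graphs["global"].nodes, modules=modules,
            threshold=cfg.key_threshold,
        )
        files["key_genes"] = out / "key_genes.tsv"
        keys.to_csv(files["key_genes"], sep="\t", float_format="%.6g")
        files["key_gene_summary"] = out / "key_gene_summary.tsv"
        two_state.key_gene_summary(modules, keys).to_csv(
            files["key_gene_summary"], sep="\t"
        )

        if cfg.gmt is not None:
            current = stage("enrichment")
            annotations = io.read_gmt(cfg.gmt)
            universe = set(modules.index) & set(annotations.all_genes())
            module_sets = {
                m: set(genes) & universe
                for m, genes in (
                    (m, modules.index[modules == m]) for m in pd.unique(modules)
                )
                if m != wgcna.UNASSIGNED and len(set(genes) & universe) > 0
            }
            table = enr.hypergeom_enrich(module_sets, annotations, universe=universe)
            files["enrichment"] = out / "enrichment.tsv"
            table.to_csv(files["enrichment"], sep="\t", index=False, float_format="%.6g")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(current, exc) from exc

    current = stage("manifest")
    manifest = {
        "config": asdict(cfg),
        "config_sha256": cfg.digest(),
        "power_used": int(beta),
        "files": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline done in %.1fs", time.monotonic() - t0)
    return manifest
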