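"""Config-driven orchestration of end-to-end screen analysis runs.

A run is described by one structured YAML config with a stage list, per-stage
parameter blocks, and a mandatory global seed. Stages execute in dependency
order; every table written carries a provenance header (tool version, config
hash, seed) as comment lines. On stage failure, files written by the failing
stage are retained with a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import clones as clones_mod
from . import enrichment
from .counting import ReadLayout, UmiCountTable, count_guides, write_count_table
from .synthetic import (
    GuideLibrary,
    ScreenDesign,
    default_fitness,
    emit_reads,
    make_library,
    simulate_invivo_screen,
)

logger = logging.getLogger("cropscreen")

STAGE_ORDER = ["simulate", "count", "split_replicates", "clones", "test", "ssmd"]


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    stages: list[str]
    seed: int
    outdir: Path
    params: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ConfigError("config must define a global seed")
        stages = raw.get("stages", [])
        unknown = [s for s in stages if s not in STAGE_ORDER]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")
        cfg = cls(
            stages=stages,
            seed=int(raw["seed"]),
            outdir=Path(raw.get("outdir", "cropscreen_run")),
            params={k: v for k, v in raw.items() if k in STAGE_ORDER},
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for stage, block in self.params.items():
            for key, value in (block or {}).items():
                if key.endswith(("_path", "_file")) and value is not None:
                    if not Path(value).exists():
                        raise ConfigError(
                            f"stage {stage!r}: referenced file {value!r} does not exist"
                        )

    @property
    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "stages": self.stages,
                "seed": self.seed,
                "params": self.params,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def provenance_header(config: RunConfig) -> str:
    return (
        f"# cropscreen v{__version__} config_hash={config.config_hash} seed={config.seed}\n"
    )


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config))
        df.to_csv(fh, sep="\t", index=index)


@dataclass
class RunReport:
    stages_run: list[str]
    outputs: dict[str, list[str]]
    summary: dict[str, object]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in dependency order."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    state: dict[str, object] = {}
    outputs: dict[str, list[str]] = {}
    summary: dict[str, object] = {}
    ordered = [s for s in STAGE_ORDER if s in config.stages]

    for stage in ordered:
        fn = _STAGES[stage]
        written: list[Path] = []
        logger.info("running stage %s", stage)
        try:
            fn(config, state, written, summary)
        except Exception as exc:
            for path in written:
                if path.exists():
                    path.rename(path.with_name(path.name + ".partial"))
            raise StageError(stage, exc) from exc
        outputs[stage] = [str(p) for p in written]

    report = RunReport(stages_run=ordered, outputs=outputs, summary=summary)
    report_path = config.outdir / "run_report.json"
    with open(report_path, "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config_hash": config.config_hash,
                "seed": config.seed,
                "stages_run": report.stages_run,
                "outputs": report.outputs,
                "summary": report.summary,
            },
            fh, indent=2, default=str,
        )
    return report


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state, written, summary) -> None:
    p = config.params.get("simulate", {}) or {}
    library = make_library(
        n_target_genes=p.get("n_target_genes", 10),
        guides_per_gene=p.get("guides_per_gene", 4),
        n_essential=p.get("n_essential", 8),
        n_nonessential=p.get("n_nonessential", 8),
        n_safe_harbour=p.get("n_safe_harbour", 4),
        seed=config.seed,
    )
    fitness = default_fitness(library, essential_s=p.get("essential_s", -0.3))
    for gene, s in (p.get("fitness_by_gene") or {}).items():
        fitness[gene] = s
    design = ScreenDesign(
        guides_per_gene=p.get("guides_per_gene", 4),
        n_clones_founding=p.get("n_clones_founding", 2000),
        bottleneck_fraction=p.get("bottleneck_fraction", 0.5),
        n_generations=p.get("n_generations", 6),
        fitness_by_gene=fitness,
        depth=p.get("depth", 50_000),
        error_rate=p.get("error_rate", 0.003),
        seed=config.seed,
    )
    lib_path = config.outdir / "library.tsv"
    library.to_tsv(lib_path)
    written.append(lib_path)

    samples, _ = simulate_invivo_screen(library, design, n_samples=1)
    sample = samples[0]
    # reference readout from founding representation; test readout from final counts
    from .synthetic import CloneTruth

    founding_clones = [
        CloneTruth(c.umi, c.guide_id, c.founding_count, c.founding_count)
        for c in sample.clones
    ]
    for name, clone_set in (("day0", founding_clones), ("final", sample.clones)):
        r1 = config.outdir / f"{name}.r1.fastq"
        r2 = config.outdir / f"{name}.r2.fastq"
        manifest = config.outdir / f"{name}.manifest.tsv"
        emit_reads(clone_set, library, design, "invivo_cropseq", r1, r2, manifest, sample=name)
        written.extend([r1, r2, manifest])
    state["library"] = library
    state["design"] = design
    summary["n_guides"] = len(library)
    summary["degenerate_sample"] = sample.degenerate


def _stage_count(config: RunConfig, state, written, summary) -> None:
    p = config.params.get("count", {}) or {}
    library: GuideLibrary = state.get("library") or GuideLibrary.from_tsv(p["library_path"])
    layout = ReadLayout()
    counts = {}
    qcs = {}
    for name in ("day0", "final"):
        r1 = Path(p.get(f"{name}_r1_path", config.outdir / f"{name}.r1.fastq"))
        r2 = Path(p.get(f"{name}_r2_path", config.outdir / f"{name}.r2.fastq"))
        series, umi_table, qc = count_guides(
            r1, r2, library, layout, with_umi=True, sample=name
        )
        counts[name] = series
        qcs[name] = qc.to_dict()
        umi_path = config.outdir / f"{name}.umi_counts.tsv"
        umi_table.to_tsv(umi_path)
        written.append(umi_path)
        state[f"umi_{name}"] = umi_table
    table = pd.DataFrame(counts)
    counts_path = config.outdir / "counts.tsv"
    write_count_table(table, library, counts_path)
    written.append(counts_path)
    qc_path = config.outdir / "count_qc.tsv"
    _write_table(pd.DataFrame(qcs).T.rename_axis("sample"), qc_path, config, index=True)
    written.append(qc_path)
    state["counts"] = table
    summary["alignment_rate_final"] = qcs["final"]["alignment_rate"]


def _stage_split_replicates(config: RunConfig, state, written, summary) -> None:
    p = config.params.get("split_replicates", {}) or {}
    prefix_length = p.get("prefix_length", 1)
    umi_table: UmiCountTable = state.get("umi_final") or UmiCountTable.from_tsv(
        p["umi_counts_path"]
    )
    replicate_set = clones_mod.split_internal_replicates(umi_table, prefix_length)
    index_rows = []
    for prefix, table in replicate_set.tables.items():
        path = config.outdir / f"replicate_{prefix or 'all'}.tsv"
        _write_table(table.rename("count").rename_axis("guide_id").reset_index(), path, config)
        written.append(path)
        index_rows.append({"prefix": prefix, "path": path.name, "total": int(table.sum())})
    index_path = config.outdir / "replicates_index.tsv"
    _write_table(pd.DataFrame(index_rows), index_path, config)
    written.append(index_path)
    state["replicates"] = replicate_set
    summary["n_replicate_tables"] = len(replicate_set.tables)


def _stage_clones(config: RunConfig, state, written, summary) -> None:
    p = config.params.get("clones", {}) or {}
    umi_table: UmiCountTable = state.get("umi_final") or UmiCountTable.from_tsv(
        p["umi_counts_path"]
    )
    points = clones_mod.knee_points(umi_table)
    points_path = config.outdir / "knee_points.tsv"
    _write_table(points, points_path, config)
    written.append(points_path)
    fit = clones_mod.fit_knee(
        points, exclude_top=p.get("exclude_top", 50), min_reads=p.get("min_reads", 10)
    )
    report = {
        "converged": fit.converged, "L": fit.L, "k": fit.k, "x0": fit.x0, "b": fit.b,
        "rss": fit.rss, "n_points": fit.n_points, "reason": fit.reason,
    }
    if fit.converged:
        estimate = clones_mod.count_clones(fit, umi_table)
        report["clone_count"] = estimate.clone_count
        report["n_umis_total"] = estimate.n_umis_total
        summary["clone_count"] = estimate.clone_count
    fit_path = config.outdir / "clone_fit.tsv"
    _write_table(pd.DataFrame([report]), fit_path, config)
    written.append(fit_path)


def _stage_test(config: RunConfig, state, written, summary) -> None:
    p = config.params.get("test", {}) or {}
    library: GuideLibrary = state["library"]
    counts: pd.DataFrame = state["counts"]
    control_genes = library.genes_in_category("nonessential") or None
    method = "control_genes" if control_genes else "median_ratio"
    table = counts.copy()
    table.insert(0, "gene", [library.gene_of(g) for g in table.index])
    normed, _factors = enrichment.normalize(table, method=method, control_genes=control_genes)
    genes = pd.Series({g: library.gene_of(g) for g in counts.index})
    stats = enrichment.guide_lfc(normed["final"], normed["day0"], genes=genes)
    results = enrichment.gene_test(
        stats, n_perm=p.get("n_perm", 1000), seed=config.seed
    )
    results = enrichment.call_hits(
        results,
        lfc_threshold=p.get("lfc_threshold", 1.5),
        fdr_threshold=p.get("fdr_threshold", 0.01),
    )
    guide_path = config.outdir / "guide_stats.tsv"
    _write_table(stats.reset_index(), guide_path, config)
    gene_path = config.outdir / "gene_results.tsv"
    _write_table(results, gene_path, config)
    written.extend([guide_path, gene_path])
    state["gene_results"] = results
    state["guide_stats"] = stats
    summary["n_hits"] = int(results["hit"].sum())


def _stage_ssmd(config: RunConfig, state, written, summary) -> None:
    library: GuideLibrary = state["library"]
    results: pd.DataFrame = state["gene_results"]
    lfcs = results.set_index("gene")["lfc"]
    essential = library.genes_in_category("essential")
    nonessential = library.genes_in_category("nonessential")
    res = enrichment.ssmd(lfcs, essential, nonessential)
    path = config.outdir / "ssmd.tsv"
    _write_table(
        pd.DataFrame(
            [
                {
                    "ssmd": res.ssmd,
                    "mean_essential": res.mean_essential,
                    "mean_nonessential": res.mean_nonessential,
                    "sd_essential": res.sd_essential,
                    "sd_nonessential": res.sd_nonessential,
                    "n_essential": res.n_essential,
                    "n_nonessential": res.n_nonessential,
                    "low_quality": res.low_quality,
                }
            ]
        ),
        path, config,
    )
    written.append(path)
    summary["ssmd"] = res.ssmd


_STAGES = {
    "simulate": _stage_simulate,
    "count": _stage_count,
    "split_replicates": _stage_split_replicates,
    "clones": _stage_clones,
    "test": _stage_test,
    "ssmd": _stage_ssmd,
}


def setup_logging(logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
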