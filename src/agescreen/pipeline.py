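"""End-to-end screening runs: simulate/load -> QC -> gate -> screen -> correlate.

`run_pipeline` executes every stage in memory and returns all intermediate
objects; `run_screen` wraps it, writes the output files and a machine- and
human-readable report. A run is driven by a single :class:`RunConfig` that
either embeds a :class:`~agescreen.simulate.SimulationConfig` (self-contained
synthetic run) or points at an on-disk count-matrix triple with annotation
and group labels — exactly one of the two.

The configured seed governs only the simulation; every analysis stage is
deterministic, so a fixed config and seed reproduce all outputs byte for
byte. Output files carry no timestamps for the same reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData

from . import __version__
from .coexpression import (
    CorrelationMatrix,
    GeneSetCorrelation,
    geneset_correlation,
    pairwise_correlation,
)
from .errors import AnalysisError, ConfigurationError, InputFormatError
from .io import (
    atomic_write_dataframe,
    atomic_write_text,
    read_annotation,
    read_count_matrix,
    read_gene_set,
    read_groups,
    write_annotation,
    write_correlation_matrix,
    write_count_matrix,
    write_simulation_config,
    write_truth,
)
from .qc import compute_rpkm, gate_positive_cells, qc_filter
from .screening import (
    call_positive,
    positive_rates,
    rank_by_rate_difference,
    select_candidates,
)
from .simulate import SimTruth, SimulationConfig, generate_annotation, simulate_counts

__all__ = ["RunConfig", "RunReport", "PipelineResult", "run_pipeline", "run_screen"]

logger = logging.getLogger("agescreen")

GROUPS = ("young", "old")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full screening run.

    Exactly one input source must be given: an embedded simulation config,
    or the (counts_dir, annotation_path, groups_path) triple of an existing
    data set.
    """

    simulation: Optional[SimulationConfig] = None
    counts_dir: Optional[Path] = None
    annotation_path: Optional[Path] = None
    groups_path: Optional[Path] = None
    gate_symbol: str = "Alb"
    threshold_rpkm: float = 1.0
    min_genes: int = 200
    max_mito: float = 0.20
    top_k: int = 43
    require_ortholog: bool = True
    correlation_genes: tuple[str, ...] = ()
    gene_set_path: Optional[Path] = None
    correlation_method: str = "pearson"
    high_r: float = 0.6
    outdir: Path = Path("agescreen_run")
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        simulated = self.simulation is not None
        external = self.counts_dir is not None
        if simulated == external:
            raise ConfigurationError(
                "exactly one of RunConfig.simulation and RunConfig.counts_dir must be set"
            )
        if external and (self.annotation_path is None or self.groups_path is None):
            raise ConfigurationError(
                "external input requires RunConfig.annotation_path and RunConfig.groups_path"
            )
        if self.threshold_rpkm < 0:
            raise ConfigurationError("invalid RunConfig.threshold_rpkm: must be >= 0")
        if self.min_genes < 0:
            raise ConfigurationError("invalid RunConfig.min_genes: must be >= 0")
        if not 0.0 <= self.max_mito <= 1.0:
            raise ConfigurationError("invalid RunConfig.max_mito: must be in [0, 1]")
        if self.top_k < 1:
            raise ConfigurationError("invalid RunConfig.top_k: must be >= 1")
        if not -1.0 <= self.high_r <= 1.0:
            raise ConfigurationError("invalid RunConfig.high_r: must be in [-1, 1]")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ConfigurationError(
                f"invalid RunConfig.correlation_method: {self.correlation_method!r}"
            )
        if simulated and self.seed is not None:
            object.__setattr__(
                self, "simulation", dataclasses.replace(self.simulation, seed=int(self.seed))
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict() if self.simulation else None
        for key in ("counts_dir", "annotation_path", "groups_path", "gene_set_path", "outdir"):
            if d[key] is not None:
                d[key] = str(d[key])
        d["correlation_genes"] = list(self.correlation_genes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigurationError(f"unknown RunConfig fields: {unknown}")
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        for key in ("counts_dir", "annotation_path", "groups_path", "gene_set_path", "outdir"):
            if d.get(key) is not None:
                d[key] = Path(d[key])
        if d.get("correlation_genes") is not None:
            d["correlation_genes"] = tuple(d["correlation_genes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        path = Path(path)
        if not path.is_file():
            raise InputFormatError(f"missing configuration file: {path}")
        try:
            data = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise InputFormatError(f"malformed YAML in {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping of RunConfig fields")
        return cls.from_dict(data)


@dataclass
class PipelineResult:
    """All in-memory artifacts of one screening run."""

    config: RunConfig
    counts: AnnData
    annotation: pd.DataFrame
    groups: pd.Series
    truth: Optional[SimTruth]
    qc_report: pd.DataFrame
    expression: AnnData
    gated_cells: list[str]
    rates: pd.DataFrame
    ranking: pd.DataFrame
    candidates: pd.DataFrame
    correlations: dict[str, CorrelationMatrix]
    geneset: dict[str, GeneSetCorrelation]
    stage_counts: dict
    log_lines: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    """Summary of a run: stage counts, candidates, correlation digests."""

    version: str
    seed: Optional[int]
    config: dict
    stage_counts: dict
    candidates: list[dict]
    correlation_summary: dict
    geneset_summary: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_text(self) -> str:
        lines = [
            f"agescreen {self.version} screening report",
            f"seed: {self.seed}",
            "",
            "stage counts (cells):",
        ]
        for stage in ("input", "post_qc", "post_gate"):
            counts = self.stage_counts[stage]
            lines.append(
                f"  {stage:<10} young={counts['young']:>6}  old={counts['old']:>6}"
            )
        lines.append(f"genes: {self.stage_counts['genes']}")
        lines.append("")
        lines.append(f"candidates (top {len(self.candidates)} by rate difference):")
        for c in self.candidates:
            lines.append(
                f"  rank {c['rank']:>4}  {c['gene_id']}  {c['symbol']:<10} "
                f"young={c['rate_young']:.4f} old={c['rate_old']:.4f} "
                f"delta={c['delta']:+.4f}"
            )
        lines.append("")
        for group, s in self.correlation_summary.items():
            lines.append(
                f"correlations ({group}, n={s['n_cells']} cells): "
                f"{s['n_pairs']} pairs, {s['n_undefined']} undefined, "
                f"max={s['max']}, mean={s['mean']}"
            )
        return "\n".join(lines) + "\n"


def _group_counts(cell_ids, groups: pd.Series) -> dict[str, int]:
    labels = groups.reindex(list(cell_ids))
    return {g: int((labels == g).sum()) for g in GROUPS}


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = config.simulation
        logger.info("simulating %d young + %d old cells, %d genes (seed %d)",
                    sim.n_cells_young, sim.n_cells_old, sim.n_genes, sim.seed)
        annotation = generate_annotation(sim)
        counts, truth = simulate_counts(sim, annotation)
        groups = pd.Series(
            counts.obs["group"].astype(str).values, index=counts.obs_names
        )
        return counts, annotation, groups, truth
    counts = read_count_matrix(config.counts_dir)
    annotation = read_annotation(config.annotation_path)
    groups = read_groups(config.groups_path)
    ann_index = annotation.set_index("gene_id")
    carry = ann_index.reindex(counts.var_names)
    counts.var = carry.reset_index().set_index(
        pd.Index(list(counts.var_names))
    ).rename(columns={"index": "gene_id"})
    return counts, annotation, groups, None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full screen in memory and return every artifact."""
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)
        logger.info("%s", msg)

    gene_set = read_gene_set(config.gene_set_path) if config.gene_set_path else None

    counts, annotation, groups, truth = _load_inputs(config)
    unassigned = [c for c in counts.obs_names if c not in groups.index]
    if unassigned:
        raise AnalysisError(f"cells without a group label: {unassigned[:10]}")

    input_counts = _group_counts(counts.obs_names, groups)
    note(f"input: young={input_counts['young']} old={input_counts['old']} "
         f"genes={counts.n_vars}")

    kept, qc_report = qc_filter(
        counts, annotation, min_genes=config.min_genes, max_mito=config.max_mito
    )
    post_qc = _group_counts(kept.obs_names, groups)
    note(f"post-QC: young={post_qc['young']} old={post_qc['old']}")

    expr = compute_rpkm(kept, annotation)
    gated = gate_positive_cells(
        expr, gate_symbol=config.gate_symbol, threshold_rpkm=config.threshold_rpkm
    )
    expr_gated = expr[gated].copy()
    post_gate = _group_counts(gated, groups)
    note(f"post-gate ({config.gate_symbol}): young={post_gate['young']} "
         f"old={post_gate['old']}")

    for g in GROUPS:
        if not post_gate[g] <= post_qc[g] <= input_counts[g]:
            raise AnalysisError(
                f"stage counts not monotone for group {g!r}: "
                f"{input_counts[g]} -> {post_qc[g]} -> {post_gate[g]}"
            )

    calls = call_positive(expr_gated, threshold_rpkm=config.threshold_rpkm)
    rates = positive_rates(calls, groups.loc[gated])
    ranking = rank_by_rate_difference(rates)
    candidates = select_candidates(
        ranking, annotation, top_k=config.top_k, require_ortholog=config.require_ortholog
    )
    note(f"ranked {len(ranking)} genes; selected {len(candidates)} candidates")

    corr_genes = list(config.correlation_genes)
    if not corr_genes:
        if truth is not None and truth.marker_gene_ids:
            corr_genes = list(truth.marker_gene_ids)
        else:
            corr_genes = candidates["gene_id"].head(5).tolist()

    correlations: dict[str, CorrelationMatrix] = {}
    geneset: dict[str, GeneSetCorrelation] = {}
    group_labels = groups.loc[gated]
    for g in GROUPS:
        members = [c for c in gated if group_labels[c] == g]
        if len(members) < 3:
            note(f"skipping correlations for group {g!r}: only {len(members)} cells")
            continue
        correlations[g] = pairwise_correlation(
            expr_gated, corr_genes, members, method=config.correlation_method
        )
        if gene_set is not None:
            geneset[g] = geneset_correlation(
                expr_gated,
                corr_genes,
                gene_set,
                members,
                high_r=config.high_r,
                method=config.correlation_method,
            )

    stage_counts = {
        "input": input_counts,
        "post_qc": post_qc,
        "post_gate": post_gate,
        "genes": int(counts.n_vars),
    }
    return PipelineResult(
        config=config,
        counts=counts,
        annotation=annotation,
        groups=groups,
        truth=truth,
        qc_report=qc_report,
        expression=expr_gated,
        gated_cells=gated,
        rates=rates,
        ranking=ranking,
        candidates=candidates,
        correlations=correlations,
        geneset=geneset,
        stage_counts=stage_counts,
        log_lines=log,
    )


def _round6(x: float) -> Optional[float]:
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else round(float(x), 6)


def build_report(result: PipelineResult) -> RunReport:
    candidates = [
        {
            "rank": int(r["rank"]),
            "gene_id": r["gene_id"],
            "symbol": r["symbol"],
            "ortholog_symbol": None if pd.isna(r["ortholog_symbol"]) else r["ortholog_symbol"],
            "rate_young": float(r["rate_young"]),
            "rate_old": float(r["rate_old"]),
            "delta": float(r["delta"]),
        }
        for _, r in result.candidates.iterrows()
    ]
    corr_summary = {}
    for group, corr in result.correlations.items():
        vals = corr.matrix.to_numpy()
        mask = ~np.eye(len(vals), dtype=bool)
        off = vals[mask]
        defined = off[~np.isnan(off)]
        corr_summary[group] = {
            "n_cells": corr.n_cells,
            "n_pairs": int(mask.sum() // 2),
            "n_undefined": int(np.isnan(off).sum() // 2),
            "max": _round6(defined.max()) if defined.size else None,
            "mean": _round6(defined.mean()) if defined.size else None,
        }
    geneset_summary = {}
    for group, gs in result.geneset.items():
        geneset_summary[group] = {
            "gene_set": gs.gene_set,
            "n_rows": int(len(gs.table)),
            "n_high": int(gs.table["high"].sum()) if len(gs.table) else 0,
            "n_undefined": int((~gs.table["defined"]).sum()) if len(gs.table) else 0,
            "not_measured": list(gs.not_measured),
        }
    seed = result.config.seed
    if seed is None and result.config.simulation is not None:
        seed = result.config.simulation.seed
    return RunReport(
        version=__version__,
        seed=seed,
        config=result.config.to_dict(),
        stage_counts=result.stage_counts,
        candidates=candidates,
        correlation_summary=corr_summary,
        geneset_summary=geneset_summary,
    )


def run_screen(config: RunConfig) -> RunReport:
    """Run the screen and write all outputs under ``config.outdir``.

    Outputs: the simulated inputs (when simulating), the QC report, the
    Supplementary-Table-style ranking, the candidate list, the per-group
    positive-rate table (dot-plot data), per-group correlation matrices
    (``"-"`` marks undefined pairs), optional gene-set correlation tables,
    and the run report as JSON and text. All writes are atomic.
    """
    result = run_pipeline(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        write_count_matrix(result.counts, outdir / "counts")
        write_annotation(result.annotation, outdir / "annotation.tsv")
        write_simulation_config(config.simulation, outdir / "simulation_config.yaml")
        if result.truth is not None:
            write_truth(result.truth, outdir / "truth.tsv")

    atomic_write_dataframe(outdir / "qc_report.tsv", result.qc_report, float_format="%.6f")
    atomic_write_dataframe(outdir / "rates.tsv", result.rates, float_format="%.6f")

    ranking_out = result.ranking.merge(
        result.annotation[["gene_id", "symbol", "ortholog_symbol"]], on="gene_id", how="left"
    )[["gene_id", "symbol", "rate_young", "rate_old", "delta", "rank", "ortholog_symbol"]]
    atomic_write_dataframe(outdir / "ranking.tsv", ranking_out, float_format="%.6f", na_rep="")
    atomic_write_dataframe(
        outdir / "candidates.tsv",
        result.candidates[
            ["rank", "gene_id", "symbol", "rate_young", "rate_old", "delta", "ortholog_symbol"]
        ],
        float_format="%.6f",
        na_rep="",
    )
    for group, corr in result.correlations.items():
        write_correlation_matrix(corr, outdir / f"correlation_{group}.tsv")
    for group, gs in result.geneset.items():
        atomic_write_dataframe(
            outdir / f"geneset_correlation_{group}.tsv",
            gs.table,
            float_format="%.6f",
            na_rep="-",
        )

    report = build_report(result)
    atomic_write_text(
        outdir / "report.json", json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    atomic_write_text(outdir / "report.txt", report.to_text())
    atomic_write_text(outdir / "run.log", "\n".join(result.log_lines) + "\n")
    return report
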