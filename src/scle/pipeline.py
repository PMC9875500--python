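"""End-to-end orchestration: load -> network -> SCLE -> critical call ->
DNB report -> neighbor reversal, with a reproducible run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import scle
from scle import core, dnb, expression_io, network as net, reversal as rev

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run.

    Everything except ``outdir`` determines the analysis result; identical
    analysis fields (and inputs) reproduce byte-identical output files.
    """

    expression: str
    labels: str
    network: str
    outdir: str
    stage_order: tuple[str, ...]
    expression_format: str = "dense_tsv"
    genes_file: str | None = None
    cells_file: str | None = None
    top_fraction: float = 0.05
    min_cells: int = expression_io.DEFAULT_MIN_CELLS
    score_column: str | None = None
    min_score: float | None = None
    permutations: int = 0  # 0 = skip the permutation test
    seed: int = 0
    q1_entropy: float = 1.0
    max_pairs: int = dnb.DEFAULT_MAX_PAIRS
    reversal_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        self.stage_order = tuple(self.stage_order)
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.permutations < 0:
            raise ValueError("permutations must be >= 0")


@dataclass
class PipelineResult:
    profile: core.ScleProfile
    report: dnb.DnbReport
    reversal: pd.DataFrame
    manifest: dict
    outdir: Path


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _analysis_config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("outdir")  # destination, not an analysis input
    d["stage_order"] = list(config.stage_order)
    return d


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write all output tables plus a manifest.

    Outputs in ``config.outdir``: ``stage_scores.tsv``, ``local_scores.tsv``,
    ``dnb_genes.txt``, ``dnb_neighbors.txt``, ``dnb_statistics.tsv``,
    ``reversal.tsv`` and ``manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for label, path in [
        ("expression", config.expression),
        ("labels", config.labels),
        ("network", config.network),
    ]:
        if not Path(path).exists():
            raise FileNotFoundError(f"{label} file not found: {path}")

    logger.info("loading expression from %s", config.expression)
    raw = expression_io.load_expression(
        config.expression,
        format=config.expression_format,
        genes_path=config.genes_file,
        cells_path=config.cells_file,
    )
    series = expression_io.assemble_stage_series(
        expression_io.normalize_log1p(raw),
        expression_io.read_labels_tsv(config.labels),
        config.stage_order,
        min_cells=config.min_cells,
    )
    edges = net.load_edge_list(
        config.network, score_column=config.score_column, min_score=config.min_score
    )
    template = net.build_template_network(
        edges, raw.genes, provenance={"source": str(config.network)}
    )
    logger.info(
        "template network: %d genes, %d edges", template.n_nodes, template.n_edges
    )

    profile = core.stage_scle(
        series, template, top_fraction=config.top_fraction, q1_entropy=config.q1_entropy
    )
    call = core.detect_critical_stage(profile)
    if config.permutations > 0:
        core.permutation_pvalue(
            series,
            template,
            profile,
            B=config.permutations,
            seed=config.seed,
            q1_entropy=config.q1_entropy,
        )
    report = dnb.dnb_report(
        series, template, profile, max_pairs=config.max_pairs, seed=config.seed
    )
    reversal_table = rev.reversal_scan(
        series,
        sorted(report.neighbors),
        call.stage,
        epsilon=config.reversal_epsilon,
    )

    _write_outputs(outdir, profile, report, reversal_table)
    manifest = {
        "package": "scle",
        "version": scle.__version__,
        "config": _analysis_config_dict(config),
        "inputs": {
            "expression_sha256": _sha256(config.expression),
            "labels_sha256": _sha256(config.labels),
            "network_sha256": _sha256(config.network),
        },
        "results": {
            "critical_stage": call.stage,
            "fold_change": call.fold_change if call.fold_change != float("inf") else "inf",
            "end_of_series_warning": call.end_of_series_warning,
            "pvalue": profile.pvalue,
            "R": profile.R,
            "n_network_genes": template.n_nodes,
            "n_cells_retained": series.matrix.n_cells,
            "n_reversed_neighbors": int(reversal_table["reversed"].sum()),
        },
    }
    (outdir / MANIFEST_NAME).write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return PipelineResult(
        profile=profile,
        report=report,
        reversal=reversal_table,
        manifest=manifest,
        outdir=outdir,
    )


def _write_outputs(outdir: Path, profile, report, reversal_table) -> None:
    h = profile.stage_scores
    fold = [""]
    for prev, cur in zip(h.to_numpy()[:-1], h.to_numpy()[1:]):
        fold.append("inf" if prev == 0 else f"{cur / prev:.10g}")
    stage_df = pd.DataFrame(
        {
            "stage": list(profile.stage_order),
            "H_t": h.to_numpy(),
            "R": profile.R,
            "fold_change": fold,
        }
    )
    stage_df.to_csv(outdir / "stage_scores.tsv", sep="\t", index=False)
    profile.local_scores.to_csv(outdir / "local_scores.tsv", sep="\t", index=False)
    (outdir / "dnb_genes.txt").write_text(
        "".join(f"{g}\n" for g in sorted(report.dnb_genes))
    )
    (outdir / "dnb_neighbors.txt").write_text(
        "".join(f"{g}\n" for g in sorted(report.neighbors))
    )
    report.statistics.to_csv(outdir / "dnb_statistics.tsv", sep="\t", index=False)
    reversal_table.to_csv(outdir / "reversal.tsv", sep="\t", index=False)


def run_from_manifest(manifest_path: str | Path, outdir: str | Path) -> PipelineResult:
    """Re-run a pipeline bit-identically from its manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = dict(manifest["config"])
    cfg["stage_order"] = tuple(cfg["stage_order"])
    return run_pipeline(RunConfig(outdir=str(outdir), **cfg))
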