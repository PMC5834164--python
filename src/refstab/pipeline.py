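"""Full-workflow orchestration: screen -> rank -> aggregate -> express.

:func:`run_full_pipeline` executes whichever stages the inputs allow — the
RNA-Seq candidate screen (if a count matrix is given), the four qPCR
stability methods with the comprehensive ranking (if a Cq table is given),
and the 2^-ddCt validation (if target genes are configured) — writing one
TSV per result plus a machine-readable JSON summary and a run record that
suffices to re-run the pipeline bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .datamodel import CqTable, CountMatrix, RefstabError, RunConfig
from .io import (
    read_cq_table,
    read_count_matrix,
    write_json_summary,
    write_result_table,
)
from .model import ReferenceGeneStability, RelativeExpression
from .screen import screen_candidates

__all__ = ["PipelineRunRecord", "run_full_pipeline", "render_report"]


@dataclass
class PipelineRunRecord:
    """Everything needed to reproduce one pipeline run."""

    config: dict
    inputs: dict
    outputs: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage -> "ok" | "skipped" | error
    version: str = __version__
    seed: int = 0

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineRunRecord":
        return cls(**json.loads(Path(path).read_text()))


def run_full_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    cq_path: str | Path | None = None,
    counts_path: str | Path | None = None,
    meta_path: str | Path | None = None,
    cq_table: CqTable | None = None,
    count_matrix: CountMatrix | None = None,
    candidate_genes: list[str] | None = None,
) -> PipelineRunRecord:
    """Run every stage the inputs support; returns the run record.

    Accepts either file paths or in-memory tables.  On a stage failure the
    record is still written, with the failing stage named and a FAILED
    marker file left in the output directory, and the error re-raised.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = PipelineRunRecord(
        config={
            "calibrator": config.calibrator,
            "reference_genes": list(config.reference_genes),
            "target_genes": list(config.target_genes),
            "screen_k": config.screen_k,
            "normalization": config.normalization,
            "alpha": config.alpha,
            "n_recommended": config.n_recommended,
            "seed": config.seed,
        },
        inputs={
            "cq": str(cq_path) if cq_path else None,
            "counts": str(counts_path) if counts_path else None,
            "meta": str(meta_path) if meta_path else None,
        },
        seed=config.seed,
    )
    summary: dict = {"version": __version__, "seed": config.seed}
    stage = "setup"
    try:
        # ---- read inputs -------------------------------------------------
        if cq_table is None and cq_path is not None:
            stage = "read_cq_table"
            cq_table = read_cq_table(cq_path)
        if count_matrix is None and counts_path is not None:
            stage = "read_count_matrix"
            count_matrix = read_count_matrix(counts_path, meta_path)

        # ---- RNA-Seq screen ----------------------------------------------
        if count_matrix is not None:
            stage = "screen"
            screen = screen_candidates(count_matrix, config=config)
            p = out_dir / "screen.tsv"
            write_result_table(screen, p)
            record.outputs["screen"] = str(p)
            record.stages["screen"] = "ok"
            summary["screen"] = {
                "selected": screen.selected,
                "excluded_zero_expression": screen.excluded,
            }
        else:
            record.stages["screen"] = "skipped"

        # ---- stability + comprehensive ranking ---------------------------
        results = None
        if cq_table is not None:
            stage = "stability"
            candidates = candidate_genes
            if candidates is None:
                drop = set(config.target_genes)
                candidates = [g for g in cq_table.genes if g not in drop]
            model = ReferenceGeneStability(cq_table, genes=candidates)
            results = model.fit()
            for method, res in results.by_method.items():
                p = out_dir / f"{method}.tsv"
                write_result_table(res, p)
                record.outputs[method] = str(p)
            p = out_dir / "comprehensive.tsv"
            write_result_table(results.comprehensive, p)
            record.outputs["comprehensive"] = str(p)
            p = out_dir / "cq_spread.tsv"
            write_result_table(results.spread.reset_index(), p)
            record.outputs["cq_spread"] = str(p)
            record.stages["stability"] = "ok"
            recommended = results.recommended(config.n_recommended)
            summary["stability"] = {
                "comprehensive_order": results.comprehensive.genes,
                "recommended_references": recommended,
            }
        else:
            record.stages["stability"] = "skipped"

        # ---- expression validation ---------------------------------------
        if cq_table is not None and config.target_genes:
            stage = "expression"
            refs = list(config.reference_genes)
            if not refs:
                refs = results.recommended(config.n_recommended)
            calibrator = config.calibrator or cq_table.conditions[0]
            exp = RelativeExpression(
                cq_table,
                targets=list(config.target_genes),
                references=refs,
                calibrator=calibrator,
                alpha=config.alpha,
            ).fit()
            p = out_dir / "expression.tsv"
            write_result_table(exp.expression, p)
            record.outputs["expression"] = str(p)
            record.stages["expression"] = "ok"
            summary["expression"] = {
                "references_used": refs,
                "calibrator": calibrator,
                "fold_changes": {
                    g: {
                        c: exp.fold_change(g, c)
                        for c in exp.expression.conditions
                    }
                    for g in config.target_genes
                },
            }
        else:
            record.stages["expression"] = "skipped"

        stage = "summary"
        write_json_summary(summary, out_dir / "summary.json")
        record.outputs["summary"] = str(out_dir / "summary.json")
        record.save(out_dir / "record.json")
        return record
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        record.stages[stage] = f"failed: {exc}"
        record.save(out_dir / "record.json")
        raise RefstabError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _section(title: str, path: str | None) -> list[str]:
    lines = [f"## {title}", ""]
    if path is None or not Path(path).exists():
        lines += ["_unavailable_", ""]
        return lines
    frame = pd.read_csv(path, sep="\t")
    lines += [frame.to_markdown(index=False), ""]
    return lines


def render_report(record: PipelineRunRecord) -> str:
    """Markdown report assembled from a run record's output tables."""
    out = record.outputs
    lines = [
        "# Reference-gene stability report",
        "",
        f"refstab {record.version}, seed {record.seed}",
        "",
    ]
    lines += _section("Raw Cq spread per gene", out.get("cq_spread"))
    for method, title in [
        ("delta_ct", "Comparative dCt"),
        ("bestkeeper", "BestKeeper"),
        ("normfinder", "NormFinder"),
        ("genorm", "geNorm"),
    ]:
        if record.stages.get("stability") == "ok":
            lines += _section(title, out.get(method))
    lines += _section("Comprehensive ranking", out.get("comprehensive"))
    if record.stages.get("screen") == "ok":
        lines += _section("RNA-Seq candidate screen", out.get("screen"))
    if record.stages.get("expression") == "ok":
        lines += _section("Relative expression (2^-ddCt)", out.get("expression"))
    return "\n".join(lines)
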