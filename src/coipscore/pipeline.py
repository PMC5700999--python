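"""End-to-end workflow: score interactors, then characterize their sequences.

The pipeline is a pure function of its inputs and configuration: no
timestamps or machine state enter any output, so repeated runs are
byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import properties, scoring
from .errors import CoipScoreError
from .io_formats import (
    read_cleavage_table,
    read_fasta,
    read_quant_table,
    write_results,
)


@dataclass
class PipelineConfig:
    quant_path: str | Path = ""
    design_path: str | Path = ""
    fasta_path: str | Path | None = None
    cleavage_path: str | Path | None = None
    interactors_path: str | Path | None = None  # override the called list
    exclude_path: str | Path | None = None  # chaperone-exclusion id list
    fdr_alpha: float = 0.05
    n_bins: int = 10
    threshold: float = 0.05
    n_null: int = 5000
    score_threshold: float = 0.5
    seed: int = 0
    out_dir: str | Path = "results/pipeline"

    def params(self) -> dict[str, object]:
        return {
            "fdr_alpha": self.fdr_alpha,
            "n_bins": self.n_bins,
            "threshold": self.threshold,
            "n_null": self.n_null,
            "score_threshold": self.score_threshold,
            "seed": self.seed,
        }


def _read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def run_score_stage(cfg: PipelineConfig, out: Path) -> dict[str, object]:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    q = read_quant_table(cfg.quant_path, cfg.design_path)
    records, diff, model = scoring.score_quant_table(
        q, fdr_alpha=cfg.fdr_alpha, n_bins=cfg.n_bins, threshold=cfg.threshold
    )
    called = scoring.call_interactors(records, threshold=cfg.threshold)

    write_results(scoring.records_frame(records, diff), out / "results.tsv")
    anchors = pd.DataFrame({"x_log10_intensity": model.x, "error_probability": model.e})
    write_results(anchors, out / "anchors.tsv")
    lo, hi = model.domain
    grid = np.linspace(lo, hi, 200) if hi > lo else np.array([lo])
    curve = pd.DataFrame({"x_log10_intensity": grid, "error_probability": model(grid)})
    write_results(curve, out / "curve.tsv")
    with open(out / "interactors.txt", "w") as fh:
        fh.write("".join(pid + "\n" for pid in called))
    return {
        "records": records,
        "model": model,
        "called": called,
        "n_identified": len(q.protein_ids),
        "n_trained": sum(r.in_training_set for r in records),
        "n_called": len(called),
    }


def run_props_stage(cfg: PipelineConfig, called: list[str], out: Path) -> dict[str, object]:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    precursor = read_fasta(cfg.fasta_path)
    # "whole proteome" residue frequencies feed the Monte-Carlo null
    freqs = properties.aa_frequencies(precursor)

    if cfg.cleavage_path:
        cleavage = read_cleavage_table(cfg.cleavage_path)
        background = properties.strip_transit_peptides(
            precursor, cleavage, cfg.score_threshold
        )
        sequence_form = "mature"
    else:
        background = dict(precursor)
        sequence_form = "precursor"

    interactor_ids = list(called)
    if cfg.interactors_path:
        interactor_ids = _read_id_list(cfg.interactors_path)
    excluded = set(_read_id_list(cfg.exclude_path)) if cfg.exclude_path else set()
    interactor_ids = [p for p in interactor_ids if p not in excluded]

    pool = background if sequence_form == "mature" else precursor
    interactor_seqs = {
        p: (pool[p] if p in pool else precursor[p]) for p in interactor_ids if p in precursor
    }
    background_seqs = {p: s for p, s in background.items() if p not in set(interactor_ids)}
    if len(interactor_seqs) < 2 or len(background_seqs) < 2:
        raise CoipScoreError(
            "props stage needs at least 2 interactor and 2 background sequences"
        )

    prof_int = properties.property_profiles(
        interactor_seqs, freqs, n_null=cfg.n_null, seed=cfg.seed
    )
    prof_bg = properties.property_profiles(
        background_seqs, freqs, n_null=cfg.n_null, seed=cfg.seed
    )
    comparison = properties.compare_profiles(prof_int, prof_bg)

    write_results(prof_int, out / "profiles_interactors.tsv")
    write_results(prof_bg, out / "profiles_background.tsv")
    write_results(comparison, out / "comparison.tsv")
    for col in [c for c in prof_int.columns if c.endswith("_z")] + ["pI"]:
        frames = []
        for group, prof in (("interactors", prof_int), ("background", prof_bg)):
            if np.unique(prof[col]).size < 2:
                continue
            curve = properties.kde(prof[col].to_numpy())
            frames.append(
                pd.DataFrame(
                    {"group": group, "grid": curve.grid, "density": curve.density}
                )
            )
        if frames:
            write_results(pd.concat(frames, ignore_index=True), out / f"density_{col}.tsv")
    return {
        "comparison": comparison,
        "sequence_form": sequence_form,
        "n_interactors_profiled": len(prof_int),
        "n_background_profiled": len(prof_bg),
    }


def render_report(
    score_out: dict[str, object],
    props_out: dict[str, object] | None,
    params: dict[str, object],
) -> str:
    """Deterministic markdown summary of one pipeline run."""
    lines = ["# co-IP interactor scoring report", "", "## Parameters", ""]
    for key in sorted(params):
        lines.append(f"- {key} = {params[key]}")
    lines += [
        "",
        "## Counts",
        "",
        f"- proteins identified: {score_out['n_identified']}",
        f"- proteins in training set: {score_out['n_trained']}",
        f"- interactors called (p-score <= threshold): {score_out['n_called']}",
        "",
        "## Error-model anchors",
        "",
        "| log10 stress intensity | error probability |",
        "|---|---|",
    ]
    model = score_out["model"]
    for x, e in zip(model.x, model.e):
        lines.append(f"| {x:.4f} | {e:.4f} |")
    lines += ["", "## Called interactors", ""]
    records = {r.protein_id: r for r in score_out["records"]}
    called = score_out["called"]
    if not called:
        lines.append("No interactors called at this threshold.")
    else:
        lines += ["| protein | p-score |", "|---|---|"]
        for pid in called:  # already ascending by p-score
            lines.append(f"| {pid} | {records[pid].p_score:.4f} |")
    if props_out is not None:
        lines += [
            "",
            "## Sequence-property comparison",
            "",
            f"Sequences used: {props_out['sequence_form']}; "
            f"{props_out['n_interactors_profiled']} interactors vs "
            f"{props_out['n_background_profiled']} background proteins.",
            "",
            "| property | scale | t | df | p |",
            "|---|---|---|---|---|",
        ]
        for _, row in props_out["comparison"].iterrows():
            lines.append(
                f"| {row['property']} | {row['scale']} | {row['t']:.4f} "
                f"| {row['df']:.2f} | {row['p_value']:.3g} |"
            )
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Score, optionally characterize, and write a report; returns the out dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"{k} = {v}" for k, v in sorted(cfg.params().items())]
    log_lines.append(f"quant = {cfg.quant_path}")
    log_lines.append(f"design = {cfg.design_path}")
    try:
        score_out = run_score_stage(cfg, out)
    except CoipScoreError as exc:
        raise CoipScoreError(f"score stage failed: {exc}") from exc
    props_out = None
    if cfg.fasta_path:
        enough = cfg.interactors_path is not None or len(score_out["called"]) >= 2
        if enough:
            try:
                props_out = run_props_stage(cfg, score_out["called"], out)
            except CoipScoreError as exc:
                raise CoipScoreError(f"props stage failed: {exc}") from exc
        else:
            log_lines.append(
                "props stage skipped: fewer than 2 called interactors to profile"
            )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "report.md").write_text(render_report(score_out, props_out, cfg.params()))
    return out
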