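"""End-to-end orchestration: simulate → filter → SV → annotate → report.

Everything downstream of the generator also runs on user-supplied call
files through the CLI; this module wires the stages together for one
reproducible run and scores the result against the simulation truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .core import MutationCatalog, SVRecord, VariantKey
from .effects import GeneSet, annotate_catalog
from .filtering import (
    FilterConfig,
    filter_small_variants,
    write_accepted_vcf,
    write_rejection_log,
)
from .report import SpectrumReport, build_report
from .simulate import SimulationConfig, SimulationResult, simulate_all
from .sv import SVConfig, consensus_and_uniqueness, support_filter, write_sv_bed, write_sv_table

__all__ = ["PipelineResult", "run_pipeline", "consolidate_svs", "evaluate_against_truth"]


@dataclass
class PipelineResult:
    simulation: SimulationResult
    catalog: MutationCatalog
    annotations: pd.DataFrame
    report: SpectrumReport
    evaluation: pd.DataFrame


def consolidate_svs(
    sv_records: Iterable[SVRecord],
    config: SimulationConfig,
    sv_cfg: SVConfig,
) -> Dict[str, List[SVRecord]]:
    """Support-filter and consolidate raw per-caller SV calls per line."""
    filtered = support_filter(list(sv_records), sv_cfg)
    control_ids = {l.line_id for l in config.control_lines}
    per_line = {
        line.line_id: [r for r in filtered if r.line_id == line.line_id]
        for line in config.mutant_lines
    }
    controls = [r for r in filtered if r.line_id in control_ids]
    reps = {l.line_id: list(l.replicate_ids) for l in config.mutant_lines}
    result = consensus_and_uniqueness(per_line, controls, sv_cfg, replicate_ids=reps)
    return result.accepted


def run_pipeline(
    config: SimulationConfig,
    filter_cfg: FilterConfig = FilterConfig(),
    sv_cfg: SVConfig = SVConfig(),
    database_keys: Iterable[VariantKey] = (),
    outdir: Optional[str | Path] = None,
) -> PipelineResult:
    """One reproducible run over a synthetic population.

    Writes, when ``outdir`` is given, the simulated inputs plus the
    accepted-mutation VCF, rejection log, consolidated SV tables,
    effect annotations, spectrum report and a run manifest.
    """
    outdir = Path(outdir) if outdir is not None else None
    sim = simulate_all(config, outdir / "sim" if outdir else None)

    catalog = filter_small_variants(sim.calls, sim.manifest, database_keys, filter_cfg)
    all_sv = [r for recs in sim.sv_callsets.values() for r in recs]
    catalog.accepted_svs = consolidate_svs(all_sv, config, sv_cfg)

    genes = GeneSet(sim.reference.genes)
    annotations = annotate_catalog(catalog, genes, sim.reference.sequences)
    line_info = {l.line_id: (l.treatment, l.dose_gy) for l in config.mutant_lines}
    genome_size = config.n_chroms * config.chrom_length
    report = build_report(catalog, line_info, genome_size=genome_size)
    evaluation = evaluate_against_truth(sim.truth, catalog, sv_cfg.merge_tolerance)

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        write_accepted_vcf(catalog, outdir / "accepted.vcf", sim.reference.chrom_lengths)
        write_rejection_log(catalog, outdir / "rejections.tsv")
        accepted_sv = [r for line in sorted(catalog.accepted_svs) for r in catalog.accepted_svs[line]]
        write_sv_table(accepted_sv, outdir / "accepted_sv.tsv")
        write_sv_bed([r for r in accepted_sv], outdir / "accepted_sv.bed")
        annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        report.to_tsv(outdir / "report.tsv")
        report.to_json(outdir / "report.json")
        evaluation.to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
        _write_run_manifest(outdir, config, catalog, evaluation)
    return PipelineResult(sim, catalog, annotations, report, evaluation)


def _write_run_manifest(
    outdir: Path,
    config: SimulationConfig,
    catalog: MutationCatalog,
    evaluation: pd.DataFrame,
) -> None:
    cfg_repr = repr(config).encode()
    manifest = {
        "config_sha256": hashlib.sha256(cfg_repr).hexdigest(),
        "seed": config.seed,
        "n_lines": len(config.mutant_lines),
        "counts": {
            line: catalog.counts(line) for line in catalog.line_ids
        },
        "n_rejections": len(catalog.rejections),
        "mean_small_precision": float(
            evaluation.loc[evaluation["var_class"] == "small", "precision"].mean()
        ),
        "mean_small_recall": float(
            evaluation.loc[evaluation["var_class"] == "small", "recall"].mean()
        ),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def evaluate_against_truth(
    truth, catalog: MutationCatalog, tolerance: int
) -> pd.DataFrame:
    """Precision/recall of the accepted catalog against simulation truth.

    Small variants match on exact key; SVs match on type and both
    breakpoints within the merge tolerance.
    """
    rows = []
    for line_id in catalog.line_ids:
        truth_small = truth.induced_keys(line_id)
        called = catalog.accepted_small(line_id)
        tp = len(called & truth_small)
        rows.append(_eval_row(line_id, "small", len(truth_small), len(called), tp))

        truth_svs = truth.induced_svs.get(line_id, [])
        called_svs = catalog.accepted_svs.get(line_id, [])
        tp_sv = sum(1 for t in truth_svs if _sv_matched(t, called_svs, tolerance))
        matched_calls = sum(1 for c in called_svs if _sv_matched(c, truth_svs, tolerance))
        rows.append(
            _eval_row(line_id, "sv", len(truth_svs), len(called_svs), tp_sv,
                      precision_tp=matched_calls)
        )
    return pd.DataFrame(
        rows, columns=["line_id", "var_class", "n_truth", "n_called", "tp",
                       "precision", "recall"],
    )


def _eval_row(
    line_id: str, var_class: str, n_truth: int, n_called: int, tp: int,
    precision_tp: Optional[int] = None,
) -> dict:
    p_tp = tp if precision_tp is None else precision_tp
    return {
        "line_id": line_id,
        "var_class": var_class,
        "n_truth": n_truth,
        "n_called": n_called,
        "tp": tp,
        "precision": p_tp / n_called if n_called else 1.0,
        "recall": tp / n_truth if n_truth else 1.0,
    }


def _sv_matched(rec: SVRecord, pool, tolerance: int) -> bool:
    return any(
        o.sv_type is rec.sv_type
        and o.chrom_pair == rec.chrom_pair
        and abs(o.start - rec.start) <= tolerance
        and abs(o.second_coord - rec.second_coord) <= tolerance
        for o in pool
    )
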