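"""Per-line mutation spectrum and density reporting.

Summarizes an accepted-mutation catalog the way the field reports
mutagenized populations: class counts per line (SNV, indel, each SV
type), bp/event mutation frequencies (genome size divided by event
count; smaller = denser), and SV composition shares. By convention a
translocation is also recorded as a deletion at its origin locus, so
the reported deletion count includes translocations and the SV total is
DEL + DUP + INV + INS after that accounting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import pandas as pd

from .core import MutationCatalog, SVType

__all__ = ["GENOME_SIZE_RICE", "mutation_frequency", "SpectrumReport", "build_report"]

GENOME_SIZE_RICE = 430_000_000  # bp, the genome size used for rice frequencies


def mutation_frequency(genome_size: int, n_events: int) -> Optional[float]:
    """bp per event: genome_size / n_events, to 2 decimals.

    Undefined (None, reported as absent) when there are no events.
    """
    if genome_size < 1:
        raise ValueError("genome_size must be >= 1")
    if n_events == 0:
        return None
    return round(genome_size / n_events, 2)


@dataclass
class SpectrumReport:
    """Per-line spectrum table plus SV composition and an aggregate row."""

    per_line: pd.DataFrame
    sv_composition: pd.DataFrame
    genome_size: int

    @property
    def aggregate(self) -> pd.Series:
        df = self.per_line
        count_cols = [c for c in df.columns if c.startswith("n_")]
        agg = df[count_cols].sum()
        agg["freq_small"] = mutation_frequency(self.genome_size, int(agg["n_small"])) if agg["n_small"] else None
        agg["freq_all"] = mutation_frequency(self.genome_size, int(agg["n_total"])) if agg["n_total"] else None
        return agg

    def summary(self) -> str:
        df = self.per_line
        lines = [f"{len(df)} lines, genome size {self.genome_size:,} bp"]
        with_sv = df[df["n_total"] > 0]
        if len(with_sv):
            lines.append(
                "sv_share min {:.2f}% max {:.2f}%".format(
                    with_sv["sv_share"].min(), with_sv["sv_share"].max()
                )
            )
        freq = df["freq_small"].dropna()
        if len(freq):
            lines.append(
                "small-variant frequency 1/{:.0f} bp to 1/{:.0f} bp".format(
                    freq.min(), freq.max()
                )
            )
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.per_line.to_csv(path, sep="\t", index=False, float_format="%.2f")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genome_size": self.genome_size,
            "per_line": json.loads(self.per_line.to_json(orient="records")),
            "sv_composition": json.loads(self.sv_composition.to_json(orient="records")),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def build_report(
    catalog: MutationCatalog,
    line_info: Optional[Mapping[str, Tuple[str, int]]] = None,
    genome_size: int = GENOME_SIZE_RICE,
    translocations_as_deletions: bool = True,
) -> SpectrumReport:
    """Build the per-line spectrum/density report from a catalog.

    ``line_info`` optionally maps line_id -> (treatment, dose_gy).
    When ``translocations_as_deletions`` is set (the default), each
    ITX/CTX also counts as one deletion at its origin locus, and the SV
    total is DEL + DUP + INV + INS after that accounting.
    """
    rows = []
    for line_id in catalog.line_ids:
        c = catalog.counts(line_id)
        n_del = c["n_del"] + (c["n_itx"] + c["n_ctx"] if translocations_as_deletions else 0)
        if translocations_as_deletions:
            n_sv = n_del + c["n_dup"] + c["n_inv"] + c["n_ins"]
        else:
            n_sv = sum(c[f"n_{t.value.lower()}"] for t in SVType)
        n_small = c["n_snv"] + c["n_indel"]
        n_total = n_small + n_sv
        treatment, dose = ("", 0)
        if line_info and line_id in line_info:
            treatment, dose = line_info[line_id]
        rows.append(
            {
                "line_id": line_id, "treatment": treatment, "dose_gy": dose,
                "n_snv": c["n_snv"], "n_indel": c["n_indel"], "n_small": n_small,
                "n_del": n_del, "n_dup": c["n_dup"], "n_inv": c["n_inv"],
                "n_ins": c["n_ins"], "n_itx": c["n_itx"], "n_ctx": c["n_ctx"],
                "n_sv": n_sv, "n_total": n_total,
                "freq_small": mutation_frequency(genome_size, n_small),
                "freq_all": mutation_frequency(genome_size, n_total),
                "freq_sv": mutation_frequency(genome_size, n_sv),
                "sv_share": round(100.0 * n_sv / n_total, 2) if n_total else None,
            }
        )
    per_line = pd.DataFrame(
        rows,
        columns=["line_id", "treatment", "dose_gy", "n_snv", "n_indel", "n_small",
                 "n_del", "n_dup", "n_inv", "n_ins", "n_itx", "n_ctx", "n_sv",
                 "n_total", "freq_small", "freq_all", "freq_sv", "sv_share"],
    )
    totals = per_line[["n_del", "n_dup", "n_inv", "n_ins", "n_itx", "n_ctx"]].sum()
    sv_total = int(per_line["n_sv"].sum())
    comp_rows = []
    for t in SVType:
        n = int(totals[f"n_{t.value.lower()}"])
        comp_rows.append(
            {
                "sv_type": t.value,
                "count": n,
                "pct_of_sv": round(100.0 * n / sv_total, 2) if sv_total else None,
            }
        )
    sv_composition = pd.DataFrame(comp_rows, columns=["sv_type", "count", "pct_of_sv"])
    return SpectrumReport(per_line=per_line, sv_composition=sv_composition, genome_size=genome_size)
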