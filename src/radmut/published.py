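"""Loaders for the published summary tables shipped with the package.

Three small TSV fixtures travel with the code:

``published_line_counts.tsv``
    Per-line mutation counts and derived frequencies reported for the 11
    sequenced mutant lines of the gamma/X-ray rice population this
    pipeline models (SNVs, indels, SV type breakdown, bp/event
    frequencies at a 430 Mbp genome). The printed "del" column already
    includes deletions arising at translocation origin loci; the itx/ctx
    columns list those events separately and are not added again to the
    SV total.

``published_effect_counts.tsv``
    Per-line functional-effect counts (missense/nonsense/silent) and
    impact-tier counts (HIGH/LOW/MODERATE/MODIFIER) with the printed
    percentages. Impact counts are per variant-annotation pair, which is
    why they exceed the per-variant totals.

``validation_panel.tsv``
    The 34-entry Sanger validation panel: 30 predictions that passed
    filtering (all confirmed) and 4 negative controls that were removed
    — three heterozygous calls with alt-allele read ratios 3/29, 2/21
    and 2/25, and one low-coverage call. Read depths for the negatives
    are the published ones; depths for the confirmed entries are
    synthetic representative passing values (the study prints depths
    only for the negatives).

These are regression/replay inputs, not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import Genotype, SampleCall, VariantKey

GENOME_SIZE = 430_000_000  # rice genome size used for bp/event frequencies


def _read(name: str) -> pd.DataFrame:
    with resources.files("radmut.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def line_counts() -> pd.DataFrame:
    """Published per-line mutation counts and frequencies (11 lines)."""
    return _read("published_line_counts.tsv")


def effect_counts() -> pd.DataFrame:
    """Published per-line effect-class and impact-tier counts (11 lines)."""
    return _read("published_effect_counts.tsv")


def validation_panel() -> pd.DataFrame:
    """The Sanger validation panel with per-entry calls and read depths."""
    df = _read("validation_panel.tsv")
    df["pos"] = df["pos"].astype(int)
    return df


def validation_panel_calls() -> list[tuple[VariantKey, SampleCall, str]]:
    """Validation panel as (key, call, status) triples ready for filtering."""
    out = []
    for row in validation_panel().itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        call = SampleCall(
            sample_id=f"{row.line_id}_r1",
            genotype=Genotype(row.called_genotype),
            depth=int(row.depth),
            alt_depth=int(row.alt_depth),
        )
        out.append((key, call, row.status))
    return out
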