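"""Structural-variant consolidation.

Short-read SV callers disagree on exact breakpoints, so call sets from
several callers and both biological replicates of a line are reconciled
by single-linkage clustering with a coordinate tolerance (default
±2000 bp on both breakpoints) before any counting. On top of merging,
the module applies read-support thresholds (strict >100 reads for
translocations; caller-specific minimums elsewhere), replicate and
caller consensus requirements, cross-line/control uniqueness, and a
read-depth bin scan that recovers large deletions and duplications from
coverage ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import SVRecord, SVType

__all__ = [
    "SVConfig",
    "support_filter",
    "merge_records",
    "merge_translocations",
    "consensus_and_uniqueness",
    "bin_depth_scan",
    "GeneInterval",
    "sv_gene_overlap",
    "read_sv_table",
    "write_sv_table",
    "write_sv_bed",
]


@dataclass(frozen=True)
class SVConfig:
    """Thresholds for SV support filtering, merging and consensus.

    Translocation support is a strict inequality (>100 reads); the
    caller-specific minimums are inclusive. The ±2000 bp merge tolerance
    stated for translocations is applied to all SV types for
    cross-caller and cross-line matching, there being no other stated
    tolerance. ``cross_line_filter`` may be "strict" (shared SVs removed
    as natural variation, mirroring the small-variant cascade) or
    "report" (shared SVs kept but flagged).
    """

    translocation_min_support: int = 100
    breakdancer_min_pairs: int = 50
    lumpy_min_support: int = 50
    min_support: int = 1
    merge_tolerance: int = 2000
    min_callers: int = 1
    require_both_replicates: bool = True
    cross_line_filter: str = "strict"
    bin_sizes: Tuple[int, ...] = (1_000, 5_000, 10_000, 100_000)
    del_depth_ratio_max: float = 0.25
    dup_depth_ratio_min: float = 1.75
    pseudo_depth: float = 0.5

    def __post_init__(self) -> None:
        if self.merge_tolerance < 0:
            raise ValueError("merge_tolerance must be >= 0")
        for name in ("translocation_min_support", "breakdancer_min_pairs",
                     "lumpy_min_support", "min_support", "min_callers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cross_line_filter not in ("strict", "report"):
            raise ValueError("cross_line_filter must be 'strict' or 'report'")


def _caller_min(caller_id: str, cfg: SVConfig) -> int:
    cid = caller_id.lower()
    if "breakdancer" in cid:
        return cfg.breakdancer_min_pairs
    if "lumpy" in cid:
        return cfg.lumpy_min_support
    return cfg.min_support


def support_filter(records: Iterable[SVRecord], cfg: SVConfig = SVConfig()) -> List[SVRecord]:
    """Drop records below their read-support threshold.

    Translocations (ITX/CTX) need strictly more than
    ``translocation_min_support`` reads; other types need at least the
    minimum for their caller of origin.
    """
    kept = []
    for rec in records:
        if rec.sv_type in (SVType.ITX, SVType.CTX):
            if rec.support > cfg.translocation_min_support:
                kept.append(rec)
        elif rec.support >= _caller_min(rec.caller_id, cfg):
            kept.append(rec)
    return kept


def _canonical_sort(records: Sequence[SVRecord]) -> List[SVRecord]:
    return sorted(
        records,
        key=lambda r: (r.sv_type.value, r.chrom_pair, r.start, r.second_coord,
                       -r.support, r.caller_id, r.sample_id, r.line_id),
    )


def _cluster_single_linkage(records: Sequence[SVRecord], tol: int) -> List[List[SVRecord]]:
    """Single-linkage clusters: two records link iff same type and chrom
    pair, and both breakpoints are within ``tol``. Canonical sorting
    makes the result independent of input order."""
    recs = _canonical_sort(records)
    n = len(recs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # records sorted by start within groups: a sliding window keeps this
    # near-linear for well separated events
    by_group: Dict[Tuple, List[int]] = {}
    for idx, r in enumerate(recs):
        by_group.setdefault((r.sv_type, r.chrom_pair), []).append(idx)
    for idxs in by_group.values():
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1:]:
                if recs[j].start - recs[i].start > tol:
                    break
                if abs(recs[i].second_coord - recs[j].second_coord) <= tol:
                    union(i, j)
    clusters: Dict[int, List[SVRecord]] = {}
    for idx in range(n):
        clusters.setdefault(find(idx), []).append(recs[idx])
    return [clusters[root] for root in sorted(clusters)]


def _consensus_record(cluster: Sequence[SVRecord]) -> SVRecord:
    """Collapse a cluster into one record: support-weighted mean
    coordinates (rounded), support = max, callers/samples joined."""
    w = np.array([max(r.support, 1) for r in cluster], dtype=float)
    w /= w.sum()
    start = int(round(float(np.dot(w, [r.start for r in cluster]))))
    second = int(round(float(np.dot(w, [r.second_coord for r in cluster]))))
    first = cluster[0]
    callers = ",".join(sorted({r.caller_id for r in cluster if r.caller_id}))
    samples = ",".join(sorted({r.sample_id for r in cluster if r.sample_id}))
    support = max(r.support for r in cluster)
    if first.sv_type is SVType.CTX:
        return SVRecord(
            sv_type=first.sv_type, chrom=first.chrom, start=start, end=start,
            size=None, support=support, caller_id=callers, line_id=first.line_id,
            sample_id=samples, chrom2=first.chrom2, pos2=second,
        )
    start, second = min(start, second), max(start, second)
    return SVRecord(
        sv_type=first.sv_type, chrom=first.chrom, start=start, end=second,
        size=second - start + 1 if first.sv_type is not SVType.INS else first.size,
        support=support, caller_id=callers, line_id=first.line_id, sample_id=samples,
    )


def merge_records(records: Sequence[SVRecord], cfg: SVConfig = SVConfig()) -> List[SVRecord]:
    """Cluster same-type records at the merge tolerance and collapse each
    cluster into a consensus record."""
    out = []
    for cluster in _cluster_single_linkage(records, cfg.merge_tolerance):
        out.append(_consensus_record(cluster))
    return out


def merge_translocations(records: Sequence[SVRecord], cfg: SVConfig = SVConfig()) -> List[SVRecord]:
    """Merge translocation calls sharing similar coordinates (±tolerance).

    All input records must be of one translocation type; mixing types is
    an error so DEL/DUP records cannot silently enter translocation
    accounting.
    """
    types = {r.sv_type for r in records}
    if len(types) > 1:
        raise ValueError(f"mixed sv_types in translocation merge: {sorted(t.value for t in types)}")
    if types and next(iter(types)) not in (SVType.ITX, SVType.CTX):
        raise ValueError("merge_translocations expects ITX or CTX records")
    return merge_records(records, cfg)


@dataclass
class ConsensusResult:
    """Per-line consolidated SVs plus the removal/flag log."""

    accepted: Dict[str, List[SVRecord]]
    log: pd.DataFrame  # columns: line_id, sv_type, chrom, start, end, status, reason


def consensus_and_uniqueness(
    per_line: Mapping[str, Sequence[SVRecord]],
    control_records: Sequence[SVRecord] = (),
    cfg: SVConfig = SVConfig(),
    replicate_ids: Optional[Mapping[str, Sequence[str]]] = None,
) -> ConsensusResult:
    """Consolidate per-caller/per-replicate SV calls into per-line sets.

    Within each line, same-type records are merged at the tolerance; a
    consensus record survives only if reported by at least
    ``min_callers`` distinct callers and (when replicate identities are
    available) seen in both replicates. Records matching an SV in
    another line or in a control within the tolerance are natural
    variation: removed under the strict policy, flagged under "report".
    """
    merged: Dict[str, List[SVRecord]] = {}
    rows: List[dict] = []
    for line_id in sorted(per_line):
        kept: List[SVRecord] = []
        for cluster in _cluster_single_linkage(per_line[line_id], cfg.merge_tolerance):
            cons = _consensus_record(cluster).with_(line_id=line_id)
            callers = {r.caller_id for r in cluster if r.caller_id}
            if callers and len(callers) < cfg.min_callers:
                rows.append(_log_row(line_id, cons, "removed", "too_few_callers"))
                continue
            samples = {r.sample_id for r in cluster if r.sample_id}
            reps = set(replicate_ids.get(line_id, [])) if replicate_ids else set()
            if cfg.require_both_replicates and reps and samples and not reps <= samples:
                rows.append(_log_row(line_id, cons, "removed", "replicate_discordant"))
                continue
            kept.append(cons)
        merged[line_id] = kept

    control_merged = merge_records(list(control_records), cfg) if control_records else []
    accepted: Dict[str, List[SVRecord]] = {}
    for line_id, recs in merged.items():
        others = [r for other, lst in merged.items() if other != line_id for r in lst]
        final: List[SVRecord] = []
        for rec in recs:
            if _matches_any(rec, control_merged, cfg.merge_tolerance):
                reason = "in_control"
            elif _matches_any(rec, others, cfg.merge_tolerance):
                reason = "shared_across_lines"
            else:
                reason = None
            if reason is None:
                final.append(rec)
            elif cfg.cross_line_filter == "strict":
                rows.append(_log_row(line_id, rec, "removed", reason))
            else:
                rows.append(_log_row(line_id, rec, "flagged", reason))
                final.append(rec)
        accepted[line_id] = _canonical_sort(final)
    log = pd.DataFrame(
        rows, columns=["line_id", "sv_type", "chrom", "start", "end", "status", "reason"]
    )
    return ConsensusResult(accepted=accepted, log=log)


def _log_row(line_id: str, rec: SVRecord, status: str, reason: str) -> dict:
    return {
        "line_id": line_id, "sv_type": rec.sv_type.value, "chrom": rec.chrom,
        "start": rec.start, "end": rec.end, "status": status, "reason": reason,
    }


def _matches_any(rec: SVRecord, others: Sequence[SVRecord], tol: int) -> bool:
    return any(
        o.sv_type is rec.sv_type
        and o.chrom_pair == rec.chrom_pair
        and abs(o.start - rec.start) <= tol
        and abs(o.second_coord - rec.second_coord) <= tol
        for o in others
    )


def bin_depth_scan(
    depth_mutant: Sequence[float],
    depth_control: Sequence[float],
    chrom: str,
    bin_size: int,
    cfg: SVConfig = SVConfig(),
    bin_start: int = 1,
    line_id: str = "",
) -> List[SVRecord]:
    """Scan library-size-normalized binned depths for DEL/DUP candidates.

    Per bin the ratio (mutant + eps) / (control + eps) is computed with a
    pseudodepth eps; maximal runs of bins at or below
    ``del_depth_ratio_max`` become deletion candidates and runs at or
    above ``dup_depth_ratio_min`` duplication candidates, with the run
    extent as coordinates and the run length (bins) as support.
    """
    mut = np.asarray(depth_mutant, dtype=float)
    ctl = np.asarray(depth_control, dtype=float)
    if mut.shape != ctl.shape:
        raise ValueError(f"bin vectors differ in length: {mut.shape} vs {ctl.shape}")
    eps = cfg.pseudo_depth
    ratio = (mut + eps) / (ctl + eps)
    out: List[SVRecord] = []
    for sv_type, mask in (
        (SVType.DEL, ratio <= cfg.del_depth_ratio_max),
        (SVType.DUP, ratio >= cfg.dup_depth_ratio_min),
    ):
        for i0, i1 in _runs(mask):
            start = bin_start + i0 * bin_size
            end = bin_start + (i1 + 1) * bin_size - 1
            out.append(
                SVRecord(sv_type=sv_type, chrom=chrom, start=start, end=end,
                         support=i1 - i0 + 1, caller_id="bin_depth", line_id=line_id)
            )
    return out


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    is_transposon: bool = False


def sv_gene_overlap(
    records: Sequence[SVRecord], genes: Sequence[GeneInterval]
) -> pd.DataFrame:
    """Label each SV genic/intergenic and flag transposon overlap.

    An SV is genic when its [start, end] interval on ``chrom`` overlaps
    at least one gene interval; translocation second breakpoints are
    checked on their own chromosome too.
    """
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    rows = []
    for rec in records:
        hits = set(trees.get(rec.chrom, IntervalTree()).overlap(rec.start, rec.end + 1))
        if rec.sv_type is SVType.CTX and rec.chrom2 is not None:
            hits |= set(trees.get(rec.chrom2, IntervalTree()).overlap(rec.pos2, rec.pos2 + 1))
        gene_objs = [h.data for h in hits]
        rows.append(
            {
                "line_id": rec.line_id,
                "sv_type": rec.sv_type.value,
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "overlap_class": "genic" if gene_objs else "intergenic",
                "genes": ",".join(sorted(g.gene_id for g in gene_objs)),
                "transposon_overlap": any(g.is_transposon for g in gene_objs),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["line_id", "sv_type", "chrom", "start", "end",
                 "overlap_class", "genes", "transposon_overlap"],
    )


# ---------------------------------------------------------------------------
# Table input-output

_SV_COLUMNS = ["caller_id", "line_id", "sample_id", "sv_type", "chrom",
               "start", "end", "chrom2", "pos2", "size", "support"]


def write_sv_table(records: Sequence[SVRecord], path: str | Path) -> None:
    rows = [
        {
            "caller_id": r.caller_id, "line_id": r.line_id, "sample_id": r.sample_id,
            "sv_type": r.sv_type.value, "chrom": r.chrom, "start": r.start,
            "end": r.end, "chrom2": r.chrom2 or "", "pos2": r.pos2 if r.pos2 is not None else "",
            "size": r.size if r.size is not None else "", "support": r.support,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_SV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sv_table(path: str | Path) -> List[SVRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "chrom2": str}, keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            SVRecord(
                sv_type=SVType(r.sv_type), chrom=str(r.chrom), start=int(r.start),
                end=int(r.end), size=int(r.size) if str(r.size) != "" else None,
                support=int(r.support), caller_id=str(r.caller_id),
                line_id=str(r.line_id), sample_id=str(r.sample_id),
                chrom2=str(r.chrom2) if str(r.chrom2) != "" else None,
                pos2=int(r.pos2) if str(r.pos2) != "" else None,
            )
        )
    return out


def write_sv_bed(records: Sequence[SVRecord], path: str | Path) -> None:
    """BED export: 1-based inclusive internal coordinates become 0-based
    half-open."""
    with open(path, "w") as fh:
        for r in _canonical_sort(records):
            name = f"{r.line_id}:{r.sv_type.value}" if r.line_id else r.sv_type.value
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t{r.support}\n")
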