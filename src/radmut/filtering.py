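"""Small-variant filtering: depth filter, zygosity recalibration and the
four-step natural-variation subtraction cascade.

Induced-mutation discovery in a selfed mutant population works by
elimination. Every sample (two biological replicates per mutant line,
plus non-irradiated controls grown from the same seed bulk) is genotyped
at every variant site; a site counts as an induced mutation for a line
only if it survives, in order:

0. per-sample preparation — calls below a minimum read depth (default
   20x) are dropped, and heterozygous calls with an extreme
   alt-allele read fraction (< 20% or > 80%, strict) are re-scored as
   homozygous reference / homozygous alternative;
1. subtraction of everything seen in the non-irradiated controls;
2. removal of variation carried by samples of more than one mutant line
   (shared variation is founder polymorphism, not independent hits);
3. biological-replicate concordance — the variant must be non-reference
   in BOTH replicates of the line;
4. subtraction of a species-wide natural-variation catalog (a stand-in
   for the 3000-genomes SNP-Seek database).

Every candidate ends up either accepted or in the rejection log with a
reason code, so the bookkeeping is conservative: nothing is silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
import pysam

from .core import (
    Genotype,
    MutationCatalog,
    Rejection,
    RejectionReason,
    SampleCall,
    VariantKey,
    normalize_variant,
)

__all__ = [
    "FilterConfig",
    "ManifestEntry",
    "Manifest",
    "CallSet",
    "recalibrate_zygosity",
    "depth_filter",
    "prepare_calls",
    "build_natural_catalog",
    "run_cascade",
    "filter_small_variants",
    "read_multisample_vcf",
    "read_catalog_vcf",
    "write_accepted_vcf",
    "write_rejection_log",
]

#: calls indexed by variant identity, then by sample.
CallSet = Dict[VariantKey, Dict[str, SampleCall]]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for per-sample call preparation and the cascade.

    ``min_depth`` is inclusive (a 20-read call passes the default 20x
    threshold); the heterozygous allele-ratio bounds are strict (a call
    at exactly 20% or 80% stays heterozygous).
    """

    min_depth: int = 20
    het_low: float = 0.20
    het_high: float = 0.80
    require_both_replicates: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.het_low < self.het_high < 1.0):
            raise ValueError("need 0 < het_low < het_high < 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    line_id: str
    treatment: str = "none"
    dose_gy: int = 0
    role: str = "mutant_rep"  # or "control"


@dataclass
class Manifest:
    """Sample-to-line bookkeeping for one sequencing experiment."""

    entries: List[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample_id in manifest")

    @property
    def control_samples(self) -> List[str]:
        return [e.sample_id for e in self.entries if e.role == "control"]

    @property
    def mutant_lines(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for e in self.entries:
            if e.role != "control":
                out.setdefault(e.line_id, []).append(e.sample_id)
        return out

    @property
    def sample_to_line(self) -> Dict[str, str]:
        return {e.sample_id: e.line_id for e in self.entries if e.role != "control"}

    def line_info(self, line_id: str) -> ManifestEntry:
        for e in self.entries:
            if e.line_id == line_id:
                return e
        raise KeyError(line_id)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Manifest":
        df = pd.read_csv(path, sep="\t")
        return cls(
            [
                ManifestEntry(
                    str(r.sample_id), str(r.line_id), str(r.treatment), int(r.dose_gy), str(r.role)
                )
                for r in df.itertuples(index=False)
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([e.__dict__ for e in self.entries]).to_csv(path, sep="\t", index=False)


def recalibrate_zygosity(call: SampleCall, cfg: FilterConfig = FilterConfig()) -> SampleCall:
    """Re-score heterozygous calls with extreme alt-allele read ratios.

    A het call with alt fraction strictly below ``het_low`` becomes
    homozygous reference; strictly above ``het_high``, homozygous
    alternative. Fractions exactly at a bound stay heterozygous.
    Homozygous and missing calls pass through untouched; a het call with
    zero depth is uninformative and is marked missing.
    """
    if call.genotype is not Genotype.HET:
        return call
    if call.depth == 0:
        return replace(call, genotype=Genotype.MISSING)
    frac = call.alt_fraction
    if frac < cfg.het_low:
        return replace(call, genotype=Genotype.HOM_REF)
    if frac > cfg.het_high:
        return replace(call, genotype=Genotype.HOM_ALT)
    return call


def depth_filter(calls: CallSet, cfg: FilterConfig = FilterConfig()) -> CallSet:
    """Drop per-sample calls below the minimum depth (inclusive threshold)."""
    out: CallSet = {}
    for key, per_sample in calls.items():
        kept = {s: c for s, c in per_sample.items() if c.depth >= cfg.min_depth}
        if kept:
            out[key] = kept
    return out


def prepare_calls(
    calls: CallSet, cfg: FilterConfig = FilterConfig()
) -> Tuple[CallSet, Dict[Tuple[VariantKey, str], RejectionReason]]:
    """Apply depth filtering then zygosity recalibration to every call.

    Returns the processed call set plus a map recording, for each raw
    variant call that stopped being a variant call, whether it was lost
    to the depth filter or to allele-ratio recalibration. The map is
    what lets the cascade assign precise rejection reasons later.
    """
    processed: CallSet = {}
    dropped: Dict[Tuple[VariantKey, str], RejectionReason] = {}
    for key, per_sample in calls.items():
        for sid, call in per_sample.items():
            if call.depth < cfg.min_depth:
                if call.genotype.is_variant():
                    dropped[(key, sid)] = RejectionReason.LOW_DEPTH
                continue
            recal = recalibrate_zygosity(call, cfg)
            if call.genotype.is_variant() and not recal.genotype.is_variant():
                dropped[(key, sid)] = RejectionReason.ALLELE_RATIO
            processed.setdefault(key, {})[sid] = recal
    return processed, dropped


def build_natural_catalog(
    calls: CallSet,
    control_samples: Sequence[str],
    database_keys: Iterable[VariantKey] = (),
) -> Tuple[Set[VariantKey], Set[VariantKey]]:
    """Catalog natural variation from controls and an external database.

    The control catalog is the union of all non-reference keys carried
    by any control sample (cascade step 1); the database catalog simply
    deduplicates the supplied keys (step 4).
    """
    if not control_samples:
        raise ValueError("at least one non-irradiated control sample is required")
    controls = set(control_samples)
    control_catalog = {
        key
        for key, per_sample in calls.items()
        if any(s in controls and c.genotype.is_variant() for s, c in per_sample.items())
    }
    return control_catalog, set(database_keys)


def run_cascade(
    calls: CallSet,
    manifest: Manifest,
    control_catalog: Set[VariantKey],
    database_catalog: Set[VariantKey],
    cfg: FilterConfig = FilterConfig(),
    dropped: Optional[Mapping[Tuple[VariantKey, str], RejectionReason]] = None,
) -> MutationCatalog:
    """Run the four-step natural-variation subtraction cascade.

    ``calls`` must already be depth-filtered and recalibrated (see
    :func:`prepare_calls`); ``dropped`` carries the per-sample dropout
    reasons from that preparation so replicate-concordance failures can
    be attributed to low depth or allele-ratio recalibration rather than
    genuine discordance.

    Cross-line sharing (step 2) is evaluated on each line's carrier set
    before replicate intersection: any post-recalibration non-reference
    call in any sample of another mutant line disqualifies the key for
    every line — the maximally conservative reading.
    """
    dropped = dropped or {}
    lines = manifest.mutant_lines
    if cfg.require_both_replicates:
        bad = [l for l, reps in lines.items() if len(reps) != 2]
        if bad:
            raise ValueError(f"mutant lines must have exactly 2 replicates: {bad}")

    sample_line = manifest.sample_to_line
    carrier_samples: Dict[VariantKey, Set[str]] = {}
    for key, per_sample in calls.items():
        carriers = {s for s, c in per_sample.items() if c.genotype.is_variant()}
        if carriers:
            carrier_samples[key] = carriers

    carrier_lines: Dict[VariantKey, Set[str]] = {
        key: {sample_line[s] for s in samples if s in sample_line}
        for key, samples in carrier_samples.items()
    }

    required = 2 if cfg.require_both_replicates else 1
    catalog = MutationCatalog()
    for line_id in sorted(lines):
        reps = set(lines[line_id])
        candidates = {
            key for key, samples in carrier_samples.items() if samples & reps
        }
        candidates |= {key for (key, sid) in dropped if sid in reps}
        catalog.accepted_snvs.setdefault(line_id, set())
        catalog.accepted_indels.setdefault(line_id, set())
        for key in sorted(candidates):
            reason = _evaluate_key(
                key, line_id, reps, carrier_samples, carrier_lines,
                control_catalog, database_catalog, dropped, required,
            )
            if reason is None:
                catalog.add_accepted(line_id, key)
            else:
                catalog.rejections.append(Rejection(line_id, key, reason))
    return catalog


def _evaluate_key(
    key: VariantKey,
    line_id: str,
    reps: Set[str],
    carrier_samples: Mapping[VariantKey, Set[str]],
    carrier_lines: Mapping[VariantKey, Set[str]],
    control_catalog: Set[VariantKey],
    database_catalog: Set[VariantKey],
    dropped: Mapping[Tuple[VariantKey, str], RejectionReason],
    required: int,
) -> Optional[RejectionReason]:
    # step 1: founder variation seen in the non-irradiated controls
    if key in control_catalog:
        return RejectionReason.IN_CONTROL
    # step 2: variation carried by more than one mutant line
    if len(carrier_lines.get(key, set())) > 1:
        return RejectionReason.SHARED_ACROSS_LINES
    # step 3: both biological replicates must carry the variant
    if len(carrier_samples.get(key, set()) & reps) < required:
        rep_reasons = {dropped.get((key, s)) for s in reps}
        if RejectionReason.LOW_DEPTH in rep_reasons:
            return RejectionReason.LOW_DEPTH
        if RejectionReason.ALLELE_RATIO in rep_reasons:
            return RejectionReason.ALLELE_RATIO
        return RejectionReason.REPLICATE_DISCORDANT
    # step 4: species-wide natural-variation database
    if key in database_catalog:
        return RejectionReason.IN_DATABASE
    return None


def filter_small_variants(
    calls: CallSet,
    manifest: Manifest,
    database_keys: Iterable[VariantKey] = (),
    cfg: FilterConfig = FilterConfig(),
    reference: Optional[Mapping[str, str]] = None,
) -> MutationCatalog:
    """End-to-end small-variant filtering for one experiment.

    Normalizes variant identities (when a reference is supplied), builds
    the control catalog from the manifest's control samples, prepares
    calls (depth filter + recalibration) and runs the cascade.
    """
    if reference is not None:
        calls = normalize_callset(calls, reference)
    control_catalog, database_catalog = build_natural_catalog(
        calls, manifest.control_samples, database_keys
    )
    processed, dropped = prepare_calls(calls, cfg)
    return run_cascade(processed, manifest, control_catalog, database_catalog, cfg, dropped)


def normalize_callset(calls: CallSet, reference: Mapping[str, str]) -> CallSet:
    """Left-normalize every key against the reference, merging duplicates."""
    out: CallSet = {}
    for key, per_sample in calls.items():
        seq = reference.get(key.chrom)
        norm = (
            normalize_variant(key.chrom, key.pos, key.ref, key.alt, seq)
            if seq is not None
            else key
        )
        out.setdefault(norm, {}).update(per_sample)
    return out


# ---------------------------------------------------------------------------
# VCF / TSV input-output


def _genotype_for_alt(gt: Tuple[Optional[int], ...], alt_index: int) -> Genotype:
    if gt is None or any(a is None for a in gt):
        return Genotype.MISSING
    n_alt = sum(1 for a in gt if a == alt_index)
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == len(gt):
        return Genotype.HOM_ALT
    return Genotype.HET


def read_multisample_vcf(path: str | Path) -> CallSet:
    """Read a multi-sample VCF (GT:AD:DP) into a call set.

    Multi-allelic records are split into one key per alt allele. A
    record whose samples lack both DP and AD is a hard error — the depth
    filter is undefined without depths.
    """
    calls: CallSet = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for i, alt in enumerate(rec.alts or (), start=1):
                key = VariantKey(rec.chrom, rec.pos, rec.ref, str(alt))
                per_sample: Dict[str, SampleCall] = {}
                for sample in rec.samples.values():
                    ad = sample.get("AD")
                    dp = sample.get("DP")
                    if dp is None and (ad is None or all(a is None for a in ad)):
                        raise ValueError(
                            f"record {rec.chrom}:{rec.pos} sample {sample.name}: "
                            "no DP or AD field; depth filtering is undefined"
                        )
                    alt_depth = 0
                    if ad is not None and len(ad) > i and ad[i] is not None:
                        alt_depth = int(ad[i])
                    depth = int(dp) if dp is not None else int(sum(a or 0 for a in ad))
                    per_sample[sample.name] = SampleCall(
                        sample_id=sample.name,
                        genotype=_genotype_for_alt(sample.get("GT"), i),
                        depth=depth,
                        alt_depth=min(alt_depth, depth),
                    )
                calls.setdefault(key, {}).update(per_sample)
    return calls


def read_catalog_vcf(path: str | Path) -> Set[VariantKey]:
    """Read the keys of a (sites-only or genotyped) natural-variation VCF."""
    keys: Set[VariantKey] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                keys.add(VariantKey(rec.chrom, rec.pos, rec.ref, str(alt)))
    return keys


def write_accepted_vcf(
    catalog: MutationCatalog,
    path: str | Path,
    contigs: Optional[Mapping[str, int]] = None,
) -> None:
    """Write all accepted small variants to a sites-only VCF with a LINE tag."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=LINE,Number=.,Type=String,Description="Mutant line carrying the induced variant">')
    header.add_line('##INFO=<ID=VARCLASS,Number=1,Type=String,Description="snv or indel">')
    keys: Dict[VariantKey, List[str]] = {}
    for line_id in catalog.line_ids:
        for key in catalog.accepted_small(line_id):
            keys.setdefault(key, []).append(line_id)
    if contigs is None:
        contigs = {c: 2**29 for c in sorted({k.chrom for k in keys})}
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(keys):
            rec = out.new_record(
                contig=key.chrom, start=key.pos - 1, alleles=(key.ref, key.alt)
            )
            rec.info["LINE"] = ",".join(sorted(keys[key]))
            rec.info["VARCLASS"] = "snv" if key.is_snv else "indel"
            out.write(rec)


def read_accepted_vcf(path: str | Path) -> MutationCatalog:
    """Rebuild the small-variant part of a catalog from an accepted VCF
    written by :func:`write_accepted_vcf`."""
    catalog = MutationCatalog()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            lines = rec.info.get("LINE")
            if lines is None:
                continue
            if isinstance(lines, str):
                lines = lines.split(",")
            else:
                lines = [part for v in lines for part in str(v).split(",")]
            for alt in rec.alts or ():
                key = VariantKey(rec.chrom, rec.pos, rec.ref, str(alt))
                for line_id in lines:
                    catalog.add_accepted(line_id, key)
    return catalog


def write_rejection_log(catalog: MutationCatalog, path: str | Path) -> None:
    rows = [
        {
            "line_id": r.line_id,
            "chrom": r.key.chrom,
            "pos": r.key.pos,
            "ref": r.key.ref,
            "alt": r.key.alt,
            "reason": r.reason.value,
            "step": r.step,
        }
        for r in catalog.rejections
    ]
    pd.DataFrame(
        rows, columns=["line_id", "chrom", "pos", "ref", "alt", "reason", "step"]
    ).to_csv(path, sep="\t", index=False)
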