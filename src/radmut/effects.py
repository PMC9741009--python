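"""Codon-level functional-effect classification for accepted mutations.

A deliberately small annotator in the SNPeff tradition: given reference
sequence and gene models, each SNV is resolved to its codon on the
coding strand and classified (silent / missense / nonsense / start or
stop lost) via the standard genetic code; indels are classified by
whether their net coding-length change preserves frame. Non-coding
variants map to intronic / upstream / downstream / intergenic MODIFIER
classes. Counting is per variant-annotation pair: a variant inside the
footprint or flanking window of two genes contributes two annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .core import MutationCatalog, VariantKey

__all__ = [
    "TranscriptModel",
    "EffectCall",
    "GeneSet",
    "classify_snv",
    "classify_indel",
    "classify_variant",
    "annotate_catalog",
    "effect_percentages",
    "load_gff3",
]

FLANK_BP = 5_000  # upstream/downstream annotation window
SPLICE_WARN_BP = 2  # variants this close to an intron boundary get a warning

HIGH, MODERATE, LOW, MODIFIER = "HIGH", "MODERATE", "LOW", "MODIFIER"

_IMPACT = {
    "nonsense": HIGH,
    "frameshift": HIGH,
    "stop_lost": HIGH,
    "start_lost": HIGH,
    "missense": MODERATE,
    "inframe_indel": MODERATE,
    "silent": LOW,
    "intronic": MODIFIER,
    "intergenic": MODIFIER,
    "upstream": MODIFIER,
    "downstream": MODIFIER,
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """A protein-coding gene model: ordered CDS intervals on one strand.

    ``cds_intervals`` are 1-based inclusive genomic intervals in
    ascending genomic order; the spliced CDS read on the coding strand
    must start with ATG, end with a stop codon, and have length
    divisible by 3.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: Tuple[Tuple[int, int], ...]
    is_transposon: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ivs = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")
        object.__setattr__(self, "cds_intervals", tuple(ivs))

    @property
    def footprint(self) -> Tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def contains_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_intervals)

    def cds_offset(self, pos: int) -> int:
        """0-based offset of a genomic position in the spliced CDS,
        counted along the coding strand."""
        off = 0
        for s, e in self.cds_intervals:
            if pos < s:
                raise ValueError(f"{pos} not in CDS of {self.gene_id}")
            if pos <= e:
                off += pos - s
                break
            off += e - s + 1
        else:
            raise ValueError(f"{pos} not in CDS of {self.gene_id}")
        if self.strand == "-":
            return self.cds_length - 1 - off
        return off

    def spliced_cds(self, chrom_seq: str) -> str:
        """Spliced coding sequence on the coding strand."""
        parts = [chrom_seq[s - 1 : e] for s, e in self.cds_intervals]
        cds = "".join(parts).upper()
        return _revcomp(cds) if self.strand == "-" else cds

    def near_splice(self, pos: int) -> bool:
        """Within SPLICE_WARN_BP of an internal CDS (intron) boundary."""
        if len(self.cds_intervals) < 2:
            return False
        bounds = []
        for i, (s, e) in enumerate(self.cds_intervals):
            if i > 0:
                bounds.append(s)
            if i < len(self.cds_intervals) - 1:
                bounds.append(e)
        return any(abs(pos - b) <= SPLICE_WARN_BP for b in bounds)


@dataclass(frozen=True)
class EffectCall:
    effect: str
    impact: str
    gene_id: str = ""
    warning: str = ""


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_snv(
    key: VariantKey, model: TranscriptModel, reference: Mapping[str, str]
) -> EffectCall:
    """Classify an SNV against one gene model.

    Raises if the stated ref allele does not match the reference base —
    that is a coordinate bug, not a data condition to tolerate.
    """
    seq = reference[key.chrom]
    _check_ref(key, seq)
    if model.contains_cds(key.pos):
        off = model.cds_offset(key.pos)
        cds = model.spliced_cds(seq)
        codon_i, within = divmod(off, 3)
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        alt = key.alt if model.strand == "+" else _revcomp(key.alt)
        mutant = codon[:within] + alt.upper() + codon[within + 1 :]
        aa_ref, aa_alt = _translate(codon), _translate(mutant)
        warning = "near_splice" if model.near_splice(key.pos) else ""
        if aa_ref == aa_alt:
            effect = "silent"
        elif aa_ref == "*":
            effect = "stop_lost"
        elif aa_alt == "*":
            effect = "nonsense"
        elif codon_i == 0:
            effect = "start_lost"
        else:
            effect = "missense"
        return EffectCall(effect, _IMPACT[effect], model.gene_id, warning)
    return _noncoding_call(key.pos, key.pos, model)


def classify_indel(
    key: VariantKey, model: TranscriptModel, reference: Mapping[str, str]
) -> EffectCall:
    """Classify a small indel (or MNV) against one gene model.

    A coding indel whose net coding-length change is not a multiple of 3
    is a frameshift (HIGH); an in-frame indel is MODERATE unless it
    creates a premature stop or destroys the stop codon (HIGH).
    """
    seq = reference[key.chrom]
    _check_ref(key, seq)
    ref, alt, pos = key.ref.upper(), key.alt.upper(), key.pos
    # strip the shared VCF anchor prefix to find the edited region
    p = 0
    while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
        p += 1
    deleted = ref[p:]
    inserted = alt[p:]
    del_start, del_end = pos + p, pos + p + len(deleted) - 1  # empty when pure insertion
    if deleted:
        touched = (del_start, del_end)
    else:
        touched = (pos + p - 1, pos + p)  # insertion breakpoint

    del_in_cds = sum(
        max(0, min(del_end, e) - max(del_start, s) + 1)
        for s, e in model.cds_intervals
    ) if deleted else 0
    ins_in_cds = len(inserted) if model.contains_cds(touched[1]) and model.contains_cds(touched[0]) else 0
    coding = del_in_cds > 0 or ins_in_cds > 0
    if not coding:
        call = _noncoding_call(touched[0], touched[1], model)
        if call.effect == "intronic" and model.near_splice(touched[0]):
            return EffectCall(call.effect, call.impact, call.gene_id, "near_splice")
        return call

    net = ins_in_cds - del_in_cds
    warning = "near_splice" if model.near_splice(touched[0]) else ""
    if net % 3 != 0:
        return EffectCall("frameshift", HIGH, model.gene_id, warning)
    effect, impact = "inframe_indel", MODERATE
    mutant_cds = _mutant_cds_if_contained(key, model, seq, p, deleted, inserted)
    if mutant_cds is not None:
        ref_prot = _protein(model.spliced_cds(seq))
        alt_prot = _protein(mutant_cds)
        if alt_prot is None:
            effect, impact = "stop_lost", HIGH
        elif ref_prot is not None and len(alt_prot) < len(ref_prot) + net // 3:
            # shorter than the in-frame length change explains: new stop
            impact = HIGH
    return EffectCall(effect, impact, model.gene_id, warning)


def _protein(cds: str) -> Optional[str]:
    """Translate to the first stop; None if no stop codon remains."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    if "*" not in prot:
        return None
    return prot[: prot.index("*")]


def _mutant_cds_if_contained(
    key: VariantKey,
    model: TranscriptModel,
    seq: str,
    prefix: int,
    deleted: str,
    inserted: str,
) -> Optional[str]:
    """Spliced mutant CDS when the edit falls wholly inside one CDS
    interval; None otherwise (frame logic alone is then used)."""
    start = key.pos + prefix
    end = start + max(len(deleted), 1) - 1
    for s, e in model.cds_intervals:
        if s <= start and (end <= e if deleted else start - 1 >= s):
            break
    else:
        return None
    # build the edit on the + strand spliced coordinates
    plus_cds_parts = [seq[a - 1 : b] for a, b in model.cds_intervals]
    plus = "".join(plus_cds_parts).upper()
    plus_off = 0
    for a, b in model.cds_intervals:
        if start > b:
            plus_off += b - a + 1
        else:
            plus_off += start - a
            break
    if deleted:
        mutant_plus = plus[:plus_off] + inserted + plus[plus_off + len(deleted):]
    else:
        # inserted bases sit between the anchor (start-1) and start
        mutant_plus = plus[:plus_off] + inserted + plus[plus_off:]
    return _revcomp(mutant_plus) if model.strand == "-" else mutant_plus


def _noncoding_call(start: int, end: int, model: TranscriptModel) -> EffectCall:
    fs, fe = model.footprint
    if end >= fs and start <= fe:
        return EffectCall("intronic", MODIFIER, model.gene_id)
    upstream_side = start < fs if model.strand == "+" else end > fe
    dist = fs - end if end < fs else start - fe
    if dist <= FLANK_BP:
        effect = "upstream" if upstream_side else "downstream"
        return EffectCall(effect, MODIFIER, model.gene_id)
    return EffectCall("intergenic", MODIFIER)


def _check_ref(key: VariantKey, seq: str) -> None:
    found = seq[key.pos - 1 : key.pos - 1 + len(key.ref)].upper()
    if found != key.ref.upper():
        raise ValueError(
            f"reference mismatch at {key.chrom}:{key.pos}: expected {key.ref}, found {found}"
        )


class GeneSet:
    """All gene models of a genome with an interval index for lookup."""

    def __init__(self, models: Sequence[TranscriptModel]):
        self.models = list(models)
        self._trees: Dict[str, IntervalTree] = {}
        for m in self.models:
            fs, fe = m.footprint
            self._trees.setdefault(m.chrom, IntervalTree()).addi(
                max(1, fs - FLANK_BP), fe + FLANK_BP + 1, m
            )

    def __len__(self) -> int:
        return len(self.models)

    def overlapping(self, chrom: str, start: int, end: int) -> List[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        return sorted(hits, key=lambda m: (m.footprint, m.gene_id))


def classify_variant(
    key: VariantKey, genes: GeneSet, reference: Mapping[str, str]
) -> List[EffectCall]:
    """Per-annotation classification: one EffectCall per gene whose
    footprint-plus-flank the variant touches, or a single intergenic
    call when it touches none."""
    span = max(len(key.ref), 1)
    models = genes.overlapping(key.chrom, key.pos, key.pos + span - 1)
    if not models:
        return [EffectCall("intergenic", MODIFIER)]
    fn = classify_snv if key.is_snv else classify_indel
    return [fn(key, m, reference) for m in models]


def annotate_catalog(
    catalog: MutationCatalog, genes: GeneSet, reference: Mapping[str, str]
) -> pd.DataFrame:
    """Annotate every accepted small variant of every line.

    Returns one row per variant-annotation pair with effect and impact.
    """
    rows = []
    for line_id in catalog.line_ids:
        for key in sorted(catalog.accepted_small(line_id)):
            for call in classify_variant(key, genes, reference):
                rows.append(
                    {
                        "line_id": line_id, "chrom": key.chrom, "pos": key.pos,
                        "ref": key.ref, "alt": key.alt,
                        "var_class": "snv" if key.is_snv else "indel",
                        "gene_id": call.gene_id or ".", "effect": call.effect,
                        "impact": call.impact, "warning": call.warning,
                    }
                )
    return pd.DataFrame(
        rows, columns=["line_id", "chrom", "pos", "ref", "alt", "var_class",
                       "gene_id", "effect", "impact", "warning"],
    )


def effect_percentages(
    counts: Mapping[str, int], decimals: Optional[int] = None
) -> Dict[str, float]:
    """Percentages within the functional family (missense, nonsense,
    silent) and the impact family (high, low, moderate, modifier), each
    over its own family total. Families with an all-zero denominator are
    omitted rather than raising."""
    for v in counts.values():
        if v < 0:
            raise ValueError("counts must be non-negative")
    out: Dict[str, float] = {}
    for family in (("missense", "nonsense", "silent"),
                   ("high", "low", "moderate", "modifier")):
        present = {k: counts[k] for k in family if k in counts}
        total = sum(present.values())
        if total == 0:
            continue
        for k, v in present.items():
            pct = 100.0 * v / total
            out[f"{k}_pct"] = round(pct, decimals) if decimals is not None else pct
    return out


def load_gff3(path: str | Path, transposon_keywords: Sequence[str] = ("transposon", "retrotransposon")) -> List[TranscriptModel]:
    """Read protein-coding gene models (CDS features grouped by parent)
    from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        note = " ".join(gene.attributes.get("Note", [])).lower()
        is_tn = any(k in note for k in transposon_keywords)
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = [(c.start, c.end) for c in db.children(mrna, featuretype="CDS")]
            if not cds:
                continue
            models.append(
                TranscriptModel(
                    gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                    cds_intervals=tuple(sorted(cds)), is_transposon=is_tn,
                )
            )
    return models
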