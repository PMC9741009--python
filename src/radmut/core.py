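"""Core domain types shared across the pipeline.

A small variant is identified by its :class:`VariantKey` (chromosome,
1-based position, ref allele, alt allele) after splitting multi-allelic
records and left-normalizing indels, so that set operations between
samples, lines, controls and catalogs are exact — the same identity
``bcftools isec`` uses. Structural variants are carried as
:class:`SVRecord` with explicit breakpoints and read support.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

__all__ = [
    "Genotype",
    "VariantKey",
    "SampleCall",
    "SVType",
    "SVRecord",
    "RejectionReason",
    "Rejection",
    "MutationCatalog",
    "normalize_variant",
]


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    def is_variant(self) -> bool:
        """Whether the call carries at least one alternative allele."""
        return self in (Genotype.HET, Genotype.HOM_ALT)


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a small variant: (chrom, 1-based pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        """Both alleles length 1; anything else (incl. MNVs) counts as indel."""
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class SampleCall:
    """One sample's genotype call at a site, with its read depths.

    ``depth`` is the total read depth (DP) and ``alt_depth`` the reads
    supporting the alternative allele (from AD).
    """

    sample_id: str
    genotype: Genotype
    depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        if not (0 <= self.alt_depth <= self.depth):
            raise ValueError(
                f"alt_depth must satisfy 0 <= {self.alt_depth} <= depth {self.depth} "
                f"(sample {self.sample_id})"
            )

    @property
    def alt_fraction(self) -> float:
        """Fraction of reads supporting the alternative allele; 0 if no reads."""
        if self.depth == 0:
            return 0.0
        return self.alt_depth / self.depth


class SVType(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    INS = "INS"
    ITX = "ITX"  # intra-chromosomal translocation
    CTX = "CTX"  # inter-chromosomal translocation


@dataclass(frozen=True)
class SVRecord:
    """A structural-variant call.

    Coordinates are 1-based inclusive. For CTX the second breakpoint
    lives on ``chrom2``/``pos2`` and ``size`` is not defined; for
    DEL/DUP/INV, ``size == end - start + 1``.
    """

    sv_type: SVType
    chrom: str
    start: int
    end: int
    size: Optional[int] = None
    support: int = 0
    caller_id: str = ""
    line_id: str = ""
    sample_id: str = ""
    chrom2: Optional[str] = None
    pos2: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.sv_type is SVType.CTX:
            if self.chrom2 is None or self.pos2 is None:
                raise ValueError("CTX requires chrom2 and pos2")
            if self.chrom2 == self.chrom:
                raise ValueError("CTX breakpoints must be on different chromosomes")
        elif self.sv_type is SVType.ITX:
            if self.chrom2 is not None and self.chrom2 != self.chrom:
                raise ValueError("ITX breakpoints must share one chromosome")
        if self.sv_type in (SVType.DEL, SVType.DUP, SVType.INV) and self.size is None:
            object.__setattr__(self, "size", self.end - self.start + 1)

    @property
    def second_coord(self) -> int:
        """The coordinate used as the 'other end' when matching records."""
        if self.sv_type is SVType.CTX:
            assert self.pos2 is not None
            return self.pos2
        return self.end

    @property
    def chrom_pair(self) -> Tuple[str, str]:
        return (self.chrom, self.chrom2 if self.chrom2 is not None else self.chrom)

    def with_(self, **kwargs) -> "SVRecord":
        return replace(self, **kwargs)


class RejectionReason(str, enum.Enum):
    IN_CONTROL = "in_control"
    SHARED_ACROSS_LINES = "shared_across_lines"
    REPLICATE_DISCORDANT = "replicate_discordant"
    IN_DATABASE = "in_database"
    LOW_DEPTH = "low_depth"
    ALLELE_RATIO = "allele_ratio_recalibrated_to_ref"


#: Which cascade step each rejection reason belongs to (0 = pre-cascade
#: per-sample filtering, 1..4 = the four natural-variation subtraction steps).
REASON_STEP: Mapping[RejectionReason, int] = {
    RejectionReason.IN_CONTROL: 1,
    RejectionReason.SHARED_ACROSS_LINES: 2,
    RejectionReason.LOW_DEPTH: 3,
    RejectionReason.ALLELE_RATIO: 3,
    RejectionReason.REPLICATE_DISCORDANT: 3,
    RejectionReason.IN_DATABASE: 4,
}


@dataclass(frozen=True)
class Rejection:
    line_id: str
    key: VariantKey
    reason: RejectionReason

    @property
    def step(self) -> int:
        return REASON_STEP[self.reason]


@dataclass
class MutationCatalog:
    """Per-line accepted induced mutations plus the full rejection log.

    Invariant: for each line, every evaluated candidate key appears in
    exactly one of the accepted sets or the rejection log.
    """

    accepted_snvs: Dict[str, Set[VariantKey]] = field(default_factory=dict)
    accepted_indels: Dict[str, Set[VariantKey]] = field(default_factory=dict)
    accepted_svs: Dict[str, List[SVRecord]] = field(default_factory=dict)
    rejections: List[Rejection] = field(default_factory=list)

    @property
    def line_ids(self) -> List[str]:
        return sorted(set(self.accepted_snvs) | set(self.accepted_indels) | set(self.accepted_svs))

    def accepted_small(self, line_id: str) -> Set[VariantKey]:
        return self.accepted_snvs.get(line_id, set()) | self.accepted_indels.get(line_id, set())

    def rejected_keys(self, line_id: str) -> Set[VariantKey]:
        return {r.key for r in self.rejections if r.line_id == line_id}

    def add_accepted(self, line_id: str, key: VariantKey) -> None:
        target = self.accepted_snvs if key.is_snv else self.accepted_indels
        target.setdefault(line_id, set()).add(key)

    def counts(self, line_id: str) -> Dict[str, int]:
        svs = self.accepted_svs.get(line_id, [])
        out = {
            "n_snv": len(self.accepted_snvs.get(line_id, set())),
            "n_indel": len(self.accepted_indels.get(line_id, set())),
        }
        for t in SVType:
            out[f"n_{t.value.lower()}"] = sum(1 for r in svs if r.sv_type is t)
        return out


def normalize_variant(
    chrom: str, pos: int, ref: str, alt: str, sequence: str
) -> VariantKey:
    """Left-normalize an indel representation against the reference.

    Implements the standard parsimony/left-alignment algorithm: trim
    shared trailing bases (extending left with reference sequence when an
    allele would become empty), then trim shared leading bases. SNVs pass
    through unchanged. ``sequence`` is the full chromosome sequence
    (0-based indexing internally; ``pos`` is 1-based).
    """
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        return VariantKey(chrom, pos, ref, alt)
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise ValueError("cannot left-extend past chromosome start")
                pad = sequence[pos - 2].upper()
                ref, alt, pos = pad + ref, pad + alt, pos - 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return VariantKey(chrom, pos, ref, alt)
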