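"""Synthetic population generator with machine-readable truth.

Raw reads for a mutagenized rice population are impractical at desk
scale, so this module emulates the downstream call-level data the
pipeline consumes: a reference genome with protein-coding gene models,
founder natural variation shared by every sample (the seed-bulk
polymorphism the controls exist to subtract), line-unique induced
mutations present in both biological replicates, per-sample genotype
calls with binomial allele-depth noise around Poisson total depth
(~30x), and multi-caller SV call sets with breakpoint jitter and
configurable false positives. Every generated dataset is paired with a
truth table so filtering precision and recall can be measured exactly.

The default population mirrors the study design this pipeline models:
11 mutant lines (gamma 150–450 Gy, X-ray 75–150 Gy) with two replicates
each, two non-irradiated controls, and per-line induced-mutation counts
scaled down 1/150 from the published per-line totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pysam

from .core import Genotype, SampleCall, SVRecord, SVType, VariantKey
from .effects import TranscriptModel
from .filtering import CallSet, Manifest, ManifestEntry
from .sv import GeneInterval, write_sv_table
from . import published

__all__ = [
    "LineSpec",
    "SimulationConfig",
    "Reference",
    "TruthTable",
    "SimulationResult",
    "default_population",
    "generate_reference",
    "generate_truth",
    "sample_population_calls",
    "simulate_sv_callsets",
    "simulate_depth_bins",
    "simulate_all",
    "write_fasta",
    "write_gff3",
    "write_vcf",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_DOSES = (0, 75, 150, 300, 450, 600)
_SV_WEIGHTS = {  # composition roughly matching the published SV spectrum
    SVType.DEL: 0.80, SVType.DUP: 0.06, SVType.INV: 0.04,
    SVType.INS: 0.05, SVType.ITX: 0.01, SVType.CTX: 0.04,
}
_CALLER_NAMES = ("breakdancer_sim", "lumpy_sim", "manta_sim", "depthbin_sim")


@dataclass(frozen=True)
class LineSpec:
    """One line of the population: treatment, dose and induced load."""

    line_id: str
    treatment: str  # gamma, xray or none
    dose_gy: int
    induced_snv_count: int = 0
    induced_indel_count: int = 0
    induced_sv_count: int = 0
    replicate_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.treatment not in ("gamma", "xray", "none"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.dose_gy not in _DOSES:
            raise ValueError(f"dose must be one of {_DOSES}, got {self.dose_gy}")
        if self.treatment == "none":
            if self.induced_snv_count or self.induced_indel_count or self.induced_sv_count:
                raise ValueError(f"control line {self.line_id} must have zero induced counts")
        else:
            if len(self.replicate_ids) != 2:
                raise ValueError(
                    f"mutant line {self.line_id} needs exactly 2 replicates, "
                    f"got {len(self.replicate_ids)}"
                )

    @property
    def is_control(self) -> bool:
        return self.treatment == "none"


def default_population(scale: float = 1 / 150) -> Tuple[LineSpec, ...]:
    """The study population at desk scale: 11 mutant lines + 2 controls.

    Induced counts are the published per-line SNV/indel/SV counts times
    ``scale`` (at least 1 each), preserving the relative mutation loads
    across treatments and doses.
    """
    specs = []
    for row in published.line_counts().itertuples(index=False):
        specs.append(
            LineSpec(
                line_id=row.line_id,
                treatment=row.treatment,
                dose_gy=int(row.dose_gy),
                induced_snv_count=max(1, round(row.snv * scale)),
                induced_indel_count=max(1, round(row.indel * scale)),
                induced_sv_count=max(1, round(row.sv * scale)),
                replicate_ids=(f"{row.line_id}_r1", f"{row.line_id}_r2"),
            )
        )
    specs.append(LineSpec("control_1", "none", 0, replicate_ids=("C43801",)))
    specs.append(LineSpec("control_2", "none", 0, replicate_ids=("C43802",)))
    return tuple(specs)


@dataclass
class SimulationConfig:
    """All knobs of the generator; one seed drives every stage.

    Defaults emulate the modeled study: ~30x mean depth, heterozygous
    alt fraction 0.5, induced mutations mostly fixed homozygous by the
    seventh selfed generation with a 5% heterozygous residual, four SV
    callers.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 300_000
    n_genes: int = 20
    natural_variant_density: float = 1e-3
    lines: Optional[Tuple[LineSpec, ...]] = None
    depth_mean: float = 30.0
    het_alt_fraction_mean: float = 0.5
    genotyping_error_rate: float = 0.001
    seq_error_rate: float = 0.005
    induced_het_fraction: float = 0.05
    founder_indel_fraction: float = 0.10
    indel_max_len: int = 15
    sv_min_size: int = 179
    sv_max_size: int = 10_000
    #: distinct truth SVs keep breakpoints at least this far apart, so
    #: identity under a +/-2 kb matching tolerance stays unambiguous;
    #: deliberate collisions are injected explicitly instead.
    sv_min_separation: int = 4_500
    sv_breakpoint_jitter_sd: float = 150.0
    n_sv_callers: int = 4
    sv_detection_prob: float = 0.9
    sv_false_positive_rate: float = 0.05
    sv_support_mean: float = 200.0
    n_natural_svs: int = 2
    n_cross_line_collisions: int = 0
    noiseless: bool = False

    def __post_init__(self) -> None:
        if self.lines is None:
            self.lines = default_population()
        self.lines = tuple(self.lines)
        if self.chrom_length < 10_000:
            raise ValueError("chrom_length must be >= 10,000")
        if self.natural_variant_density < 0:
            raise ValueError("natural_variant_density must be >= 0")
        if self.sv_breakpoint_jitter_sd < 0:
            raise ValueError("sv_breakpoint_jitter_sd must be >= 0")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.n_sv_callers < 1:
            raise ValueError("n_sv_callers must be >= 1")

    @property
    def mutant_lines(self) -> Tuple[LineSpec, ...]:
        return tuple(l for l in self.lines if not l.is_control)

    @property
    def control_lines(self) -> Tuple[LineSpec, ...]:
        return tuple(l for l in self.lines if l.is_control)

    @property
    def sample_ids(self) -> List[str]:
        out: List[str] = []
        for line in self.control_lines + self.mutant_lines:
            out.extend(line.replicate_ids)
        return out

    def manifest(self) -> Manifest:
        entries = []
        for line in self.control_lines + self.mutant_lines:
            role = "control" if line.is_control else "mutant_rep"
            for sid in line.replicate_ids:
                entries.append(
                    ManifestEntry(sid, line.line_id, line.treatment, line.dose_gy, role)
                )
        return Manifest(entries)

    def _stage_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stage)))


@dataclass
class Reference:
    sequences: Dict[str, str]
    genes: List[TranscriptModel]

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def gene_intervals(self) -> List[GeneInterval]:
        return [
            GeneInterval(m.gene_id, m.chrom, m.footprint[0], m.footprint[1], m.is_transposon)
            for m in self.genes
        ]


@dataclass
class TruthTable:
    """Ground truth: founder catalog, per-line induced variants, SVs."""

    founder: List[Tuple[VariantKey, str]]
    induced_small: Dict[str, List[Tuple[VariantKey, str]]]
    induced_svs: Dict[str, List[SVRecord]]
    natural_svs: List[SVRecord]

    def founder_keys(self) -> Set[VariantKey]:
        return {k for k, _ in self.founder}

    def induced_keys(self, line_id: str) -> Set[VariantKey]:
        return {k for k, _ in self.induced_small.get(line_id, [])}

    def write_tsv(self, outdir: str | Path) -> None:
        import pandas as pd

        outdir = Path(outdir)
        rows = [
            {"line_id": "", "origin": "founder", "chrom": k.chrom, "pos": k.pos,
             "ref": k.ref, "alt": k.alt, "zygosity": z,
             "var_class": "snv" if k.is_snv else "indel"}
            for k, z in self.founder
        ]
        for line_id in sorted(self.induced_small):
            rows.extend(
                {"line_id": line_id, "origin": "induced", "chrom": k.chrom, "pos": k.pos,
                 "ref": k.ref, "alt": k.alt, "zygosity": z,
                 "var_class": "snv" if k.is_snv else "indel"}
                for k, z in self.induced_small[line_id]
            )
        pd.DataFrame(
            rows, columns=["line_id", "origin", "chrom", "pos", "ref", "alt",
                           "zygosity", "var_class"]
        ).to_csv(outdir / "truth_small.tsv", sep="\t", index=False)
        svs = [r for line in sorted(self.induced_svs) for r in self.induced_svs[line]]
        write_sv_table(svs + list(self.natural_svs), outdir / "truth_sv.tsv")


# ---------------------------------------------------------------------------
# reference genome


def generate_reference(config: SimulationConfig) -> Reference:
    """Random reference chromosomes carrying well-formed gene models.

    Each gene is one or two CDS exons whose spliced sequence starts with
    ATG, ends with a stop codon, contains no internal stop, and has
    length divisible by 3; roughly a fifth of genes are annotated as
    transposon-related for overlap classification. Raises when the
    chromosomes are too short to hold ``n_genes`` without overlap.
    """
    rng = config._stage_rng(0)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs = {
        c: rng.choice(_BASES, size=config.chrom_length) for c in chroms
    }
    genes: List[TranscriptModel] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    max_span = 3 * 252 + 500  # longest CDS + longest intron
    edge = 2_000
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        slot = (config.chrom_length - 2 * edge) // n_here
        if slot < max_span + 200:
            raise ValueError(
                f"chrom_length {config.chrom_length} too small to place "
                f"{config.n_genes} genes (need >= {max_span + 200} bp per gene slot)"
            )
        for g in range(n_here):
            slot_start = edge + g * slot
            genes.append(
                _place_gene(rng, seqs[chrom], chrom, slot_start, slot, len(genes))
            )
    return Reference(sequences={c: "".join(s) for c, s in seqs.items()}, genes=genes)


def _random_cds(rng: np.random.Generator) -> str:
    n_codons = int(rng.integers(80, 251))
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in _STOPS:
            codons.append(codon)
    stop = _STOPS[int(rng.integers(0, 3))]
    return "ATG" + "".join(codons) + stop


def _place_gene(
    rng: np.random.Generator,
    seq: np.ndarray,
    chrom: str,
    slot_start: int,
    slot: int,
    index: int,
) -> TranscriptModel:
    cds = _random_cds(rng)
    two_exons = bool(rng.random() < 0.7)
    intron = int(rng.integers(100, 501)) if two_exons else 0
    span = len(cds) + intron
    offset = int(rng.integers(0, max(1, slot - span - 100)))
    start = slot_start + offset + 1  # 1-based
    strand = "+" if rng.random() < 0.5 else "-"
    genomic = cds if strand == "+" else _revcomp(cds)
    if two_exons:
        cut = int(rng.integers(30, len(cds) - 30))
        ivs = (
            (start, start + cut - 1),
            (start + cut + intron, start + len(cds) + intron - 1),
        )
        pieces = (genomic[:cut], genomic[cut:])
    else:
        ivs = ((start, start + len(cds) - 1),)
        pieces = (genomic,)
    for (s, e), piece in zip(ivs, pieces):
        seq[s - 1 : e] = list(piece)
    return TranscriptModel(
        gene_id=f"gene{index + 1:04d}",
        chrom=chrom,
        strand=strand,
        cds_intervals=ivs,
        is_transposon=bool(rng.random() < 0.2),
    )


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# truth variants


def generate_truth(config: SimulationConfig, reference: Reference) -> TruthTable:
    """Draw founder variation and per-line induced mutations.

    Founder variants (fixed homozygous in every sample, controls
    included) are placed at density ``natural_variant_density``; induced
    variants are unique per line unless cross-line collisions are
    explicitly injected, and are homozygous-alternative with a small
    heterozygous residual.
    """
    rng = config._stage_rng(1)
    chroms = sorted(reference.sequences)
    used: Set[Tuple[str, int]] = set()

    def reserve(chrom: str, pos: int, span: int = 1) -> bool:
        span_positions = [(chrom, p) for p in range(pos, pos + span)]
        if any(sp in used for sp in span_positions):
            return False
        used.update(span_positions)
        return True

    def draw_small(is_indel: bool) -> Optional[VariantKey]:
        for _ in range(50):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            seq = reference.sequences[chrom]
            pos = int(rng.integers(2, len(seq) - config.indel_max_len - 2))
            if not is_indel:
                if not reserve(chrom, pos):
                    continue
                ref = seq[pos - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                return VariantKey(chrom, pos, ref, alt)
            length = int(rng.integers(1, config.indel_max_len + 1))
            if rng.random() < 0.5:  # deletion
                if not reserve(chrom, pos, length + 1):
                    continue
                ref = seq[pos - 1 : pos + length]
                return VariantKey(chrom, pos, ref, ref[0])
            if not reserve(chrom, pos):
                continue
            anchor = seq[pos - 1]
            ins = "".join(rng.choice(_BASES, size=length))
            return VariantKey(chrom, pos, anchor, anchor + ins)
        return None

    total_len = sum(reference.chrom_lengths.values())
    n_founder = int(rng.binomial(total_len, min(1.0, config.natural_variant_density)))
    founder: List[Tuple[VariantKey, str]] = []
    for _ in range(n_founder):
        is_indel = bool(rng.random() < config.founder_indel_fraction)
        key = draw_small(is_indel)
        if key is not None:
            founder.append((key, "hom_alt"))
    founder.sort(key=lambda kz: kz[0])

    induced_small: Dict[str, List[Tuple[VariantKey, str]]] = {}
    induced_svs: Dict[str, List[SVRecord]] = {}
    sv_breakpoints: Dict[str, List[int]] = {}
    for line in config.mutant_lines:
        smalls: List[Tuple[VariantKey, str]] = []
        for i in range(line.induced_snv_count + line.induced_indel_count):
            key = draw_small(is_indel=i >= line.induced_snv_count)
            if key is None:
                continue
            zyg = "het" if rng.random() < config.induced_het_fraction else "hom_alt"
            smalls.append((key, zyg))
        smalls.sort(key=lambda kz: kz[0])
        induced_small[line.line_id] = smalls
        induced_svs[line.line_id] = [
            _draw_sv(rng, config, reference, line.line_id, sv_breakpoints)
            for _ in range(line.induced_sv_count)
        ]

    # injected cross-line collisions: the same induced key in two lines
    mutant_ids = [l.line_id for l in config.mutant_lines]
    for j in range(config.n_cross_line_collisions):
        if len(mutant_ids) < 2:
            break
        a = mutant_ids[j % len(mutant_ids)]
        b = mutant_ids[(j + 1) % len(mutant_ids)]
        if induced_small[a]:
            idx = int(rng.integers(0, len(induced_small[a])))
            key, _ = induced_small[a][idx]
            induced_small[b].append((key, "hom_alt"))
            induced_small[b].sort(key=lambda kz: kz[0])

    natural_svs = [
        _draw_sv(rng, config, reference, "", sv_breakpoints)
        for _ in range(config.n_natural_svs)
    ]
    return TruthTable(founder, induced_small, induced_svs, natural_svs)


def _draw_sv(
    rng: np.random.Generator,
    config: SimulationConfig,
    reference: Reference,
    line_id: str,
    taken: Dict[str, List[int]],
) -> SVRecord:
    """Draw one truth SV whose breakpoints keep ``sv_min_separation``
    distance from every previously drawn truth breakpoint, so records
    remain distinguishable under the downstream matching tolerance."""
    chroms = sorted(reference.sequences)
    types = list(_SV_WEIGHTS)
    weights = np.array([_SV_WEIGHTS[t] for t in types])
    if len(chroms) < 2:  # CTX impossible on a single chromosome
        weights[types.index(SVType.CTX)] = 0.0
    weights /= weights.sum()
    sep = config.sv_min_separation

    def free(chrom: str, *positions: int) -> bool:
        return all(
            abs(p - q) >= sep for p in positions for q in taken.get(chrom, [])
        )

    def register(chrom: str, *positions: int) -> None:
        taken.setdefault(chrom, []).extend(positions)

    for _ in range(500):
        sv_type = types[int(rng.choice(len(types), p=weights))]
        max_size = min(config.sv_max_size, config.chrom_length // 5)
        size = int(round(math.exp(rng.uniform(math.log(config.sv_min_size), math.log(max_size)))))
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = reference.chrom_lengths[chrom]
        if sv_type is SVType.CTX:
            others = [c for c in chroms if c != chrom]
            chrom2 = others[int(rng.integers(0, len(others)))]
            start = int(rng.integers(1_000, length - 1_000))
            pos2 = int(rng.integers(1_000, reference.chrom_lengths[chrom2] - 1_000))
            if not (free(chrom, start) and free(chrom2, pos2)):
                continue
            register(chrom, start)
            register(chrom2, pos2)
            return SVRecord(sv_type=sv_type, chrom=chrom, start=start, end=start,
                            support=0, caller_id="truth", line_id=line_id,
                            chrom2=chrom2, pos2=pos2)
        if sv_type is SVType.INS:
            start = int(rng.integers(1_000, length - 1_000))
            if not free(chrom, start):
                continue
            register(chrom, start)
            return SVRecord(sv_type=sv_type, chrom=chrom, start=start, end=start,
                            size=size, support=0, caller_id="truth", line_id=line_id)
        start = int(rng.integers(1_000, length - size - 1_000))
        end = start + size - 1
        if not free(chrom, start, end):
            continue
        register(chrom, start, end)
        return SVRecord(sv_type=sv_type, chrom=chrom, start=start, end=end,
                        support=0, caller_id="truth", line_id=line_id)
    raise ValueError(
        "could not place a truth SV with the required breakpoint separation; "
        "increase chrom_length or lower sv_min_separation / SV counts"
    )


# ---------------------------------------------------------------------------
# sample-level small-variant calls


def sample_population_calls(
    config: SimulationConfig, truth: TruthTable
) -> Tuple[CallSet, List[str], List[Tuple[VariantKey, str]]]:
    """Emit per-sample genotype calls with depth noise at every truth site.

    Depth is Poisson(depth_mean) per sample and site; alt reads are
    binomial around the genotype's expected alt fraction; the emitted
    genotype is then re-called from the read ratio (mimicking a
    short-read caller) and flipped with probability
    ``genotyping_error_rate``. In noiseless mode depth is fixed, allele
    fractions are honored exactly and the emitted genotype is the truth.

    Returns (calls, ordered sample ids, dropout log of (key, sample)
    pairs that received zero reads).
    """
    rng = config._stage_rng(2)
    samples = config.sample_ids
    sample_line = {
        sid: line.line_id for line in config.lines for sid in line.replicate_ids
    }

    sites: Dict[VariantKey, Dict[str, str]] = {}
    for key, _zyg in truth.founder:
        sites.setdefault(key, {})  # founder: hom_alt for everyone (default below)
    for line_id, smalls in truth.induced_small.items():
        reps = next(l.replicate_ids for l in config.lines if l.line_id == line_id)
        for key, zyg in smalls:
            per = sites.setdefault(key, {})
            for rep in reps:
                per[rep] = zyg
    founder_keys = truth.founder_keys()

    calls: CallSet = {}
    dropout: List[Tuple[VariantKey, str]] = []
    depth_fixed = int(round(config.depth_mean))
    for key in sorted(sites):
        carriers = sites[key]
        per_sample: Dict[str, SampleCall] = {}
        for sid in samples:
            if key in founder_keys:
                true_gt = carriers.get(sid, "hom_alt")
            else:
                true_gt = carriers.get(sid, "hom_ref")
            if config.noiseless:
                dp = depth_fixed
                alt = {"hom_ref": 0, "het": int(round(dp * config.het_alt_fraction_mean)),
                       "hom_alt": dp}[true_gt]
                gt = Genotype(true_gt)
            else:
                dp = int(rng.poisson(config.depth_mean))
                if dp == 0:
                    dropout.append((key, sid))
                    per_sample[sid] = SampleCall(sid, Genotype.MISSING, 0, 0)
                    continue
                p = {"hom_ref": config.seq_error_rate,
                     "het": config.het_alt_fraction_mean,
                     "hom_alt": 1.0 - config.seq_error_rate}[true_gt]
                alt = int(rng.binomial(dp, p))
                gt = _call_genotype(alt, dp)
                if rng.random() < config.genotyping_error_rate:
                    gt = _flip_genotype(gt, rng)
            per_sample[sid] = SampleCall(sid, gt, dp, alt)
        calls[key] = per_sample
    return calls, samples, dropout


def _call_genotype(alt: int, dp: int) -> Genotype:
    """Naive ratio-based caller: the raw call later recalibrated."""
    af = alt / dp
    if af < 0.10:
        return Genotype.HOM_REF
    if af > 0.90:
        return Genotype.HOM_ALT
    return Genotype.HET


def _flip_genotype(gt: Genotype, rng: np.random.Generator) -> Genotype:
    options = [g for g in (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT) if g is not gt]
    return options[int(rng.integers(0, len(options)))]


# ---------------------------------------------------------------------------
# SV call sets


def simulate_sv_callsets(
    truth: TruthTable, config: SimulationConfig
) -> Dict[str, List[SVRecord]]:
    """Per-caller SV call tables with jitter, support noise and false
    positives.

    Every truth SV is reported by each caller with probability
    ``sv_detection_prob`` per replicate (at least one caller is
    guaranteed), with breakpoints perturbed by Normal(0, jitter_sd) and
    support drawn around ``sv_support_mean``. Natural SVs appear in all
    lines and the controls; false positives are injected per caller and
    replicate at rate ``sv_false_positive_rate``. Noiseless mode
    disables all three noise sources.
    """
    rng = config._stage_rng(3)
    callers = [
        _CALLER_NAMES[i] if i < len(_CALLER_NAMES) else f"caller{i + 1}_sim"
        for i in range(config.n_sv_callers)
    ]
    out: Dict[str, List[SVRecord]] = {c: [] for c in callers}
    detection = 1.0 if config.noiseless else config.sv_detection_prob
    fp_rate = 0.0 if config.noiseless else config.sv_false_positive_rate
    jitter_sd = 0.0 if config.noiseless else config.sv_breakpoint_jitter_sd

    for line in config.lines:
        line_truth = list(truth.induced_svs.get(line.line_id, [])) + list(truth.natural_svs)
        for rep in line.replicate_ids:
            for sv in line_truth:
                reporting = [c for c in callers if rng.random() < detection]
                if not reporting:
                    reporting = [callers[int(rng.integers(0, len(callers)))]]
                for caller in reporting:
                    out[caller].append(
                        _jittered(sv, rng, jitter_sd, config, caller, line.line_id, rep)
                    )
            for caller in callers:
                for _ in range(int(rng.poisson(fp_rate))):
                    out[caller].append(_false_positive(rng, config, caller, line.line_id, rep))
    return out


def _jittered(
    sv: SVRecord,
    rng: np.random.Generator,
    jitter_sd: float,
    config: SimulationConfig,
    caller: str,
    line_id: str,
    sample_id: str,
) -> SVRecord:
    def j(x: int) -> int:
        return max(1, int(round(x + rng.normal(0.0, jitter_sd)))) if jitter_sd > 0 else x

    if config.noiseless:
        support = int(round(config.sv_support_mean))
    else:
        support = max(1, int(rng.poisson(config.sv_support_mean)))
    if sv.sv_type is SVType.CTX:
        start = j(sv.start)
        return SVRecord(sv_type=sv.sv_type, chrom=sv.chrom, start=start, end=start,
                        support=support, caller_id=caller, line_id=line_id,
                        sample_id=sample_id, chrom2=sv.chrom2, pos2=j(sv.pos2))
    if sv.sv_type is SVType.INS:
        start = j(sv.start)
        return SVRecord(sv_type=sv.sv_type, chrom=sv.chrom, start=start, end=start,
                        size=sv.size, support=support, caller_id=caller,
                        line_id=line_id, sample_id=sample_id)
    a, b = sorted((j(sv.start), j(sv.end)))
    return SVRecord(sv_type=sv.sv_type, chrom=sv.chrom, start=a, end=b,
                    support=support, caller_id=caller, line_id=line_id,
                    sample_id=sample_id)


def _false_positive(
    rng: np.random.Generator,
    config: SimulationConfig,
    caller: str,
    line_id: str,
    sample_id: str,
) -> SVRecord:
    chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
    size = int(rng.integers(config.sv_min_size, min(config.sv_max_size, config.chrom_length // 5)))
    start = int(rng.integers(1_000, config.chrom_length - size - 1_000))
    support = max(1, int(rng.poisson(25)))
    return SVRecord(sv_type=SVType.DEL, chrom=chrom, start=start, end=start + size - 1,
                    support=support, caller_id=caller, line_id=line_id, sample_id=sample_id)


def simulate_depth_bins(
    config: SimulationConfig,
    truth: TruthTable,
    line_id: str,
    chrom: str,
    bin_size: int,
    chrom_length: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Binned read depth for one mutant line and the control.

    Homozygous truth deletions suppress mutant coverage over their span
    (proportionally for partial bins); duplications double it. Poisson
    counting noise is applied per bin unless the config is noiseless.
    """
    import zlib

    tag = zlib.crc32(f"{line_id}:{chrom}:{bin_size}".encode())
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 4, tag)))
    length = chrom_length or config.chrom_length
    n_bins = length // bin_size
    factor = np.ones(n_bins)
    for sv in truth.induced_svs.get(line_id, []):
        if sv.chrom != chrom or sv.sv_type not in (SVType.DEL, SVType.DUP):
            continue
        mult = 0.0 if sv.sv_type is SVType.DEL else 2.0
        first = (sv.start - 1) // bin_size
        last = min(n_bins - 1, (sv.end - 1) // bin_size)
        for b in range(first, last + 1):
            bs, be = b * bin_size + 1, (b + 1) * bin_size
            ov = max(0, min(sv.end, be) - max(sv.start, bs) + 1)
            frac = ov / bin_size
            factor[b] = factor[b] * (1 - frac) + mult * frac
    expect = config.depth_mean * bin_size
    if config.noiseless:
        mutant = factor * expect / bin_size
        control = np.full(n_bins, config.depth_mean)
    else:
        mutant = rng.poisson(np.maximum(factor, 0.0) * expect) / bin_size
        control = rng.poisson(np.full(n_bins, expect)) / bin_size
    return mutant, control


# ---------------------------------------------------------------------------
# writers and orchestration


def write_fasta(reference: Reference, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sorted(reference.sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(reference: Reference, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in sorted(reference.sequences.items()):
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for m in sorted(reference.genes, key=lambda g: (g.chrom, g.footprint)):
            fs, fe = m.footprint
            note = ";Note=retrotransposon" if m.is_transposon else ""
            fh.write(
                f"{m.chrom}\tradmut\tgene\t{fs}\t{fe}\t.\t{m.strand}\t.\tID={m.gene_id}{note}\n"
            )
            fh.write(
                f"{m.chrom}\tradmut\tmRNA\t{fs}\t{fe}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}.1;Parent={m.gene_id}\n"
            )
            off = 0
            for s, e in m.cds_intervals:
                if m.strand == "+":
                    phase = (3 - off % 3) % 3 if off % 3 else 0
                else:
                    phase = 0  # phase tracking is cosmetic for this generator
                fh.write(
                    f"{m.chrom}\tradmut\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID=cds.{m.gene_id};Parent={m.gene_id}.1\n"
                )
                off += e - s + 1


def write_vcf(
    calls: CallSet,
    samples: Sequence[str],
    contigs: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write a multi-sample VCF 4.2 with GT:AD:DP per sample."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">')
    for chrom, length in sorted(contigs.items()):
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for s in samples:
        header.add_sample(s)
    gt_map = {
        Genotype.HOM_REF: (0, 0),
        Genotype.HET: (0, 1),
        Genotype.HOM_ALT: (1, 1),
        Genotype.MISSING: (None, None),
    }
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(calls):
            rec = out.new_record(contig=key.chrom, start=key.pos - 1,
                                 alleles=(key.ref, key.alt))
            for sid in samples:
                call = calls[key].get(sid)
                fmt = rec.samples[sid]
                if call is None:
                    fmt["GT"] = (None, None)
                    continue
                fmt["GT"] = gt_map[call.genotype]
                fmt["AD"] = (call.depth - call.alt_depth, call.alt_depth)
                fmt["DP"] = call.depth
            out.write(rec)


@dataclass
class SimulationResult:
    config: SimulationConfig
    reference: Reference
    truth: TruthTable
    calls: CallSet
    samples: List[str]
    dropout: List[Tuple[VariantKey, str]]
    sv_callsets: Dict[str, List[SVRecord]]
    manifest: Manifest


def simulate_all(config: SimulationConfig, outdir: Optional[str | Path] = None) -> SimulationResult:
    """Run every generator stage; optionally write the full artifact set.

    With ``outdir`` set, writes reference.fa, genes.gff3, calls.vcf,
    manifest.tsv, truth tables and one SV call table per caller — all
    byte-deterministic under a fixed seed.
    """
    reference = generate_reference(config)
    truth = generate_truth(config, reference)
    calls, samples, dropout = sample_population_calls(config, truth)
    sv_callsets = simulate_sv_callsets(truth, config)
    manifest = config.manifest()
    result = SimulationResult(config, reference, truth, calls, samples, dropout,
                              sv_callsets, manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(reference, outdir / "reference.fa")
        write_gff3(reference, outdir / "genes.gff3")
        write_vcf(calls, samples, reference.chrom_lengths, outdir / "calls.vcf")
        manifest.to_tsv(outdir / "manifest.tsv")
        truth.write_tsv(outdir)
        sv_dir = outdir / "sv_calls"
        sv_dir.mkdir(exist_ok=True)
        for caller, records in sorted(sv_callsets.items()):
            write_sv_table(records, sv_dir / f"{caller}.tsv")
        if dropout:
            import pandas as pd

            pd.DataFrame(
                [{"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt,
                  "sample_id": s} for k, s in dropout]
            ).to_csv(outdir / "dropout.tsv", sep="\t", index=False)
    return result
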