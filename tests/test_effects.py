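"""Codon-level classification against a protein-diff brute-force oracle."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from radmut.core import VariantKey
from radmut.effects import (
    GeneSet,
    TranscriptModel,
    classify_indel,
    classify_snv,
    classify_variant,
    effect_percentages,
)

# A minimal 3-codon gene on a hand-written chromosome:
#            pos: 123456789012345678
CHROM = "TTTT" + "ATGGAATAA" + "TTTTT"  # gene at 5..13, CDS = ATG GAA TAA
GENE = TranscriptModel("g1", "c", "+", ((5, 13),))
REF = {"c": CHROM}


class TestClassifySNV:
    def test_stop_gain_is_nonsense_high(self):
        # GAA -> TAA at codon 2 position 1
        call = classify_snv(VariantKey("c", 8, "G", "T"), GENE, REF)
        assert (call.effect, call.impact) == ("nonsense", "HIGH")

    def test_third_base_wobble_is_silent_low(self):
        # GAA -> GAG
        call = classify_snv(VariantKey("c", 10, "A", "G"), GENE, REF)
        assert (call.effect, call.impact) == ("silent", "LOW")

    def test_missense_matches_codon_table(self):
        # GAA (Glu) -> GCA (Ala)
        call = classify_snv(VariantKey("c", 9, "A", "C"), GENE, REF)
        assert (call.effect, call.impact) == ("missense", "MODERATE")
        assert str(Seq("GAA").translate()) == "E" and str(Seq("GCA").translate()) == "A"

    def test_start_codon_loss_is_high(self):
        call = classify_snv(VariantKey("c", 5, "A", "G"), GENE, REF)
        assert (call.effect, call.impact) == ("start_lost", "HIGH")

    def test_stop_codon_loss_is_high(self):
        call = classify_snv(VariantKey("c", 11, "T", "C"), GENE, REF)
        assert (call.effect, call.impact) == ("stop_lost", "HIGH")

    def test_far_from_any_gene_is_intergenic_modifier(self):
        genes = GeneSet([GENE])
        chrom = CHROM + "A" * 20_000
        [call] = classify_variant(VariantKey("c", 15_000, "A", "T"), genes, {"c": chrom})
        assert (call.effect, call.impact) == ("intergenic", "MODIFIER")

    def test_reference_mismatch_is_a_hard_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            classify_snv(VariantKey("c", 8, "C", "T"), GENE, REF)


class TestClassifyIndel:
    def test_frameshift_two_bp_deletion(self):
        call = classify_indel(VariantKey("c", 6, "TGG", "T"), GENE, REF)
        assert (call.effect, call.impact) == ("frameshift", "HIGH")

    def test_inframe_codon_deletion_moderate(self):
        # delete GAA (codon 2) exactly: ref pos7 GGAA -> G
        call = classify_indel(VariantKey("c", 7, "GGAA", "G"), GENE, REF)
        assert (call.effect, call.impact) == ("inframe_indel", "MODERATE")

    def test_fourteen_bp_deletion_is_frameshift_high(self):
        """The longest deletion of the published validation panel (a 14 bp
        net loss, allele AGCGCATGTGCCATG -> A) placed inside a synthetic
        CDS: 14 % 3 != 0 -> frameshift."""
        allele_ref, allele_alt = "AGCGCATGTGCCATG", "A"
        assert len(allele_ref) - len(allele_alt) == 14
        # CDS = ATG C <allele> CC TAA (24 bp, no internal stop), gene at 4..27
        chrom = "GGG" + "ATG" + "C" + allele_ref + "CC" + "TAA" + "GG"
        gene = TranscriptModel("g3", "c", "+", ((4, 27),))
        call = classify_indel(VariantKey("c", 8, allele_ref, allele_alt), gene, {"c": chrom})
        assert (call.effect, call.impact) == ("frameshift", "HIGH")

    def test_intronic_indel_is_modifier(self):
        gene = TranscriptModel("g4", "c", "+", ((5, 10), (200, 293)))
        chrom = CHROM[:10] + "T" * 300
        call = classify_indel(VariantKey("c", 50, "TT", "T"), gene, {"c": chrom})
        assert (call.effect, call.impact) == ("intronic", "MODIFIER")


# ---------------------------------------------------------------------------
# protein-diff oracle


def oracle_effect(model: TranscriptModel, reference, key: VariantKey):
    """Independent classification by editing the chromosome, re-splicing
    and diffing the translated proteins."""
    seq = reference[key.chrom]
    net = len(key.alt) - len(key.ref)
    mutant = seq[: key.pos - 1] + key.alt + seq[key.pos - 1 + len(key.ref) :]
    # shift CDS intervals right of the edit
    edit_point = key.pos
    new_ivs = []
    for s, e in model.cds_intervals:
        s2 = s + net if s > edit_point else s
        e2 = e + net if e >= edit_point + len(key.ref) - 1 and e > edit_point else e
        new_ivs.append((s2, e2))
    parts = [mutant[s - 1 : e] for s, e in new_ivs]
    cds_alt = "".join(parts).upper()
    if model.strand == "-":
        cds_alt = str(Seq(cds_alt).reverse_complement())
    cds_ref = model.spliced_cds(seq)

    def prot(cds):
        aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
        return aa.split("*")[0] if "*" in aa else None

    p_ref, p_alt = prot(cds_ref), prot(cds_alt)
    if key.is_snv:
        aa_ref = str(Seq(cds_ref).translate())
        aa_alt = str(Seq(cds_alt).translate())
        if aa_ref == aa_alt:
            return "silent", "LOW"
        diffs = [i for i, (a, b) in enumerate(zip(aa_ref, aa_alt)) if a != b]
        i = diffs[0]
        if aa_ref[i] == "*":
            return "stop_lost", "HIGH"
        if aa_alt[i] == "*":
            return "nonsense", "HIGH"
        if i == 0:
            return "start_lost", "HIGH"
        return "missense", "MODERATE"
    if net % 3 != 0:
        return "frameshift", "HIGH"
    if p_alt is None:
        return "stop_lost", "HIGH"
    if p_ref is not None and len(p_alt) < len(p_ref) + net // 3:
        return "inframe_indel", "HIGH"  # premature stop
    return "inframe_indel", "MODERATE"


def _random_coding_variants(reference, rng, n):
    """Random SNVs and contained indels inside CDS intervals."""
    out = []
    genes = reference.genes
    while len(out) < n:
        model = genes[int(rng.integers(0, len(genes)))]
        seq = reference.sequences[model.chrom]
        s, e = model.cds_intervals[int(rng.integers(0, len(model.cds_intervals)))]
        kind = rng.random()
        if kind < 0.6:  # SNV
            pos = int(rng.integers(s, e + 1))
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            out.append((model, VariantKey(model.chrom, pos, ref, alt)))
        elif kind < 0.8:  # deletion fully inside the interval
            max_len = min(9, e - s - 1)
            if max_len < 1:
                continue
            length = int(rng.integers(1, max_len + 1))
            pos = int(rng.integers(s, e - length))
            ref = seq[pos - 1 : pos + length]
            out.append((model, VariantKey(model.chrom, pos, ref, ref[0])))
        else:  # insertion between two CDS bases
            pos = int(rng.integers(s, e))  # anchor at pos, insert before pos+1
            length = int(rng.integers(1, 10))
            ins = "".join(rng.choice(list("ACGT"), size=length))
            anchor = seq[pos - 1]
            out.append((model, VariantKey(model.chrom, pos, anchor, anchor + ins)))
    return out


class TestOracleAgreement:
    def test_classifier_agrees_with_protein_diff_oracle(self, reference_300k):
        rng = np.random.default_rng(123)
        variants = _random_coding_variants(reference_300k, rng, 400)
        for model, key in variants:
            expected = oracle_effect(model, reference_300k.sequences, key)
            fn = classify_snv if key.is_snv else classify_indel
            got = fn(key, model, reference_300k.sequences)
            assert (got.effect, got.impact) == expected, (key, model.gene_id, model.strand)

    def test_strand_consistency(self, reference_300k):
        """An SNV's effect on a minus-strand gene equals the effect after
        mirroring the whole chromosome onto the plus strand."""
        rng = np.random.default_rng(5)
        minus_genes = [m for m in reference_300k.genes if m.strand == "-"]
        for model in minus_genes[:5]:
            seq = reference_300k.sequences[model.chrom]
            L = len(seq)
            mirrored_seq = str(Seq(seq).reverse_complement())
            ivs = tuple(sorted((L - e + 1, L - s + 1) for s, e in model.cds_intervals))
            mirrored = TranscriptModel(model.gene_id, model.chrom, "+", ivs)
            for _ in range(20):
                s, e = model.cds_intervals[int(rng.integers(0, len(model.cds_intervals)))]
                pos = int(rng.integers(s, e + 1))
                ref = seq[pos - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                direct = classify_snv(VariantKey(model.chrom, pos, ref, alt),
                                      model, {model.chrom: seq})
                mpos = L - pos + 1
                comp = str(Seq(ref).reverse_complement()), str(Seq(alt).reverse_complement())
                mirror = classify_snv(VariantKey(model.chrom, mpos, comp[0], comp[1]),
                                      mirrored, {model.chrom: mirrored_seq})
                assert (direct.effect, direct.impact) == (mirror.effect, mirror.impact)


class TestEffectPercentages:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((131, 1, 83), (60.93, 0.465, 38.605)),
            ((100, 4, 97), (49.751, 1.99, 48.259)),
            ((1, 0, 0), (100.0, 0.0, 0.0)),
        ],
    )
    def test_functional_family(self, counts, expected):
        m, n, s = counts
        pct = effect_percentages({"missense": m, "nonsense": n, "silent": s})
        got = (pct["missense_pct"], pct["nonsense_pct"], pct["silent_pct"])
        for g, e in zip(got, expected):
            assert round(g, 3) == pytest.approx(e, abs=5e-4) or round(g, 2) == e

    def test_families_sum_to_100(self):
        pct = effect_percentages(
            {"missense": 7, "nonsense": 2, "silent": 5,
             "high": 3, "low": 11, "moderate": 9, "modifier": 77}
        )
        assert sum(v for k, v in pct.items()
                   if k in ("missense_pct", "nonsense_pct", "silent_pct")) == pytest.approx(100)
        assert sum(v for k, v in pct.items()
                   if k in ("high_pct", "low_pct", "moderate_pct", "modifier_pct")) == pytest.approx(100)

    def test_zero_denominator_yields_empty_not_error(self):
        assert effect_percentages({"missense": 0, "nonsense": 0, "silent": 0}) == {}

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            effect_percentages({"missense": -1})
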