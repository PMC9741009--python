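"""SV support filtering, tolerance merging, consensus and depth scanning."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from radmut.core import SVRecord, SVType
from radmut.sv import (
    GeneInterval,
    SVConfig,
    bin_depth_scan,
    consensus_and_uniqueness,
    merge_records,
    merge_translocations,
    support_filter,
    sv_gene_overlap,
)

CFG = SVConfig()


def rec(sv_type=SVType.DEL, chrom="chr1", start=10_000, end=12_000, support=200,
        caller="manta_sim", line="M1", sample="M1_r1", chrom2=None, pos2=None):
    return SVRecord(sv_type=sv_type, chrom=chrom, start=start, end=end,
                    support=support, caller_id=caller, line_id=line,
                    sample_id=sample, chrom2=chrom2, pos2=pos2)


def ctx(start, pos2, support=200, **kw):
    return rec(sv_type=SVType.CTX, start=start, end=start, chrom2="chr2",
               pos2=pos2, support=support, **kw)


class TestSupportFilter:
    def test_translocation_threshold_is_strict(self):
        kept = support_filter([ctx(100_000, 50_000, support=101),
                               ctx(200_000, 60_000, support=100)], CFG)
        assert [r.support for r in kept] == [101]

    def test_caller_specific_minimums(self):
        records = [
            rec(support=49, caller="breakdancer_sim"),
            rec(support=50, caller="breakdancer_sim", start=30_000, end=31_000),
            rec(support=9, caller="lumpy_sim", start=50_000, end=51_000),
            rec(support=3, caller="manta_sim", start=70_000, end=71_000),
        ]
        kept = support_filter(records, CFG)
        assert {(r.caller_id, r.support) for r in kept} == {
            ("breakdancer_sim", 50), ("manta_sim", 3)
        }

    def test_lumpy_alternative_threshold(self):
        cfg = SVConfig(lumpy_min_support=10)
        kept = support_filter([rec(support=10, caller="lumpy_sim")], cfg)
        assert len(kept) == 1

    def test_empty_input(self):
        assert support_filter([], CFG) == []


class TestMergeTranslocations:
    def test_within_tolerance_merged(self):
        out = merge_translocations(
            [ctx(100_000, 50_000), ctx(101_500, 51_200)], CFG
        )
        assert len(out) == 1

    def test_beyond_tolerance_not_merged(self):
        out = merge_translocations([ctx(100_000, 50_000), ctx(102_500, 50_000)], CFG)
        assert len(out) == 2

    def test_single_linkage_chain(self):
        """A-B and B-C within tolerance, A-C beyond: one cluster of three,
        agreeing with a brute-force transitive-closure oracle."""
        records = [ctx(100_000, 50_000), ctx(101_500, 50_000), ctx(103_000, 50_000)]
        out = merge_translocations(records, CFG)
        assert len(out) == _oracle_cluster_count(records, 2000)
        assert len(out) == 1

    def test_mixed_types_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            merge_translocations([ctx(1_000, 2_000), rec()], CFG)

    def test_consensus_support_weighted_coordinates(self):
        a = ctx(100_000, 50_000, support=300)
        b = ctx(101_000, 50_000, support=100)
        [out] = merge_translocations([a, b], CFG)
        assert out.start == round((100_000 * 300 + 101_000 * 100) / 400)
        assert out.support == 300


def _oracle_cluster_count(records, tol):
    """Brute force: all-pairs linkage graph, count connected components."""
    n = len(records)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        a, b = records[i], records[j]
        if (a.sv_type is b.sv_type and a.chrom_pair == b.chrom_pair
                and abs(a.start - b.start) <= tol
                and abs(a.second_coord - b.second_coord) <= tol):
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), 0
    for i in range(n):
        if i in seen:
            continue
        comps += 1
        stack = [i]
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            stack.extend(adj[k] - seen)
    return comps


class TestMergeProperties:
    @given(st.data())
    def test_order_independent_and_matches_oracle(self, data):
        starts = data.draw(st.lists(st.integers(10_000, 60_000), min_size=1, max_size=8))
        records = [
            rec(start=s, end=s + 5_000, support=data.draw(st.integers(1, 300)),
                sample=f"s{i}")
            for i, s in enumerate(starts)
        ]
        merged = merge_records(records, CFG)
        assert len(merged) == _oracle_cluster_count(records, CFG.merge_tolerance)
        perm = data.draw(st.permutations(records))
        merged_perm = merge_records(list(perm), CFG)
        key = lambda r: (r.sv_type, r.chrom, r.start, r.end, r.support)
        assert sorted(map(key, merged)) == sorted(map(key, merged_perm))


class TestConsensusAndUniqueness:
    def test_two_of_three_callers_with_jitter(self):
        per_line = {
            "M1": [
                rec(start=20_000, end=25_000, caller="manta_sim", sample="M1_r1"),
                rec(start=20_480, end=25_510, caller="lumpy_sim", sample="M1_r2"),
            ]
        }
        out = consensus_and_uniqueness(per_line, cfg=SVConfig(min_callers=2),
                                       replicate_ids={"M1": ["M1_r1", "M1_r2"]})
        assert len(out.accepted["M1"]) == 1

    def test_min_callers_unmet_removed(self):
        per_line = {"M1": [rec(caller="manta_sim", sample="M1_r1"),
                           rec(caller="manta_sim", sample="M1_r2", start=10_100)]}
        out = consensus_and_uniqueness(per_line, cfg=SVConfig(min_callers=2),
                                       replicate_ids={"M1": ["M1_r1", "M1_r2"]})
        assert out.accepted["M1"] == []
        assert list(out.log.reason) == ["too_few_callers"]

    def test_replicate_discordant_removed(self):
        per_line = {"M1": [rec(sample="M1_r1")]}
        out = consensus_and_uniqueness(per_line, replicate_ids={"M1": ["M1_r1", "M1_r2"]})
        assert out.accepted["M1"] == []
        assert list(out.log.reason) == ["replicate_discordant"]

    def test_shared_across_lines_removed_from_both(self):
        shared = dict(start=40_000, end=41_000)
        per_line = {
            "M166": [rec(**shared, sample="M166_r1"), rec(**shared, sample="M166_r2")],
            "M225": [rec(**shared, line="M225", sample="M225_r1"),
                     rec(**shared, line="M225", sample="M225_r2")],
        }
        reps = {"M166": ["M166_r1", "M166_r2"], "M225": ["M225_r1", "M225_r2"]}
        out = consensus_and_uniqueness(per_line, cfg=CFG, replicate_ids=reps)
        assert out.accepted["M166"] == [] and out.accepted["M225"] == []
        assert set(out.log.reason) == {"shared_across_lines"}

    def test_report_only_mode_keeps_shared_but_flags(self):
        shared = dict(start=40_000, end=41_000)
        per_line = {
            "A": [rec(**shared, line="A", sample="")],
            "B": [rec(**shared, line="B", sample="")],
        }
        out = consensus_and_uniqueness(per_line, cfg=SVConfig(cross_line_filter="report"))
        assert len(out.accepted["A"]) == 1 and len(out.accepted["B"]) == 1
        assert set(out.log.status) == {"flagged"}

    def test_control_sv_removed_everywhere(self):
        control = [rec(line="", sample="CA", start=30_000, end=33_000)]
        per_line = {"M1": [rec(start=30_200, end=33_100, sample="")]}
        out = consensus_and_uniqueness(per_line, control_records=control, cfg=CFG)
        assert out.accepted["M1"] == []
        assert list(out.log.reason) == ["in_control"]


class TestBinDepthScan:
    def test_constructed_homozygous_deletion(self):
        control = np.full(50, 30.0)
        mutant = control.copy()
        mutant[10:20] = 0.0
        [out] = bin_depth_scan(mutant, control, "chr1", 1_000, CFG)
        assert out.sv_type is SVType.DEL
        assert (out.start, out.end) == (10_001, 20_000)
        assert out.end - out.start + 1 == 10_000

    def test_duplication_run(self):
        control = np.full(30, 30.0)
        mutant = control.copy()
        mutant[5:8] = 60.0
        [out] = bin_depth_scan(mutant, control, "chr1", 5_000, CFG)
        assert out.sv_type is SVType.DUP

    def test_flat_coverage_yields_nothing(self):
        control = np.full(40, 30.0)
        assert bin_depth_scan(control, control, "chr1", 1_000, CFG) == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            bin_depth_scan(np.ones(5), np.ones(6), "chr1", 1_000, CFG)

    def test_synthetic_deletion_recovered_within_one_bin(self):
        """A homozygous 5 kb deletion in simulated binned depth is found
        with boundary error of at most one bin."""
        import radmut as rm
        from conftest import tiny_lines

        lines = (rm.LineSpec("M1", "gamma", 150, 1, 1, 0, replicate_ids=("a", "b")),) + tuple(
            l for l in tiny_lines() if l.is_control
        )
        cfg = rm.SimulationConfig(seed=21, n_chroms=1, chrom_length=60_000,
                                  n_genes=0, lines=lines, n_natural_svs=0)
        ref = rm.generate_reference(cfg)
        truth = rm.generate_truth(cfg, ref)
        truth.induced_svs["M1"] = [
            SVRecord(sv_type=SVType.DEL, chrom="chr1", start=20_001, end=25_000,
                     caller_id="truth", line_id="M1")
        ]
        bin_size = 1_000
        mut, ctl = rm.simulate_depth_bins(cfg, truth, "M1", "chr1", bin_size)
        candidates = [r for r in bin_depth_scan(mut, ctl, "chr1", bin_size, CFG)
                      if r.sv_type is SVType.DEL]
        assert len(candidates) == 1
        assert abs(candidates[0].start - 20_001) <= bin_size
        assert abs(candidates[0].end - 25_000) <= bin_size


class TestGeneOverlap:
    GENES = [
        GeneInterval("g1", "chr1", 10_000, 12_000),
        GeneInterval("tn1", "chr1", 50_000, 52_000, is_transposon=True),
    ]

    def test_genic_and_intergenic_labels(self):
        df = sv_gene_overlap(
            [rec(start=11_000, end=11_500), rec(start=30_000, end=31_000)], self.GENES
        )
        assert list(df.overlap_class) == ["genic", "intergenic"]

    def test_transposon_flag(self):
        df = sv_gene_overlap([rec(start=49_000, end=51_000)], self.GENES)
        assert bool(df.transposon_overlap[0])

    def test_intergenic_percentage(self):
        """Share computation over an SV set: 126 intergenic of 340 is 37%."""
        n_total, n_intergenic = 340, 126
        assert round(100 * n_intergenic / n_total) == 37
        records = [rec(start=30_000 + 10_000 * i, end=30_500 + 10_000 * i, chrom="chr9")
                   for i in range(4)] + [rec(start=11_000, end=11_200)]
        df = sv_gene_overlap(records, self.GENES)
        share = 100 * (df.overlap_class == "intergenic").mean()
        assert share == pytest.approx(80.0)
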