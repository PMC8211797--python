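"""Confidence filtering, control subtraction, A-to-I accounting."""

import random

import pytest

from bescan.errors import FormatError
from bescan.rna_offtarget import (
    RnaVariantRecord,
    classify_a_to_i,
    confidence_filter,
    editing_rate,
    read_rna_vcf,
    run_pipeline,
    shared_by_all,
    shared_events,
    subtract_control,
)
from bescan.synthetic_data import simulate_rna_vcfs


def rec(pos=1000, ref="A", alt="G", fs=1.0, qd=10.0, dp=100,
        chrom="1", ad=(70, 30), sample="s1"):
    return RnaVariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                            fisher_strand=fs, qual_by_depth=qd, depth=dp,
                            allele_depths=ad, sample_id=sample)


class TestConfidenceFilter:
    def test_strand_bias_removed(self):
        kept, removed = confidence_filter([rec(fs=35.0)])
        assert kept == []
        assert removed["strand_bias"] == 1

    def test_low_qd_and_depth_removed(self):
        kept, removed = confidence_filter([rec(qd=1.5), rec(dp=29)])
        assert kept == []
        assert removed["low_qd"] == 1
        assert removed["low_depth"] == 1

    def test_boundary_values_kept(self):
        # thresholds are strict: FS=30.0, QD=2.0, DP=30 all survive
        kept, removed = confidence_filter([rec(fs=30.0, qd=2.0, dp=30)])
        assert len(kept) == 1
        assert sum(removed.values()) == 0

    def test_cluster_window_arithmetic(self):
        cluster = [rec(pos=p) for p in (100, 110, 120, 125, 134)]
        lone = rec(pos=200)
        kept, removed = confidence_filter(cluster + [lone])
        assert [r.pos for r in kept] == [200]
        assert removed["cluster"] == 5

    def test_four_snvs_not_a_cluster(self):
        records = [rec(pos=p) for p in (100, 110, 120, 134)]
        kept, removed = confidence_filter(records)
        assert len(kept) == 4

    def test_span_36_not_a_cluster(self):
        records = [rec(pos=p) for p in (100, 110, 120, 125, 135)]
        kept, removed = confidence_filter(records)
        assert len(kept) == 5

    def test_missing_annotation(self):
        bad = RnaVariantRecord(chrom="1", pos=5, ref="A", alt="G",
                               fisher_strand=None, qual_by_depth=3.0,
                               depth=50)
        with pytest.raises(FormatError):
            confidence_filter([bad])
        kept, removed = confidence_filter([bad], permissive=True)
        assert kept == []
        assert removed["missing_annotation"] == 1

    def test_conservation(self):
        records = [rec(pos=100 + 7 * i, fs=float(i * 5),
                       qd=float(i), dp=10 * i) for i in range(1, 12)]
        kept, removed = confidence_filter(records)
        assert len(kept) + sum(removed.values()) == len(records)

    def test_monotonicity_in_thresholds(self):
        records = [rec(pos=100 + 50 * i, fs=float(i * 4),
                       qd=float(i), dp=15 * i) for i in range(1, 15)]
        base_kept, _ = confidence_filter(records)
        for kwargs in ({"fs_max": 20.0}, {"qd_min": 5.0},
                       {"dp_min": 100}, {"cluster_n": 2},
                       {"cluster_window": 500}):
            kept, _ = confidence_filter(records, **kwargs)
            assert len(kept) <= len(base_kept)

    def test_order_invariance(self):
        records = [rec(pos=p, fs=fs) for p, fs in
                   [(100, 1.0), (110, 50.0), (120, 2.0), (300, 1.0),
                    (305, 1.0), (310, 1.0), (315, 1.0), (320, 1.0)]]
        kept1, _ = confidence_filter(records)
        shuffled = records[:]
        random.Random(0).shuffle(shuffled)
        kept2, _ = confidence_filter(shuffled)
        assert {r.key for r in kept1} == {r.key for r in kept2}


class TestSubtractAndClassify:
    def test_subtract_by_full_key(self):
        x = rec(pos=100, ref="A", alt="G")
        y = rec(pos=200, ref="T", alt="C")
        same_pos_other_alt = rec(pos=100, ref="A", alt="C", sample="ctrl")
        assert subtract_control([x], [x]) == []
        assert subtract_control([x, y], [x]) == [y]
        assert subtract_control([x], [same_pos_other_alt]) == [x]

    @pytest.mark.parametrize("ref,alt,expected", [
        ("A", "G", True),   # A-to-I read on the + strand
        ("T", "C", True),   # the same edit read from the - strand cDNA
        ("C", "T", False),
        ("G", "A", False),
    ])
    def test_a_to_i_definition(self, ref, alt, expected):
        (event,) = classify_a_to_i([rec(ref=ref, alt=alt)])
        assert event.a_to_i is expected

    def test_editing_rate_uses_dp_denominator(self):
        assert editing_rate(rec(dp=100, ad=(70, 30))) == pytest.approx(0.30)
        assert editing_rate(rec(dp=100, ad=(100, 0))) == 0.0
        assert editing_rate(rec(dp=100, ad=(16, 84))) == pytest.approx(0.84)
        assert editing_rate(rec(dp=0, ad=(0, 0))) is None


class TestSharedEvents:
    def test_planted_shared_set(self):
        common = [rec(pos=1000 + 40 * i) for i in range(22)]
        lists = {}
        for s in range(3):
            private = [rec(pos=50_000 + 1000 * s + 40 * i)
                       for i in range(5 + s)]
            lists[f"s{s}"] = classify_a_to_i(common + private)
        assert len(shared_by_all(lists)) == 22

    def test_disjoint_samples(self):
        lists = {"a": classify_a_to_i([rec(pos=100)]),
                 "b": classify_a_to_i([rec(pos=200)])}
        assert shared_by_all(lists) == set()

    def test_duplicated_sample(self):
        events = classify_a_to_i([rec(pos=100), rec(pos=200)])
        lists = {"a": events, "b": events}
        assert len(shared_by_all(lists)) == 2

    def test_histogram(self):
        lists = {"a": classify_a_to_i([rec(pos=100), rec(pos=200)]),
                 "b": classify_a_to_i([rec(pos=100)])}
        _, hist = shared_events(lists)
        assert hist == {1: 1, 2: 1}


class TestPipelineRecovery:
    def test_planted_events_recovered_exactly(self):
        treated, control, truth = simulate_rna_vcfs(
            seed=17, n_samples=3, shared_true_events=22,
            decoys_per_rule=1)
        report = run_pipeline(treated, control)
        planted = {("1", ev["pos"], ev["ref"], ev["alt"])
                   for ev in truth.planted if ev["role"] == "shared_event"}
        assert report["shared_by_all"] == planted
        assert len(planted) == 22
        # every decoy is gone from every sample's kept set
        decoy_keys = {("1", d["pos"], d["ref"], d["alt"])
                      for d in truth.planted if d["role"] == "decoy"}
        snp_keys = {("1", d["pos"], d["ref"], d["alt"])
                    for d in truth.planted if d["role"] == "control_snp"}
        for sample, info in report["per_sample"].items():
            kept_keys = {r.key for r in info["kept"]}
            assert not (decoy_keys & kept_keys)
            assert not (snp_keys & kept_keys)
            # threshold decoys are attributed to their rules
            assert info["removal_counts"]["strand_bias"] == 1
            assert info["removal_counts"]["low_qd"] == 1
            assert info["removal_counts"]["low_depth"] == 1
            assert info["removal_counts"]["cluster"] == 5

    def test_vcf_round_trip(self, tmp_path):
        treated, control, truth = simulate_rna_vcfs(
            seed=18, n_samples=2, shared_true_events=5,
            decoys_per_rule=1, control_snps=4, out_dir=tmp_path)
        re_read = read_rna_vcf(tmp_path / "treated1.vcf",
                               sample_id="treated1")
        orig = treated["treated1"]
        assert {r.key for r in re_read} == {r.key for r in orig}
        r0 = {r.key: r for r in re_read}
        o0 = {r.key: r for r in orig}
        for k in o0:
            assert r0[k].depth == o0[k].depth
            assert r0[k].allele_depths == o0[k].allele_depths
            assert r0[k].fisher_strand == pytest.approx(
                o0[k].fisher_strand)
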