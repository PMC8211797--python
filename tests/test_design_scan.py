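"""Guide design, bystander inventory, consequences and batch scanning."""

import numpy as np
import pytest

from bescan import fixtures
from bescan.design_scan import (
    EditorProfile,
    find_guides_for_variant,
    get_profile,
    classify_consequence,
    scan_variant_table,
    variant_is_gc_to_at,
)
from bescan.errors import ReferenceMismatchError
from bescan.seqcore import (
    CdsModel,
    GenomeIndex,
    VariantRecord,
    iupac_match,
    reverse_complement,
)
from bescan.synthetic_data import gen_variant_table


def brute_force_designs(genome, variant, editor):
    """Independent oracle: enumerate every protospacer placement on both
    strands by direct string slicing of the mutant contig."""
    seq = genome[variant.chrom]
    mutant = seq[:variant.pos - 1] + variant.alt + seq[variant.pos:]
    L = editor.protospacer_length
    found = set()
    for strand in "+-":
        s = mutant if strand == "+" else reverse_complement(mutant)
        n = len(s)
        for i in range(n - L + 1):
            proto = s[i:i + L]
            # 1-based coordinate (on +) of each placement position
            for pat in editor.pam_patterns:
                k = len(pat)
                if i + L + k > n:
                    continue
                if not iupac_match(pat, s[i + L:i + L + k]):
                    continue
                for p in range(1, L + 1):
                    genomic = (i + p) if strand == "+" else (n - i - p + 1)
                    if genomic == variant.pos and proto[p - 1] == "A":
                        found.add((strand, p, proto))
                break
    return found


class TestMdx4cvDesign:
    def test_ng_profile_finds_position_4(self, mdx4cv, ng_profile):
        designs = find_guides_for_variant(mdx4cv.genome, mdx4cv.variant,
                                          ng_profile)
        hit = [d for d in designs
               if d.protospacer == fixtures.MDX4CV_PROTOSPACER]
        assert len(hit) == 1
        d = hit[0]
        assert d.target_position == 4
        assert d.pam_observed == "TGT"
        assert d.strand == "-"
        assert d.in_window

    def test_ngg_profile_has_no_in_window_design(self, mdx4cv, ngg_profile):
        designs = find_guides_for_variant(mdx4cv.genome, mdx4cv.variant,
                                          ngg_profile)
        assert not any(d.in_window for d in designs)

    def test_non_at_alt_yields_nothing(self, mdx4cv, ng_profile):
        v = VariantRecord(chrom=mdx4cv.chrom, pos=mdx4cv.variant.pos,
                          ref="C", alt="G")
        assert find_guides_for_variant(mdx4cv.genome, v, ng_profile) == []

    def test_reference_mismatch_is_hard_stop(self, mdx4cv, ng_profile):
        v = VariantRecord(chrom=mdx4cv.chrom, pos=mdx4cv.variant.pos,
                          ref="G", alt="A")
        with pytest.raises(ReferenceMismatchError):
            find_guides_for_variant(mdx4cv.genome, v, ng_profile)

    def test_agrees_with_brute_force(self, mdx4cv, ng_profile):
        designs = find_guides_for_variant(mdx4cv.genome, mdx4cv.variant,
                                          ng_profile)
        got = {(d.strand, d.target_position, d.protospacer)
               for d in designs}
        assert got == brute_force_designs(mdx4cv.genome, mdx4cv.variant,
                                          ng_profile)


class TestBruteForceOracleRandom:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_contigs(self, seed, ng_profile):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
        pos = int(rng.integers(30, 370))
        ref = seq[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        genome = GenomeIndex({"c": seq})
        v = VariantRecord(chrom="c", pos=pos, ref=ref, alt=str(alt))
        designs = find_guides_for_variant(genome, v, ng_profile)
        got = {(d.strand, d.target_position, d.protospacer)
               for d in designs}
        assert got == brute_force_designs(genome, v, ng_profile)


class TestBystanders:
    def test_mdx4cv_inventory(self, mdx4cv, ng_profile):
        designs = find_guides_for_variant(mdx4cv.genome, mdx4cv.variant,
                                          ng_profile)
        d = next(d for d in designs
                 if d.protospacer == fixtures.MDX4CV_PROTOSPACER)
        # only one adenine (the target) within the 4-8 window
        assert d.bystander_adenines_in_window == []
        assert d.window_cytosines == [6, 8]
        # adenines of the printed guide sit at 4 (target) and 18 only
        assert [p for p, b in enumerate(d.protospacer, 1)
                if b == "A"] == [4, 18]

    def test_dysf_like_inventory(self):
        spec = fixtures.dysf_like_amplicon_spec()
        proto = spec.protospacer
        assert [p for p, b in enumerate(proto, 1) if b == "A"] == [6, 8, 11]
        # via design machinery
        from bescan.design_scan import GuideDesign, inventory_bystanders
        d = GuideDesign(protospacer=proto, strand="+", chrom="c",
                        genomic_start=1, pam_observed="TGA",
                        pam_pattern_matched="NGN", target_position=6,
                        in_window=True)
        inventory_bystanders(d, spec.editor)
        assert d.bystander_adenines_in_window == [8]
        assert d.bystander_adenines_reported == [8, 11]


class TestConsequence:
    def test_mdx4cv_target_restores_reference(self, mdx4cv, ng_profile):
        designs = find_guides_for_variant(mdx4cv.genome, mdx4cv.variant,
                                          ng_profile)
        d = next(d for d in designs
                 if d.protospacer == fixtures.MDX4CV_PROTOSPACER)
        labels = classify_consequence(mdx4cv.genome, d, mdx4cv.variant,
                                      mdx4cv.cds)
        assert labels[d.target_position] == "restores_reference"

    def test_synonymous_third_position(self):
        # disease C->A makes codon GCA (Ala); editing back A->G yields
        # GCG, still Ala: synonymous without restoring the reference
        seq = "TTTGCC" + "T" * 16 + "TGT" + "TTTT"
        genome = GenomeIndex({"c": seq})
        v = VariantRecord(chrom="c", pos=6, ref="C", alt="A")
        editor = get_profile("NG")
        designs = find_guides_for_variant(genome, v, editor)
        d = next(d for d in designs if d.strand == "+")
        cds = CdsModel(strand="+", frame_anchor=4)
        labels = classify_consequence(genome, d, v, cds)
        # the edit A->G does not restore the C reference, codon GCA->GCG
        assert labels[d.target_position] == "synonymous"

    def test_window_cytosine_creates_stop(self):
        # TGG (Trp) -> TGA (stop) via C->T on the - strand (G->A on +)
        #   coding codon at 4-6: TGG; protospacer on - strand carries the
        #   complementary C of the third G.
        seq = "TTTTGGATTTTTTTTTTTTTTTTTTTTTTTTTTTTTTT"
        genome = GenomeIndex({"c": seq})
        cds = CdsModel(strand="+", frame_anchor=4)
        # build a - strand design whose window cytosine sits at coding pos 6
        from bescan.design_scan import GuideDesign, inventory_bystanders
        editor = get_profile("NG")
        start = 10  # 5' end of protospacer on - strand (coordinate 10)
        proto = reverse_complement(seq[start - 20:start]) \
            if start >= 20 else reverse_complement(seq[:start])
        # instead place protospacer 5' at coordinate 25 covering pos 6
        start = 25
        proto = reverse_complement(seq[start - 20:start])
        d = GuideDesign(protospacer=proto, strand="-", chrom="c",
                        genomic_start=start, pam_observed="NGN",
                        pam_pattern_matched="NGN",
                        target_position=start - 7 + 1, in_window=False)
        inventory_bystanders(d, editor)
        p_c = start - 6 + 1  # protospacer position over coding pos 6
        assert d.protospacer[p_c - 1] == "C"
        v = VariantRecord(chrom="c", pos=7, ref="A", alt="T")
        d.window_cytosines = [p_c]
        labels = classify_consequence(genome, d, v, cds)
        assert labels[p_c] == "creates_stop"


class TestScanTable:
    def test_planted_targetable_count(self, ng_profile):
        genome, variants, truth = gen_variant_table(
            seed=5, n=100, targetable_fraction=0.4, editor=ng_profile)
        reports, summary = scan_variant_table(genome, variants,
                                              [ng_profile])
        assert summary["editors"]["NG"]["n_targetable"] == 40
        # per-variant agreement with the generator's ground truth
        for report, row in zip(reports, truth.planted):
            assert report.targetable_by["NG"] == \
                (row["category"] == "targetable")
            if report.targetable_by["NG"]:
                assert report.best_design is not None

    def test_empty_table(self, ng_profile):
        genome = GenomeIndex({"c": "ACGT" * 30})
        reports, summary = scan_variant_table(genome, [], [ng_profile])
        assert reports == []
        assert summary["empty_input"]
        assert summary["frac_gc_to_at"] is None
        assert summary["editors"]["NG"]["n_targetable"] == 0

    def test_all_gc_alt_untargetable(self, ng_profile):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=500))
        genome = GenomeIndex({"c": seq})
        variants = []
        for pos in range(50, 400, 50):
            ref = seq[pos - 1]
            alt = "C" if ref != "C" else "G"
            variants.append(VariantRecord(chrom="c", pos=pos, ref=ref,
                                          alt=alt))
        reports, summary = scan_variant_table(genome, variants,
                                              [ng_profile])
        assert summary["n_gc_to_at"] == 0
        assert summary["editors"]["NG"]["n_targetable"] == 0


class TestInvariants:
    def test_gc_to_at_classes(self):
        assert variant_is_gc_to_at(
            VariantRecord(chrom="c", pos=1, ref="G", alt="A"))
        assert variant_is_gc_to_at(
            VariantRecord(chrom="c", pos=1, ref="C", alt="T"))
        assert not variant_is_gc_to_at(
            VariantRecord(chrom="c", pos=1, ref="A", alt="G"))

    def test_strand_symmetry(self, mdx4cv, ng_profile):
        genome = mdx4cv.genome
        mirrored = genome.reverse_complemented()
        n = genome.contig_length(mdx4cv.chrom)
        v = mdx4cv.variant
        mv = VariantRecord(chrom=mdx4cv.chrom, pos=n - v.pos + 1,
                           ref=reverse_complement(v.ref),
                           alt=reverse_complement(v.alt))
        fwd = find_guides_for_variant(genome, v, ng_profile)
        rev = find_guides_for_variant(mirrored, mv, ng_profile)
        fwd_set = {(d.target_position, d.protospacer, d.pam_observed,
                    tuple(d.bystander_adenines_in_window),
                    tuple(d.window_cytosines)) for d in fwd}
        rev_set = {(d.target_position, d.protospacer, d.pam_observed,
                    tuple(d.bystander_adenines_in_window),
                    tuple(d.window_cytosines)) for d in rev}
        assert fwd_set == rev_set

    def test_pam_repertoire_monotonicity(self, mdx4cv):
        narrow = EditorProfile(name="n", pam_patterns=("NGG",))
        wide = EditorProfile(name="w", pam_patterns=("NGG", "NGN"))
        d_narrow = find_guides_for_variant(mdx4cv.genome, mdx4cv.variant,
                                           narrow)
        d_wide = find_guides_for_variant(mdx4cv.genome, mdx4cv.variant,
                                         wide)
        keys = lambda ds: {(d.strand, d.target_position) for d in ds}
        assert keys(d_narrow) <= keys(d_wide)

    def test_window_widening_monotonicity(self, mdx4cv):
        tight = EditorProfile(name="t", window=(4, 6))
        loose = EditorProfile(name="l", window=(4, 8))
        dt = find_guides_for_variant(mdx4cv.genome, mdx4cv.variant, tight)
        dl = find_guides_for_variant(mdx4cv.genome, mdx4cv.variant, loose)
        assert any(d.in_window for d in dt) <= any(d.in_window for d in dl)
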