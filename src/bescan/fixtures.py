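"""Packaged worked-example loci.

The mdx4cv locus is rebuilt from its published 20-nt protospacer and
3' PAM: the dystrophic mouse carries a CAA->TAA nonsense mutation in
Dmd exon 53 whose mutant adenine reads at protospacer position 4 on
the noncoding strand, with a TGT PAM (an NG-repertoire site).

The dysferlin-like locus is a synthetic stand-in (not the real DYSF
sequence) built to share the feature that matters for bystander
analysis: a target adenine at position 6 with bystander adenines at
positions 8 and 11.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .amplicon_quant import AmpliconSpec
from .design_scan import EditorProfile, get_profile
from .seqcore import CdsModel, GenomeIndex, VariantRecord, reverse_complement

#: Published guide targeting the mdx4cv mutation (noncoding strand),
#: with its 3'-adjacent PAM.
MDX4CV_PROTOSPACER = "GTTATCTCCTGTTCTGCAGC"
MDX4CV_PAM = "TGT"
#: The mutant adenine sits at protospacer position 4.
MDX4CV_TARGET_POSITION = 4

#: Synthetic dysferlin-like protospacer: adenines at 6 (target), 8, 11.
DYSF_LIKE_PROTOSPACER = "CTGGCACAGCACTTGCGGCT"
DYSF_LIKE_PAM = "TGA"
DYSF_LIKE_TARGET_POSITION = 6


@dataclass
class LocusFixture:
    genome: GenomeIndex
    variant: VariantRecord
    cds: CdsModel
    chrom: str
    protospacer: str
    target_position: int


def _random_flank(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def build_mdx4cv_fixture(seed: int = 0, flank: int = 40,
                         chrom: str = "chrTest") -> LocusFixture:
    """Reference contig around the mdx4cv stop-codon mutation.

    The coding strand is the + strand of the contig; the protospacer
    lies on the - (noncoding) strand.  The contig carries the healthy
    reference allele (CAA codon); the pathogenic variant is C->T at
    the codon's first base, which reads as the target adenine on the
    noncoding strand.
    """
    rng = np.random.default_rng(seed)
    # Coding-strand fragment: revcomp(protospacer + PAM); the mutant T
    # sits at fragment position 20 (codon TAA at 20-22).
    mutant_fragment = reverse_complement(MDX4CV_PROTOSPACER + MDX4CV_PAM)
    idx = len(MDX4CV_PAM) + (len(MDX4CV_PROTOSPACER)
                             - MDX4CV_TARGET_POSITION)  # 0-based: 19
    assert mutant_fragment[idx] == "T"
    ref_fragment = mutant_fragment[:idx] + "C" + mutant_fragment[idx + 1:]
    left = _random_flank(rng, flank)
    right = _random_flank(rng, flank)
    contig = left + ref_fragment + right
    pos = flank + idx + 1
    genome = GenomeIndex({chrom: contig})
    variant = VariantRecord(chrom=chrom, pos=pos, ref="C", alt="T",
                            significance="pathogenic", gene="Dmd")
    cds = CdsModel(strand="+", frame_anchor=pos)
    return LocusFixture(
        genome=genome, variant=variant, cds=cds, chrom=chrom,
        protospacer=MDX4CV_PROTOSPACER,
        target_position=MDX4CV_TARGET_POSITION,
    )


def build_amplicon_spec(protospacer: str, pam: str, target_position: int,
                        editor: EditorProfile | None = None,
                        strand: str = "-", flank: int = 100,
                        seed: int = 7) -> AmpliconSpec:
    """An amplicon embedding *protospacer* + *pam* with random flanks.

    With strand '-', the amplicon + strand is the coding strand and the
    protospacer reads on the - strand (the mdx4cv layout).
    """
    editor = editor or get_profile("NG")
    rng = np.random.default_rng(seed)
    site = protospacer + pam
    if strand == "-":
        insert = reverse_complement(site)
        reference = (_random_flank(rng, flank) + insert
                     + _random_flank(rng, flank))
        # protospacer position 1 = rightmost footprint base on + axis
        protospacer_start = flank + len(pam) + len(protospacer)
    else:
        reference = (_random_flank(rng, flank) + site
                     + _random_flank(rng, flank))
        protospacer_start = flank + 1
    return AmpliconSpec(reference=reference,
                        protospacer_start=protospacer_start,
                        strand=strand, editor=editor,
                        target_position=target_position)


def mdx4cv_amplicon_spec(flank: int = 100, seed: int = 7) -> AmpliconSpec:
    """Amplicon around the (mutant) mdx4cv locus for quantification."""
    return build_amplicon_spec(MDX4CV_PROTOSPACER, MDX4CV_PAM,
                               MDX4CV_TARGET_POSITION, strand="-",
                               flank=flank, seed=seed)


def dysf_like_amplicon_spec(flank: int = 100, seed: int = 11) -> AmpliconSpec:
    return build_amplicon_spec(DYSF_LIKE_PROTOSPACER, DYSF_LIKE_PAM,
                               DYSF_LIKE_TARGET_POSITION, strand="+",
                               flank=flank, seed=seed)
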