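"""Strand-aware ABE guide design and batch targetability scanning.

An adenine base editor (ABE) converts A:T to G:C within a protospacer
"editing window" (positions 4-8 by default, numbered 1-based from the
PAM-distal 5' end so the PAM-adjacent base of a 20-mer is position 20).
A disease allele is correctable when it reads as an adenine on one
strand, a repertoire PAM lies immediately 3' of a protospacer placement
containing it, and the adenine falls inside the window.

Guides are enumerated on the *mutant* sequence (the alt allele
substituted into the reference context): the editor acts on patient
DNA.  The unsubstituted reference genome is only consulted to decide
whether an edit restores the reference allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import ContractError, CoordinateError, ReferenceMismatchError
from .seqcore import (
    CdsModel,
    GenomeIndex,
    VariantRecord,
    iupac_match,
    reverse_complement,
)


@dataclass(frozen=True)
class EditorProfile:
    """A base editor's PAM repertoire, editing window and edited base.

    ``window`` is the efficient-editing span; ``reporting_window`` is a
    wider span over which out-of-window bystanders are still listed
    (flagged, not counted as in-window).
    """

    name: str
    pam_patterns: tuple[str, ...] = ("NGN",)
    protospacer_length: int = 20
    window: tuple[int, int] = (4, 8)
    reporting_window: tuple[int, int] = (1, 12)
    edited_base: str = "A"
    cytosine_offtarget_tracked: bool = True
    preferred_pam: Optional[str] = None  # annotation only (e.g. NGA subtype)

    def __post_init__(self):
        lo, hi = self.window
        if not (1 <= lo <= hi <= self.protospacer_length):
            raise ContractError(f"invalid window {self.window}")
        rlo, rhi = self.reporting_window
        if not (rlo <= lo and rhi >= hi):
            raise ContractError("reporting_window must contain window")
        if not self.pam_patterns:
            raise ContractError("pam_patterns must be non-empty")


#: Built-in profiles.  The NGA-preferring editor recognises the full NG
#: repertoire; its NGA preference is carried as an annotation on designs
#: whose observed PAM matches NGA.
BUILTIN_PROFILES = {
    "NGG": EditorProfile(name="NGG", pam_patterns=("NGG",)),
    "NG": EditorProfile(name="NG", pam_patterns=("NGN",)),
    "NGA": EditorProfile(name="NGA", pam_patterns=("NGN",),
                         preferred_pam="NGA"),
}


def get_profile(name: str, **overrides) -> EditorProfile:
    if name not in BUILTIN_PROFILES:
        raise ContractError(
            f"unknown editor profile {name!r}; built-ins: "
            f"{sorted(BUILTIN_PROFILES)}"
        )
    prof = BUILTIN_PROFILES[name]
    return replace(prof, **overrides) if overrides else prof


@dataclass
class GuideDesign:
    """One protospacer placement covering the disease adenine."""

    protospacer: str
    strand: str  # +/- relative to the input reference contig
    chrom: str
    genomic_start: int  # 1-based coordinate of the protospacer 5' base
    pam_observed: str
    pam_pattern_matched: str
    target_position: int  # 1-based, PAM-distal end = position 1
    in_window: bool = False
    pam_preferred: bool = False
    bystander_adenines_in_window: list[int] = field(default_factory=list)
    bystander_adenines_reported: list[int] = field(default_factory=list)
    window_cytosines: list[int] = field(default_factory=list)

    def genomic_position(self, protospacer_position: int) -> int:
        """Genomic (forward-axis) coordinate of a protospacer position."""
        if self.strand == "+":
            return self.genomic_start + protospacer_position - 1
        return self.genomic_start - (protospacer_position - 1)


@dataclass
class TargetabilityReport:
    variant: VariantRecord
    is_gc_to_at: bool
    designs: list[GuideDesign]
    targetable_by: dict[str, bool]
    best_design: Optional[GuideDesign] = None


def variant_is_gc_to_at(variant: VariantRecord) -> bool:
    """True for the ABE-correctable transition classes: G->A on the
    reported strand (disease allele reads A on +) or C->T (reads A on -)."""
    return (variant.ref, variant.alt) in (("G", "A"), ("C", "T"))


def inventory_bystanders(design: GuideDesign,
                         editor: EditorProfile) -> GuideDesign:
    """Populate the bystander fields of a design in place.

    Bystanders are adenines other than the target within the editing
    window (counted) or the reporting window (listed); window cytosines
    are tracked when the profile quantifies ABE cytosine off-target
    (C-to-T) activity.
    """
    lo, hi = editor.window
    rlo, rhi = editor.reporting_window
    proto = design.protospacer
    t = design.target_position
    design.bystander_adenines_in_window = [
        p for p in range(lo, hi + 1)
        if p != t and proto[p - 1] == "A"
    ]
    design.bystander_adenines_reported = [
        p for p in range(rlo, rhi + 1)
        if p != t and proto[p - 1] == "A"
    ]
    design.window_cytosines = (
        [p for p in range(lo, hi + 1) if proto[p - 1] == "C"]
        if editor.cytosine_offtarget_tracked else []
    )
    return design


def _check_reference(genome: GenomeIndex, variant: VariantRecord) -> None:
    found = genome.fetch(variant.chrom, variant.pos, variant.pos)
    if found != variant.ref:
        raise ReferenceMismatchError(variant.chrom, variant.pos,
                                     variant.ref, found)


def find_guides_for_variant(genome: GenomeIndex, variant: VariantRecord,
                            editor: EditorProfile) -> list[GuideDesign]:
    """Enumerate every protospacer placement whose footprint covers the
    disease adenine and that carries a 3'-adjacent repertoire PAM.

    The disease allele must read A on the scanned strand: alt=A scans
    the + strand, alt=T scans the - strand, anything else yields no
    designs.  Placements are evaluated on the mutant sequence.
    """
    _check_reference(genome, variant)
    strands = []
    if variant.alt == "A":
        strands.append("+")
    elif variant.alt == "T":
        strands.append("-")
    if not strands:
        return []

    L = editor.protospacer_length
    contig = genome[variant.chrom]
    n = len(contig)
    pos = variant.pos
    # Mutant contig: alt substituted at the variant position.
    mutant = contig[:pos - 1] + variant.alt + contig[pos:]

    designs: list[GuideDesign] = []
    for strand in strands:
        for p in range(1, L + 1):
            if strand == "+":
                s = pos - (p - 1)  # protospacer 5' coordinate
                if s < 1 or s + L - 1 > n:
                    continue
                proto = mutant[s - 1:s - 1 + L]
                flank_start = s + L  # PAM starts here (1-based)
                five_prime = s
            else:
                e = pos + (p - 1)  # protospacer 5' coordinate on -
                if e > n or e - L + 1 < 1:
                    continue
                proto = reverse_complement(mutant[e - L:e])
                five_prime = e
            if proto[p - 1] != "A":
                continue  # defensive; alt substitution guarantees A
            for pattern in editor.pam_patterns:
                k = len(pattern)
                if strand == "+":
                    if flank_start + k - 1 > n:
                        continue
                    pam = mutant[flank_start - 1:flank_start - 1 + k]
                else:
                    pam_hi = e - L  # PAM occupies [e-L-k+1, e-L] on +
                    if pam_hi - k + 1 < 1:
                        continue
                    pam = reverse_complement(mutant[pam_hi - k:pam_hi])
                if not iupac_match(pattern, pam):
                    continue
                lo, hi = editor.window
                d = GuideDesign(
                    protospacer=proto, strand=strand, chrom=variant.chrom,
                    genomic_start=five_prime, pam_observed=pam,
                    pam_pattern_matched=pattern, target_position=p,
                    in_window=lo <= p <= hi,
                    pam_preferred=bool(
                        editor.preferred_pam
                        and len(editor.preferred_pam) == len(pam)
                        and iupac_match(editor.preferred_pam, pam)
                    ),
                )
                inventory_bystanders(d, editor)
                designs.append(d)
                break  # one design per placement; first matching pattern
    return designs


CONSEQUENCE_LABELS = (
    "restores_reference", "synonymous", "missense",
    "creates_stop", "removes_stop", "not_coding",
)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]


def _translate_codon(codon: str) -> str:
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return str(Seq(codon).translate())


def _codon_at(seq: str, g: int, cds: CdsModel) -> Optional[tuple[int, str, int]]:
    """Return (codon_start, codon, offset_within_codon) for genomic
    position g, reading frame from cds; None when outside the contig."""
    if cds.strand == "+":
        off = (g - cds.frame_anchor) % 3
        start = g - off
        if start < 1 or start + 2 > len(seq):
            return None
        return start, seq[start - 1:start + 2], off
    off = (cds.frame_anchor - g) % 3
    first = g + off  # codon first base (highest coordinate on -)
    if first > len(seq) or first - 2 < 1:
        return None
    return first, reverse_complement(seq[first - 3:first]), off


def classify_consequence(genome: GenomeIndex, design: GuideDesign,
                         variant: VariantRecord,
                         cds: CdsModel) -> dict[int, str]:
    """Label the codon-level consequence of each edited position.

    Returns a map from protospacer position to a label in
    :data:`CONSEQUENCE_LABELS`.  The target adenine and every reported
    bystander adenine are modelled as A->G on the protospacer strand;
    window cytosines as C->T.  Each position is evaluated as if edited
    alone on the mutant sequence.
    """
    contig = genome[variant.chrom]
    mutant = (contig[:variant.pos - 1] + variant.alt + contig[variant.pos:])

    positions = {design.target_position: ("A", "G")}
    for p in design.bystander_adenines_reported:
        positions[p] = ("A", "G")
    for p in design.window_cytosines:
        positions[p] = ("C", "T")

    out: dict[int, str] = {}
    for p, (frm, to) in positions.items():
        g = design.genomic_position(p)
        if design.strand == "+":
            new_plus = to
        else:
            new_plus = reverse_complement(to)
        if cds.region and not (cds.region[0] <= g <= cds.region[1]):
            out[p] = "not_coding"
            continue
        edited = mutant[:g - 1] + new_plus + mutant[g:]
        if edited[g - 1] == contig[g - 1]:
            out[p] = "restores_reference"
            continue
        loc = _codon_at(mutant, g, cds)
        if loc is None:
            out[p] = "not_coding"
            continue
        loc2 = _codon_at(edited, g, cds)
        aa_old = _translate_codon(loc[1])
        aa_new = _translate_codon(loc2[1])
        if aa_new == aa_old:
            out[p] = "synonymous"
        elif aa_new == "*":
            out[p] = "creates_stop"
        elif aa_old == "*":
            out[p] = "removes_stop"
        else:
            out[p] = "missense"
    return out


def _best_design(designs: list[GuideDesign],
                 editor: EditorProfile) -> Optional[GuideDesign]:
    """Pick the preferred in-window design: fewest in-window bystanders,
    then target position closest to the window centre (ties resolved
    toward the window's low end), then + strand first."""
    in_window = [d for d in designs if d.in_window]
    if not in_window:
        return None
    lo, hi = editor.window
    centre = (lo + hi) / 2

    def key(d: GuideDesign):
        return (len(d.bystander_adenines_in_window),
                abs(d.target_position - centre),
                d.target_position,
                0 if d.strand == "+" else 1)

    return min(in_window, key=key)


def scan_variant_table(genome: GenomeIndex, variants: list[VariantRecord],
                       editors: list[EditorProfile]
                       ) -> tuple[list[TargetabilityReport], dict]:
    """One report per variant plus a per-editor summary.

    The summary records, for every editor, the count and fraction of
    G:C->A:T transitions and of targetable variants (an in-window
    design exists), together with the window and PAM repertoire used so
    the counting criteria are explicit.
    """
    reports: list[TargetabilityReport] = []
    for variant in variants:
        designs_by_editor: dict[str, list[GuideDesign]] = {}
        for editor in editors:
            try:
                designs_by_editor[editor.name] = find_guides_for_variant(
                    genome, variant, editor)
            except ReferenceMismatchError as exc:
                raise ReferenceMismatchError(
                    variant.chrom, variant.pos, variant.ref,
                    genome.fetch(variant.chrom, variant.pos, variant.pos),
                ) from exc
        all_designs = [d for ds in designs_by_editor.values() for d in ds]
        targetable_by = {
            name: any(d.in_window for d in ds)
            for name, ds in designs_by_editor.items()
        }
        primary = editors[0] if editors else None
        reports.append(TargetabilityReport(
            variant=variant,
            is_gc_to_at=variant_is_gc_to_at(variant),
            designs=all_designs,
            targetable_by=targetable_by,
            best_design=(_best_design(all_designs, primary)
                         if primary else None),
        ))

    n = len(variants)
    n_gc_at = sum(r.is_gc_to_at for r in reports)
    summary: dict = {
        "n_variants": n,
        "n_gc_to_at": n_gc_at,
        "frac_gc_to_at": (n_gc_at / n) if n else None,
        "empty_input": n == 0,
        "editors": {},
    }
    for editor in editors:
        n_t = sum(r.targetable_by.get(editor.name, False) for r in reports)
        summary["editors"][editor.name] = {
            "n_targetable": n_t,
            "frac_targetable": (n_t / n) if n else None,
            "window": list(editor.window),
            "pam_patterns": list(editor.pam_patterns),
            "protospacer_length": editor.protospacer_length,
        }
    return reports, summary
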