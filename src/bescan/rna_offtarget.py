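"""Transcriptome-wide A-to-I off-target variant filtering.

Downstream of RNA-seq variant calling (consumed as a finished VCF with
FS/QD/DP annotations and per-sample AD), the procedure is:

1. confidence filtering: drop strand-biased calls (FS > 30.0), poorly
   supported calls (QD < 2.0, DP < 30) and SNV clusters (>= 5 SNVs in
   any 35-base window) — comparisons strict, so boundary values are
   kept;
2. control subtraction: drop any call whose (chrom, pos, ref, alt) also
   appears among the control sample's confident calls;
3. A-to-I classification: A->G calls plus T->C calls (the same edit
   read from the opposite cDNA strand);
4. per-site editing rate = alt reads / DP, and cross-replicate sharing.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import FormatError
from .seqcore import CANONICAL_CHROMS, normalize_chrom

log = logging.getLogger(__name__)

FS_MAX = 30.0
QD_MIN = 2.0
DP_MIN = 30
CLUSTER_N = 5
CLUSTER_WINDOW = 35

REMOVAL_RULES = ("strand_bias", "low_qd", "low_depth", "cluster",
                 "missing_annotation")


@dataclass(frozen=True)
class RnaVariantRecord:
    """One called RNA SNV with the annotations the filter stack consumes.

    ``depth`` is the caller's DP; it is used as the editing-rate
    denominator and is not assumed to equal the sum of allele depths.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    fisher_strand: Optional[float]
    qual_by_depth: Optional[float]
    depth: Optional[int]
    allele_depths: tuple[Optional[int], Optional[int]] = (None, None)
    sample_id: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_a_to_i(self) -> bool:
        return (self.ref, self.alt) in (("A", "G"), ("T", "C"))


@dataclass
class EditingEvent:
    chrom: str
    pos: int
    ref: str
    alt: str
    a_to_i: bool
    editing_rate: Optional[float]
    sample_id: str = ""
    samples_observed: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def read_rna_vcf(path, sample_id: str = "",
                 canonical_only: bool = True,
                 species: str = "mouse") -> list[RnaVariantRecord]:
    """Read SNVs from a VCF carrying INFO FS/QD/DP and FORMAT AD."""
    from cyvcf2 import VCF

    canonical = CANONICAL_CHROMS[species]
    records: list[RnaVariantRecord] = []
    vcf = VCF(str(path))
    sid = sample_id or (vcf.samples[0] if vcf.samples else "")
    for v in vcf:
        if canonical_only and normalize_chrom(v.CHROM) not in canonical:
            continue
        if len(v.REF) != 1:
            continue
        ad = None
        try:
            fmt = v.format("AD")
            if fmt is not None:
                ad = [int(x) for x in fmt[0]]
        except KeyError:
            ad = None
        dp = v.INFO.get("DP")
        for i, alt in enumerate(v.ALT):
            if len(alt) != 1 or alt not in "ACGT" or v.REF not in "ACGT":
                continue
            allele_depths = (None, None)
            if ad is not None and len(ad) > i + 1:
                allele_depths = (ad[0], ad[i + 1])
            records.append(RnaVariantRecord(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                fisher_strand=v.INFO.get("FS"),
                qual_by_depth=v.INFO.get("QD"),
                depth=int(dp) if dp is not None else None,
                allele_depths=allele_depths,
                sample_id=sid,
            ))
    return records


def _cluster_members(records: list[RnaVariantRecord],
                     cluster_n: int, cluster_window: int) -> set[int]:
    """Indices of records belonging to any same-chromosome window of
    *cluster_window* bases (inclusive span) holding >= *cluster_n* SNVs.

    Distinct alleles at one position count once toward cluster size:
    clustering is a positional artefact signature.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for idx, r in enumerate(records):
        by_chrom[r.chrom].append((r.pos, idx))
    flagged: set[int] = set()
    for chrom, items in by_chrom.items():
        items.sort()
        positions = sorted({p for p, _ in items})
        bad_positions: set[int] = set()
        j = 0
        for i in range(len(positions)):
            if j < i:
                j = i
            while (j + 1 < len(positions)
                   and positions[j + 1] - positions[i] <= cluster_window - 1):
                j += 1
            if j - i + 1 >= cluster_n:
                bad_positions.update(positions[i:j + 1])
        for p, idx in items:
            if p in bad_positions:
                flagged.add(idx)
    return flagged


def confidence_filter(records: Iterable[RnaVariantRecord],
                      fs_max: float = FS_MAX,
                      qd_min: float = QD_MIN,
                      dp_min: int = DP_MIN,
                      cluster_n: int = CLUSTER_N,
                      cluster_window: int = CLUSTER_WINDOW,
                      permissive: bool = False
                      ) -> tuple[list[RnaVariantRecord], dict[str, int]]:
    """Apply the confidence filters; return kept records and per-rule
    removal counts.

    All threshold comparisons are strict (FS > fs_max, QD < qd_min,
    DP < dp_min removed), so records exactly at a threshold are kept.
    Every member of any violating cluster window is removed.  Each
    removed record is attributed to exactly one rule (annotation,
    strand bias, QD, DP, then cluster), so kept + removals == input.
    """
    records = list(records)
    removal = {rule: 0 for rule in REMOVAL_RULES}
    cluster_idx = _cluster_members(records, cluster_n, cluster_window)
    kept: list[RnaVariantRecord] = []
    for idx, r in enumerate(records):
        if (r.fisher_strand is None or r.qual_by_depth is None
                or r.depth is None):
            if not permissive:
                raise FormatError(
                    f"missing FS/QD/DP annotation at "
                    f"{r.chrom}:{r.pos} {r.ref}>{r.alt}"
                )
            removal["missing_annotation"] += 1
        elif r.fisher_strand > fs_max:
            removal["strand_bias"] += 1
        elif r.qual_by_depth < qd_min:
            removal["low_qd"] += 1
        elif r.depth < dp_min:
            removal["low_depth"] += 1
        elif idx in cluster_idx:
            removal["cluster"] += 1
        else:
            kept.append(r)
    assert len(kept) + sum(removal.values()) == len(records)
    return kept, removal


def subtract_control(treated: Iterable[RnaVariantRecord],
                     control: Iterable[RnaVariantRecord]
                     ) -> list[RnaVariantRecord]:
    """Remove treated records whose full (chrom, pos, ref, alt) key
    appears among the control's confident calls."""
    control_keys = {r.key for r in control}
    return [r for r in treated if r.key not in control_keys]


def apply_blacklist(records: Iterable[RnaVariantRecord],
                    blacklist: Iterable[tuple[str, int, str, str]]
                    ) -> list[RnaVariantRecord]:
    """Optional known-SNP masking (emulates upstream dbSNP handling)."""
    keys = set(blacklist)
    return [r for r in records if r.key not in keys]


def editing_rate(record: RnaVariantRecord) -> Optional[float]:
    """Alt reads divided by DP; None (flagged undefined) at zero depth."""
    alt_reads = record.allele_depths[1]
    if not record.depth or alt_reads is None:
        return None
    return alt_reads / record.depth


def classify_a_to_i(records: Iterable[RnaVariantRecord]
                    ) -> list[EditingEvent]:
    """Wrap records as events with the A-to-I flag set.

    A-to-I comprises A->G calls on the positive strand and T->C calls
    sourced from the negative strand (cDNA sequencing reads either
    strand of the same edit).  Non-A-to-I records are retained with the
    flag false; the A-to-I subset is the headline count.
    """
    return [EditingEvent(
        chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt,
        a_to_i=r.is_a_to_i, editing_rate=editing_rate(r),
        sample_id=r.sample_id, samples_observed={r.sample_id},
    ) for r in records]


def shared_events(event_lists: dict[str, list[EditingEvent]]
                  ) -> tuple[dict[tuple, set[str]], dict[int, int]]:
    """Cross-replicate sharing of events keyed on (chrom,pos,ref,alt).

    Returns the site -> sample-set membership table and a histogram of
    how many sites are observed in exactly k samples.  Duplicate sites
    within one sample are deduplicated with a warning.
    """
    membership: dict[tuple, set[str]] = defaultdict(set)
    for sample, events in event_lists.items():
        seen = set()
        dup = 0
        for e in events:
            if e.key in seen:
                dup += 1
                continue
            seen.add(e.key)
            membership[e.key].add(sample)
        if dup:
            log.warning("sample %s: %d duplicate sites deduplicated",
                        sample, dup)
    histogram = dict(sorted(Counter(
        len(samples) for samples in membership.values()).items()))
    return dict(membership), histogram


def shared_by_all(event_lists: dict[str, list[EditingEvent]]) -> set[tuple]:
    membership, _ = shared_events(event_lists)
    n = len(event_lists)
    return {k for k, samples in membership.items() if len(samples) == n}


def run_pipeline(treated: dict[str, list[RnaVariantRecord]],
                 control: list[RnaVariantRecord],
                 blacklist: Optional[Iterable[tuple]] = None,
                 **filter_kwargs) -> dict:
    """Full procedure over one control and >= 1 treated samples.

    Returns a report with, per sample: kept records, removal counts,
    events (all confident non-control variants) and the A-to-I subset;
    plus cross-sample sharing counts for both definitions.
    """
    control_kept, control_removed = confidence_filter(control,
                                                      **filter_kwargs)
    per_sample: dict[str, dict] = {}
    events_all: dict[str, list[EditingEvent]] = {}
    events_atoi: dict[str, list[EditingEvent]] = {}
    for sample, records in treated.items():
        kept, removed = confidence_filter(records, **filter_kwargs)
        kept = subtract_control(kept, control_kept)
        if blacklist:
            kept = apply_blacklist(kept, blacklist)
        events = classify_a_to_i(kept)
        events_all[sample] = events
        events_atoi[sample] = [e for e in events if e.a_to_i]
        per_sample[sample] = {
            "kept": kept,
            "removal_counts": removed,
            "n_events": len(events),
            "n_a_to_i": len(events_atoi[sample]),
        }
    report = {
        "per_sample": per_sample,
        "control_removal_counts": control_removed,
        "n_control_confident": len(control_kept),
    }
    if len(treated) >= 2:
        report["shared_by_all"] = shared_by_all(events_all)
        report["shared_by_all_a_to_i"] = shared_by_all(events_atoi)
        _, report["sharing_histogram"] = shared_events(events_all)
    return report
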