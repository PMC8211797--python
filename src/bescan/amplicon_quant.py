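"""Per-position editing quantification from amplicon reads or traces.

Quantifies the programmed ABE edit (A->G on the protospacer strand) and
the ABE cytosine off-target edit (C->T) at every protospacer position,
from either deep-sequencing FASTQ reads or Sanger-trace per-position
peak-intensity tables, together with allele-class summaries.

ABE products are substitutions, so reads are placed against the
amplicon gaplessly; reads with no acceptable gapless placement (which
would imply an indel) are excluded from substitution tallies but
counted, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .design_scan import EditorProfile
from .errors import ContractError, FormatError
from .seqcore import reverse_complement

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class AmpliconSpec:
    """An amplicon with the protospacer placed inside it.

    ``protospacer_start`` is the 1-based amplicon coordinate of
    protospacer position 1 (the PAM-distal 5' end on the protospacer
    strand); for a '-' strand protospacer that is the rightmost base of
    the footprint.
    """

    reference: str
    protospacer_start: int
    strand: str  # protospacer strand relative to the amplicon
    editor: EditorProfile
    target_position: int

    def __post_init__(self):
        ref = self.reference.upper()
        if not ref or any(b not in "ACGT" for b in ref):
            raise ContractError("amplicon reference must be ACGT only")
        object.__setattr__(self, "reference", ref)
        if self.strand not in ("+", "-"):
            raise ContractError("strand must be + or -")
        lo, hi = self.footprint
        if lo < 1 or hi > len(ref):
            raise ContractError("protospacer footprint outside amplicon")
        L = self.editor.protospacer_length
        if not (1 <= self.target_position <= L):
            raise ContractError("target_position outside protospacer")
        if self.protospacer[self.target_position - 1] != "A":
            raise ContractError(
                "amplicon reference does not read A at the target "
                "position on the protospacer strand"
            )

    @property
    def footprint(self) -> tuple[int, int]:
        """Inclusive 1-based amplicon interval covered by the protospacer."""
        L = self.editor.protospacer_length
        if self.strand == "+":
            return (self.protospacer_start, self.protospacer_start + L - 1)
        return (self.protospacer_start - L + 1, self.protospacer_start)

    @property
    def protospacer(self) -> str:
        lo, hi = self.footprint
        seg = self.reference[lo - 1:hi]
        return seg if self.strand == "+" else reverse_complement(seg)

    def amplicon_index(self, p: int) -> int:
        """0-based amplicon index of protospacer position p."""
        if self.strand == "+":
            return self.protospacer_start - 1 + (p - 1)
        return self.protospacer_start - 1 - (p - 1)

    def reverse_complemented(self) -> "AmpliconSpec":
        n = len(self.reference)
        return AmpliconSpec(
            reference=reverse_complement(self.reference),
            protospacer_start=n - self.protospacer_start + 1,
            strand="-" if self.strand == "+" else "+",
            editor=self.editor,
            target_position=self.target_position,
        )


@dataclass
class SiteEditingTable:
    """Per-protospacer-position base tallies and edit frequencies."""

    per_position: pd.DataFrame  # position, ref_base, depth, A,C,G,T, edit_freq
    reads_total: int = 0
    reads_used: int = 0
    reads_discarded_indel: int = 0
    reads_discarded_quality: int = 0

    def __post_init__(self):
        df = self.per_position
        sums = df[["A", "C", "G", "T"]].sum(axis=1)
        if not (sums == df["depth"]).all():
            raise ContractError("base counts do not sum to depth")
        used = self.reads_used + self.reads_discarded_indel \
            + self.reads_discarded_quality
        if used != self.reads_total:
            raise ContractError("read accounting does not balance")

    def frequency(self, position: int) -> float:
        row = self.per_position.set_index("position").loc[position]
        return float(row["edit_freq"])


@dataclass
class AlleleSummary:
    """Read counts per protospacer-footprint allele and per allele class.

    Classes partition ``reads_used``: unedited, precise (target edit
    only), bystander_containing (any non-target A->G), cytosine_edit_
    containing (window-cytosine C->T without adenine bystanders), other
    (unexpected substitutions, e.g. sequencing error).
    """

    alleles: dict[str, int] = field(default_factory=dict)
    classes: dict[str, int] = field(default_factory=dict)

    def check_partition(self, reads_used: int) -> None:
        if sum(self.classes.values()) != reads_used:
            raise ContractError("allele classes do not partition reads_used")


_CLASS_NAMES = ("unedited", "precise", "bystander_containing",
                "cytosine_edit_containing", "other")


def _classify_allele(allele: str, proto: str, target: int) -> str:
    has_target = False
    has_bystander = False
    has_cytosine = False
    has_other = False
    for i, (obs, ref) in enumerate(zip(allele, proto), start=1):
        if obs == ref:
            continue
        if ref == "A" and obs == "G":
            if i == target:
                has_target = True
            else:
                has_bystander = True
        elif ref == "C" and obs == "T":
            has_cytosine = True
        else:
            has_other = True
    if has_other:
        return "other"
    if has_bystander:
        return "bystander_containing"
    if has_cytosine:
        return "cytosine_edit_containing"
    if has_target:
        return "precise"
    return "unedited"


def _empty_position_frame(spec: AmpliconSpec) -> pd.DataFrame:
    proto = spec.protospacer
    return pd.DataFrame({
        "position": np.arange(1, len(proto) + 1),
        "ref_base": list(proto),
        "depth": 0,
        "A": 0, "C": 0, "G": 0, "T": 0,
        "edit_freq": np.nan,
    })


def _finalize_table(counts: np.ndarray, spec: AmpliconSpec,
                    reads_total: int, reads_used: int,
                    indel: int, quality: int) -> SiteEditingTable:
    proto = spec.protospacer
    df = _empty_position_frame(spec)
    for b, j in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        df[b] = counts[:, j]
    df["depth"] = counts.sum(axis=1)
    freqs = []
    for i, ref in enumerate(proto):
        depth = df.at[i, "depth"]
        if depth == 0:
            freqs.append(np.nan)
        elif ref == "A":
            freqs.append(df.at[i, "G"] / depth)
        elif ref == "C":
            freqs.append(df.at[i, "T"] / depth)
        else:
            freqs.append(np.nan)
    df["edit_freq"] = freqs
    return SiteEditingTable(
        per_position=df, reads_total=reads_total, reads_used=reads_used,
        reads_discarded_indel=indel, reads_discarded_quality=quality,
    )


def _iter_reads(reads) -> Iterable[tuple[str, str]]:
    """Yield (sequence, phred_string) from a FASTQ path or an iterable
    of SeqRecords / (seq, qual) pairs."""
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        from Bio import SeqIO
        for rec in SeqIO.parse(str(reads), "fastq"):
            qual = "".join(chr(q + 33)
                           for q in rec.letter_annotations["phred_quality"])
            yield str(rec.seq).upper(), qual
        return
    for item in reads:
        if isinstance(item, tuple):
            yield item[0].upper(), item[1]
        else:  # SeqRecord
            qual = "".join(chr(q + 33)
                           for q in item.letter_annotations["phred_quality"])
            yield str(item.seq).upper(), qual


def _place_read(seq: str, amp: str, amp_codes: np.ndarray,
                min_overlap: int, max_mismatch_frac: float
                ) -> Optional[int]:
    """Best gapless offset of *seq* in *amp* (full containment), or None
    when no placement satisfies the overlap/mismatch ceiling (an indel
    or an unrelated read)."""
    r = len(seq)
    if r > len(amp) or r < min_overlap:
        return None
    ceiling = int(math.floor(max_mismatch_frac * r))
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if r == len(amp):  # only one containment offset exists
        mm = int((amp_codes != codes).sum())
        return 0 if mm <= ceiling else None
    # Anchor: exact match of a flank k-mer places most error-free reads.
    k = min(16, r)
    candidates = []
    o = amp.find(seq[:k])
    if o >= 0 and o + r <= len(amp):
        candidates.append(o)
    o = amp.find(seq[-k:])
    if o >= 0:
        o2 = o - (r - k)
        if 0 <= o2 and o2 + r <= len(amp) and o2 not in candidates:
            candidates.append(o2)
    best, best_mm = None, ceiling + 1
    for o in candidates:
        mm = int((amp_codes[o:o + r] != codes).sum())
        if mm < best_mm:
            best, best_mm = o, mm
    if best is not None and best_mm == 0:
        return best
    # Fallback: exhaustive gapless placement.
    windows = np.lib.stride_tricks.sliding_window_view(amp_codes, r)
    mms = (windows != codes).sum(axis=1)
    o = int(mms.argmin())
    if int(mms[o]) < best_mm:
        best, best_mm = o, int(mms[o])
    return best if best_mm <= ceiling else None


def quantify_reads(reads, spec: AmpliconSpec,
                   min_mean_quality: float = 20.0,
                   min_overlap: int = 50,
                   max_mismatch_frac: float = 0.2,
                   base_quality_mask: int = 10
                   ) -> tuple[SiteEditingTable, AlleleSummary]:
    """Tally per-position substitutions over the protospacer footprint.

    Each read is placed against the amplicon by its best gapless offset
    (exact flank-anchor first, minimal-Hamming fallback).  Reads failing
    the mean-quality filter or without an acceptable placement are
    discarded and counted.  Bases below *base_quality_mask* are masked
    (excluded from depth).  Frequencies use post-masking depth as the
    denominator.
    """
    amp = spec.reference
    amp_codes = np.frombuffer(amp.encode("ascii"), dtype=np.uint8)
    L = spec.editor.protospacer_length
    proto = spec.protospacer
    amp_idx = [spec.amplicon_index(p) for p in range(1, L + 1)]
    flip = spec.strand == "-"

    counts = np.zeros((L, 4), dtype=np.int64)
    alleles: dict[str, int] = {}
    classes = {name: 0 for name in _CLASS_NAMES}
    total = n_indel = n_quality = 0

    # Placement pass; reads sharing (offset, length) are tallied in one
    # vectorised batch afterwards.
    groups: dict[tuple[int, int], list[tuple[str, str]]] = {}
    for seq, qual in _iter_reads(reads):
        total += 1
        q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
        if q.size and q.mean() - 33 < min_mean_quality:
            n_quality += 1
            continue
        offset = _place_read(seq, amp, amp_codes, min_overlap,
                             max_mismatch_frac)
        if offset is None:
            n_indel += 1
            continue
        groups.setdefault((offset, len(seq)), []).append((seq, qual))

    used = sum(len(g) for g in groups.values())
    comp_lut = np.arange(256, dtype=np.uint8)
    for a, b in (("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")):
        comp_lut[ord(a)] = ord(b)
    base_codes = {b: ord(b) for b in "ACGT"}

    for (offset, rlen), items in groups.items():
        n = len(items)
        seq_mat = np.frombuffer(
            "".join(s for s, _ in items).encode("ascii"),
            dtype=np.uint8).reshape(n, rlen)
        qual_mat = np.frombuffer(
            "".join(q for _, q in items).encode("ascii"),
            dtype=np.uint8).reshape(n, rlen)
        ok = qual_mat >= base_quality_mask + 33
        # per-read allele over the footprint; uncovered or masked
        # positions read as reference
        allele_mat = np.tile(
            np.frombuffer(proto.encode("ascii"), dtype=np.uint8), (n, 1))
        for p in range(1, L + 1):
            g = amp_idx[p - 1]
            c = g - offset
            if not (0 <= c < rlen):
                continue
            col_bases = seq_mat[:, c]
            if flip:
                col_bases = comp_lut[col_bases]
            valid = ok[:, c]
            hist = np.bincount(col_bases[valid], minlength=256)
            for j, b in enumerate("ACGT"):
                counts[p - 1, j] += int(hist[base_codes[b]])
            known = valid & np.isin(col_bases,
                                    list(base_codes.values()))
            allele_mat[known, p - 1] = col_bases[known]
        uniq, inv_counts = np.unique(allele_mat, axis=0,
                                     return_counts=True)
        for row, cnt in zip(uniq, inv_counts):
            a = row.tobytes().decode("ascii")
            alleles[a] = alleles.get(a, 0) + int(cnt)
            classes[_classify_allele(a, proto,
                                     spec.target_position)] += int(cnt)

    table = _finalize_table(counts, spec, total, used, n_indel, n_quality)
    summary = AlleleSummary(alleles=alleles, classes=classes)
    summary.check_partition(used)
    return table, summary


def read_trace_table(path) -> pd.DataFrame:
    """5-column TSV: pos, A, C, G, T peak intensities (header required)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("pos", "A", "C", "G", "T") if c not in df.columns]
    if missing:
        raise FormatError(f"trace table missing columns {missing}")
    return df


def quantify_trace(trace: Union[pd.DataFrame, str],
                   spec: AmpliconSpec) -> SiteEditingTable:
    """Per-position edit frequency from Sanger-trace peak intensities.

    Rows align 1:1 with amplicon positions.  At each protospacer
    position the frequency is the edited-base peak share normalised
    over the two relevant bases only (reference + edited), because
    four-channel trace baselines are instrument-specific.  Positions
    outside the protospacer whose dominant peak disagrees with the
    reference are flagged (alignment sanity check).
    """
    if not isinstance(trace, pd.DataFrame):
        trace = read_trace_table(trace)
    amp = spec.reference
    if len(trace) != len(amp):
        raise FormatError(
            f"trace has {len(trace)} rows but amplicon has {len(amp)} "
            "positions"
        )
    L = spec.editor.protospacer_length
    proto = spec.protospacer
    flip = spec.strand == "-"
    intensities = trace[["A", "C", "G", "T"]].to_numpy(dtype=float)
    chan = {"A": 0, "C": 1, "G": 2, "T": 3}

    footprint = {spec.amplicon_index(p) for p in range(1, L + 1)}
    flagged = []
    bases = "ACGT"
    for i in range(len(amp)):
        if i in footprint:
            continue
        dominant = bases[int(intensities[i].argmax())]
        if dominant != amp[i]:
            flagged.append(i + 1)

    df = _empty_position_frame(spec)
    depth_scale = 1000  # intensities mapped to pseudo-counts per position
    counts = np.zeros((L, 4), dtype=np.int64)
    freqs = []
    for p in range(1, L + 1):
        ref = proto[p - 1]
        edited = {"A": "G", "C": "T"}.get(ref)
        g = spec.amplicon_index(p)
        row = intensities[g]
        if edited is None:
            freqs.append(np.nan)
            counts[p - 1, chan[ref]] = depth_scale
            continue
        ref_amp = _amp_channel(ref, flip)
        ed_amp = _amp_channel(edited, flip)
        ref_i = row[chan[ref_amp]]
        ed_i = row[chan[ed_amp]]
        denom = ref_i + ed_i
        f = float(ed_i / denom) if denom > 0 else np.nan
        freqs.append(f)
        if denom > 0:
            ed_counts = int(round(f * depth_scale))
            counts[p - 1, chan[edited]] = ed_counts
            counts[p - 1, chan[ref]] = depth_scale - ed_counts
    table = _finalize_table(counts, spec, 0, 0, 0, 0)
    table.per_position["edit_freq"] = freqs
    table.per_position.attrs["flagged_positions"] = flagged
    return table


def _amp_channel(base_on_proto_strand: str, flip: bool) -> str:
    return _COMPLEMENT[base_on_proto_strand] if flip else base_on_proto_strand


def summarize_bystanders(table: SiteEditingTable,
                         spec: AmpliconSpec) -> pd.DataFrame:
    """Rows for the target, in-window/reported adenine bystanders and
    window cytosines, with edit frequency and depth per row.

    Positions use the same 1-based protospacer numbering as guide
    design.  Zero-depth rows carry NaN frequency and are flagged.
    """
    proto = spec.protospacer
    lo, hi = spec.editor.window
    rlo, rhi = spec.editor.reporting_window
    t = spec.target_position
    roles: list[tuple[int, str]] = [(t, "target")]
    for p in range(1, len(proto) + 1):
        if p == t:
            continue
        if proto[p - 1] == "A":
            if lo <= p <= hi:
                roles.append((p, "bystander_in_window"))
            elif rlo <= p <= rhi:
                roles.append((p, "bystander_reported"))
        elif proto[p - 1] == "C" and lo <= p <= hi \
                and spec.editor.cytosine_offtarget_tracked:
            roles.append((p, "window_cytosine"))
    pp = table.per_position.set_index("position")
    rows = []
    for p, role in sorted(roles):
        depth = int(pp.at[p, "depth"])
        freq = float(pp.at[p, "edit_freq"]) if depth > 0 else float("nan")
        rows.append({
            "position": p, "role": role, "ref_base": proto[p - 1],
            "depth": depth, "edit_freq": freq,
            "undefined": depth == 0 or math.isnan(freq),
        })
    return pd.DataFrame(rows,
                        columns=["position", "role", "ref_base", "depth",
                                 "edit_freq", "undefined"])
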